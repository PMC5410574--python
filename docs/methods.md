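# Methods

This note documents the models, assumptions, parameter choices and known
limitations of `cdpmarkov`, in the order the pipeline runs.

## Synthetic experiments

The original cat recordings are not publicly deposited, so every analysis
here runs on synthetic experiments whose statistical structure matches
what the method assumes. The generator is first-class, tested code; its
defaults define the study conditions and are not tuned per analysis.

**Waveform templates.** Each shape class is a sum of one dominant positive
Gaussian bump and 1–3 smaller side bumps (amplitudes 0.15–0.45 of the
main, random centers/widths/signs), low-pass filtered at 60 Hz — safely
inside the 70 Hz detection band — cropped to a 100 ms window centered on
the global maximum, edge-tapered, and scaled to a peak of 0.8–1.2 mV.
Templates are redrawn until all pairwise Euclidean distances exceed
1.0 mV (well above 5× the 0.02 mV default noise sd); without this margin
two classes can be statistically indistinguishable after smoothing and
PCA denoising, and no clustering method could tell them apart.

**Symbol process.** Sequences are first-order Markov chains over the
shape alphabet plus the pause symbol `$` (typically 12 + 1 = 13 states,
up to 6,000 symbols per 10-minute time step). Maneuver matrices come from
`make_state_specs`: a shared random (Dirichlet) base matrix mixed with a
maneuver-specific cyclic-shift permutation matrix with weight *s*
(default 0.35), which makes any two maneuvers exactly *s* apart in
per-row total-variation distance — a controlled contrast knob. Per
segment, each maneuver matrix is further mixed (weight 0.1) with a
segment-specific random stochastic matrix to emulate inter-segment
variability.

**Timing.** An event following k intervening pause tokens is placed
(1 + k)·pause periods after the previous event (pause default 0.12 s,
matching ~100 events per 12 s), plus Gaussian jitter (sd 10% of the pause
period, truncated at 40%). Consecutive events are additionally kept at
least one event window (+2 ms) apart: real CDPs are followed by an
inhibitory silent phase, and the symbolization assumes a single event per
100 ms analysis window. Stationary Gaussian noise (default sd 0.02 mV,
SNR ≈ 50) is added to the whole trace.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic CDP morphology beyond "smooth,
distinct, band-limited", amplitude non-stationarity, line noise and
movement artifacts, drifting baselines, overlapping events, cross-channel
synchronization, and any slow drift of the transition structure within a
time step.

## Event detection

Peaks are localized on a zero-phase (forward–backward) 4th-order
Butterworth low-pass at 70 Hz; zero phase keeps time-stamps unbiased, and
the smoothed copy is used *only* for localization — stored windows are
raw. A candidate peak becomes an event when it satisfies all of:

* prominence ≥ half the amplitude threshold (rejects noise wiggles riding
  on an event's flank);
* baseline-subtracted amplitude ≥ `min_amplitude_mv` (default 0.1 mV),
  where the baseline is the **higher** of the two window-edge means — a
  genuine event rises from and returns to baseline, while a low saddle
  between two events sits below at least one neighbour's flank;
* the peak is the maximum of its own 100 ms window (the time-stamp is
  defined as the window maximum);
* the peak clears the threshold above the global trace median (the
  recordings are AC-coupled, so the median is a meaningful zero);
* no second smoothed local maximum inside the window exceeds 80% of the
  central amplitude (rejects double events).

Overlapping candidates are resolved greedily, larger peak first, with a
minimum spacing of half a window. Windows truncated by the recording
edges are dropped with a warning. At the 5×-noise-sd threshold the false
alarm rate on pure noise is below one event per 10 minutes, and ≥ 95% of
planted events are recovered within ±2 ms down to SNR 5 (both tested).

Accepted 100 ms windows are resampled from 10 kHz to 1.6 kHz
(polyphase FIR, 160 samples) and baseline-aligned by subtracting the mean
of the first 10% of samples; the alignment is idempotent.

## Shape dictionary

Windows are denoised by projecting on the minimal set of leading
principal components reaching 98% cumulative variance and reconstructing;
clustering *and* nearest-prototype labelling both operate on this
reconstruction, so training assignment and labelling agree. The number of
clusters is chosen by consensus (modal vote, ties to the smaller k) of
two internal validity indices — silhouette and Calinski–Harabasz — over a
candidate range; if even the best silhouette is below 0.1 the data shows
no cluster structure and the minimum candidate is returned with a
warning. k-means runs 10 restarts on a fixed seed stream; labels A, B, …
are assigned by decreasing cluster size so the labelling is deterministic
given the seed. Events are labelled by minimum Euclidean distance to the
prototypes, exact ties to the lowest index.

## Symbolization

The pause period is the arithmetic mean of the inter-event-interval
distribution. Between consecutive events with gap g, the number of
inserted `$` tokens is `max(0, round(g / pause) − 1)`: a gap near one
period — the typical spacing — inserts nothing, a gap near (1 + k)
periods inserts k. Chosen over a plain floor rule because it inverts the
generator's placement model exactly and is robust to timing jitter up to
half a period, while still inserting nothing for gaps under 1.5 periods.
Note the estimated pause period is biased high by the pauses themselves
(mean gap = pause × (1 + mean pause count)); with a ~1/13 pause marginal
this is ≈ 8% and the rounding rule absorbs it for all but very long gaps.
An alternative fixed 100 ms pause (one analysis window) can be forced via
configuration. Leading and trailing pauses of a planted sequence are
unobservable (the symbolizer only sees event times), so round-trip
comparisons strip them.

## Markov-order tests

Pair counts treat `$` as an ordinary symbol (special row and column).
The independence expectation uses n = number of adjacent pairs
(length − 1), not the token count, so observed and expected tables share
their total; the divergence sums (O−E)²/E over cells with E > 0 (cells
with E = O = 0 contribute nothing; E = 0 with O > 0 cannot occur when
both tables come from one sequence and is rejected defensively).

**Degrees of freedom.** For an alphabet of m symbols the χ² reference
uses (m−1)² degrees of freedom — the classical result for the order-0 vs
order-1 test when the marginals are estimated from the same sequence.
The m(m−1) figure sometimes quoted for this test makes it conservative:
simulation of the null at m = 13, length 6,000 puts the statistic's mean
at 143.6 ≈ (13−1)² = 144, with the nominal 5% level realized at df 144
(5.5% rejections) but not at df 156 (0.8%). The test suite checks this
calibration; the rejection decision on strongly first-order data is
unaffected by the choice.

**Randomized tests.** p-values use the (1 + exceedances)/(1 + draws)
convention, so p is never zero and "p below 1/N" is the strongest
possible outcome. Order-0 surrogates are uniform random permutations
(symbol histogram preserved exactly). Order-1 surrogates preserve the
full pair-count matrix: the transition multigraph is closed into an
Eulerian circuit by one auxiliary edge (last → first symbol), a uniform
spanning arborescence toward the circuit's start vertex is drawn by
Wilson's loop-erased-random-walk algorithm, and the BEST-theorem
bijection (tree edge last in each vertex's out-edge order) yields a
uniform Eulerian trail — i.e. a uniform draw from all sequences with the
original's pair counts and initial symbol. Uniformity and exact coverage
of the feasible set are verified against a brute-force trail enumeration
oracle on small alphabets. Fixing the pair counts fixes both endpoint
symbols whenever the multigraph is unbalanced; for balanced inputs the
initial symbol is conserved by convention (the enumeration oracle uses
the same convention).

**Order-2 statistic.** The divergence of observed triplet counts
N(i,j,k) from their first-order expectation N'(i,j)·P(k|j), with N' the
pair counts over triplet-prefix positions and P estimated from the whole
sequence — the natural second-order analogue of the pair divergence.
Whenever a triplet is observed both factors of its expectation are
positive, so the statistic is always defined. Its null distribution comes
from the Whittle surrogates (1,000 by default; with 1,000 draws the
smallest attainable p is ~0.001). On first-order chains the test is
calibrated (rejection ≈ α, mean p ≈ 0.5); a planted second-order rule at
length 6,000 is detected at p ≤ 0.01 (both tested).

## State classification

Per-(segment, step) models use additive smoothing,
probs = (counts + α)/(row + α·m), default α = 0.5: the evaluation scores
held-out data under models trained on other steps, where unseen
transitions would otherwise give log 0. α = 0 reproduces the plain
estimate and is supported (−∞ log-likelihoods are flagged). The held-out
"last k events" counts non-pause tokens, with interleaved pauses carried
along (pauses participate in the likelihood through the `$` row and
column). Success means maneuver-type match — confusing two control steps
is not an error — with exact-step accuracy reported secondarily.
Prediction ties break toward the earlier step; the cross-segment
consensus is the modal predicted maneuver, ties broken by the largest
summed best-candidate log-likelihood. The random-classifier baseline
draws the true and predicted steps uniformly (Monte Carlo, 10,000 trials
by default) and agrees with the exact Σ(n_t/N)² within binomial error
(tested over random configurations).

## Problem sizes and numerical choices

Analyses and tests use deliberately chosen scales: full-length
(6,000-token) sequences wherever the statistics need them; 999
permutation and 199 Whittle surrogates in the replicated Monte-Carlo
studies (the library defaults remain 10,000 and 1,000, the values used
for single-sequence reports); rendered recordings of ~900 events per step
for the signal-level stages; 500 (type-I) and 200 (order-2 calibration)
replicates in the acceptance suite. Monte-Carlo assertions are made on
means over seeds where a single draw would sit at its own noise level
(e.g. the worst-cell matrix-recovery error at 10,000 tokens, whose
per-seed maximum over 169 cells lies near its binomial 3σ ≈ 0.05).
Stochastic-matrix rows are validated to 1e-6; probability rows sum to 1
within 1e-9 after normalization; all randomness flows through
`numpy.random.Generator` objects seeded from a single entry point.

## Known limitations

* The pause-duration estimator inherits the mean-gap definition and is
  therefore upward-biased when pauses are frequent; the rounding rule
  compensates only up to moderate gap lengths.
* Tests of order above 2 are out of scope (the triplet tensor is already
  sparse at realistic sequence lengths), as are continuous-time models,
  multi-channel joint symbolization, artifact rejection, and unsupervised
  discovery of functional states.
* The similarity structure *between* time steps (beyond maneuver labels)
  is not modelled.
* With default jitter, rare near-window-length gaps can still leave two
  waveforms adjacent enough to perturb a single label; exact round-trip
  recovery is guaranteed only in the noiseless, zero-jitter limit.
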