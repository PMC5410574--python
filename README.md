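# cdpmarkov

Markov-chain analysis of spontaneous **cord dorsum potential (CDP)**
sequences.

Spontaneous CDPs are voltage deflections recorded from the dorsal surface
of the spinal cord, generated by synchronized ensembles of dorsal horn
neurons. In the anesthetized cat, the repertoire of CDP waveforms recorded
from a lumbar segment can be clustered into a small dictionary of shape
classes, which turns a multichannel voltage recording into a sequence of
symbols (plus a pause symbol `$` for intervals without an identifiable
event). Two questions follow:

1. **Does the sequence have memory?** If the class of the next CDP depends
   on the class of the previous one, the sequence is a Markov chain of
   order ≥ 1 rather than a renewal (memoryless) process — evidence of
   structured inhibitory interactions between the generating ensembles.
2. **Can a short stretch of recording be assigned to a functional state?**
   If each experimental maneuver — control (*ctrl*), spinalization (*esp*),
   intradermic capsaicin (*capsa*) — leaves a distinct transition-probability
   signature, the state that produced a held-out sequence can be identified
   by likelihood.

This package implements the full pipeline for both questions, driven by a
ground-truthed synthetic generator that emulates the (non-public) cat
recordings: event detection in 10 kHz traces, PCA + k-means shape
dictionaries, symbolization with pause tokens, Markov-order testing with
surrogate data, and log-likelihood state classification. It is aimed at
electrophysiologists and methodologists working with symbolic dynamics of
population events.

## The statistics at the core

With an alphabet of m symbols (shape classes + `$`), the first-order model
is the row-stochastic matrix estimated by pair counting:

    P(c_j | c_i) = N(c_i -> c_j) / N(c_i ·)

**Order 0 vs 1.** The observed pair counts O are compared with the
independence expectation E_ij = n·P(c_i)·P(c_j) (n = number of adjacent
pairs) through the Pearson divergence X² = Σ (O−E)²/E, referred either to
its χ² distribution with (m−1)² degrees of freedom, or to a null sample of
10,000 histogram-preserving random permutations of the sequence.

**Order 1 vs 2.** Observed triplet counts N(i,j,k) are compared with their
first-order expectation N(i,j)·P(k|j); because the triplet tensor has m³
entries (2,197 at m = 13) the χ² approximation is unreliable, so the null
comes from 1,000 **Whittle surrogates** — sequences sampled *uniformly*
among all sequences with exactly the original pair counts, generated as
uniform random Eulerian trails of the transition multigraph via Wilson
spanning-arborescence sampling (BEST theorem).

**State identification.** Per (segment, time step), a smoothed model
m_{l,s} is fit on all but the last k events; a held-out suffix C is scored
under every candidate model by

    log P(C | m) = Σ_t log P(c_{t+1} | c_t ; m)

and the top-ranked model's maneuver is the prediction. The random-classifier
baseline is Σ_t (n_t/N)² over maneuver step counts, estimated by Monte Carlo.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
experiments and write their tables under `results/analysis/`:

```bash
python analysis/01_simulate_experiment.py --seed 1
python analysis/02_extract_sequences.py  --seed 1
python analysis/03_markov_order_tests.py --seed 1
python analysis/04_state_classification.py --seed 1
python analysis/05_robustness_sweep.py   --seed 1
```

Script 02 reports, for eight rendered 10-minute-scale recordings:

```
pooled 6645 windows; PCA keeps 5 components (98% variance); consensus dictionary size k = 12
mean event recovery 100.0% within 2 ms; mean pause period 0.130 s
```

i.e. detection recovered every planted event, the validity-index consensus
found the true 12 shape classes, and the estimated pause period sits near
the planted 0.12 s mean inter-event interval. Script 03 then tests all 88
(segment, step) sequences:

```
order-1 (vs renewal): max chi-square p = 2.23e-308, max permutation p = 0.0010
order-2: mean p = 0.49, rejections at alpha=0.05: 5/88
```

— the renewal hypothesis is rejected for every sequence while the order-2
test stays at chance, exactly matching how the data were generated
(first-order chains). Script 04 prints the accuracy table (success % vs
held-out test length, with the Monte-Carlo random baseline):

```
            random_classifier     50    100    150    200    250    300
e110906                  50.9  100.0  100.0  100.0  100.0  100.0  100.0
e130221                  36.9  100.0  100.0  100.0  100.0  100.0  100.0
...
e130221: consensus across 11 segments correct for 100% of steps
```

With 0.35 total-variation separation between maneuver matrices, the
likelihood classifier identifies the maneuver of every held-out sequence;
with identical matrices it falls back to the random baseline (see the test
suite). A `cdpmarkov` command-line tool exposes the same stages
(`run`, `simulate`, `test-markov`, `sweep`) over YAML configs.

## Layout

    src/cdpmarkov/       library: simulate, detect, dictionary, symbolize,
                         markov, classify, pipeline, plotting, io, cli
    analysis/            numbered narrative drivers (see above)
    scripts/acceptance.py  from-scratch recomputation of headline numbers
    docs/methods.md      model, assumptions, numerical choices, limitations
    tests/               pytest suite (unit + property + acceptance)
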