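"""Ground-truthed synthetic CDP experiments.

The cat recordings behind this analysis are not publicly deposited, so the
pipeline is exercised on synthetic experiments whose statistical structure
matches what the analysis assumes: smooth, band-limited (< 70 Hz) event
waveforms ~100 ms long, drawn from a small dictionary of distinct shapes,
occurring as a first-order Markov process over shape classes plus a pause
symbol ``$``, rendered into a 10 kHz voltage trace with additive stationary
Gaussian noise.  Experiments mirror the real layout: several lumbar-segment
channels ("segments") recorded over ~10-minute time steps grouped into
maneuvers (control / spinalization / capsaicin analogues).

Timing model: an event following k intervening pause tokens is placed
``pause_duration * (1 + k)`` after the previous event (plus truncated
Gaussian jitter), so with the default mean inter-event interval of 0.12 s
a hundred events span roughly 12 s.  The symbolization stage recovers the
planted pause count exactly in the noiseless limit.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .detect import Recording
from .errors import InvalidArgumentError, InvalidModelError, InvalidSymbolError
from .symbolize import PAUSE

__all__ = [
    "DEFAULT_NOISE_SD",
    "DEFAULT_PAUSE_S",
    "PAUSE",
    "ShapeTemplate",
    "StateSpec",
    "SyntheticExperiment",
    "make_templates",
    "sample_markov_sequence",
    "render_recording",
    "make_state_specs",
    "make_experiment",
]

DEFAULT_NOISE_SD = 0.02  # mV, background noise standard deviation
DEFAULT_PAUSE_S = 0.12  # s, mean inter-event interval (~100 events / 12 s)


@dataclass(frozen=True)
class ShapeTemplate:
    """One prototype event waveform.

    ``waveform`` is in mV at ``rate_hz`` over the event window; its global
    maximum sits at the window centre so that the detector's centre-peak
    rule fires on a planted copy.
    """

    label: str
    waveform: np.ndarray
    rate_hz: float


@dataclass(frozen=True)
class StateSpec:
    """Generating model for one maneuver: a first-order chain over the
    shape alphabet plus ``$``, repeated for ``n_steps`` time steps."""

    maneuver_label: str
    transition_matrix: np.ndarray
    alphabet: tuple[str, ...]
    n_steps: int = 1
    symbols_per_step: int = 6_000

    def __post_init__(self):
        P = np.asarray(self.transition_matrix, dtype=float)
        if self.n_steps < 1:
            raise InvalidArgumentError("n_steps must be >= 1")
        if P.ndim != 2 or P.shape[0] != P.shape[1] or P.shape[0] != len(self.alphabet):
            raise InvalidArgumentError("transition matrix must be square over the alphabet")
        _check_stochastic(P)


@dataclass
class SyntheticExperiment:
    """A full synthetic experiment with its generating ground truth."""

    recordings: dict  # (segment_id, step_id) -> Recording (may be empty if unrendered)
    truth_symbols: dict  # (segment_id, step_id) -> list[str]
    truth_times: dict  # (segment_id, step_id) -> np.ndarray, s, non-$ tokens only
    truth_matrices: dict  # (segment_id, step_id) -> np.ndarray
    step_maneuvers: dict  # step_id -> maneuver label
    alphabet: tuple[str, ...]
    templates: list[ShapeTemplate] = field(default_factory=list)
    seed: int | None = None


def _check_stochastic(P: np.ndarray, tol: float = 1e-6) -> None:
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > tol):
        raise InvalidModelError("rows must be non-negative and sum to 1")


def _lowpass(x: np.ndarray, rate_hz: float, cutoff_hz: float) -> np.ndarray:
    sos = _signal.butter(4, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return _signal.sosfiltfilt(sos, x)


def make_templates(n_shapes: int, window_ms: float = 100.0, rate_hz: float = 10_000.0,
                   seed=None, amplitude_mv: tuple[float, float] = (0.8, 1.2),
                   min_separation_mv: float | None = None) -> list[ShapeTemplate]:
    """Build ``n_shapes`` distinct, smooth event templates.

    Each template is a sum of one dominant positive bump and 1-3 smaller
    side bumps with random centres/widths/signs, low-pass filtered at
    60 Hz (safely inside the 70 Hz detection band), tapered to zero at the
    window edges and re-centred so the global maximum is at the window
    centre.  Templates are redrawn until every pairwise Euclidean distance
    exceeds ``min_separation_mv`` (default: 5x the default noise sd).
    """
    if n_shapes < 1:
        raise InvalidArgumentError("n_shapes must be >= 1")
    if window_ms <= 0 or rate_hz <= 0:
        raise InvalidArgumentError("window_ms and rate_hz must be positive")
    if n_shapes > len(string.ascii_uppercase):
        raise InvalidArgumentError("at most 26 shape labels supported")
    if min_separation_mv is None:
        # well above 5x the default noise sd: shapes must stay separable
        # after smoothing/denoising for the dictionary to be recoverable
        min_separation_mv = 1.0

    rng = np.random.default_rng(seed)
    n = int(round(window_ms / 1000.0 * rate_hz))
    buf = 2 * n  # build on a longer support, then crop around the peak
    t = np.arange(buf) / rate_hz
    span = buf / rate_hz

    templates: list[ShapeTemplate] = []
    waves: list[np.ndarray] = []
    attempts = 0
    while len(templates) < n_shapes:
        attempts += 1
        if attempts > 200 * n_shapes:
            raise InvalidArgumentError("could not draw sufficiently distinct templates")
        main_w = rng.uniform(0.06, 0.16) * (window_ms / 1000.0)
        wave = np.exp(-0.5 * ((t - span / 2) / main_w) ** 2)
        for _ in range(rng.integers(1, 4)):
            c = rng.uniform(0.3, 0.7) * span
            w = rng.uniform(0.04, 0.12) * (window_ms / 1000.0)
            a = rng.uniform(0.15, 0.45) * rng.choice([-1.0, 1.0])
            wave = wave + a * np.exp(-0.5 * ((t - c) / w) ** 2)
        wave = _lowpass(wave, rate_hz, 60.0)
        peak = int(np.argmax(wave))
        lo = peak - n // 2
        if lo < 0 or lo + n > buf:
            continue
        win = wave[lo:lo + n].copy()
        win *= _signal.windows.tukey(n, alpha=0.3)
        peak_in = int(np.argmax(np.abs(win)))
        if abs(peak_in - n // 2) > 0.1 * n or win[peak_in] <= 0:
            continue
        # reject a second positive local maximum >= 80% of the main peak
        maxima, _ = _signal.find_peaks(win)
        others = maxima[maxima != peak_in]
        if others.size and np.any(win[others] >= 0.75 * win[peak_in]):
            continue
        win *= rng.uniform(*amplitude_mv) / win[peak_in]
        if any(np.linalg.norm(win - w) <= min_separation_mv for w in waves):
            continue
        waves.append(win)
        templates.append(ShapeTemplate(string.ascii_uppercase[len(templates)], win, rate_hz))
    return templates


def sample_markov_sequence(transition_matrix: np.ndarray, length: int,
                           start_distribution=None, seed=None,
                           alphabet=None) -> list[str]:
    """Sample a token sequence from a first-order chain.

    ``alphabet`` defaults to A, B, ... over the matrix dimension; pass the
    full alphabet (including ``$``) to obtain pause tokens.
    """
    P = np.asarray(transition_matrix, dtype=float)
    if length < 1:
        raise InvalidArgumentError("length must be >= 1")
    _check_stochastic(P)
    m = P.shape[0]
    if alphabet is None:
        alphabet = tuple(string.ascii_uppercase[:m])
    if len(alphabet) != m:
        raise InvalidArgumentError("alphabet size must match matrix dimension")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if start_distribution is None:
        start = rng.integers(m)
    else:
        p0 = np.asarray(start_distribution, dtype=float)
        if abs(p0.sum() - 1.0) > 1e-6 or np.any(p0 < 0):
            raise InvalidModelError("start distribution must be a probability vector")
        start = int(np.searchsorted(np.cumsum(p0), rng.random()))
    cum = np.cumsum(P, axis=1)
    out = np.empty(length, dtype=np.int64)
    out[0] = start
    r = rng.random(length)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], r[i])
    return [alphabet[i] for i in out]


def render_recording(symbols, templates, pause_duration_s: float = DEFAULT_PAUSE_S,
                     jitter_sd_s: float | None = None, noise_sd: float = DEFAULT_NOISE_SD,
                     rate_hz: float = 10_000.0, seed=None,
                     segment_id: str = "S1", step_id: str = "step_1",
                     maneuver: str | None = None):
    """Render a token sequence into a noisy voltage trace.

    Events are placed left to right: each pause token advances the clock by
    one ``pause_duration_s``; a non-pause token places its template one
    pause period after the previous event (so k intervening pauses yield a
    gap of (1 + k) pause periods), plus Gaussian jitter truncated at 40% of
    the pause period to preserve ordering.  Returns the recording and the
    planted peak times of non-pause tokens.
    """
    symbols = list(symbols)
    if pause_duration_s <= 0:
        raise InvalidArgumentError("pause_duration_s must be positive")
    if jitter_sd_s is None:
        jitter_sd_s = 0.1 * pause_duration_s
    by_label = {tpl.label: tpl for tpl in templates}
    unknown = sorted({s for s in symbols if s != PAUSE and s not in by_label})
    if unknown:
        raise InvalidSymbolError(f"no template for token(s) {unknown}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    nwin = len(templates[0].waveform) if templates else int(round(0.1 * rate_hz))
    margin = nwin / rate_hz  # keep full windows inside the trace
    # consecutive events never closer than one event window: each event is
    # followed by a refractory silent phase, and the symbolization assumes
    # a single event per analysis window
    min_sep = nwin / rate_hz + 0.002
    clock = margin
    times: list[float] = []
    labels: list[str] = []
    clip = 0.4 * pause_duration_s
    for s in symbols:
        clock += pause_duration_s
        if s == PAUSE:
            continue
        jitter = float(np.clip(rng.normal(0.0, jitter_sd_s), -clip, clip)) if jitter_sd_s > 0 else 0.0
        t = clock + jitter
        if times:
            t = max(t, times[-1] + min_sep)
        times.append(t)
        labels.append(s)
    duration = (times[-1] if times else clock) + margin + pause_duration_s
    nsamp = int(np.ceil(duration * rate_hz))
    trace = np.zeros(nsamp)
    for t0, lab in zip(times, labels):
        w = by_label[lab].waveform
        centre = int(round(t0 * rate_hz))
        lo = centre - len(w) // 2
        trace[lo:lo + len(w)] += w
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, nsamp)
    rec = Recording(segment_id=segment_id, step_id=step_id, samples=trace,
                    rate_hz=rate_hz, maneuver=maneuver)
    # planted peak times, quantized to the sample grid actually written
    truth = np.array([int(round(t * rate_hz)) / rate_hz for t in times])
    return rec, truth


def _random_stochastic(m: int, rng, concentration: float = 1.0) -> np.ndarray:
    return rng.dirichlet(np.full(m, concentration), size=m)


def make_state_specs(maneuver_steps, n_shapes: int = 12, separation: float = 0.35,
                     symbols_per_step: int = 6_000, seed=None) -> list[StateSpec]:
    """Build one StateSpec per maneuver with controlled between-state contrast.

    ``maneuver_steps`` is an ordered mapping maneuver -> number of steps
    (e.g. ``{"ctrl": 2, "esp": 2, "capsa": 4}``).  Each maneuver's matrix is
    a convex mix (weight ``separation``) of a shared random base matrix with
    a maneuver-specific cyclic-shift permutation matrix; distinct shifts
    differ in every row, so any two maneuvers are exactly ``separation``
    apart in per-row total-variation distance.
    """
    if not maneuver_steps:
        raise InvalidArgumentError("maneuver_steps must be non-empty")
    if not 0.0 <= separation <= 1.0:
        raise InvalidArgumentError("separation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alphabet = tuple([PAUSE] + list(string.ascii_uppercase[:n_shapes]))
    m = len(alphabet)
    base = _random_stochastic(m, rng)
    eye = np.eye(m)
    specs = []
    for i, (label, n_steps) in enumerate(dict(maneuver_steps).items()):
        perm = np.roll(eye, i + 1, axis=1)
        P = (1.0 - separation) * base + separation * perm
        specs.append(StateSpec(label, P, alphabet, n_steps=int(n_steps),
                               symbols_per_step=symbols_per_step))
    return specs


def make_experiment(states, n_segments: int, templates=None, seed=None,
                    segment_mix: float = 0.1, render: bool = True,
                    pause_duration_s: float = DEFAULT_PAUSE_S,
                    jitter_sd_s: float | None = None,
                    noise_sd: float = DEFAULT_NOISE_SD,
                    rate_hz: float = 10_000.0) -> SyntheticExperiment:
    """Generate a full multi-segment, multi-step synthetic experiment.

    One recording per (segment, step); all steps of one maneuver share that
    maneuver's matrix, perturbed per segment by convex mixing (weight
    ``segment_mix``) with a segment-specific random stochastic matrix to
    emulate inter-segment variation.  ``render=False`` skips waveform
    rendering and keeps only token sequences and truth metadata (useful for
    sequence-level studies).  Fully reproducible from ``seed``.
    """
    states = list(states)
    if not states:
        raise InvalidArgumentError("states must be non-empty")
    if n_segments < 1:
        raise InvalidArgumentError("n_segments must be >= 1")
    alphabet = states[0].alphabet
    if any(s.alphabet != alphabet for s in states):
        raise InvalidArgumentError("all states must share one alphabet")
    if render:
        if templates is None:
            raise InvalidArgumentError("templates required when render=True")
        needed = set(alphabet) - {PAUSE}
        have = {t.label for t in templates}
        if not needed <= have:
            raise InvalidSymbolError(f"missing templates for {sorted(needed - have)}")
    rng = np.random.default_rng(seed)
    m = len(alphabet)
    segment_ids = [f"S{i + 1:02d}" for i in range(n_segments)]

    step_ids: list[tuple[str, StateSpec]] = []
    step_maneuvers: dict[str, str] = {}
    for spec in states:
        for j in range(spec.n_steps):
            sid = f"{spec.maneuver_label}_{j + 1}"
            step_ids.append((sid, spec))
            step_maneuvers[sid] = spec.maneuver_label

    exp = SyntheticExperiment({}, {}, {}, {}, step_maneuvers, alphabet,
                              list(templates or []),
                              int(seed) if isinstance(seed, (int, np.integer)) else None)
    for seg in segment_ids:
        perturb = {spec.maneuver_label: _random_stochastic(m, rng) for spec in states}
        for sid, spec in step_ids:
            P = (1.0 - segment_mix) * spec.transition_matrix + segment_mix * perturb[spec.maneuver_label]
            toks = sample_markov_sequence(P, spec.symbols_per_step, seed=rng, alphabet=alphabet)
            key = (seg, sid)
            exp.truth_symbols[key] = toks
            exp.truth_matrices[key] = P
            if render:
                rec, truth = render_recording(
                    toks, exp.templates, pause_duration_s=pause_duration_s,
                    jitter_sd_s=jitter_sd_s, noise_sd=noise_sd, rate_hz=rate_hz,
                    seed=rng, segment_id=seg, step_id=sid,
                    maneuver=spec.maneuver_label)
                exp.recordings[key] = rec
                exp.truth_times[key] = truth
            else:
                exp.truth_times[key] = np.array([])
    return exp
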