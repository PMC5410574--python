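"""Event detection in cord-dorsum voltage traces.

Candidate events are peaks of a 70 Hz zero-phase low-pass smoothed copy of
the signal (the smoothing is used only for peak localization, never for the
stored waveform).  A candidate is kept when its baseline-subtracted
amplitude clears a threshold and no second smoothed local maximum inside
its 100 ms window reaches 80% of the central peak; overlapping candidates
are resolved greedily, larger peak first.  Accepted events are cut out at
the native rate and preprocessed for clustering: resampled from 10 kHz to
1.6 kHz and baseline-aligned by subtracting the mean of the first 10% of
window samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import ndimage as _ndimage
from scipy import signal as _signal

from .errors import InvalidArgumentError

__all__ = ["Recording", "DetectionParams", "Event",
           "lowpass_smooth", "detect_events", "preprocess_event"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Recording:
    """One channel's voltage trace plus provenance."""

    segment_id: str
    step_id: str
    samples: np.ndarray  # mV
    rate_hz: float
    maneuver: str | None = None

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise InvalidArgumentError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz


@dataclass(frozen=True)
class DetectionParams:
    window_ms: float = 100.0
    smooth_cutoff_hz: float = 70.0
    min_amplitude_mv: float = 0.1
    baseline_fraction: float = 0.1
    target_rate_hz: float = 1_600.0
    dominance_ratio: float = 0.8  # reject windows with a competing peak

    def __post_init__(self):
        if not 0.0 < self.baseline_fraction < 0.5:
            raise InvalidArgumentError("baseline_fraction must be in (0, 0.5)")
        if self.window_ms <= 0 or self.target_rate_hz <= 0:
            raise InvalidArgumentError("window_ms and target_rate_hz must be positive")

    def window_samples(self, rate_hz: float) -> int:
        return int(round(self.window_ms / 1000.0 * rate_hz))


@dataclass(frozen=True)
class Event:
    """A detected event: time-stamp plus raw and preprocessed windows."""

    segment_id: str
    step_id: str
    peak_index: int  # 0-based sample index at the native rate
    rate_hz: float
    raw_window: np.ndarray
    processed_window: np.ndarray | None = None

    @property
    def peak_time_s(self) -> float:
        return self.peak_index / self.rate_hz


def lowpass_smooth(trace: np.ndarray, rate_hz: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass of the trace.

    Forward-backward filtering keeps the peak time-stamp unbiased.
    """
    if cutoff_hz >= rate_hz / 2:
        raise InvalidArgumentError("cutoff must be below the Nyquist frequency")
    trace = np.asarray(trace, dtype=float)
    if len(trace) == 0:
        return trace.copy()
    sos = _signal.butter(4, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return _signal.sosfiltfilt(sos, trace)


def detect_events(recording: Recording, params: DetectionParams | None = None) -> list[Event]:
    """Detect candidate events in a recording.

    Returns events sorted by peak index; each satisfies the centre-peak,
    amplitude, single-dominant-peak and half-window-overlap rules.  Windows
    that would be truncated by the recording edges are never produced.
    """
    params = params or DetectionParams()
    x = np.asarray(recording.samples, dtype=float)
    w = params.window_samples(recording.rate_hz)
    half = w // 2
    if len(x) <= w:
        return []
    sm = lowpass_smooth(x, recording.rate_hz, params.smooth_cutoff_hz)
    # prominence floor rejects noise wiggles riding on an event's shoulder
    peaks, _ = _signal.find_peaks(sm, prominence=0.5 * params.min_amplitude_mv)
    if peaks.size == 0:
        return []
    inside = (peaks >= half) & (peaks + (w - half) <= len(x))
    peaks = peaks[inside]
    if peaks.size == 0:
        return []

    nb = max(1, int(params.baseline_fraction * w))
    cs = np.concatenate(([0.0], np.cumsum(sm)))
    starts = peaks - half
    ends = starts + w
    # amplitude is referenced to the higher of the two window-edge means: a
    # genuine event rises from and returns to baseline, while a saddle
    # between two events sits below at least one neighbour's flank
    first_means = (cs[starts + nb] - cs[starts]) / nb
    last_means = (cs[ends] - cs[ends - nb]) / nb
    baselines = np.maximum(first_means, last_means)
    amps = sm[peaks] - baselines
    # the time-stamp is the maximum of its window: the centre peak must not
    # be exceeded anywhere inside the window
    win_max = _ndimage.maximum_filter1d(sm, size=w, mode="nearest")
    is_window_max = sm[peaks] >= win_max[peaks] - 1e-12
    # recordings are AC-coupled, so the trace median is a global zero
    # reference; low saddles between two events never clear it
    above_global = sm[peaks] - np.median(sm) >= params.min_amplitude_mv
    cand = np.flatnonzero((amps >= params.min_amplitude_mv) & is_window_max & above_global)

    all_peaks = peaks  # prominent maxima, including sub-threshold competitors
    kept_idx: list[int] = []
    for i in cand:
        p = peaks[i]
        lo, hi = p - half, p - half + w
        j0, j1 = np.searchsorted(all_peaks, (lo, hi))
        competitors = all_peaks[j0:j1]
        competitors = competitors[competitors != p]
        if competitors.size and np.any(
                sm[competitors] - baselines[i] > params.dominance_ratio * amps[i]):
            continue
        kept_idx.append(i)
    if not kept_idx:
        return []

    # greedy overlap resolution: larger peak wins, minimum spacing half a window
    kept_idx = sorted(kept_idx, key=lambda i: -amps[i])
    accepted: list[int] = []
    for i in kept_idx:
        p = peaks[i]
        if all(abs(p - peaks[j]) >= half for j in accepted):
            accepted.append(i)
    accepted.sort(key=lambda i: peaks[i])

    events = []
    for i in accepted:
        p = int(peaks[i])
        events.append(Event(recording.segment_id, recording.step_id, p,
                            recording.rate_hz, x[p - half:p - half + w].copy()))
    return events


def preprocess_event(event: Event, params: DetectionParams | None = None) -> Event:
    """Resample the raw window to the target rate and align its baseline.

    The mean of the first ``baseline_fraction`` of processed samples is
    subtracted, so repeated application is a no-op.
    """
    params = params or DetectionParams()
    w = params.window_samples(event.rate_hz)
    if event.raw_window is None or len(event.raw_window) != w:
        log.warning("event at index %d dropped: truncated window", event.peak_index)
        return replace(event, processed_window=None)
    frac = Fraction(params.target_rate_hz / event.rate_hz).limit_denominator(10_000)
    y = _signal.resample_poly(event.raw_window, frac.numerator, frac.denominator,
                              padtype="line")
    n_target = int(round(params.window_ms / 1000.0 * params.target_rate_hz))
    y = y[:n_target]
    nb = max(1, int(params.baseline_fraction * len(y)))
    y = y - y[:nb].mean()
    return replace(event, processed_window=y)
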