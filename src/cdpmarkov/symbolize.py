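"""Symbolization: labelled, time-stamped events -> discrete token sequences.

The pause symbol ``$`` stands for one mean inter-event interval without an
identifiable event.  The mean of the distribution of gaps between
consecutive events defines the pause duration; a gap of roughly (1 + k)
pause periods between two events inserts k pause tokens (``round(gap /
pause) - 1``, clipped at zero), so a gap near one period — the typical
spacing — inserts nothing, and the planted pause count of a synthetic
rendering is recovered exactly for jitter below half a period.

Sequence files are plain text: a whitespace-separated token file, a YAML
header with provenance, and a two-column CSV of event times.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InsufficientDataError, InvalidArgumentError, ParseError

__all__ = ["PAUSE", "SymbolSequence", "PauseModel", "estimate_pause_duration",
           "discretize", "symbol_frequencies", "write_sequence", "read_sequence"]

log = logging.getLogger(__name__)

PAUSE = "$"
_TOKEN_RE = re.compile(r"^(\$|[A-Za-z]\w*)$")


@dataclass
class SymbolSequence:
    """Ordered tokens over the shape alphabet plus ``$``, with the event
    times of the non-pause tokens and provenance."""

    tokens: list[str]
    event_times: np.ndarray = field(default_factory=lambda: np.array([]))
    segment_id: str = ""
    step_id: str = ""
    maneuver: str = ""
    pause_duration_s: float | None = None

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, dtype=float)
        n_events = sum(1 for t in self.tokens if t != PAUSE)
        if len(self.event_times) not in (0, n_events):
            raise InvalidArgumentError("event_times must cover exactly the non-pause tokens")
        if len(self.event_times) > 1 and np.any(np.diff(self.event_times) <= 0):
            raise InvalidArgumentError("event_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_events(self) -> int:
        return sum(1 for t in self.tokens if t != PAUSE)


@dataclass(frozen=True)
class PauseModel:
    pause_duration_s: float

    def __post_init__(self):
        if self.pause_duration_s <= 0:
            raise InvalidArgumentError("pause_duration_s must be positive")


def estimate_pause_duration(event_times) -> PauseModel:
    """Mean of the consecutive inter-event intervals."""
    t = np.asarray(event_times, dtype=float)
    if len(t) < 2:
        raise InsufficientDataError("need at least 2 events to estimate the pause duration")
    return PauseModel(float(np.diff(t).mean()))


def discretize(labels, event_times, pause: PauseModel, **provenance) -> SymbolSequence:
    """Interleave pause tokens between labelled events.

    Between consecutive events with gap g, insert ``max(0, round(g /
    pause) - 1)`` pause tokens; event tokens keep their order and times.
    """
    labels = list(labels)
    t = np.asarray(event_times, dtype=float)
    if len(labels) != len(t):
        raise InvalidArgumentError("labels and event_times must align")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("event_times must be strictly increasing")
    p = pause.pause_duration_s
    tokens: list[str] = []
    for i, lab in enumerate(labels):
        if i > 0:
            gap = t[i] - t[i - 1]
            tokens.extend([PAUSE] * max(0, int(np.floor(gap / p + 0.5)) - 1))
        tokens.append(lab)
    return SymbolSequence(tokens, t, pause_duration_s=p, **provenance)


def symbol_frequencies(sequences) -> pd.DataFrame:
    """Per-step occurrence probability of each shape among non-pause tokens.

    Sequences are pooled by ``step_id``; rows sum to 1.  Steps without any
    event get a zero row, flagged in the log and in ``df.attrs['empty_steps']``.
    """
    sequences = list(sequences)
    if not sequences:
        raise InvalidArgumentError("sequences must be non-empty")
    symbols = sorted({t for s in sequences for t in s.tokens if t != PAUSE})
    steps: dict[str, dict] = {}
    for s in sequences:
        counts = steps.setdefault(s.step_id, {sym: 0 for sym in symbols})
        for t in s.tokens:
            if t != PAUSE:
                counts[t] += 1
    df = pd.DataFrame.from_dict(steps, orient="index", columns=symbols).fillna(0.0)
    totals = df.sum(axis=1)
    empty = [str(i) for i in df.index[totals == 0]]
    if empty:
        log.warning("steps with no events: %s", empty)
    df = df.div(totals.where(totals > 0, 1.0), axis=0)
    df.attrs["empty_steps"] = empty
    return df


# ---------------------------------------------------------------------------
# plain-text serialization


def _paths(stem) -> tuple[Path, Path, Path]:
    stem = Path(stem)
    return (stem.with_name(stem.name + ".tokens.txt"),
            stem.with_name(stem.name + ".meta.yaml"),
            stem.with_name(stem.name + ".times.csv"))


def write_sequence(seq: SymbolSequence, stem) -> None:
    """Write ``<stem>.tokens.txt`` / ``.meta.yaml`` / ``.times.csv``."""
    tok_p, meta_p, times_p = _paths(stem)
    tok_p.parent.mkdir(parents=True, exist_ok=True)
    tok_p.write_text(" ".join(seq.tokens) + ("\n" if seq.tokens else ""))
    meta = {"segment_id": seq.segment_id, "step_id": seq.step_id,
            "maneuver": seq.maneuver, "pause_duration_s": seq.pause_duration_s,
            "alphabet": sorted({t for t in seq.tokens if t != PAUSE})}
    meta_p.write_text(yaml.safe_dump(meta, sort_keys=True))
    labels = [t for t in seq.tokens if t != PAUSE]
    pd.DataFrame({"time_s": seq.event_times,
                  "label": labels[:len(seq.event_times)]}).to_csv(times_p, index=False)


def read_sequence(stem) -> SymbolSequence:
    """Read a sequence written by :func:`write_sequence` (lossless)."""
    tok_p, meta_p, times_p = _paths(stem)
    meta = yaml.safe_load(meta_p.read_text()) if meta_p.exists() else {}
    allowed = set(meta.get("alphabet") or []) | {PAUSE}
    tokens: list[str] = []
    for lineno, line in enumerate(tok_p.read_text().splitlines(), start=1):
        for tok in line.split():
            if not _TOKEN_RE.match(tok) or (meta.get("alphabet") and tok not in allowed):
                raise ParseError(f"{tok_p}:{lineno}: unknown token {tok!r}")
            tokens.append(tok)
    times = np.array([])
    if times_p.exists():
        tdf = pd.read_csv(times_p)
        times = tdf["time_s"].to_numpy(dtype=float) if len(tdf) else np.array([])
    return SymbolSequence(tokens, times,
                          segment_id=meta.get("segment_id", ""),
                          step_id=meta.get("step_id", ""),
                          maneuver=meta.get("maneuver", ""),
                          pause_duration_s=meta.get("pause_duration_s"))
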