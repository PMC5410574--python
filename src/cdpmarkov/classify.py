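"""Likelihood-based identification of functional states.

One first-order transition model per (segment, time step), fit with
additive smoothing so held-out transitions never have zero probability; a
held-out suffix (the last k events of a step, pauses carried along) is
scored under every candidate model of its segment, and the top-ranked
model's maneuver is the prediction.  Success means maneuver-type match:
confusing two control steps is not an error.  The evaluation reports
accuracy versus test length, top-k success rates, a per-step consensus
across segments, and a Monte-Carlo random-classifier baseline.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (InsufficientDataError, InvalidArgumentError,
                     InvalidSymbolError)
from .markov import pair_counts
from .symbolize import PAUSE, SymbolSequence

__all__ = ["StepModel", "ModelSet", "Prediction", "EvalReport",
           "fit_model", "loglik", "split_holdout", "predict", "evaluate",
           "topk_rates", "consensus", "random_baseline", "analytic_baseline"]

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.5
DEFAULT_K_LENGTHS = (50, 100, 150, 200, 250, 300)


@dataclass(frozen=True)
class StepModel:
    segment_id: str
    step_id: str
    maneuver: str
    alphabet: tuple[str, ...]
    probs: np.ndarray  # (m, m) row-stochastic when smoothing_alpha > 0
    smoothing_alpha: float
    trained_on: int  # token count


@dataclass
class ModelSet:
    models: dict  # (segment_id, step_id) -> StepModel

    def for_segment(self, segment_id: str) -> list[StepModel]:
        return [m for (seg, _), m in sorted(self.models.items()) if seg == segment_id]


@dataclass
class Prediction:
    segment_id: str
    true_step: str
    true_maneuver: str
    ranking: list  # (step_id, loglik), descending
    predicted_step: str
    predicted_maneuver: str

    @property
    def success(self) -> bool:
        return self.predicted_maneuver == self.true_maneuver

    @property
    def exact_success(self) -> bool:
        return self.predicted_step == self.true_step


@dataclass
class EvalReport:
    accuracy_by_length: pd.DataFrame  # index: test length; columns: maneuver/exact %
    success_flags: pd.DataFrame  # segment x step booleans at the reference length
    topk: pd.Series  # k -> success %
    consensus_by_step: pd.Series  # step -> consensus maneuver
    consensus_accuracy: float  # %
    baseline_percent: float  # Monte-Carlo random-classifier baseline
    predictions: dict = field(default_factory=dict, repr=False)  # length -> [Prediction]
    skipped: list = field(default_factory=list)


# ---------------------------------------------------------------------------


def _tokens_of(seq) -> list[str]:
    return list(seq.tokens) if isinstance(seq, SymbolSequence) else list(seq)


def fit_model(seq, alpha: float = DEFAULT_ALPHA, alphabet=None,
              segment_id: str = "", step_id: str = "", maneuver: str = "") -> StepModel:
    """Additively smoothed transition probabilities from one sequence.

    probs = (counts + alpha) / (row_sum + alpha * m); alpha = 0 reproduces
    the plain row-normalized estimate, leaving unseen rows at zero.
    """
    tokens = _tokens_of(seq)
    if len(tokens) < 2:
        raise InsufficientDataError("need at least 2 tokens to fit a model")
    if alpha < 0:
        raise InvalidArgumentError("alpha must be >= 0")
    if isinstance(seq, SymbolSequence):
        segment_id = segment_id or seq.segment_id
        step_id = step_id or seq.step_id
        maneuver = maneuver or seq.maneuver
    pc = pair_counts(tokens, alphabet=alphabet)
    m = len(pc.alphabet)
    c = pc.counts.astype(float) + alpha
    row = c.sum(axis=1)
    probs = np.zeros((m, m))
    np.divide(c, row[:, None], out=probs, where=row[:, None] > 0)
    return StepModel(segment_id, step_id, maneuver, pc.alphabet, probs,
                     float(alpha), len(tokens))


def loglik(seq, model: StepModel) -> float:
    """Log-likelihood of a token sequence under a step model.

    Sum of log transition probabilities over adjacent pairs; 0 for empty or
    singleton sequences; -inf (logged) if an unsmoothed model assigns a
    transition zero probability.
    """
    tokens = _tokens_of(seq)
    index = {s: i for i, s in enumerate(model.alphabet)}
    try:
        ints = [index[t] for t in tokens]
    except KeyError as exc:
        raise InvalidSymbolError(f"token {exc} not in model alphabet") from exc
    if len(ints) < 2:
        return 0.0
    p = model.probs[ints[:-1], ints[1:]]
    if np.any(p == 0):
        log.warning("zero-probability transition under unsmoothed model %s/%s",
                    model.segment_id, model.step_id)
        return float("-inf")
    return float(np.log(p).sum())


def split_holdout(seq: SymbolSequence, k_events: int = 100):
    """Split off the suffix holding exactly the last ``k_events`` non-pause
    tokens (with the pauses interleaved among them); train is the prefix.
    Concatenating train and test restores the original."""
    tokens = seq.tokens
    n_events = seq.n_events
    if n_events <= k_events:
        raise InsufficientDataError(
            f"sequence has {n_events} events; need more than {k_events}")
    seen = 0
    cut = len(tokens)
    for i in range(len(tokens) - 1, -1, -1):
        if tokens[i] != PAUSE:
            seen += 1
            if seen == k_events:
                cut = i
                break
    times = seq.event_times
    t_cut = n_events - k_events if len(times) else 0
    train = SymbolSequence(tokens[:cut], times[:t_cut] if len(times) else [],
                           seq.segment_id, seq.step_id, seq.maneuver,
                           seq.pause_duration_s)
    test = SymbolSequence(tokens[cut:], times[t_cut:] if len(times) else [],
                          seq.segment_id, seq.step_id, seq.maneuver,
                          seq.pause_duration_s)
    return train, test


def predict(test_seq, candidates: list[StepModel]) -> Prediction:
    """Rank one segment's candidate models by log-likelihood.

    Ties go to the earlier step (and are logged); the prediction is the
    maneuver of the top-ranked step.
    """
    if not candidates:
        raise InvalidArgumentError("need at least one candidate model")
    lls = [(m.step_id, loglik(test_seq, m), m.maneuver) for m in candidates]
    best = max(ll for _, ll, _ in lls)
    if sum(1 for _, ll, _ in lls if ll == best) > 1:
        log.info("log-likelihood tie broken toward the earlier step")
    ranking = sorted(lls, key=lambda x: -x[1])  # stable: earlier step wins ties
    true_step = getattr(test_seq, "step_id", "")
    true_man = getattr(test_seq, "maneuver", "")
    return Prediction(candidates[0].segment_id, true_step, true_man,
                      [(s, ll) for s, ll, _ in ranking],
                      ranking[0][0], ranking[0][2])


def topk_rates(predictions: list[Prediction], ks=(1, 2, 3, 4)) -> pd.Series:
    """Success % when the true maneuver may appear anywhere in the top k."""
    if any(k < 1 for k in ks):
        raise InvalidArgumentError("k must be >= 1")
    rates = {}
    for k in ks:
        ok = sum(any(_maneuver_of_step(s) == p.true_maneuver
                     for s, _ in p.ranking[:k])
                 for p in predictions)
        rates[k] = 100.0 * ok / len(predictions) if predictions else float("nan")
    return pd.Series(rates, name="topk_percent")


def _maneuver_of_step(step_id: str) -> str:
    # step ids follow "<maneuver>_<index>"
    return step_id.rsplit("_", 1)[0]


def consensus(predictions: list[Prediction]) -> str:
    """Modal predicted maneuver across segments for one step.

    Vote ties are broken by the highest summed log-likelihood of each
    maneuver's best-ranked step across segments.
    """
    if not predictions:
        raise InvalidArgumentError("need at least one prediction")
    votes = Counter(p.predicted_maneuver for p in predictions)
    top = max(votes.values())
    tied = [m for m, c in votes.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    scores = {m: 0.0 for m in tied}
    for p in predictions:
        for m in tied:
            best = max((ll for s, ll in p.ranking if _maneuver_of_step(s) == m),
                       default=float("-inf"))
            scores[m] += best
    return max(tied, key=lambda m: scores[m])


def evaluate(sequences: dict, step_maneuvers: dict,
             k_lengths=DEFAULT_K_LENGTHS, alpha: float = DEFAULT_ALPHA,
             reference_length: int = 100, topk=(1, 2, 3, 4),
             baseline_trials: int = 10_000, baseline_seed=0) -> EvalReport:
    """Hold-out evaluation over a whole experiment.

    ``sequences`` maps (segment_id, step_id) to a SymbolSequence.  For each
    test length k: every step's last k events are held out, all models are
    refit on the remainders, and each held-out suffix is scored against its
    segment's models.  Cells with too few events are skipped and flagged.
    """
    keys = sorted(sequences)
    segments = sorted({seg for seg, _ in keys})
    skipped: list = []
    predictions_by_len: dict[int, list[Prediction]] = {}
    alphabet = tuple(sorted({t for s in sequences.values() for t in _tokens_of(s)}))

    rows = []
    for klen in sorted(set(k_lengths)):
        preds: list[Prediction] = []
        for seg in segments:
            seg_keys = [k for k in keys if k[0] == seg]
            splits = {}
            for key in seg_keys:
                try:
                    splits[key] = split_holdout(sequences[key], klen)
                except InsufficientDataError:
                    skipped.append((key, klen))
            models = [fit_model(splits[key][0], alpha=alpha, alphabet=alphabet,
                                segment_id=key[0], step_id=key[1],
                                maneuver=step_maneuvers[key[1]])
                      for key in seg_keys if key in splits]
            if not models:
                continue
            for key in seg_keys:
                if key not in splits:
                    continue
                test = splits[key][1]
                test.maneuver = step_maneuvers[key[1]]
                preds.append(predict(test, models))
        predictions_by_len[klen] = preds
        if preds:
            rows.append({"length": klen,
                         "maneuver_percent": 100.0 * np.mean([p.success for p in preds]),
                         "exact_percent": 100.0 * np.mean([p.exact_success for p in preds])})
    acc = pd.DataFrame(rows).set_index("length") if rows else pd.DataFrame()

    ref = reference_length if reference_length in predictions_by_len else sorted(predictions_by_len)[0]
    ref_preds = predictions_by_len[ref]
    flags = pd.DataFrame(False, index=segments,
                         columns=sorted({k[1] for k in keys}))
    for p in ref_preds:
        flags.loc[p.segment_id, p.true_step] = p.success
    tk = topk_rates(ref_preds, ks=topk)

    cons = {}
    n_cons_ok = 0
    steps = sorted({k[1] for k in keys})
    for step in steps:
        sp = [p for p in ref_preds if p.true_step == step]
        if sp:
            cons[step] = consensus(sp)
            n_cons_ok += cons[step] == step_maneuvers[step]
    cons_acc = 100.0 * n_cons_ok / len(cons) if cons else float("nan")

    man_counts = Counter(step_maneuvers[s] for s in steps)
    base = random_baseline(man_counts, n_trials=baseline_trials, seed=baseline_seed)

    return EvalReport(acc, flags, tk, pd.Series(cons), cons_acc, base,
                      predictions=predictions_by_len, skipped=skipped)


# ---------------------------------------------------------------------------
# random-classifier baseline


def analytic_baseline(maneuver_step_counts: dict) -> float:
    """Exact success % of a uniform random classifier: 100 * sum (n_t/N)^2."""
    counts = np.array(list(maneuver_step_counts.values()), dtype=float)
    if counts.size == 0 or np.any(counts <= 0):
        raise InvalidArgumentError("counts must be positive")
    frac = counts / counts.sum()
    return float(100.0 * (frac ** 2).sum())


def random_baseline(maneuver_step_counts: dict, n_trials: int = 10_000,
                    seed=None) -> float:
    """Monte-Carlo success % when both the true and the predicted step are
    uniform over all steps and success is maneuver match."""
    counts = {k: int(v) for k, v in dict(maneuver_step_counts).items()}
    if not counts or any(v <= 0 for v in counts.values()):
        raise InvalidArgumentError("counts must be positive")
    if n_trials < 1:
        raise InvalidArgumentError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(counts)), list(counts.values()))
    true = labels[rng.integers(len(labels), size=n_trials)]
    pred = labels[rng.integers(len(labels), size=n_trials)]
    return float(100.0 * np.mean(true == pred))
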