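"""Markov-order analysis of symbol sequences.

Estimates first-order transition structure from labelled event sequences
(pause symbol ``$`` included as an ordinary state) and tests the Markov
order of the process:

* order 0 vs. order 1 — Pearson chi-square goodness of fit of the observed
  pair counts against the independence expectation, and a randomized test
  using symbol-histogram-preserving permutation surrogates;
* order 1 vs. order 2 — a randomized test whose null distribution comes
  from pair-count-preserving (Whittle) surrogates, sampled uniformly over
  all sequences with the original's transition counts via random
  spanning-arborescence (BEST-theorem) Eulerian-trail sampling.

Sequences are plain lists of string tokens; alphabets are inferred from
the data and ordered deterministically (sorted, which places ``$`` first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedCellError,
)

__all__ = [
    "PairCounts",
    "TransitionMatrix",
    "IndependenceExpectation",
    "OrderTestResult",
    "pair_counts",
    "transition_probs",
    "independence_expected",
    "chi2_divergence",
    "chi2_test_order1",
    "permutation_test_order1",
    "whittle_surrogate",
    "surrogate_test_order2",
    "triplet_counts",
    "enumerate_pair_preserving",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PairCounts:
    """Counts of adjacent symbol pairs; entry (i, j) = # times j follows i."""

    alphabet: tuple[str, ...]
    counts: np.ndarray  # (m, m) non-negative integers

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic estimate P(next = j | current = i).

    Rows of symbols that never occur as a predecessor carry no information;
    they are left at zero and flagged ``supported = False``.
    """

    alphabet: tuple[str, ...]
    probs: np.ndarray
    supported: np.ndarray  # (m,) bool


@dataclass(frozen=True)
class IndependenceExpectation:
    """Expected pair counts under the order-0 (renewal) hypothesis."""

    alphabet: tuple[str, ...]
    expected: np.ndarray  # (m, m), entry (i, j) = n * P(i) * P(j)


@dataclass(frozen=True)
class OrderTestResult:
    """Outcome of a Markov-order hypothesis test.

    ``df`` is set for the analytic chi-square variant; ``null_statistics``
    holds the surrogate null sample for randomized variants.
    """

    statistic: float
    p_value: float
    df: int | None = None
    n_surrogates: int | None = None
    seed: int | None = None
    method: str = ""
    null_statistics: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# encoding helpers


def _alphabet_of(seq: list[str]) -> tuple[str, ...]:
    return tuple(sorted(set(seq)))


def _encode(seq, alphabet=None):
    seq = list(seq)
    if alphabet is None:
        alphabet = _alphabet_of(seq)
    index = {s: i for i, s in enumerate(alphabet)}
    try:
        ints = np.fromiter((index[s] for s in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:  # pragma: no cover - guarded by callers
        raise InvalidArgumentError(f"token {exc} not in alphabet") from exc
    return ints, tuple(alphabet)


def _pair_count_matrix(ints: np.ndarray, m: int) -> np.ndarray:
    codes = ints[:-1] * m + ints[1:]
    return np.bincount(codes, minlength=m * m).reshape(m, m)


# ---------------------------------------------------------------------------
# estimation


def pair_counts(seq, alphabet=None) -> PairCounts:
    """Count adjacent symbol pairs over the whole sequence.

    Pauses are ordinary symbols, contributing a ``$`` row and column.
    """
    seq = list(seq)
    if len(seq) < 2:
        raise InsufficientDataError("need at least 2 tokens to count pairs")
    ints, alphabet = _encode(seq, alphabet)
    return PairCounts(alphabet, _pair_count_matrix(ints, len(alphabet)))


def transition_probs(counts: PairCounts) -> TransitionMatrix:
    """Row-normalize pair counts into P(c_j | c_i)."""
    if counts.total() < 1:
        raise InsufficientDataError("no pairs observed")
    c = counts.counts.astype(float)
    row = c.sum(axis=1)
    supported = row > 0
    probs = np.zeros_like(c)
    probs[supported] = c[supported] / row[supported, None]
    return TransitionMatrix(counts.alphabet, probs, supported)


def independence_expected(seq, alphabet=None) -> IndependenceExpectation:
    """Expected pair counts if consecutive symbols were independent.

    E[i, j] = n * P(i) * P(j) with marginal frequencies taken over the whole
    sequence and n the number of adjacent pairs (length - 1), so that the
    expected and observed tables share the same total.
    """
    seq = list(seq)
    if len(seq) < 2:
        raise InsufficientDataError("need at least 2 tokens")
    ints, alphabet = _encode(seq, alphabet)
    m = len(alphabet)
    p = np.bincount(ints, minlength=m) / len(ints)
    expected = (len(ints) - 1) * np.outer(p, p)
    return IndependenceExpectation(alphabet, expected)


def chi2_divergence(observed: PairCounts, expected: IndependenceExpectation) -> float:
    """Pearson divergence sum (O - E)^2 / E over cells with E > 0.

    Cells with E = 0 and O = 0 contribute nothing; E = 0 with O > 0 cannot
    arise when both tables come from the same sequence and is rejected.
    """
    O = np.asarray(observed.counts, dtype=float)
    E = np.asarray(expected.expected, dtype=float)
    if O.shape != E.shape:
        raise InvalidArgumentError("observed/expected shapes differ")
    if np.any((E == 0) & (O > 0)):
        raise UndefinedCellError("observed counts in a cell with zero expectation")
    mask = E > 0
    return float(((O[mask] - E[mask]) ** 2 / E[mask]).sum())


def _divergence_ints(ints: np.ndarray, m: int, E: np.ndarray, mask: np.ndarray) -> float:
    O = _pair_count_matrix(ints, m)
    return float(((O[mask] - E[mask]) ** 2 / E[mask]).sum())


# ---------------------------------------------------------------------------
# order-1 tests


def chi2_test_order1(seq) -> OrderTestResult:
    """Pearson chi-square test of order 0 (renewal) against order 1.

    Degrees of freedom are (m - 1)^2 for alphabet size m (pause included):
    the marginals are estimated from the sequence itself, which removes
    2(m - 1) + 1 constraints from the m^2 cells.  The often-quoted
    m(m - 1) figure makes the test conservative; simulation of the null
    confirms the (m - 1)^2 calibration (see the package methods note).
    """
    seq = list(seq)
    if len(seq) < 2:
        raise InsufficientDataError("need at least 2 tokens")
    obs = pair_counts(seq)
    exp = independence_expected(seq, alphabet=obs.alphabet)
    statistic = chi2_divergence(obs, exp)
    m = len(obs.alphabet)
    df = (m - 1) ** 2
    p = float(_stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return OrderTestResult(statistic, max(p, np.finfo(float).tiny), df=df,
                           method="chi2-order1")


def permutation_test_order1(seq, n_surrogates: int = 10_000, seed=None) -> OrderTestResult:
    """Randomized order-0-vs-order-1 test with permutation surrogates.

    Each surrogate is a uniform random permutation of the sequence, which
    preserves the symbol histogram exactly while destroying any sequential
    structure.  The divergence of each surrogate is computed against the
    (shared) independence expectation; p = (1 + #{null >= observed}) /
    (1 + n_surrogates), so p is never zero.
    """
    seq = list(seq)
    if len(seq) < 3:
        raise InsufficientDataError("need at least 3 tokens")
    if n_surrogates < 1:
        raise InvalidArgumentError("n_surrogates must be >= 1")
    rng = np.random.default_rng(seed)
    ints, alphabet = _encode(seq)
    m = len(alphabet)
    exp = independence_expected(seq, alphabet=alphabet)
    E, mask = exp.expected, exp.expected > 0
    observed = _divergence_ints(ints, m, E, mask)

    null = np.empty(n_surrogates)
    chunk = max(1, min(n_surrogates, 4_000_000 // max(len(ints), 1)))
    done = 0
    Eflat = E.ravel()
    sel = mask.ravel()
    while done < n_surrogates:
        b = min(chunk, n_surrogates - done)
        batch = rng.permuted(np.broadcast_to(ints, (b, len(ints))), axis=1)
        codes = batch[:, :-1] * m + batch[:, 1:]
        offs = (np.arange(b) * (m * m))[:, None]
        O = np.bincount((codes + offs).ravel(), minlength=b * m * m).reshape(b, m * m)
        null[done:done + b] = (((O[:, sel] - Eflat[sel]) ** 2) / Eflat[sel]).sum(axis=1)
        done += b
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_surrogates)
    return OrderTestResult(observed, p, n_surrogates=n_surrogates,
                           seed=None if seed is None or not np.isscalar(seed) else int(seed),
                           method="permutation-order1", null_statistics=null)


# ---------------------------------------------------------------------------
# Whittle (pair-preserving) surrogates


def _wilson_arborescence(C: np.ndarray, root: int, rng) -> np.ndarray:
    """Uniform random arborescence oriented toward ``root``.

    Wilson's loop-erased random-walk algorithm on the directed multigraph
    with edge multiplicities ``C``; transition u -> v with probability
    proportional to C[u, v] makes every edge-level arborescence equally
    likely.  Vertices with no outgoing edges are ignored.
    """
    m = C.shape[0]
    cum = np.cumsum(C, axis=1)
    rowsum = cum[:, -1]
    in_tree = np.zeros(m, dtype=bool)
    in_tree[root] = True
    nxt = np.full(m, -1, dtype=np.int64)
    for u in range(m):
        if rowsum[u] == 0 or in_tree[u]:
            continue
        v = u
        while not in_tree[v]:
            nxt[v] = int(np.searchsorted(cum[v], rng.integers(rowsum[v]), side="right"))
            v = nxt[v]
        v = u
        while not in_tree[v]:
            in_tree[v] = True
            v = nxt[v]
    return nxt


def _euler_surrogate_ints(ints: np.ndarray, m: int, rng) -> np.ndarray:
    """One uniform draw from the sequences sharing ``ints``'s pair counts.

    The transition multigraph is closed into an Eulerian circuit by one
    auxiliary edge (last -> first).  A uniform arborescence toward the
    circuit's start vertex plus uniform orderings of the remaining
    out-edges (tree edge last) is, by the BEST theorem, a bijection onto
    Eulerian circuits through the auxiliary edge — i.e. onto trails from
    the first to the last symbol.
    """
    n = len(ints)
    first, last = int(ints[0]), int(ints[-1])
    C = _pair_count_matrix(ints, m)
    C[last, first] += 1

    nxt = _wilson_arborescence(C, root=last, rng=rng)

    succ: list[list[int]] = [[] for _ in range(m)]
    for u in range(m):
        deg = int(C[u].sum())
        if deg == 0:
            continue
        targets = np.repeat(np.arange(m), C[u])
        if u == last:
            forced = first  # the auxiliary edge starts the circuit
        else:
            forced = int(nxt[u])  # tree edge must be used last
        pos = int(np.searchsorted(targets, forced))
        targets = np.delete(targets, pos)
        rng.shuffle(targets)
        if u == last:
            order = np.concatenate(([forced], targets))
        else:
            order = np.concatenate((targets, [forced]))
        succ[u] = order.tolist()

    out = np.empty(n, dtype=np.int64)
    ptr = [0] * m
    cur = last
    for t in range(n):
        nxt_v = succ[cur][ptr[cur]]
        ptr[cur] += 1
        out[t] = nxt_v
        cur = nxt_v
    return out


def whittle_surrogate(seq, seed=None) -> list[str]:
    """Random sequence with exactly the input's pair counts.

    Sampled uniformly over all sequences sharing the pair-count matrix and
    the initial symbol (the endpoints are fixed by the counts whenever the
    transition multigraph is unbalanced; for balanced inputs the starting
    symbol is conserved by convention, matching the enumeration oracle).
    """
    seq = list(seq)
    if len(seq) < 3:
        raise InsufficientDataError("need at least 3 tokens")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ints, alphabet = _encode(seq)
    out = _euler_surrogate_ints(ints, len(alphabet), rng)
    return [alphabet[i] for i in out]


def enumerate_pair_preserving(seq) -> set[tuple[str, ...]]:
    """All sequences with the input's pair counts and initial symbol.

    Brute-force depth-first enumeration of Eulerian trails of the
    transition multigraph; exponential, intended as an exactness oracle
    for small inputs (length <= ~10).
    """
    seq = list(seq)
    if len(seq) < 2:
        return {tuple(seq)}
    ints, alphabet = _encode(seq)
    m = len(alphabet)
    C = _pair_count_matrix(ints, m)
    n_edges = int(C.sum())
    found: set[tuple[int, ...]] = set()
    path = [int(ints[0])]

    def walk(cur: int, used: int) -> None:
        if used == n_edges:
            found.add(tuple(path))
            return
        for j in range(m):
            if C[cur, j] > 0:
                C[cur, j] -= 1
                path.append(j)
                walk(j, used + 1)
                path.pop()
                C[cur, j] += 1

    walk(int(ints[0]), 0)
    return {tuple(alphabet[i] for i in t) for t in found}


# ---------------------------------------------------------------------------
# order-2 test


def triplet_counts(seq, alphabet=None):
    """Counts of adjacent symbol triplets as an (m, m, m) tensor.

    For an alphabet of 13 symbols the tensor has 13^3 = 2197 entries, which
    is why a chi-square approximation is unreliable at a few thousand
    tokens and a surrogate null is used instead.
    """
    seq = list(seq)
    if len(seq) < 3:
        raise InsufficientDataError("need at least 3 tokens to count triplets")
    ints, alphabet = _encode(seq, alphabet)
    m = len(alphabet)
    codes = ints[:-2] * m * m + ints[1:-1] * m + ints[2:]
    counts = np.bincount(codes, minlength=m ** 3).reshape(m, m, m)
    return alphabet, counts


def _order2_statistic(ints: np.ndarray, m: int) -> float:
    """Divergence of triplet counts from their order-1 expectation.

    Expected N(i, j, k) = N'(i, j) * P(k | j), with N' the pair counts over
    triplet-prefix positions and P the first-order transition estimate from
    the full sequence.  Whenever a triplet (i, j, k) is observed, both the
    prefix pair (i, j) and the transition (j, k) were observed, so E > 0 on
    every occupied cell.
    """
    codes3 = ints[:-2] * m * m + ints[1:-1] * m + ints[2:]
    O3 = np.bincount(codes3, minlength=m ** 3).reshape(m, m, m)
    Cfull = _pair_count_matrix(ints, m)
    prefix = _pair_count_matrix(ints[:-1], m).astype(float)
    row = Cfull.sum(axis=1)
    P = np.zeros((m, m))
    np.divide(Cfull, row[:, None], out=P, where=row[:, None] > 0)
    E3 = prefix[:, :, None] * P[None, :, :]
    mask = E3 > 0
    return float(((O3[mask] - E3[mask]) ** 2 / E3[mask]).sum())


def surrogate_test_order2(seq, n_surrogates: int = 1_000, seed=None) -> OrderTestResult:
    """Randomized test of order 1 against order 2.

    The statistic is the chi-square-style divergence of observed triplet
    counts from their first-order expectation; the null sample comes from
    Whittle surrogates, which keep all pair counts (hence the fitted
    first-order model) while erasing any genuine triplet structure.
    """
    seq = list(seq)
    if len(seq) < 4:
        raise InsufficientDataError("need at least 4 tokens")
    if n_surrogates < 1:
        raise InvalidArgumentError("n_surrogates must be >= 1")
    rng = np.random.default_rng(seed)
    ints, alphabet = _encode(seq)
    m = len(alphabet)
    observed = _order2_statistic(ints, m)
    null = np.empty(n_surrogates)
    for i in range(n_surrogates):
        null[i] = _order2_statistic(_euler_surrogate_ints(ints, m, rng), m)
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_surrogates)
    return OrderTestResult(observed, p, n_surrogates=n_surrogates,
                           seed=None if seed is None or not np.isscalar(seed) else int(seed),
                           method="whittle-order2", null_statistics=null)
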