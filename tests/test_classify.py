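"""Transition models, log-likelihood scoring, hold-out evaluation."""

import numpy as np
import pytest

from cdpmarkov import (StepModel, SymbolSequence, analytic_baseline, consensus,
                       evaluate, fit_model, loglik, make_experiment,
                       make_state_specs, predict, random_baseline,
                       split_holdout, topk_rates)
from cdpmarkov.errors import (InsufficientDataError, InvalidArgumentError,
                              InvalidSymbolError)


def _seqs_from(exp):
    return {k: SymbolSequence(list(v), [], segment_id=k[0], step_id=k[1],
                              maneuver=exp.step_maneuvers[k[1]])
            for k, v in exp.truth_symbols.items()}


# ---------------------------------------------------------------------------
# model fitting and likelihood


def test_fit_model_unsmoothed_matches_pair_estimate():
    m = fit_model(list("ABAB"), alpha=0.0, alphabet=("A", "B"))
    assert m.probs[0, 1] == pytest.approx(1.0)
    assert m.probs[1, 0] == pytest.approx(1.0)


def test_fit_model_additive_smoothing_hand_value():
    m = fit_model(list("ABAB"), alpha=1.0, alphabet=("A", "B"))
    assert m.probs[0, 1] == pytest.approx(0.75)  # (2+1)/(2+2)
    assert np.all(m.probs > 0)
    assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-9)


def test_fit_model_insufficient():
    with pytest.raises(InsufficientDataError):
        fit_model(["A"])


def test_loglik_deterministic_chain_is_zero():
    m = fit_model(list("ABCABCABC"), alpha=0.0, alphabet=("A", "B", "C"))
    assert loglik(list("ABCABC"), m) == pytest.approx(0.0)


def test_loglik_hand_value():
    probs = np.array([[0.5, 0.5], [1.0, 0.0]])
    m = StepModel("s", "t", "ctrl", ("A", "B"), probs, 0.0, 0)
    assert loglik(list("AAB"), m) == pytest.approx(2 * np.log(0.5))


def test_loglik_unknown_token_and_zero_prob():
    m = fit_model(list("ABAB"), alpha=0.0, alphabet=("A", "B"))
    with pytest.raises(InvalidSymbolError):
        loglik(list("AXA"), m)
    assert loglik(list("AA"), m) == float("-inf")
    assert loglik(["A"], m) == 0.0


def test_loglik_mle_optimality():
    """The unsmoothed fit maximizes its own training likelihood."""
    rng = np.random.default_rng(0)
    seq = [["A", "B", "C"][i] for i in rng.integers(0, 3, 400)]
    mle = fit_model(seq, alpha=0.0, alphabet=("A", "B", "C"))
    best = loglik(seq, mle)
    for _ in range(100):
        Q = rng.dirichlet(np.ones(3), size=3)
        rand = StepModel("s", "t", "x", ("A", "B", "C"), Q, 0.0, 0)
        assert best >= loglik(seq, rand) - 1e-9


def test_smoothed_ranking_converges_to_unsmoothed():
    rng = np.random.default_rng(1)
    train = [["A", "B", "C"][i] for i in rng.integers(0, 3, 500)]
    test = [["A", "B", "C"][i] for i in rng.integers(0, 3, 60)]
    m0 = fit_model(train, alpha=0.0, alphabet=("A", "B", "C"))
    ll0 = loglik(test, m0)
    assert np.isfinite(ll0)  # all transitions seen in training
    for alpha in (1e-3, 1e-6):
        ma = fit_model(train, alpha=alpha, alphabet=("A", "B", "C"))
        assert loglik(test, ma) == pytest.approx(ll0, abs=0.05)


# ---------------------------------------------------------------------------
# hold-out split


def _toy_sequence(n_events=600, pause_every=5):
    toks, times = [], []
    t = 0.0
    for i in range(n_events):
        if i and i % pause_every == 0:
            toks.append("$")
        toks.append("AB"[i % 2])
        t += 0.12
        times.append(t)
    return SymbolSequence(toks, times, "seg", "ctrl_1", "ctrl", 0.12)


def test_split_holdout_counts_and_partition():
    seq = _toy_sequence()
    train, test = split_holdout(seq, 100)
    assert test.n_events == 100
    assert train.tokens + test.tokens == seq.tokens
    assert len(train.event_times) + len(test.event_times) == len(seq.event_times)


def test_split_holdout_span_about_12s():
    seq = _toy_sequence()
    _, test = split_holdout(seq, 100)
    span = test.event_times[-1] - test.event_times[0]
    assert span == pytest.approx(0.12 * 99, rel=0.05)


def test_split_holdout_insufficient():
    with pytest.raises(InsufficientDataError):
        split_holdout(_toy_sequence(80), 100)


# ---------------------------------------------------------------------------
# prediction


def test_predict_single_candidate():
    m = fit_model(list("ABABAB"), alphabet=("A", "B"),
                  segment_id="s", step_id="ctrl_1", maneuver="ctrl")
    seq = SymbolSequence(list("ABA"), [], "s", "ctrl_1", "ctrl")
    p = predict(seq, [m])
    assert p.predicted_step == "ctrl_1" and p.predicted_maneuver == "ctrl"


def test_predict_empty_candidates():
    with pytest.raises(InvalidArgumentError):
        predict(SymbolSequence(["A"], []), [])


def test_predict_counts_maneuver_match_not_exact_step():
    """A sibling step of the same maneuver outranking the true step still
    counts as success."""
    rng = np.random.default_rng(2)
    toks = [["A", "B"][i] for i in rng.integers(0, 2, 300)]
    m1 = fit_model(toks, alphabet=("A", "B"), segment_id="s",
                   step_id="ctrl_1", maneuver="ctrl")
    m2 = fit_model(toks[::-1], alphabet=("A", "B"), segment_id="s",
                   step_id="ctrl_2", maneuver="ctrl")
    seq = SymbolSequence(toks[:50], [], "s", "ctrl_1", "ctrl")
    p = predict(seq, [m1, m2])
    assert p.success  # whichever control step ranks first


def test_separated_states_high_holdout_accuracy():
    specs = make_state_specs({"ctrl": 1, "capsa": 1}, separation=0.4,
                             symbols_per_step=3000, seed=3)
    exp = make_experiment(specs, 4, render=False, seed=4)
    rep = evaluate(_seqs_from(exp), exp.step_maneuvers, k_lengths=(100,))
    assert rep.accuracy_by_length.loc[100, "maneuver_percent"] >= 90.0


def test_evaluate_perfect_separation_limit():
    """States with disjoint alphabet usage are always identified."""
    seqs = {}
    maneuvers = {"a_1": "a", "b_1": "b"}
    for seg in ("S1", "S2"):
        seqs[(seg, "a_1")] = SymbolSequence(list("AB" * 300), [], seg, "a_1", "a")
        seqs[(seg, "b_1")] = SymbolSequence(list("CD" * 300), [], seg, "b_1", "b")
    rep = evaluate(seqs, maneuvers, k_lengths=(50, 100, 200))
    assert (rep.accuracy_by_length["maneuver_percent"] == 100.0).all()


def test_evaluate_skips_short_cells():
    seqs = {("S1", "a_1"): SymbolSequence(list("AB" * 300), [], "S1", "a_1", "a"),
            ("S1", "b_1"): SymbolSequence(list("CD" * 30), [], "S1", "b_1", "b")}
    rep = evaluate(seqs, {"a_1": "a", "b_1": "b"}, k_lengths=(100,))
    assert (("S1", "b_1"), 100) in rep.skipped


# ---------------------------------------------------------------------------
# top-k, consensus, baseline


def test_topk_monotone_and_exhaustive():
    specs = make_state_specs({"ctrl": 2, "capsa": 2}, symbols_per_step=2000, seed=5)
    exp = make_experiment(specs, 3, render=False, seed=6)
    rep = evaluate(_seqs_from(exp), exp.step_maneuvers, k_lengths=(100,),
                   topk=(1, 2, 3, 4))
    rates = rep.topk
    assert (rates.diff().dropna() >= 0).all()
    assert rates[4] == 100.0  # k = number of candidate steps
    assert rates[1] == rep.accuracy_by_length.loc[100, "maneuver_percent"]


def test_consensus_majority_and_single():
    from cdpmarkov.classify import Prediction
    mk_p = lambda man: Prediction("s", "ctrl_1", "ctrl", [(man + "_1", -1.0)],
                                  man + "_1", man)
    preds = [mk_p("ctrl")] * 6 + [mk_p("capsa")] * 5
    assert consensus(preds) == "ctrl"
    assert consensus([mk_p("esp")]) == "esp"


def test_consensus_improves_on_average_segment():
    """Majority vote across 11 segments is at least as accurate as the
    average single segment when per-segment accuracy is high."""
    accs, cons = [], []
    for seed in range(5):
        specs = make_state_specs({"ctrl": 2, "esp": 2, "capsa": 4},
                                 symbols_per_step=2000, seed=20 + seed)
        exp = make_experiment(specs, 11, render=False, seed=30 + seed)
        rep = evaluate(_seqs_from(exp), exp.step_maneuvers, k_lengths=(100,))
        accs.append(rep.accuracy_by_length.loc[100, "maneuver_percent"])
        cons.append(rep.consensus_accuracy)
    assert np.mean(cons) >= np.mean(accs)


def test_random_baseline_printed_configurations():
    assert analytic_baseline({"ctrl": 2, "capsa": 3}) == pytest.approx(52.0)
    assert analytic_baseline({"ctrl": 2, "esp": 2, "capsa": 4}) == pytest.approx(37.5)
    mc = random_baseline({"ctrl": 2, "capsa": 3}, n_trials=200_000, seed=0)
    assert mc == pytest.approx(52.0, abs=0.5)


def test_random_baseline_single_maneuver():
    assert random_baseline({"ctrl": 3}, n_trials=100, seed=0) == 100.0
    assert analytic_baseline({"ctrl": 3}) == 100.0


def test_random_baseline_agrees_with_analytic():
    """Monte Carlo vs exact within 3 binomial standard errors, 20 configs."""
    rng = np.random.default_rng(7)
    for i in range(20):
        counts = {f"m{j}": int(rng.integers(1, 6))
                  for j in range(rng.integers(1, 5))}
        exact = analytic_baseline(counts)
        n = 10_000
        mc = random_baseline(counts, n_trials=n, seed=100 + i)
        se = 100 * np.sqrt(exact / 100 * (1 - exact / 100) / n)
        assert abs(mc - exact) <= max(3 * se, 1e-9)


def test_random_baseline_errors():
    with pytest.raises(InvalidArgumentError):
        random_baseline({}, 100)
    with pytest.raises(InvalidArgumentError):
        random_baseline({"a": 1}, 0)
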