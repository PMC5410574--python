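"""End-to-end orchestration with reproducible configuration.

Stages: simulate (or load pre-symbolized sequences) -> detect -> build
per-segment shape dictionaries -> symbolize -> Markov order tests ->
state classification.  Every report file records the configuration hash
and seed; identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import classify as _classify
from . import dictionary as _dictionary
from . import markov as _markov
from . import simulate as _simulate
from . import symbolize as _symbolize
from .detect import DetectionParams, detect_events, preprocess_event
from .errors import InvalidArgumentError

__all__ = ["RunConfig", "run_pipeline", "robustness_sweep"]

log = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    seed: int = 0
    outdir: str = "results/run"

    # synthetic experiment (ignored when input_sequences_dir is set)
    maneuver_steps: dict[str, int] = Field(
        default_factory=lambda: {"ctrl": 2, "esp": 2, "capsa": 4})
    n_segments: int = 2
    n_shapes: int = 12
    symbols_per_step: int = 600
    separation: float = 0.35
    segment_mix: float = 0.1
    noise_sd: float = _simulate.DEFAULT_NOISE_SD
    pause_duration_s: float = _simulate.DEFAULT_PAUSE_S
    jitter_fraction: float = 0.1
    rate_hz: float = 10_000.0
    render: bool = True

    # detection
    window_ms: float = 100.0
    smooth_cutoff_hz: float = 70.0
    min_amplitude_mv: float = 0.1
    baseline_fraction: float = 0.1
    target_rate_hz: float = 1_600.0

    # dictionary
    variance_target: float = 0.98
    k_min: int = 2
    k_max: int = 15
    forced_k: int | None = None

    # pause rule ($ insertion); None = estimate the mean inter-event gap
    pause_override_s: float | None = None

    # Markov order tests
    n_surrogates_order1: int = 10_000
    n_surrogates_order2: int = 1_000
    run_order2: bool = True

    # classification
    k_lengths: tuple[int, ...] = (50, 100, 150, 200, 250, 300)
    smoothing_alpha: float = 0.5
    topk: tuple[int, ...] = (1, 2, 3, 4)

    make_plots: bool = False
    input_sequences_dir: str | None = None

    @field_validator("maneuver_steps")
    @classmethod
    def _steps_positive(cls, v):
        if not v or any(n < 1 for n in v.values()):
            raise ValueError("maneuver_steps must be non-empty with positive counts")
        return v

    @field_validator("symbols_per_step")
    @classmethod
    def _symbols_cap(cls, v):
        if not 1 <= v <= 6_000:
            raise ValueError("symbols_per_step must be in [1, 6000]")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def detection_params(self) -> DetectionParams:
        return DetectionParams(window_ms=self.window_ms,
                               smooth_cutoff_hz=self.smooth_cutoff_hz,
                               min_amplitude_mv=self.min_amplitude_mv,
                               baseline_fraction=self.baseline_fraction,
                               target_rate_hz=self.target_rate_hz)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


# ---------------------------------------------------------------------------
# stage helpers


def _simulate_stage(config: RunConfig, rng):
    specs = _simulate.make_state_specs(
        config.maneuver_steps, n_shapes=config.n_shapes,
        separation=config.separation, symbols_per_step=config.symbols_per_step,
        seed=rng)
    templates = _simulate.make_templates(
        config.n_shapes, window_ms=config.window_ms, rate_hz=config.rate_hz,
        seed=rng) if config.render else None
    return _simulate.make_experiment(
        specs, config.n_segments, templates=templates, seed=rng,
        segment_mix=config.segment_mix, render=config.render,
        pause_duration_s=config.pause_duration_s,
        jitter_sd_s=config.jitter_fraction * config.pause_duration_s,
        noise_sd=config.noise_sd, rate_hz=config.rate_hz)


def _extract_windows(experiment, params: DetectionParams):
    """Detect and preprocess events for every rendered recording."""
    windows, times = {}, {}
    for key, rec in sorted(experiment.recordings.items()):
        events = [preprocess_event(e, params) for e in detect_events(rec, params)]
        events = [e for e in events if e.processed_window is not None]
        windows[key] = np.array([e.processed_window for e in events])
        times[key] = np.array([e.peak_time_s for e in events])
    return windows, times


def _build_dictionaries(windows, config: RunConfig, seed):
    """One dictionary per segment, pooled over that segment's steps."""
    dictionaries = {}
    segments = sorted({seg for seg, _ in windows})
    for i, seg in enumerate(segments):
        pool = np.vstack([w for (s, _), w in sorted(windows.items()) if s == seg and len(w)])
        basis, recon = _dictionary.pca_reduce(pool, config.variance_target)
        if config.forced_k is not None:
            k = config.forced_k
        else:
            kmax = min(config.k_max, len(recon) - 1)
            k = _dictionary.choose_k(recon, range(config.k_min, kmax + 1), seed=seed + i)
        dictionaries[seg] = _dictionary.fit_dictionary(recon, k, seed=seed + i, pca=basis)
    return dictionaries


def _symbolize_stage(windows, times, dictionaries, step_maneuvers, config: RunConfig):
    sequences = {}
    for (seg, step), w in sorted(windows.items()):
        labels = [_dictionary.label_event(x, dictionaries[seg]) for x in w]
        t = times[(seg, step)]
        if config.pause_override_s is not None:
            pause = _symbolize.PauseModel(config.pause_override_s)
        elif len(t) >= 2:
            pause = _symbolize.estimate_pause_duration(t)
        else:
            pause = _symbolize.PauseModel(config.pause_duration_s)
        sequences[(seg, step)] = _symbolize.discretize(
            labels, t, pause, segment_id=seg, step_id=step,
            maneuver=step_maneuvers.get(step, ""))
    return sequences


def _markov_stage(sequences, config: RunConfig, seed):
    rows = []
    for i, (key, seq) in enumerate(sorted(sequences.items())):
        toks = seq.tokens
        chi = _markov.chi2_test_order1(toks)
        perm = _markov.permutation_test_order1(
            toks, n_surrogates=config.n_surrogates_order1, seed=seed + 2 * i)
        row = {"segment": key[0], "step": key[1], "n_tokens": len(toks),
               "chi2_stat": chi.statistic, "chi2_df": chi.df, "chi2_p": chi.p_value,
               "perm_stat": perm.statistic, "perm_p": perm.p_value,
               "perm_n_surrogates": perm.n_surrogates}
        if config.run_order2 and len(toks) >= 4:
            o2 = _markov.surrogate_test_order2(
                toks, n_surrogates=config.n_surrogates_order2, seed=seed + 2 * i + 1)
            row.update(order2_stat=o2.statistic, order2_p=o2.p_value,
                       order2_n_surrogates=o2.n_surrogates)
        rows.append(row)
    return pd.DataFrame(rows)


def _load_sequences(directory):
    directory = Path(directory)
    stems = sorted({p.name[:-len(".tokens.txt")] for p in directory.glob("*.tokens.txt")})
    if not stems:
        raise InvalidArgumentError(f"no *.tokens.txt files under {directory}")
    sequences, step_maneuvers = {}, {}
    for stem in stems:
        seq = _symbolize.read_sequence(directory / stem)
        sequences[(seq.segment_id, seq.step_id)] = seq
        step_maneuvers[seq.step_id] = seq.maneuver
    return sequences, step_maneuvers


# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and persist reports under ``config.outdir``.

    Returns the in-memory artifacts (experiment, sequences, dictionaries,
    Markov test table, evaluation report).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (out / "config.json").write_text(json.dumps(
        {"config_hash": chash, **config.model_dump(mode="json")}, indent=2, sort_keys=True))

    seed0 = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2 ** 31))
    artifacts: dict = {"config_hash": chash}

    if config.input_sequences_dir:
        sequences, step_maneuvers = _load_sequences(config.input_sequences_dir)
        experiment = None
    else:
        rng = np.random.default_rng(config.seed)
        experiment = _simulate_stage(config, rng)
        step_maneuvers = experiment.step_maneuvers
        if config.render:
            windows, times = _extract_windows(experiment, config.detection_params())
            dictionaries = _build_dictionaries(windows, config, seed0)
            artifacts["dictionaries"] = dictionaries
            sequences = _symbolize_stage(windows, times, dictionaries,
                                         step_maneuvers, config)
        else:
            sequences = {key: _symbolize.SymbolSequence(
                list(toks), [], segment_id=key[0], step_id=key[1],
                maneuver=step_maneuvers[key[1]])
                for key, toks in experiment.truth_symbols.items()}
    artifacts["experiment"] = experiment
    artifacts["sequences"] = sequences

    seq_dir = out / "sequences"
    for (seg, step), seq in sorted(sequences.items()):
        _symbolize.write_sequence(seq, seq_dir / f"{seg}_{step}")

    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for (seg, step), seq in sorted(sequences.items()):
        tm = _markov.transition_probs(_markov.pair_counts(seq.tokens))
        pd.DataFrame(tm.probs, index=tm.alphabet, columns=tm.alphabet).to_csv(
            mat_dir / f"{seg}_{step}.csv")

    tests = _markov_stage(sequences, config, seed0 + 1000)
    tests.insert(0, "config_hash", chash)
    tests.to_csv(out / "markov_tests.csv", index=False)
    artifacts["markov_tests"] = tests

    max_len = max(config.k_lengths)
    usable = {k: s for k, s in sequences.items() if s.n_events > max_len}
    if usable:
        report = _classify.evaluate(usable, step_maneuvers,
                                    k_lengths=config.k_lengths,
                                    alpha=config.smoothing_alpha,
                                    topk=config.topk,
                                    baseline_seed=seed0 + 7)
        report.accuracy_by_length.to_csv(out / "accuracy_by_length.csv")
        report.topk.rename_axis("k").to_csv(out / "topk.csv")
        report.consensus_by_step.rename_axis("step").to_csv(
            out / "consensus.csv", header=["consensus_maneuver"])
        (out / "classification.yaml").write_text(yaml.safe_dump(
            {"config_hash": chash, "seed": config.seed,
             "consensus_accuracy_percent": float(report.consensus_accuracy),
             "random_baseline_percent": float(report.baseline_percent)}))
        artifacts["evaluation"] = report
    else:
        log.warning("no sequence has more than %d events; classification skipped", max_len)

    if config.make_plots and "dictionaries" in artifacts:
        from .plotting import plot_dictionary, plot_transition_heatmap
        for seg, dic in artifacts["dictionaries"].items():
            plot_dictionary(dic, path=out / f"dictionary_{seg}.png")
        key = sorted(sequences)[0]
        tm = _markov.transition_probs(_markov.pair_counts(sequences[key].tokens))
        plot_transition_heatmap(tm, path=out / f"transitions_{key[0]}_{key[1]}.png")

    return artifacts


def robustness_sweep(config: RunConfig, k_values) -> pd.DataFrame:
    """Re-run the order-1 permutation test at forced dictionary sizes.

    For each forced k the per-segment dictionaries are rebuilt, events are
    relabelled and re-discretized, and the permutation test runs on every
    (segment, step) sequence; the reported p-value per k is the maximum
    over sequences.  Infeasible k are flagged and skipped.
    """
    if not config.render or config.input_sequences_dir:
        raise InvalidArgumentError("robustness_sweep needs rendered recordings")
    rng = np.random.default_rng(config.seed)
    experiment = _simulate_stage(config, rng)
    params = config.detection_params()
    windows, times = _extract_windows(experiment, params)
    seed0 = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2 ** 31))

    rows = []
    for k in k_values:
        if k < 2 or any(len(w) <= k for w in windows.values()):
            log.warning("forced k=%s infeasible; skipped", k)
            rows.append({"k": k, "max_p": np.nan, "n_sequences": 0, "feasible": False})
            continue
        cfg_k = config.model_copy(update={"forced_k": int(k)})
        dictionaries = _build_dictionaries(windows, cfg_k, seed0 + 13 * k)
        sequences = _symbolize_stage(windows, times, dictionaries,
                                     experiment.step_maneuvers, cfg_k)
        ps = []
        for i, (key, seq) in enumerate(sorted(sequences.items())):
            if len(set(seq.tokens)) < 2:
                log.warning("degenerate single-symbol sequence for %s; skipped", key)
                continue
            res = _markov.permutation_test_order1(
                seq.tokens, n_surrogates=config.n_surrogates_order1,
                seed=seed0 + 97 * k + i)
            ps.append(res.p_value)
        rows.append({"k": k, "max_p": max(ps) if ps else np.nan,
                     "n_sequences": len(ps), "feasible": bool(ps)})
    df = pd.DataFrame(rows)
    df.insert(0, "config_hash", config.config_hash())
    return df
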