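#!/usr/bin/env python
"""Generate the synthetic experiments used by the downstream analyses.

Two artefacts are produced under results/analysis/:

* ``sequences/`` — a sequence-level experiment with the 2-control,
  2-spinalization, 4-capsaicin step layout over 11 lumbar-segment
  channels, 6,000 symbols per 10-minute step (the scale of a real
  experiment); used for the Markov order tests and state classification.
* ``recordings/`` — a rendered signal-level subset (1 segment, all 8
  steps, 900 symbols per step at 10 kHz) used to exercise detection,
  dictionary building and symbolization end to end.
"""

import argparse
from pathlib import Path

import numpy as np

from cdpmarkov import (SymbolSequence, make_experiment, make_state_specs,
                       make_templates, write_sequence)
from cdpmarkov.io import save_recording, save_truth

LAYOUT = {"ctrl": 2, "esp": 2, "capsa": 4}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    out = args.out

    # sequence-level experiment (11 segments, full length)
    specs = make_state_specs(LAYOUT, n_shapes=12, separation=0.35,
                             symbols_per_step=6000, seed=args.seed)
    exp = make_experiment(specs, 11, render=False, seed=args.seed + 1)
    for (seg, step), toks in sorted(exp.truth_symbols.items()):
        seq = SymbolSequence(list(toks), [], segment_id=seg, step_id=step,
                             maneuver=exp.step_maneuvers[step])
        write_sequence(seq, out / "sequences" / f"{seg}_{step}")
    print(f"sequence-level experiment: {len(exp.truth_symbols)} (segment, step) "
          f"cells, alphabet {len(exp.alphabet)} symbols, "
          f"{len(exp.truth_symbols[('S01', 'ctrl_1')])} tokens per cell")

    # rendered signal-level subset (1 segment)
    templates = make_templates(12, seed=args.seed + 2)
    specs_r = make_state_specs(LAYOUT, n_shapes=12, separation=0.35,
                               symbols_per_step=900, seed=args.seed)
    exp_r = make_experiment(specs_r, 1, templates=templates, seed=args.seed + 3)
    for key, rec in sorted(exp_r.recordings.items()):
        save_recording(rec, out / "recordings" / f"{key[0]}_{key[1]}.h5")
        save_truth(exp_r.truth_symbols[key], exp_r.truth_times[key],
                   out / "recordings" / f"{key[0]}_{key[1]}")
    durations = [r.duration_s for r in exp_r.recordings.values()]
    print(f"rendered subset: {len(exp_r.recordings)} recordings of "
          f"{np.mean(durations):.0f} s at 10 kHz "
          f"(~{np.mean([len(t) for t in exp_r.truth_times.values()]):.0f} "
          f"events each)")


if __name__ == "__main__":
    main()
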