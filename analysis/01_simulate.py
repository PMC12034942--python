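#!/usr/bin/env python
"""Generate the synthetic MET dataset used throughout the analysis.

Emulates a national-variety-trial series: nine 4 x 12 trials sharing
sixteen entries in three replicate blocks, with AR1 column correlation in
every trial, extraneous column effects in alternating trials, a global
column trend in every third trial, and a two-factor (FA-2) between-trial
genetic covariance.  Writes the plot table, the layout sidecar, and the
generating truth under results/data/.
"""

import argparse
import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "scripts"))
from acceptance import build_truth  # noqa: E402  (same study conditions)

from metfa import generate_met, write_met_csv
from metfa.data import write_layout_json


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/data")
    args = ap.parse_args()

    designs, truth = build_truth(args.seed)
    d, truth = generate_met(designs, truth)
    os.makedirs(args.out_dir, exist_ok=True)
    write_met_csv(d, os.path.join(args.out_dir, "met_yield.csv"))
    write_layout_json(d, os.path.join(args.out_dir, "met_layout.json"))
    with open(os.path.join(args.out_dir, "truth.json"), "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    print(
        f"wrote {len(d.records)} plots across {len(d.trials)} trials to "
        f"{args.out_dir} (seed {args.seed})"
    )
    print(f"true genetic correlations span "
          f"[{min(truth.Ge[i, j] / (truth.Ge[i, i] * truth.Ge[j, j]) ** 0.5 for i in range(truth.t) for j in range(i)):.2f}, "
          f"{max(truth.Ge[i, j] / (truth.Ge[i, i] * truth.Ge[j, j]) ** 0.5 for i in range(truth.t) for j in range(i)):.2f}]")


if __name__ == "__main__":
    main()
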