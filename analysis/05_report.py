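#!/usr/bin/env python
"""Assemble the figures and the markdown report from the saved tables.

Reads the CSV outputs of steps 02-04 and renders the correlation heat map,
the dissimilarity dendrogram with the 0.5 cut, residual heat maps, the
heritability bar chart, and a single markdown report under
results/report/.
"""

import argparse
import glob
import os

import numpy as np
import pandas as pd

from metfa import cluster_trials, render_outputs


def _read(path, **kw):
    return pd.read_csv(path, **kw) if os.path.exists(path) else None


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", default="results")
    ap.add_argument("--out-dir", default="results/report")
    args = ap.parse_args()

    corr_df = _read(os.path.join(args.in_dir, "genetic_correlation.csv"), index_col=0)
    correlation = None
    if corr_df is not None:
        correlation = cluster_trials(
            corr_df.to_numpy(), cut=0.5, trial_names=list(corr_df.index)
        )

    grids = {}
    for before in glob.glob(os.path.join(args.in_dir, "residuals_before_*.csv")):
        trial = os.path.basename(before)[len("residuals_before_"):-4]
        after = os.path.join(args.in_dir, f"residuals_after_{trial}.csv")
        if os.path.exists(after):
            grids[trial] = (
                np.loadtxt(before, delimiter=","), np.loadtxt(after, delimiter=","),
            )

    files = render_outputs(
        args.out_dir,
        correlation=correlation,
        residual_grids=grids or None,
        spatial_table=_read(os.path.join(args.in_dir, "spatial_selection.csv")),
        fa_table=_read(os.path.join(args.in_dir, "fa_comparison.csv")),
        variance_table=_read(os.path.join(args.in_dir, "variance_summary.csv"), index_col=0),
        heritability=_read(os.path.join(args.in_dir, "heritability.csv"), index_col=0),
    )
    print(f"wrote {len(files)} report artifacts to {args.out_dir}")
    if correlation is not None:
        print(f"{correlation.n_clusters} trial clusters at dissimilarity cut 0.5")


if __name__ == "__main__":
    main()
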