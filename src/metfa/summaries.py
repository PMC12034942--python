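"""Genetic-correlation summaries, trial clustering, and report assembly.

The between-trial genetic covariance Ge from the spatial + G x E analysis
is summarized as a correlation matrix (heat map), converted to the
dissimilarity d = 1 - r, clustered by average-linkage agglomeration, and
cut (default height 0.5) into groups of trials that rank genotypes alike.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["CorrelationSummary", "genetic_correlation", "cluster_trials", "render_outputs"]


@dataclass
class CorrelationSummary:
    corr: np.ndarray
    dissim: np.ndarray
    linkage_tree: np.ndarray
    labels: np.ndarray  # cluster labels, 1-based
    cut: float
    trial_names: list[str]

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def genetic_correlation(Ge: np.ndarray, trial_names: list[str] | None = None) -> np.ndarray:
    """Correlation matrix D^-1/2 Ge D^-1/2 from a PSD genetic covariance."""
    Ge = np.asarray(Ge, dtype=float)
    dvec = np.diag(Ge)
    bad = np.where(dvec <= 0)[0]
    if bad.size:
        names = (
            [trial_names[i] for i in bad] if trial_names is not None else bad.tolist()
        )
        raise ValueError(f"zero genetic variance for trial(s) {names}; correlation undefined")
    s = 1.0 / np.sqrt(dvec)
    corr = Ge * np.outer(s, s)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def cluster_trials(
    corr: np.ndarray, cut: float = 0.5, method: str = "average",
    trial_names: list[str] | None = None, halved: bool = False,
) -> CorrelationSummary:
    """Hierarchical clustering of trials on the dissimilarity 1 - r.

    ``halved=True`` uses the alternative (1 - r)/2 scaling.  Cutting the
    average-linkage tree at the given height yields the cluster labels;
    the result is deterministic and invariant to trial input order up to
    relabeling.
    """
    corr = np.asarray(corr, dtype=float)
    t = corr.shape[0]
    if t < 2:
        raise ValueError("clustering needs at least two trials")
    dissim = 1.0 - corr
    if halved:
        dissim = dissim / 2.0
    np.fill_diagonal(dissim, 0.0)
    dissim = 0.5 * (dissim + dissim.T)
    tree = linkage(squareform(dissim, checks=False), method=method)
    labels = fcluster(tree, t=cut, criterion="distance")
    return CorrelationSummary(
        corr=corr, dissim=dissim, linkage_tree=tree, labels=labels, cut=cut,
        trial_names=list(trial_names) if trial_names is not None else [f"T{j+1}" for j in range(t)],
    )


def _heatmap(ax, M, labels, title, diverging=True, vlim=None):
    vmax = vlim if vlim is not None else np.nanmax(np.abs(M))
    kwargs = {"cmap": "RdBu_r", "vmin": -vmax, "vmax": vmax} if diverging else {"cmap": "viridis"}
    im = ax.imshow(M, **kwargs)
    ax.set_title(title, fontsize=9)
    if labels is not None and len(labels) <= 20:
        ax.set_xticks(range(len(labels)))
        ax.set_yticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=90, fontsize=6)
        ax.set_yticklabels(labels, fontsize=6)
    return im


def render_outputs(
    out_dir: str,
    *,
    correlation: CorrelationSummary | None = None,
    residual_grids: dict | None = None,  # trial -> (before, after) arrays
    spatial_table: pd.DataFrame | None = None,
    fa_table: pd.DataFrame | None = None,
    variance_table: pd.DataFrame | None = None,
    heritability: pd.DataFrame | None = None,
    fmt: str = "png",
) -> list[str]:
    """Write the report artifacts: CSV tables, heat maps, dendrogram, bar
    chart, and a markdown summary.  Filenames are deterministic; re-running
    with identical inputs reproduces identical CSV bytes.  Returns the list
    of files written."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def path(name):
        p = os.path.join(out_dir, name)
        written.append(p)
        return p

    report = ["# MET analysis report", ""]

    if spatial_table is not None and len(spatial_table):
        spatial_table.to_csv(path("spatial_selection.csv"), index=False)
        report += ["## Spatial selection", spatial_table.to_markdown(index=False), ""]
    else:
        report += ["## Spatial selection", "_stage skipped_", ""]

    if fa_table is not None and len(fa_table):
        fa_table.to_csv(path("fa_comparison.csv"), index=False)
        report += ["## FA model comparison", fa_table.to_markdown(index=False), ""]
    else:
        report += ["## FA model comparison", "_stage skipped_", ""]

    if variance_table is not None:
        variance_table.to_csv(path("variance_summary.csv"))
        report += ["## Variance summary", variance_table.to_markdown(), ""]

    if heritability is not None:
        heritability.to_csv(path("heritability.csv"))
        fig, ax = plt.subplots(figsize=(6, 3))
        heritability.plot.bar(ax=ax)
        ax.set_ylabel("Cullis $H^2$")
        ax.set_ylim(0, 1)
        fig.tight_layout()
        fig.savefig(path(f"heritability.{fmt}"), dpi=120)
        plt.close(fig)
        report += ["## Heritability", heritability.to_markdown(), ""]

    if correlation is not None:
        names = correlation.trial_names
        pd.DataFrame(correlation.corr, index=names, columns=names).to_csv(
            path("genetic_correlation.csv")
        )
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = _heatmap(ax, correlation.corr, names, "Genetic correlation", vlim=1.0)
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(path(f"genetic_correlation.{fmt}"), dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 3.2))
        dendrogram(correlation.linkage_tree, labels=names, ax=ax, color_threshold=correlation.cut)
        ax.axhline(correlation.cut, color="grey", ls="--", lw=0.8)
        ax.set_ylabel("dissimilarity 1 - r")
        fig.tight_layout()
        fig.savefig(path(f"dendrogram.{fmt}"), dpi=120)
        plt.close(fig)
        report += [
            "## Trial clusters",
            f"{correlation.n_clusters} clusters at dissimilarity cut {correlation.cut}: "
            + ", ".join(
                f"{n}:{l}" for n, l in zip(names, correlation.labels)
            ),
            "",
        ]
    else:
        report += ["## Trial clusters", "_stage skipped_", ""]

    if residual_grids:
        for trial, (before, after) in residual_grids.items():
            np.savetxt(path(f"residuals_before_{trial}.csv"), before, delimiter=",")
            np.savetxt(path(f"residuals_after_{trial}.csv"), after, delimiter=",")
            fig, axes = plt.subplots(1, 2, figsize=(7, 3))
            vlim = np.nanmax(np.abs([before, after]))
            _heatmap(axes[0], before.T, None, f"{trial}: before", vlim=vlim)
            im = _heatmap(axes[1], after.T, None, f"{trial}: after", vlim=vlim)
            fig.colorbar(im, ax=axes, shrink=0.8)
            fig.savefig(path(f"residual_heatmap_{trial}.{fmt}"), dpi=120)
            plt.close(fig)
    else:
        report += ["## Residual heat maps", "_stage skipped_", ""]

    with open(path("report.md"), "w") as fh:
        fh.write("\n".join(report) + "\n")
    return written
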