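"""Two-stage ANOVA-based comparator: trial means, then AMMI or GGE.

Stage one estimates the genotype x environment two-way table of means from
each trial's own model (genotype cell means adjusted for replicate blocks).
Stage two applies a singular-value decomposition: AMMI double-centers the
table and decomposes the interaction; GGE centers by environment means only
and decomposes genotype-plus-interaction.  The known weakness of the
two-stage path with incomplete tables is preserved: decomposition refuses
missing cells unless iterative-SVD imputation is explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import METDataset

__all__ = ["TwoWayTable", "SVDDecomposition", "trial_means", "ammi_decompose", "gge_decompose"]


@dataclass
class TwoWayTable:
    """Genotype x environment mean table (NaN = missing cell)."""

    means: pd.DataFrame  # genotypes x trials
    r: pd.DataFrame  # replicate counts per cell

    @property
    def complete(self) -> bool:
        return not self.means.isna().any().any()


@dataclass
class SVDDecomposition:
    singular_values: np.ndarray  # non-increasing, >= 0
    genotype_scores: np.ndarray  # m x c, orthonormal columns
    environment_scores: np.ndarray  # t x c, orthonormal columns
    pct_ss: np.ndarray  # percent of decomposed sum of squares per axis
    residual: np.ndarray  # after the requested number of axes
    centered: np.ndarray  # the matrix that was decomposed


def trial_means(d: METDataset) -> TwoWayTable:
    """Least-squares genotype means per trial, adjusted for replicate blocks.

    With complete, balanced replication these reduce to arithmetic means;
    with missing plots they are the block-adjusted LS means.
    """
    genos = d.genotypes
    trials = d.trial_names
    means = pd.DataFrame(np.nan, index=genos, columns=trials)
    counts = pd.DataFrame(0, index=genos, columns=trials)
    for trial in trials:
        recs = [r for r in d.records_for(trial) if r.yield_value is not None]
        if not recs:
            continue
        t_genos = sorted({r.genotype for r in recs})
        reps = sorted({r.replicate for r in recs})
        g_idx = {g: i for i, g in enumerate(t_genos)}
        m, b = len(t_genos), len(reps)
        # genotype cell means + sum-to-zero replicate effects
        X = np.zeros((len(recs), m + b - 1))
        y = np.empty(len(recs))
        for i, r in enumerate(recs):
            X[i, g_idx[r.genotype]] = 1.0
            k = reps.index(r.replicate)
            if k < b - 1:
                X[i, m + k] = 1.0
            else:
                X[i, m :] = -1.0
            y[i] = r.yield_value
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        for g in t_genos:
            means.loc[g, trial] = beta[g_idx[g]]
            counts.loc[g, trial] = sum(
                1 for r in recs if r.genotype == g
            )
    return TwoWayTable(means=means, r=counts)


def _impute_iterative_svd(M: np.ndarray, rank: int = 1, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """EM-style missing-cell imputation by iterated truncated SVD."""
    miss = np.isnan(M)
    out = M.copy()
    out[miss] = np.nanmean(M)
    for _ in range(max_iter):
        mu = out.mean()
        a = out.mean(axis=1) - mu
        b = out.mean(axis=0) - mu
        fitted = mu + a[:, None] + b[None, :]
        U, s, Vt = np.linalg.svd(out - fitted, full_matrices=False)
        k = min(rank, len(s))
        recon = fitted + (U[:, :k] * s[:k]) @ Vt[:k]
        delta = np.max(np.abs(out[miss] - recon[miss])) if miss.any() else 0.0
        out[miss] = recon[miss]
        if delta < tol:
            break
    return out


def _svd_with_sign_fix(G: np.ndarray, n_pc: int):
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    V = Vt.T
    for l in range(V.shape[1]):  # largest-magnitude environment score positive
        j = np.argmax(np.abs(V[:, l]))
        if V[j, l] < 0:
            V[:, l] = -V[:, l]
            U[:, l] = -U[:, l]
    total_ss = float(np.sum(s**2))
    pct = 100.0 * s**2 / total_ss if total_ss > 0 else np.zeros_like(s)
    c = min(n_pc, len(s))
    recon = (U[:, :c] * s[:c]) @ V[:, :c].T
    return SVDDecomposition(
        singular_values=s, genotype_scores=U, environment_scores=V,
        pct_ss=pct, residual=G - recon, centered=G,
    )


def _prepare(tbl: TwoWayTable, impute_missing: bool, what: str) -> np.ndarray:
    M = tbl.means.to_numpy(dtype=float)
    if np.isnan(M).any():
        if not impute_missing:
            raise ValueError(
                f"{what} requires a complete two-way table; "
                "missing cells present (pass impute_missing=True for "
                "iterative-SVD imputation)"
            )
        M = _impute_iterative_svd(M)
    return M


def ammi_decompose(tbl: TwoWayTable, n_pc: int = 2, impute_missing: bool = False) -> SVDDecomposition:
    """AMMI: remove grand mean and both main effects, decompose the interaction."""
    M = _prepare(tbl, impute_missing, "AMMI")
    mu = M.mean()
    a = M.mean(axis=1) - mu
    b = M.mean(axis=0) - mu
    interaction = M - mu - a[:, None] - b[None, :]
    return _svd_with_sign_fix(interaction, n_pc)


def gge_decompose(tbl: TwoWayTable, n_pc: int = 2, impute_missing: bool = False) -> SVDDecomposition:
    """GGE: remove environment means only, decompose genotype + interaction."""
    M = _prepare(tbl, impute_missing, "GGE")
    return _svd_with_sign_fix(M - M.mean(axis=0)[None, :], n_pc)
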