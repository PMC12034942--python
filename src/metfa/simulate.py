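"""Synthetic MET data with known truth, under the package's own model.

The generator draws plot yields from

    y = trial mean + block + u_g + column + row + linear trends + eps,

with G x E effects u_g built by the factor construction
u_g = (Lambda (x) I_m) f + xi (f ~ N(0, I), xi ~ N(0, Psi (x) I_m)) so that
var(u_g) = (Lambda Lambda' + Psi) (x) I_m, and per-trial residuals drawn
with separable covariance sigma_j^2 Sigma_c(rho_c_j) (x) Sigma_r(rho_r_j)
in rows-within-columns order.  Replicate blocks tile the grid as contiguous
column-major bands; genotypes are randomized within blocks.  Every quantity
used to generate the data is recorded in the truth object, so parameter
recovery is checkable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import METDataset, PlotRecord, TrialDesign
from .structures import ar1_matrix, fa_covariance

__all__ = [
    "SimulationTruth",
    "generate_met",
    "draw_genetic_effects",
    "ar1_sample_cov_check",
    "uniform_designs",
]


@dataclass
class SimulationTruth:
    """All generative parameters for a t-trial MET simulation.

    Vectors are indexed by trial.  ``Lambda`` is the t x k loading matrix
    and ``Psi`` the specific variances of the factor-analytic genetic
    covariance Ge = Lambda Lambda' + diag(Psi); ``sigma2``, ``rho_col``,
    ``rho_row`` parameterize the separable spatial residual; ``col_var`` /
    ``row_var`` are extraneous random column/row effect variances;
    ``lcol_slope`` / ``lrow_slope`` are global linear trend coefficients
    (t/ha per column or row, on centered indices); ``block_var`` is the
    replicate block variance; ``trial_mean`` the fixed yield level.
    """

    Lambda: np.ndarray
    Psi: np.ndarray
    sigma2: np.ndarray
    rho_col: np.ndarray
    rho_row: np.ndarray
    col_var: np.ndarray
    row_var: np.ndarray
    lcol_slope: np.ndarray
    lrow_slope: np.ndarray
    block_var: np.ndarray
    trial_mean: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, dtype=float))
        t = self.Lambda.shape[0]
        for name in (
            "Psi", "sigma2", "rho_col", "rho_row", "col_var", "row_var",
            "lcol_slope", "lrow_slope", "block_var", "trial_mean",
        ):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (t,)).copy()
            setattr(self, name, v)
        if np.any(self.Psi < 0) or np.any(self.col_var < 0) or np.any(
            self.row_var < 0
        ) or np.any(self.block_var < 0):
            raise ValueError("variances must be nonnegative")
        if np.any(self.sigma2 < 0):
            raise ValueError("residual variances must be nonnegative")
        if np.any(np.abs(self.rho_col) >= 1) or np.any(np.abs(self.rho_row) >= 1):
            raise ValueError("AR1 correlations must lie strictly inside (-1, 1)")

    @property
    def t(self) -> int:
        return self.Lambda.shape[0]

    @property
    def k(self) -> int:
        return self.Lambda.shape[1]

    @property
    def Ge(self) -> np.ndarray:
        return fa_covariance(self.Lambda, self.Psi)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}


def uniform_designs(
    t: int, n_cols: int, n_rows: int, n_entries: int, n_reps: int,
    entry_prefix: str = "G", trial_prefix: str = "T",
) -> list[TrialDesign]:
    """t identical rectangular trials sharing one entry list (full concurrence)."""
    entries = tuple(f"{entry_prefix}{i + 1:03d}" for i in range(n_entries))
    return [
        TrialDesign(f"{trial_prefix}{j + 1:02d}", n_cols, n_rows, entries, n_reps)
        for j in range(t)
    ]


def draw_genetic_effects(truth: SimulationTruth, genotypes, rng) -> np.ndarray:
    """Draw the t x m matrix of G x E effects via the factor construction."""
    m = len(genotypes)
    f = rng.standard_normal((m, truth.k))
    xi = rng.standard_normal((truth.t, m)) * np.sqrt(truth.Psi)[:, None]
    return truth.Lambda @ f.T + xi


def generate_met(
    designs: list[TrialDesign],
    truth: SimulationTruth,
    concurrence_plan: dict | None = None,
) -> tuple[METDataset, SimulationTruth]:
    """Simulate one MET dataset; identical seed gives an identical dataset.

    ``concurrence_plan`` optionally overrides each trial's entry subset
    (values must come from the union of entries across designs), emulating
    incomplete concurrence with exact truth bookkeeping.
    """
    t = len(designs)
    if t != truth.t:
        raise ValueError(f"{t} designs but truth has {truth.t} trials")
    if concurrence_plan:
        designs = [
            TrialDesign(d.trial, d.n_cols, d.n_rows,
                        tuple(concurrence_plan.get(d.trial, d.entries)), d.n_reps)
            for d in designs
        ]
    master: list[str] = []
    for d in designs:
        for g in d.entries:
            if g not in master:
                master.append(g)
    g_index = {g: i for i, g in enumerate(master)}

    rng = np.random.default_rng(truth.seed)
    u = draw_genetic_effects(truth, master, rng)  # t x m_master

    records: list[PlotRecord] = []
    for j, d in enumerate(designs):
        m_j = len(d.entries)
        n_plots = d.n_cols * d.n_rows
        if m_j * d.n_reps > n_plots:
            raise ValueError(
                f"trial {d.trial!r}: {m_j} entries x {d.n_reps} reps exceed "
                f"{n_plots} plots"
            )
        # spatial surfaces on the full grid
        col_eff = rng.normal(0.0, np.sqrt(truth.col_var[j]), d.n_cols)
        row_eff = rng.normal(0.0, np.sqrt(truth.row_var[j]), d.n_rows)
        block_eff = rng.normal(0.0, np.sqrt(truth.block_var[j]), d.n_reps)
        Sc = ar1_matrix(d.n_cols, truth.rho_col[j])
        Sr = ar1_matrix(d.n_rows, truth.rho_row[j])
        L = np.linalg.cholesky(np.kron(Sc, Sr) + 1e-12 * np.eye(n_plots))
        eps = np.sqrt(truth.sigma2[j]) * (L @ rng.standard_normal(n_plots))

        # contiguous column-major bands of m_j plots per replicate block
        for k in range(d.n_reps):
            perm = rng.permutation(m_j)
            for slot, gi in enumerate(perm):
                plot = k * m_j + slot  # column-major plot index
                c, r = divmod(plot, d.n_rows)
                geno = d.entries[gi]
                yield_value = (
                    truth.trial_mean[j]
                    + block_eff[k]
                    + u[j, g_index[geno]]
                    + col_eff[c]
                    + row_eff[r]
                    + truth.lcol_slope[j] * ((c + 1) - (d.n_cols + 1) / 2.0)
                    + truth.lrow_slope[j] * ((r + 1) - (d.n_rows + 1) / 2.0)
                    + eps[plot]
                )
                records.append(
                    PlotRecord(d.trial, geno, f"R{k + 1}", c + 1, r + 1, float(yield_value))
                )
    return METDataset(trials=list(designs), records=records), truth


def ar1_sample_cov_check(
    n: int, rho: float, n_sims: int, seed: int, lag: int = 1
) -> float:
    """Monte-Carlo diagnostic: |empirical lag-h correlation - rho^h| for AR1 draws."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(ar1_matrix(n, rho))
    x = rng.standard_normal((n_sims, n)) @ L.T
    a = x[:, :-lag].ravel()
    b = x[:, lag:].ravel()
    emp = np.corrcoef(a, b)[0, 1]
    return float(abs(emp - rho ** lag))
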