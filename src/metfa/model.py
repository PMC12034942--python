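"""Mixed-model assembly for MET data: y = X tau + Z_g u_g + Z_o u_o + e.

Observations are ordered trial-major with plots in rows-within-columns
order inside each trial, so every trial's residual block is a (possibly
incomplete) separable column x row covariance.  Random-term design matrices
are single-indicator factors and are stored as integer code vectors rather
than dense matrices; the REML engine exploits this.

G x E effect columns are ordered trial-major with genotype varying fastest,
so var(u_g) = Ge (x) I_m for both the diagonal-by-trial and the
factor-analytic genetic models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .data import METDataset, METValidationError
from .structures import (
    DiagByGroup,
    FAVariance,
    IdentityVariance,
    TrialResidual,
    VarianceStructure,
)

__all__ = ["RandomTerm", "MixedModel", "build_trial_model", "build_met_model", "build_matrices"]


@dataclass
class RandomTerm:
    """One random factor: each observation loads on exactly one effect column."""

    name: str
    codes: np.ndarray  # (n,) int, column index of the single 1 in Z
    q: int
    structure: VarianceStructure
    labels: list | None = None

    def dense_Z(self) -> np.ndarray:
        Z = np.zeros((len(self.codes), self.q))
        inside = self.codes >= 0  # -1 marks observations the term does not touch
        Z[np.nonzero(inside)[0], self.codes[inside]] = 1.0
        return Z


@dataclass
class MixedModel:
    """Assembled design: response, fixed design, random terms, residual blocks."""

    y: np.ndarray
    X: np.ndarray
    fixed_labels: list[str]
    terms: list[RandomTerm]
    residuals: list[tuple[str, slice, TrialResidual]]  # (trial, obs slice, structure)
    dropped_fixed: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def term(self, name: str) -> RandomTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _drop_aliased(X: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove aliased (rank-deficient) columns via pivoted QR; report removals."""
    if X.shape[1] == 0:
        return X, labels, []
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int(np.sum(diag > tol))
    keep = sorted(piv[:rank])
    dropped = [labels[j] for j in sorted(piv[rank:])]
    return X[:, keep], [labels[j] for j in keep], dropped


def _ordered_obs(d: METDataset, trials: list[str]):
    """Observed records (yield present) in trial-major, rows-within-columns order."""
    by_trial = {t: [] for t in trials}
    for r in d.records:
        if r.trial in by_trial and r.yield_value is not None:
            by_trial[r.trial].append(r)
    designs = d.design_by_trial
    out = []
    for t in trials:
        recs = by_trial[t]
        if not recs:
            raise METValidationError(f"trial {t!r} has no non-missing yields")
        recs.sort(key=lambda r: ((r.column - 1) * designs[t].n_rows + (r.row - 1)))
        out.append(recs)
    return out


def _centered(coord_1based: np.ndarray, n_levels: int) -> np.ndarray:
    return coord_1based - (n_levels + 1) / 2.0


def build_trial_model(
    d: METDataset,
    trial: str,
    *,
    ar1_col: bool = False,
    ar1_row: bool = False,
    random_column: bool = False,
    random_row: bool = False,
    lcol: bool = False,
    lrow: bool = False,
    replicate: bool = True,
    genotype: bool = True,
) -> MixedModel:
    """Single-trial model used through the spatial selection sequence.

    Baseline (all flags off) is the RCB analysis: fixed intercept, random
    replicate and variety effects, iid residual.
    """
    design = d.design_by_trial.get(trial)
    if design is None:
        raise METValidationError(f"unknown trial {trial!r}")
    (recs,) = _ordered_obs(d, [trial])
    n = len(recs)
    cols = np.array([r.column - 1 for r in recs])
    rows = np.array([r.row - 1 for r in recs])

    reps = sorted({r.replicate for r in recs})
    if replicate and len(reps) < 2:
        raise METValidationError(
            f"trial {trial!r}: at least two replicates are required (found {len(reps)})"
        )
    genos = sorted({r.genotype for r in recs})
    if genotype and len(genos) < 2:
        raise METValidationError(f"trial {trial!r}: fewer than two genotypes with data")

    Xcols, labels = [np.ones(n)], ["intercept"]
    if lcol:
        Xcols.append(_centered(cols + 1.0, design.n_cols))
        labels.append("lcol")
    if lrow:
        Xcols.append(_centered(rows + 1.0, design.n_rows))
        labels.append("lrow")
    X, labels, dropped = _drop_aliased(np.column_stack(Xcols), labels)

    terms: list[RandomTerm] = []
    if replicate:
        rep_code = np.array([reps.index(r.replicate) for r in recs])
        terms.append(RandomTerm("replicate", rep_code, len(reps), IdentityVariance(len(reps)), reps))
    if genotype:
        g_code = np.array([genos.index(r.genotype) for r in recs])
        terms.append(
            RandomTerm("genotype", g_code, len(genos), IdentityVariance(len(genos), init_frac=0.2), genos)
        )
    if random_column:
        terms.append(RandomTerm("column", cols, design.n_cols, IdentityVariance(design.n_cols)))
    if random_row:
        terms.append(RandomTerm("row", rows, design.n_rows, IdentityVariance(design.n_rows)))

    resid = TrialResidual(cols, rows, ar1_col, ar1_row)
    model = MixedModel(
        y=np.array([r.yield_value for r in recs]),
        X=X,
        fixed_labels=labels,
        terms=terms,
        residuals=[(trial, slice(0, n), resid)],
        dropped_fixed=dropped,
        meta={
            "trial": trial,
            "genotypes": genos,
            "replicates": reps,
            "design": design,
            "cols": cols,
            "rows": rows,
        },
    )
    return model


def build_met_model(
    d: METDataset,
    *,
    genetic: str = "diag",
    fa_order: int = 1,
    spatial_specs: dict | None = None,
    trials: list[str] | None = None,
) -> MixedModel:
    """Combined across-trial model with G x E random effects.

    Parameters
    ----------
    genetic : "diag" for trial-specific genetic variances with zero
        between-trial covariance (the combined baseline), or "fa" for the
        factor-analytic model Ge = Lambda Lambda' + diag(Psi).
    spatial_specs : optional {trial: SpatialModelSpec-like} carrying the
        retained per-trial spatial terms (attributes ar1_col, ar1_row,
        random_column, random_row, lcol, lrow); defaults to the plain
        combined model (iid residuals, no extraneous/global terms).
    trials : optional subset/order of trials to include (e.g. after
        excluding trials with no genetic variance).
    """
    trial_names = trials if trials is not None else d.trial_names
    designs = d.design_by_trial
    obs_by_trial = _ordered_obs(d, trial_names)
    genos = d.genotypes
    m, t = len(genos), len(trial_names)
    g_index = {g: i for i, g in enumerate(genos)}

    y_parts, Xblocks, terms, residuals = [], [], [], []
    labels: list[str] = ["intercept"]
    trial_codes_all, gxe_codes_all = [], []
    offset = 0
    lin_cols: list[tuple[str, str, np.ndarray]] = []  # (label, trial, values)

    for j, (trial, recs) in enumerate(zip(trial_names, obs_by_trial)):
        design = designs[trial]
        nj = len(recs)
        sl = slice(offset, offset + nj)
        offset += nj
        cols = np.array([r.column - 1 for r in recs])
        rows = np.array([r.row - 1 for r in recs])
        y_parts.append(np.array([r.yield_value for r in recs]))
        trial_codes_all.append(np.full(nj, j))
        gxe_codes_all.append(np.array([j * m + g_index[r.genotype] for r in recs]))

        spec = (spatial_specs or {}).get(trial)
        ar1_c = bool(getattr(spec, "ar1_col", False))
        ar1_r = bool(getattr(spec, "ar1_row", False))
        residuals.append((trial, sl, TrialResidual(cols, rows, ar1_c, ar1_r)))

        reps = sorted({r.replicate for r in recs})
        rep_code = np.array([reps.index(r.replicate) for r in recs])
        terms.append(
            RandomTerm(f"replicate[{trial}]", rep_code, len(reps), IdentityVariance(len(reps)), reps)
        )
        if spec is not None and getattr(spec, "random_column", False):
            terms.append(RandomTerm(f"column[{trial}]", cols, design.n_cols, IdentityVariance(design.n_cols)))
        if spec is not None and getattr(spec, "random_row", False):
            terms.append(RandomTerm(f"row[{trial}]", rows, design.n_rows, IdentityVariance(design.n_rows)))
        if spec is not None and getattr(spec, "lcol", False):
            lin_cols.append((f"lcol[{trial}]", trial, _centered(cols + 1.0, design.n_cols)))
        if spec is not None and getattr(spec, "lrow", False):
            lin_cols.append((f"lrow[{trial}]", trial, _centered(rows + 1.0, design.n_rows)))

    n = offset
    y = np.concatenate(y_parts)
    trial_code = np.concatenate(trial_codes_all)
    gxe_code = np.concatenate(gxe_codes_all)

    # per-trial terms were built on per-trial observation subsets; lift the
    # replicate/column/row code vectors to the full observation vector,
    # with code -1 marking observations outside the term's trial
    lifted: list[RandomTerm] = []
    for term in terms:
        trial = term.name.split("[", 1)[1][:-1]
        sl = next(s for (tn, s, _) in residuals if tn == trial)
        codes = np.full(n, -1, dtype=int)
        codes[sl] = term.codes
        lifted.append(RandomTerm(term.name, codes, term.q, term.structure, term.labels))
    terms = lifted

    # fixed: intercept + trial main effects (aliasing handled by QR) + trends
    Xcols = [np.ones(n)]
    for j, trial in enumerate(trial_names):
        Xcols.append((trial_code == j).astype(float))
        labels.append(f"trial[{trial}]")
    for label, trial, values in lin_cols:
        col = np.zeros(n)
        sl = next(s for (tn, s, _) in residuals if tn == trial)
        col[sl] = values
        Xcols.append(col)
        labels.append(label)
    X, labels, dropped = _drop_aliased(np.column_stack(Xcols), labels)

    if genetic == "diag":
        structure: VarianceStructure = DiagByGroup(
            groups=np.repeat(np.arange(t), m), n_groups=t, init_frac=0.2
        )
    elif genetic == "fa":
        structure = FAVariance(t=t, k=fa_order, m=m)
    else:
        raise ValueError(f"unknown genetic model {genetic!r}")
    gxe = RandomTerm("gxe", gxe_code, t * m, structure)

    return MixedModel(
        y=y,
        X=X,
        fixed_labels=labels,
        terms=[gxe] + terms,
        residuals=residuals,
        dropped_fixed=dropped,
        meta={
            "trials": trial_names,
            "genotypes": genos,
            "m": m,
            "t": t,
            "trial_code": trial_code,
        },
    )


def build_matrices(d: METDataset, **kwargs):
    """Return (y, X, Z_g, Z_o, indicator) for the combined MET model.

    Z_g columns are ordered trial-major with genotype fastest, so
    var(u_g) = Ge (x) I_m.  The indicator marks which of the dataset's
    records entered the observation vector (missing yields are excluded
    while residual structures keep full-grid plot distances).
    """
    model = build_met_model(d, **kwargs)
    Zg = model.term("gxe").dense_Z()
    others = [t for t in model.terms if t.name != "gxe"]
    if others:
        Zo = np.column_stack([t.dense_Z() for t in others])
    else:
        Zo = np.zeros((model.n, 0))
    indicator = np.array([r.yield_value is not None for r in d.records])
    return model.y, model.X, Zg, Zo, indicator
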