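"""Per-trial spatial analysis: RCB baseline, then local AR1, extraneous
row/column effects, and global linear trends, with REMLRT/Wald gatekeeping.

The staged sequence follows the Gilmour-style decomposition of field-trial
variation: *local* trend as a separable AR1 x AR1 residual correlation,
*extraneous* variation as iid random column and row effects, and *global*
trend as fixed linear covariates on centered column/row indices.  Each
candidate term must survive its test at level alpha (REMLRT for variance
terms, with the boundary chi-square mixture for variances tested at zero;
Wald for fixed trends).  A single re-check pass after the global stage
drops any earlier term that loses significance in the final model.
Replicate and variety random effects stay in the model throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import METDataset
from .reml import REMLFit, REMLOptions, reml_fit, remlrt, wald_test

__all__ = [
    "SpatialModelSpec",
    "TestRecord",
    "fit_rcb",
    "select_local",
    "select_extraneous",
    "select_global",
    "run_spatial_pipeline",
    "residual_grid",
    "spatial_report",
]


@dataclass
class TestRecord:
    term: str
    kind: str  # "local" | "extraneous" | "global" | "recheck"
    test: str  # "REMLRT" | "Wald"
    statistic: float
    df: int
    p_value: float
    retained: bool


@dataclass
class SpatialModelSpec:
    """Selected spatial structure for one trial (the per-trial report row)."""

    trial: str
    ar1_col: bool = False
    ar1_row: bool = False
    rho_col: float | None = None
    rho_row: float | None = None
    random_column: bool = False
    random_row: bool = False
    column_var: float | None = None
    row_var: float | None = None
    lcol: bool = False
    lrow: bool = False
    lcol_slope: float | None = None
    lrow_slope: float | None = None
    # estimates from the final per-trial fit, reused to warm-start the
    # combined across-trial model
    sigma2: float | None = None
    genetic_var: float | None = None
    rep_var: float | None = None
    tests: list[TestRecord] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    @property
    def local_label(self) -> str:
        c = "ar1" if self.ar1_col else "id"
        r = "ar1" if self.ar1_row else "id"
        return f"{c}(Column):{r}(Row)"

    def model_kwargs(self) -> dict:
        return dict(
            ar1_col=self.ar1_col, ar1_row=self.ar1_row,
            random_column=self.random_column, random_row=self.random_row,
            lcol=self.lcol, lrow=self.lrow,
        )

    def to_dict(self) -> dict:
        """JSON-serializable form (tests included as plain records)."""
        out = {
            "trial": self.trial, "local": self.local_label,
            **self.model_kwargs(),
            "rho_col": self.rho_col, "rho_row": self.rho_row,
            "column_var": self.column_var, "row_var": self.row_var,
            "lcol_slope": self.lcol_slope, "lrow_slope": self.lrow_slope,
            "sigma2": self.sigma2, "genetic_var": self.genetic_var,
            "rep_var": self.rep_var,
            "tests": [vars(t) for t in self.tests], "log": list(self.log),
        }
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "SpatialModelSpec":
        spec = cls(trial=raw["trial"])
        for k in ("ar1_col", "ar1_row", "random_column", "random_row", "lcol",
                  "lrow", "rho_col", "rho_row", "column_var", "row_var",
                  "lcol_slope", "lrow_slope", "sigma2", "genetic_var", "rep_var"):
            if k in raw:
                setattr(spec, k, raw[k])
        spec.tests = [TestRecord(**t) for t in raw.get("tests", [])]
        spec.log = list(raw.get("log", []))
        return spec


def _warm_start(model, ref: REMLFit | None) -> np.ndarray | None:
    """Start vector for a candidate model, copying every parameter block the
    reference fit shares with it (nested warm starts keep the staged search
    monotone and avoid spurious local modes)."""
    if ref is None:
        return None
    vscale = float(np.var(model.y)) or 1.0
    ref_blocks = {name: (sl, s) for name, sl, s in ref.blocks}
    parts = []
    for term in model.terms:
        if term.name in ref_blocks:
            parts.append(ref.block_params(term.name))
        else:
            # a new variance term starts near zero so the candidate begins
            # at (essentially) the reference optimum and ascent is monotone
            parts.append(term.structure.initial(0.02 * vscale))
    for trial, _, resid in model.residuals:
        name = f"residual[{trial}]"
        if name in ref_blocks:
            sl, rstruct = ref_blocks[name]
            nat = rstruct.natural(ref.tp[sl])
            tp = [np.log(max(nat["sigma2"], 1e-10))]
            if resid.ar1_col:
                tp.append(np.arctanh(np.clip(nat.get("rho_col", 0.1), -0.98, 0.98)))
            if resid.ar1_row:
                tp.append(np.arctanh(np.clip(nat.get("rho_row", 0.1), -0.98, 0.98)))
            parts.append(np.array(tp))
        else:
            parts.append(resid.initial(vscale))
    return np.concatenate(parts)


def _fit(d, trial, options, warm_from: REMLFit | None = None, **kwargs) -> REMLFit | None:
    from .model import build_trial_model

    try:
        model = build_trial_model(d, trial, **kwargs)
        start = _warm_start(model, warm_from)
        return reml_fit(model, start=start, options=options)
    except (np.linalg.LinAlgError, ValueError):
        return None


def _safe_remlrt(fit0, fit1, boundary):
    try:
        return remlrt(fit0, fit1, boundary=boundary)
    except ValueError:
        return None


def fit_rcb(d: METDataset, trial: str, options: REMLOptions | None = None) -> REMLFit:
    """RCB baseline: intercept, random replicate + variety, iid residual."""
    from .model import build_trial_model

    model = build_trial_model(d, trial)
    return reml_fit(model, options=options or REMLOptions())


def select_local(
    d: METDataset, trial: str, base: REMLFit, alpha: float = 0.05,
    options: REMLOptions | None = None, spec: SpatialModelSpec | None = None,
):
    """Choose among id:id, ar1:id, id:ar1, ar1:ar1 residual correlation.

    Fits all three AR1 variants and keeps the most complex variant whose
    every AR1 parameter is individually supported by an REMLRT at df 1
    against the nested reduction, tie-broken by likelihood.
    """
    options = options or REMLOptions()
    spec = spec or SpatialModelSpec(trial=trial)
    design = d.design_by_trial[trial]
    fits: dict[tuple[bool, bool], REMLFit | None] = {(False, False): base}
    for flags in [(True, False), (False, True), (True, True)]:
        if (flags[0] and design.n_cols < 2) or (flags[1] and design.n_rows < 2):
            fits[flags] = None
            spec.log.append(f"local {flags}: skipped (degenerate grid)")
            continue
        f = _fit(d, trial, options, warm_from=base, ar1_col=flags[0], ar1_row=flags[1])
        if f is None or not f.converged:
            spec.log.append(f"local {flags}: candidate skipped (non-convergence)")
            f = None
        fits[flags] = f

    def test(big, small, term):
        if fits[big] is None or fits[small] is None:
            return None
        return _safe_remlrt(fits[small], fits[big], boundary=False)

    chosen = (False, False)
    # prefer ar1:ar1 when both parameters are individually supported
    t_c_in_full = test((True, True), (False, True), "rho_col")
    t_r_in_full = test((True, True), (True, False), "rho_row")
    if (
        t_c_in_full and t_r_in_full
        and t_c_in_full[2] <= alpha and t_r_in_full[2] <= alpha
    ):
        chosen = (True, True)
        spec.tests.append(TestRecord("ar1(Column)", "local", "REMLRT", t_c_in_full[0], 1, t_c_in_full[2], True))
        spec.tests.append(TestRecord("ar1(Row)", "local", "REMLRT", t_r_in_full[0], 1, t_r_in_full[2], True))
    else:
        t_c = test((True, False), (False, False), "rho_col")
        t_r = test((False, True), (False, False), "rho_row")
        ok_c = t_c is not None and t_c[2] <= alpha
        ok_r = t_r is not None and t_r[2] <= alpha
        if ok_c and ok_r:
            # both marginally supported but not jointly: pick the better ll
            chosen = (True, False) if fits[(True, False)].loglik >= fits[(False, True)].loglik else (False, True)
        elif ok_c:
            chosen = (True, False)
        elif ok_r:
            chosen = (False, True)
        if t_c:
            spec.tests.append(TestRecord("ar1(Column)", "local", "REMLRT", t_c[0], 1, t_c[2], chosen[0]))
        if t_r:
            spec.tests.append(TestRecord("ar1(Row)", "local", "REMLRT", t_r[0], 1, t_r[2], chosen[1]))

    spec.ar1_col, spec.ar1_row = chosen
    fit = fits[chosen] if fits[chosen] is not None else base
    _record_rhos(spec, fit, trial)
    return fit, spec


def _record_rhos(spec: SpatialModelSpec, fit: REMLFit, trial: str) -> None:
    nat = fit.natural().get(f"residual[{trial}]", {})
    spec.rho_col = nat.get("rho_col") if spec.ar1_col else None
    spec.rho_row = nat.get("rho_row") if spec.ar1_row else None


def select_extraneous(
    d: METDataset, trial: str, fit: REMLFit, alpha: float = 0.05,
    options: REMLOptions | None = None, spec: SpatialModelSpec | None = None,
):
    """Test iid random Column effects, then iid random Row effects.

    Each variance is tested at its boundary, so the REMLRT reference is the
    1/2 chi2_0 + 1/2 chi2_1 mixture.
    """
    options = options or REMLOptions()
    spec = spec or SpatialModelSpec(trial=trial)
    design = d.design_by_trial[trial]
    for term, attr, n_levels in (
        ("Column", "random_column", design.n_cols),
        ("Row", "random_row", design.n_rows),
    ):
        if n_levels < 2:
            spec.log.append(f"extraneous {term}: skipped (single {term.lower()}, inestimable)")
            continue
        kwargs = spec.model_kwargs()
        kwargs[attr] = True
        cand = _fit(d, trial, options, warm_from=fit, **kwargs)
        if cand is None or not cand.converged:
            spec.log.append(f"extraneous {term}: candidate skipped (non-convergence)")
            continue
        res = _safe_remlrt(fit, cand, boundary=True)
        if res is None:
            spec.log.append(f"extraneous {term}: candidate skipped (test failure)")
            continue
        stat, df, p = res
        keep = p <= alpha
        spec.tests.append(TestRecord(term, "extraneous", "REMLRT", stat, df, p, keep))
        if keep:
            setattr(spec, attr, True)
            fit = cand
    nat = fit.natural()
    spec.column_var = nat.get(f"column[{trial}]", nat.get("column", {})).get("sigma2") if spec.random_column else None
    spec.row_var = nat.get(f"row[{trial}]", nat.get("row", {})).get("sigma2") if spec.random_row else None
    return fit, spec


def select_global(
    d: METDataset, trial: str, fit: REMLFit, alpha: float = 0.05,
    options: REMLOptions | None = None, spec: SpatialModelSpec | None = None,
    recheck: bool = True,
):
    """Add fixed centered linear trends lcol/lrow, retained by Wald test.

    Finishes with one re-check pass: every retained random/local term is
    re-tested in the final model and dropped if it loses significance.
    """
    options = options or REMLOptions()
    spec = spec or SpatialModelSpec(trial=trial)
    design = d.design_by_trial[trial]

    kwargs = spec.model_kwargs()
    kwargs["lcol"] = design.n_cols >= 2
    kwargs["lrow"] = design.n_rows >= 2
    cand = _fit(d, trial, options, warm_from=fit, **kwargs)
    if cand is not None and cand.converged:
        for term, attr in (("lcol", "lcol"), ("lrow", "lrow")):
            if term in cand.model.dropped_fixed:
                spec.log.append(f"global {term}: dropped (aliased with design terms)")
                continue
            if term not in cand.fixed_labels:
                continue
            stat, df, p = wald_test(cand, term)
            keep = p <= alpha
            spec.tests.append(TestRecord(term, "global", "Wald", stat, df, p, keep))
            setattr(spec, attr, keep)
    else:
        spec.log.append("global: candidate skipped (non-convergence)")

    fit = _refit(d, trial, spec, options, warm_from=fit) or fit
    if recheck:
        fit, spec = _recheck_pass(d, trial, fit, alpha, options, spec)
    _record_estimates(spec, fit, trial)
    return fit, spec


def _refit(d, trial, spec, options, warm_from=None):
    return _fit(d, trial, options, warm_from=warm_from, **spec.model_kwargs())


def _recheck_pass(d, trial, fit, alpha, options, spec):
    """Drop any earlier term that is no longer supported in the final model."""
    changed = False
    # random/local variance terms by REMLRT against the model without them
    candidates = []
    if spec.ar1_col:
        candidates.append(("ar1(Column)", "ar1_col", False))
    if spec.ar1_row:
        candidates.append(("ar1(Row)", "ar1_row", False))
    if spec.random_column:
        candidates.append(("Column", "random_column", True))
    if spec.random_row:
        candidates.append(("Row", "random_row", True))
    for term, attr, boundary in candidates:
        kwargs = spec.model_kwargs()
        kwargs[attr] = False
        reduced = _fit(d, trial, options, warm_from=fit, **kwargs)
        if reduced is None or not reduced.converged:
            continue
        res = _safe_remlrt(reduced, fit, boundary=boundary)
        if res is None:
            continue
        stat, df, p = res
        if p > alpha:
            spec.tests.append(TestRecord(term, "recheck", "REMLRT", stat, df, p, False))
            setattr(spec, attr, False)
            fit = reduced
            changed = True
    # global trends by Wald in the current model
    for term, attr in (("lcol", "lcol"), ("lrow", "lrow")):
        if not getattr(spec, attr) or term not in fit.fixed_labels:
            continue
        stat, df, p = wald_test(fit, term)
        if p > alpha:
            spec.tests.append(TestRecord(term, "recheck", "Wald", stat, df, p, False))
            setattr(spec, attr, False)
            changed = True
    if changed:
        fit = _refit(d, trial, spec, options, warm_from=fit) or fit
    return fit, spec


def _record_estimates(spec: SpatialModelSpec, fit: REMLFit, trial: str) -> None:
    _record_rhos(spec, fit, trial)
    nat = fit.natural()
    spec.column_var = nat.get(f"column[{trial}]", nat.get("column", {})).get("sigma2") if spec.random_column else None
    spec.row_var = nat.get(f"row[{trial}]", nat.get("row", {})).get("sigma2") if spec.random_row else None
    spec.lcol_slope = (
        float(fit.beta[fit.fixed_labels.index("lcol")]) if spec.lcol and "lcol" in fit.fixed_labels else None
    )
    spec.lrow_slope = (
        float(fit.beta[fit.fixed_labels.index("lrow")]) if spec.lrow and "lrow" in fit.fixed_labels else None
    )
    spec.sigma2 = nat.get(f"residual[{trial}]", {}).get("sigma2")
    spec.genetic_var = nat.get("genotype", {}).get("sigma2")
    spec.rep_var = nat.get("replicate", {}).get("sigma2")


def run_spatial_pipeline(
    d: METDataset, trial: str, alpha: float = 0.05,
    options: REMLOptions | None = None, recheck: bool = True,
):
    """Full per-trial sequence: RCB -> local -> extraneous -> global.

    Returns (final fit, SpatialModelSpec).  The retained model's likelihood
    never decreases across accepted steps.
    """
    options = options or REMLOptions()
    base = fit_rcb(d, trial, options)
    spec = SpatialModelSpec(trial=trial)
    fit, spec = select_local(d, trial, base, alpha, options, spec)
    fit, spec = select_extraneous(d, trial, fit, alpha, options, spec)
    fit, spec = select_global(d, trial, fit, alpha, options, spec, recheck=recheck)
    return fit, spec


def residual_grid(fit: REMLFit, trial: str) -> np.ndarray:
    """Conditional residuals arranged on the column x row grid (NaN = missing).

    Shape (n_cols, n_rows), the "Column x Row" field orientation; ready
    for heat-map rendering of spatial patterns before/after modeling.
    """
    meta = fit.model.meta
    if meta.get("trial") != trial:
        raise KeyError(f"fit does not contain trial {trial!r}")
    design = meta["design"]
    grid = np.full((design.n_cols, design.n_rows), np.nan)
    e = fit.residuals()
    grid[meta["cols"], meta["rows"]] = e
    return grid


def spatial_report(specs: list[SpatialModelSpec]) -> pd.DataFrame:
    """Combined tabular report of the spatial selection: one row per test."""
    rows = []
    for spec in specs:
        for t in spec.tests:
            rows.append(
                {
                    "Trial": spec.trial,
                    "Spatial variation": t.kind,
                    "Model term": t.term,
                    "Test": t.test,
                    "Statistic": t.statistic,
                    "df": t.df,
                    "P-value": t.p_value,
                    "Retained": t.retained,
                }
            )
    return pd.DataFrame(rows)
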