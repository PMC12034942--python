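"""Combined spatial + factor-analytic G x E analysis across trials.

The combined model keeps every trial's selected spatial terms and
trial-specific error variances, models G x E effects first with a
diagonal-by-trial genetic variance (confirming each trial has genetic
variance; trials pinned at zero are excluded), then fits a nested sequence
FA-1, FA-2, ... for the between-trial genetic covariance
Ge = Lambda Lambda' + diag(Psi), each order warm-started from the last.
Orders are compared by REMLRT and by the percentage of G x E variance
captured by the factor part, %var = 100 tr(Lambda Lambda') / tr(Ge).
Per-trial Cullis heritabilities H^2_j = 1 - A_j / (2 sigma^2_gj) come from
the prediction-error variances of the genotype-effect BLUPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import METDataset
from .model import build_met_model
from .reml import REMLFit, REMLOptions, reml_fit
from .structures import FAVariance, fa_covariance
from scipy.stats import chi2

__all__ = [
    "FAGxEResult",
    "fit_combined",
    "fit_fa_sequence",
    "percent_var",
    "select_final",
    "cullis_heritability",
    "heritability_from_components",
    "variance_summary",
    "comparison_table",
]


class NoGeneticVarianceError(RuntimeError):
    """Raised when no trial shows positive genetic variance."""


@dataclass
class FAGxEResult:
    """One fitted FA order with its comparison-table bookkeeping."""

    order: int
    Lambda: np.ndarray
    Psi: np.ndarray
    Ge: np.ndarray
    pct_var: float
    per_trial_genetic_var: np.ndarray
    per_trial_error_var: np.ndarray
    loglik: float
    remlrt_stat: float | None
    remlrt_df: int | None
    remlrt_p: float | None
    converged: bool
    selected: bool = False
    heritability: np.ndarray | None = None
    excluded_trials: list[str] = field(default_factory=list)
    trials: list[str] = field(default_factory=list)
    fit: REMLFit | None = None
    selection_log: list[str] = field(default_factory=list)


def percent_var(Lambda: np.ndarray, Psi: np.ndarray) -> float:
    """Percentage of total G x E variance captured by the factor part.

    100 * tr(Lambda Lambda') / tr(Lambda Lambda' + diag(Psi)).
    """
    Lambda = np.atleast_2d(np.asarray(Lambda, dtype=float))
    if Lambda.shape[0] == 1 and np.size(Psi) > 1:
        Lambda = Lambda.T
    Psi = np.asarray(Psi, dtype=float).ravel()
    common = float(np.sum(Lambda * Lambda))
    total = common + float(np.sum(Psi))
    if total <= 0:
        raise ValueError("total genetic variance is zero; %var undefined")
    return 100.0 * common / total


def percent_var_by_trial(Lambda: np.ndarray, Psi: np.ndarray) -> float:
    """Configurable alternative: mean over trials of per-trial ratios."""
    Ge = fa_covariance(Lambda, Psi)
    common = np.sum(np.atleast_2d(Lambda) ** 2, axis=1)
    return float(np.mean(100.0 * common / np.diag(Ge)))


def _combined_start(model, specs: dict | None) -> np.ndarray | None:
    """Warm start for the combined diagonal model from the per-trial fits'
    estimates stored on the spatial specs (falls back to generic initials
    for anything missing)."""
    if not specs:
        return None
    vscale = float(np.var(model.y)) or 1.0

    def logv(v, default):
        return np.log(max(v, 1e-8 * vscale)) if v else np.log(default)

    parts = []
    for term in model.terms:
        if term.name == "gxe":
            g = []
            for tr in model.meta["trials"]:
                gv = getattr(specs.get(tr), "genetic_var", None)
                g.append(logv(gv, 0.2 * vscale))
            parts.append(np.array(g))
            continue
        base, tr = term.name.split("[", 1)
        sp = specs.get(tr[:-1])
        attr = {"replicate": "rep_var", "column": "column_var", "row": "row_var"}[base]
        v = getattr(sp, attr, None) if sp is not None else None
        parts.append(np.array([logv(v, 0.1 * vscale)]))
    for tr, _, resid in model.residuals:
        sp = specs.get(tr)
        v = getattr(sp, "sigma2", None) if sp is not None else None
        tp = [logv(v, 0.5 * vscale)]
        if resid.ar1_col:
            rho = getattr(sp, "rho_col", None) or 0.1
            tp.append(np.arctanh(np.clip(rho, -0.95, 0.95)))
        if resid.ar1_row:
            rho = getattr(sp, "rho_row", None) or 0.1
            tp.append(np.arctanh(np.clip(rho, -0.95, 0.95)))
        parts.append(np.array(tp))
    return np.concatenate(parts)


def fit_combined(
    d: METDataset,
    specs: dict | None = None,
    options: REMLOptions | None = None,
    trials: list[str] | None = None,
) -> tuple[REMLFit, list[str]]:
    """Fit the combined across-trial model with diagonal genetic variance.

    Returns (fit, excluded) where ``excluded`` lists trials whose genetic
    variance pinned to the boundary ("no genetic variance"); such trials
    are dropped from the subsequent FA sequence.
    """
    options = options or REMLOptions()
    model = build_met_model(d, genetic="diag", spatial_specs=specs, trials=trials)
    fit = reml_fit(model, start=_combined_start(model, specs), options=options)
    trial_names = model.meta["trials"]
    boundary = fit.block_boundary("gxe")
    excluded = [t for t, b in zip(trial_names, boundary) if b]
    if len(excluded) == len(trial_names):
        raise NoGeneticVarianceError("no trial shows positive genetic variance")
    return fit, excluded


def _fa_start(model, diag_fit: REMLFit, prev: REMLFit | None, k: int) -> np.ndarray:
    """Warm start for FA-k: previous order's fit plus a small deterministic
    perturbation for the new loading column (FA-1 splits the diagonal fit
    50/50 between common and specific variance)."""
    fa: FAVariance = model.term("gxe").structure
    source = prev if prev is not None else diag_fit
    rest = source.tp[source.blocks[0][1].stop :]
    if prev is None:
        s2g = np.maximum(diag_fit.natural()["gxe"]["sigma2"], 1e-6)
        Lambda = np.zeros((fa.t, fa.k))
        Lambda[:, 0] = np.sqrt(0.5 * s2g)
        Psi = 0.5 * s2g
    else:
        prev_fa: FAVariance = prev.model.term("gxe").structure
        L_prev, Psi_prev = prev_fa.unpack(prev.block_params("gxe"))
        Lambda = np.zeros((fa.t, fa.k))
        Lambda[:, : k - 1] = L_prev
        eps = 0.1 * np.sqrt(max(np.mean(Psi_prev), 1e-8))
        signs = np.where(np.arange(fa.t) % 2 == 0, 1.0, -1.0)  # deterministic
        Lambda[:, k - 1] = eps * signs
        for j in range(fa.t):  # respect the rotation constraint
            for h in range(fa.k):
                if j < h:
                    Lambda[j, h] = 0.0
        Psi = np.maximum(Psi_prev, 1e-8)
    return np.concatenate([fa.pack(Lambda, np.maximum(Psi, 1e-10)), rest])


def fit_fa_sequence(
    d: METDataset,
    specs: dict | None = None,
    k_max: int = 3,
    alpha: float = 0.05,
    options: REMLOptions | None = None,
    compute_heritability: bool = True,
    stall_tol: float = 0.05,
) -> list[FAGxEResult]:
    """Fit FA-1 ... FA-k_max, warm-starting each order from the previous.

    Each order is compared to the previous by REMLRT (for FA-1, against the
    diagonal genetic model).  The sequence stops early after two successive
    likelihood gains below ``stall_tol``.  Exclusion of zero-genetic-variance
    trials from the diagonal combined fit is propagated.
    """
    options = options or REMLOptions()
    diag_fit, excluded = fit_combined(d, specs, options)
    trials = [t for t in diag_fit.model.meta["trials"] if t not in excluded]
    if excluded:
        model = build_met_model(d, genetic="diag", spatial_specs=specs, trials=trials)
        diag_fit = reml_fit(model, start=_combined_start(model, specs), options=options)
    t = len(trials)
    k_max = min(k_max, max(t - 1, 1))

    results: list[FAGxEResult] = []
    prev_fit: REMLFit | None = None
    prev_ll = diag_fit.loglik
    prev_np = diag_fit.n_params
    stalls = 0
    for k in range(1, k_max + 1):
        model = build_met_model(d, genetic="fa", fa_order=k, spatial_specs=specs, trials=trials)
        start = _fa_start(model, diag_fit, prev_fit, k)
        try:
            fit = reml_fit(model, start=start, options=options)
        except Exception:
            results and results[-1].selection_log.append(f"FA-{k}: fit failed")
            continue
        fa: FAVariance = model.term("gxe").structure
        Lambda, Psi = fa.unpack(fit.block_params("gxe"))
        Ge = fa_covariance(Lambda, Psi)
        stat = 2.0 * (fit.loglik - prev_ll)
        df = fit.n_params - prev_np
        stat_c = max(stat, 0.0)
        p = float(chi2.sf(stat_c, df)) if df > 0 else float("nan")
        err = np.array([
            fit.natural()[f"residual[{tr}]"]["sigma2"] for tr in trials
        ])
        res = FAGxEResult(
            order=k, Lambda=Lambda, Psi=Psi, Ge=Ge,
            pct_var=percent_var(Lambda, Psi),
            per_trial_genetic_var=np.diag(Ge).copy(),
            per_trial_error_var=err,
            loglik=fit.loglik,
            remlrt_stat=stat_c, remlrt_df=df, remlrt_p=p,
            converged=fit.converged,
            excluded_trials=list(excluded), trials=list(trials), fit=fit,
        )
        if compute_heritability:
            res.heritability = np.array(
                [cullis_heritability(fit, tr) for tr in trials]
            )
        results.append(res)
        if fit.converged:
            if fit.loglik - prev_ll < stall_tol:
                stalls += 1
            else:
                stalls = 0
            prev_fit, prev_ll, prev_np = fit, fit.loglik, fit.n_params
        if stalls >= 2 or k >= t:
            break
    return results


def select_final(
    results: list[FAGxEResult], alpha: float = 0.05,
    pct_floor: float = 65.0, allow_override: bool = False,
) -> FAGxEResult:
    """Pick the final FA order: the largest k whose REMLRT against k-1 is
    significant (FA-1 is the fallback).  If that model's %var is below
    ``pct_floor`` and the next order adds >= 15 points, the next order may
    be accepted under the explicit override flag; everything is logged."""
    if not results:
        raise ValueError("no FA results to select from")
    converged = [r for r in results if r.converged] or results
    chosen = converged[0]
    for r in converged:
        if r.order == 1 or (r.remlrt_p is not None and r.remlrt_p <= alpha):
            chosen = r
    log = [
        f"rule: largest order with REMLRT p <= {alpha}; candidate FA-{chosen.order} "
        f"(%var {chosen.pct_var:.1f})"
    ]
    if chosen.pct_var < pct_floor:
        nxt = next((r for r in converged if r.order == chosen.order + 1), None)
        if nxt is not None and nxt.pct_var - chosen.pct_var >= 15.0:
            if allow_override:
                log.append(
                    f"override: %var {chosen.pct_var:.1f} < floor {pct_floor}; "
                    f"accepting FA-{nxt.order} (%var {nxt.pct_var:.1f})"
                )
                chosen = nxt
            else:
                log.append(
                    f"note: %var {chosen.pct_var:.1f} < floor {pct_floor} and "
                    f"FA-{nxt.order} adds {nxt.pct_var - chosen.pct_var:.1f} points; "
                    "override flag not set"
                )
    for r in results:
        r.selected = r is chosen
    chosen.selection_log.extend(log)
    return chosen


def heritability_from_components(sigma2_g: float, A: float) -> float:
    """Cullis generalized heritability H^2 = 1 - A / (2 sigma^2_g), clipped to [0, 1]."""
    if sigma2_g <= 0:
        raise ValueError("genetic variance must be positive")
    return float(np.clip(1.0 - A / (2.0 * sigma2_g), 0.0, 1.0))


def _pairwise_pev_mean(S: np.ndarray) -> float:
    """Mean over genotype pairs of var(u_i - u_l) = PEV_ii + PEV_ll - 2 PEV_il."""
    m = S.shape[0]
    dvec = np.diag(S)
    M = dvec[:, None] + dvec[None, :] - 2.0 * S
    return float(M.sum() / (m * (m - 1)))


def cullis_heritability(fit: REMLFit, trial: str) -> float:
    """Per-trial Cullis heritability from a fitted model's PEV blocks.

    Works on a single-trial fit (RCB or spatial; uses the "genotype" term)
    or on a combined MET fit (uses the trial's slice of the "gxe" term;
    with the diagonal genetic model only genotypes observed in the trial
    enter the pairwise average, with the FA model every genotype linked
    through Ge does).  Returns NaN when the trial's genetic variance is at
    the boundary.
    """
    names = [t.name for t in fit.model.terms]
    if "genotype" in names:
        if fit.block_boundary("genotype").any():
            return float("nan")
        u, PEV = fit.blups["genotype"]
        s2g = fit.natural()["genotype"]["sigma2"]
        if PEV.shape[0] < 2:
            raise ValueError("heritability needs at least two genotype effects")
        return heritability_from_components(s2g, _pairwise_pev_mean(PEV))
    # combined fit
    meta = fit.model.meta
    trials, m = meta["trials"], meta["m"]
    if trial not in trials:
        raise KeyError(f"trial {trial!r} not in combined fit")
    j = trials.index(trial)
    structure = fit.model.term("gxe").structure
    _, PEV = fit.blups["gxe"]
    if isinstance(structure, FAVariance):
        Ge = structure.ge(fit.block_params("gxe"))
        s2g = float(Ge[j, j])
        idx = np.arange(j * m, (j + 1) * m)
        if s2g <= 0:
            return float("nan")
    else:
        s2g = float(fit.natural()["gxe"]["sigma2"][j])
        if fit.block_boundary("gxe")[j]:
            return float("nan")
        # only genotypes with data in this trial are linked under the
        # diagonal model
        codes = fit.model.term("gxe").codes
        tc = meta["trial_code"]
        observed = np.unique(codes[tc == j])
        idx = observed
    if len(idx) < 2:
        raise ValueError("heritability needs at least two genotype effects")
    S = PEV[np.ix_(idx, idx)]
    return heritability_from_components(s2g, _pairwise_pev_mean(S))


def variance_summary(
    rcb_fits: dict[str, REMLFit],
    spatial_fits: dict[str, REMLFit],
    fa_result: FAGxEResult,
    with_heritability: bool = True,
) -> pd.DataFrame:
    """Dataset-level summary: mean genetic and error variance (and mean H^2)
    under the RCB, spatial, and spatial + G x E analyses."""
    rows = {}
    for label, fits in (("RCB", rcb_fits), ("Spatial", spatial_fits)):
        gv, ev, h2 = [], [], []
        for trial, fit in fits.items():
            nat = fit.natural()
            gv.append(nat["genotype"]["sigma2"])
            ev.append(nat[f"residual[{trial}]"]["sigma2"])
            if with_heritability:
                h2.append(cullis_heritability(fit, trial))
        rows[label] = (np.mean(gv), np.mean(ev), np.nanmean(h2) if h2 else np.nan)
    h2fa = (
        np.nanmean(fa_result.heritability)
        if with_heritability and fa_result.heritability is not None
        else np.nan
    )
    rows["Spatial+GxE"] = (
        float(np.mean(fa_result.per_trial_genetic_var)),
        float(np.mean(fa_result.per_trial_error_var)),
        h2fa,
    )
    df = pd.DataFrame(rows, index=["genetic_variance", "error_variance", "heritability"]).T
    if not with_heritability:
        df = df.drop(columns=["heritability"])
    return df


def comparison_table(results: list[FAGxEResult]) -> pd.DataFrame:
    """FA order comparison table: order, %var, likelihood, REMLRT."""
    return pd.DataFrame(
        {
            "FA model": [f"FA-{r.order}" for r in results],
            "%var": [r.pct_var for r in results],
            "loglik": [r.loglik for r in results],
            "REMLRT stat": [r.remlrt_stat for r in results],
            "REMLRT p": [r.remlrt_p for r in results],
            "converged": [r.converged for r in results],
            "selected": [r.selected for r in results],
        }
    )
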