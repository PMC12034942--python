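"""Average-information REML for Gaussian mixed models on MET data.

The residual log-likelihood maximized is the Patterson-Thompson criterion

    l_R(theta) = -1/2 [ log|H| + log|X' H^-1 X| - log|X' X|
                        + y' P y + (n - p) log 2 pi ]

(the -log|X'X| normalization makes l_R invariant under invertible
reparameterizations of X; differences between models sharing X are
unaffected)

with H = sum_b Z_b G_b(theta) Z_b' + R(theta) and
P = H^-1 - H^-1 X (X' H^-1 X)^-1 X' H^-1.  Updates are Newton steps on the
transformed parameter scale using the average-information matrix

    AI_ij = 1/2 (P y)' dH_i P dH_j (P y),

with step-halving to guarantee a monotone likelihood trace; when an AI
step fails to improve, a diagonally-scaled gradient step is tried, and an
L-BFGS-B polish with the analytic score finishes any stubborn fit.
Variance parameters live on the log scale and are pinned when they hit the
boundary log(1e-8 * var(y)); AR1 correlations live on the Fisher-z scale.

BLUEs, BLUPs and prediction-error-variance (PEV) blocks come from the
converged fit via G Z' P y and G - G (Z' P Z) G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.optimize
from scipy.stats import chi2

from .model import MixedModel

__all__ = ["REMLFit", "REMLOptions", "reml_fit", "remlrt", "wald_test"]

from .structures import LOGVAR, ZCORR, Z_MAX


class REMLError(RuntimeError):
    pass


@dataclass
class REMLOptions:
    max_iter: int = 100
    tol_loglik: float = 1e-6
    tol_score: float = 1e-4
    max_halvings: int = 14
    boundary_frac: float = 1e-8  # variance floor as a fraction of var(y)
    polish: bool = True  # L-BFGS-B rescue if AI iterations stall
    verbose: bool = False


@dataclass
class REMLFit:
    """A converged (or flagged) REML fit."""

    model: MixedModel
    tp: np.ndarray  # transformed variance parameters
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)
    score: np.ndarray | None = None
    at_boundary: np.ndarray | None = None
    blocks: list = field(default_factory=list)  # (name, slice, structure)
    beta: np.ndarray | None = None
    beta_cov: np.ndarray | None = None
    blups: dict = field(default_factory=dict)  # name -> (u, PEV)
    ai_cov: np.ndarray | None = None  # inverse AI at the optimum

    @property
    def n_params(self) -> int:
        return len(self.tp)

    @property
    def fixed_labels(self) -> list[str]:
        return self.model.fixed_labels

    def natural(self) -> dict:
        out = {}
        for name, sl, structure in self.blocks:
            out[name] = structure.natural(self.tp[sl])
        return out

    def block_params(self, name: str) -> np.ndarray:
        for bname, sl, _ in self.blocks:
            if bname == name:
                return self.tp[sl]
        raise KeyError(name)

    def block_boundary(self, name: str) -> np.ndarray:
        for bname, sl, _ in self.blocks:
            if bname == name:
                return self.at_boundary[sl]
        raise KeyError(name)

    def summary(self) -> dict:
        """JSON-serializable fit summary: likelihood, variance parameters on
        the natural scale, fixed-effect estimates, convergence flags."""

        def clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        nat = {
            name: {k: clean(v) for k, v in params.items()}
            for name, params in self.natural().items()
        }
        return {
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_variance_params": int(self.n_params),
            "variance_parameters": nat,
            "at_boundary": [bool(b) for b in self.at_boundary],
            "fixed_effects": {
                lab: {"estimate": float(b), "se": float(se)}
                for lab, b, se in zip(
                    self.fixed_labels, self.beta, np.sqrt(np.diag(self.beta_cov))
                )
            },
            "dropped_fixed": list(self.model.dropped_fixed),
        }

    def residuals(self) -> np.ndarray:
        """Conditional residuals y - X beta - sum_b Z_b u_b."""
        e = self.model.y - self.model.X @ self.beta
        for term in self.model.terms:
            u, _ = self.blups[term.name]
            inside = term.codes >= 0
            e[inside] -= u[term.codes[inside]]
        return e


class _Engine:
    def __init__(self, model: MixedModel, options: REMLOptions):
        self.model = model
        self.opt = options
        self.n = model.n
        self.vscale = float(np.var(model.y)) or 1.0
        # parameter layout: random terms first, then residual blocks
        self.blocks = []
        pos = 0
        for term in model.terms:
            sl = slice(pos, pos + term.structure.n_params)
            self.blocks.append((term.name, sl, term.structure))
            pos += term.structure.n_params
        for trial, osl, resid in model.residuals:
            sl = slice(pos, pos + resid.n_params)
            self.blocks.append((f"residual[{trial}]", sl, resid))
            pos += resid.n_params
        self.n_par = pos
        self.kinds = []
        for _, _, s in self.blocks:
            self.kinds.extend(s.param_kinds())
        self.kinds = np.array(self.kinds)
        self.lb = np.full(self.n_par, -np.inf)
        self.ub = np.full(self.n_par, np.inf)
        logvar = self.kinds == LOGVAR
        self.lb[logvar] = np.log(self.opt.boundary_frac * self.vscale)
        self.ub[logvar] = np.log(1e8 * self.vscale)
        zc = self.kinds == ZCORR
        self.lb[zc], self.ub[zc] = -Z_MAX, Z_MAX
        self.logdetXtX = float(np.linalg.slogdet(model.X.T @ model.X)[1])
        # precompute -1 -> dummy column mapping per term
        self._codes2 = {
            t.name: np.where(t.codes < 0, t.q, t.codes) for t in model.terms
        }

    def initial(self) -> np.ndarray:
        tp = np.empty(self.n_par)
        for (_, sl, s) in self.blocks:
            tp[sl] = s.initial(self.vscale)
        return np.clip(tp, self.lb, self.ub)

    # ---- likelihood -----------------------------------------------------

    def _build_H(self, tp: np.ndarray) -> np.ndarray:
        m = self.model
        H = np.zeros((self.n, self.n))
        resid_blocks = iter(b for b in self.blocks if b[0].startswith("residual["))
        for name, sl, structure in self.blocks:
            if name.startswith("residual["):
                continue
            term = m.term(name)
            G = structure.cov(tp[sl])
            Gp = np.zeros((term.q + 1, term.q + 1))
            Gp[: term.q, : term.q] = G
            c2 = self._codes2[name]
            H += Gp[np.ix_(c2, c2)]
        for (trial, osl, resid), (_, sl, _) in zip(m.residuals, resid_blocks):
            H[osl, osl] += resid.cov(tp[sl])
        return H

    def loglik(self, tp: np.ndarray) -> float:
        try:
            return self._core(tp, derivs=False)[0]
        except (np.linalg.LinAlgError, sla.LinAlgError):
            return -np.inf

    def _core(self, tp: np.ndarray, derivs: bool):
        m = self.model
        X, y = m.X, m.y
        H = self._build_H(tp)
        cF = sla.cho_factor(H, lower=True, check_finite=False)
        logdetH = 2.0 * np.sum(np.log(np.diag(cF[0])))
        Hi_y = sla.cho_solve(cF, y, check_finite=False)
        Hi_X = sla.cho_solve(cF, X, check_finite=False)
        A = X.T @ Hi_X
        cA = sla.cho_factor(A, lower=True, check_finite=False)
        logdetA = 2.0 * np.sum(np.log(np.diag(cA[0])))
        Xt_Hi_y = X.T @ Hi_y
        beta = sla.cho_solve(cA, Xt_Hi_y, check_finite=False)
        yPy = float(y @ Hi_y - Xt_Hi_y @ beta)
        n, p = self.n, X.shape[1]
        ll = -0.5 * (
            logdetH + logdetA - self.logdetXtX + yPy + (n - p) * np.log(2.0 * np.pi)
        )
        if not derivs:
            return ll, None
        Hi = sla.cho_solve(cF, np.eye(n), check_finite=False)
        P = Hi - Hi_X @ sla.cho_solve(cA, Hi_X.T, check_finite=False)
        P = 0.5 * (P + P.T)
        Py = Hi_y - Hi_X @ beta
        score = np.empty(self.n_par)
        V = np.zeros((n, self.n_par))
        for name, sl, structure in self.blocks:
            if name.startswith("residual["):
                trial = name[len("residual[") : -1]
                osl = next(s for (tn, s, _) in m.residuals if tn == trial)
                Pb = P[osl, osl]
                Pyb = Py[osl]
                tr = structure.dcov_trace(tp[sl], Pb)
                D = structure.dcov_matvec(tp[sl], Pyb)
                quad = Pyb @ D
                score[sl] = -0.5 * (tr - quad)
                V[osl, sl.start : sl.stop] = D
            else:
                term = m.term(name)
                q = term.q
                c2 = self._codes2[name]
                acc = np.zeros((q + 1, n))
                np.add.at(acc, c2, P)
                MT = np.zeros((q + 1, q + 1))
                np.add.at(MT, c2, acc.T)
                M = MT[:q, :q].T  # Z' P Z
                w = np.zeros(q + 1)
                np.add.at(w, c2, Py)
                w = w[:q]
                tr = structure.dcov_trace(tp[sl], M)
                D = structure.dcov_matvec(tp[sl], w)  # (q, n_b)
                quad = w @ D
                score[sl] = -0.5 * (tr - quad)
                Dp = np.vstack([D, np.zeros((1, D.shape[1]))])
                V[:, sl.start : sl.stop] = Dp[c2]
        AI = 0.5 * (V.T @ (P @ V))
        return ll, (score, AI, P, Py, cA, Hi_X, beta)

    # ---- fitting --------------------------------------------------------

    def fit(self, start: np.ndarray | None = None) -> REMLFit:
        tp = self.initial() if start is None else np.clip(np.asarray(start, float), self.lb, self.ub)
        trace = []
        ll, aux = self._core(tp, derivs=True)
        if not np.isfinite(ll):
            raise REMLError("initial variance parameters give a singular model")
        converged = False
        it = 0
        stalled = 0  # consecutive near-zero improvements with a large score
        for it in range(1, self.opt.max_iter + 1):
            score, AI = aux[0], aux[1]
            pinned = self._pinned(tp, score)
            free = ~pinned
            max_score = np.max(np.abs(score[free])) if free.any() else 0.0
            trace.append({"iter": it, "loglik": ll, "max_score": max_score})
            if self.opt.verbose:
                print(f"  it {it}: ll={ll:.6f} max|s|={max_score:.2e}")
            new_tp, new_ll, improved = self._step(tp, ll, score, AI, free)
            if improved:
                d_ll = new_ll - ll
                tp, ll = new_tp, new_ll
                ll2, aux = self._core(tp, derivs=True)
                ll = ll2
                score = aux[0]
                pinned = self._pinned(tp, score)
                free = ~pinned
                max_score = np.max(np.abs(score[free])) if free.any() else 0.0
                if d_ll < self.opt.tol_loglik and max_score < self.opt.tol_score:
                    converged = True
                    break
                stalled = stalled + 1 if d_ll < 10 * self.opt.tol_loglik else 0
                if stalled >= 3:
                    break  # AI is creeping along a ridge; hand over to polish
            else:
                if max_score < self.opt.tol_score:
                    converged = True
                break
        if not converged and self.opt.polish:
            tp, ll = self._polish(tp)
            ll2, aux = self._core(tp, derivs=True)
            ll = ll2
            score = aux[0]
            pinned = self._pinned(tp, score)
            free = ~pinned
            max_score = np.max(np.abs(score[free])) if free.any() else 0.0
            converged = max_score < 10 * self.opt.tol_score
            trace.append({"iter": it + 1, "loglik": ll, "max_score": max_score, "polish": True})
        return self._finish(tp, ll, aux, converged, it, trace)

    def _pinned(self, tp, score) -> np.ndarray:
        at_lb = tp <= self.lb + 1e-10
        at_ub = tp >= self.ub - 1e-10
        return (at_lb & (score < 0)) | (at_ub & (score > 0))

    def _try_direction(self, tp, ll, delta):
        step = 1.0
        for _ in range(self.opt.max_halvings):
            cand = np.clip(tp + step * delta, self.lb, self.ub)
            cll = self.loglik(cand)
            if np.isfinite(cll) and cll > ll + 1e-12:
                return cand, cll, True
            step *= 0.5
        return tp, ll, False

    def _step(self, tp, ll, score, AI, free):
        nf = int(free.sum())
        if nf == 0:
            return tp, ll, False
        A = AI[np.ix_(free, free)]
        s = score[free]
        ridge = 0.0
        for _ in range(6):
            try:
                d = np.linalg.solve(A + ridge * np.eye(nf), s)
            except np.linalg.LinAlgError:
                d = None
            if d is not None and np.all(np.isfinite(d)):
                delta = np.zeros(self.n_par)
                delta[free] = d
                cand, cll, ok = self._try_direction(tp, ll, delta)
                if ok:
                    return cand, cll, True
            ridge = max(2.0 * ridge, 1e-4 * (np.trace(A) / nf + 1.0))
        # gradient fallback (diagonally scaled)
        d = s / (np.abs(np.diag(A)) + 1e-8)
        delta = np.zeros(self.n_par)
        delta[free] = d
        return self._try_direction(tp, ll, delta)

    def _polish(self, tp0):
        def neg(tp):
            ll, aux = self._core(tp, derivs=True)
            if not np.isfinite(ll):
                return 1e12, np.zeros_like(tp)
            return -ll, -aux[0]

        bounds = list(zip(self.lb, self.ub))
        res = scipy.optimize.minimize(
            neg, tp0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 80, "ftol": 1e-12, "gtol": 1e-6},
        )
        ll0 = self.loglik(tp0)
        if np.isfinite(res.fun) and -res.fun > ll0:
            return res.x, -res.fun
        return tp0, ll0

    def _finish(self, tp, ll, aux, converged, n_iter, trace) -> REMLFit:
        score, AI, P, Py, cA, Hi_X, beta = aux
        m = self.model
        beta_cov = sla.cho_solve(cA, np.eye(m.p), check_finite=False)
        blups = {}
        for name, sl, structure in self.blocks:
            if name.startswith("residual["):
                continue
            term = m.term(name)
            q = term.q
            c2 = self._codes2[name]
            G = structure.cov(tp[sl])
            w = np.zeros(q + 1)
            np.add.at(w, c2, Py)
            w = w[:q]
            u = G @ w
            acc = np.zeros((q + 1, self.n))
            np.add.at(acc, c2, P)
            MT = np.zeros((q + 1, q + 1))
            np.add.at(MT, c2, acc.T)
            M = MT[:q, :q].T
            PEV = G - G @ M @ G
            PEV = 0.5 * (PEV + PEV.T)
            blups[name] = (u, PEV)
        at_boundary = self._pinned(tp, score) | (
            (self.kinds == LOGVAR) & (tp <= self.lb + 1e-10)
        )
        try:
            ai_cov = np.linalg.pinv(AI)
        except np.linalg.LinAlgError:
            ai_cov = None
        return REMLFit(
            model=m, tp=tp, loglik=ll, converged=converged, n_iter=n_iter,
            trace=trace, score=score, at_boundary=at_boundary,
            blocks=self.blocks, beta=beta, beta_cov=beta_cov, blups=blups,
            ai_cov=ai_cov,
        )


def reml_fit(
    model: MixedModel,
    start: np.ndarray | None = None,
    options: REMLOptions | None = None,
    n_starts: int = 1,
    start_seed: int = 0,
) -> REMLFit:
    """Fit a mixed model by AI-REML; deterministic given inputs and options.

    ``n_starts > 1`` reruns the fit from seeded perturbations of the
    starting point and keeps the best likelihood — useful for multimodal
    factor-analytic fits.
    """
    engine = _Engine(model, options or REMLOptions())
    base = engine.initial() if start is None else np.clip(
        np.asarray(start, float), engine.lb, engine.ub
    )
    rng = np.random.default_rng(start_seed)
    best: REMLFit | None = None
    for i in range(max(n_starts, 1)):
        s = base if i == 0 else np.clip(
            base + 0.4 * rng.standard_normal(len(base)), engine.lb, engine.ub
        )
        try:
            fit = engine.fit(start=s)
        except (REMLError, np.linalg.LinAlgError):
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise REMLError("all starting points failed")
    if n_starts > 1:
        best.trace.append({"multistart": n_starts, "loglik": best.loglik})
    return best


def reml_loglik(model: MixedModel, tp: np.ndarray) -> float:
    """Residual log-likelihood at a given transformed parameter vector.

    Exposed so that brute-force optimizers can serve as independent oracles
    against the AI-REML path.
    """
    return _Engine(model, REMLOptions()).loglik(np.asarray(tp, float))


def remlrt(fit0: REMLFit, fit1: REMLFit, boundary: bool = False):
    """Residual likelihood-ratio test of nested variance models.

    Requires identical fixed-effect structures.  With ``boundary=True`` the
    null distribution is the 1/2 chi2_{df-1} + 1/2 chi2_df mixture for a
    single variance tested on its boundary.
    Returns (statistic, df, p).
    """
    if fit0.fixed_labels != fit1.fixed_labels:
        raise ValueError(
            "REMLRT requires identical fixed-effect structures: "
            f"{fit0.fixed_labels} vs {fit1.fixed_labels}"
        )
    df = fit1.n_params - fit0.n_params
    if df <= 0:
        raise ValueError("fit1 must have more variance parameters than fit0")
    stat = 2.0 * (fit1.loglik - fit0.loglik)
    if stat < -0.01:
        raise ValueError(
            f"nested model has higher likelihood (stat={stat:.4g}); "
            "check convergence of the larger model"
        )
    stat = max(stat, 0.0)
    if stat == 0.0:
        return 0.0, df, 1.0
    if boundary:
        # 1/2 chi2_{df-1} + 1/2 chi2_df; chi2_0 is a point mass at zero
        p_low = chi2.sf(stat, df - 1) if df > 1 else 0.0
        p = 0.5 * p_low + 0.5 * chi2.sf(stat, df)
    else:
        p = chi2.sf(stat, df)
    return float(stat), int(df), float(p)


def wald_test(fit: REMLFit, labels: list[str] | str):
    """Wald chi-square test for a subset of fixed-effect coefficients."""
    if isinstance(labels, str):
        labels = [labels]
    idx = []
    for lab in labels:
        if lab not in fit.fixed_labels:
            raise KeyError(f"fixed term {lab!r} not in model ({fit.fixed_labels})")
        idx.append(fit.fixed_labels.index(lab))
    tau = fit.beta[idx]
    V = fit.beta_cov[np.ix_(idx, idx)]
    try:
        stat = float(tau @ np.linalg.solve(V, tau))
    except np.linalg.LinAlgError:
        raise ValueError("singular variance block for the selected coefficients")
    df = len(idx)
    return stat, df, float(chi2.sf(stat, df))
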