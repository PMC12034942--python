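"""Variance structures for the MET mixed model and their REML derivatives.

Each structure G_b(theta) for a random term (or residual block) works on an
unconstrained *transformed* parameter scale — log for variances, Fisher-z
(atanh) for AR1 correlations, raw for factor loadings — and exposes exactly
what average-information REML needs:

  cov(tp)                the dense covariance matrix,
  dcov_trace(tp, M)      tr(M dG_i) for every parameter i,
  dcov_matvec(tp, w)     dG_i @ w stacked column-wise,

with derivatives taken with respect to the transformed parameters (chain
rule included).  Structures stay small and dense: MET models at desk scale
have random-effect dimensions in the hundreds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ar1_matrix",
    "ar1_logdet",
    "ar1_inverse",
    "fa_covariance",
    "IdentityVariance",
    "DiagByGroup",
    "FAVariance",
    "KroneckerProduct",
    "AR1Corr",
    "TrialResidual",
]

# transformed-parameter kinds, used by the engine for clipping/pinning
LOGVAR = "logvar"
ZCORR = "zcorr"
FREE = "free"

Z_MAX = 4.0  # |rho| <= tanh(4) ~ 0.9993


def ar1_matrix(n: int, rho: float) -> np.ndarray:
    """AR1 correlation matrix with entries rho^|i-j| (unit diagonal).

    Positive definite for |rho| < 1; raises otherwise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(rho) >= 1:
        raise ValueError(f"AR1 correlation must satisfy |rho| < 1, got {rho}")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def ar1_logdet(n: int, rho: float) -> float:
    """Closed-form log-determinant of the AR1 correlation: (n-1) log(1-rho^2)."""
    if abs(rho) >= 1:
        raise ValueError(f"AR1 correlation must satisfy |rho| < 1, got {rho}")
    return (n - 1) * np.log1p(-rho * rho)


def ar1_inverse(n: int, rho: float) -> np.ndarray:
    """Closed-form tridiagonal inverse of the AR1 correlation matrix."""
    if abs(rho) >= 1:
        raise ValueError(f"AR1 correlation must satisfy |rho| < 1, got {rho}")
    if n == 1:
        return np.array([[1.0]])
    out = np.zeros((n, n))
    c = 1.0 / (1.0 - rho * rho)
    d = np.full(n, (1.0 + rho * rho) * c)
    d[0] = d[-1] = c
    np.fill_diagonal(out, d)
    off = -rho * c
    idx = np.arange(n - 1)
    out[idx, idx + 1] = off
    out[idx + 1, idx] = off
    return out


def fa_covariance(Lambda: np.ndarray, Psi: np.ndarray) -> np.ndarray:
    """Factor-analytic between-trial genetic covariance Ge = Lambda Lambda' + diag(Psi)."""
    Lambda = np.atleast_2d(np.asarray(Lambda, dtype=float))
    if Lambda.shape[0] == 1 and Lambda.shape[1] > 1 and np.ndim(Psi) == 1 and len(Psi) > 1:
        Lambda = Lambda.T  # accept a 1-D loading vector for k = 1
    Psi = np.asarray(Psi, dtype=float).ravel()
    if Lambda.shape[0] != Psi.shape[0]:
        raise ValueError("Lambda rows and Psi length must both equal the trial count")
    if np.any(Psi < 0):
        raise ValueError("specific variances Psi must be nonnegative")
    return Lambda @ Lambda.T + np.diag(Psi)


class VarianceStructure:
    """Base class: a parametric covariance for one random term."""

    q: int
    n_params: int

    def param_kinds(self) -> list[str]:
        raise NotImplementedError

    def initial(self, vscale: float) -> np.ndarray:
        raise NotImplementedError

    def cov(self, tp: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dcov_trace(self, tp: np.ndarray, M: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dcov_matvec(self, tp: np.ndarray, w: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def natural(self, tp: np.ndarray) -> dict:
        raise NotImplementedError


@dataclass
class IdentityVariance(VarianceStructure):
    """sigma^2 I_q — iid random effects (blocks, varieties, extraneous rows/columns)."""

    q: int
    init_frac: float = 0.1

    def __post_init__(self) -> None:
        self.n_params = 1

    def param_kinds(self):
        return [LOGVAR]

    def initial(self, vscale):
        return np.array([np.log(self.init_frac * vscale)])

    def cov(self, tp):
        return np.exp(tp[0]) * np.eye(self.q)

    def dcov_trace(self, tp, M):
        return np.array([np.exp(tp[0]) * np.trace(M)])

    def dcov_matvec(self, tp, w):
        return (np.exp(tp[0]) * w)[:, None]

    def natural(self, tp):
        return {"sigma2": float(np.exp(tp[0]))}


@dataclass
class DiagByGroup(VarianceStructure):
    """Separate variance per group level: diag over a grouping of the q effects.

    Used for the diagonal-by-trial genetic model, where group = trial of
    each (trial, genotype) effect column.
    """

    groups: np.ndarray  # int codes 0..g-1, length q
    n_groups: int
    init_frac: float = 0.1

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=int)
        self.q = len(self.groups)
        self.n_params = self.n_groups
        self._masks = [self.groups == g for g in range(self.n_groups)]

    def param_kinds(self):
        return [LOGVAR] * self.n_groups

    def initial(self, vscale):
        return np.full(self.n_groups, np.log(self.init_frac * vscale))

    def cov(self, tp):
        return np.diag(np.exp(tp)[self.groups])

    def dcov_trace(self, tp, M):
        dM = np.diag(M)
        s2 = np.exp(tp)
        return np.array(
            [s2[g] * dM[self._masks[g]].sum() for g in range(self.n_groups)]
        )

    def dcov_matvec(self, tp, w):
        s2 = np.exp(tp)
        out = np.zeros((self.q, self.n_groups))
        for g in range(self.n_groups):
            out[self._masks[g], g] = s2[g] * w[self._masks[g]]
        return out

    def natural(self, tp):
        return {"sigma2": np.exp(tp)}


class FAVariance(VarianceStructure):
    """Factor-analytic G x E covariance (Lambda Lambda' + diag(Psi)) (x) I_m.

    Effects are ordered trial-major with genotype varying fastest, so the
    covariance is a t x t matrix of m x m scalar blocks.  Identifiability
    uses the upper-triangle rotation constraint lambda_{j,h} = 0 for j < h,
    leaving t*k - k(k-1)/2 free loadings plus t specific variances.
    Parameter order: free loadings column-by-column, then log Psi.
    """

    def __init__(self, t: int, k: int, m: int):
        if k < 1 or k > t:
            raise ValueError("FA order must satisfy 1 <= k <= t")
        self.t, self.k, self.m = t, k, m
        self.q = t * m
        # (row, col) of free loadings, column-major
        self._free = [(j, h) for h in range(k) for j in range(t) if j >= h]
        self.n_free = len(self._free)
        self.n_params = self.n_free + t

    def param_kinds(self):
        return [FREE] * self.n_free + [LOGVAR] * self.t

    def pack(self, Lambda: np.ndarray, Psi: np.ndarray) -> np.ndarray:
        lam = np.array([Lambda[j, h] for j, h in self._free])
        return np.concatenate([lam, np.log(np.maximum(Psi, 1e-300))])

    def unpack(self, tp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Lambda = np.zeros((self.t, self.k))
        for val, (j, h) in zip(tp[: self.n_free], self._free):
            Lambda[j, h] = val
        Psi = np.exp(tp[self.n_free :])
        return Lambda, Psi

    def initial(self, vscale):
        Lambda = np.zeros((self.t, self.k))
        Lambda[:, 0] = np.sqrt(0.05 * vscale)
        Psi = np.full(self.t, 0.05 * vscale)
        return self.pack(Lambda, Psi)

    def ge(self, tp) -> np.ndarray:
        Lambda, Psi = self.unpack(tp)
        return fa_covariance(Lambda, Psi)

    def cov(self, tp):
        return np.kron(self.ge(tp), np.eye(self.m))

    def _block_traces(self, M: np.ndarray) -> np.ndarray:
        """T[a, b] = tr of the (a, b) m x m block of M."""
        t, m = self.t, self.m
        Mr = M.reshape(t, m, t, m)
        return np.einsum("aibi->ab", Mr)

    def dcov_trace(self, tp, M):
        Lambda, Psi = self.unpack(tp)
        T = self._block_traces(M)  # tr(M (A (x) I)) = sum_ab A[b,a] T[a,b]
        out = np.empty(self.n_params)
        for i, (j, h) in enumerate(self._free):
            # dGe = e_j lam_h' + lam_h e_j'
            lam = Lambda[:, h]
            out[i] = (T[:, j] @ lam) + (lam @ T[j, :])
        for j in range(self.t):
            out[self.n_free + j] = Psi[j] * T[j, j]
        return out

    def dcov_matvec(self, tp, w):
        Lambda, Psi = self.unpack(tp)
        W = w.reshape(self.t, self.m)
        out = np.empty((self.q, self.n_params))
        for i, (j, h) in enumerate(self._free):
            lam = Lambda[:, h]
            R = np.outer(lam, W[j])  # lam e_j' W
            R[j] += lam @ W  # e_j lam' W
            out[:, i] = R.ravel()
        for j in range(self.t):
            R = np.zeros_like(W)
            R[j] = Psi[j] * W[j]
            out[:, self.n_free + j] = R.ravel()
        return out

    def natural(self, tp):
        Lambda, Psi = self.unpack(tp)
        return {"Lambda": Lambda, "Psi": Psi, "Ge": fa_covariance(Lambda, Psi)}


@dataclass
class AR1Corr:
    """AR1 correlation component for composing Kronecker products."""

    n: int

    def matrix(self, rho: float) -> np.ndarray:
        return ar1_matrix(self.n, rho)

    def logdet(self, rho: float) -> float:
        return ar1_logdet(self.n, rho)

    def inverse(self, rho: float) -> np.ndarray:
        return ar1_inverse(self.n, rho)


@dataclass
class KroneckerProduct:
    """Separable product of two components; dims multiply."""

    left: AR1Corr
    right: AR1Corr

    @property
    def n(self) -> int:
        return self.left.n * self.right.n

    def matrix(self, rho_left: float, rho_right: float) -> np.ndarray:
        return np.kron(self.left.matrix(rho_left), self.right.matrix(rho_right))

    def logdet(self, rho_left: float, rho_right: float) -> float:
        # log|A (x) B| = n_B log|A| + n_A log|B|
        return self.right.n * self.left.logdet(rho_left) + self.left.n * self.right.logdet(rho_right)


class TrialResidual(VarianceStructure):
    """Residual covariance of one trial: sigma^2 Sigma_c(rho_c) (x) Sigma_r(rho_r).

    Built on the full column x row grid and restricted to observed plots, so
    holes in the grid keep their true inter-plot distances.  Either AR1
    dimension can be switched off (identity), giving the reduced forms
    ar1:id, id:ar1 and the iid id:id structure.
    Parameters: log sigma^2 [, z(rho_c)] [, z(rho_r)].
    """

    def __init__(self, cols: np.ndarray, rows: np.ndarray, ar1_col: bool, ar1_row: bool):
        # cols/rows: 0-based grid coordinates of the *observed* plots,
        # already in rows-within-columns order.
        self.cols = np.asarray(cols, dtype=int)
        self.rows = np.asarray(rows, dtype=int)
        self.q = len(self.cols)
        self.ar1_col = ar1_col
        self.ar1_row = ar1_row
        self.n_params = 1 + int(ar1_col) + int(ar1_row)
        self.Dc = np.abs(self.cols[:, None] - self.cols[None, :])
        self.Dr = np.abs(self.rows[:, None] - self.rows[None, :])
        self._Dc1 = np.where(self.Dc > 0, self.Dc - 1, 0)
        self._Dr1 = np.where(self.Dr > 0, self.Dr - 1, 0)

    def param_kinds(self):
        kinds = [LOGVAR]
        if self.ar1_col:
            kinds.append(ZCORR)
        if self.ar1_row:
            kinds.append(ZCORR)
        return kinds

    def initial(self, vscale):
        tp = [np.log(0.5 * vscale)]
        if self.ar1_col:
            tp.append(np.arctanh(0.1))
        if self.ar1_row:
            tp.append(np.arctanh(0.1))
        return np.array(tp)

    def _split(self, tp):
        s2 = np.exp(tp[0])
        i = 1
        rc = rr = 0.0
        if self.ar1_col:
            rc = np.tanh(tp[i])
            i += 1
        if self.ar1_row:
            rr = np.tanh(tp[i])
        return s2, rc, rr

    def _corr_parts(self, rc, rr):
        Cc = rc ** self.Dc if self.ar1_col else (self.Dc == 0).astype(float)
        Cr = rr ** self.Dr if self.ar1_row else (self.Dr == 0).astype(float)
        return Cc, Cr

    def cov(self, tp):
        s2, rc, rr = self._split(tp)
        Cc, Cr = self._corr_parts(rc, rr)
        return s2 * Cc * Cr

    def _derivs(self, tp):
        """List of dR_i (dense) wrt transformed params."""
        s2, rc, rr = self._split(tp)
        Cc, Cr = self._corr_parts(rc, rr)
        R = s2 * Cc * Cr
        out = [R]  # wrt log sigma^2
        if self.ar1_col:
            dCc = np.where(self.Dc > 0, self.Dc * rc ** self._Dc1, 0.0)
            out.append(s2 * dCc * Cr * (1.0 - rc * rc))  # chain: drho/dz
        if self.ar1_row:
            dCr = np.where(self.Dr > 0, self.Dr * rr ** self._Dr1, 0.0)
            out.append(s2 * Cc * dCr * (1.0 - rr * rr))
        return out

    def dcov_trace(self, tp, M):
        return np.array([float(np.sum(M * dR)) for dR in self._derivs(tp)])

    def dcov_matvec(self, tp, w):
        return np.column_stack([dR @ w for dR in self._derivs(tp)])

    def natural(self, tp):
        s2, rc, rr = self._split(tp)
        out = {"sigma2": float(s2)}
        if self.ar1_col:
            out["rho_col"] = float(rc)
        if self.ar1_row:
            out["rho_row"] = float(rr)
        return out
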