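"""Independent oracles used by the test suite.

These deliberately avoid the package's AI-REML path: the residual
log-likelihood is recomputed from dense matrices with plain numpy, and
maximization uses generic derivative-free optimization, so agreement with
the engine is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize


def dense_reml_loglik(y, X, H) -> float:
    """Patterson-Thompson residual log-likelihood from a dense H = var(y)."""
    n, p = X.shape
    sign, logdetH = np.linalg.slogdet(H)
    assert sign > 0
    Hi = np.linalg.inv(H)
    A = X.T @ Hi @ X
    signA, logdetA = np.linalg.slogdet(A)
    assert signA > 0
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    beta = np.linalg.solve(A, X.T @ Hi @ y)
    P = Hi - Hi @ X @ np.linalg.solve(A, X.T @ Hi)
    yPy = float(y @ P @ y)
    return -0.5 * (logdetH + logdetA - logdetXtX + yPy + (n - p) * np.log(2 * np.pi))


def brute_force_max(loglik_fn, x0, n_starts: int = 4, seed: int = 0, spread: float = 0.5):
    """Multi-start Nelder-Mead (with a Powell refine) maximization.

    Returns (best log-likelihood, argmax).
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)

    def neg(x):
        v = loglik_fn(x)
        return 1e12 if not np.isfinite(v) else -v

    best = (np.inf, x0)
    starts = [x0] + [x0 + spread * rng.standard_normal(len(x0)) for _ in range(n_starts - 1)]
    for s in starts:
        r = scipy.optimize.minimize(
            neg, s, method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
        )
        r = scipy.optimize.minimize(
            neg, r.x, method="Powell", options={"maxiter": 20000, "xtol": 1e-10, "ftol": 1e-13}
        )
        if r.fun < best[0]:
            best = (r.fun, r.x)
    return -best[0], best[1]
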