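"""REML engine: closed-form limits, oracle equivalence, tests, and BLUP
agreement with a direct mixed-model-equation solve."""

import numpy as np
import pytest
import scipy.linalg
import scipy.stats

from metfa import (
    METDataset,
    PlotRecord,
    TrialDesign,
    build_matrices,
    build_met_model,
    build_trial_model,
    generate_met,
    reml_fit,
    remlrt,
    uniform_designs,
    wald_test,
)
from metfa.model import MixedModel, RandomTerm
from metfa.reml import REMLOptions, reml_loglik
from metfa.structures import IdentityVariance, TrialResidual, ar1_matrix
from tests.conftest import make_truth
from tests._oracles import brute_force_max, dense_reml_loglik


def iid_residual(n):
    return TrialResidual(np.zeros(n, dtype=int), np.arange(n), False, False)


def simple_model(y, X, labels, terms, resid=None):
    n = len(y)
    return MixedModel(
        y=y, X=X, fixed_labels=labels, terms=terms,
        residuals=[("t", slice(0, n), resid or iid_residual(n))],
    )


class TestClosedFormLimits:
    def test_ols_limit(self):
        """With no random terms and iid residual, REML returns RSS/(n-p) and
        the closed-form residual log-likelihood."""
        rng = np.random.default_rng(0)
        n, p = 40, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = X @ [1.0, 0.5, -0.2] + 0.7 * rng.standard_normal(n)
        fit = reml_fit(simple_model(y, X, ["b0", "b1", "b2"], []))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        s2 = rss / (n - p)
        assert fit.natural()["residual[t]"]["sigma2"] == pytest.approx(s2, rel=1e-8)
        ll = -0.5 * ((n - p) * (np.log(2 * np.pi) + np.log(s2)) + rss / s2)
        assert fit.loglik == pytest.approx(ll, abs=1e-8)

    def test_balanced_one_way_anova(self):
        """Balanced one-way random model: REML equals the ANOVA estimators
        sigma_g^2 = (MSB - MSE)/r, sigma_e^2 = MSE."""
        rng = np.random.default_rng(1)
        g, r = 10, 4
        gc = np.repeat(np.arange(g), r)
        y = 2.0 + np.sqrt(0.5) * rng.standard_normal(g)[gc] + 0.8 * rng.standard_normal(g * r)
        fit = reml_fit(
            simple_model(y, np.ones((g * r, 1)), ["int"],
                         [RandomTerm("group", gc, g, IdentityVariance(g))])
        )
        gm = y.reshape(g, r).mean(axis=1)
        msb = r * np.sum((gm - gm.mean()) ** 2) / (g - 1)
        mse = np.sum((y.reshape(g, r) - gm[:, None]) ** 2) / (g * (r - 1))
        nat = fit.natural()
        assert nat["group"]["sigma2"] == pytest.approx(max(0, (msb - mse) / r), rel=1e-5)
        assert nat["residual[t]"]["sigma2"] == pytest.approx(mse, rel=1e-5)

    def test_zero_variance_data_all_boundary(self):
        y = np.full(24, 3.0)
        gc = np.tile(np.arange(6), 4)
        fit = reml_fit(
            simple_model(y, np.ones((24, 1)), ["int"],
                         [RandomTerm("group", gc, 6, IdentityVariance(6))])
        )
        assert fit.at_boundary[0]  # group variance pinned at the floor


class TestLikelihoodProperties:
    def _ar1_model(self, seed=2):
        d, _ = generate_met(
            uniform_designs(1, 4, 5, 10, 2),
            make_truth(1, sigma2=0.3, rho_col=0.4, rho_row=0.2, block_var=0.0, seed=seed),
        )
        return build_trial_model(d, "T01", ar1_col=True, ar1_row=True, replicate=False)

    def test_invariance_under_x_reparameterization(self):
        """l_R is unchanged when X is replaced by X A for invertible A."""
        rng = np.random.default_rng(3)
        n = 30
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n) + X[:, 1]
        gc = np.tile(np.arange(5), 6)
        tp = np.array([np.log(0.3), np.log(0.5)])
        for _ in range(3):
            A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
            m1 = simple_model(y, X, list("abc"), [RandomTerm("g", gc, 5, IdentityVariance(5))])
            m2 = simple_model(y, X @ A, list("abc"), [RandomTerm("g", gc, 5, IdentityVariance(5))])
            assert reml_loglik(m1, tp) == pytest.approx(reml_loglik(m2, tp), abs=1e-8)

    def test_kronecker_path_matches_dense_oracle(self):
        """The engine's separable-AR1 likelihood equals the dense-H formula
        computed independently on a 4x5 grid."""
        model = self._ar1_model()
        tp = np.concatenate([
            np.log([0.25]),  # genotype variance
            [np.log(0.3), np.arctanh(0.4), np.arctanh(0.2)],  # residual
        ])
        s2g = 0.25
        Zg = model.term("genotype").dense_Z()
        cols, rows = model.meta["cols"], model.meta["rows"]
        R = 0.3 * (
            0.4 ** np.abs(cols[:, None] - cols[None, :])
            * 0.2 ** np.abs(rows[:, None] - rows[None, :])
        )
        H = Zg @ (s2g * np.eye(Zg.shape[1])) @ Zg.T + R
        expected = dense_reml_loglik(model.y, model.X, H)
        assert reml_loglik(model, tp) == pytest.approx(expected, abs=1e-8)

    def test_monotone_likelihood_trace(self):
        fit = reml_fit(self._ar1_model(seed=4))
        lls = [rec["loglik"] for rec in fit.trace]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    @pytest.mark.parametrize("seed", [5, 6])
    def test_oracle_equivalence_small(self, seed):
        """AI-REML matches brute-force maximization of the same l_R."""
        model = self._ar1_model(seed=seed)
        fit = reml_fit(model)
        x0 = np.array([np.log(0.1), np.log(0.2), 0.0, 0.0])
        ll_oracle, x_oracle = brute_force_max(
            lambda tp: reml_loglik(model, tp), x0, n_starts=3, seed=seed
        )
        assert fit.loglik == pytest.approx(ll_oracle, abs=1e-4)
        # identifiable-scale comparison
        assert np.exp(fit.tp[0]) == pytest.approx(np.exp(x_oracle[0]), abs=1e-3 * (1 + np.exp(x_oracle[0])))
        assert np.tanh(fit.tp[2]) == pytest.approx(np.tanh(x_oracle[2]), abs=1e-3)


class TestStatisticalTests:
    def _fit_pair(self):
        d, _ = generate_met(
            uniform_designs(1, 4, 6, 12, 2), make_truth(1, rho_col=0.5, seed=8)
        )
        f0 = reml_fit(build_trial_model(d, "T01"))
        f1 = reml_fit(build_trial_model(d, "T01", ar1_col=True))
        return f0, f1

    def test_remlrt_arithmetic(self):
        f0, f1 = self._fit_pair()
        stat, df, p = remlrt(f0, f1)
        assert stat == pytest.approx(2 * (f1.loglik - f0.loglik))
        assert df == 1
        assert p == pytest.approx(scipy.stats.chi2.sf(stat, 1))

    def test_remlrt_reference_values(self):
        # statistic 4 at df 1: p = 0.0455 plain, 0.02275 with the boundary mixture
        class F:  # minimal stand-in fits
            def __init__(self, ll, np_):
                self.loglik, self.n_params = ll, np_
                self.fixed_labels = ["int"]

        stat, df, p = remlrt(F(0.0, 1), F(2.0, 2), boundary=False)
        assert (stat, df) == (4.0, 1) and p == pytest.approx(0.0455, abs=2e-4)
        _, _, p_mix = remlrt(F(0.0, 1), F(2.0, 2), boundary=True)
        assert p_mix == pytest.approx(0.02275, abs=1e-4)
        _, _, p_eq = remlrt(F(1.0, 1), F(1.0, 2), boundary=True)
        assert p_eq == 1.0

    def test_remlrt_requires_same_fixed_effects(self):
        d, _ = generate_met(
            uniform_designs(1, 4, 6, 12, 2), make_truth(1, seed=8)
        )
        f0 = reml_fit(build_trial_model(d, "T01"))
        f1 = reml_fit(build_trial_model(d, "T01", lcol=True, ar1_col=True))
        with pytest.raises(ValueError, match="fixed-effect"):
            remlrt(f0, f1)

    def test_wald_reference_and_bruteforce(self):
        d, _ = generate_met(
            uniform_designs(1, 5, 8, 10, 4), make_truth(1, lcol_slope=0.1, seed=9)
        )
        fit = reml_fit(build_trial_model(d, "T01", lcol=True, lrow=True))
        stat, df, p = wald_test(fit, ["lcol", "lrow"])
        idx = [fit.fixed_labels.index("lcol"), fit.fixed_labels.index("lrow")]
        tau = fit.beta[idx]
        V = fit.beta_cov[np.ix_(idx, idx)]
        assert stat == pytest.approx(float(tau @ np.linalg.inv(V) @ tau), abs=1e-10)
        assert df == 2 and p == pytest.approx(scipy.stats.chi2.sf(stat, 2))
        # scalar reference: tau=2, var=1 -> stat 4, p = 0.0455 (checked on a
        # synthetic fit object)
        fit.beta = np.array([0.0, 2.0, 0.0])
        fit.beta_cov = np.eye(3)
        s, d_, p_ = wald_test(fit, "lcol")
        assert (s, d_) == (4.0, 1) and p_ == pytest.approx(0.0455, abs=2e-4)
        fit.beta[1] = 0.0
        s0, _, p0 = wald_test(fit, "lcol")
        assert s0 == 0.0 and p0 == 1.0


class TestDesignBuilding:
    def test_zg_ordering_genotype_fastest_within_trial(self, small_met):
        d, _ = small_met
        y, X, Zg, Zo, ind = build_matrices(d)
        t, m = 4, 10
        assert Zg.shape[1] == t * m
        # each observation's column index = trial_code * m + genotype_code
        model = build_met_model(d)
        codes = model.term("gxe").codes
        tc = model.meta["trial_code"]
        assert ((codes // m) == tc).all()

    def test_intercept_plus_trial_aliasing_reported(self, small_met):
        d, _ = small_met
        model = build_met_model(d)
        # intercept + 4 trial dummies -> 4 columns after aliasing removal
        assert model.X.shape[1] == 4
        assert len(model.dropped_fixed) == 1

    def test_all_missing_trial_errors(self):
        t1 = TrialDesign("A", 2, 2, ("g1", "g2"), 2)
        recs = [
            PlotRecord("A", "g1", "R1", 1, 1, None),
            PlotRecord("A", "g2", "R1", 1, 2, None),
        ]
        d = METDataset(trials=[t1], records=recs)
        with pytest.raises(Exception, match="no non-missing"):
            build_met_model(d)

    def test_blup_matches_direct_mme_solve(self):
        """Two-trial toy with a genotype absent from trial 2: BLUE/BLUP from
        the engine equal the direct mixed-model-equation solution, and the
        unobserved (trial 2, genotype) effect is the Ge-implied shrinkage."""
        designs = uniform_designs(2, 2, 3, 3, 2)
        plan = {"T02": ["G001", "G002"]}
        d, _ = generate_met(
            uniform_designs(2, 2, 3, 3, 2), make_truth(2, seed=10), concurrence_plan=plan
        )
        model = build_met_model(d, genetic="fa", fa_order=1)
        tp = np.zeros(1 + 0)
        # assemble a full start vector: fa loadings, psi, rep vars, residuals
        fa = model.term("gxe").structure
        start = np.concatenate([
            fa.pack(np.array([[0.5], [0.4]]), np.array([0.1, 0.2])),
            [np.log(0.05), np.log(0.05)],  # replicate variances
            [np.log(0.2), np.log(0.25)],  # residual variances
        ])
        fit = reml_fit(model, start=start, options=REMLOptions(max_iter=0, polish=False))
        # direct dense MME at the same variance parameters
        X, y = model.X, model.y
        Zs = [model.term(t.name).dense_Z() for t in model.terms]
        Gs = [t.structure.cov(fit.block_params(t.name)) for t in model.terms]
        Z = np.hstack(Zs)
        G = scipy.linalg.block_diag(*Gs)
        Rinv = np.linalg.inv(
            scipy.linalg.block_diag(
                *[res.cov(fit.block_params(f"residual[{tr}]")) for tr, _, res in model.residuals]
            )
        )
        C = np.block([
            [X.T @ Rinv @ X, X.T @ Rinv @ Z],
            [Z.T @ Rinv @ X, Z.T @ Rinv @ Z + np.linalg.inv(G)],
        ])
        rhs = np.concatenate([X.T @ Rinv @ y, Z.T @ Rinv @ y])
        sol = np.linalg.solve(C, rhs)
        p = X.shape[1]
        np.testing.assert_allclose(fit.beta, sol[:p], atol=1e-8)
        u_all = np.concatenate([fit.blups[t.name][0] for t in model.terms])
        np.testing.assert_allclose(u_all, sol[p:], atol=1e-8)
        # the absent genotype's trial-2 BLUP is pulled from trial 1 via Ge
        m = model.meta["m"]
        g3 = model.meta["genotypes"].index("G003")
        u_g = fit.blups["gxe"][0]
        assert u_g[1 * m + g3] != 0.0
        Ge = fa.ge(fit.block_params("gxe"))
        assert np.sign(u_g[1 * m + g3]) == np.sign(u_g[0 * m + g3] * Ge[0, 1])
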