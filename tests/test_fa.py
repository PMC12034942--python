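"""Factor-analytic G x E pipeline: %var, order selection, heritability,
combined-model structure, and oracle equivalence of the FA fit."""

import numpy as np
import pytest

from metfa import (
    SimulationTruth,
    build_met_model,
    cullis_heritability,
    fit_combined,
    fit_fa_sequence,
    generate_met,
    heritability_from_components,
    percent_var,
    reml_fit,
    select_final,
    uniform_designs,
    variance_summary,
    fit_rcb,
)
from metfa.fa import FAGxEResult, comparison_table
from metfa.reml import REMLOptions, reml_loglik
from metfa.structures import FAVariance
from tests.conftest import make_truth
from tests._oracles import brute_force_max, dense_reml_loglik


class TestPercentVar:
    def test_boundary_values(self):
        assert percent_var(np.ones((3, 1)), np.zeros(3)) == 100.0
        assert percent_var(np.zeros((3, 1)), np.ones(3)) == 0.0

    def test_two_trial_worked_case(self):
        # Lambda = (1, 0)', Psi = (1, 1): 100 * 1/3
        assert percent_var(np.array([[1.0], [0.0]]), [1.0, 1.0]) == pytest.approx(33.33, abs=0.01)

    def test_rotation_and_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        L = rng.standard_normal((5, 2))
        Psi = rng.uniform(0.1, 1, 5)
        theta = 0.7
        Q = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        assert percent_var(L, Psi) == pytest.approx(percent_var(L @ Q, Psi))
        perm = rng.permutation(5)
        assert percent_var(L[perm], Psi[perm]) == pytest.approx(percent_var(L, Psi))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_var(np.zeros((2, 1)), np.zeros(2))


def _fake_result(order, p, pct=70.0):
    return FAGxEResult(
        order=order, Lambda=np.zeros((2, 1)), Psi=np.ones(2), Ge=np.eye(2),
        pct_var=pct, per_trial_genetic_var=np.ones(2), per_trial_error_var=np.ones(2),
        loglik=0.0, remlrt_stat=0.0, remlrt_df=1, remlrt_p=p, converged=True,
    )


class TestSelectFinal:
    def test_largest_significant_order(self):
        # p-sequence (-, <0.001, <0.001, 0.281) -> order 3
        res = [_fake_result(1, None), _fake_result(2, 1e-4), _fake_result(3, 1e-4),
               _fake_result(4, 0.281)]
        assert select_final(res).order == 3
        # p-sequence (-, 0.026, 0.082, 0.058, 0.035, 0.342) -> order 5
        ps = [None, 0.026, 0.082, 0.058, 0.035, 0.342]
        res = [_fake_result(k + 1, p) for k, p in enumerate(ps)]
        assert select_final(res).order == 5

    def test_single_result_falls_back_to_fa1(self):
        assert select_final([_fake_result(1, None)]).order == 1

    def test_pct_floor_override_flag(self):
        res = [_fake_result(1, None, pct=40.0), _fake_result(2, 0.5, pct=80.0)]
        assert select_final(res, allow_override=False).order == 1
        assert select_final(res, allow_override=True).order == 2


class TestHeritabilityArithmetic:
    def test_reference_values(self):
        assert heritability_from_components(0.5, 0.0) == 1.0
        assert heritability_from_components(0.5, 2 * 0.5) == 0.0
        assert heritability_from_components(0.5, 0.2) == pytest.approx(0.8)

    def test_positive_variance_required(self):
        with pytest.raises(ValueError):
            heritability_from_components(0.0, 0.1)

    def test_unit_rescaling_invariance(self, small_met):
        """Multiplying all yields by a constant leaves H^2 unchanged."""
        from metfa.data import METDataset, PlotRecord

        d, _ = small_met
        opts = REMLOptions(tol_loglik=1e-10, tol_score=1e-6)
        h2 = [cullis_heritability(fit_rcb(d, t, opts), t) for t in d.trial_names]
        c = 7.3
        scaled = METDataset(
            trials=d.trials,
            records=[
                PlotRecord(r.trial, r.genotype, r.replicate, r.column, r.row,
                           None if r.yield_value is None else c * r.yield_value)
                for r in d.records
            ],
        )
        h2s = [cullis_heritability(fit_rcb(scaled, t, opts), t) for t in scaled.trial_names]
        np.testing.assert_allclose(h2, h2s, atol=1e-6)


class TestCombinedModel:
    def test_block_independence_oracle(self):
        """With zero between-trial genetic covariance and no shared
        parameters, the combined likelihood equals the sum of the two
        independent single-trial likelihoods."""
        d, _ = generate_met(uniform_designs(2, 4, 6, 12, 2), make_truth(2, seed=21))
        opts = REMLOptions(tol_loglik=1e-9, tol_score=1e-5)
        combined, _ = fit_combined(d, options=opts)
        singles = [fit_rcb(d, t, opts) for t in d.trial_names]
        assert combined.loglik == pytest.approx(sum(f.loglik for f in singles), abs=1e-3)

    def test_zero_genetic_variance_trial_excluded(self):
        L = np.array([[0.5], [0.0], [0.5]])
        truth = SimulationTruth(
            Lambda=L, Psi=[0.05, 0.0, 0.05], sigma2=[0.1] * 3,
            rho_col=[0.0] * 3, rho_row=[0.0] * 3, col_var=[0.0] * 3,
            row_var=[0.0] * 3, lcol_slope=[0.0] * 3, lrow_slope=[0.0] * 3,
            block_var=[0.02] * 3, trial_mean=[4.0] * 3, seed=24,
        )
        d, _ = generate_met(uniform_designs(3, 4, 10, 20, 2), truth)
        _, excluded = fit_combined(d)
        assert excluded == ["T02"]
        res = fit_fa_sequence(d, k_max=1)
        assert res[0].excluded_trials == ["T02"]
        assert res[0].trials == ["T01", "T03"]

    def test_fa2_attains_unstructured_loglik_at_t3(self):
        """At t=3, FA-2 saturates the PSD cone: its maximized likelihood
        matches a brute-force unstructured-covariance fit (dense-matrix
        likelihood, derivative-free optimizer)."""
        d, _ = generate_met(
            uniform_designs(3, 2, 5, 5, 2),
            make_truth(3, gvar=0.3, psi=0.1, sigma2=0.1, block_var=0.0, seed=23),
        )
        model = build_met_model(d, genetic="fa", fa_order=2)
        # drop replicate terms for a compact oracle parameterization
        model.terms = [t for t in model.terms if t.name == "gxe"]
        fit = reml_fit(
            model, options=REMLOptions(tol_loglik=1e-9, tol_score=1e-5),
            n_starts=8, start_seed=1,
        )

        y, X = model.y, model.X
        Zg = model.term("gxe").dense_Z()
        m = model.meta["m"]
        tcode = model.meta["trial_code"]

        def oracle_ll(x):
            Lc = np.zeros((3, 3))
            Lc[np.tril_indices(3)] = x[:6]
            Ge = Lc @ Lc.T
            s2 = np.exp(x[6:9])
            H = Zg @ np.kron(Ge, np.eye(m)) @ Zg.T + np.diag(s2[tcode])
            try:
                return dense_reml_loglik(y, X, H)
            except (AssertionError, np.linalg.LinAlgError):
                return -np.inf

        x0 = np.concatenate([[0.5, 0.1, 0.5, 0.1, 0.1, 0.5], np.log([0.1] * 3)])
        ll_oracle, _ = brute_force_max(oracle_ll, x0, n_starts=4, seed=23, spread=0.3)
        assert fit.loglik == pytest.approx(ll_oracle, abs=1e-4)


class TestFASequence:
    def test_order_recovery_single_run(self):
        t, m = 6, 20
        L = np.zeros((t, 2))
        L[:, 0] = np.linspace(0.4, 0.7, t)
        L[:, 1] = np.tile([0.3, -0.3], 3)
        truth = make_truth(t, Lambda=L, psi=0.05, sigma2=0.15, seed=11)
        d, _ = generate_met(uniform_designs(t, 5, 8, m, 2), truth)
        res = fit_fa_sequence(d, k_max=3)
        final = select_final(res)
        assert final.order == 2
        tbl = comparison_table(res)
        assert tbl["selected"].sum() == 1
        # nested, warm-started orders never lose likelihood or %var
        assert np.all(np.diff(tbl["loglik"]) >= -1e-6)
        assert np.all(np.diff(tbl["%var"]) >= -1e-6)
        # heritabilities are valid proportions
        assert np.all((final.heritability >= 0) & (final.heritability <= 1))

    def test_variance_summary_shape(self, small_met):
        d, _ = small_met
        rcb = {t: fit_rcb(d, t) for t in d.trial_names}
        res = fit_fa_sequence(d, k_max=1)
        tbl = variance_summary(rcb, rcb, res[0])
        assert list(tbl.index) == ["RCB", "Spatial", "Spatial+GxE"]
        assert np.all(tbl["genetic_variance"] > 0)
        # identical fits in the first two rows give identical summaries
        assert tbl.loc["RCB"].equals(tbl.loc["Spatial"])
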