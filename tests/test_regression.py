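import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icnet.regression import (
    AIC_PERFECT_FIT,
    RankDeficientError,
    RegressionProblem,
    _fit_subset,
    aic_score,
    bonferroni_adjust,
    coefficient_pvalues,
    constrained_least_squares,
    kkt_residual,
    stepwise_select,
)
from oracles import (
    exhaustive_min_aic,
    lsq_objective,
    projected_gradient_lsq,
    random_sign_constrained_problem,
)


def _sign_problem(design, response, nonneg_cols):
    p = design.shape[1]
    cons = []
    for j in sorted(nonneg_cols):
        row = np.zeros(p)
        row[j] = -1.0
        cons.append((row, 0.0))
    labels = tuple(f"c{i:02d}" for i in range(p))
    return RegressionProblem(response, design, labels, tuple(cons))


class TestConstrainedLeastSquares:
    def test_decoupled_projection(self):
        prob = _sign_problem(np.eye(2), np.array([1.0, -2.0]), {1})
        theta, active = constrained_least_squares(prob)
        np.testing.assert_allclose(theta, [1.0, 0.0], atol=1e-9)
        assert active == (0,)

    def test_feasible_ols_returned(self, rng):
        design = rng.normal(size=(30, 4))
        beta = np.abs(rng.normal(size=4)) + 0.5  # all positive -> constraints slack
        response = design @ beta
        prob = _sign_problem(design, response, {0, 2})
        theta, active = constrained_least_squares(prob)
        ols = np.linalg.lstsq(design, response, rcond=None)[0]
        np.testing.assert_allclose(theta, ols, atol=1e-9)
        assert active == ()

    def test_matches_projected_gradient_oracle(self, rng):
        # randomized suite; the full 200-instance run lives in the acceptance suite
        for _ in range(40):
            design, response, nonneg = random_sign_constrained_problem(rng)
            prob = _sign_problem(design, response, nonneg)
            theta, _ = constrained_least_squares(prob)
            oracle = projected_gradient_lsq(design, response, nonneg)
            gap = lsq_objective(design, response, theta) - lsq_objective(
                design, response, oracle
            )
            assert gap <= 1e-6
            assert kkt_residual(prob, theta) <= 1e-6

    def test_constraints_satisfied(self, rng):
        for _ in range(20):
            design, response, nonneg = random_sign_constrained_problem(rng)
            prob = _sign_problem(design, response, nonneg)
            theta, _ = constrained_least_squares(prob)
            for row, bound in prob.constraints:
                assert row @ theta <= bound + 1e-9

    def test_rank_deficiency_names_columns(self, rng):
        col = rng.normal(size=20)
        design = np.column_stack([col, 2 * col, rng.normal(size=20)])
        prob = RegressionProblem(rng.normal(size=20), design, ("dup1", "dup2", "ok"))
        with pytest.raises(RankDeficientError) as exc:
            constrained_least_squares(prob)
        assert set(exc.value.columns) & {"dup1", "dup2"}


class TestAic:
    def test_arithmetic(self):
        assert aic_score(10.0, 10, 2) == pytest.approx(4.0)

    def test_param_penalty(self):
        assert aic_score(5.0, 10, 3) - aic_score(5.0, 10, 2) == pytest.approx(2.0)

    def test_perfect_fit_sentinel(self):
        assert aic_score(0.0, 10, 2) == AIC_PERFECT_FIT

    def test_requires_spare_dof(self):
        with pytest.raises(ValueError):
            aic_score(1.0, 5, 5)


class TestStepwise:
    def _problem(self, rng, ncand, beta_true=None, noise=0.0):
        n = 40
        design = np.column_stack(
            [rng.normal(size=(n, ncand)), rng.normal(size=n), np.ones(n)]
        )
        beta = np.zeros(ncand + 2)
        if beta_true:
            for j, v in beta_true.items():
                beta[j] = v
        beta[-2], beta[-1] = 0.5, 0.2
        response = design @ beta + (rng.normal(size=n) * noise if noise else 0.0)
        labels = tuple(f"c{i:02d}" for i in range(ncand)) + ("retention", "basal")
        row = np.zeros(ncand + 2)
        row[-1] = -1.0
        return RegressionProblem(response, design, labels, ((row, 0.0),))

    def test_no_candidates_returns_mandatory_fit(self, rng):
        prob = self._problem(rng, 0, noise=0.3)
        fit = stepwise_select(prob, ("retention", "basal"))
        assert fit.selected == ("retention", "basal")

    def test_noise_free_single_column_recovered(self):
        # orthogonal design, one active column: exhaustive AIC agrees
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(24, 5)))
        design = q * math.sqrt(24)
        labels = ("cA", "cB", "cC", "retention", "basal")
        response = design[:, 1] * 1.0 + 0.5 * design[:, 3] + 0.2 * design[:, 4]
        row = np.zeros(5)
        row[-1] = -1.0
        prob = RegressionProblem(response, design, labels, ((row, 0.0),))
        fit = stepwise_select(prob, ("retention", "basal"))
        assert set(fit.selected) == {"cB", "retention", "basal"}
        assert fit.aic == AIC_PERFECT_FIT
        assert exhaustive_min_aic(prob, ("retention", "basal"), _fit_subset) == fit.aic

    def test_matches_exhaustive_on_random_suite(self, rng):
        # 30 instances here; the spec-scale 100-instance run is in acceptance
        matches = 0
        for _ in range(30):
            ncand = int(rng.integers(3, 9))
            active = {int(j): float(rng.uniform(0.5, 1.5)) for j in
                      rng.choice(ncand, size=2, replace=False)}
            prob = self._problem(rng, ncand, beta_true=active, noise=0.5)
            fit = stepwise_select(prob, ("retention", "basal"))
            best = exhaustive_min_aic(prob, ("retention", "basal"), _fit_subset)
            mand_fit = _fit_subset(prob, ("retention", "basal"))
            full_fit = _fit_subset(prob, prob.column_labels)
            assert fit.aic <= min(mand_fit.aic, full_fit.aic) + 1e-9
            if abs(fit.aic - best) < 1e-8:
                matches += 1
        assert matches >= 27

    def test_every_fit_satisfies_constraints(self, rng):
        prob = self._problem(rng, 5, beta_true={0: 1.0}, noise=0.5)
        fit = stepwise_select(prob, ("retention", "basal"))
        assert fit.coef("basal") >= -1e-9


class TestCoefficientPvalues:
    def _fit(self, rng, n=40, p=4):
        design = np.column_stack([rng.normal(size=(n, p - 1)), np.ones(n)])
        response = design @ np.r_[np.zeros(p - 1), 0.3] + rng.normal(size=n)
        labels = tuple(f"c{i}" for i in range(p - 1)) + ("basal",)
        prob = RegressionProblem(response, design, labels)
        fit = _fit_subset(prob, labels)
        return prob, fit

    def test_zero_estimate_gives_p_one(self):
        prob = RegressionProblem(
            np.array([1.0, -1.0, 1.0, -1.0]),
            np.column_stack([[1.0, 1, -1, -1], [1.0, -1, 1, -1]]),
            ("a", "b"),
        )
        fit = _fit_subset(prob, ("a", "b"))
        coefficient_pvalues(prob, fit)
        assert fit.theta[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.p_raw[0] == pytest.approx(1.0)

    def test_p_monotone_decreasing_in_t(self):
        from scipy import stats

        ps = [2 * stats.t.sf(t, 20) for t in (0.5, 1.5, 3.0, 6.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_textbook_quantile(self, rng):
        # df = 30, |t| = 2.042 is the classic two-sided 5% point
        prob, fit = self._fit(rng, n=34, p=4)  # df = 30
        coefficient_pvalues(prob, fit)
        from scipy import stats

        assert 2 * stats.t.sf(2.042, 30) == pytest.approx(0.05, abs=2e-3)

    def test_df_guard(self, rng):
        # a saturated model (n_obs == n_params) is rejected before inference
        design = rng.normal(size=(4, 4))
        prob = RegressionProblem(rng.normal(size=4), design, tuple("abcd"))
        with pytest.raises(ValueError):
            _fit_subset(prob, tuple("abcd"))


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(
            bonferroni_adjust([0.01, 0.2, 0.004], 3), [0.03, 0.6, 0.012]
        )
        assert bonferroni_adjust([0.5], 3)[0] == 1.0

    def test_family_one_identity(self):
        np.testing.assert_allclose(bonferroni_adjust([0.2], 1), [0.2])

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2], 3)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], 1)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=8),
        st.integers(8, 40),
    )
    def test_monotone_and_order_invariant(self, p_raw, family):
        adj = bonferroni_adjust(p_raw, family)
        order = np.argsort(p_raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in p_raw
        perm = np.random.default_rng(0).permutation(len(p_raw))
        np.testing.assert_allclose(
            bonferroni_adjust(np.asarray(p_raw)[perm], family), adj[perm]
        )
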