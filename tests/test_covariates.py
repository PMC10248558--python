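"""Factorial regression, AIC stepwise selection and NIPALS PLSR."""

import numpy as np
import pandas as pd
import pytest

from metstab import (
    CovariateLink,
    CovariateMatrix,
    SimulationSpec,
    center_covariates,
    fit_factorial_regression,
    fit_plsr,
    generate_covariate_linked,
    plsr_biplot_coords,
    stepwise_fr_aic,
)
from metstab.simulate import default_covariate_link


def _cov(values, names=None):
    values = np.asarray(values, dtype=float)
    e, k = values.shape
    names = names or [f"v{i + 1}" for i in range(k)]
    return center_covariates(
        CovariateMatrix([f"E{j + 1}" for j in range(e)], list(names), values)
    )


def _linked(seed=0, residual_sd=0.0, active=(3, 2), g=12):
    link = default_covariate_link(g=g, residual_sd=residual_sd, active=active)
    spec = SimulationSpec(g=g, e=8, r=2, interaction_singular_values=(), covariate_link=link, seed=seed)
    return generate_covariate_linked(spec)


class TestFactorialRegression:
    def test_exact_recovery_of_sensitivities(self):
        data, cov, truth = _linked(seed=3)
        model = fit_factorial_regression(truth.interaction, center_covariates(cov))
        names = cov.variable_names
        for k, name in enumerate(names):
            np.testing.assert_allclose(model.xi[:, k], truth.xi_true[:, k], atol=1e-6)
        assert model.residual_ss == pytest.approx(0.0, abs=1e-12 * model.total_ss)

    def test_orthogonal_covariate_gets_zero_sensitivity(self):
        # interaction rows proportional to v1; v2 orthogonal to v1
        z = _cov([[1, 1], [0, -1], [-1, 1], [0, -1]])
        ge = np.outer([2.0, -1.0, -1.0], z.values[:, 0])
        model = fit_factorial_regression(ge, z)
        np.testing.assert_allclose(model.xi[:, 1], 0, atol=1e-10)

    def test_empty_variable_list_is_null_model(self):
        data, cov, truth = _linked(seed=1)
        model = fit_factorial_regression(truth.interaction, center_covariates(cov), variables=[])
        assert model.residual_ss == pytest.approx(model.total_ss)
        np.testing.assert_array_equal(model.fitted_interaction, 0)

    def test_xi_columns_centered_and_ss_decomposition(self):
        data, cov, truth = _linked(seed=5, residual_sd=30.0)
        model = fit_factorial_regression(truth.interaction, center_covariates(cov))
        np.testing.assert_allclose(model.xi.sum(axis=0), 0, atol=1e-8)
        assert model.explained_ss_per_variable.sum() + model.residual_ss == pytest.approx(
            model.total_ss, rel=1e-8
        )

    def test_collinear_design_rejected(self):
        z = _cov([[1, 2], [2, 4], [3, 6], [0, 0]])
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            fit_factorial_regression(np.zeros((3, 4)), z)

    def test_saturated_fit_reproduces_interaction(self):
        rng = np.random.default_rng(8)
        g, e = 5, 6
        raw = rng.normal(size=(g, e))
        ge = raw - raw.mean(0) - raw.mean(1)[:, None] + raw.mean()
        z = _cov(rng.normal(size=(e, e - 1)))
        model = fit_factorial_regression(ge, z)
        np.testing.assert_allclose(model.fitted_interaction, ge, atol=1e-8)


class TestStepwiseAIC:
    def test_single_active_covariate_chosen_first(self):
        data, cov, truth = _linked(seed=2, active=(3,))
        model = stepwise_fr_aic(truth.interaction, center_covariates(cov))
        assert model.selected_variables[0] == "FallT"
        assert model.aic_trace.loc[0, "AIC"] > model.aic_trace.loc[1, "AIC"]

    def test_orthogonal_interaction_selects_empty_model(self):
        rng = np.random.default_rng(3)
        e, g = 8, 10
        z = _cov(rng.normal(size=(e, 3)))
        # build an interaction in the orthogonal complement of the covariate span
        q, _ = np.linalg.qr(np.column_stack([np.ones(e), z.values]))
        raw = rng.normal(size=(g, e))
        proj = raw - (raw @ q) @ q.T
        ge = proj - proj.mean(axis=0, keepdims=True)
        model = stepwise_fr_aic(ge, z)
        assert model.selected_variables == []
        assert model.residual_ss == pytest.approx(model.total_ss)

    def test_duplicate_columns_tie_break_first_in_order(self):
        rng = np.random.default_rng(4)
        e, g = 8, 10
        zvals = rng.normal(size=(e, 1))
        z = _cov(np.hstack([zvals, zvals]), names=["dupA", "dupB"])
        xi = rng.normal(size=(g, 1))
        xi -= xi.mean()
        zc = zvals - zvals.mean()
        ge = xi @ zc.T
        model = stepwise_fr_aic(ge, z)
        assert model.selected_variables == ["dupA"]

    def test_perfect_fit_flagged(self):
        data, cov, truth = _linked(seed=7, active=(0,))
        model = stepwise_fr_aic(truth.interaction, center_covariates(cov))
        assert model.perfect_fit
        assert model.residual_ss <= 1e-10 * model.total_ss


class TestPLSR:
    def test_rank1_recovery(self):
        # mutually orthogonal covariate columns make the driving column an
        # eigendirection of XX', so one PLS factor captures all of Y
        rng = np.random.default_rng(5)
        e, k, g = 7, 4, 9
        raw = rng.normal(size=(e, k))
        raw -= raw.mean(axis=0, keepdims=True)
        qx, _ = np.linalg.qr(raw)
        x = _cov(qx)
        q = rng.normal(size=g)
        y = np.outer(x.values[:, 1], q)
        model = fit_plsr(x, y, n_factors=2)
        assert model.percent_y_explained[0] >= 99.9
        # scores orthogonal
        tt = model.x_scores.T @ model.x_scores
        off = np.abs(tt - np.diag(np.diag(tt))).max()
        assert off < 1e-8 * np.diag(tt).max()

    def test_zero_response(self):
        rng = np.random.default_rng(6)
        x = _cov(rng.normal(size=(6, 3)))
        model = fit_plsr(x, np.zeros((6, 4)), n_factors=2)
        np.testing.assert_array_equal(model.percent_y_explained, 0)

    def test_cumulative_percent_reaches_100_at_full_rank(self):
        rng = np.random.default_rng(7)
        e, g = 7, 5
        x = _cov(rng.normal(size=(e, 6)))
        raw = rng.normal(size=(e, g))
        y = raw - raw.mean(axis=0, keepdims=True)
        model = fit_plsr(x, y, n_factors=6)
        cum = model.percent_y_explained.cumsum()
        assert np.all(np.diff(cum) >= -1e-9)
        assert cum[-1] == pytest.approx(100.0, abs=1e-6)

    def test_matches_sklearn_pls2(self):
        """Independent oracle: scikit-learn's NIPALS PLS2 on the same matrices."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(9)
        e, k, g = 8, 5, 6
        xvals = rng.normal(size=(e, k))
        # well-separated factor structure so both NIPALS runs converge tightly
        raw = (
            np.outer(xvals[:, 0] + xvals[:, 1], rng.normal(size=g))
            + 0.3 * np.outer(xvals[:, 2], rng.normal(size=g))
            + 0.05 * rng.normal(size=(e, g))
        )
        y = raw - raw.mean(axis=0, keepdims=True)
        x = _cov(xvals)
        mine = fit_plsr(x, y, n_factors=3, tol=1e-13)
        ref = sklearn.PLSRegression(n_components=3, scale=False, tol=1e-12, max_iter=10_000).fit(x.values, y)
        for a in range(3):
            got = mine.x_scores[:, a]
            exp = ref.x_scores_[:, a]
            sign = np.sign(got @ exp)
            np.testing.assert_allclose(got, sign * exp, atol=1e-6 * np.abs(exp).max())

    def test_genotype_loadings_track_true_sensitivities(self):
        data, cov, truth = _linked(seed=11, active=(2,))
        x = center_covariates(cov, standardize=True)
        model = fit_plsr(x, truth.interaction.T, n_factors=2)
        r = np.corrcoef(model.y_loadings[:, 0], truth.xi_true[:, 2])[0, 1]
        assert abs(r) > 0.99

    def test_biplot_coordinates_and_sign_convention(self):
        data, cov, truth = _linked(seed=12)
        x = center_covariates(cov, standardize=True)
        m1 = fit_plsr(x, truth.interaction.T, n_factors=2)
        m2 = fit_plsr(x, truth.interaction.T, n_factors=2)
        c1, c2 = plsr_biplot_coords(m1), plsr_biplot_coords(m2)
        pd.testing.assert_frame_equal(c1, c2)
        for a in range(2):
            i = np.argmax(np.abs(m1.x_loadings[:, a]))
            assert m1.x_loadings[i, a] > 0
        with pytest.raises(ValueError):
            plsr_biplot_coords(fit_plsr(x, truth.interaction.T, n_factors=1))

    def test_uncentered_x_rejected(self):
        cov = CovariateMatrix(["E1", "E2", "E3"], ["v"], np.array([[1.0], [2.0], [3.0]]))
        with pytest.raises(ValueError, match="centered"):
            fit_plsr(cov, np.zeros((3, 2)), 1)
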