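"""ANOVA/ANCOVA fits: oracle agreement, invariants and error paths."""

import numpy as np
import pytest
from scipy import stats

from svpls import (
    CollinearScoreError,
    DegenerateDesignError,
    DimensionMismatchError,
    ExpressionMatrix,
    GroupDesign,
    SimulationSpec,
    ZeroRssError,
    corrected_matrix,
    fit_ancova,
    fit_anova,
    gene_tests,
    model_aic,
    simulate_dataset,
    svpls,
)
from svpls.containers import LinearFit

from oracles import aic_formula, ols_normal_equations, stacked_ols


def _design_matrix(design, scores=None):
    cols = [np.ones(design.n_samples), design.indicator()]
    if scores is not None:
        cols.append(scores)
    return np.column_stack(cols)


class TestFitAnova:
    def test_equal_replicates_give_exact_cell_means(self, toy_matrix, four_sample_design):
        fit = fit_anova(toy_matrix, four_sample_design)
        assert fit.n_surrogates == 0
        np.testing.assert_allclose(fit.contrast, [2.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(fit.intercept, [1.0, 2.0], atol=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_constant_matrix_has_zero_contrasts(self, four_sample_design):
        Y = ExpressionMatrix(np.full((3, 4), 2.5), ("a", "b", "c"), ("s1", "s2", "s3", "s4"))
        fit = fit_anova(Y, four_sample_design)
        np.testing.assert_allclose(fit.contrast, 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.intercept, 2.5, atol=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_coefficients_match_normal_equations_oracle(self, random_dataset):
        Y, design = random_dataset
        fit = fit_anova(Y, design)
        X = _design_matrix(design)
        for g in range(Y.n_genes):
            beta = ols_normal_equations(X, Y.values[g])
            assert fit.intercept[g] == pytest.approx(beta[0], abs=1e-8)
            assert fit.contrast[g] == pytest.approx(beta[1], abs=1e-8)

    def test_residuals_sum_to_zero_within_cells(self, random_dataset):
        Y, design = random_dataset
        fit = fit_anova(Y, design)
        for variety in (1, 2):
            cell = fit.residuals[:, design.variety == variety]
            np.testing.assert_allclose(cell.sum(axis=1), 0.0, atol=1e-8)

    def test_fitted_plus_residual_reproduces_input(self, random_dataset):
        Y, design = random_dataset
        fit = fit_anova(Y, design)
        np.testing.assert_allclose(fit.fitted() + fit.residuals, Y.values, rtol=1e-8)

    def test_dimension_mismatch_rejected(self, toy_matrix):
        with pytest.raises(DimensionMismatchError):
            fit_anova(toy_matrix, GroupDesign(np.array([1, 1, 1, 2, 2, 2])))

    def test_single_sample_variety_rejected(self):
        with pytest.raises(DegenerateDesignError):
            GroupDesign(np.array([1, 2, 2, 2]))


class TestFitAncova:
    def test_k0_reduces_to_anova(self, random_dataset):
        Y, design = random_dataset
        a = fit_anova(Y, design)
        b = fit_ancova(Y, design, np.empty((Y.n_samples, 0)))
        assert a.rss == b.rss
        assert a.aic == b.aic
        np.testing.assert_array_equal(a.contrast, b.contrast)

    def test_centered_variety_score_is_collinear(self, random_dataset):
        Y, design = random_dataset
        score = design.indicator() - design.indicator().mean()
        with pytest.raises(CollinearScoreError) as err:
            fit_ancova(Y, design, score[:, None])
        assert err.value.column == 2

    def test_coefficients_match_oracle_with_score(self, rng):
        values = rng.normal(0, 1, size=(3, 6))
        Y = ExpressionMatrix(values, ("g1", "g2", "g3"), tuple(f"s{i}" for i in range(6)))
        design = GroupDesign(np.repeat([1, 2], 3))
        score = rng.normal(0, 1, 6)
        score -= score.mean()
        fit = fit_ancova(Y, design, score[:, None])
        X = _design_matrix(design, score)
        rss = 0.0
        for g in range(3):
            beta = ols_normal_equations(X, values[g])
            assert fit.contrast[g] == pytest.approx(beta[1], abs=1e-8)
            assert fit.surrogate_coefs[g, 0] == pytest.approx(beta[2], abs=1e-8)
            rss += np.sum((values[g] - X @ beta) ** 2)
        assert fit.rss == pytest.approx(rss, rel=1e-8)

    def test_pergene_fit_equals_stacked_block_ols(self, random_dataset):
        Y, design = random_dataset
        fit = fit_anova(Y, design)
        coefs = stacked_ols(_design_matrix(design), Y.values)
        np.testing.assert_allclose(
            np.column_stack([fit.intercept, fit.contrast]), coefs, atol=1e-8
        )

    def test_rss_nonincreasing_in_nested_scores(self, rng):
        values = rng.normal(0, 1, size=(10, 12))
        Y = ExpressionMatrix(
            values, tuple(f"g{i}" for i in range(10)), tuple(f"s{i}" for i in range(12))
        )
        design = GroupDesign(np.repeat([1, 2], 6))
        scores = rng.normal(0, 1, size=(12, 3))
        scores -= scores.mean(axis=0)
        rss = [fit_ancova(Y, design, scores[:, :k]).rss for k in range(4)]
        assert all(rss[k + 1] <= rss[k] + 1e-10 for k in range(3))

    def test_residuals_orthogonal_to_design(self, rng):
        values = rng.normal(0, 1, size=(6, 10))
        Y = ExpressionMatrix(
            values, tuple(f"g{i}" for i in range(6)), tuple(f"s{i}" for i in range(10))
        )
        design = GroupDesign(np.repeat([1, 2], 5))
        scores = rng.normal(0, 1, size=(10, 2))
        fit = fit_ancova(Y, design, scores)
        inner = fit.residuals @ fit.design  # genes x design-cols
        scale = np.linalg.norm(fit.residuals) * np.linalg.norm(fit.design)
        assert np.max(np.abs(inner)) < 1e-6 * scale


class TestModelAic:
    def _fit_with(self, rss, p, n, k):
        q = 2 + k
        return LinearFit(
            n_surrogates=k,
            intercept=np.zeros(p),
            contrast=np.zeros(p),
            surrogate_coefs=np.zeros((p, k)),
            sigma2=rss / (p * n - p * q),
            df_resid=p * n - p * q,
            rss=rss,
            aic=aic_formula(rss, p, n, q) if rss > 0 else None,
            residuals=np.zeros((p, n)),
            design=np.zeros((n, q)),
            xtx_inv=np.eye(q),
            gene_ids=tuple(f"g{i}" for i in range(p)),
            sample_ids=tuple(f"s{i}" for i in range(n)),
        )

    def test_equal_rss_penalty_gap_is_2p(self):
        p = 7
        low = self._fit_with(3.5, p, 30, 1)
        high = self._fit_with(3.5, p, 30, 2)
        assert model_aic(high) - model_aic(low) == pytest.approx(2 * p)

    def test_matches_direct_formula(self, rng):
        values = rng.normal(0, 1, size=(3, 4))
        Y = ExpressionMatrix(values, ("g1", "g2", "g3"), ("s1", "s2", "s3", "s4"))
        fit = fit_anova(Y, GroupDesign(np.array([1, 1, 2, 2])))
        assert model_aic(fit) == pytest.approx(aic_formula(fit.rss, 3, 4, 2), rel=1e-12)

    def test_zero_rss_is_an_error(self, toy_matrix, four_sample_design):
        fit = fit_anova(toy_matrix, four_sample_design)
        with pytest.raises(ZeroRssError):
            model_aic(fit)
        with pytest.raises(ZeroRssError):
            gene_tests(fit)


class TestGeneTests:
    def test_null_contrast_gives_t0_p1(self, rng):
        values = np.vstack([rng.normal(0, 1, 4), [1.0, 2.0, 1.0, 2.0]])
        Y = ExpressionMatrix(values, ("g1", "g2"), ("s1", "s2", "s3", "s4"))
        fit = fit_anova(Y, GroupDesign(np.array([1, 1, 2, 2])))
        table = gene_tests(fit)
        row = table.set_index("gene_id").loc["g2"]
        assert row["t"] == pytest.approx(0.0, abs=1e-10)
        assert row["p_raw"] == pytest.approx(1.0, abs=1e-10)

    def test_se_matches_covariance_oracle(self, rng):
        values = rng.normal(0, 1, size=(2, 6))
        Y = ExpressionMatrix(values, ("g1", "g2"), tuple(f"s{i}" for i in range(6)))
        design = GroupDesign(np.repeat([1, 2], 3))
        fit = fit_anova(Y, design)
        X = _design_matrix(design)
        se_oracle = np.sqrt(fit.sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        table = gene_tests(fit)
        np.testing.assert_allclose(table["se"], se_oracle, rtol=1e-10)

    def test_global_null_type_one_error_calibrated(self):
        spec = SimulationSpec(
            n_genes=500, n_subjects=16, de_effect=0.0, affected_set1=None, seed=4242
        )
        ds = simulate_dataset(spec)
        table = gene_tests(fit_anova(ds.expression, ds.design))
        frac = float((table["p_raw"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_contrast_interval_coverage_near_nominal(self):
        rng = np.random.default_rng(101)
        p, n = 1000, 20
        variety = np.repeat([1, 2], 10)
        d_true = rng.normal(0, 1, p)
        values = (
            rng.normal(0, 1, p)[:, None]
            + np.outer(d_true, (variety == 2).astype(float))
            + rng.normal(0, 0.3, (p, n))
        )
        Y = ExpressionMatrix(
            values, tuple(f"g{i}" for i in range(p)), tuple(f"s{j}" for j in range(n))
        )
        fit = fit_anova(Y, GroupDesign(variety))
        se = np.sqrt(fit.sigma2 * fit.xtx_inv[1, 1])
        crit = stats.t.ppf(0.975, fit.df_resid)
        coverage = float(np.mean(np.abs(fit.contrast - d_true) <= crit * se))
        assert coverage == pytest.approx(0.95, abs=0.02)


class TestCorrectedMatrix:
    def test_k0_returns_input(self, random_dataset):
        Y, design = random_dataset
        fit = fit_anova(Y, design)
        assert corrected_matrix(fit, Y, np.empty((Y.n_samples, 0))) is Y

    def test_additivity_identity(self, rng):
        values = rng.normal(0, 1, size=(8, 10))
        Y = ExpressionMatrix(
            values, tuple(f"g{i}" for i in range(8)), tuple(f"s{i}" for i in range(10))
        )
        design = GroupDesign(np.repeat([1, 2], 5))
        scores = rng.normal(0, 1, size=(10, 2))
        fit = fit_ancova(Y, design, scores)
        corrected = corrected_matrix(fit, Y, scores)
        hidden = fit.surrogate_coefs @ scores.T
        np.testing.assert_allclose(corrected.values + hidden, Y.values, atol=1e-10)

    def test_hidden_effect_tracks_planted_confounder(self, setting1_dataset):
        ds = setting1_dataset
        result = svpls(ds.expression, ds.design)
        assert result.selected_k >= 1
        column_means = result.hidden_effects.mean(axis=0)
        corr = np.corrcoef(column_means, ds.confounder1)[0, 1]
        assert abs(corr) > 0.9
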