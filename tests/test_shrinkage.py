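import numpy as np
import pytest
from scipy.stats import gaussian_kde

from hyperplex.io import RunConfig, ValidationError
from hyperplex.shrinkage import (
    DegenerateInputError,
    LognormalShrinkage,
    MarkerMixture,
    fit_mixture,
    merge_unseparated,
    preprocess,
    shrink,
)
from hyperplex.synthetic import generate_cells, well_separated_panel


def two_comp_mixture():
    """Hand-built two-component fit: centers {0, 3}, SDs 0.2, equal weights."""
    c = np.array([0.0, 3.0])
    return MarkerMixture(np.array([0.5, 0.5]), c, np.array([0.2, 0.2]), c.copy())


class TestFitMixture:
    def test_single_lognormal_recovery(self, rng):
        """One lognormal(meanlog=1, sdlog=0.3): BIC picks K=1, center ~ 1."""
        values = np.exp(rng.normal(1.0, 0.3, 10000))
        mix = fit_mixture(values, max_components=5, seed=0, pseudocount=0.0)
        assert mix.n_components == 1
        assert abs(mix.centers[0] - 1.0) < 0.05

    def test_two_component_recovery(self, rng):
        """Equal lognormal mixture at meanlog {0, 3}: centers and weights recovered."""
        values = np.concatenate(
            [np.exp(rng.normal(0.0, 0.2, 5000)), np.exp(rng.normal(3.0, 0.2, 5000))]
        )
        mix = fit_mixture(values, max_components=5, seed=0, pseudocount=0.0)
        assert mix.n_components == 2
        assert abs(mix.centers[0] - 0.0) < 0.1
        assert abs(mix.centers[1] - 3.0) < 0.1
        assert abs(mix.weights[0] - 0.5) < 0.05

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_mixture(np.full(100, 2.5))

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            fit_mixture(np.arange(5.0))

    def test_components_sorted_by_center(self, rng):
        values = np.concatenate(
            [np.exp(rng.normal(2.0, 0.2, 3000)), np.exp(rng.normal(0.0, 0.2, 3000))]
        )
        mix = fit_mixture(values, seed=0, pseudocount=0.0)
        assert np.all(np.diff(mix.centers) > 0)


class TestMergeUnseparated:
    def test_overlapping_components_merge_preserving_moments(self):
        m = MarkerMixture(
            np.array([0.6, 0.4]), np.array([0.0, 0.5]),
            np.array([0.3, 0.3]), np.array([0.0, 0.5]),
        )
        total_mean = 0.6 * 0.0 + 0.4 * 0.5
        total_var = 0.6 * (0.09 + 0.0) + 0.4 * (0.09 + 0.25) - total_mean**2
        merged = merge_unseparated(m, threshold=4.0)
        assert merged.n_components == 1
        assert np.isclose(merged.centers[0], total_mean)
        assert np.isclose(merged.sds[0] ** 2, total_var)

    def test_separated_components_kept(self):
        assert merge_unseparated(two_comp_mixture(), threshold=4.0).n_components == 2

    def test_threshold_zero_disables(self):
        m = MarkerMixture(
            np.array([0.5, 0.5]), np.array([0.0, 0.1]),
            np.array([0.3, 0.3]), np.array([0.0, 0.1]),
        )
        assert merge_unseparated(m, threshold=0.0).n_components == 2


class TestShrink:
    def test_identity_at_lambda_one(self, rng):
        x = rng.normal(1.5, 1.0, 500)
        assert np.array_equal(shrink(x, two_comp_mixture(), 1.0), x)

    def test_collapse_at_lambda_zero_limit(self, rng):
        mix = two_comp_mixture()
        x = np.concatenate([rng.normal(0, 0.2, 200), rng.normal(3, 0.2, 200)])
        out = shrink(x, mix, 1e-12)
        centers = mix.centers[mix.assign(x)]
        assert np.max(np.abs(out - centers)) < 1e-9

    def test_hand_computed_example(self):
        """x=2.9 belongs to the upper component; x' = 3 + 0.5*(2.9-3) = 2.95."""
        out = shrink(np.array([2.9]), two_comp_mixture(), 0.5)
        assert np.isclose(out[0], 2.95)

    def test_within_component_distances_scale_exactly(self, rng):
        lam = 0.37
        mix = two_comp_mixture()
        x = rng.normal(3.0, 0.15, 100)  # all in the upper component
        out = shrink(x, mix, lam)
        d_in = np.abs(x[:, None] - x[None, :])
        d_out = np.abs(out[:, None] - out[None, :])
        np.testing.assert_allclose(d_out, lam * d_in, rtol=1e-12, atol=1e-12)

    def test_order_preserved_within_component(self, rng):
        x = np.sort(rng.normal(0, 0.2, 100))
        out = shrink(x, two_comp_mixture(), 0.3)
        assert np.all(np.diff(out) >= 0)

    def test_invalid_contraction(self):
        with pytest.raises(ValidationError):
            shrink(np.zeros(3), two_comp_mixture(), 0.0)


class TestPreprocess:
    def test_columns_standardized(self, toy_table):
        table, _ = toy_table
        m = preprocess(table, RunConfig(seed=0))
        np.testing.assert_allclose(m.values.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(m.values.std(axis=0), 1, atol=1e-6)

    def test_deterministic(self, toy_table):
        table, _ = toy_table
        a = preprocess(table, RunConfig(seed=0))
        b = preprocess(table, RunConfig(seed=0))
        assert np.array_equal(a.values, b.values)

    def test_constant_marker_flagged_as_zero_column(self, rng):
        from hyperplex.io import CellTable

        markers = np.column_stack([np.exp(rng.normal(0, 0.5, 200)), np.full(200, 3.0)])
        table = CellTable(np.arange(200), rng.uniform(0, 9, 200),
                          rng.uniform(0, 9, 200), markers, ["A", "const"])
        m = preprocess(table, RunConfig(seed=0))
        assert m.constant_mask.tolist() == [False, True]
        assert np.all(m.values[:, 1] == 0)

    def test_variance_scales_with_lambda_squared(self, rng):
        """Single-component marker: shrinking at lambda vs 1 scales the
        (pre-standardization) variance by exactly lambda^2."""
        values = np.exp(rng.normal(0.5, 0.4, 5000))
        mix = merge_unseparated(fit_mixture(values, seed=0))
        logv = np.log1p(values)
        v1 = shrink(logv, mix, 1.0)
        v01 = shrink(logv, mix, 0.1)
        assert mix.n_components == 1
        assert np.isclose(v01.var() / v1.var(), 0.01, rtol=1e-9)

    def test_never_nonfinite(self):
        spec = well_separated_panel(n_cells=400)
        table, _ = generate_cells(spec, seed=11)
        m = preprocess(table, RunConfig(seed=1))
        assert np.all(np.isfinite(m.values))

    def test_bimodality_enhanced(self, rng):
        """Two-mode marker: the valley-to-peak density ratio of shrunk data is
        no larger than that of the raw log data."""
        logv = np.concatenate([rng.normal(0, 0.35, 3000), rng.normal(2, 0.35, 3000)])
        mix = fit_mixture(np.exp(logv), seed=0, pseudocount=0.0)
        shrunk = shrink(logv, mix, 0.5)

        def valley_to_peak(v):
            kde = gaussian_kde(v)
            grid = np.linspace(v.min(), v.max(), 400)
            dens = kde(grid)
            mid = (grid > 0.5) & (grid < 1.5)
            return dens[mid].min() / dens.max()

        assert valley_to_peak(shrunk) <= valley_to_peak(logv)


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        est = LognormalShrinkage(contraction=0.3)
        assert est.get_params()["contraction"] == 0.3
        est.set_params(max_components=2)
        assert est.max_components == 2

    def test_transform_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            LognormalShrinkage().transform(np.ones((20, 2)))

    def test_median_target_changes_centers(self, rng):
        X = np.exp(rng.normal(1.0, 0.5, (2000, 1)))
        mean_model = LognormalShrinkage(target="mean", contraction=0.2).fit(X)
        med_model = LognormalShrinkage(target="median", contraction=0.2).fit(X)
        assert mean_model.mixtures_[0].shrink_centers[0] != pytest.approx(
            med_model.mixtures_[0].shrink_centers[0], abs=1e-12
        )

    def test_serializable_to_dict(self, rng):
        X = np.exp(rng.normal(0, 0.4, (500, 2)))
        model = LognormalShrinkage().fit(X)
        import json

        blob = json.dumps(model.to_dict())
        assert "markers" in json.loads(blob)

    def test_pipeline_composable(self, rng):
        from sklearn.pipeline import Pipeline
        from sklearn.decomposition import PCA

        X = np.exp(rng.normal(0, 0.4, (300, 3)))
        pipe = Pipeline([("shrink", LognormalShrinkage()), ("pca", PCA(2))])
        out = pipe.fit_transform(X)
        assert out.shape == (300, 2)
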