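import numpy as np
import pytest
from scipy.stats import chisquare

from nichefill import (
    DomainError,
    EnvRaster,
    density_contour,
    fit_weighted_pca,
    sample_background,
    sampling_effort_surface,
    screen_variables,
)
from nichefill.envspace import density_quantile_mask


@pytest.fixture()
def flat_raster():
    return EnvRaster(np.ones((20, 20)), origin=(0, 20), cell_size=(1, 1), crs_id="km")


class TestScreenVariables:
    def test_identical_columns_drop_lower_priority(self, rng):
        x = rng.standard_normal(200)
        out = screen_variables(np.column_stack([x, x]), ["A", "B"])
        assert out == ["A"]

    def test_independent_columns_all_kept(self, rng):
        X = rng.standard_normal((500, 4))
        assert screen_variables(X, list("ABCD")) == list("ABCD")

    def test_correlated_pair_resolved_by_priority(self, rng):
        a = rng.standard_normal(2000)
        b = 0.92 * a + np.sqrt(1 - 0.92**2) * rng.standard_normal(2000)
        c = rng.standard_normal(2000)
        out = screen_variables(np.column_stack([a, b, c]), ["A", "B", "C"], threshold=0.85)
        assert out == ["A", "C"]

    def test_constant_column_excluded(self, rng):
        X = np.column_stack([rng.standard_normal(100), np.full(100, 3.0)])
        assert screen_variables(X, ["A", "const"]) == ["A"]

    def test_invariant_to_duplicating_a_dropped_variable(self, rng):
        a = rng.standard_normal(1000)
        b = 0.95 * a + 0.05 * rng.standard_normal(1000)
        base = screen_variables(np.column_stack([a, b]), ["A", "B"])
        again = screen_variables(np.column_stack([a, b, b]), ["A", "B", "B2"])
        assert base == ["A"] and again == ["A"]


class TestSamplingEffort:
    def test_normalized_and_uniform_fallback(self, flat_raster):
        prob = sampling_effort_surface(np.empty((0, 2)), flat_raster)
        assert prob.values.sum() == pytest.approx(1.0)
        assert np.allclose(prob.values, prob.values[0, 0])

    def test_mode_at_record_cluster_and_positive_floor(self, flat_raster):
        pts = np.full((50, 2), [5.5, 14.5])  # all in one cell
        prob = sampling_effort_surface(pts, flat_raster)
        assert prob.values.sum() == pytest.approx(1.0)
        r, c = np.unravel_index(np.argmax(prob.values), prob.shape)
        assert (r, c) == flat_raster.cell_of(5.5, 14.5)
        assert (prob.values > 0).all()  # unsampled climates keep a floor


class TestSampleBackground:
    def test_reproducible_and_zero_prob_respected(self, flat_raster):
        vals = np.ones((20, 20))
        vals[:, :10] = 0.0
        prob = EnvRaster(vals / vals.sum(), origin=(0, 20), cell_size=(1, 1), crs_id="km")
        a = sample_background(prob, n=500, seed=7)
        b = sample_background(prob, n=500, seed=7)
        np.testing.assert_array_equal(a.points, b.points)
        assert (a.points[:, 0] >= 10).all()
        assert a.weights.sum() == pytest.approx(1.0)

    def test_uniform_surface_multinomial(self, flat_raster):
        prob = EnvRaster(np.full((20, 20), 1 / 400), origin=(0, 20), cell_size=(1, 1), crs_id="km")
        s = sample_background(prob, n=10_000, seed=3)
        counts, _, _ = np.histogram2d(s.points[:, 0], s.points[:, 1], bins=[np.arange(21)] * 2)
        assert chisquare(counts.ravel()).pvalue > 0.001

    def test_cell_frequencies_converge_with_n(self, flat_raster, rng):
        vals = rng.random((20, 20))
        prob = EnvRaster(vals / vals.sum(), origin=(0, 20), cell_size=(1, 1), crs_id="km")

        def l1(n, seed):
            s = sample_background(prob, n=n, seed=seed)
            counts, _, _ = np.histogram2d(
                s.points[:, 0], 20 - s.points[:, 1], bins=[np.arange(21)] * 2
            )
            return np.abs(counts.T / n - prob.values).sum()

        assert l1(100_000, 5) < l1(1_000, 5)


class TestWeightedPca:
    def test_uniform_weights_match_plain_pca(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = rng.standard_normal((300, 4)) @ rng.standard_normal((4, 4))
        model = fit_weighted_pca(X)
        Z = (X - X.mean(0)) / X.std(0)
        ref = sklearn.PCA(n_components=4).fit(Z)
        for k in range(4):
            dot = abs(np.dot(model.loadings[:, k], ref.components_[k]))
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_collinear_data_pc1_explains_everything(self, rng):
        t = rng.standard_normal(100)
        X = np.column_stack([t, 2 * t + 1])
        model = fit_weighted_pca(X)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_scores_have_zero_weighted_mean_and_orthonormal_loadings(self, rng):
        X = rng.standard_normal((400, 5))
        w = rng.random(400)
        model = fit_weighted_pca(X, w)
        scores = model.project(X)
        wn = w / w.sum()
        np.testing.assert_allclose(wn @ scores, 0.0, atol=1e-10)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(model.loadings.shape[1]), atol=1e-10
        )
        assert model.explained_variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(model.explained_variance_fraction) <= 1e-12).all()

    def test_weights_change_the_axes(self, rng):
        X = np.vstack([rng.normal(0, [3, 1], (200, 2)), rng.normal(0, [1, 3], (200, 2))])
        w = np.r_[np.ones(200), np.full(200, 1e-6)]
        model = fit_weighted_pca(X, w)
        # with nearly all weight on the first cloud, PC1 is its long axis (x)
        assert abs(model.loadings[0, 0]) > abs(model.loadings[1, 0])


class TestDensityContour:
    def test_quantile_masks_nest_and_grow(self, rng):
        pts = rng.standard_normal((500, 2))
        extent = (-4, 4, -4, 4)
        areas = []
        prev = None
        for q in (0.25, 0.5, 0.75, 1.0):
            mask, _ = density_contour(pts, q, extent=extent, resolution=60)
            if prev is not None:
                assert (mask | prev == mask).all()  # nesting
            areas.append(mask.sum())
            prev = mask
        assert areas == sorted(areas)

    def test_cluster_centroid_inside_mask(self, rng):
        pts = np.array([5.0, 5.0]) + 0.1 * rng.standard_normal((100, 2))
        mask, extent = density_contour(pts, 0.5, resolution=50)
        xmin, xmax, ymin, ymax = extent
        col = int((5.0 - xmin) / (xmax - xmin) * 50)
        row = int((5.0 - ymin) / (ymax - ymin) * 50)
        assert mask[row, col]

    def test_degenerate_quantile_rejected(self, rng):
        with pytest.raises(DomainError):
            density_contour(rng.standard_normal((50, 2)), 0.0)

    def test_quantile_mask_holds_requested_mass(self, rng):
        dens = rng.random((40, 40))
        mask = density_quantile_mask(dens, 0.5)
        assert dens[mask].sum() / dens.sum() >= 0.5
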