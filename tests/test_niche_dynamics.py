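import numpy as np
import pytest

from nichefill import (
    DensityGrid,
    DomainError,
    classify_env_regions,
    niche_dynamics_indices,
    niche_similarity_test,
    occupancy_mask,
    occurrence_density_grid,
    random_niche_pair,
    schoener_d,
)
from nichefill.niche_dynamics import REGION_LABELS, grid_centers, kde_grid

EXTENT = (0.0, 1.0, 0.0, 1.0)


def grid_from(z, e=None, extent=EXTENT):
    """DensityGrid whose z_cor is proportional to ``z`` (uniform availability)."""
    z = np.asarray(z, dtype=float)
    e = np.ones_like(z) if e is None else np.asarray(e, dtype=float)
    return DensityGrid(extent=extent, R=z.shape[-1], o=z, e=e)


def schoener_oracle(p1, p2):
    """Direct elementwise formula evaluation."""
    p1 = p1 / p1.sum()
    p2 = p2 / p2.sum()
    return 1.0 - 0.5 * sum(abs(a - b) for a, b in zip(p1.ravel(), p2.ravel()))


class TestDensityGrid:
    def test_z_uncor_normalized_to_max_one(self, rng):
        g = grid_from(rng.random((10, 10)))
        assert g.z_uncor.max() == pytest.approx(1.0)
        assert g.z_cor.max() == pytest.approx(1.0)

    def test_single_occurrence_density_peaks_at_its_cell(self, rng):
        bg = rng.uniform(0, 10, (500, 2))
        occ = np.array([[7.3, 2.6]])
        g = occurrence_density_grid(occ, bg, (0, 10, 0, 10), R=50, bandwidth=(0.5, 0.5))
        r, c = np.unravel_index(np.argmax(g.o), g.o.shape)
        xs, ys = grid_centers(g.extent, g.R)
        assert xs[c] == pytest.approx(7.3, abs=0.2)
        assert ys[r] == pytest.approx(2.6, abs=0.2)

    def test_uniform_occurrences_in_uniform_background_flat_z_cor(self, rng):
        bg = rng.uniform(0, 10, (5000, 2))
        occ = rng.uniform(0, 10, (5000, 2))
        g = occurrence_density_grid(occ, bg, (0, 10, 0, 10), R=40)
        z = g.z_cor[g.available]
        # interior cells only: edge cells share the same kernel falloff in o and e
        assert z.std() / z.mean() < 0.3

    def test_occurrence_outside_extent_rejected(self, rng):
        with pytest.raises(DomainError):
            occurrence_density_grid(np.array([[20.0, 0.5]]), rng.random((50, 2)), EXTENT)

    def test_kde_grid_matches_direct_evaluation(self, rng):
        pts = rng.random((40, 2))
        xs = np.linspace(0, 1, 7)
        ys = np.linspace(0, 1, 5)
        got = kde_grid(pts, xs, ys, (0.3, 0.2))
        direct = np.zeros((5, 7))
        for j, y in enumerate(ys):
            for i, x in enumerate(xs):
                k = np.exp(-0.5 * (((x - pts[:, 0]) / 0.3) ** 2 + ((y - pts[:, 1]) / 0.2) ** 2))
                direct[j, i] = k.sum() / (40 * 2 * np.pi * 0.3 * 0.2)
        np.testing.assert_allclose(got, direct, rtol=1e-12)


class TestSchoenerD:
    def test_identity_disjoint_and_exact_example(self):
        z = np.array([[0.5, 0.5], [0.0, 0.0]])
        u = np.array([[0.25, 0.25], [0.25, 0.25]])
        assert schoener_d(z, z) == pytest.approx(1.0)
        assert schoener_d(z, u) == pytest.approx(0.5)
        disjoint = np.array([[0.0, 0.0], [0.5, 0.5]])
        assert schoener_d(z, disjoint) == pytest.approx(0.0)

    def test_matches_oracle_on_random_grids(self, rng):
        for _ in range(50):
            a, b = rng.random((2, 10, 10))
            assert schoener_d(a, b) == pytest.approx(schoener_oracle(a, b), abs=1e-12)
            assert schoener_d(a, b) == schoener_d(b, a)
            assert 0.0 <= schoener_d(a, b) <= 1.0

    def test_mismatched_grids_rejected(self, rng):
        g1 = grid_from(rng.random((5, 5)))
        g2 = grid_from(rng.random((5, 5)), extent=(0, 2, 0, 2))
        with pytest.raises(DomainError):
            schoener_d(g1, g2)


class TestSimilarityTest:
    def test_p_bounds_and_reproducibility(self, rng):
        g1, g2 = random_niche_pair(np.random.default_rng(0), n_occ=60, n_background=500, R=40)
        p1, D1, null1 = niche_similarity_test(g1, g2, n_reps=49, seed=5)
        p2, D2, null2 = niche_similarity_test(g1, g2, n_reps=49, seed=5)
        assert p1 == p2 and np.array_equal(null1, null2)
        assert 1 / 50 <= p1 <= 1.0
        assert D1 == D2

    def test_colocated_niches_attain_minimum_p(self):
        g1, g2 = random_niche_pair(np.random.default_rng(9), colocated=True)
        p, D, _ = niche_similarity_test(g1, g2, n_reps=100, seed=2)
        assert p == pytest.approx(1 / 101)
        assert D > 0.5


class TestDynamicsIndices:
    def exact(self, z1, z2, **kw):
        g1, g2 = grid_from(np.atleast_2d(z1)), grid_from(np.atleast_2d(z2))
        kw.setdefault("occupancy_quantile", None)  # exact-threshold mode
        return niche_dynamics_indices(g1, g2, **kw)

    def test_four_cell_worked_example(self):
        E, S, U = self.exact([0.5, 0.5, 0.0, 0.0], [0.0, 0.5, 0.5, 0.0])
        assert (E, S, U) == (pytest.approx(0.5), pytest.approx(0.5), pytest.approx(0.5))

    def test_nested_support_no_expansion(self):
        E, S, U = self.exact([0.4, 0.4, 0.2, 0.0], [0.0, 1.0, 0.0, 0.0])
        assert E == 0.0 and S == 1.0

    def test_disjoint_supports_full_turnover(self):
        E, S, U = self.exact([1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0])
        assert E == 1.0 and U == 1.0 and S == 0.0

    def test_stability_complements_expansion_and_scale_invariance(self, rng):
        z1 = rng.random(8)
        z2 = rng.random(8)
        E, S, U = self.exact(z1, z2)
        assert E + S == pytest.approx(1.0, abs=1e-12)
        E2, S2, U2 = self.exact(z1, 3.7 * z2)
        # z_cor is rescaled to max 1 inside the grid, so a positive rescaling
        # of the input densities cannot change any index
        assert (E2, U2) == (pytest.approx(E), pytest.approx(U))

    def test_zero_density_in_analog_space_rejected(self):
        with pytest.raises(DomainError):
            self.exact([1.0, 1.0], [0.0, 0.0])

    def test_binary_occupancy_mode(self):
        E, S, U = self.exact(
            [0.9, 0.1, 0.0, 0.0], [0.0, 0.1, 0.9, 0.0], density_weighted=False
        )
        assert E == pytest.approx(0.5) and U == pytest.approx(0.5)


class TestOccupancyMask:
    def test_plain_threshold_and_quantile_trim(self):
        z = np.array([[0.5, 0.3, 0.15, 0.05, 0.0]])
        assert occupancy_mask(z).tolist() == [[True, True, True, True, False]]
        trimmed = occupancy_mask(z, mass_quantile=0.06)
        assert trimmed.tolist() == [[True, True, True, False, False]]


class TestClassifyRegions:
    def test_labels_partition_and_key_cases(self):
        shape = (1, 6)
        z1 = grid_from(np.array([[1.0, 1.0, 0.0, 0.0, 0.0, 0.0]]), e=np.array([[1, 1, 1, 1, 1, 0.0]]))
        z2 = grid_from(np.array([[0.0, 1.0, 1.0, 0.0, 0.0, 0.0]]), e=np.array([[1, 1, 1, 1, 0, 1.0]]))
        fund = np.array([[True, True, True, True, True, False]])
        out = classify_env_regions(
            z1.available, z2.available, z1, z2, fund, occupancy_quantile=None
        )
        assert out.shape == shape
        assert set(np.unique(out)) <= set(REGION_LABELS)
        assert out[0, 0] == "analog-native-only"
        assert out[0, 1] == "analog-occupied-both"
        assert out[0, 2] == "analog-nonnative-only"
        assert out[0, 3] == "analog-unoccupied-suitable"
        assert out[0, 4] == "non-analog-native-side"
        assert out[0, 5] == "unsuitable"  # outside the fundamental niche

    def test_suitable_but_unavailable_region(self):
        z1 = grid_from(np.array([[1.0, 0.0]]), e=np.array([[1.0, 0.0]]))
        z2 = grid_from(np.array([[1.0, 0.0]]), e=np.array([[1.0, 0.0]]))
        fund = np.array([[True, True]])
        out = classify_env_regions(z1.available, z2.available, z1, z2, fund, occupancy_quantile=None)
        assert out[0, 1] == "suitable-not-currently-available"

    def test_counts_sum_to_grid_size(self, rng):
        z1 = grid_from(rng.random((12, 12)))
        z2 = grid_from(rng.random((12, 12)))
        fund = rng.random((12, 12)) > 0.5
        out = classify_env_regions(z1.available, z2.available, z1, z2, fund)
        assert out.size == 144
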