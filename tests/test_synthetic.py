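import numpy as np
import pytest

from nichefill import (
    DomainError,
    FeasibilityError,
    ScenarioTruth,
    corner_bias_surface,
    default_turtle_model,
    make_invasion_scenario,
    make_landscape,
    simulate_virtual_species,
    suitability_map,
)
from nichefill.synthetic_data import CLIMATE_VARS


def lag1_autocorr(field):
    a = field[:, :-1].ravel()
    b = field[:, 1:].ravel()
    return np.corrcoef(a, b)[0, 1]


class TestMakeLandscape:
    def test_bit_reproducible(self):
        l1 = make_landscape(seed=5, size=(60, 60))
        l2 = make_landscape(seed=5, size=(60, 60))
        for v in l1.stack.names:
            np.testing.assert_array_equal(l1.stack[v].values, l2.stack[v].values)

    def test_neardist_consistent_with_water(self, small_landscape):
        water = small_landscape.stack["water"].values == 1
        near = small_landscape.stack["NearDist"].values
        assert (near[water] == 0).all()
        assert (near[~water] > 0).all()

    def test_temperature_spans_requested_range_and_autocorrelates(self):
        ls = make_landscape(seed=2, size=(100, 100), temp_range=(-15, 45))
        bio1 = ls.stack["BIO1"].values
        assert bio1.min() == pytest.approx(-15, abs=1e-6)
        assert bio1.max() == pytest.approx(45, abs=1e-6)
        assert lag1_autocorr(bio1) > 0.5

    def test_all_expected_layers_present(self, small_landscape):
        assert set(CLIMATE_VARS) <= set(small_landscape.stack.names)
        assert {"water", "NearDist"} <= set(small_landscape.stack.names)

    def test_invalid_arguments(self):
        with pytest.raises(DomainError):
            make_landscape(size=(20, 20))
        with pytest.raises(DomainError):
            make_landscape(n_water_bodies=0)


class TestSimulateVirtualSpecies:
    def test_reproducible_and_only_suitable_cells(self, small_landscape):
        model = default_turtle_model()
        occ1 = simulate_virtual_species(small_landscape, model, 300, seed=9)
        occ2 = simulate_virtual_species(small_landscape, model, 300, seed=9)
        assert [(r.lon, r.lat) for r in occ1] == [(r.lon, r.lat) for r in occ2]
        suit = suitability_map(small_landscape.stack, model)
        for r in occ1:
            row, col = suit.cell_of(r.lon, r.lat)
            assert suit.values[row, col] > 0

    def test_sampling_tracks_suitability(self, small_landscape):
        model = default_turtle_model()
        suit = suitability_map(small_landscape.stack, model)
        occ = simulate_virtual_species(small_landscape, model, 1000, seed=4)
        at_points = [suit.values[suit.cell_of(r.lon, r.lat)] for r in occ]
        assert np.mean(at_points) > np.nanmean(suit.values)

    def test_bias_surface_shifts_sampling(self, small_landscape):
        model = default_turtle_model()
        bias = corner_bias_surface(small_landscape, strength=0.95)
        occ = simulate_virtual_species(small_landscape, model, 800, seed=4, bias_surface=bias)
        occ_flat = simulate_virtual_species(small_landscape, model, 800, seed=4)
        # the bias bump sits near the low-x, high-y corner
        assert np.mean([r.lon for r in occ]) < np.mean([r.lon for r in occ_flat])


class TestInvasionScenario:
    def test_achieved_matches_targets_by_construction(self):
        truth = ScenarioTruth(target_unfilling=0.4, target_expansion=0.3, seed=2,
                              n_native=50, n_nonnative=50, n_reference=50)
        sc = make_invasion_scenario(truth, size=(60, 60))
        assert truth.achieved["unfilling"] == pytest.approx(0.4, abs=0.01)
        assert truth.achieved["expansion"] == pytest.approx(0.3, abs=0.01)
        assert truth.achieved["stability"] == pytest.approx(0.7, abs=0.01)
        assert len(sc.occ_native) == 50 and len(sc.occ_nonnative) == 50
        assert sc.reference_native.shape == (50, 2)

    def test_null_targets_share_everything(self):
        truth = ScenarioTruth(0.0, 0.0, seed=2, n_native=40, n_nonnative=40, n_reference=40)
        sc = make_invasion_scenario(truth, size=(60, 60))
        assert truth.achieved["unfilling"] == 0.0
        assert truth.achieved["expansion"] == 0.0
        assert sc.landscape_nonnative is sc.landscape_native
        xs = np.linspace(-5, 38, 500)
        np.testing.assert_allclose(
            sc.model_native.responses["BIO1"](xs), sc.model_nonnative.responses["BIO1"](xs)
        )

    def test_extreme_targets_are_infeasible(self):
        with pytest.raises(FeasibilityError):
            make_invasion_scenario(ScenarioTruth(0.0, 1.0, seed=1), size=(60, 60))

    def test_expansion_interval_outside_analog_rejected(self):
        truth = ScenarioTruth(0.2, 0.2, seed=1, n_native=30, n_nonnative=30)
        with pytest.raises(FeasibilityError):
            make_invasion_scenario(truth, expansion_interval=(50.0, 60.0), size=(60, 60))

    def test_nonnative_suitability_zero_in_unfilled_zone(self):
        truth = ScenarioTruth(0.4, 0.3, seed=2, n_native=30, n_nonnative=30, n_reference=30)
        sc = make_invasion_scenario(truth, size=(60, 60))
        cut = truth.achieved["cut_temperature"]
        xs = np.linspace(cut + 1e-6, 23.0, 200)
        assert (sc.model_nonnative.responses["BIO1"](xs)[xs > cut] == 0).all()
        lobe = np.linspace(29.5, 34.5, 50)
        assert (sc.model_nonnative.responses["BIO1"](lobe) > 0).all()
        assert (sc.model_native.responses["BIO1"](lobe) == 0).all()
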