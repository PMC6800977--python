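import numpy as np
import pytest

from nichefill import (
    DomainError,
    RasterStack,
    ToleranceLimits,
    VirtualSpeciesModel,
    beta_response,
    compose_tolerance_curve,
    default_turtle_model,
    logistic_response,
    occupied_range,
    suitability_map,
    unfilled_tolerance_report,
    water_distance_response,
)
from nichefill.fundamental_niche import ComposedCurve, ResponseCurve, beta_params_for_range


class TestBetaResponse:
    def test_zero_at_and_outside_bounds(self):
        assert beta_response(0.0, 0, 10, 2, 2) == 0.0
        assert beta_response(10.0, 0, 10, 2, 2) == 0.0
        assert beta_response(-3.0, 0, 10, 2, 2) == 0.0

    def test_symmetric_mode_reaches_one(self):
        assert beta_response(5.0, 0, 10, 2, 2) == pytest.approx(1.0)

    def test_closed_form_mode_location(self):
        # mode = (alpha p2 + gamma p1)/(alpha + gamma) = (2*9 + 1*0)/3 = 6
        xs = np.linspace(0, 9, 9001)
        f = beta_response(xs, 0, 9, 2, 1)
        assert xs[np.argmax(f)] == pytest.approx(6.0, abs=1e-2)
        assert beta_response(6.0, 0, 9, 2, 1) == pytest.approx(1.0, abs=1e-12)

    def test_parameter_errors(self):
        with pytest.raises(DomainError):
            beta_response(1.0, 5, 5, 2, 2)
        with pytest.raises(DomainError):
            beta_response(1.0, 0, 10, -1, 2)

    def test_codomain_unit_interval(self, rng):
        xs = rng.uniform(-50, 50, 1_000_000)
        f = beta_response(xs, -12.6, 42.3, 3.1, 1.7)
        assert (f >= 0).all() and (f <= 1).all()


class TestLogisticResponse:
    def test_midpoint_and_monotonicity(self):
        assert logistic_response(10.0, 2.5, 10.0) == pytest.approx(0.5)
        xs = np.linspace(-20, 50, 500)
        f = logistic_response(xs, 2.5, 10.0)
        assert (np.diff(f) < 0).all()

    def test_water_curve_orders_around_buffer(self):
        curve = water_distance_response()
        assert curve(np.array([0.0]))[0] > 0.5 > curve(np.array([20.0]))[0]
        assert curve(np.array([5.0]))[0] >= 0.88  # turtles roam 5-10 km to water


class TestRangeEncodedBeta:
    @pytest.mark.parametrize("lo,hi", [(16.8, 32.1), (10.0, 37.0), (26.7, 31.2)])
    def test_five_percent_height_at_endpoints(self, lo, hi):
        p = beta_params_for_range(lo, hi, -12.6, 42.3, rel_height=0.05)
        assert beta_response(lo, **p) == pytest.approx(0.05, abs=1e-8)
        assert beta_response(hi, **p) == pytest.approx(0.05, abs=1e-8)
        inside = np.linspace(lo, hi, 200)
        assert (beta_response(inside, **p) >= 0.05 - 1e-9).all()


class TestComposedToleranceCurve:
    curve = compose_tolerance_curve()

    def test_zero_at_and_beyond_lethal_limits(self):
        f = self.curve(np.array([-12.6, 42.3, 45.0, -20.0]))
        assert (f == 0.0).all()

    def test_support_is_open_lethal_interval(self):
        xs = np.linspace(-12.59, 42.29, 5001)
        assert (self.curve(xs) > 0).all()

    def test_maximum_one_inside_basking_incubation_zone(self):
        assert 25.6 <= self.curve.max_location <= 31.2
        xs = np.linspace(-12.6, 42.3, 20001)
        assert self.curve(xs).max() == pytest.approx(1.0, abs=1e-6)

    def test_product_with_disjoint_supports_rejected(self):
        comps = {
            "a": ResponseCurve("beta", {"p1": 0, "p2": 1, "alpha": 2, "gamma": 2}),
            "b": ResponseCurve("beta", {"p1": 2, "p2": 3, "alpha": 2, "gamma": 2}),
        }
        with pytest.raises(DomainError):
            ComposedCurve(comps, {"a": 1, "b": 1}, combine="product", support=(0, 3))

    def test_limit_invariants_enforced(self):
        with pytest.raises(DomainError):
            ToleranceLimits(lethal_range=(30.0, 20.0))
        with pytest.raises(DomainError):
            ToleranceLimits(egg_incubation_opt=50.0)


class TestSuitability:
    def test_product_bounded_by_min_component(self, small_landscape):
        model = default_turtle_model()
        model.rescale = False  # the bound concerns the raw composition
        suit = suitability_map(small_landscape.stack, model).values
        bio1 = small_landscape.stack["BIO1"].values
        dist = small_landscape.stack["NearDist"].values
        temp_resp = model.responses["BIO1"](bio1)
        dist_resp = model.responses["NearDist"](dist)
        ok = np.isfinite(suit)
        assert (suit[ok] <= np.minimum(temp_resp, dist_resp)[ok] + 1e-9).all()
        assert (suit[ok] >= 0).all() and (suit[ok] <= 1).all()

    def test_lethal_temperature_gives_zero(self, small_landscape):
        model = default_turtle_model()
        hot = {"BIO1": np.array([45.0]), "NearDist": np.array([0.0])}
        assert model.suitability(hot)[0] == 0.0

    def test_missing_variable_named_in_error(self, small_landscape):
        model = VirtualSpeciesModel(responses={"BIO99": lambda x: x})
        with pytest.raises(DomainError, match="BIO99"):
            suitability_map(small_landscape.stack, model)

    def test_monotone_in_each_response(self, rng):
        env = {"a": rng.random(100), "b": rng.random(100)}
        low = VirtualSpeciesModel({"a": lambda x: 0.3 * x, "b": lambda x: x}, composition="product")
        high = VirtualSpeciesModel({"a": lambda x: 0.6 * x, "b": lambda x: x}, composition="product")
        assert (high.suitability(env) >= low.suitability(env)).all()
        low_m = VirtualSpeciesModel(dict(low.responses), composition="mean")
        high_m = VirtualSpeciesModel(dict(high.responses), composition="mean")
        assert (high_m.suitability(env) >= low_m.suitability(env)).all()

    def test_rescaled_joint_optimum_reaches_one(self, small_landscape):
        suit = suitability_map(small_landscape.stack, default_turtle_model())
        assert np.nanmax(suit.values) == pytest.approx(1.0)


class TestOccupiedRange:
    def test_constant_values_collapse(self):
        (lo, hi), _ = occupied_range(np.full(50, 21.0))
        assert lo == hi == pytest.approx(21.0)

    def test_uniform_sample_covers_bulk(self, rng):
        (lo, hi), (xs, dens) = occupied_range(rng.uniform(0, 20, 5000))
        assert lo <= 2.0 and hi >= 18.0
        assert dens.max() == pytest.approx(1.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(DomainError):
            occupied_range([1.0] * 5)


class TestUnfilledReport:
    tolerance = staticmethod(lambda x: beta_response(x, 0.0, 10.0, 2.0, 2.0))

    def support(self):
        xs = np.linspace(0, 10, 4096)
        f = self.tolerance(xs)
        on = xs[f > 0.05]
        return on[0], on[-1]

    def test_full_filling_and_one_sided(self):
        lo, hi = self.support()
        assert unfilled_tolerance_report((lo, hi), self.tolerance, support=(0, 10)) == (0.0, 0.0)
        low, high = unfilled_tolerance_report((-5.0, lo - 0.1), self.tolerance, support=(0, 10))
        assert high == pytest.approx(1.0, abs=0.01) and low == 0.0

    def test_lower_half_occupied(self):
        lo, hi = self.support()
        low, high = unfilled_tolerance_report((lo, 5.0), self.tolerance, support=(0, 10))
        assert low == 0.0
        assert high == pytest.approx(0.5, abs=0.01)
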