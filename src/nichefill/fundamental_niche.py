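"""Mechanistic fundamental-niche model from physiological tolerance limits.

The slider turtle's temperature physiology, compiled from laboratory and
field reports, is encoded as response curves: each behaviour (egg
incubation, daily activity, feeding, normal activity, basking) becomes a
beta-shaped curve on the lethal interval, and distance to fresh water a
decreasing logistic. Curves compose into a habitat-suitability function that
projects onto rasters to map the potential distribution, and the occupied
temperature range (kernel density of temperatures at occurrence points) can
be laid against the tolerance curve to quantify how much of the fundamental
niche is left unfilled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import optimize
from scipy.stats import gaussian_kde

from .io_geo import DomainError, EnvRaster, RasterStack

__all__ = [
    "ToleranceLimits",
    "ResponseCurve",
    "ComposedCurve",
    "VirtualSpeciesModel",
    "beta_response",
    "logistic_response",
    "beta_params_for_mode",
    "beta_params_for_range",
    "compose_tolerance_curve",
    "default_turtle_model",
    "suitability_map",
    "occupied_range",
    "unfilled_tolerance_report",
]


@dataclass(frozen=True)
class ToleranceLimits:
    """Physiological tolerance constants (°C, km) for the slider turtle."""

    egg_incubation_opt: float = 29.5
    daily_activity_opt: float = 25.6
    feeding_range: tuple[float, float] = (16.8, 32.1)
    normal_activity_range: tuple[float, float] = (10.0, 37.0)
    basking_range: tuple[float, float] = (26.7, 31.2)
    lethal_range: tuple[float, float] = (-12.6, 42.3)
    water_buffer_km: float = 10.0

    def __post_init__(self) -> None:
        lo, hi = self.lethal_range
        if lo >= hi:
            raise DomainError("lethal range must be increasing")
        for opt in (self.egg_incubation_opt, self.daily_activity_opt):
            if not lo < opt < hi:
                raise DomainError(f"optimum {opt} outside lethal range")
        for rng in (self.feeding_range, self.normal_activity_range, self.basking_range):
            if not (lo <= rng[0] < rng[1] <= hi):
                raise DomainError(f"behaviour range {rng} not inside lethal range")


def beta_response(x, p1: float, p2: float, alpha: float, gamma: float) -> np.ndarray:
    """Beta-shaped response: k (x−p1)^alpha (p2−x)^gamma on (p1, p2), else 0.

    k normalizes the maximum to 1; the mode sits at
    (alpha·p2 + gamma·p1)/(alpha + gamma).
    """
    if p1 >= p2:
        raise DomainError("beta response requires p1 < p2")
    if alpha <= 0 or gamma <= 0:
        raise DomainError("alpha and gamma must be positive")
    x = np.asarray(x, dtype=float)
    mode = (alpha * p2 + gamma * p1) / (alpha + gamma)
    log_k = -(alpha * np.log(mode - p1) + gamma * np.log(p2 - mode))
    out = np.zeros_like(x, dtype=float)
    inside = (x > p1) & (x < p2)
    xi = x[inside]
    out[inside] = np.exp(log_k + alpha * np.log(xi - p1) + gamma * np.log(p2 - xi))
    return out


def logistic_response(x, alpha: float, beta_mid: float) -> np.ndarray:
    """f(x) = 1 / (1 + exp((x − beta_mid)/alpha)); decreasing for alpha > 0."""
    if alpha == 0:
        raise DomainError("alpha must be nonzero")
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(np.clip((x - beta_mid) / alpha, -500, 500)))


@dataclass
class ResponseCurve:
    """A named, evaluable response function with codomain within [0, 1]."""

    kind: str  # "beta" | "logistic"
    params: dict
    variable: str = ""
    units: str = ""

    def __call__(self, x) -> np.ndarray:
        if self.kind == "beta":
            return beta_response(x, **self.params)
        if self.kind == "logistic":
            return logistic_response(x, **self.params)
        raise DomainError(f"unknown response kind {self.kind!r}")

    @property
    def support(self) -> tuple[float, float]:
        if self.kind == "beta":
            return (self.params["p1"], self.params["p2"])
        return (-np.inf, np.inf)


def beta_params_for_mode(mode: float, p1: float, p2: float, concentration: float = 6.0) -> dict:
    """Beta parameters with a prescribed mode on (p1, p2).

    The mode equation leaves one degree of freedom; ``concentration`` fixes
    alpha + gamma (larger = narrower peak).
    """
    if not p1 < mode < p2:
        raise DomainError("mode must lie strictly inside (p1, p2)")
    alpha = concentration * (mode - p1) / (p2 - p1)
    return {"p1": p1, "p2": p2, "alpha": alpha, "gamma": concentration - alpha}


def beta_params_for_range(
    lo: float, hi: float, p1: float, p2: float, rel_height: float = 0.05
) -> dict:
    """Beta parameters whose curve crosses ``rel_height`` exactly at lo and hi.

    Encodes a reported behavioural range (lo, hi) as a near-plateau beta on
    the lethal interval (p1, p2): the curve equals ``rel_height`` of its
    maximum at the range endpoints, solved numerically for (alpha, gamma).
    """
    if not (p1 < lo < hi < p2):
        raise DomainError("range endpoints must lie strictly inside (p1, p2)")
    log_h = np.log(rel_height)

    def alpha_gamma(mode):
        # at a fixed mode the two endpoint conditions are linear in (alpha, gamma)
        A = np.array(
            [
                [np.log((lo - p1) / (mode - p1)), np.log((p2 - lo) / (p2 - mode))],
                [np.log((hi - p1) / (mode - p1)), np.log((p2 - hi) / (p2 - mode))],
            ]
        )
        return np.linalg.solve(A, [log_h, log_h])

    def mode_resid(mode):
        a, g = alpha_gamma(mode)
        if a <= 0 or g <= 0:
            return np.nan
        return (a * p2 + g * p1) / (a + g) - mode

    # scan for a sign change of the mode self-consistency residual, then refine
    grid = np.linspace(lo, hi, 402)[1:-1]
    resid = np.array([mode_resid(m) for m in grid])
    ok = np.isfinite(resid)
    sign_change = np.nonzero(ok[:-1] & ok[1:] & (resid[:-1] * resid[1:] <= 0))[0]
    if sign_change.size == 0:
        raise DomainError(f"no beta curve matches range ({lo}, {hi}) at height {rel_height} on ({p1}, {p2})")
    i = int(sign_change[0])
    mode = optimize.brentq(mode_resid, grid[i], grid[i + 1], xtol=1e-13)
    a, g = alpha_gamma(mode)
    return {"p1": p1, "p2": p2, "alpha": float(a), "gamma": float(g)}


@dataclass
class ComposedCurve:
    """Weighted combination of behaviour response curves on a shared support.

    The combined curve is exactly 0 at and beyond the lethal limits and is
    rescaled so its maximum is 1 (the location of the maximum is found
    numerically and cached).
    """

    components: dict[str, ResponseCurve]
    weights: dict[str, float]
    combine: str = "mean"  # "mean" | "product"
    support: tuple[float, float] = (-12.6, 42.3)
    _scale: float = field(init=False, default=1.0)
    max_location: float = field(init=False, default=np.nan)

    def __post_init__(self) -> None:
        wsum = sum(self.weights.values())
        if wsum <= 0:
            raise DomainError("weights must have positive sum")
        self.weights = {k: v / wsum for k, v in self.weights.items()}
        xs = np.linspace(self.support[0], self.support[1], 20001)[1:-1]
        raw = self._raw(xs)
        peak = raw.max()
        if peak <= 0:
            raise DomainError("composed curve is identically zero (disjoint behaviour supports under product)")
        i = int(np.argmax(raw))
        res = optimize.minimize_scalar(
            lambda x: -self._raw(np.array([x]))[0],
            bounds=(xs[max(i - 1, 0)], xs[min(i + 1, xs.size - 1)]),
            method="bounded",
            options={"xatol": 1e-12},
        )
        self._scale = 1.0 / -res.fun
        self.max_location = float(res.x)

    def _raw(self, x: np.ndarray) -> np.ndarray:
        vals = {k: c(x) for k, c in self.components.items()}
        if self.combine == "product":
            out = np.ones_like(np.asarray(x, dtype=float))
            for v in vals.values():
                out *= v
            return out
        out = np.zeros_like(np.asarray(x, dtype=float))
        for k, v in vals.items():
            out += self.weights[k] * v
        return out

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        lo, hi = self.support
        inside = (x > lo) & (x < hi)
        out[inside] = np.minimum(self._raw(x[inside]) * self._scale, 1.0)
        return out


def compose_tolerance_curve(
    limits: ToleranceLimits = ToleranceLimits(),
    weights: Mapping[str, float] | None = None,
    combine: str = "mean",
    rel_height: float = 0.05,
    concentration: float = 6.0,
) -> ComposedCurve:
    """The overall temperature tolerance curve combining all behaviours.

    Optima map to mode-pinned beta curves and reported ranges to near-plateau
    betas (``rel_height`` crossing at the range endpoints); every curve lives
    on the open lethal interval, so the composite is 0 at and beyond the
    lethal limits. Default combination: normalized equal-weight mean.
    """
    lo, hi = limits.lethal_range
    comp = {
        "egg_incubation": ResponseCurve("beta", beta_params_for_mode(limits.egg_incubation_opt, lo, hi, concentration), "BIO1", "degC"),
        "daily_activity": ResponseCurve("beta", beta_params_for_mode(limits.daily_activity_opt, lo, hi, concentration), "BIO1", "degC"),
        "feeding": ResponseCurve("beta", beta_params_for_range(*limits.feeding_range, lo, hi, rel_height), "BIO1", "degC"),
        "normal_activity": ResponseCurve("beta", beta_params_for_range(*limits.normal_activity_range, lo, hi, rel_height), "BIO1", "degC"),
        "basking": ResponseCurve("beta", beta_params_for_range(*limits.basking_range, lo, hi, rel_height), "BIO1", "degC"),
    }
    w = dict(weights) if weights is not None else {k: 1.0 for k in comp}
    return ComposedCurve(components=comp, weights=w, combine=combine, support=(lo, hi))


def water_distance_response(limits: ToleranceLimits = ToleranceLimits(), alpha: float = 2.5) -> ResponseCurve:
    """Decreasing logistic in distance-to-water with midpoint at the 10 km
    buffer; the default slope keeps suitability ≥ 0.88 at 5 km (turtles
    routinely roam 5–10 km overland to reach water)."""
    return ResponseCurve("logistic", {"alpha": alpha, "beta_mid": limits.water_buffer_km}, "NearDist", "km")


@dataclass
class VirtualSpeciesModel:
    """Response curves per environmental variable plus a composition rule."""

    responses: dict[str, Callable]
    composition: str = "product"  # "product" | "mean"
    rescale: bool = True

    def __post_init__(self) -> None:
        if not self.responses:
            raise DomainError("need at least one response")
        if self.composition not in ("product", "mean"):
            raise DomainError(f"unknown composition {self.composition!r}")

    def suitability(self, env: Mapping[str, np.ndarray]) -> np.ndarray:
        missing = [v for v in self.responses if v not in env]
        if missing:
            raise DomainError(f"missing variable(s) in environment: {missing}")
        vals = [np.clip(self.responses[v](np.asarray(env[v], dtype=float)), 0.0, 1.0) for v in self.responses]
        if self.composition == "product":
            out = vals[0].copy()
            for v in vals[1:]:
                out = out * v
            return out
        return sum(vals) / len(vals)


def default_turtle_model(limits: ToleranceLimits = ToleranceLimits()) -> VirtualSpeciesModel:
    """Product-composed suitability from the temperature tolerance composite
    (on annual mean temperature) and the distance-to-water logistic."""
    return VirtualSpeciesModel(
        responses={
            "BIO1": compose_tolerance_curve(limits),
            "NearDist": water_distance_response(limits),
        },
        composition="product",
        rescale=True,
    )


def suitability_map(stack: RasterStack, model: VirtualSpeciesModel) -> EnvRaster:
    """Per-cell habitat suitability in [0, 1]; nodata propagates.

    With ``model.rescale`` the surface is divided by its maximum over valid
    cells (when positive), matching the virtual-species convention.
    """
    missing = [v for v in model.responses if v not in stack]
    if missing:
        raise DomainError(f"stack is missing variable(s): {missing}")
    template = stack.template
    env = {v: stack[v].values for v in model.responses}
    valid = np.ones(template.shape, dtype=bool)
    for v in model.responses:
        valid &= stack[v].valid_mask
    filled = {v: np.where(valid, env[v], 0.0) for v in env}
    suit = model.suitability(filled)
    if model.rescale:
        peak = suit[valid].max() if valid.any() else 0.0
        if peak > 0:
            suit = suit / peak
    suit = np.where(valid, suit, np.nan)
    return template.like(suit)


def occupied_range(
    values,
    threshold_fraction: float = 0.05,
    grid_n: int = 2048,
) -> tuple[tuple[float, float], tuple[np.ndarray, np.ndarray]]:
    """Occupied interval of an environmental axis from occurrence values.

    A Gaussian KDE of the occupied values is rescaled to max 1; the returned
    interval is the contiguous region around the density mode where the
    density stays at or above ``threshold_fraction`` of its maximum. Also
    returns the (x, density) curve for plotting against tolerance curves.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise DomainError("need at least 10 values")
    if np.allclose(v.std(), 0):
        x = np.linspace(v[0] - 1, v[0] + 1, grid_n)
        dens = np.zeros(grid_n)
        dens[np.argmin(np.abs(x - v[0]))] = 1.0
        return (float(v[0]), float(v[0])), (x, dens)
    kde = gaussian_kde(v)
    pad = 4.0 * v.std() * kde.factor
    x = np.linspace(v.min() - pad, v.max() + pad, grid_n)
    dens = kde(x)
    dens = dens / dens.max()
    above = dens >= threshold_fraction
    i = int(np.argmax(dens))
    lo = i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i
    while hi < grid_n - 1 and above[hi + 1]:
        hi += 1
    return (float(x[lo]), float(x[hi])), (x, dens)


def unfilled_tolerance_report(
    occupied: tuple[float, float],
    tolerance: Callable,
    threshold: float = 0.05,
    grid_n: int = 4096,
    support: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Fractions of the tolerance support left unoccupied on each side.

    The tolerance support is where the (max-1) tolerance curve exceeds
    ``threshold``; returns (low-side, high-side) fractions of that support
    lying below/above the occupied interval, both in [0, 1].
    """
    if support is None:
        support = getattr(tolerance, "support", (-12.6, 42.3))
    xs = np.linspace(support[0], support[1], grid_n)
    f = np.asarray(tolerance(xs), dtype=float)
    on = f > threshold
    total = on.sum()
    if total == 0:
        raise DomainError("tolerance curve support is empty at this threshold")
    low = float(np.sum(on & (xs < occupied[0])) / total)
    high = float(np.sum(on & (xs > occupied[1])) / total)
    return low, high
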