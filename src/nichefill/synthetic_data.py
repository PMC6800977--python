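"""Synthetic landscapes and virtual-species occurrence sets with known truth.

The generator emulates, at desk scale, the inputs of a worldwide
niche-change study: six spatially autocorrelated climate-like surfaces on a
projected-km grid, a sparse freshwater mask with its distance layer, and
occurrence samples drawn proportionally to a known suitability surface with
optional sampling bias. Invasion scenarios carve a designed amount of niche
unfilling and expansion into the non-native suitability function along the
temperature axis, and record the *achieved* fractions so estimators can be
scored against what was actually constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fundamental_niche import VirtualSpeciesModel, beta_response, suitability_map
from .io_geo import (
    DomainError,
    EnvRaster,
    OccurrenceRecord,
    RangeLabel,
    RasterStack,
    distance_to_water,
)

CLIMATE_VARS = ["BIO1", "BIO10", "BIO11", "BIO12", "BIO14", "RAD"]


class FeasibilityError(DomainError):
    """Requested scenario targets cannot be realized on these landscapes."""


@dataclass
class SyntheticLandscape:
    stack: RasterStack
    seed: int
    size: tuple[int, int]
    truth: dict = field(default_factory=dict)

    @property
    def template(self) -> EnvRaster:
        return self.stack.template


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def make_landscape(
    seed: int = 0,
    size: tuple[int, int] = (200, 200),
    n_water_bodies: int = 8,
    temp_range: tuple[float, float] = (-15.0, 45.0),
    autocorr_cells: float = 15.0,
    cell_km: float = 1.0,
) -> SyntheticLandscape:
    """Generate an aligned stack of climate-like surfaces plus water layers.

    Each surface is a broad spatial gradient plus Gaussian-filtered noise
    (autocorrelation length ``autocorr_cells``); the annual-temperature
    surface spans ``temp_range``, warm/cold-quarter surfaces track it with
    ±8 °C offsets, precipitation runs along the other gradient direction, and
    water bodies are random disks whose distance field (km) is computed with
    the package's own distance transform. Bit-reproducible under ``seed``.
    """
    nrow, ncol = size
    if nrow < 50 or ncol < 50:
        raise DomainError("landscape must be at least 50x50")
    if n_water_bodies < 1:
        raise DomainError("need at least one water body")
    rng = np.random.default_rng(seed)
    rows, cols = np.indices(size).astype(float)
    gx = cols / (ncol - 1)
    gy = rows / (nrow - 1)

    def field01(gradient, noise_amp):
        f = gradient + noise_amp * _smooth_noise(rng, size, autocorr_cells)
        f -= f.min()
        peak = f.max()
        return f / peak if peak > 0 else f

    t0, t1 = temp_range
    bio1 = t0 + (t1 - t0) * field01(gx, 0.25)
    bio10 = bio1 + 8.0 + 2.0 * _smooth_noise(rng, size, autocorr_cells)
    bio11 = bio1 - 8.0 + 2.0 * _smooth_noise(rng, size, autocorr_cells)
    bio12 = 3000.0 * field01(gy, 0.3)
    bio14 = np.clip(bio12 / 15.0 + 25.0 * _smooth_noise(rng, size, autocorr_cells), 0.0, None)
    rad = 12000.0 + 8000.0 * field01(0.5 * (gx + gy), 0.3)

    water = np.zeros(size)
    centers = rng.integers(0, [nrow, ncol], size=(n_water_bodies, 2))
    radii = rng.uniform(2.0, 6.0, size=n_water_bodies)
    for (r, c), rad_cells in zip(centers, radii):
        water[(rows - r) ** 2 + (cols - c) ** 2 <= rad_cells**2] = 1.0

    origin = (0.0, nrow * cell_km)
    cs = (cell_km, cell_km)
    crs = "synthetic-km"
    layers = {
        "BIO1": EnvRaster(bio1, origin, cs, crs),
        "BIO10": EnvRaster(bio10, origin, cs, crs),
        "BIO11": EnvRaster(bio11, origin, cs, crs),
        "BIO12": EnvRaster(bio12, origin, cs, crs),
        "BIO14": EnvRaster(bio14, origin, cs, crs),
        "RAD": EnvRaster(rad, origin, cs, crs),
        "water": EnvRaster(water, origin, cs, crs),
    }
    layers["NearDist"] = distance_to_water(layers["water"])
    stack = RasterStack(layers)
    truth = {
        "temp_range": temp_range,
        "autocorr_cells": autocorr_cells,
        "n_water_bodies": n_water_bodies,
        "cell_km": cell_km,
        "water_centers": centers.tolist(),
        "water_radii": radii.tolist(),
    }
    return SyntheticLandscape(stack=stack, seed=seed, size=size, truth=truth)


def corner_bias_surface(landscape: SyntheticLandscape, strength: float = 0.5, sigma_fraction: float = 0.25) -> np.ndarray:
    """Multiplicative sampling-bias field: a Gaussian bump near one corner
    (uneven recording effort), blended with a uniform floor by ``strength``."""
    nrow, ncol = landscape.size
    rows, cols = np.indices(landscape.size).astype(float)
    r0, c0 = 0.15 * nrow, 0.15 * ncol
    sigma = sigma_fraction * max(nrow, ncol)
    bump = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2.0 * sigma**2))
    return (1.0 - strength) + strength * bump


def simulate_virtual_species(
    landscape: SyntheticLandscape,
    model: VirtualSpeciesModel,
    n: int,
    seed: int | np.random.Generator = 0,
    bias_surface: np.ndarray | None = None,
    label: RangeLabel = RangeLabel.UNASSIGNED,
) -> list[OccurrenceRecord]:
    """Sample occurrences with cell probability ∝ suitability × bias.

    One point is placed uniformly inside each sampled cell (cells may repeat);
    zero-suitability cells are never sampled.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    suit = suitability_map(landscape.stack, model)
    p = np.where(suit.valid_mask, suit.values, 0.0)
    if bias_surface is not None:
        p = p * np.asarray(bias_surface, dtype=float)
    total = p.sum()
    if total <= 0:
        raise DomainError("suitability is zero everywhere; cannot sample occurrences")
    flat = (p / total).ravel()
    nrow, ncol = suit.shape
    idx = rng.choice(flat.size, size=n, p=flat)
    rr, cc = np.divmod(idx, ncol)
    ox, oy = suit.origin
    dx, dy = suit.cell_size
    u = rng.random((n, 2))
    xs = ox + (cc + u[:, 0]) * dx
    ys = oy - (rr + u[:, 1]) * dy
    return [
        OccurrenceRecord(id=str(i), lon=float(x), lat=float(y), range_label=label, source="synthetic")
        for i, (x, y) in enumerate(zip(xs, ys))
    ]


class NicheResponse:
    """1-D suitability along temperature for a scenario range.

    Base beta niche on (t_lo, t_hi), optionally truncated above ``cut``
    (the unfilled portion) and augmented by a separate expansion lobe — a
    beta-shaped bump scaled to height ``expansion_height`` on
    ``expansion_interval``.
    """

    def __init__(self, t_lo, t_hi, alpha=2.0, gamma=2.0, cut=None, taper=0.0, expansion_interval=None, expansion_height=0.0):
        self.t_lo, self.t_hi = t_lo, t_hi
        self.alpha, self.gamma = alpha, gamma
        self.cut = cut
        self.taper = taper
        self.expansion_interval = expansion_interval
        self.expansion_height = expansion_height

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = beta_response(x, self.t_lo, self.t_hi, self.alpha, self.gamma)
        if self.cut is not None:
            if self.taper > 0:
                # cosine ramp down to exactly 0 at the cut: a gradual range
                # retreat rather than a cliff edge
                w = self.taper
                ramp = np.where(
                    x <= self.cut - w,
                    1.0,
                    np.where(x >= self.cut, 0.0, 0.5 * (1.0 + np.cos(np.pi * (x - (self.cut - w)) / w))),
                )
                out = out * ramp
            else:
                out = np.where(x > self.cut, 0.0, out)
        if self.expansion_interval is not None and self.expansion_height > 0:
            a, b = self.expansion_interval
            out = out + self.expansion_height * beta_response(x, a, b, 2.0, 2.0)
        return np.clip(out, 0.0, 1.0)

    @property
    def support(self) -> tuple[float, float]:
        hi = self.t_hi if self.cut is None else self.cut
        if self.expansion_interval is not None and self.expansion_height > 0:
            return (self.t_lo, max(hi, self.expansion_interval[1]))
        return (self.t_lo, hi)


@dataclass
class ScenarioTruth:
    """Design targets and (after construction) achieved values of a scenario."""

    target_unfilling: float = 0.0
    target_expansion: float = 0.0
    n_native: int = 1000
    n_nonnative: int = 1000
    n_reference: int = 2000
    bias_strength: float = 0.5
    seed: int = 0
    model: VirtualSpeciesModel | None = None
    achieved: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in (self.target_unfilling, self.target_expansion):
            if not 0.0 <= t <= 1.0:
                raise DomainError("targets must be in [0, 1]")


@dataclass
class InvasionScenario:
    occ_native: list[OccurrenceRecord]
    occ_nonnative: list[OccurrenceRecord]
    landscape_native: SyntheticLandscape
    landscape_nonnative: SyntheticLandscape
    model_native: VirtualSpeciesModel
    model_nonnative: VirtualSpeciesModel
    truth: ScenarioTruth
    #: reference-taxon records whose density mirrors recording effort only
    #: (the analysis estimates its sampling-effort surface from these)
    reference_native: np.ndarray | None = None
    reference_nonnative: np.ndarray | None = None


def sample_reference_points(
    landscape: SyntheticLandscape,
    n: int,
    seed: int | np.random.Generator = 0,
    bias_surface: np.ndarray | None = None,
) -> np.ndarray:
    """Reference-taxon records: points whose density reflects recording
    effort (the bias surface) but not the focal species' suitability —
    the raw material for a sampling-effort correction."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template = landscape.template
    p = template.valid_mask.astype(float)
    if bias_surface is not None:
        p = p * np.asarray(bias_surface, dtype=float)
    flat = (p / p.sum()).ravel()
    nrow, ncol = template.shape
    idx = rng.choice(flat.size, size=n, p=flat)
    rr, cc = np.divmod(idx, ncol)
    ox, oy = template.origin
    dx, dy = template.cell_size
    u = rng.random((n, 2))
    return np.column_stack([ox + (cc + u[:, 0]) * dx, oy - (rr + u[:, 1]) * dy])


def _mass(f, lo, hi, n=20001):
    xs = np.linspace(lo, hi, n)
    return np.trapezoid(f(xs), xs)


def make_invasion_scenario(
    truth: ScenarioTruth,
    landscape_native: SyntheticLandscape | None = None,
    landscape_nonnative: SyntheticLandscape | None = None,
    niche_interval: tuple[float, float] = (5.0, 23.0),
    expansion_interval: tuple[float, float] = (29.0, 35.0),
    taper_width: float = 3.0,
    size: tuple[int, int] = (200, 200),
) -> InvasionScenario:
    """Build native/non-native occurrence sets with designed niche change.

    The native niche is a beta response on annual temperature over
    ``niche_interval``. The non-native niche (a) truncates the warm tail of
    the native niche at the temperature below which exactly
    1 − ``target_unfilling`` of the native suitability mass lies, and (b) adds
    an expansion lobe on ``expansion_interval`` — outside the native niche but
    inside the climates available to *both* ranges (analog space) — scaled to
    carry ``target_expansion`` of the non-native suitability mass. Achieved
    fractions are recomputed by numeric integration over the analog
    temperature interval and stored in ``truth.achieved``.
    """
    rng = np.random.default_rng(truth.seed)
    null_scenario = truth.target_unfilling == 0.0 and truth.target_expansion == 0.0
    base_seed = int(rng.integers(2**31))
    if landscape_native is None:
        landscape_native = make_landscape(seed=base_seed, size=size, temp_range=(-5.0, 38.0))
    if landscape_nonnative is None:
        # same structural seed, shifted thermal regime: the invaded region
        # shares the native region's internal climate organisation but offers
        # warmer (non-analog) climates at its margin
        landscape_nonnative = (
            landscape_native
            if null_scenario
            else make_landscape(seed=base_seed, size=size, temp_range=(0.0, 43.0))
        )

    t_lo, t_hi = niche_interval
    bio1_n = landscape_native.stack["BIO1"].values
    bio1_i = landscape_nonnative.stack["BIO1"].values
    analog_lo = max(np.nanmin(bio1_n), np.nanmin(bio1_i))
    analog_hi = min(np.nanmax(bio1_n), np.nanmax(bio1_i))
    if not (analog_lo < t_lo and t_hi < analog_hi):
        raise FeasibilityError(
            f"native niche {niche_interval} not inside the analog temperature interval "
            f"({analog_lo:.1f}, {analog_hi:.1f})"
        )
    if truth.target_expansion > 0 and not (t_hi <= expansion_interval[0] < expansion_interval[1] <= analog_hi):
        raise FeasibilityError(
            f"expansion interval {expansion_interval} must lie between the native niche "
            f"upper limit {t_hi} and the analog maximum {analog_hi:.1f}"
        )
    if truth.target_unfilling >= 1.0 or truth.target_expansion >= 1.0:
        raise FeasibilityError("targets must be < 1: some shared niche must remain")

    base = NicheResponse(t_lo, t_hi)
    native_model = truth.model or VirtualSpeciesModel(responses={"BIO1": base}, composition="product", rescale=True)

    # (a) unfilling: cut the warm tail carrying target_unfilling of native mass
    cut = None
    if truth.target_unfilling > 0:
        total = _mass(base, t_lo, t_hi)
        lo_grid = np.linspace(t_lo, t_hi, 4001)
        cum = np.array([_mass(base, t_lo, t) for t in lo_grid]) / total
        cut = float(np.interp(1.0 - truth.target_unfilling, cum, lo_grid))
    # (b) expansion: lobe height making the lobe target_expansion of non-native mass
    height = 0.0
    taper = taper_width if cut is not None else 0.0
    if truth.target_expansion > 0:
        shared = NicheResponse(t_lo, t_hi, cut=cut, taper=taper)
        m_shared = _mass(shared, t_lo, t_hi)
        m_lobe_unit = _mass(lambda x: beta_response(x, *expansion_interval, 2.0, 2.0), *expansion_interval)
        e = truth.target_expansion
        height = float(e / (1.0 - e) * m_shared / m_lobe_unit)
        if height > 1.0:
            raise FeasibilityError(
                f"target expansion {e} needs lobe height {height:.2f} > 1; "
                "widen expansion_interval or lower the target"
            )
    invader = NicheResponse(t_lo, t_hi, cut=cut, taper=taper, expansion_interval=expansion_interval if height > 0 else None, expansion_height=height)
    nonnative_model = VirtualSpeciesModel(responses={"BIO1": invader}, composition="product", rescale=True)

    # achieved fractions over the analog interval (uniform measure over climate)
    xs = np.linspace(analog_lo, analog_hi, 40001)
    s1 = base(xs)
    s2 = invader(xs)
    eps = 1e-12
    u_ach = float(np.trapezoid(np.where(s2 <= eps, s1, 0.0), xs) / np.trapezoid(s1, xs))
    e_ach = float(np.trapezoid(np.where(s1 <= eps, s2, 0.0), xs) / np.trapezoid(s2, xs))
    truth.achieved = {
        "unfilling": u_ach,
        "expansion": e_ach,
        "stability": 1.0 - e_ach,
        "cut_temperature": cut,
        "expansion_height": height,
        "analog_interval": (float(analog_lo), float(analog_hi)),
    }

    bias_n = corner_bias_surface(landscape_native, truth.bias_strength) if truth.bias_strength > 0 else None
    bias_i = corner_bias_surface(landscape_nonnative, truth.bias_strength) if truth.bias_strength > 0 else None
    ref_n = sample_reference_points(landscape_native, truth.n_reference, np.random.default_rng([truth.seed, 3]), bias_n)
    ref_i = sample_reference_points(landscape_nonnative, truth.n_reference, np.random.default_rng([truth.seed, 4]), bias_i)
    occ_native = simulate_virtual_species(
        landscape_native, native_model, truth.n_native,
        seed=np.random.default_rng([truth.seed, 1]), bias_surface=bias_n, label=RangeLabel.NATIVE,
    )
    occ_nonnative = simulate_virtual_species(
        landscape_nonnative, nonnative_model, truth.n_nonnative,
        seed=np.random.default_rng([truth.seed, 2]), bias_surface=bias_i, label=RangeLabel.NON_NATIVE,
    )
    return InvasionScenario(
        occ_native=occ_native,
        occ_nonnative=occ_nonnative,
        landscape_native=landscape_native,
        landscape_nonnative=landscape_nonnative,
        model_native=native_model,
        model_nonnative=nonnative_model,
        truth=truth,
        reference_native=ref_n,
        reference_nonnative=ref_i,
    )
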