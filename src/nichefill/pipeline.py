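"""Configuration-driven orchestration of the full niche-change analysis.

``run_pipeline`` executes the whole workflow on a synthetic invasion
scenario: landscape + occurrence generation, background sampling, weighted
PCA, occurrence-density grids, overlap/similarity/niche-change indices,
6-D hypervolume set operations, the CPCA covariance hierarchy, tolerance
curves and suitability projection, and the analog/non-analog region
classification — writing one consolidated JSON report (plus grids and
optional plots) with every stage's parameters and seeds logged. All
randomness flows from one master seed through named substreams, so a rerun
with the same config is bit-identical.

File-based inputs (occurrence CSVs, ASCII-grid rasters, GeoJSON range
polygons) are handled by composing the :mod:`nichefill.io_geo` functions
directly; the examples show that path.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cpca as cpca_mod
from . import hypervolume as hv_mod
from .envspace import default_extent, fit_weighted_pca, sample_background, sampling_effort_surface
from .fundamental_niche import (
    ToleranceLimits,
    compose_tolerance_curve,
    occupied_range,
    suitability_map,
    unfilled_tolerance_report,
)
from .io_geo import DomainError, RasterStack, extract_env, write_ascii_grid
from .niche_dynamics import (
    DEFAULT_OCCUPANCY_QUANTILE,
    DensityGrid,
    NicheDynamics,
    classify_env_regions,
    niche_dynamics_indices,
    niche_similarity_test,
    occurrence_density_grid,
    schoener_d,
    silverman_grid_bandwidth,
)
from .synthetic_data import CLIMATE_VARS, InvasionScenario, ScenarioTruth, make_invasion_scenario

logger = logging.getLogger(__name__)

#: fixed substream indices so stage seeds never depend on execution order
STAGE_STREAMS = {"scenario": 1, "background": 2, "similarity": 3, "hypervolume": 4}


@dataclass
class RunConfig:
    """Everything a full synthetic-scenario run needs, in one place."""

    seed: int = 0
    target_unfilling: float = 0.4
    target_expansion: float = 0.3
    n_native: int = 1000
    n_nonnative: int = 1000
    bias_strength: float = 0.5
    landscape_size: tuple[int, int] = (200, 200)
    n_background: int = 10000
    grid_R: int = 100
    n_reps: int = 100
    tau: float = 0.0
    occupancy_quantile: float | None = DEFAULT_OCCUPANCY_QUANTILE
    hv_samples_per_point: int = 100
    hv_threshold_quantile: float = 1.0
    tolerance_limits: ToleranceLimits = field(default_factory=ToleranceLimits)
    make_plots: bool = False
    out_dir: str | None = None

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, STAGE_STREAMS[stage]])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["landscape_size"] = list(self.landscape_size)
        d["tolerance_limits"] = dataclasses.asdict(self.tolerance_limits)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tolerance_limits" in raw:
            tl = raw.pop("tolerance_limits")
            for key in ("feeding_range", "normal_activity_range", "basking_range", "lethal_range"):
                if key in tl:
                    tl[key] = tuple(tl[key])
            raw["tolerance_limits"] = ToleranceLimits(**tl)
        if "landscape_size" in raw:
            raw["landscape_size"] = tuple(raw["landscape_size"])
        return cls(**raw)


def env_matrix_for(records, landscape, variables=CLIMATE_VARS) -> np.ndarray:
    """Climate matrix at occurrence points; rows flagged invalid are dropped."""
    stack = RasterStack({v: landscape.stack[v] for v in variables})
    mat, flags = extract_env(records, stack)
    return mat[flags == "ok"]


def analyze_scenario(
    scenario: InvasionScenario,
    n_background: int = 10000,
    R: int = 100,
    n_reps: int = 100,
    seed: int = 0,
    tau: float = 0.0,
    occupancy_quantile: float | None = DEFAULT_OCCUPANCY_QUANTILE,
    overlap_bw_scale: float = 2.0,
):
    """Environmental-space niche comparison for an invasion scenario.

    Backgrounds are sampled from each landscape's sampling-effort surface
    (estimated from the scenario's reference-taxon records; uniform over
    valid cells when none exist), the
    PCA is calibrated on the pooled backgrounds and occurrences (all rows at
    equal weight, each occurrence counting as one background point), and the
    two leading axes host the density grids. Returns
    ``(NicheDynamics, grid_native, grid_nonnative, pca, scores_dict)``.
    """
    rng_bg = np.random.default_rng([seed, STAGE_STREAMS["background"]])
    rng_sim = np.random.default_rng([seed, STAGE_STREAMS["similarity"]])
    env, scores = {}, {}
    for key, landscape, occ, ref in (
        ("native", scenario.landscape_native, scenario.occ_native, scenario.reference_native),
        ("nonnative", scenario.landscape_nonnative, scenario.occ_nonnative, scenario.reference_nonnative),
    ):
        template = landscape.stack[CLIMATE_VARS[0]]
        # background weighted by recording effort (estimated from the
        # reference-taxon records), so z_cor cancels the sampling bias
        prob = sampling_effort_surface(ref if ref is not None else np.empty((0, 2)), template)
        bg = sample_background(prob, n_background, seed=rng_bg)
        env[f"bg_{key}"] = env_matrix_for(bg.points, landscape)
        env[f"occ_{key}"] = env_matrix_for(occ, landscape)

    pooled = np.vstack([env["bg_native"], env["bg_nonnative"], env["occ_native"], env["occ_nonnative"]])
    pca = fit_weighted_pca(pooled, variable_names=list(CLIMATE_VARS))
    for key, mat in env.items():
        scores[key] = pca.project(mat, n_axes=2)
    extent = default_extent(pca.project(pooled, n_axes=2))

    # one bandwidth (pooled occurrences) for all four densities: the o/e
    # ratio and any cross-range comparison require a common smoothing scale.
    # Two estimands, two scales: occupancy *support* (E/S/U masks) keeps the
    # Silverman bandwidth for resolution, while the overlap statistic D and
    # its randomization test use ``overlap_bw_scale``-times-smoother grids —
    # D compares whole distributions, where kernel variance, not boundary
    # resolution, dominates the error.
    bw_n = silverman_grid_bandwidth(scores["occ_native"])
    bw_i = silverman_grid_bandwidth(scores["occ_nonnative"])
    bw = (0.5 * (bw_n[0] + bw_i[0]), 0.5 * (bw_n[1] + bw_i[1]))
    grid_native = occurrence_density_grid(scores["occ_native"], scores["bg_native"], extent, R=R, bandwidth=bw)
    grid_nonnative = occurrence_density_grid(scores["occ_nonnative"], scores["bg_nonnative"], extent, R=R, bandwidth=bw)
    bw_s = (bw[0] * overlap_bw_scale, bw[1] * overlap_bw_scale)
    smooth_native = occurrence_density_grid(scores["occ_native"], scores["bg_native"], extent, R=R, bandwidth=bw_s)
    smooth_nonnative = occurrence_density_grid(scores["occ_nonnative"], scores["bg_nonnative"], extent, R=R, bandwidth=bw_s)

    D = schoener_d(smooth_native, smooth_nonnative)
    p12, _, _ = niche_similarity_test(smooth_native, smooth_nonnative, n_reps=n_reps, direction="1to2", seed=rng_sim)
    p21, _, _ = niche_similarity_test(smooth_native, smooth_nonnative, n_reps=n_reps, direction="2to1", seed=rng_sim)
    expansion, stability, unfilling = niche_dynamics_indices(
        grid_native, grid_nonnative, tau=tau, occupancy_quantile=occupancy_quantile
    )
    dyn = NicheDynamics(
        D=D,
        p_native_to_nonnative=p12,
        p_nonnative_to_native=p21,
        n_reps=n_reps,
        expansion=expansion,
        stability=stability,
        unfilling=unfilling,
    )
    return dyn, grid_native, grid_nonnative, pca, scores


def fundamental_mask_in_env_space(pca, extent, R, model) -> np.ndarray:
    """Fundamental-niche mask over the PCA plane by linear back-projection.

    Each grid cell's center is mapped back to climate space through the
    minimum-norm PCA inverse (means + sds · loadings[:, :2] pc'), and the
    cell counts as suitable when the model's responses (restricted to PCA
    variables) are jointly positive there. Covers the whole plane, including
    climates not currently available anywhere — exactly the region the
    invasion framework needs for "suitable but not currently available".
    """
    from .niche_dynamics import grid_centers

    xs, ys = grid_centers(extent, R)
    XX, YY = np.meshgrid(xs, ys)
    pcs = np.column_stack([XX.ravel(), YY.ravel()])
    recon = pca.means + pca.sds * (pcs @ pca.loadings[:, :2].T)
    env = {v: recon[:, i] for i, v in enumerate(pca.variable_names)}
    usable = {v: r for v, r in model.responses.items() if v in env}
    if not usable:
        raise DomainError("model has no responses on PCA variables")
    suit = np.ones(pcs.shape[0])
    for v, resp in usable.items():
        suit = suit * np.clip(resp(env[v]), 0.0, 1.0)
    return (suit > 0).reshape(R, R)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis for a config; returns (and writes) the report."""
    report: dict = {"config": config.to_dict(), "stages": {}}

    truth = ScenarioTruth(
        target_unfilling=config.target_unfilling,
        target_expansion=config.target_expansion,
        n_native=config.n_native,
        n_nonnative=config.n_nonnative,
        bias_strength=config.bias_strength,
        seed=int(config.stage_rng("scenario").integers(2**31)),
    )
    scenario = make_invasion_scenario(truth, size=config.landscape_size)
    report["stages"]["scenario"] = {
        "seed": truth.seed,
        "n_native": len(scenario.occ_native),
        "n_nonnative": len(scenario.occ_nonnative),
        "achieved": {k: v for k, v in truth.achieved.items() if not isinstance(v, tuple)},
        "analog_interval": list(truth.achieved["analog_interval"]),
    }
    logger.info("scenario built: achieved U=%.3f E=%.3f", truth.achieved["unfilling"], truth.achieved["expansion"])

    dyn, grid_n, grid_i, pca, scores = analyze_scenario(
        scenario,
        n_background=config.n_background,
        R=config.grid_R,
        n_reps=config.n_reps,
        seed=config.seed,
        tau=config.tau,
        occupancy_quantile=config.occupancy_quantile,
    )
    report["stages"]["envspace"] = {
        "n_background": config.n_background,
        "explained_variance_fraction": pca.explained_variance_fraction.tolist(),
        "pc12_fraction": float(pca.explained_variance_fraction[:2].sum()),
    }
    report["stages"]["dynamics"] = dyn.to_dict() | {
        "tau": config.tau,
        "occupancy_quantile": config.occupancy_quantile,
    }

    # 6-D hypervolumes on the occurrence climates, native-range standardization
    X1 = env_matrix_for(scenario.occ_native, scenario.landscape_native)
    X2 = env_matrix_for(scenario.occ_nonnative, scenario.landscape_nonnative)
    Z1, mu, sd = hv_mod.standardize(X1)
    Z2, _, _ = hv_mod.standardize(X2, mu, sd)
    rng_hv = config.stage_rng("hypervolume")
    h1 = hv_mod.build_hypervolume(
        Z1, config.hv_threshold_quantile, config.hv_samples_per_point, seed=int(rng_hv.integers(2**31))
    )
    h2 = hv_mod.build_hypervolume(
        Z2, config.hv_threshold_quantile, config.hv_samples_per_point, seed=int(rng_hv.integers(2**31))
    )
    hv_set = hv_mod.hypervolume_set(h1, h2)
    importance = {
        "native": dict(zip(CLIMATE_VARS, hv_mod.hypervolume_variable_importance(h1).round(6).tolist())),
        "nonnative": dict(zip(CLIMATE_VARS, hv_mod.hypervolume_variable_importance(h2).round(6).tolist())),
    }
    report["stages"]["hypervolume"] = {k: float(v) for k, v in hv_set.items()} | {
        "variable_importance": importance
    }

    S1 = np.cov(X1, rowvar=False)
    S2 = np.cov(X2, rowvar=False)
    models, best = cpca_mod.fit_cpc_hierarchy(S1, S2, X1.shape[0], X2.shape[0])
    report["stages"]["cpca"] = {"table": [m.row() for m in models], "best": best.name}

    tol = compose_tolerance_curve(config.tolerance_limits)
    bio1_native = X1[:, CLIMATE_VARS.index("BIO1")]
    bio1_nonnative = X2[:, CLIMATE_VARS.index("BIO1")]
    occ_rng_native, _ = occupied_range(bio1_native)
    occ_rng_nonnative, _ = occupied_range(bio1_nonnative)
    occ_rng_all, _ = occupied_range(np.concatenate([bio1_native, bio1_nonnative]))
    low_frac, high_frac = unfilled_tolerance_report(occ_rng_all, tol)
    report["stages"]["fundamental"] = {
        "tolerance_support": list(tol.support),
        "tolerance_max_location": tol.max_location,
        "occupied_range_native": list(occ_rng_native),
        "occupied_range_nonnative": list(occ_rng_nonnative),
        "occupied_range_all": list(occ_rng_all),
        "unfilled_fraction_low": low_frac,
        "unfilled_fraction_high": high_frac,
    }

    suit = suitability_map(scenario.landscape_nonnative.stack, scenario.model_nonnative)
    vals = suit.values[suit.valid_mask]
    report["stages"]["suitability"] = {
        "mean": float(vals.mean()),
        "fraction_suitable": float((vals > 0).mean()),
    }

    fund_mask = fundamental_mask_in_env_space(pca, grid_n.extent, config.grid_R, scenario.model_native)
    regions = classify_env_regions(
        grid_n.available, grid_i.available, grid_n, grid_i, fund_mask,
        tau=config.tau, occupancy_quantile=config.occupancy_quantile,
    )
    labels, counts = np.unique(regions.astype(str), return_counts=True)
    report["stages"]["regions"] = {str(l): int(c) for l, c in zip(labels, counts)}

    report["schema_version"] = 1
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
        np.savetxt(out / "z_cor_native.csv", grid_n.z_cor, delimiter=",")
        np.savetxt(out / "z_cor_nonnative.csv", grid_i.z_cor, delimiter=",")
        write_ascii_grid(suit, out / "suitability_nonnative.asc")
        if config.make_plots:
            _write_plots(out, scenario, grid_n, grid_i, scores, tol, config)
    return report


def _write_plots(out: Path, scenario, grid_n: DensityGrid, grid_i: DensityGrid, scores, tol, config: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xmin, xmax, ymin, ymax = grid_n.extent
    fig, ax = plt.subplots(figsize=(6, 5))
    for grid, color, name in ((grid_n, "tab:orange", "native"), (grid_i, "tab:blue", "non-native")):
        ax.contour(grid.available.astype(float), levels=[0.5], extent=(xmin, xmax, ymin, ymax), colors=color, linestyles="dotted")
        ax.contour(grid.z_cor, levels=[0.1], extent=(xmin, xmax, ymin, ymax), colors=color)
    ax.scatter(*scores["occ_native"].T, s=2, c="tab:green", alpha=0.3, label="native occ")
    ax.scatter(*scores["occ_nonnative"].T, s=2, c="tab:blue", alpha=0.3, label="non-native occ")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(loc="best", fontsize=8)
    fig.savefig(out / "env_space.png", dpi=120)
    plt.close(fig)

    xs = np.linspace(*config.tolerance_limits.lethal_range, 800)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(xs, tol(xs), "k-", lw=2, label="tolerance composite")
    for comp, curve in tol.components.items():
        ax.plot(xs, curve(xs), lw=0.8, alpha=0.6, label=comp)
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel("response")
    ax.legend(fontsize=7)
    fig.savefig(out / "tolerance_curves.png", dpi=120)
    plt.close(fig)

    suit = suitability_map(scenario.landscape_nonnative.stack, scenario.model_nonnative)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(suit.values, cmap="viridis", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="suitability")
    fig.savefig(out / "suitability_map.png", dpi=120)
    plt.close(fig)
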