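"""Reduced environmental space: variable screening, sampling-effort-weighted
background points, weighted PCA and kernel-density contours of availability.

The two leading axes of a weighted PCA of the (standardized) bioclimatic
variables define the plane in which realized niches are compared. The PCA is
calibrated on background points that characterize the climates *available*
worldwide, weighted by a sampling-effort surface so that well-recorded regions
do not dominate the axes, with the focal species' occurrences included at a
small uniform weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde

from .io_geo import DomainError, EnvRaster

logger = logging.getLogger(__name__)


@dataclass
class BackgroundSample:
    """Random availability points with their sampling weights (sum to 1)."""

    points: np.ndarray  # (n, 2) lon/lat
    weights: np.ndarray  # (n,), nonnegative, sum 1
    n: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.n <= 0:
            raise DomainError("background sample must be non-empty")
        if np.any(self.weights < 0):
            raise DomainError("background weights must be nonnegative")


@dataclass
class PcaModel:
    """Weighted PCA of standardized variables.

    ``loadings`` columns are orthonormal eigenvectors of the weighted
    correlation-scale covariance; each column is sign-fixed so that its
    largest-magnitude entry is positive.
    """

    variable_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (p, k)
    explained_variance_fraction: np.ndarray

    def project(self, env_matrix: np.ndarray, n_axes: int | None = None) -> np.ndarray:
        X = (np.asarray(env_matrix, dtype=float) - self.means) / self.sds
        scores = X @ self.loadings
        return scores if n_axes is None else scores[:, :n_axes]

    def to_dict(self) -> dict:
        return {
            "variable_names": self.variable_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
        }


def screen_variables(
    env_matrix: np.ndarray,
    variable_names: list[str],
    threshold: float = 0.85,
    priority: list[str] | None = None,
) -> list[str]:
    """Drop variables until every retained pair has |Pearson r| < threshold.

    ``priority`` orders variables from most to least preferred (defaults to
    input order); when a pair violates the threshold the lower-priority member
    is dropped. Constant (zero-variance) columns are excluded with a warning.
    """
    if not 0 < threshold <= 1:
        raise DomainError("threshold must be in (0, 1]")
    X = np.asarray(env_matrix, dtype=float)
    if X.shape[1] != len(variable_names) or X.shape[1] < 2:
        raise DomainError("need >= 2 variables matching variable_names")
    priority = priority or list(variable_names)
    order = sorted(range(len(variable_names)), key=lambda i: priority.index(variable_names[i]))

    sd = X.std(axis=0)
    retained: list[int] = []
    for i in order:
        if sd[i] == 0:
            logger.warning("screen_variables: constant variable %r excluded", variable_names[i])
            continue
        ok = True
        for j in retained:
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if abs(r) >= threshold:
                ok = False
                break
        if ok:
            retained.append(i)
    retained.sort()
    return [variable_names[i] for i in retained]


def sampling_effort_surface(
    reference_points: np.ndarray,
    template: EnvRaster,
    bandwidth_cells: float = 3.0,
    floor_fraction: float = 1e-6,
) -> EnvRaster:
    """Probability surface for background sampling, from record density.

    Reference occurrences (any well-sampled clade, not just the focal species)
    are binned on the template grid, Gaussian-smoothed (sd ``bandwidth_cells``),
    floored at ``floor_fraction`` of the maximum on valid cells — absence of
    records may be a sampling artifact, so no available climate gets zero
    probability — and normalized to sum 1 over valid cells.
    """
    valid = template.valid_mask
    counts = np.zeros(template.shape)
    pts = np.asarray(reference_points, dtype=float).reshape(-1, 2)
    n_out = 0
    for x, y in pts:
        cell = template.cell_of(x, y)
        if cell is None:
            n_out += 1
            continue
        counts[cell] += 1.0
    if n_out:
        logger.info("sampling_effort_surface: %d points outside template dropped", n_out)
    if counts.sum() == 0:
        logger.info("sampling_effort_surface: no reference points; uniform surface")
        prob = valid.astype(float)
    else:
        smooth = ndimage.gaussian_filter(counts, sigma=bandwidth_cells)
        smooth[~valid] = 0.0
        prob = smooth + floor_fraction * smooth.max() * valid
    total = prob.sum()
    if total <= 0:
        raise DomainError("sampling effort surface has no valid cells")
    return template.like(prob / total)


def sample_background(prob: EnvRaster, n: int = 100_000, seed: int | np.random.Generator = 0) -> BackgroundSample:
    """Draw ``n`` random points from a cell-probability surface.

    Cells are drawn multinomially with their probabilities; each point is
    placed uniformly within its cell. Reproducible under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.where(prob.valid_mask, prob.values, 0.0).ravel()
    total = p.sum()
    if total <= 0:
        raise DomainError("probability surface is empty")
    p = p / total
    nrow, ncol = prob.shape
    idx = rng.choice(p.size, size=n, p=p)
    rows, cols = np.divmod(idx, ncol)
    ox, oy = prob.origin
    dx, dy = prob.cell_size
    u = rng.random((n, 2))
    xs = ox + (cols + u[:, 0]) * dx
    ys = oy - (rows + u[:, 1]) * dy
    return BackgroundSample(points=np.column_stack([xs, ys]), weights=np.full(n, 1.0 / n), n=n)


def fit_weighted_pca(
    env_matrix: np.ndarray,
    weights: np.ndarray | None = None,
    variable_names: list[str] | None = None,
) -> PcaModel:
    """Weighted PCA of standardized variables.

    Rows are weighted (nonnegative, not all zero); variables are centered and
    scaled by their weighted mean/SD before eigen-decomposition, since the
    bioclimatic units are incommensurate. Loadings are eigenvectors of the
    weighted covariance of the standardized data; explained fractions are
    sorted descending and sum to 1 over the retained rank.
    """
    X = np.asarray(env_matrix, dtype=float)
    n, p = X.shape
    if n < p:
        raise DomainError("need at least as many rows as variables")
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise DomainError("weights must be nonnegative and not all zero")
    w = w / w.sum()
    means = w @ X
    var = w @ (X - means) ** 2
    if np.any(var <= 0):
        raise DomainError("constant variable in PCA input; screen variables first")
    sds = np.sqrt(var)
    Z = (X - means) / sds
    cov = (Z * w[:, None]).T @ Z
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals.max(), 0) * 1e-12))
    if rank < p:
        logger.warning("fit_weighted_pca: covariance rank %d < %d; trailing components omitted", rank, p)
    evals, evecs = evals[:rank], evecs[:, :rank]
    # deterministic orientation: largest-magnitude loading in each column positive
    for k in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, k])), k] < 0:
            evecs[:, k] *= -1
    names = variable_names or [f"v{i}" for i in range(p)]
    return PcaModel(
        variable_names=list(names),
        means=means,
        sds=sds,
        loadings=evecs,
        explained_variance_fraction=evals / evals.sum(),
    )


def density_contour(
    scores: np.ndarray,
    quantile: float,
    extent: tuple[float, float, float, float] | None = None,
    resolution: int = 100,
    bw_method: str | float = "silverman",
) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    """Smallest kernel-density region holding ``quantile`` of total density.

    Returns a boolean mask over a ``resolution``×``resolution`` grid in score
    space, plus the extent used (defaults to the score bounding box ± 5%).
    ``quantile = 1.0`` yields the full (numerically nonzero) kernel support.
    """
    pts = np.asarray(scores, dtype=float)
    if pts.shape[0] < 3:
        raise DomainError("need at least 3 points for a density contour")
    if not 0 < quantile <= 1:
        raise DomainError("quantile must be in (0, 1]")
    if extent is None:
        extent = default_extent(pts)
    xmin, xmax, ymin, ymax = extent
    xs = np.linspace(xmin, xmax, resolution)
    ys = np.linspace(ymin, ymax, resolution)
    XX, YY = np.meshgrid(xs, ys)
    if np.allclose(pts.std(axis=0), 0):
        logger.warning("density_contour: degenerate scores; single-cell mask")
        mask = np.zeros((resolution, resolution), dtype=bool)
        i = np.argmin((XX - pts[0, 0]) ** 2 + (YY - pts[0, 1]) ** 2)
        mask.ravel()[i] = True
        return mask, extent
    kde = gaussian_kde(pts.T, bw_method=bw_method)
    dens = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(resolution, resolution)
    mask = density_quantile_mask(dens, quantile)
    return mask, extent


def default_extent(pts: np.ndarray, margin: float = 0.05) -> tuple[float, float, float, float]:
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    mx = (xmax - xmin) * margin or 1.0
    my = (ymax - ymin) * margin or 1.0
    return (xmin - mx, xmax + mx, ymin - my, ymax + my)


def density_quantile_mask(dens: np.ndarray, quantile: float) -> np.ndarray:
    """Highest-density cells jointly holding ``quantile`` of the total mass."""
    total = dens.sum()
    if total <= 0:
        raise DomainError("density surface is empty")
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) / total
    k = int(np.searchsorted(cum, quantile)) if quantile < 1.0 else int(np.sum(flat > 0)) - 1
    cutoff = flat[min(k, flat.size - 1)]
    return dens >= max(cutoff, np.finfo(float).tiny)
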