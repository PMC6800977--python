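"""Kernel-based n-dimensional hypervolumes with Monte Carlo volume estimation.

Each data point carries an axis-aligned hyperbox kernel whose half-width per
dimension follows a Silverman-style rule. The hypervolume is the union of
these boxes; its volume is estimated by importance sampling: candidate points
are drawn uniformly from randomly chosen boxes and accepted with probability
1/(number of boxes containing them), which leaves the accepted points exactly
uniform over the union. Box kernels make inclusion tests exact, so set
operations (intersection, unique fractions) reduce to cross-inclusion counts
of each hypervolume's uniform points in the other's support.

Inputs should be z-scored with a *common* set of statistics (use
:func:`standardize` with the native-range mean/SD for both ranges) whenever
two hypervolumes are to be compared — volumes are only commensurable under a
shared scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_geo import DomainError


class MatrixError(DomainError):
    pass


#: box half-width as a multiple of the Silverman factor, calibrated once so
#: the union volume of 500 uniform points recovers the 3-D unit cube
#: (balances boundary dilation against interior holes)
BOX_HALFWIDTH_SCALE = 0.7


def silverman_bandwidth(points: np.ndarray, scale: float = BOX_HALFWIDTH_SCALE) -> np.ndarray:
    """Per-dimension box half-width: scale · (4 / (m (d + 2)))^(1/(d+4)) · sd_k.

    ``m`` counts *distinct* points: duplicated records carry no extra
    information about the support geometry, so they must not shrink the
    kernels (volume is invariant to duplicating the dataset).
    """
    X = np.asarray(points, dtype=float)
    m = np.unique(X, axis=0).shape[0]
    d = X.shape[1]
    sd = X.std(axis=0, ddof=1)
    return scale * (4.0 / (m * (d + 2.0))) ** (1.0 / (d + 4.0)) * sd


def standardize(points: np.ndarray, means: np.ndarray | None = None, sds: np.ndarray | None = None):
    """Z-score columns; returns (scaled, means, sds). Pass the reference
    group's statistics to place a second group on the same scale."""
    X = np.asarray(points, dtype=float)
    means = X.mean(axis=0) if means is None else np.asarray(means, dtype=float)
    sds = X.std(axis=0, ddof=1) if sds is None else np.asarray(sds, dtype=float)
    if np.any(sds <= 0):
        raise MatrixError("constant dimension; cannot standardize")
    return (X - means) / sds, means, sds


@dataclass
class Hypervolume:
    dim: int
    data_points: np.ndarray
    bandwidth: np.ndarray
    random_points: np.ndarray  # uniform samples retained in the support
    point_multiplicity: np.ndarray  # kernel count at each retained sample
    density_cutoff: int  # minimum kernel count for inclusion (1 = full support)
    volume: float
    point_density: float
    threshold_quantile: float
    seed: int | None = None
    _tree: cKDTree | None = None

    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.data_points / self.bandwidth)
        return self._tree

    def kernel_count(self, points: np.ndarray) -> np.ndarray:
        """Number of data-point boxes containing each query point."""
        q = np.atleast_2d(np.asarray(points, dtype=float)) / self.bandwidth
        return np.asarray(self.tree().query_ball_point(q, r=1.0, p=np.inf, return_length=True))

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.kernel_count(points) >= max(self.density_cutoff, 1)

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "n_data": int(self.data_points.shape[0]),
            "bandwidth": self.bandwidth.tolist(),
            "volume": self.volume,
            "point_density": self.point_density,
            "threshold_quantile": self.threshold_quantile,
            "seed": self.seed,
        }


def build_hypervolume(
    points: np.ndarray,
    threshold_quantile: float = 1.0,
    samples_per_point: int = 100,
    seed: int | np.random.Generator = 0,
    bandwidth: np.ndarray | None = None,
) -> Hypervolume:
    """Estimate the kernel hypervolume of a point cloud.

    ``threshold_quantile`` keeps the highest-density region holding that
    fraction of the estimated probability mass (1.0 — the default, matching a
    threshold that includes 100% of the total probability density — keeps the
    full kernel support). ``samples_per_point`` is the accuracy/runtime knob:
    the number of Monte Carlo candidates per data point.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise MatrixError("points must be a 2-D matrix")
    n, d = X.shape
    if n < d + 1:
        raise MatrixError(f"need at least d+1={d + 1} points, got {n}")
    if np.any(X.std(axis=0) == 0):
        raise MatrixError("constant dimension gives a degenerate (zero) volume")
    if not 0 < threshold_quantile <= 1:
        raise DomainError("threshold_quantile must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h = silverman_bandwidth(X) if bandwidth is None else np.asarray(bandwidth, dtype=float)
    if np.any(h <= 0):
        raise MatrixError("bandwidths must be positive")

    Y = X / h  # unit-half-width boxes in scaled space
    tree = cKDTree(Y)
    n_samples = samples_per_point * n
    owners = rng.integers(n, size=n_samples)
    cand = Y[owners] + rng.uniform(-1.0, 1.0, size=(n_samples, d))
    mult = np.asarray(tree.query_ball_point(cand, r=1.0, p=np.inf, return_length=True))
    # accept w.p. 1/mult -> accepted points are uniform over the box union
    accept = rng.random(n_samples) * mult < 1.0
    acc = cand[accept]
    acc_mult = mult[accept]
    if acc.shape[0] == 0:
        raise DomainError("no Monte Carlo samples accepted; increase samples_per_point")
    box_vol_scaled = 2.0 ** d
    union_volume = float(np.prod(h) * n * box_vol_scaled * acc.shape[0] / n_samples)

    cutoff = 1
    keep = np.ones(acc.shape[0], dtype=bool)
    if threshold_quantile < 1.0:
        # each uniform point carries probability mass proportional to local
        # kernel density, i.e. to its multiplicity
        order = np.argsort(acc_mult)  # lowest density first
        mass = np.cumsum(acc_mult[order]) / acc_mult.sum()
        drop = order[mass <= (1.0 - threshold_quantile)]
        keep[drop] = False
        cutoff = int(acc_mult[keep].min()) if keep.any() else int(acc_mult.max())
    retained = acc[keep] * h
    volume = union_volume * keep.sum() / acc.shape[0]
    return Hypervolume(
        dim=d,
        data_points=X,
        bandwidth=h,
        random_points=retained,
        point_multiplicity=acc_mult[keep],
        density_cutoff=cutoff,
        volume=volume,
        point_density=retained.shape[0] / volume,
        threshold_quantile=threshold_quantile,
        seed=seed if isinstance(seed, int) else None,
    )


def hypervolume_set(h1: Hypervolume, h2: Hypervolume, overlap_denominator: str = "union") -> dict:
    """Set operations via cross-inclusion of uniform samples.

    The intersection volume is the average of the two one-sided estimates
    (fraction of each hypervolume's uniform points inside the other, times its
    volume); union, unique fractions and ratios follow. ``overlap_fraction``
    divides by the union by default, or by the mean of the two volumes with
    ``overlap_denominator="mean"``.
    """
    if h1.dim != h2.dim:
        raise MatrixError(f"dimension mismatch: {h1.dim} vs {h2.dim}")
    frac1_in_2 = float(np.mean(h2.contains(h1.random_points)))
    frac2_in_1 = float(np.mean(h1.contains(h2.random_points)))
    inter = 0.5 * (h1.volume * frac1_in_2 + h2.volume * frac2_in_1)
    inter = min(inter, h1.volume, h2.volume)
    union = h1.volume + h2.volume - inter
    denom = union if overlap_denominator == "union" else 0.5 * (h1.volume + h2.volume)
    return {
        "volume_1": h1.volume,
        "volume_2": h2.volume,
        "volume_union": union,
        "volume_intersection": inter,
        "unique_1": h1.volume - inter,
        "unique_2": h2.volume - inter,
        "overlap_fraction": inter / denom if denom > 0 else 0.0,
        "size_ratio": h2.volume / h1.volume,
    }


def hypervolume_variable_importance(h: Hypervolume, samples_per_point: int = 100) -> np.ndarray:
    """Per-variable contribution scores (sum to 1).

    Variable k's raw contribution is the shrinkage factor volume(full) /
    volume(rebuilt without dimension k), rebuilt with the same seed; a
    dimension with larger spread removes more volume when dropped and scores
    higher. Undefined for 1-D hypervolumes.
    """
    if h.dim < 2:
        raise DomainError("variable importance undefined for a 1-D hypervolume")
    seed = h.seed if h.seed is not None else 0
    raw = np.empty(h.dim)
    for k in range(h.dim):
        sub = np.delete(h.data_points, k, axis=1)
        hv = build_hypervolume(
            sub, threshold_quantile=h.threshold_quantile, samples_per_point=samples_per_point, seed=seed
        )
        raw[k] = h.volume / hv.volume
    return raw / raw.sum()
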