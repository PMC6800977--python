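"""Occurrence, polygon and raster I/O plus the spatial preprocessing steps.

Rasters are modelled as single-band grids with a top-left origin
(row 0 is the northernmost row) and are stored on disk as ESRI ASCII
grids — a plain-text format that keeps synthetic fixtures diffable.
Occurrence tables are delimited text with ``lon``/``lat`` columns in
WGS84 decimal degrees; native-range limits are GeoJSON polygons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import shape as geojson_shape

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


class NicheFillError(Exception):
    """Base class for package errors."""


class FormatError(NicheFillError):
    """A file does not match the expected layout (missing columns, bad header)."""


class CoordinateValidationError(NicheFillError):
    """One or more rows carry coordinates outside valid WGS84 bounds.

    The offending rows (0-based data row index, message) are collected in
    :attr:`rows` rather than silently dropped.
    """

    def __init__(self, rows: list[tuple[int, str]]):
        self.rows = rows
        detail = "; ".join(f"row {i}: {msg}" for i, msg in rows)
        super().__init__(f"{len(rows)} invalid occurrence row(s): {detail}")


class GeometryError(NicheFillError):
    """Invalid polygon geometry."""


class DomainError(NicheFillError):
    """Input is outside the domain of an operation (e.g. a mask with no water)."""


class RangeLabel(str, Enum):
    NATIVE = "native"
    NON_NATIVE = "non_native"
    UNASSIGNED = "unassigned"


@dataclass
class OccurrenceRecord:
    """A single georeferenced record with an optional native/non-native label."""

    id: str
    lon: float
    lat: float
    range_label: RangeLabel = RangeLabel.UNASSIGNED
    source: str = ""

    def validate(self) -> str | None:
        if not (-180.0 <= self.lon <= 180.0):
            return f"lon {self.lon} outside [-180, 180]"
        if not (-90.0 <= self.lat <= 90.0):
            return f"lat {self.lat} outside [-90, 90]"
        return None


@dataclass
class EnvRaster:
    """Single-band grid. ``values`` uses NaN for nodata; ``origin`` is the
    outer corner of the top-left cell; ``cell_size`` is (dx, dy), both > 0,
    with rows running southwards from the origin."""

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: tuple[float, float] = (1.0, 1.0)
    crs_id: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("raster values must be 2-D")
        dx, dy = self.cell_size
        if dx <= 0 or dy <= 0:
            raise FormatError("cell_size components must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Containing cell using half-open intervals [x, x+dx); None if outside."""
        ox, oy = self.origin
        dx, dy = self.cell_size
        col = int(np.floor((lon - ox) / dx))
        row = int(np.floor((oy - lat) / dy))
        nrow, ncol = self.shape
        if 0 <= row < nrow and 0 <= col < ncol:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        ox, oy = self.origin
        dx, dy = self.cell_size
        return ox + (col + 0.5) * dx, oy - (row + 0.5) * dy

    def like(self, values: np.ndarray) -> "EnvRaster":
        return EnvRaster(values, self.origin, self.cell_size, self.crs_id)


@dataclass
class RasterStack:
    """Aligned named grids; alignment is verified on construction."""

    layers: dict[str, EnvRaster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rasters = list(self.layers.values())
        if rasters:
            ref = rasters[0]
            for r in rasters[1:]:
                if (
                    r.shape != ref.shape
                    or not np.allclose(r.origin, ref.origin)
                    or not np.allclose(r.cell_size, ref.cell_size)
                    or r.crs_id != ref.crs_id
                ):
                    raise FormatError("raster layers are not aligned")

    def __getitem__(self, name: str) -> EnvRaster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> EnvRaster:
        return next(iter(self.layers.values()))

    def add(self, name: str, raster: EnvRaster) -> None:
        if name in self.layers:
            raise FormatError(f"duplicate layer name {name!r}")
        self.layers[name] = raster
        self.__post_init__()


# ---------------------------------------------------------------------------
# ASCII grid I/O (ESRI .asc: plain text, one header block then the grid)

def write_ascii_grid(raster: EnvRaster, path: str | Path, nodata: float = -9999.0) -> None:
    nrow, ncol = raster.shape
    dx, dy = raster.cell_size
    if not np.isclose(dx, dy):
        raise FormatError("ASCII grids require square cells")
    ox, oy = raster.origin
    vals = np.where(raster.valid_mask, raster.values, nodata)
    header = (
        f"ncols {ncol}\nnrows {nrow}\nxllcorner {ox!r}\n"
        f"yllcorner {oy - nrow * dy!r}\ncellsize {dx!r}\nNODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path, crs_id: str = "EPSG:4326") -> EnvRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    ncol, nrow = int(header["ncols"]), int(header["nrows"])
    vals = vals.reshape(nrow, ncol)
    nodata = header.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    cs = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrow * cs)
    return EnvRaster(vals, origin, (cs, cs), crs_id)


# ---------------------------------------------------------------------------
# Occurrences

def read_occurrences(path: str | Path, label: str = "from_column") -> list[OccurrenceRecord]:
    """Read a delimited occurrence table into records, preserving file order.

    ``label`` is either ``"from_column"`` (use a ``label`` column when present,
    else unassigned) or a fixed :class:`RangeLabel` value applied to all rows.
    Rows with out-of-bounds coordinates raise :class:`CoordinateValidationError`
    listing every offending row; duplicates are retained (thinning is a
    separate, explicit step).
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "lon" not in df.columns or "lat" not in df.columns:
        raise FormatError(f"{path}: missing lon/lat columns (found {list(df.columns)})")
    records, bad = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        if label == "from_column":
            lab = RangeLabel(d.get("label")) if d.get("label") else RangeLabel.UNASSIGNED
        else:
            lab = RangeLabel(label)
        rec = OccurrenceRecord(
            id=str(d.get("id", i)),
            lon=float(d["lon"]),
            lat=float(d["lat"]),
            range_label=lab,
            source=str(d.get("source", "") or ""),
        )
        msg = rec.validate()
        if msg is not None:
            bad.append((i, msg))
        else:
            records.append(rec)
    if bad:
        raise CoordinateValidationError(bad)
    return records


def write_occurrences(records: Iterable[OccurrenceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"id": r.id, "lon": r.lon, "lat": r.lat, "label": r.range_label.value, "source": r.source}
            for r in records
        ]
    ).to_csv(path, index=False)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6,371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def thin_occurrences(records: Sequence[OccurrenceRecord], min_km: float = 5.0) -> list[OccurrenceRecord]:
    """Greedy single-pass spatial thinning.

    Scans records in input order and keeps one iff it lies at least ``min_km``
    (great-circle) from every record already kept. Deterministic for a fixed
    input order; sort by id beforehand for an order-free result.
    """
    if min_km <= 0:
        raise DomainError("min_km must be positive")
    kept: list[OccurrenceRecord] = []
    kept_lon = np.empty(0)
    kept_lat = np.empty(0)
    for rec in records:
        if kept and np.any(haversine_km(kept_lon, kept_lat, rec.lon, rec.lat) < min_km):
            continue
        kept.append(rec)
        kept_lon = np.append(kept_lon, rec.lon)
        kept_lat = np.append(kept_lat, rec.lat)
    return kept


def read_native_polygons(path: str | Path):
    """Load native-range polygons from a GeoJSON file into shapely geometries."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [geojson_shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [geojson_shape(gj["geometry"])]
    else:
        geoms = [geojson_shape(gj)]
    for g in geoms:
        if not g.is_valid:
            raise GeometryError(f"invalid polygon geometry: {shapely.is_valid_reason(g)}")
    return geoms


def assign_range_labels(records: Sequence[OccurrenceRecord], native_polygons) -> list[OccurrenceRecord]:
    """Label each record native/non-native by containment in the range polygons.

    Boundary points count as native (``covers`` semantics): the native label is
    the conservative choice for points exactly on a digitized range edge.
    """
    for g in native_polygons:
        if not g.is_valid:
            raise GeometryError(f"invalid polygon geometry: {shapely.is_valid_reason(g)}")
    pts = shapely.points([(r.lon, r.lat) for r in records]) if records else np.empty(0, dtype=object)
    inside = np.zeros(len(records), dtype=bool)
    for g in native_polygons:
        inside |= shapely.covers(g, pts)
    out = []
    for rec, nat in zip(records, inside):
        lab = RangeLabel.NATIVE if nat else RangeLabel.NON_NATIVE
        out.append(OccurrenceRecord(rec.id, rec.lon, rec.lat, lab, rec.source))
    return out


# ---------------------------------------------------------------------------
# Distance to water

def distance_to_water(water_mask: EnvRaster, cell_km: float | None = None) -> EnvRaster:
    """Euclidean distance (km) from each cell center to the nearest water cell.

    ``water_mask`` holds 1 for water, 0 for land, NaN for nodata. Distances are
    computed on the grid itself, treating ``cell_size`` (or ``cell_km`` when
    the grid is not in km units) as an isotropic km cell edge — adequate for
    projected-km grids; for geographic grids pass an effective ``cell_km`` at a
    reference latitude.
    """
    vals = water_mask.values
    water = vals == 1
    if not water.any():
        raise DomainError("water mask contains no water cells")
    dx, dy = water_mask.cell_size
    sampling = (cell_km, cell_km) if cell_km is not None else (dy, dx)
    dist = ndimage.distance_transform_edt(~water, sampling=sampling)
    dist = np.where(np.isnan(vals), np.nan, dist)
    return water_mask.like(dist)


# ---------------------------------------------------------------------------
# Point-wise extraction

def extract_env(
    points: Sequence[tuple[float, float]] | Sequence[OccurrenceRecord],
    stack: RasterStack,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract layer values at each point's containing cell.

    Returns ``(matrix, flags)`` with one row per point and one column per
    layer (in ``stack.names`` order). ``flags`` is a string array:
    ``"ok"``, ``"nodata"`` (cell is nodata in some layer) or ``"outside"``
    (point beyond the raster extent). Rows that are not ``"ok"`` hold NaN and
    are meant to be excluded downstream; counts are logged, never silent.
    """
    coords = [(p.lon, p.lat) if isinstance(p, OccurrenceRecord) else (float(p[0]), float(p[1])) for p in points]
    names = stack.names
    template = stack.template
    n = len(coords)
    mat = np.full((n, len(names)), np.nan)
    flags = np.full(n, "ok", dtype=object)
    for i, (x, y) in enumerate(coords):
        cell = template.cell_of(x, y)
        if cell is None:
            flags[i] = "outside"
            continue
        r, c = cell
        row = np.array([stack[name].values[r, c] for name in names])
        if np.isnan(row).any():
            flags[i] = "nodata"
        mat[i] = row
    n_bad = int(np.sum(flags != "ok"))
    if n_bad:
        logger.info("extract_env: %d/%d points flagged invalid", n_bad, n)
    return mat, flags
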