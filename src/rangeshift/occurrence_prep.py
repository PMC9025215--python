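"""Occurrence cleaning, alpha-hull study area, and spatial/environmental thinning.

The cleaning pipeline runs in a fixed order — temporal/uncertainty filter,
per-cell deduplication, geographic thinning, environmental thinning — and
survivor counts are monotonically non-increasing through it.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import ConvexHull, Delaunay
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from rangeshift.grid import KM_PER_DEGREE, GridSpec, pairwise_haversine_km

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced observation."""

    lon: float
    lat: float
    year: int
    coord_uncertainty_m: float | None = None


@dataclasses.dataclass
class StudyArea:
    """Buffered alpha-hull extent of occurrence."""

    polygon: Polygon
    buffer_km: float
    alpha: float


def filter_records(
    records: pd.DataFrame,
    min_year: int = 1970,
    max_uncertainty_km: float = 9.25,
) -> pd.DataFrame:
    """Drop pre-cutoff, high-uncertainty and non-georeferenced records.

    Keeps rows with ``year >= min_year``, valid lon/lat, and coordinate
    uncertainty that is either missing or <= ``max_uncertainty_km``
    (removal is strictly greater-than). Input order is preserved.
    """
    lon = pd.to_numeric(records["lon"], errors="coerce")
    lat = pd.to_numeric(records["lat"], errors="coerce")
    year = pd.to_numeric(records["year"], errors="coerce")
    unc_km = pd.to_numeric(records["coord_uncertainty_m"], errors="coerce") / 1000.0

    keep = (
        lon.notna()
        & lat.notna()
        & lon.between(-180.0, 180.0)
        & lat.between(-90.0, 90.0)
        & (year >= min_year)
        & (unc_km.isna() | (unc_km <= max_uncertainty_km))
    )
    return records.loc[keep].copy()


def dedupe_by_cell(records: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Keep at most one record per raster cell (first in input wins).

    Records outside the grid extent are dropped with a logged warning.
    """
    row, col = grid.cell_of(records["lon"].to_numpy(), records["lat"].to_numpy())
    inside = row >= 0
    n_outside = int((~inside).sum())
    if n_outside:
        logger.warning("dedupe_by_cell: dropping %d record(s) outside the grid extent", n_outside)
    sub = records.loc[inside].copy()
    cell_id = row[inside] * grid.ncols + col[inside]
    keep = ~pd.Series(cell_id, index=sub.index).duplicated(keep="first")
    return sub.loc[keep]


# ---------------------------------------------------------------------------
# alpha-hull EOO


def _alpha_complex(points: np.ndarray, alpha: float) -> list[Polygon]:
    """Delaunay triangles whose circumradius is at most ``alpha`` (degrees)."""
    tri = Delaunay(points)
    keep = []
    for simplex in tri.simplices:
        a, b, c = points[simplex]
        la, lb, lc = np.linalg.norm(b - c), np.linalg.norm(a - c), np.linalg.norm(a - b)
        u, v = b - a, c - a
        area2 = abs(u[0] * v[1] - u[1] * v[0])
        if area2 < 1e-15:
            continue
        circumradius = la * lb * lc / (2.0 * area2)
        if circumradius <= alpha:
            keep.append(Polygon([a, b, c]))
    return keep


def alpha_hull_eoo(points: pd.DataFrame | np.ndarray, alpha: float = 2.0, buffer_km: float = 250.0) -> StudyArea:
    """Buffered alpha-hull around the occurrence points.

    ``alpha`` is a circumradius cutoff in degrees (larger alpha converges to
    the convex hull). The hull is unioned with the points themselves before
    buffering, so the result always contains 100% of the inputs (exactly on
    the boundary when ``buffer_km`` is 0 and a point is isolated).
    """
    if isinstance(points, pd.DataFrame):
        xy = points[["lon", "lat"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(points, dtype=float)
    xy = np.unique(xy, axis=0)
    if xy.shape[0] < 3:
        raise ValueError(f"alpha-hull needs at least 3 distinct points, got {xy.shape[0]}")
    try:
        if np.isfinite(alpha):
            triangles = _alpha_complex(xy, alpha)
        else:
            hull = ConvexHull(xy)
            triangles = [Polygon(xy[hull.vertices])]
    except Exception as exc:  # qhull degeneracy
        raise ValueError(f"insufficient non-collinear points for a hull: {exc}") from exc
    geom = unary_union(triangles + [MultiPoint(xy)])
    buffer_deg = buffer_km / KM_PER_DEGREE
    polygon = geom.buffer(buffer_deg) if buffer_deg > 0 else geom
    if polygon.is_empty or polygon.area == 0 and buffer_km > 0:
        raise ValueError("degenerate study area")
    return StudyArea(polygon=polygon, buffer_km=buffer_km, alpha=alpha)


def study_area_to_geojson(area: StudyArea) -> dict:
    return {
        "type": "Feature",
        "properties": {"buffer_km": area.buffer_km, "alpha": area.alpha},
        "geometry": shapely.geometry.mapping(area.polygon),
    }


# ---------------------------------------------------------------------------
# thinning


def _thin_once(dist: np.ndarray, thin_dist_km: float, rng: np.random.Generator) -> np.ndarray:
    """One randomized greedy removal pass; returns a boolean keep mask."""
    n = dist.shape[0]
    close = dist < thin_dist_km
    np.fill_diagonal(close, False)
    alive = np.ones(n, dtype=bool)
    counts = close.sum(axis=1)
    while True:
        max_count = counts[alive].max() if alive.any() else 0
        if max_count == 0:
            break
        worst = np.flatnonzero(alive & (counts == max_count))
        victim = int(rng.choice(worst))
        alive[victim] = False
        counts = counts - close[:, victim].astype(int)
        counts[victim] = 0
        counts[~alive] = 0
    return alive


def spatial_thin(
    records: pd.DataFrame, thin_dist_km: float, n_reps: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Great-circle spatial thinning (randomized greedy, best of ``n_reps``).

    No two retained records are within ``thin_dist_km`` of each other; among
    the repeated randomized removal runs, one with the maximal retained
    count is returned. Deterministic given ``seed``.
    """
    if thin_dist_km <= 0:
        raise ValueError("thin_dist_km must be positive")
    if len(records) <= 1:
        return records.copy()
    lons = records["lon"].to_numpy(dtype=float)
    lats = records["lat"].to_numpy(dtype=float)
    dist = pairwise_haversine_km(lons, lats)
    rng = np.random.default_rng(seed)
    best_mask: np.ndarray | None = None
    for _ in range(max(n_reps, 1)):
        mask = _thin_once(dist, thin_dist_km, rng)
        if best_mask is None or mask.sum() > best_mask.sum():
            best_mask = mask
    return records.loc[np.asarray(best_mask)]


def env_thin(
    records: pd.DataFrame,
    env_values: pd.DataFrame | np.ndarray,
    n_bins_per_var: int = 25,
    seed: int = 0,
    ranges: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Environmental-space thinning: one record per occupied multidim bin.

    Each environmental axis is split into ``n_bins_per_var`` equal-width bins
    over its observed range (or the explicit ``ranges``, which make repeated
    applications use identical bin edges); exactly one record
    (seeded-random choice) is kept per occupied bin. A constant variable
    collapses to one bin (logged).
    """
    if n_bins_per_var < 2:
        raise ValueError("n_bins_per_var must be >= 2")
    env = np.asarray(env_values, dtype=float)
    if env.ndim == 1:
        env = env[:, None]
    if env.shape[0] != len(records):
        raise ValueError("env_values length does not match records")

    bins = np.zeros(env.shape, dtype=int)
    for j in range(env.shape[1]):
        col = env[:, j]
        lo, hi = ranges[j] if ranges is not None else (np.nanmin(col), np.nanmax(col))
        if hi == lo:
            logger.warning("env_thin: variable %d is constant; axis collapses to one bin", j)
            continue
        idx = np.floor((col - lo) / (hi - lo) * n_bins_per_var).astype(int)
        bins[:, j] = np.clip(idx, 0, n_bins_per_var - 1)

    rng = np.random.default_rng(seed)
    keep_positions = []
    groups: dict[tuple, list[int]] = {}
    for pos, key in enumerate(map(tuple, bins)):
        groups.setdefault(key, []).append(pos)
    for key in sorted(groups):
        members = groups[key]
        keep_positions.append(members[int(rng.integers(len(members)))])
    return records.iloc[sorted(keep_positions)]
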