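"""Binary range maps and range-change / centroid / altitude statistics.

Range change follows the unlimited-dispersal convention: percentages are
relative to the current range size and every newly suitable cell counts as
colonizable. Cells missing in either map are excluded from all counts.
Reported percentages are rounded to 2 decimals (half-up) only at
serialization time.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from rangeshift.grid import GridSpec, Raster, haversine_km

#: integer codes for transition maps: 0 absent, 1 lost, 2 stable, 3 gained
TRANSITION_CODES = {"absent": 0, "lost": 1, "stable": 2, "gained": 3}


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class BinaryMap:
    """Presence/absence grid derived from one suitability map and threshold.

    ``values`` holds 1.0 (presence), 0.0 (absence) or NaN (masked).
    """

    grid: GridSpec
    values: np.ndarray
    threshold: float
    scenario: str = "current"

    def presence_mask(self) -> np.ndarray:
        return self.values == 1.0

    @property
    def n_presence(self) -> int:
        return int(np.nansum(self.values == 1.0))


def binarize(suitability: Raster | np.ndarray, threshold: float, grid: GridSpec | None = None,
             scenario: str = "current") -> BinaryMap:
    """1 where suitability >= threshold, 0 below; NaN propagates."""
    if isinstance(suitability, Raster):
        grid, arr = suitability.grid, suitability.values
    else:
        if grid is None:
            raise ValueError("grid required when passing a bare array")
        arr = np.asarray(suitability, dtype=float)
    vals = np.where(np.isnan(arr), np.nan, (arr >= threshold).astype(float))
    return BinaryMap(grid=grid, values=vals, threshold=float(threshold), scenario=scenario)


@dataclasses.dataclass
class RangeChangeReport:
    """Loss/gain/overall-change percentages plus counts for one transition."""

    scenario: str
    loss_pct: float
    gain_pct: float
    overall_change_pct: float
    counts: dict[str, int]
    occ_lost_pct: float | None = None
    centroid: tuple[float, float] | None = None
    mean_altitude_m: float | None = None

    def to_row(self) -> dict:
        row = {
            "scenario": self.scenario,
            "loss_pct": round_half_up(self.loss_pct),
            "gain_pct": round_half_up(self.gain_pct),
            "overall_change_pct": round_half_up(self.overall_change_pct),
        }
        if self.occ_lost_pct is not None:
            row["occ_lost_pct"] = round_half_up(self.occ_lost_pct)
        row.update({f"n_{k}": v for k, v in self.counts.items()})
        if self.centroid is not None:
            row["centroid_lon"], row["centroid_lat"] = self.centroid
        if self.mean_altitude_m is not None:
            row["mean_altitude_m"] = round_half_up(self.mean_altitude_m, 1)
        return row


def range_change(current: BinaryMap, future: BinaryMap) -> RangeChangeReport:
    """Unlimited-dispersal range change between two co-registered binary maps.

    With C = number of current-presence cells (over cells with data in both
    maps): loss% = 100 * lost / C, gain% = 100 * gained / C, and
    overall% = gain% - loss%.
    """
    if current.grid != future.grid:
        raise ValueError("binary maps are not co-registered")
    valid = np.isfinite(current.values) & np.isfinite(future.values)
    cur = current.values == 1.0
    fut = future.values == 1.0
    lost = int((valid & cur & ~fut).sum())
    stable = int((valid & cur & fut).sum())
    gained = int((valid & ~cur & fut).sum())
    absent = int((valid & ~cur & ~fut).sum())
    c = lost + stable
    if c == 0:
        raise ValueError("current map has no presence cells in the shared data area")
    loss_pct = 100.0 * lost / c
    gain_pct = 100.0 * gained / c
    return RangeChangeReport(
        scenario=future.scenario,
        loss_pct=loss_pct,
        gain_pct=gain_pct,
        overall_change_pct=gain_pct - loss_pct,
        counts={"lost": lost, "stable": stable, "gained": gained, "absent": absent},
    )


def transition_map(current: BinaryMap, future: BinaryMap) -> Raster:
    """Integer-coded transition raster (absent/lost/stable/gained)."""
    valid = np.isfinite(current.values) & np.isfinite(future.values)
    cur = current.values == 1.0
    fut = future.values == 1.0
    codes = np.full(current.grid.shape, np.nan)
    codes[valid & ~cur & ~fut] = TRANSITION_CODES["absent"]
    codes[valid & cur & ~fut] = TRANSITION_CODES["lost"]
    codes[valid & cur & fut] = TRANSITION_CODES["stable"]
    codes[valid & ~cur & fut] = TRANSITION_CODES["gained"]
    return Raster(current.grid, codes)


def occurrences_lost(occurrences: pd.DataFrame, future: BinaryMap, current: BinaryMap | None = None) -> float:
    """Percent of occurrence records whose cell is unsuitable (or masked) in
    the future map, among records that fall in data cells of the current map
    (the future map itself when no current map is given)."""
    ref = current if current is not None else future
    row, col = ref.grid.cell_of(occurrences["lon"].to_numpy(), occurrences["lat"].to_numpy())
    inside = row >= 0
    usable = inside.copy()
    usable[inside] = np.isfinite(ref.values[row[inside], col[inside]])
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no occurrence records fall in data cells")
    fut_vals = np.full(len(occurrences), np.nan)
    fut_vals[usable] = future.values[row[usable], col[usable]]
    lost = np.sum(usable & ((fut_vals != 1.0) | np.isnan(fut_vals)))
    return 100.0 * float(lost) / n_usable


def aggregate_scenarios(reports: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Mean percentages across GCMs per SSP x time-slice group.

    ``reports`` needs the percentage columns plus the grouping keys
    (default ``["ssp", "time_slice"]``). Means are unweighted arithmetic
    means, rounded half-up to 2 decimals for reporting.
    """
    by = by if by is not None else ["ssp", "time_slice"]
    pct_cols = [c for c in ("loss_pct", "gain_pct", "overall_change_pct", "occ_lost_pct") if c in reports.columns]
    grouped = reports.groupby(by, sort=True)[pct_cols].mean().reset_index()
    for c in pct_cols:
        grouped[c] = grouped[c].map(lambda v: round_half_up(v, 2))
    return grouped


def median_centroid(bmap: BinaryMap, geometric: bool = False) -> tuple[float, float]:
    """Component-wise median (default) or mean of presence-cell centers."""
    rows, cols = np.nonzero(bmap.presence_mask())
    if rows.size == 0:
        raise ValueError("empty binary map: no presence cells")
    lon, lat = bmap.grid.cell_center(rows, cols)
    agg = np.mean if geometric else np.median
    return float(agg(lon)), float(agg(lat))


def centroid_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance (km) between two (lon, lat) centroids."""
    return float(haversine_km(a[0], a[1], b[0], b[1]))


def centroid_distance_matrix(centroids: dict[str, tuple[float, float]]) -> pd.DataFrame:
    names = list(centroids)
    mat = [[centroid_distance(centroids[a], centroids[b]) for b in names] for a in names]
    return pd.DataFrame(mat, index=names, columns=names)


def mean_altitude(bmap: BinaryMap, elevation: Raster) -> float:
    """Arithmetic mean elevation (m) over presence cells."""
    if elevation.grid != bmap.grid:
        raise ValueError("elevation raster is not co-registered with the binary map")
    mask = bmap.presence_mask()
    vals = elevation.values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty binary map: no presence cells with elevation data")
    return float(vals.mean())


def altitude_samples(bmap: BinaryMap, elevation: Raster) -> np.ndarray:
    """Per-presence-cell elevations (the samples behind the shift tests)."""
    vals = elevation.values[bmap.presence_mask()]
    return vals[np.isfinite(vals)]


@dataclasses.dataclass
class ShiftTestResult:
    kw_stat: float
    kw_df: int
    kw_p: float
    pairwise_p: pd.DataFrame  # Holm-adjusted two-sided rank-sum p-values
    adjust: str = "holm"


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def shift_tests(groups: dict[str, np.ndarray]) -> ShiftTestResult:
    """Kruskal-Wallis across scenario groups + pairwise Wilcoxon rank-sum.

    ``groups`` maps scenario label to its per-presence-cell elevation sample.
    Pairwise two-sided Mann-Whitney/Wilcoxon rank-sum p-values are
    Holm-adjusted.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = []
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        samples.append(arr)
    kw = stats.kruskal(*samples)
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    raw = np.array(
        [stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided").pvalue for i, j in pairs]
    )
    adj = _holm(raw)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for (i, j), p in zip(pairs, adj):
        mat.iloc[i, j] = mat.iloc[j, i] = p
    return ShiftTestResult(
        kw_stat=float(kw.statistic),
        kw_df=len(names) - 1,
        kw_p=float(kw.pvalue),
        pairwise_p=mat,
    )
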