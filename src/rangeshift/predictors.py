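"""Derived environmental predictors and collinearity screening.

Implements the 19 classic bioclimatic layers from monthly climate, a
Thornthwaite-type aridity index, five terrain layers from elevation, a
stepwise Spearman/VIF variable filter, and per-location annual
temperature-seasonality time series.

Conventions (recorded here because they differ between toolchains):

* bio4 uses the *population* standard deviation of the 12 monthly mean
  temperatures, times 100.
* bio15 is the coefficient of variation of monthly precipitation with the
  "+1 mm" offset on the mean, times 100.
* Quarters are calendar-contiguous 3-month windows with December-January
  wraparound.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from rangeshift.grid import GridSpec, Raster, write_ascii_grid

logger = logging.getLogger(__name__)

MONTHS = 12
DAYS_PER_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
#: mid-month day of year, for solar declination
MID_MONTH_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])


def _check_monthly(*cubes: np.ndarray) -> tuple[np.ndarray, ...]:
    out = []
    shape = None
    for cube in cubes:
        arr = np.asarray(cube, dtype=float)
        if arr.ndim != 3 or arr.shape[0] != MONTHS:
            raise ValueError("monthly input must have shape (12, nrows, ncols)")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"monthly grids are not co-registered: {arr.shape} vs {shape}")
        out.append(arr)
    return tuple(out)


def _quarter_windows() -> np.ndarray:
    """12 calendar-contiguous 3-month windows with wraparound (12, 3)."""
    return np.array([[(m + k) % MONTHS for k in range(3)] for m in range(MONTHS)])


def bioclim(
    monthly_tmin: np.ndarray,
    monthly_tmax: np.ndarray,
    monthly_tavg: np.ndarray,
    monthly_prec: np.ndarray,
) -> dict[str, np.ndarray]:
    """The 19 bioclimatic layers (ANUCLIM/WorldClim definitions).

    Returns a dict ``{"bio1": ..., ..., "bio19": ...}`` of 2-D arrays.
    """
    tmin, tmax, tavg, prec = _check_monthly(monthly_tmin, monthly_tmax, monthly_tavg, monthly_prec)
    windows = _quarter_windows()

    q_tavg = np.stack([tavg[w].mean(axis=0) for w in windows])  # (12, r, c)
    q_prec = np.stack([prec[w].sum(axis=0) for w in windows])

    out: dict[str, np.ndarray] = {}
    out["bio1"] = tavg.mean(axis=0)
    out["bio2"] = (tmax - tmin).mean(axis=0)
    out["bio4"] = tavg.std(axis=0, ddof=0) * 100.0
    out["bio5"] = tmax.max(axis=0)
    out["bio6"] = tmin.min(axis=0)
    out["bio7"] = out["bio5"] - out["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["bio3"] = np.where(out["bio7"] != 0, out["bio2"] / out["bio7"] * 100.0, 0.0)
    out["bio12"] = prec.sum(axis=0)
    out["bio13"] = prec.max(axis=0)
    out["bio14"] = prec.min(axis=0)
    out["bio15"] = prec.std(axis=0, ddof=0) / (prec.mean(axis=0) + 1.0) * 100.0

    wettest_q = q_prec.argmax(axis=0)
    driest_q = q_prec.argmin(axis=0)
    warmest_q = q_tavg.argmax(axis=0)
    coldest_q = q_tavg.argmin(axis=0)

    def take(cube: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(cube, idx[None], axis=0)[0]

    out["bio8"] = take(q_tavg, wettest_q)
    out["bio9"] = take(q_tavg, driest_q)
    out["bio10"] = take(q_tavg, warmest_q)
    out["bio11"] = take(q_tavg, coldest_q)
    out["bio16"] = take(q_prec, wettest_q)
    out["bio17"] = take(q_prec, driest_q)
    out["bio18"] = take(q_prec, warmest_q)
    out["bio19"] = take(q_prec, coldest_q)
    return out


# ---------------------------------------------------------------------------
# Thornthwaite PET and aridity


def day_length_hours(lat_deg: np.ndarray, doy: float) -> np.ndarray:
    """Astronomical day length at a latitude and day of year."""
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    decl = np.radians(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    cos_ws = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_ws)


def thornthwaite_pet(monthly_tavg: np.ndarray, lat_deg: np.ndarray) -> np.ndarray:
    """Monthly potential evapotranspiration (mm) after Thornthwaite.

    Uses the standard heat-index formulation with the day-length /
    month-length correction; temperatures at or below 0 degC contribute no
    PET. ``lat_deg`` is broadcast against the spatial shape of the cubes.
    """
    (tavg,) = _check_monthly(monthly_tavg)
    lat = np.broadcast_to(np.asarray(lat_deg, dtype=float), tavg.shape[1:])
    t = np.maximum(tavg, 0.0)
    heat_index = ((t / 5.0) ** 1.514).sum(axis=0)
    a = 6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2 + 1.792e-2 * heat_index + 0.49239
    with np.errstate(divide="ignore", invalid="ignore"):
        base = np.where(heat_index > 0, 16.0 * (10.0 * t / np.where(heat_index > 0, heat_index, 1.0)) ** a, 0.0)
    corr = np.stack(
        [day_length_hours(lat, MID_MONTH_DOY[m]) / 12.0 * DAYS_PER_MONTH[m] / 30.0 for m in range(MONTHS)]
    )
    return base * corr


def thornthwaite_aridity(
    monthly_tavg: np.ndarray, monthly_prec: np.ndarray, lat_deg: np.ndarray
) -> np.ndarray:
    """Aridity index: 100 x (annual water deficit) / (annual PET).

    The deficit sums max(0, PET - precipitation) over months; 0 means no
    month is water-limited, 100 means precipitation never offsets PET.
    """
    tavg, prec = _check_monthly(monthly_tavg, monthly_prec)
    pet = thornthwaite_pet(tavg, lat_deg)
    deficit = np.maximum(pet - prec, 0.0).sum(axis=0)
    pet_annual = pet.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tai = np.where(pet_annual > 0, 100.0 * deficit / np.where(pet_annual > 0, pet_annual, 1.0), 0.0)
    return tai


# ---------------------------------------------------------------------------
# terrain


def _neighbor_grids(z: np.ndarray) -> np.ndarray:
    """Edge-replicated 3x3 neighborhood stack, shape (8, r, c)."""
    padded = np.pad(z, 1, mode="edge")
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    return np.stack([padded[1 + dr : 1 + dr + z.shape[0], 1 + dc : 1 + dc + z.shape[1]] for dr, dc in offsets])


def terrain_vars(elevation: Raster) -> dict[str, np.ndarray]:
    """slope, aspect, heat_load, tpi, tri from an elevation raster.

    Slope/aspect follow Horn's 8-neighbor finite differences with
    edge-replicated borders; TPI is the deviation from the 8-neighbor mean,
    TRI the mean absolute deviation; heat load follows McCune & Keon with
    aspect folded about the SW axis.
    """
    z = elevation.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("elevation raster must be at least 3x3")
    grid = elevation.grid
    cell_m = grid.cellsize * 111_194.9  # coarse metre conversion for gradients
    pad = np.pad(z, 1, mode="edge")

    def w(dr: int, dc: int) -> np.ndarray:
        return pad[1 + dr : 1 + dr + z.shape[0], 1 + dc : 1 + dc + z.shape[1]]

    # Horn 1981 kernels; row 0 is north
    dzdx = ((w(-1, 1) + 2 * w(0, 1) + w(1, 1)) - (w(-1, -1) + 2 * w(0, -1) + w(1, -1))) / (8 * cell_m)
    dzdy = ((w(-1, -1) + 2 * w(-1, 0) + w(-1, 1)) - (w(1, -1) + 2 * w(1, 0) + w(1, 1))) / (8 * cell_m)
    slope = np.arctan(np.hypot(dzdx, dzdy))
    # downslope direction, clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0

    nbrs = _neighbor_grids(z)
    tpi = z - nbrs.mean(axis=0)
    tri = np.abs(z - nbrs).mean(axis=0)

    lat = np.radians(grid.lonlat_mesh()[1])
    folded = np.radians(np.abs(180.0 - np.abs(aspect - 225.0)))
    heat_load = np.exp(
        -1.467
        + 1.582 * np.cos(lat) * np.cos(slope)
        - 1.500 * np.cos(folded) * np.sin(slope) * np.sin(lat)
        - 0.262 * np.sin(lat) * np.sin(slope)
        + 0.607 * np.sin(folded) * np.sin(slope)
    )
    return {
        "slope": np.degrees(slope),
        "aspect": aspect,
        "heat_load": heat_load,
        "tpi": tpi,
        "tri": tri,
    }


# ---------------------------------------------------------------------------
# predictor stack


@dataclasses.dataclass
class PredictorStack:
    """Named co-registered raster layers plus their training ranges."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    training_range: dict[str, tuple[float, float]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def subset(self, names: list[str]) -> "PredictorStack":
        return PredictorStack(
            self.grid,
            {n: self.layers[n] for n in names},
            {n: self.training_range[n] for n in names if n in self.training_range},
        )

    def record_training_range(self, mask: np.ndarray | None = None) -> None:
        """Freeze per-layer (min, max) over data cells, before any projection."""
        for name, arr in self.layers.items():
            vals = arr[mask] if mask is not None else arr
            vals = vals[np.isfinite(vals)]
            self.training_range[name] = (float(vals.min()), float(vals.max()))

    def extract(self, lon, lat) -> pd.DataFrame:
        """Layer values at point coordinates (nearest cell); NaN outside."""
        row, col = self.grid.cell_of(lon, lat)
        ok = row >= 0
        data = {}
        for name, arr in self.layers.items():
            vals = np.full(np.shape(row), np.nan)
            vals[ok] = arr[row[ok], col[ok]]
            data[name] = vals
        return pd.DataFrame(data)

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        """(ncells, nlayers) matrix in row-major cell order."""
        names = names or self.names
        return np.column_stack([self.layers[n].ravel() for n in names])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(outdir / f"{name}.asc", self.grid, arr)
        if self.training_range:
            pd.DataFrame(
                [(n, lo, hi) for n, (lo, hi) in self.training_range.items()],
                columns=["layer", "train_min", "train_max"],
            ).to_csv(outdir / "training_range.csv", index=False)


#: default candidate menu for modelling: one representative per climate
#: "family" plus terrain, so the collinearity screen has genuine work but is
#: not flooded with near-duplicates of the annual temperature cycle
DEFAULT_LAYER_MENU = (
    "bio1", "bio4", "bio12", "bio15", "aridity",
    "elevation", "slope", "aspect", "heat_load", "tpi", "tri",
)


def build_stack(
    scenario,
    elevation: Raster | None = None,
    terrain: dict[str, np.ndarray] | None = None,
    layer_menu: tuple[str, ...] | None = None,
) -> PredictorStack:
    """Bioclim + aridity (+ elevation and terrain) stack for one scenario.

    ``layer_menu`` restricts the returned layers (default: everything).
    """
    layers = bioclim(
        scenario.monthly_tmin, scenario.monthly_tmax, scenario.monthly_tavg, scenario.monthly_prec
    )
    lat = scenario.grid.lonlat_mesh()[1]
    layers["aridity"] = thornthwaite_aridity(scenario.monthly_tavg, scenario.monthly_prec, lat)
    if elevation is not None:
        layers["elevation"] = elevation.values
        layers.update(terrain if terrain is not None else terrain_vars(elevation))
    if layer_menu is not None:
        layers = {n: layers[n] for n in layer_menu if n in layers}
    return PredictorStack(scenario.grid, layers)


# ---------------------------------------------------------------------------
# collinearity screening


def _vif(x: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column against the others (OLS R^2)."""
    n, k = x.shape
    if k == 1:
        return np.array([1.0])
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    vifs = np.empty(k)
    for j in range(k):
        others = np.column_stack([np.ones(n), np.delete(xs, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, xs[:, j], rcond=None)
        resid = xs[:, j] - others @ beta
        r2 = 1.0 - resid.var() / xs[:, j].var()
        vifs[j] = 1.0 / max(1.0 - r2, 1e-12)
    return vifs


def vifcor_select(
    stack: PredictorStack,
    points: pd.DataFrame | np.ndarray,
    corr_max: float = 0.7,
    vif_max: float = 10.0,
) -> list[str]:
    """Stepwise Spearman + VIF variable filter.

    ``points`` is either a frame with lon/lat columns (layers are sampled
    there) or a (npoints, nlayers) matrix in stack layer order. While the
    largest absolute pairwise Spearman correlation is >= ``corr_max``, the
    member of that pair with the larger VIF is dropped; afterwards variables
    with VIF >= ``vif_max`` are dropped one at a time, largest first.
    Constant layers are dropped up front. Ties break alphabetically (the
    lexicographically later name is dropped).
    """
    names = stack.names
    if isinstance(points, pd.DataFrame) and {"lon", "lat"} <= set(points.columns):
        data = stack.extract(points["lon"].to_numpy(), points["lat"].to_numpy())
        x = data.to_numpy()
    else:
        x = np.asarray(points, dtype=float)
        if x.shape[1] != len(names):
            raise ValueError("point matrix width does not match number of layers")
    keep = np.all(np.isfinite(x), axis=1)
    x = x[keep]
    if x.shape[0] < 10 * len(names):
        warnings.warn(
            f"only {x.shape[0]} sample points for {len(names)} layers; "
            "collinearity estimates may be unstable",
            stacklevel=2,
        )

    cols = {n: x[:, i] for i, n in enumerate(names)}
    active = []
    for n in names:
        if np.ptp(cols[n]) == 0:
            warnings.warn(f"layer {n!r} is constant over the sample; dropped", stacklevel=2)
        else:
            active.append(n)

    def spearman_matrix(sel: list[str]) -> np.ndarray:
        mat = np.column_stack([cols[n] for n in sel])
        rho = stats.spearmanr(mat).statistic
        return np.atleast_2d(rho) if len(sel) > 1 else np.array([[1.0]])

    while len(active) > 1:
        rho = np.abs(spearman_matrix(active))
        np.fill_diagonal(rho, 0.0)
        i, j = np.unravel_index(np.argmax(rho), rho.shape)
        if rho[i, j] < corr_max:
            break
        vifs = _vif(np.column_stack([cols[n] for n in active]))
        a, b = sorted((active[i], active[j]))
        drop = b if vifs[active.index(a)] <= vifs[active.index(b)] else a
        logger.debug("vifcor: dropping %s (|rho|=%.3f with pair)", drop, rho[i, j])
        active.remove(drop)

    while len(active) > 1:
        vifs = _vif(np.column_stack([cols[n] for n in active]))
        worst = int(np.argmax(vifs))
        if vifs[worst] < vif_max:
            break
        # alphabetical tie-break on equal VIFs
        ties = [n for v, n in zip(vifs, active) if v == vifs[worst]]
        drop = sorted(ties)[-1]
        active.remove(drop)

    return active


# ---------------------------------------------------------------------------
# per-location seasonality time series


def seasonality_series(
    annual_monthly_tavg_by_year: dict[int, np.ndarray] | "pd.Series",
    location: tuple[float, float],
    grid: GridSpec,
) -> pd.Series:
    """Annual temperature-seasonality (bio4) series at one location.

    ``annual_monthly_tavg_by_year`` maps year -> (12, nrows, ncols) cube;
    the grid point nearest ``location`` (lon, lat) is used, no smoothing.
    """
    lon, lat = location
    row, col = grid.cell_of(lon, lat)
    if int(row) < 0:
        raise ValueError(f"location {location} is outside the grid extent")
    years = sorted(annual_monthly_tavg_by_year)
    values = []
    for year in years:
        cube = np.asarray(annual_monthly_tavg_by_year[year], dtype=float)
        if cube.shape != (MONTHS, *grid.shape):
            raise ValueError(f"year {year}: cube shape {cube.shape} does not match grid")
        values.append(cube[:, int(row), int(col)].std(ddof=0) * 100.0)
    return pd.Series(values, index=pd.Index(years, name="year"), name="bio4")
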