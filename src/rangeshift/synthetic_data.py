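"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes — monthly climate grids, an
elevation model, a latent "true" suitability surface, and contaminated
occurrence records — so every downstream stage can be tested end to end
without external downloads.

Design notes
------------
* Spatial autocorrelation comes from Gaussian-smoothed white noise.
* The latent truth is a logistic function of exactly two derived predictors
  (temperature seasonality and an aridity index); every other generated
  layer is correlated nuisance, so collinearity screening has real work.
* All randomness flows from one explicit integer seed per call.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from rangeshift.grid import GridSpec, Raster, write_ascii_grid

MONTHS = 12
#: month-of-year phase for the annual temperature cycle, peak in July
_CYCLE = np.cos(2.0 * np.pi * (np.arange(MONTHS) - 6.0) / 12.0)
_CYCLE2 = np.cos(4.0 * np.pi * (np.arange(MONTHS) - 2.0) / 12.0)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian field."""
    field = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = field.std()
    return field / sd if sd > 0 else field


@dataclasses.dataclass(frozen=True)
class ClimateParams:
    """Shape of the synthetic current climate.

    The south is hot and dry, the north cool and wet; the seasonal
    temperature-cycle amplitude grows northward (with a weaker west-to-east
    "continentality" gradient so seasonality is not a pure latitude proxy).
    """

    t_south: float = 20.0  # annual-mean temperature at the southern edge, degC
    t_lat_gradient: float = 1.3  # degC lost per degree of latitude northward
    lapse_rate: float = 0.0055  # degC per metre of elevation
    amp_south: float = 2.5  # seasonal half-amplitude at the southern edge, degC
    amp_lat_gradient: float = 0.6  # half-amplitude gain per degree latitude
    amp_lon_gradient: float = 0.15  # continentality: gain per degree eastward
    amp_noise: float = 1.6
    diurnal_range: float = 8.0  # mean tmax - tmin, degC
    diurnal_noise: float = 1.5
    t_noise: float = 0.7
    noise_sigma: float = 4.0
    prec_south: float = 35.0  # monthly-mean precipitation at the southern edge, mm
    prec_lat_gradient: float = 35.0  # mm gained per degree latitude northward
    prec_lon_gradient: float = -3.0  # drier eastward
    prec_seasonal_frac: float = 0.15  # winter-peaking seasonal modulation
    prec_noise: float = 6.0
    prec_monthly_noise_frac: float = 0.15  # per-month texture relative to the local mean


@dataclasses.dataclass(frozen=True)
class ScenarioParams:
    """Offsets applied to the current climate to build one future scenario."""

    name: str = "current"
    delta_t: float = 0.0
    delta_seasonality: float = 1.0  # multiplies the annual-cycle amplitude
    prec_factor: float = 1.0
    gcm: str = "current"
    ssp: str = "current"
    time_slice: str = "current"


@dataclasses.dataclass
class ClimateScenario:
    """Monthly climate fields for one scenario on one grid.

    ``monthly_*`` arrays have shape ``(12, nrows, ncols)``; temperatures in
    degC, precipitation in mm/month. Invariant: tmin <= tavg <= tmax
    cell-wise and precipitation is nonnegative.
    """

    name: str
    grid: GridSpec
    monthly_tmin: np.ndarray
    monthly_tmax: np.ndarray
    monthly_tavg: np.ndarray
    monthly_prec: np.ndarray
    delta_t: float = 0.0
    delta_seasonality: float = 1.0
    params: ScenarioParams | None = None

    def __post_init__(self) -> None:
        for name in ("monthly_tmin", "monthly_tmax", "monthly_tavg", "monthly_prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (MONTHS, *self.grid.shape):
                raise ValueError(f"{name} must have shape (12, nrows, ncols)")
            setattr(self, name, arr)
        if np.any(self.monthly_tmin > self.monthly_tavg + 1e-9) or np.any(
            self.monthly_tavg > self.monthly_tmax + 1e-9
        ):
            raise ValueError("temperature ordering violated: need tmin <= tavg <= tmax")
        if np.any(self.monthly_prec < 0):
            raise ValueError("precipitation must be nonnegative")


def default_grid(grid_shape: tuple[int, int] = (100, 100), cellsize: float = 0.1) -> GridSpec:
    """South-western Europe-like extent: lon from 0 deg E, lat from 40 deg N."""
    nrows, ncols = grid_shape
    return GridSpec(nrows=nrows, ncols=ncols, xmin=0.0, ymin=40.0, cellsize=cellsize)


def gen_elevation(
    seed: int,
    grid_shape: tuple[int, int] = (100, 100),
    grid: GridSpec | None = None,
    relief_m: float = 1200.0,
    base_m: float = 150.0,
    sigma: float = 5.0,
) -> Raster:
    """Smooth nonnegative elevation field (metres).

    ``relief_m=0`` yields a constant raster at ``base_m``.
    """
    grid = grid if grid is not None else default_grid(grid_shape)
    rng = np.random.default_rng([seed, 0xE1E])  # stream distinct from gen_climate
    field = _smooth_noise(rng, grid.shape, sigma)
    elev = base_m + relief_m * (field - field.min()) / max(np.ptp(field), 1e-12) if relief_m else np.full(grid.shape, base_m)
    return Raster(grid, np.maximum(elev, 0.0))


def gen_climate(
    seed: int,
    grid_shape: tuple[int, int] = (100, 100),
    scenario_params: ScenarioParams | None = None,
    grid: GridSpec | None = None,
    elevation: Raster | None = None,
    params: ClimateParams | None = None,
) -> ClimateScenario:
    """Generate one climate scenario.

    The same ``seed`` always produces the same "current" baseline; scenario
    deltas are deterministic transformations of that baseline, so a scenario
    with ``delta_t=0, delta_seasonality=1, prec_factor=1`` is bit-identical
    to the current climate.

    The annual temperature-cycle amplitude grows with latitude, giving
    temperature seasonality a strong south-to-north gradient, and the
    whole seasonal deviation is multiplied by ``delta_seasonality`` so its
    per-cell standard deviation scales exactly.
    """
    nrows, ncols = grid_shape
    if nrows < 1 or ncols < 1:
        raise ValueError(f"grid dimensions must be positive, got {grid_shape}")
    grid = grid if grid is not None else default_grid(grid_shape)
    sp = scenario_params if scenario_params is not None else ScenarioParams()
    p = params if params is not None else ClimateParams()
    rng = np.random.default_rng([seed, 0xC11])  # stream distinct from gen_elevation

    lon, lat = grid.lonlat_mesh()
    dlat = lat - grid.ymin
    dlon = lon - grid.xmin

    t_mean = p.t_south - p.t_lat_gradient * dlat + p.t_noise * _smooth_noise(rng, grid.shape, p.noise_sigma)
    if elevation is not None:
        if elevation.grid != grid:
            raise ValueError("elevation grid does not match climate grid")
        t_mean = t_mean - p.lapse_rate * elevation.values

    amp = (
        p.amp_south
        + p.amp_lat_gradient * dlat
        + p.amp_lon_gradient * dlon
        + p.amp_noise * _smooth_noise(rng, grid.shape, p.noise_sigma)
    )
    amp = np.maximum(amp, 0.1)
    amp2 = 0.3 * np.abs(_smooth_noise(rng, grid.shape, p.noise_sigma))

    # zero-mean seasonal deviation; scaling it scales per-cell sd exactly
    seasonal = amp[None] * _CYCLE[:, None, None] + amp2[None] * _CYCLE2[:, None, None]
    tavg = t_mean[None] + sp.delta_t + sp.delta_seasonality * seasonal
    half = 0.5 * np.maximum(
        p.diurnal_range + p.diurnal_noise * _smooth_noise(rng, grid.shape, p.noise_sigma), 1.0
    )
    tmin = tavg - half[None]
    tmax = tavg + half[None]

    p_mean = (
        p.prec_south
        + p.prec_lat_gradient * dlat
        + p.prec_lon_gradient * dlon
        + p.prec_noise * _smooth_noise(rng, grid.shape, p.noise_sigma)
    )
    p_mean = np.maximum(p_mean, 3.0)
    # winter-peaking precipitation (antiphase to the temperature cycle)
    monthly_texture = p.prec_monthly_noise_frac * p_mean[None] * np.stack(
        [_smooth_noise(rng, grid.shape, p.noise_sigma) for _ in range(MONTHS)]
    )
    prec = p_mean[None] * (1.0 - p.prec_seasonal_frac * _CYCLE[:, None, None]) + monthly_texture
    prec = np.maximum(prec * sp.prec_factor, 0.0)

    return ClimateScenario(
        name=sp.name,
        grid=grid,
        monthly_tmin=tmin,
        monthly_tmax=tmax,
        monthly_tavg=tavg,
        monthly_prec=prec,
        delta_t=sp.delta_t,
        delta_seasonality=sp.delta_seasonality,
        params=sp,
    )


def default_scenarios(
    gcm_factors: dict[str, float] | None = None,
    ssp_deltas: dict[str, tuple[float, float]] | None = None,
    time_factors: dict[str, float] | None = None,
) -> list[ScenarioParams]:
    """Factorial GCM x SSP x time-slice scenario grid (plus deterministic names).

    ``ssp_deltas`` maps SSP name to (delta_t, delta_seasonality - 1) at the
    reference time slice; GCM and time factors scale both deltas.
    """
    gcm_factors = gcm_factors or {"GCM-A": 1.15, "GCM-B": 1.0, "GCM-C": 0.85}
    ssp_deltas = ssp_deltas or {"SSP126": (1.3, 0.008), "SSP585": (3.8, 0.02)}
    time_factors = time_factors or {"2070": 1.0, "2090": 1.3}
    out = []
    for gcm, gf in gcm_factors.items():
        for ssp, (dt, ds) in ssp_deltas.items():
            for ts, tf in time_factors.items():
                out.append(
                    ScenarioParams(
                        name=f"{gcm}_{ssp}_{ts}",
                        delta_t=dt * gf * tf,
                        delta_seasonality=1.0 + ds * gf * tf,
                        prec_factor=max(1.0 - 0.06 * dt * gf * tf, 0.5),
                        gcm=gcm,
                        ssp=ssp,
                        time_slice=ts,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# latent truth


@dataclasses.dataclass(frozen=True)
class TruthParams:
    """Logistic occupancy truth on standardized predictors.

    suitability = expit(beta0 + beta_seasonality * z(bio4) + beta_aridity * z(TAI))

    Negative coefficients put the suitable band at intermediate latitudes:
    the north edge is limited by rising temperature seasonality, the south
    edge by rising aridity.
    """

    beta0: float = -20.0
    beta_seasonality: float = -16.0
    beta_aridity: float = -11.5

    def suitability(
        self,
        bio4: np.ndarray,
        aridity: np.ndarray,
        ref_stats: dict[str, tuple[float, float]] | None = None,
    ) -> np.ndarray:
        """Suitability in (0, 1). ``ref_stats`` carries the standardization
        moments of the current climate so future scenarios are scored on the
        same scale; by default moments are taken from the inputs."""
        stats = ref_stats or reference_stats(bio4, aridity)
        z4 = (bio4 - stats["bio4"][0]) / stats["bio4"][1]
        za = (aridity - stats["aridity"][0]) / stats["aridity"][1]
        from scipy.special import expit

        return expit(self.beta0 + self.beta_seasonality * z4 + self.beta_aridity * za)


def reference_stats(bio4: np.ndarray, aridity: np.ndarray) -> dict[str, tuple[float, float]]:
    return {
        "bio4": (float(np.nanmean(bio4)), float(np.nanstd(bio4)) or 1.0),
        "aridity": (float(np.nanmean(aridity)), float(np.nanstd(aridity)) or 1.0),
    }


def true_suitability(scenario: ClimateScenario, truth: TruthParams | None = None,
                     ref_stats: dict[str, tuple[float, float]] | None = None) -> Raster:
    """Latent suitability for a scenario (derives bio4 and aridity internally)."""
    from rangeshift.predictors import bioclim, thornthwaite_aridity

    truth = truth if truth is not None else TruthParams()
    bio = bioclim(
        scenario.monthly_tmin, scenario.monthly_tmax, scenario.monthly_tavg, scenario.monthly_prec
    )
    lat = scenario.grid.lonlat_mesh()[1]
    tai = thornthwaite_aridity(scenario.monthly_tavg, scenario.monthly_prec, lat)
    return Raster(scenario.grid, truth.suitability(bio["bio4"], tai, ref_stats=ref_stats))


# ---------------------------------------------------------------------------
# occurrence sampling


@dataclasses.dataclass(frozen=True)
class Contamination:
    """Fractions of deliberately dirty records mixed into the raw sample."""

    pre1970: float = 0.0
    high_uncertainty: float = 0.0
    duplicate: float = 0.0

    def __post_init__(self) -> None:
        fracs = (self.pre1970, self.high_uncertainty, self.duplicate)
        if any(f < 0 for f in fracs):
            raise ValueError("contamination fractions must be nonnegative")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError(f"contamination fractions sum to {sum(fracs)} > 1")


OCCURRENCE_COLUMNS = ["lon", "lat", "year", "coord_uncertainty_m"]


def sample_occurrences(
    true_suit: Raster,
    n_raw: int,
    seed: int,
    contamination: Contamination | None = None,
    jitter: bool = True,
) -> pd.DataFrame:
    """Draw raw occurrence records from the latent truth.

    Clean presences land in distinct cells sampled with probability
    proportional to suitability and are jittered within the cell. The
    returned frame also carries a ``contam`` column ("" for clean records,
    else one of "pre1970"/"uncertainty"/"duplicate") so cleaning tests know
    the expected survivor set.
    """
    if n_raw < 50:
        raise ValueError("n_raw must be >= 50")
    contamination = contamination if contamination is not None else Contamination()
    rng = np.random.default_rng(seed)
    grid = true_suit.grid

    n_pre = int(round(contamination.pre1970 * n_raw))
    n_unc = int(round(contamination.high_uncertainty * n_raw))
    n_dup = int(round(contamination.duplicate * n_raw))
    n_clean = n_raw - n_pre - n_unc - n_dup
    if n_clean < 0:
        raise ValueError("contamination leaves no room for clean records")

    suit = np.nan_to_num(true_suit.values, nan=0.0).ravel()
    prob = suit / suit.sum()
    n_cells = prob.size
    if n_clean + n_pre + n_unc > n_cells:
        raise ValueError("grid too small for the requested number of records")

    def draw(n: int) -> tuple[np.ndarray, np.ndarray]:
        idx = rng.choice(n_cells, size=n, replace=False, p=prob)
        row, col = np.unravel_index(idx, grid.shape)
        lon, lat = grid.cell_center(row, col)
        if jitter:
            lon = lon + rng.uniform(-0.49, 0.49, n) * grid.cellsize
            lat = lat + rng.uniform(-0.49, 0.49, n) * grid.cellsize
        return lon, lat

    frames = []
    lon, lat = draw(n_clean)
    frames.append(
        pd.DataFrame(
            {
                "lon": lon,
                "lat": lat,
                "year": rng.integers(1975, 2021, n_clean),
                "coord_uncertainty_m": rng.uniform(50.0, 5000.0, n_clean),
                "contam": "",
            }
        )
    )
    if n_pre:
        lon, lat = draw(n_pre)
        frames.append(
            pd.DataFrame(
                {
                    "lon": lon,
                    "lat": lat,
                    "year": rng.integers(1900, 1970, n_pre),
                    "coord_uncertainty_m": rng.uniform(50.0, 5000.0, n_pre),
                    "contam": "pre1970",
                }
            )
        )
    if n_unc:
        lon, lat = draw(n_unc)
        frames.append(
            pd.DataFrame(
                {
                    "lon": lon,
                    "lat": lat,
                    "year": rng.integers(1975, 2021, n_unc),
                    "coord_uncertainty_m": rng.uniform(10_000.0, 30_000.0, n_unc),
                    "contam": "uncertainty",
                }
            )
        )
    if n_dup:
        src = frames[0].iloc[rng.integers(0, n_clean, n_dup)].copy()
        src["contam"] = "duplicate"
        frames.append(src)

    out = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(out))
    return out.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# serialization


def write_scenario(scenario: ClimateScenario, outdir: str | Path) -> list[str]:
    """One ASCII grid per monthly layer; returns relative file names."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for var, cube in (
        ("tmin", scenario.monthly_tmin),
        ("tmax", scenario.monthly_tmax),
        ("tavg", scenario.monthly_tavg),
        ("prec", scenario.monthly_prec),
    ):
        for m in range(MONTHS):
            fname = f"{scenario.name}_{var}_{m + 1:02d}.asc"
            write_ascii_grid(outdir / fname, scenario.grid, cube[m])
            names.append(fname)
    return names


def write_occurrences(records: pd.DataFrame, path: str | Path) -> None:
    records[OCCURRENCE_COLUMNS].to_csv(path, index=False)


def write_manifest(path: str | Path, scenarios: dict[str, list[str]], extra: dict | None = None) -> None:
    doc = {"scenarios": scenarios}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
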