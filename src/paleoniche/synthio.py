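"""Synthetic inputs for the paleo-niche and morphometric pipelines.

The generators emulate the statistical structure of the real study inputs:

* a fine present-day climate grid (19 bioclimatic layers + net primary
  productivity) and a coarse past series whose temperature forcing cycles
  with a ~41-ka period in bins older than a switch time and a ~100-ka period
  (with larger amplitude) in younger bins;
* future warming trajectories per (emulator, ssp, period) with emulator
  climate sensitivities and scenario severities ordered like the CMIP6 set
  used for the wolf's forecasts;
* nested region geometry — species range polygons concentrated on the
  high-altitude cells, a prey (giant mole-rat) polygon, and ecoregions
  tiling the extent — over an altitude surface negatively correlated with
  temperature;
* multispecies dentognathic measurement tables with species-specific means
  and covariances at the comparative-sample sizes of the canid study.

Everything is driven by a single integer seed; identical seeds yield
bitwise-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .grids import HINDCAST_LAYERS, ClimateSeries, ClimateStack, GridRaster

__all__ = [
    "ClimateConfig",
    "RegionConfig",
    "MorphoConfig",
    "RegionSet",
    "MEASUREMENT_NAMES",
    "SPECIES_SAMPLE_SIZES",
    "generate_altitude",
    "generate_climate_series",
    "generate_regions",
    "generate_morpho_table",
    "default_morpho_config",
]

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Emulator name -> climate sensitivity (deg C per CO2 doubling).
DEFAULT_EMULATORS = {
    "MIROC6": 2.6,
    "BCC-CSM2-MR": 3.0,
    "CNRM-CM6-1": 4.3,
    "CNRM-ESM2-1": 4.8,
}

#: ssp id -> end-of-century warming (deg C) for a sensitivity-3 emulator.
DEFAULT_SSP_WARMING = {"126": 1.6, "245": 2.6, "370": 3.8, "585": 5.0}

#: Future period (calendar year) -> fraction of the end-of-century warming.
DEFAULT_PERIOD_FRACTION = {2040: 0.35, 2060: 0.55, 2080: 0.80, 2100: 1.0}


@dataclass
class ClimateConfig:
    """Geometry and forcing of the synthetic climate.

    The past series defaults to 200 bins at a 10-ka step (a desk-scale
    stand-in for the 2000 x 1-ka series of the full-scale study; full scale
    is just a config choice), with the glacial-cycle period switching from
    ~41 ka (older bins) to ~100 ka (younger bins) at 1 Ma and a larger
    amplitude after the switch.
    """

    fine_shape: tuple[int, int] = (160, 160)
    cell_size: float = 1.0
    coarse_factor: int = 4
    n_bins: int = 200
    step_ka: float = 10.0
    cycle_switch_ka: float = 1000.0
    period_old_ka: float = 41.0
    period_young_ka: float = 100.0
    amp_old: float = 0.6
    amp_young: float = 1.8
    lapse_rate: float = 6.5  # deg C per km of altitude
    base_temperature: float = 24.0  # sea-level annual mean, deg C
    max_altitude: float = 4500.0  # m
    smooth_sigma: float = 6.0  # cells; spatial autocorrelation scale
    noise_sd: float = 0.8  # deg C, spatial noise on temperature layers
    bin_noise_sd: float = 0.25  # deg C, per-bin anomaly noise (coarse)
    emulators: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EMULATORS))
    ssp_warming: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SSP_WARMING))
    period_fraction: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PERIOD_FRACTION)
    )

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if min(self.fine_shape) < 4:
            raise ValueError("grid must be at least 4x4")
        if self.cell_size <= 0 or self.coarse_factor < 1:
            raise ValueError("invalid grid geometry")


@dataclass
class RegionConfig:
    """Geometry of the synthetic range / prey / ecoregion polygons."""

    n_species_polygons: int = 12
    polygon_halfwidth: int = 3  # cells; each range polygon is a (2h+1)^2 box
    min_peak_separation: int = 24  # cells between polygon centers
    prey_buffer: int = 12  # cells added around the species bounding box
    ecoregion_tiles: tuple[int, int] = (5, 5)


@dataclass
class RegionSet:
    """Range polygons, prey polygon, ecoregion tiling and the altitude surface."""

    species_polygons: list[BaseGeometry]
    prey_polygon: BaseGeometry
    ecoregion_polygons: list[BaseGeometry]
    altitude: GridRaster


MEASUREMENT_NAMES = [
    "Lc", "Bc", "Lp4", "Bp4", "Lm1trig", "Bm1", "Lm1tal", "Bm1tal", "Lm2",
    "Bm2", "Lcm2", "JDc", "JBc", "JDp3p4", "JBp3p4", "JDp4m1", "JBp4m1",
    "JDm1m2", "JBm1m2",
]

#: Comparative-sample sizes of the eight extant canid species.
SPECIES_SAMPLE_SIZES = {
    "Canis simensis": 20,
    "Canis aureus": 19,
    "Lupulella adusta": 21,
    "Lupulella mesomelas": 21,
    "Canis latrans": 21,
    "Canis lupus": 22,
    "Lycaon pictus": 19,
    "Cuon alpinus": 21,
}

HYPERCARNIVORES = ("Canis lupus", "Lycaon pictus", "Cuon alpinus")

# Baseline mesocarnivore mandible/tooth measurements (mm): a slender,
# simensis-like jaw.  Species profiles scale this vector.
_BASE_PROFILE = np.array(
    [6.5, 4.5, 11.0, 5.0, 15.0, 8.0, 7.0, 6.5, 9.0, 7.0, 75.0, 18.0, 8.0,
     19.0, 9.0, 21.0, 10.0, 23.0, 11.0]
)
_BREADTH_IDX = np.array(
    [i for i, n in enumerate(MEASUREMENT_NAMES) if n.startswith(("B", "JB"))]
)

_SPECIES_SIZE = {
    "Canis simensis": 1.00,
    "Canis aureus": 0.92,
    "Lupulella adusta": 0.95,
    "Lupulella mesomelas": 0.90,
    "Canis latrans": 1.05,
    "Canis lupus": 1.45,
    "Lycaon pictus": 1.30,
    "Cuon alpinus": 1.25,
}


@dataclass
class MorphoConfig:
    """Per-species mean vectors / covariances and sample sizes.

    ``means`` maps species -> length-19 mean vector (mm); ``covariances``
    maps species -> 19x19 covariance (positive semidefinite); ``sizes`` maps
    species -> row count.  ``fossil_mean`` optionally adds one unlabeled
    specimen row (species = "fossil").
    """

    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    sizes: dict[str, int]
    fossil_mean: np.ndarray | None = None


def default_morpho_config() -> MorphoConfig:
    """Comparative-sample defaults: two mean clusters (hypercarnivores are
    larger and relatively broader-toothed than mesocarnivores) and an
    Ethiopian-wolf profile with an elongated muzzle and slender premolars
    that separates it from the jackals."""
    means: dict[str, np.ndarray] = {}
    covs: dict[str, np.ndarray] = {}
    for sp, size in _SPECIES_SIZE.items():
        mu = _BASE_PROFILE * size
        if sp in HYPERCARNIVORES:
            mu = mu.copy()
            mu[_BREADTH_IDX] *= 1.15  # robust, broad hypercarnivore dentition
        if sp == "Canis simensis":
            mu = mu.copy()
            mu[MEASUREMENT_NAMES.index("Lcm2")] *= 1.12  # elongated muzzle
            mu[MEASUREMENT_NAMES.index("Lm1trig")] *= 1.08
            mu[MEASUREMENT_NAMES.index("Bp4")] *= 0.90  # slender premolar
            mu[MEASUREMENT_NAMES.index("JBp3p4")] *= 0.92
        means[sp] = mu
        covs[sp] = np.diag((0.04 * mu) ** 2)  # ~4 % coefficient of variation
    fossil = means["Canis simensis"] * 0.985
    # the fossil sits between the wolf and the jackals: pull the diagnostic
    # variables a third of the way toward the golden-jackal mean
    fossil = fossil + (means["Canis aureus"] - fossil) * 0.20
    return MorphoConfig(
        means=means,
        covariances=covs,
        sizes=dict(SPECIES_SAMPLE_SIZES),
        fossil_mean=fossil,
    )


# ---------------------------------------------------------------------------
# random-field helpers
# ---------------------------------------------------------------------------

def _rng(seed: int, *spawn: int) -> np.random.Generator:
    """Independent child generator for a named sub-stream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(spawn)))


def smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth Gaussian random field (smoothed white noise)."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_altitude(config: ClimateConfig, seed: int) -> GridRaster:
    """Altitude surface (m): a smooth field with a broad central highland.

    Shared sub-stream (0,): climate and region generation call this with the
    same config/seed and obtain the identical surface.
    """
    config.validate()
    rng = _rng(seed, 0)
    nrows, ncols = config.fine_shape
    f = smooth_field(config.fine_shape, config.smooth_sigma, rng)
    yy, xx = np.mgrid[0:nrows, 0:ncols]
    cy, cx = (nrows - 1) / 2.0, (ncols - 1) / 2.0
    # broad dome so the highlands sit mid-grid, as in a continental interior
    dome = np.exp(-(((yy - cy) / (0.55 * nrows)) ** 2 + ((xx - cx) / (0.55 * ncols)) ** 2))
    relief = 1.4 * f + 2.2 * dome
    relief -= relief.min()
    alt = relief / relief.max() * config.max_altitude
    return GridRaster(alt, cell_size=config.cell_size)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def _present_fine_layers(config: ClimateConfig, alt: np.ndarray, seed: int) -> dict[str, np.ndarray]:
    """The 19 bioclimatic layers + NPP on the fine grid.

    Temperature layers fall with altitude at the configured lapse rate;
    precipitation rises with altitude (orographic rainfall); NPP peaks at
    moderate temperature and high rainfall.  Each derived layer carries its
    own small noise term so layers are collinear but not singular.
    """
    shape = alt.shape
    sig = config.smooth_sigma

    def noise(k: int, scale: float = 1.0) -> np.ndarray:
        return scale * smooth_field(shape, sig, _rng(seed, 1, k))

    alt_km = alt / 1000.0
    alt_norm = alt / alt.max()
    bio1 = config.base_temperature - config.lapse_rate * alt_km + config.noise_sd * noise(1)
    layers = {"BIO1": bio1}
    layers["BIO2"] = 12.0 + 1.0 * noise(2)
    layers["BIO3"] = 70.0 + 4.0 * noise(3)
    layers["BIO4"] = 150.0 + 20.0 * noise(4)
    layers["BIO5"] = bio1 + 10.0 + 0.4 * noise(5)
    layers["BIO6"] = bio1 - 9.0 + 0.4 * noise(6)
    layers["BIO7"] = layers["BIO5"] - layers["BIO6"]
    layers["BIO8"] = bio1 + 2.0 + 0.4 * noise(8)
    layers["BIO9"] = bio1 - 2.0 + 0.4 * noise(9)
    layers["BIO10"] = bio1 + 4.0 + 0.4 * noise(10)
    layers["BIO11"] = bio1 - 5.0 + 0.4 * noise(11)
    bio12 = 400.0 + 900.0 * alt_norm + 120.0 * noise(12)
    layers["BIO12"] = bio12
    layers["BIO13"] = 0.25 * bio12 + 15.0 * noise(13)
    layers["BIO14"] = 0.02 * bio12 + 3.0 * noise(14) + 10.0
    layers["BIO15"] = 60.0 + 8.0 * noise(15)
    layers["BIO16"] = 0.45 * bio12 + 20.0 * noise(16)
    layers["BIO17"] = 0.05 * bio12 + 5.0 * noise(17) + 15.0
    layers["BIO18"] = 0.50 * bio12 + 25.0 * noise(18)
    layers["BIO19"] = 0.12 * bio12 + 10.0 * noise(19) + 20.0
    npp = 3000.0 / (1.0 + np.exp(-(bio12 - 500.0) / 300.0))
    npp *= np.exp(-(((bio1 - 18.0) / 16.0) ** 2))
    layers["NPP"] = npp + 60.0 * noise(20)
    return layers


def temperature_offset(config: ClimateConfig, t_ka: float) -> float:
    """Glacial-cycle temperature anomaly (deg C) at ``t_ka`` before present.

    Bins older than the switch time oscillate with the short (default
    ~41 ka) period and small amplitude; younger bins with the long (default
    ~100 ka) period and larger amplitude.
    """
    if t_ka > config.cycle_switch_ka:
        period, amp = config.period_old_ka, config.amp_old
    else:
        period, amp = config.period_young_ka, config.amp_young
    return amp * np.cos(2.0 * np.pi * t_ka / period)


def _block_mean(values: np.ndarray, factor: int) -> np.ndarray:
    nr, nc = values.shape
    nr2, nc2 = nr // factor, nc // factor
    v = values[: nr2 * factor, : nc2 * factor]
    return v.reshape(nr2, factor, nc2, factor).mean(axis=(1, 3))


def generate_climate_series(config: ClimateConfig | None = None, seed: int = 0) -> ClimateSeries:
    """Generate the full climate input set for one seed.

    Returns a :class:`~paleoniche.grids.ClimateSeries` holding the fine
    present stack (BIO1-BIO19 + NPP), the coarse present stack and past
    series (BIO10, BIO11, BIO18, BIO19, NPP only), and the future stacks,
    one per (emulator, ssp, period).
    """
    config = config or ClimateConfig()
    config.validate()
    cs = config.cell_size
    alt = generate_altitude(config, seed)
    fine_layers = _present_fine_layers(config, alt.values, seed)
    present_fine = ClimateStack(
        {n: GridRaster(v, cell_size=cs) for n, v in fine_layers.items()}, time_label=0.0
    )

    # --- coarse present + past series -------------------------------------
    f = config.coarse_factor
    coarse_cs = cs * f
    coarse_base = {n: _block_mean(fine_layers[n], f) for n in HINDCAST_LAYERS}
    coarse_shape = next(iter(coarse_base.values())).shape
    present_coarse = ClimateStack(
        {n: GridRaster(v, cell_size=coarse_cs) for n, v in coarse_base.items()},
        time_label=0.0,
    )

    past = []
    for b in range(1, config.n_bins + 1):
        t = b * config.step_ka
        dT = temperature_offset(config, t)
        anom = config.bin_noise_sd * smooth_field(coarse_shape, 2.0, _rng(seed, 2, b))
        lay = {
            "BIO10": coarse_base["BIO10"] + dT + anom,
            "BIO11": coarse_base["BIO11"] + dT + anom,
            "BIO18": coarse_base["BIO18"] * (1.0 + 0.03 * dT),
            "BIO19": coarse_base["BIO19"] * (1.0 + 0.03 * dT),
            "NPP": coarse_base["NPP"] * (1.0 + 0.02 * dT),
        }
        past.append(
            ClimateStack(
                {n: GridRaster(v, cell_size=coarse_cs) for n, v in lay.items()},
                time_label=t,
            )
        )

    # --- future stacks -----------------------------------------------------
    temp_layers = {"BIO1", "BIO5", "BIO6", "BIO8", "BIO9", "BIO10", "BIO11"}
    future: dict[tuple[str, str, int], ClimateStack] = {}
    for emu, sens in config.emulators.items():
        for ssp, w2100 in config.ssp_warming.items():
            for year, frac in config.period_fraction.items():
                off = (sens / 3.0) * w2100 * frac
                lay = {}
                for n, v in fine_layers.items():
                    if n in temp_layers:
                        lay[n] = v + off
                    elif n.startswith("BIO1") and n not in ("BIO1", "BIO15") or n == "NPP":
                        lay[n] = v * (1.0 - 0.015 * off)  # drying with warming
                    else:
                        lay[n] = v
                future[(emu, ssp, year)] = ClimateStack(
                    {n: GridRaster(v, cell_size=cs) for n, v in lay.items()},
                    time_label=float(year),
                    scenario=(emu, ssp),
                )

    return ClimateSeries(
        past=past, present_fine=present_fine, present_coarse=present_coarse, future=future
    )


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def generate_regions(
    config: RegionConfig | None = None,
    climate_config: ClimateConfig | None = None,
    seed: int = 0,
) -> RegionSet:
    """Range / prey / ecoregion polygons over the altitude surface.

    Species polygons are square boxes centered on well-separated altitude
    peaks, so they sit on the high, cool cells; the prey polygon is the
    buffered bounding box of the species polygons; ecoregions tile the
    extent into rectangles.
    """
    config = config or RegionConfig()
    climate_config = climate_config or ClimateConfig()
    alt = generate_altitude(climate_config, seed)
    nrows, ncols = alt.shape
    cs = alt.cell_size
    x0, y0 = alt.origin
    extent = box(x0, y0, x0 + ncols * cs, y0 + nrows * cs)

    # greedy peak picking: highest cells first, enforcing a minimum spacing
    order = np.argsort(alt.values, axis=None)[::-1]
    peaks: list[tuple[int, int]] = []
    for idx in order:
        r, c = divmod(int(idx), ncols)
        if all(max(abs(r - pr), abs(c - pc)) >= config.min_peak_separation for pr, pc in peaks):
            peaks.append((r, c))
        if len(peaks) == config.n_species_polygons:
            break
    if len(peaks) < config.n_species_polygons:
        raise ValueError(
            "could not place the requested number of separated range polygons; "
            "reduce min_peak_separation or the polygon count"
        )

    h = config.polygon_halfwidth
    species = []
    for r, c in peaks:
        poly = box(
            x0 + (c - h) * cs, y0 + (r - h) * cs, x0 + (c + h + 1) * cs, y0 + (r + h + 1) * cs
        ).intersection(extent)
        species.append(poly)

    minx = min(p.bounds[0] for p in species)
    miny = min(p.bounds[1] for p in species)
    maxx = max(p.bounds[2] for p in species)
    maxy = max(p.bounds[3] for p in species)
    b = config.prey_buffer * cs
    prey = box(minx - b, miny - b, maxx + b, maxy + b).intersection(extent)

    tiles_y, tiles_x = config.ecoregion_tiles
    eco = []
    for i in range(tiles_y):
        for j in range(tiles_x):
            eco.append(
                box(
                    x0 + j * ncols * cs / tiles_x,
                    y0 + i * nrows * cs / tiles_y,
                    x0 + (j + 1) * ncols * cs / tiles_x,
                    y0 + (i + 1) * nrows * cs / tiles_y,
                )
            )

    return RegionSet(
        species_polygons=species, prey_polygon=prey, ecoregion_polygons=eco, altitude=alt
    )


# ---------------------------------------------------------------------------
# morphometrics
# ---------------------------------------------------------------------------

def generate_morpho_table(config: MorphoConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Multispecies dentognathic measurement table.

    Rows are specimens; columns are ``species`` plus the 19 measurements
    (mm).  Per species, rows are multivariate-normal draws from the
    configured mean/covariance (redrawn in the rare case of a non-positive
    measurement).  The fossil, if configured, is one exact row labeled
    ``"fossil"``.
    """
    config = config or default_morpho_config()
    rng = _rng(seed, 3)
    frames = []
    for sp, n in config.sizes.items():
        mu = np.asarray(config.means[sp], dtype=float)
        cov = np.asarray(config.covariances[sp], dtype=float)
        if mu.shape != (len(MEASUREMENT_NAMES),):
            raise ValueError(f"mean vector for {sp} must have length 19")
        eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError(f"covariance for {sp} is not positive semidefinite")
        draws = rng.multivariate_normal(mu, cov, size=n, method="svd")
        for _ in range(100):
            bad = (draws <= 0).any(axis=1)
            if not bad.any():
                break
            draws[bad] = rng.multivariate_normal(mu, cov, size=int(bad.sum()), method="svd")
        df = pd.DataFrame(draws, columns=MEASUREMENT_NAMES)
        df.insert(0, "species", sp)
        frames.append(df)
    if config.fossil_mean is not None:
        df = pd.DataFrame([config.fossil_mean], columns=MEASUREMENT_NAMES)
        df.insert(0, "species", "fossil")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
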