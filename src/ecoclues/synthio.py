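"""Synthetic landscape generator.

Produces spatially autocorrelated drivers, categorical land-use maps sampled
from known multinomial-logit coefficients, monthly climate, and species
occurrence points — everything the downstream pipeline consumes, with the
statistical structure it assumes, fully deterministic under a fixed seed.

The generator emulates the shape of real inputs (a DEM, climate interpolated
from stations, distances to infrastructure), not their geomorphology: fields
are smoothed Gaussian noise with physically plausible couplings (temperature
follows a -0.0065 °C/m lapse rate, rainfall is correlated with elevation,
population density decays away from settlements).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import (
    MONTH_DAYS,
    N_CLASSES,
    ClimateStack,
    DriverStack,
    GridRaster,
    LandUseMap,
    slope_from_dem,
)

LAPSE_RATE_C_PER_M = -0.0065

#: Default "true" per-class multinomial-logit coefficients on standardized
#: drivers. Each class has two drivers with |beta| >= 1, chosen so that no
#: class relies on a strongly collinear driver pair (dem/temperature and
#: dist_settlement/pop_density are correlated by construction).
DEFAULT_COEFFICIENTS: dict[int, dict[str, float]] = {
    1: {"dem": 1.2, "dist_road": 1.0},          # forest: high, remote
    2: {"dem": 1.0, "rainfall": -1.2},          # grassland: dry high steppe
    3: {"slope": -1.2, "dist_river": -1.0},     # wetland: flat valley floors
    4: {"slope": -1.0, "temperature": 1.0},     # cultivated: warm flat basins
    5: {"dist_settlement": -1.2, "pop_density": 1.0},  # artificial: peri-urban
    6: {"dist_road": 1.2, "temperature": 1.0},  # other/bare: warm, remote
}

DEFAULT_RUNOFF = {1: 0.15, 2: 0.25, 3: 0.05, 4: 0.35, 5: 0.60, 6: 0.45}


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene.

    ``logistic_coefficients`` are the true multinomial-logit betas (per class,
    on standardized drivers) from which land use is sampled; recovering them
    is what makes the suitability stage testable. ``spatial_smoothness`` is
    the Gaussian kernel radius in cells.
    """

    n_rows: int = 100
    n_cols: int = 100
    seed: int = 0
    cell_size_km: float = 1.0
    logistic_coefficients: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COEFFICIENTS.items()}
    )
    spatial_smoothness: float = 5.0
    runoff_coefficients: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RUNOFF)
    )
    dem_mean_m: float = 1000.0
    dem_relief_m: float = 8000.0  # pre-smoothing noise amplitude; ~450 m realized relief at sigma=5
    noise_amplitude: float = 0.1  # relative driver noise
    n_settlements: int = 4
    n_roads: int = 3
    n_rivers: int = 2

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.spatial_smoothness <= 0:
            raise ValueError("spatial_smoothness must be positive")
        missing = [c for c in range(1, N_CLASSES + 1) if c not in self.logistic_coefficients]
        if missing:
            raise ValueError(f"logistic coefficients missing for classes {missing}")
        for c, r in self.runoff_coefficients.items():
            if not 0 <= r <= 1:
                raise ValueError(f"runoff coefficient for class {c} outside [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, named, seed-derived random stream (stable across runs)."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        return np.random.default_rng(ss)


@dataclass
class SpeciesOccurrences:
    """Point records (row, col, species_id) plus per-species protection weight."""

    points: list[tuple[int, int, int]]
    protection_weight: dict[int, float]

    def __post_init__(self) -> None:
        for sid, w in self.protection_weight.items():
            if w <= 0:
                raise ValueError(f"protection weight for species {sid} must be positive")
        seen = {sid for _, _, sid in self.points}
        missing = set(self.protection_weight) - seen
        if missing:
            raise ValueError(f"species without occurrences: {sorted(missing)}")


def _smoothed_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-free smoothed Gaussian noise, rescaled to unit variance when possible."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def generate_dem(spec: SceneSpec) -> GridRaster:
    """Smoothed Gaussian-noise elevation field (metres).

    ``dem_relief_m`` is the white-noise amplitude *before* smoothing; the
    realized relief standard deviation is ≈ amplitude / (2σ√π), so the field
    flattens monotonically as ``spatial_smoothness`` grows (near-constant in
    the σ → ∞ limit).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    base = ndimage.gaussian_filter(
        rng.standard_normal((spec.n_rows, spec.n_cols)), spec.spatial_smoothness, mode="reflect"
    )
    return GridRaster(spec.dem_mean_m + spec.dem_relief_m * base, spec.cell_size_km)


def _distance_to_cells(mask: np.ndarray, cell_size_km: float) -> np.ndarray:
    """Euclidean distance (km) from every cell to the nearest True cell."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask) * cell_size_km


def _random_polyline_mask(
    rng: np.random.Generator, shape: tuple[int, int], n_lines: int
) -> np.ndarray:
    """Rasterized random walks across the grid — stand-ins for roads/rivers."""
    mask = np.zeros(shape, dtype=bool)
    nr, nc = shape
    for _ in range(n_lines):
        r = int(rng.integers(0, nr))
        drift = rng.uniform(-0.8, 0.8)
        for c in range(nc):
            mask[int(np.clip(r, 0, nr - 1)), c] = True
            r += drift + rng.normal(0, 0.7)
    return mask


def generate_drivers(dem: GridRaster, spec: SceneSpec) -> DriverStack:
    """Driver stack coupled to the DEM.

    Temperature follows the standard atmospheric lapse rate (-0.0065 °C/m)
    plus noise; rainfall increases with elevation (orographic proxy); distance
    rasters come from randomly seeded settlement points and road/river
    polylines via an exact Euclidean distance transform; population density
    decays exponentially with distance to the nearest settlement.
    """
    shape = dem.shape
    amp = spec.noise_amplitude

    # independent smoothed noise keeps the stack identifiable: temperature
    # and rainfall follow elevation but are not deterministic functions of it
    rng_t = spec.rng("temperature")
    temp = 18.0 + LAPSE_RATE_C_PER_M * dem.values
    if amp > 0:
        temp = temp + amp * 45.0 * _smoothed_noise(rng_t, shape, spec.spatial_smoothness)

    rng_p = spec.rng("rainfall")
    rain = 300.0 + 0.10 * (dem.values - spec.dem_mean_m)
    if amp > 0:
        rain = rain + amp * 600.0 * _smoothed_noise(rng_p, shape, spec.spatial_smoothness)
    rain = np.clip(rain, 0.0, None)

    rng_s = spec.rng("settlements")
    settle = np.zeros(shape, dtype=bool)
    n_set = max(1, spec.n_settlements)
    settle[
        rng_s.integers(0, shape[0], n_set), rng_s.integers(0, shape[1], n_set)
    ] = True
    dist_settle = _distance_to_cells(settle, dem.cell_size_km)

    road_mask = _random_polyline_mask(spec.rng("roads"), shape, max(1, spec.n_roads))
    river_mask = _random_polyline_mask(spec.rng("rivers"), shape, max(1, spec.n_rivers))
    dist_road = _distance_to_cells(road_mask, dem.cell_size_km)
    dist_river = _distance_to_cells(river_mask, dem.cell_size_km)

    rng_d = spec.rng("population")
    scale = 0.15 * max(shape) * dem.cell_size_km
    pop = 500.0 * np.exp(-dist_settle / max(scale, 1e-9))
    if amp > 0:
        pop = pop * np.exp(amp * 10.0 * _smoothed_noise(rng_d, shape, spec.spatial_smoothness))

    return DriverStack(
        {
            "dem": dem,
            "slope": slope_from_dem(dem),
            "rainfall": dem.like(rain),
            "temperature": dem.like(temp),
            "dist_road": dem.like(dist_road),
            "dist_river": dem.like(dist_river),
            "dist_settlement": dem.like(dist_settle),
            "pop_density": dem.like(pop),
        }
    )


def standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def class_utilities(drivers: DriverStack, spec: SceneSpec) -> np.ndarray:
    """(K, nrows, ncols) linear predictors over standardized drivers."""
    shape = drivers.reference.shape
    util = np.zeros((N_CLASSES,) + shape)
    std = {n: standardize(drivers[n].values) for n in drivers.names}
    for k in range(1, N_CLASSES + 1):
        for name, beta in spec.logistic_coefficients[k].items():
            if name not in std:
                raise KeyError(f"coefficient references unknown driver {name!r}")
            util[k - 1] += beta * std[name]
    return util


def generate_landuse(drivers: DriverStack, spec: SceneSpec) -> LandUseMap:
    """Sample a categorical map from a multinomial logit over the true betas.

    A multinomial (softmax) model — rather than six independent binaries —
    guarantees the classes partition every cell.
    """
    util = class_utilities(drivers, spec)
    util -= util.max(axis=0, keepdims=True)
    p = np.exp(util)
    p /= p.sum(axis=0, keepdims=True)
    cum = np.cumsum(p, axis=0)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    u = rng.random(drivers.reference.shape)
    codes = 1 + (u[None, :, :] >= cum).sum(axis=0)
    codes = np.clip(codes, 1, N_CLASSES)
    ref = drivers.reference
    return LandUseMap(codes, ref.cell_size_km, ref.nodata_mask.copy())


def generate_climate(
    spec: SceneSpec,
    temp_mean_c: float = 8.0,
    temp_amplitude_c: float = 14.0,
    precip_mean_mm: float = 35.0,
    precip_amplitude_mm: float = 30.0,
    wind_mean_ms: float = 4.0,
    humidity_mean: float = 0.5,
) -> ClimateStack:
    """Monthly climate with sinusoidal seasonal cycles plus noise.

    Layers are spatially uniform (one value per month, broadcast over the
    grid): the scene stands in for a single climate-station region. July is
    the warm/wet peak; relative humidity is clipped to [0, 1] and monthly
    precipitation floored at 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    months = np.arange(12)
    season = np.cos(2 * np.pi * (months - 6) / 12)  # +1 in July
    noise = spec.noise_amplitude
    t = temp_mean_c + temp_amplitude_c * season + rng.normal(0, 2.0 * noise, 12)
    p = np.clip(
        precip_mean_mm + precip_amplitude_mm * season + rng.normal(0, 10.0 * noise, 12), 0, None
    )
    r = np.clip(0.25 + (humidity_mean - 0.25) * (1 + season) + rng.normal(0, 0.1 * noise, 12), 0, 1)
    u = np.clip(wind_mean_ms * (1 + 0.4 * -season) + rng.normal(0, 0.5 * noise, 12), 0.1, None)

    shape = (spec.n_rows, spec.n_cols)
    tile = lambda v: np.broadcast_to(v[:, None, None], (12,) + shape).copy()  # noqa: E731
    return ClimateStack(
        precip_mm=tile(p),
        temp_c=tile(t),
        rel_humidity=tile(r),
        wind_ms=tile(u),
        days=MONTH_DAYS.copy(),
        cell_size_km=spec.cell_size_km,
    )


def generate_species(
    suitability: GridRaster, n_species: int, spec: SceneSpec, points_per_species: int = 30
) -> SpeciesOccurrences:
    """Occurrence points sampled proportional to a [0, 1] suitability surface.

    Every species receives at least one point (and by default many more);
    protection weights are drawn uniformly from {1, 2, 3} as a stand-in for
    statutory protection levels.
    """
    w = np.where(suitability.nodata_mask, 0.0, suitability.values).ravel()
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("suitability must lie in [0, 1]")
    total = w.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot place occurrences")
    prob = w / total
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
    ncols = suitability.shape[1]
    points: list[tuple[int, int, int]] = []
    weights: dict[int, float] = {}
    for sid in range(1, n_species + 1):
        flat = rng.choice(prob.size, size=max(1, points_per_species), p=prob)
        points.extend((int(f // ncols), int(f % ncols), sid) for f in flat)
        weights[sid] = float(rng.integers(1, 4))
    return SpeciesOccurrences(points, weights)


def grow_artificial(
    landuse: LandUseMap, drivers: DriverStack, n_cells: int
) -> LandUseMap:
    """Deterministic urban-growth surrogate for a later-date map.

    Converts the ``n_cells`` non-artificial cells closest to a settlement to
    artificial surface — the accretion-at-the-urban-fringe pattern the
    allocation stage is expected to reproduce.
    """
    out = landuse.copy()
    dist = drivers["dist_settlement"].values.copy()
    convertible = (out.codes != 5) & ~out.nodata_mask
    dist[~convertible] = np.inf
    order = np.argsort(dist, axis=None, kind="stable")[: min(n_cells, convertible.sum())]
    rows, cols = np.unravel_index(order, out.shape)
    out.codes[rows, cols] = 5
    return out


def generate_service_layers(
    drivers: DriverStack, landuse: LandUseMap, spec: SceneSpec
) -> dict[str, GridRaster]:
    """Auxiliary surfaces for the service calculators.

    Returns evapotranspiration (mm/yr, a temperature-scaled fraction of
    rainfall), mean NPP (gC/m²/yr, rainfall-driven), USLE rainfall erosivity
    R and soil erodibility K, vegetation cover factor C (by land-use class),
    and the wind-erosion soil factor K_s. These are plausibility-level
    stand-ins: smooth fields with the couplings the formulas expect.
    """
    ref = drivers.reference
    rain = drivers["rainfall"].values
    temp = drivers["temperature"].values

    et_frac = np.clip(0.45 + 0.02 * (temp - temp.mean()), 0.1, 0.9)
    et = et_frac * rain

    npp = np.clip(1.2 * rain + 20.0 * np.clip(temp, 0, None), 0, None)

    erosivity = np.clip(0.5 * rain - 50.0, 0.0, None)  # MJ·mm/(hm²·h·a)

    rng = spec.rng("soil")
    k_usle = np.clip(
        0.03 + 0.012 * _smoothed_noise(rng, ref.shape, spec.spatial_smoothness), 0.001, None
    )
    k_sand = np.clip(
        1.0 + 0.4 * _smoothed_noise(spec.rng("soil_sand"), ref.shape, spec.spatial_smoothness),
        0.05,
        None,
    )

    cover_by_class = {1: 0.003, 2: 0.05, 3: 0.01, 4: 0.25, 5: 1.0, 6: 0.7}
    cover = np.zeros(ref.shape)
    for code, c in cover_by_class.items():
        cover[landuse.codes == code] = c

    return {
        "evapotranspiration": ref.like(et),
        "npp": ref.like(npp),
        "erosivity_r": ref.like(erosivity),
        "erodibility_k": ref.like(k_usle),
        "cover_c": ref.like(cover),
        "soil_wind_k": ref.like(k_sand),
    }


def generate_scene(spec: SceneSpec) -> dict:
    """Full synthetic scene: drivers, land use, climate, service layers."""
    dem = generate_dem(spec)
    drivers = generate_drivers(dem, spec)
    landuse = generate_landuse(drivers, spec)
    climate = generate_climate(spec)
    layers = generate_service_layers(drivers, landuse, spec)
    return {
        "spec": spec,
        "dem": dem,
        "drivers": drivers,
        "landuse": landuse,
        "climate": climate,
        **layers,
    }
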