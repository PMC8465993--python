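"""Ecosystem-service quantity calculators.

Four services are quantified on the grid:

* water conservation — water-balance residual TQ = Σ (P − R − ET) · A,
  rainfall minus surface runoff minus evapotranspiration over class areas;
* soil conservation — USLE difference between potential and actual erosion,
  A_c = A_p − A_r = R·K·L·S·(1 − C);
* sandstorm prevention (sand fixation) — a capacity index
  S_WS = NPP_mean · K_s · F_q · D combining productivity, soil erodibility to
  wind, the wind-erosion climatic factor F_q, and surface roughness D;
* biodiversity — a rectilinear climate/terrain envelope model over species
  occurrence points.

Every calculator is deterministic and cell-local.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import (
    CLASS_CODES,
    CLASS_NAMES,
    ClimateStack,
    DimensionError,
    DriverStack,
    GridRaster,
    LandUseMap,
)
from .synthio import SpeciesOccurrences

log = logging.getLogger(__name__)

#: 1 mm of water depth over 1 km² is 1000 m³.
MM_KM2_TO_M3 = 1000.0


def estimate_runoff(
    precip: GridRaster, landuse: LandUseMap, runoff_coefficients: dict[int, float]
) -> GridRaster:
    """Surface runoff as a per-class fraction of rainfall, R = c[class] · P."""
    if not precip.aligned_with(landuse):
        raise DimensionError("precipitation and land use must be aligned")
    missing = [c for c in np.unique(landuse.unmasked()) if c not in runoff_coefficients]
    if missing:
        raise ValueError(f"runoff coefficient missing for classes {missing}")
    coef = np.zeros(precip.shape)
    for c, f in runoff_coefficients.items():
        if not 0 <= f <= 1:
            raise ValueError(f"runoff coefficient for class {c} outside [0, 1]")
        coef[landuse.codes == c] = f
    return precip.like(coef * precip.values)


def water_conservation(
    precip: GridRaster,
    runoff: GridRaster,
    evapotranspiration: GridRaster,
    landuse: LandUseMap,
) -> tuple[GridRaster, pd.Series, float]:
    """Water-balance water conservation.

    Returns the per-cell amount (m³; may be negative where ET + R exceed P),
    per-class totals, and the study-area total TQ (m³). P, R, ET are mm/yr.
    """
    for r in (runoff, evapotranspiration, landuse):
        if not precip.aligned_with(r):
            raise DimensionError("water balance inputs must be aligned")
    depth_mm = precip.values - runoff.values - evapotranspiration.values
    per_cell = depth_mm * precip.cell_area_km2 * MM_KM2_TO_M3
    valid = ~precip.nodata_mask
    totals = pd.Series(
        {c: float(per_cell[valid & (landuse.codes == c)].sum()) for c in CLASS_CODES},
        name="water_conservation_m3",
    )
    tq = float(totals.sum())
    return precip.like(per_cell), totals, tq


def soil_conservation(
    erosivity_r: GridRaster,
    erodibility_k: GridRaster,
    slope_length_l: GridRaster | float,
    slope_factor_s: GridRaster | float,
    cover_c: GridRaster,
) -> tuple[GridRaster, GridRaster, GridRaster]:
    """USLE soil conservation A_c = R·K·L·S·(1 − C) (t/hm²·a).

    Returns (A_c conservation, A_p potential erosion, A_r actual erosion);
    A_c = A_p − A_r holds exactly. L and S may be scalars (unit-plot
    convention L = 1 when no slope-length raster is available).
    """
    ref = erosivity_r
    lf = slope_length_l.values if isinstance(slope_length_l, GridRaster) else slope_length_l
    sf = slope_factor_s.values if isinstance(slope_factor_s, GridRaster) else slope_factor_s
    c = cover_c.values
    if np.any(c[~cover_c.nodata_mask] > 1) or np.any(c[~cover_c.nodata_mask] < 0):
        raise ValueError("cover factor C must lie in [0, 1]")
    a_p = erosivity_r.values * erodibility_k.values * lf * sf
    a_r = a_p * c
    return ref.like(a_p - a_r), ref.like(a_p), ref.like(a_r)


def slope_factor_mccool(slope_rad: GridRaster) -> GridRaster:
    """Slope steepness factor S from slope via McCool's piecewise relation.

    Convenience helper (S = 10.8·sinθ + 0.03 below 9% slope, else
    16.8·sinθ − 0.5); supplied for landscapes lacking a precomputed S raster.
    """
    s = np.sin(slope_rad.values)
    steep = np.tan(slope_rad.values) >= 0.09
    return slope_rad.like(np.where(steep, 16.8 * s - 0.5, 10.8 * s + 0.03))


def potential_evapotranspiration(temp_c, rel_humidity):
    """Monthly potential evapotranspiration, ETP = 0.19·(20 + T)²·(1 − r) mm.

    The quadratic is clamped to 0 for T ≤ −20 °C (it would otherwise rise
    again for colder months). Accepts scalars or arrays.
    """
    t = np.asarray(temp_c, dtype=float)
    r = np.asarray(rel_humidity, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("relative humidity must lie in [0, 1]")
    etp = 0.19 * np.square(20.0 + np.clip(t, -20.0, None)) * (1.0 - r)
    etp = np.where(t <= -20.0, 0.0, etp)
    return float(etp) if etp.ndim == 0 else etp


def wind_at_height(u1, z1: float, z2: float):
    """Wind speed extrapolated between heights by the 1/7-power profile law."""
    if z1 <= 0 or z2 <= 0:
        raise ValueError("heights must be positive")
    return u1 * (z2 / z1) ** (1.0 / 7.0)


def climate_erosivity(
    climate: ClimateStack, target_height_m: float | None = None
) -> GridRaster:
    """Wind-erosion climatic factor F_q.

    F_q = (1/100) Σ_months u³ · max(0, (ETP − P)/ETP) · d, with u the monthly
    mean wind speed (extrapolated to ``target_height_m`` by the power law if
    given), ETP the potential evapotranspiration and d the days in the month.
    Months with P ≥ ETP (no moisture deficit) or ETP ≤ 0 contribute zero:
    wind erosion is inactive when the surface is wet.
    """
    u = climate.wind_ms
    if target_height_m is not None:
        u = wind_at_height(u, climate.wind_height_m, target_height_m)
    etp = potential_evapotranspiration(climate.temp_c, climate.rel_humidity)
    with np.errstate(divide="ignore", invalid="ignore"):
        deficit = np.where(etp > 0, (etp - climate.precip_mm) / etp, 0.0)
    deficit = np.clip(deficit, 0.0, None)
    fq = (u**3 * deficit * climate.days[:, None, None]).sum(axis=0) / 100.0
    return GridRaster(fq, climate.cell_size_km, climate.nodata_mask.copy())


def surface_roughness(slope_rad: GridRaster) -> GridRaster:
    """Surface roughness factor D = 1/cos θ; strictly increasing on [0, π/2)."""
    th = slope_rad.values
    if np.any(th[~slope_rad.nodata_mask] >= np.pi / 2) or np.any(
        th[~slope_rad.nodata_mask] < 0
    ):
        raise ValueError("slope must lie in [0, pi/2)")
    return slope_rad.like(1.0 / np.cos(th))


def sand_fixation(
    npp_mean: GridRaster,
    soil_wind_k: GridRaster,
    climate_factor_fq: GridRaster,
    roughness_d: GridRaster,
) -> GridRaster:
    """Sandstorm-prevention capacity index S_WS = NPP_mean · K_s · F_q · D."""
    for r in (soil_wind_k, climate_factor_fq, roughness_d):
        if npp_mean.shape != r.shape:
            raise DimensionError("sand-fixation inputs must share shape")
    return npp_mean.like(
        npp_mean.values * soil_wind_k.values * climate_factor_fq.values * roughness_d.values
    )


def biodiversity_suitability(
    occurrences: SpeciesOccurrences,
    drivers: DriverStack,
    min_points: int = 5,
    envelope_pct: tuple[float, float] = (5.0, 95.0),
) -> GridRaster:
    """Envelope-based habitat suitability in [0, 1].

    Per species (≥ ``min_points`` occurrences), each driver gets a
    [5th, 95th]-percentile envelope of its values at the occurrence cells; a
    cell's species score is the fraction of drivers whose value there lies
    inside the envelope. The output is the protection-weighted mean over
    species. Species with too few points are skipped with a warning.
    """
    ref = drivers.reference
    names = drivers.names
    if not names:
        raise ValueError("at least one driver required")
    stacks = np.stack([drivers[n].values for n in names])  # (D, nr, nc)

    by_species: dict[int, list[tuple[int, int]]] = {}
    for r, c, sid in occurrences.points:
        if not (0 <= r < ref.shape[0] and 0 <= c < ref.shape[1]):
            raise ValueError(f"occurrence ({r}, {c}) outside grid")
        by_species.setdefault(sid, []).append((r, c))

    score = np.zeros(ref.shape)
    total_w = 0.0
    for sid, pts in sorted(by_species.items()):
        if len(pts) < min_points:
            log.warning("species %s has %d (<%d) points; skipped", sid, len(pts), min_points)
            continue
        rows = np.array([p[0] for p in pts])
        cols = np.array([p[1] for p in pts])
        vals = stacks[:, rows, cols]  # (D, n_pts)
        lo = np.percentile(vals, envelope_pct[0], axis=1)
        hi = np.percentile(vals, envelope_pct[1], axis=1)
        inside = (stacks >= lo[:, None, None]) & (stacks <= hi[:, None, None])
        w = occurrences.protection_weight.get(sid, 1.0)
        score += w * inside.mean(axis=0)
        total_w += w
    if total_w == 0:
        raise ValueError("no species with enough occurrence points")
    return ref.like(score / total_w)


def service_class_totals(service: GridRaster, landuse: LandUseMap) -> pd.DataFrame:
    """Per-land-use-class sum and mean of a service raster (reporting helper)."""
    valid = ~service.nodata_mask
    rows = []
    for c in CLASS_CODES:
        sel = valid & (landuse.codes == c)
        rows.append(
            {
                "class": c,
                "name": CLASS_NAMES[c],
                "total": float(service.values[sel].sum()),
                "mean": float(service.values[sel].mean()) if sel.any() else 0.0,
                "area_km2": float(sel.sum()) * landuse.cell_area_km2,
            }
        )
    return pd.DataFrame(rows)
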