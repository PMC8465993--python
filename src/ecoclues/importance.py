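"""Ordinal importance grading of service rasters and urban-encroachment accounting.

Cells are ranked by their contribution to a service's total; the top cells
that together provide 35% of the service are Very Important, up to 65%
Important, up to 85% Moderate, and the remainder Common (cumulative-share
prefix rule, thresholds configurable). Graded maps are combined across
services by the per-cell maximum level, and new artificial surface is
overlaid on the graded services to account for encroachment severity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from itertools import combinations

import numpy as np
import pandas as pd

from .grids import DimensionError, GridRaster, LandUseMap

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.35, 0.65, 0.85)
ARTIFICIAL_CODE = 5


class Level(IntEnum):
    """Ordinal importance levels; larger = more important."""

    COMMON = 1
    MODERATE = 2
    IMPORTANT = 3
    VERY_IMPORTANT = 4

    @property
    def label(self) -> str:
        return {
            Level.COMMON: "Common",
            Level.MODERATE: "Moderate",
            Level.IMPORTANT: "Important",
            Level.VERY_IMPORTANT: "Very Important",
        }[self]


#: Display order used by the statistics tables (most important first).
LEVEL_ORDER = (Level.VERY_IMPORTANT, Level.IMPORTANT, Level.MODERATE, Level.COMMON)


@dataclass
class ImportanceMap:
    """Ordinal raster of importance levels (values are Level codes)."""

    levels: np.ndarray
    cell_size_km: float = 1.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.levels.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        valid = self.levels[~self.nodata_mask]
        if valid.size and (valid.min() < Level.COMMON or valid.max() > Level.VERY_IMPORTANT):
            raise ValueError("levels must be Level codes 1..4")

    @property
    def shape(self) -> tuple[int, int]:
        return self.levels.shape

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def aligned_with(self, other) -> bool:
        return self.shape == other.shape and np.array_equal(
            self.nodata_mask, other.nodata_mask
        )


def grade(
    service: GridRaster, thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
) -> ImportanceMap:
    """Grade a service raster by cumulative contribution to its total.

    Cells are sorted descending (ties by row-major index); the minimal prefix
    whose cumulative share reaches thresholds[0] is Very Important, then
    thresholds[1] bounds Important and thresholds[2] Moderate; the rest is
    Common. Negative values are floored at 0 before grading. An all-zero
    raster grades entirely Common.
    """
    if not 0 < thresholds[0] < thresholds[1] < thresholds[2] < 1:
        raise ValueError("thresholds must be strictly increasing in (0, 1)")
    valid = ~service.nodata_mask
    vals = np.clip(service.values[valid], 0.0, None)
    out = np.full(service.shape, int(Level.COMMON))
    total = vals.sum()
    if total <= 0:
        log.warning("all-zero service raster; grading everything Common")
        out[service.nodata_mask] = int(Level.COMMON)
        return ImportanceMap(out, service.cell_size_km, service.nodata_mask.copy())

    order = np.argsort(-vals, kind="stable")  # ties keep row-major order
    cum = np.cumsum(vals[order]) / total
    b0 = int(np.searchsorted(cum, thresholds[0], side="left"))
    b1 = max(int(np.searchsorted(cum, thresholds[1], side="left")), b0)
    b2 = max(int(np.searchsorted(cum, thresholds[2], side="left")), b1)

    lev = np.full(vals.size, int(Level.COMMON))
    lev[order[: b0 + 1]] = int(Level.VERY_IMPORTANT)
    lev[order[b0 + 1 : b1 + 1]] = int(Level.IMPORTANT)
    lev[order[b1 + 1 : b2 + 1]] = int(Level.MODERATE)
    out[valid] = lev
    return ImportanceMap(out, service.cell_size_km, service.nodata_mask.copy())


@dataclass
class GradeStats:
    """Per-level acreage (km²) and area ratio (%), most-important level first."""

    acreage_km2: dict[Level, float]
    area_ratio_pct: dict[Level, float] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.acreage_km2.values())
        self.area_ratio_pct = {
            lv: (100.0 * a / total if total > 0 else 0.0)
            for lv, a in self.acreage_km2.items()
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Function Level": [lv.label for lv in LEVEL_ORDER],
                "Acreage (km2)": [round(self.acreage_km2[lv], 2) for lv in LEVEL_ORDER],
                "Area ratio (%)": [round(self.area_ratio_pct[lv], 2) for lv in LEVEL_ORDER],
            }
        )

    @classmethod
    def from_acreages(cls, acreages: dict[Level, float]) -> "GradeStats":
        full = {lv: float(acreages.get(lv, 0.0)) for lv in LEVEL_ORDER}
        return cls(full)


def grade_stats(imp: ImportanceMap) -> GradeStats:
    """Acreage and percentage share of each importance level."""
    valid = imp.levels[~imp.nodata_mask]
    return GradeStats(
        {lv: float((valid == int(lv)).sum()) * imp.cell_area_km2 for lv in LEVEL_ORDER}
    )


def combined_importance(maps: list[ImportanceMap]) -> ImportanceMap:
    """Per-cell maximum level across services (idempotent, order-invariant)."""
    if not maps:
        raise ValueError("need at least one importance map")
    ref = maps[0]
    for m in maps[1:]:
        if not ref.aligned_with(m):
            raise DimensionError("importance maps must be aligned")
    stacked = np.stack([m.levels for m in maps])
    return ImportanceMap(stacked.max(axis=0), ref.cell_size_km, ref.nodata_mask.copy())


def new_artificial(map_t0: LandUseMap, map_t1: LandUseMap) -> GridRaster:
    """Binary raster of cells newly converted to artificial surface (code 5)."""
    if not map_t0.aligned_with(map_t1):
        raise DimensionError("maps must be aligned")
    new = (map_t0.codes != ARTIFICIAL_CODE) & (map_t1.codes == ARTIFICIAL_CODE)
    return GridRaster(
        new.astype(float), map_t0.cell_size_km, map_t0.nodata_mask.copy()
    )


@dataclass
class EncroachmentTable:
    """Encroached acreage per severity and invaded-service combination.

    ``rows`` maps (severity Level, combination label) to acreage (km²);
    severity totals are exact sums of their combination rows.
    """

    rows: dict[tuple[Level, str], float]

    def severity_total(self, severity: Level) -> float:
        return sum(a for (s, _), a in self.rows.items() if s == severity)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for severity in (Level.MODERATE, Level.IMPORTANT, Level.VERY_IMPORTANT):
            combos = sorted(
                ((label, a) for (s, label), a in self.rows.items() if s == severity)
            )
            for i, (label, a) in enumerate(combos):
                recs.append(
                    {
                        "Invaded Eco-service function": severity.label if i == 0 else "",
                        "Type": label,
                        "Acreage (km2)": round(a, 2),
                        "Total acreage": round(self.severity_total(severity), 2)
                        if i == 0
                        else "",
                    }
                )
        return pd.DataFrame(recs)


def encroachment_table(
    new_art: GridRaster, service_maps: dict[str, ImportanceMap]
) -> EncroachmentTable:
    """Classify new-artificial cells by the services they encroach on.

    A service is "invaded" at a cell when its importance there is Moderate or
    higher. Severity follows the cardinality of the invaded set: one service →
    Moderate (keyed by the service), two → Important (keyed by the pair),
    three or more → Very Important (keyed by the combination). Cells invading
    no service are not tabulated.
    """
    if len(service_maps) != 4:
        raise ValueError("exactly four named service maps required")
    for m in service_maps.values():
        if new_art.shape != m.shape:
            raise DimensionError("rasters must be aligned")
    names = sorted(service_maps)
    valid = ~new_art.nodata_mask
    hot = new_art.values > 0.5
    cell_area = new_art.cell_area_km2

    invaded = {
        n: (service_maps[n].levels >= int(Level.MODERATE)) for n in names
    }
    rows: dict[tuple[Level, str], float] = {}
    sel = valid & hot
    if sel.any():
        flags = np.stack([invaded[n][sel] for n in names])  # (4, n_cells)
        counts = flags.sum(axis=0)
        for card, severity in ((1, Level.MODERATE), (2, Level.IMPORTANT)):
            for combo in combinations(range(len(names)), card):
                mask = (counts == card) & np.all(flags[list(combo)], axis=0)
                n_cells = int(mask.sum())
                if n_cells:
                    label = "+".join(names[i] for i in combo)
                    rows[(severity, label)] = n_cells * cell_area
        # cardinality >= 3 -> Very Important, keyed by the exact combination
        high = counts >= 3
        if high.any():
            idx = np.where(high)[0]
            for i in idx:
                combo = tuple(j for j in range(len(names)) if flags[j, i])
                label = "+".join(names[j] for j in combo)
                key = (Level.VERY_IMPORTANT, label)
                rows[key] = rows.get(key, 0.0) + cell_area
    return EncroachmentTable(rows)
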