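"""Core raster data types shared by every pipeline stage.

All rasters are rectangular numpy grids with a square cell size in km and an
explicit nodata mask (True = missing). Convention: row-major storage, origin at
the top-left corner, areas in km². NoData propagates: any operation combining
rasters masks a cell if any input masks it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Land-use / ecosystem class codes, in the column order used throughout.
CLASS_CODES = (1, 2, 3, 4, 5, 6)
CLASS_NAMES = {
    1: "forest",
    2: "grassland",
    3: "wetland",
    4: "cultivated",
    5: "artificial",
    6: "other",
}
N_CLASSES = len(CLASS_CODES)


class DimensionError(ValueError):
    """Raster too small or shapes inconsistent for the requested operation."""


@dataclass
class GridRaster:
    """A 2-D grid of real values with cell size and nodata mask.

    Parameters
    ----------
    values : ndarray of float, shape (nrows, ncols)
    cell_size_km : float
        Side length of the square cell, km. Cell area is ``cell_size_km ** 2``.
    nodata_mask : ndarray of bool, same shape; True marks missing cells.
    """

    values: np.ndarray
    cell_size_km: float = 1.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("values must be a 2-D grid")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise DimensionError("nodata_mask shape must match values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def unmasked(self) -> np.ndarray:
        """Flat array of values at valid (unmasked) cells."""
        return self.values[~self.nodata_mask]

    def like(self, values: np.ndarray) -> "GridRaster":
        """New raster with the same geometry/mask and the given values."""
        return GridRaster(values, self.cell_size_km, self.nodata_mask.copy())

    def aligned_with(self, other: "GridRaster | LandUseMap") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_km, other.cell_size_km)
            and np.array_equal(self.nodata_mask, other.nodata_mask)
        )


@dataclass
class LandUseMap:
    """Categorical raster over the six ecosystem classes.

    Codes: 1 forest, 2 grassland, 3 wetland, 4 cultivated, 5 artificial,
    6 other. Every unmasked cell carries exactly one code.
    """

    codes: np.ndarray
    cell_size_km: float = 1.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 2:
            raise DimensionError("codes must be a 2-D grid")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.codes.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.codes.shape:
                raise DimensionError("nodata_mask shape must match codes shape")
        valid = self.codes[~self.nodata_mask]
        bad = np.setdiff1d(np.unique(valid), CLASS_CODES)
        if bad.size:
            raise ValueError(f"invalid land-use class codes present: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def unmasked(self) -> np.ndarray:
        return self.codes[~self.nodata_mask]

    def aligned_with(self, other: "GridRaster | LandUseMap") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_km, other.cell_size_km)
            and np.array_equal(self.nodata_mask, other.nodata_mask)
        )

    def copy(self) -> "LandUseMap":
        return LandUseMap(self.codes.copy(), self.cell_size_km, self.nodata_mask.copy())


#: Canonical driver names; DriverStack may carry any subset (or extras).
DRIVER_NAMES = (
    "dem",  # elevation, m
    "slope",  # rad
    "rainfall",  # mm/yr
    "temperature",  # deg C annual mean
    "dist_road",  # km
    "dist_river",  # km
    "dist_settlement",  # km
    "pop_density",  # persons/km2
)


@dataclass
class DriverStack:
    """Named collection of co-registered driver rasters."""

    rasters: dict[str, GridRaster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rasters = list(self.rasters.values())
        if rasters:
            ref = rasters[0]
            for r in rasters[1:]:
                if not ref.aligned_with(r):
                    raise DimensionError("all drivers must share shape, cell size and mask")

    def __getitem__(self, name: str) -> GridRaster:
        return self.rasters[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rasters

    @property
    def names(self) -> list[str]:
        return list(self.rasters)

    @property
    def reference(self) -> GridRaster:
        return next(iter(self.rasters.values()))

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        """(n_valid_cells, n_drivers) value matrix over unmasked cells."""
        names = names if names is not None else self.names
        return np.column_stack([self.rasters[n].unmasked() for n in names])


MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass
class ClimateStack:
    """Twelve monthly layers of precipitation, temperature, relative humidity
    and wind speed, plus days-in-month.

    Arrays have shape (12, nrows, ncols); relative humidity is a fraction in
    [0, 1]; wind speed is the monthly mean at ``wind_height_m`` above ground.
    """

    precip_mm: np.ndarray
    temp_c: np.ndarray
    rel_humidity: np.ndarray
    wind_ms: np.ndarray
    days: np.ndarray = field(default_factory=lambda: MONTH_DAYS.copy())
    cell_size_km: float = 1.0
    nodata_mask: np.ndarray | None = None
    wind_height_m: float = 10.0

    def __post_init__(self) -> None:
        for name in ("precip_mm", "temp_c", "rel_humidity", "wind_ms"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 3 or arr.shape[0] != 12:
                raise DimensionError(f"{name} must have shape (12, nrows, ncols)")
            setattr(self, name, arr)
        self.days = np.asarray(self.days, dtype=int)
        if self.days.shape != (12,) or not np.all((self.days >= 28) & (self.days <= 31)):
            raise ValueError("days must be 12 integers in 28..31")
        if np.any(self.rel_humidity < 0) or np.any(self.rel_humidity > 1):
            raise ValueError("relative humidity must lie in [0, 1]")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.precip_mm.shape[1:], dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.precip_mm.shape[1:]


def slope_from_dem(dem: GridRaster) -> GridRaster:
    """Slope in radians from a DEM via Horn's 3×3 finite-difference operator.

    Edge cells use replicated borders. DEM values are metres; the horizontal
    spacing is the raster's cell size. Returns slope in [0, π/2).
    """
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise DimensionError("DEM must be at least 3x3 for slope estimation")
    z = np.pad(dem.values, 1, mode="edge")
    dx = dem.cell_size_km * 1000.0  # m
    # Horn 1981 weights: third-order finite differences over the 3x3 window
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * dx)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * dx)
    slope = np.arctan(np.hypot(dzdx, dzdy))
    return dem.like(slope)


def area_stats(landuse: LandUseMap) -> pd.Series:
    """Per-class area in km², indexed by class code 1..6.

    The six areas always sum to the total unmasked area.
    """
    valid = landuse.unmasked()
    counts = np.bincount(valid, minlength=N_CLASSES + 1)[1:]
    return pd.Series(
        counts * landuse.cell_area_km2,
        index=pd.Index(CLASS_CODES, name="class"),
        name="area_km2",
    )
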