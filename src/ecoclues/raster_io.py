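"""File formats: ESRI ASCII grids, CSV tables, YAML model/config files.

Rasters travel as ESRI ASCII grids (plain text, ``cellsize`` in km here);
nodata is honoured via ``NODATA_value``. Land-use rasters are validated
against the class codes 1–6 on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import MONTH_DAYS, ClimateStack, GridRaster, LandUseMap
from .suitability import LogisticModel
from .synthio import SpeciesOccurrences

NODATA = -9999.0


class RasterFormatError(ValueError):
    """Unreadable or malformed raster file."""


def write_ascii_grid(raster: GridRaster | LandUseMap, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (cellsize in km)."""
    values = raster.values if isinstance(raster, GridRaster) else raster.codes.astype(float)
    out = np.where(raster.nodata_mask, NODATA, values)
    nrows, ncols = out.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner 0.0\n"
        f"yllcorner 0.0\n"
        f"cellsize {raster.cell_size_km}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path, expected_kind: str = "grid") -> GridRaster | LandUseMap:
    """Read an ESRI ASCII grid.

    ``expected_kind`` is "grid" for continuous rasters or "landuse" for
    categorical maps (validated against codes 1–6; unknown codes raise a
    ValueError naming the offending values).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise RasterFormatError(f"{path}: no data rows")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        try:
            ncols = int(header["ncols"])
            nrows = int(header["nrows"])
            cellsize = float(header["cellsize"])
        except KeyError as e:
            raise RasterFormatError(f"{path}: missing header field {e}") from e
        data = np.loadtxt(fh)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape != (nrows, ncols):
        raise RasterFormatError(
            f"{path}: data shape {data.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value")
    mask = np.isclose(data, nodata) if nodata is not None else np.zeros_like(data, bool)
    if expected_kind == "landuse":
        codes = np.where(mask, 1, data).astype(int)
        return LandUseMap(codes, cellsize, mask)
    return GridRaster(np.where(mask, np.nan, data), cellsize, mask)


def write_models(models: dict[int, LogisticModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({c: m.to_dict() for c, m in models.items()}, fh, sort_keys=True)


def read_models(path: str | Path) -> dict[int, LogisticModel]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {int(c): LogisticModel.from_dict(d) for c, d in raw.items()}


def write_climate(climate: ClimateStack, path: str | Path) -> None:
    """Monthly climate as CSV (spatial means per month)."""
    df = pd.DataFrame(
        {
            "month": np.arange(1, 13),
            "precip_mm": climate.precip_mm.mean(axis=(1, 2)),
            "temp_c": climate.temp_c.mean(axis=(1, 2)),
            "rel_humidity": climate.rel_humidity.mean(axis=(1, 2)),
            "wind_ms": climate.wind_ms.mean(axis=(1, 2)),
            "days": climate.days,
        }
    )
    df.to_csv(path, index=False)


def read_climate(
    path: str | Path, grid_shape: tuple[int, int], cell_size_km: float = 1.0,
    wind_height_m: float = 10.0,
) -> ClimateStack:
    """Read monthly climate CSV, broadcasting each month over the grid."""
    df = pd.read_csv(path)
    need = {"precip_mm", "temp_c", "rel_humidity", "wind_ms"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    if len(df) != 12:
        raise ValueError("climate CSV must have exactly 12 monthly rows")
    tile = lambda col: np.broadcast_to(  # noqa: E731
        df[col].to_numpy(dtype=float)[:, None, None], (12,) + grid_shape
    ).copy()
    days = df["days"].to_numpy(dtype=int) if "days" in df else MONTH_DAYS.copy()
    return ClimateStack(
        precip_mm=tile("precip_mm"),
        temp_c=tile("temp_c"),
        rel_humidity=tile("rel_humidity"),
        wind_ms=tile("wind_ms"),
        days=days,
        cell_size_km=cell_size_km,
        wind_height_m=wind_height_m,
    )


def write_occurrences(occ: SpeciesOccurrences, path: str | Path) -> None:
    pd.DataFrame(occ.points, columns=["row", "col", "species_id"]).to_csv(path, index=False)
    wpath = Path(path).with_name(Path(path).stem + "_weights.csv")
    pd.DataFrame(
        sorted(occ.protection_weight.items()), columns=["species_id", "protection_weight"]
    ).to_csv(wpath, index=False)


def read_occurrences(path: str | Path) -> SpeciesOccurrences:
    df = pd.read_csv(path)
    wpath = Path(path).with_name(Path(path).stem + "_weights.csv")
    if wpath.exists():
        wdf = pd.read_csv(wpath)
        weights = dict(zip(wdf["species_id"].astype(int), wdf["protection_weight"].astype(float)))
    else:
        weights = {int(s): 1.0 for s in df["species_id"].unique()}
    points = [(int(r), int(c), int(s)) for r, c, s in df.itertuples(index=False)]
    return SpeciesOccurrences(points, weights)
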