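"""Transfer matrices between land-use maps and map-agreement statistics.

The transfer (change) matrix tabulates class-to-class area flows (km²)
between two dates; Cohen's kappa measures chance-corrected cell-wise
agreement between two categorical maps, the standard validation statistic
for simulated versus observed land use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import CLASS_CODES, CLASS_NAMES, N_CLASSES, DimensionError, LandUseMap

log = logging.getLogger(__name__)


@dataclass
class TransferMatrix:
    """K×K area matrix (km²): rows = class at t0, columns = class at t1.

    Row sums equal per-class areas at t0, column sums per-class areas at t1,
    and the grand total equals the total unmasked area — exactly, since
    entries are integer cell counts times the cell area.
    """

    entries: np.ndarray
    class_codes: tuple[int, ...] = field(default=CLASS_CODES)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        k = len(self.class_codes)
        if self.entries.shape != (k, k):
            raise DimensionError("entries must be K x K")
        if np.any(self.entries < 0):
            raise ValueError("transfer areas must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.entries.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.entries.sum())

    def to_frame(self, with_totals: bool = True) -> pd.DataFrame:
        names = [CLASS_NAMES.get(c, str(c)) for c in self.class_codes]
        df = pd.DataFrame(self.entries, index=names, columns=names)
        if with_totals:
            df["total_t0"] = self.row_totals
            df.loc["total_t1"] = list(self.col_totals) + [self.grand_total]
        return df


def transfer_matrix(map_t0: LandUseMap, map_t1: LandUseMap) -> TransferMatrix:
    """Class-to-class area flows between two aligned land-use maps."""
    if not map_t0.aligned_with(map_t1):
        raise DimensionError("maps must share shape, cell size and mask")
    a = map_t0.unmasked()
    b = map_t1.unmasked()
    counts = np.bincount(
        (a - 1) * N_CLASSES + (b - 1), minlength=N_CLASSES * N_CLASSES
    ).reshape(N_CLASSES, N_CLASSES)
    return TransferMatrix(counts * map_t0.cell_area_km2)


def kappa(map_a: LandUseMap, map_b: LandUseMap) -> float:
    """Cohen's kappa over unmasked cells, all six classes jointly.

    kappa = (p_o − p_e) / (1 − p_e) with p_e from the marginal class
    frequencies. If both maps are identical single-class maps (p_e = 1) the
    agreement is trivially perfect and 1.0 is returned by convention.
    """
    if not map_a.aligned_with(map_b):
        raise DimensionError("maps must share shape, cell size and mask")
    a = map_a.unmasked()
    b = map_b.unmasked()
    n = a.size
    if n == 0:
        raise ValueError("no unmasked cells")
    p_o = np.mean(a == b)
    fa = np.bincount(a, minlength=N_CLASSES + 1)[1:] / n
    fb = np.bincount(b, minlength=N_CLASSES + 1)[1:] / n
    p_e = float(fa @ fb)
    if p_e >= 1.0 - 1e-15:
        log.warning("degenerate kappa: both maps single-class; returning 1.0")
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))
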