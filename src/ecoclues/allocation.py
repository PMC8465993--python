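"""Spatial CLUE-S allocation: iterative competition of classes for cells.

Every cell is assigned the admissible class maximizing its total probability
TPROP = suitability + incumbency elasticity + ITER, where ITER is a per-class
balancing term adjusted each iteration until the allocated areas match the
demanded areas within tolerance. Elasticity in [0, 1] encodes conversion
resistance: a class with elasticity 1 is never converted away; conversion
rules and a restricted mask additionally constrain admissible transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import CLASS_CODES, N_CLASSES, DimensionError, GridRaster, LandUseMap
from .suitability import LogisticModel, probability_surface

log = logging.getLogger(__name__)


class AllocationError(RuntimeError):
    """Allocation failed to converge; carries the last per-class residuals."""

    def __init__(self, message: str, residuals: dict[int, float] | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


class InfeasibleDemandError(ValueError):
    """Demand cannot be met under the conversion rules / elasticities."""


@dataclass
class AllocationParams:
    """Tuning of the allocation loop.

    Default elasticities express typical conversion resistance (wetland water
    bodies strictly protected, artificial surfaces persistent, cultivated
    land mobile); they are configurable, not calibrated constants.
    """

    elasticity: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.6, 3: 1.0, 4: 0.4, 5: 0.9, 6: 0.3}
    )
    conversion_allowed: np.ndarray | None = None  # K x K booleans
    restricted_mask: np.ndarray | None = None
    tolerance_frac: float = 0.001
    max_iterations: int = 1000
    step_size: float = 0.05

    def __post_init__(self) -> None:
        if self.conversion_allowed is None:
            self.conversion_allowed = np.ones((N_CLASSES, N_CLASSES), dtype=bool)
        else:
            self.conversion_allowed = np.asarray(self.conversion_allowed, dtype=bool)
            if self.conversion_allowed.shape != (N_CLASSES, N_CLASSES):
                raise ValueError("conversion_allowed must be K x K")
            if not np.all(np.diag(self.conversion_allowed)):
                raise ValueError("diagonal of conversion_allowed must be True")
        for c, e in self.elasticity.items():
            if not 0 <= e <= 1:
                raise ValueError(f"elasticity for class {c} outside [0, 1]")


def allocate_year(
    current: LandUseMap,
    probs: dict[int, GridRaster],
    demand: dict[int, float],
    params: AllocationParams,
) -> tuple[LandUseMap, list[dict[int, float]]]:
    """One year of competitive allocation.

    Returns the converged map and the per-iteration residual log
    (demand − allocated, km², per class). Ties in TPROP break toward the
    lowest class code (deterministic).
    """
    valid = ~current.nodata_mask
    cur = current.codes[valid]  # (n,)
    n = cur.size
    cell_area = current.cell_area_km2
    total_area = n * cell_area

    missing = [c for c in CLASS_CODES if c not in probs]
    if missing:
        raise ValueError(f"probability surfaces missing for classes {missing}")
    demand_vec = np.array([demand[c] for c in CLASS_CODES], dtype=float)
    if abs(demand_vec.sum() - total_area) > max(1e-6 * total_area, 1e-9):
        raise ValueError(
            f"demand total {demand_vec.sum():.6g} km2 does not match study area "
            f"{total_area:.6g} km2"
        )

    P = np.stack([probs[c].values[valid] for c in CLASS_CODES])  # (K, n)
    elas = np.array([params.elasticity.get(c, 0.0) for c in CLASS_CODES])
    cur_idx = cur - 1

    # admissibility: conversion rule from current class, incumbents always
    # admissible; cells whose class has elasticity 1, and restricted cells,
    # may only keep their class
    admissible = params.conversion_allowed[cur_idx].T.copy()  # (K, n)
    locked = elas[cur_idx] >= 1.0
    if params.restricted_mask is not None:
        restricted = np.asarray(params.restricted_mask, dtype=bool)
        if restricted.shape != current.shape:
            raise DimensionError("restricted_mask shape mismatch")
        locked = locked | restricted[valid]
    incumbent = np.zeros_like(admissible)
    incumbent[cur_idx, np.arange(n)] = True
    admissible[:, locked] = incumbent[:, locked]
    admissible |= incumbent  # staying put is always possible

    # feasibility bounds: demand must fit between locked incumbency and the
    # number of cells that could ever carry the class
    locked_counts = np.bincount(cur_idx[locked], minlength=N_CLASSES) * cell_area
    capacity = admissible.sum(axis=1) * cell_area
    tol_area = params.tolerance_frac * total_area
    for k, c in enumerate(CLASS_CODES):
        if demand_vec[k] > capacity[k] + tol_area or demand_vec[k] < locked_counts[k] - tol_area:
            raise InfeasibleDemandError(
                f"demand for class {c} ({demand_vec[k]:.6g} km2) outside feasible "
                f"range [{locked_counts[k]:.6g}, {capacity[k]:.6g}] km2"
            )

    bonus = np.where(incumbent, elas[cur_idx][None, :] * incumbent, 0.0)
    iter_term = np.zeros(N_CLASSES)
    # adaptive per-class gain: the base step grows geometrically while a
    # class's residual keeps its sign and halves on overshoot, so the loop
    # converges regardless of how small the demanded change is
    gain = np.full(N_CLASSES, params.step_size)
    prev_sign = np.zeros(N_CLASSES)
    history: list[dict[int, float]] = []
    assigned = cur
    for _ in range(params.max_iterations):
        tprop = P + bonus + iter_term[:, None]
        tprop = np.where(admissible, tprop, -np.inf)
        assigned_idx = np.argmax(tprop, axis=0)  # first max -> lowest class code
        allocated = np.bincount(assigned_idx, minlength=N_CLASSES) * cell_area
        residual = demand_vec - allocated
        history.append({c: float(r) for c, r in zip(CLASS_CODES, residual)})
        if np.all(np.abs(residual) <= tol_area):
            assigned = assigned_idx + 1
            break
        sign = np.sign(residual)
        flipped = (sign != 0) & (prev_sign != 0) & (sign != prev_sign)
        gain[flipped] *= 0.5
        gain[~flipped & (sign != 0)] *= 1.3
        gain = np.clip(gain, 1e-6, 10.0)
        prev_sign = np.where(sign != 0, sign, prev_sign)
        iter_term += gain * residual / total_area
    else:
        raise AllocationError(
            f"allocation did not converge in {params.max_iterations} iterations",
            residuals=history[-1],
        )

    out = current.codes.copy()
    out[valid] = assigned
    return LandUseMap(out, current.cell_size_km, current.nodata_mask.copy()), history


def simulate(
    start: LandUseMap,
    drivers,
    models: dict[int, LogisticModel],
    demand_series,
    params: AllocationParams,
) -> dict[int, LandUseMap]:
    """Chain yearly allocations from the start map through the horizon.

    Drivers are static, so probability surfaces are computed once. Returns
    {year: map} including the start year.
    """
    probs = {c: probability_surface(m, drivers) for c, m in models.items()}
    years = demand_series.years
    current = start.copy()
    out = {years[0]: current}
    for year in years[1:]:
        current, _ = allocate_year(current, probs, demand_series.for_year(year), params)
        out[year] = current
    return out
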