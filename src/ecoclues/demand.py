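"""Non-spatial demand module: Markov projection of per-class area targets.

Transition probabilities are estimated by row-normalizing an observed
transfer matrix; demand at the horizon year is the initial area vector
propagated through the step-transition matrix, with optional per-class
scenario modifiers (protecting a class scales down its outflows; accelerating
a class scales up its inflows). Yearly demand between steps is linearly
interpolated for the spatial allocator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import CLASS_CODES
from .landuse_accounting import TransferMatrix

log = logging.getLogger(__name__)


class DemandValidationError(ValueError):
    """Scenario modifiers or inputs produce an invalid transition matrix."""


@dataclass
class TransitionProbabilities:
    """Row-stochastic K×K matrix of class transition probabilities per step."""

    matrix: np.ndarray
    class_codes: tuple[int, ...] = field(default=CLASS_CODES)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.class_codes)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix must be K x K")
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1 + 1e-12):
            raise DemandValidationError("transition probabilities must lie in [0, 1]")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise DemandValidationError("every row must sum to 1")


@dataclass
class DemandSeries:
    """Per-year target area (km²) per class; total area conserved each year."""

    years: list[int]
    areas: np.ndarray  # (n_years, K)
    class_codes: tuple[int, ...] = field(default=CLASS_CODES)

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.years), len(self.class_codes)):
            raise ValueError("areas must be (n_years, K)")
        if np.any(self.areas < -1e-9):
            raise ValueError("areas must be non-negative")
        totals = self.areas.sum(axis=1)
        if totals.size and not np.allclose(totals, totals[0], rtol=1e-6):
            raise ValueError("yearly totals must be constant (area conservation)")

    def for_year(self, year: int) -> dict[int, float]:
        i = self.years.index(year)
        return {c: float(a) for c, a in zip(self.class_codes, self.areas[i])}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": y, "class": c, "area_km2": self.areas[i, j]}
            for i, y in enumerate(self.years)
            for j, c in enumerate(self.class_codes)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DemandSeries":
        pivot = df.pivot(index="year", columns="class", values="area_km2").sort_index()
        pivot = pivot[list(CLASS_CODES)]
        return cls(list(pivot.index), pivot.to_numpy())


def estimate_transition_probs(tm: TransferMatrix) -> TransitionProbabilities:
    """Row-normalize a transfer matrix into step transition probabilities.

    A class absent at t0 (zero row) gets an identity row — it cannot be
    observed transitioning, so it is held fixed — with a warning.
    """
    m = tm.entries.copy()
    sums = m.sum(axis=1)
    for i, s in enumerate(sums):
        if s <= 0:
            log.warning("class %s absent at t0; using identity transition row", tm.class_codes[i])
            m[i] = 0.0
            m[i, i] = 1.0
            sums[i] = 1.0
    return TransitionProbabilities(m / sums[:, None], tm.class_codes)


def apply_modifiers(
    probs: TransitionProbabilities,
    outflow: dict[int, float] | None = None,
    inflow: dict[int, float] | None = None,
) -> TransitionProbabilities:
    """Scenario-adjust a transition matrix.

    ``outflow[c]`` multiplies the off-diagonal entries of row c (0 freezes a
    protected class whose change rate is held at practically zero).
    ``inflow[c]`` multiplies the off-diagonal entries of column c
    (values > 1 accelerate growth of class c). Rows are renormalized after
    scaling. Negative multipliers are rejected.
    """
    m = probs.matrix.copy()
    k = m.shape[0]
    off = ~np.eye(k, dtype=bool)
    codes = list(probs.class_codes)
    for src, mods in (("outflow", outflow or {}), ("inflow", inflow or {})):
        for c, f in mods.items():
            if f < 0:
                raise DemandValidationError(f"{src} modifier for class {c} is negative")
            i = codes.index(c)
            if src == "outflow":
                m[i, off[i]] *= f
            else:
                m[off[:, i], i] *= f
    sums = m.sum(axis=1)
    if np.any(sums <= 0):
        raise DemandValidationError("modifiers removed all probability mass from a row")
    return TransitionProbabilities(m / sums[:, None], probs.class_codes)


def project_demand(
    probs: TransitionProbabilities,
    initial_areas: dict[int, float],
    start_year: int,
    horizon_year: int,
    step_years: int = 5,
    outflow_modifiers: dict[int, float] | None = None,
    inflow_modifiers: dict[int, float] | None = None,
) -> DemandSeries:
    """Propagate class areas through the Markov chain to the horizon year.

    ``probs`` is the transition matrix over one step of ``step_years`` (the
    observation spacing of the calibration maps). Scenario modifiers are
    applied once to the step matrix. Yearly demand between step nodes is
    linearly interpolated.
    """
    span = horizon_year - start_year
    if span <= 0 or span % step_years != 0:
        raise ValueError("step_years must evenly divide the projection span")
    p = apply_modifiers(probs, outflow_modifiers, inflow_modifiers)
    codes = list(p.class_codes)
    a = np.array([initial_areas[c] for c in codes], dtype=float)

    node_years = list(range(start_year, horizon_year + 1, step_years))
    node_areas = [a]
    for _ in node_years[1:]:
        a = a @ p.matrix
        node_areas.append(a)
    nodes = np.array(node_areas)

    years = list(range(start_year, horizon_year + 1))
    out = np.empty((len(years), len(codes)))
    for j in range(len(codes)):
        out[:, j] = np.interp(years, node_years, nodes[:, j])
    return DemandSeries(years, out, p.class_codes)
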