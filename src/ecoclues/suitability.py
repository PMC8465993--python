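"""Per-class logistic suitability models with stepwise driver selection.

Each land-use class gets a binary logistic regression (cell is / is not the
class) on standardized drivers, selected by forward-stepwise Wald tests
(entry p < 0.05, removal p > 0.10 — the common SPSS defaults). The fitted
probability surface feeds the spatial allocator; model admission follows the
usual ROC > 0.7 rule, with AUC computed by the Mann–Whitney rank formulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .grids import DriverStack, GridRaster, LandUseMap

log = logging.getLogger(__name__)

ENTRY_P = 0.05
REMOVAL_P = 0.10
RIDGE_ALPHA = 1e-6


class DegenerateClassError(ValueError):
    """Class share outside the fittable range (must be in [1%, 99%])."""


@dataclass
class LogisticModel:
    """Fitted binary logistic suitability model for one land-use class.

    Coefficients are on the standardized-driver scale;
    ``standardization`` stores the (mean, std) used per selected driver so
    the model can be applied to any aligned stack.
    """

    class_code: int
    intercept: float
    coefficients: dict[str, float]
    selected_drivers: list[str]
    roc: float
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.selected_drivers):
            raise ValueError("coefficients must cover exactly the selected drivers")

    def linear_predictor(self, drivers: DriverStack) -> np.ndarray:
        ref = drivers.reference
        eta = np.full(ref.shape, self.intercept, dtype=float)
        for name in self.selected_drivers:
            if name not in drivers:
                raise KeyError(f"driver {name!r} missing from stack")
            mu, sd = self.standardization[name]
            z = (drivers[name].values - mu) / (sd if sd > 0 else 1.0)
            eta += self.coefficients[name] * z
        return eta

    def to_dict(self) -> dict:
        return {
            "class_code": self.class_code,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "selected_drivers": list(self.selected_drivers),
            "roc": self.roc,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            class_code=int(d["class_code"]),
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            selected_drivers=list(d["selected_drivers"]),
            roc=float(d["roc"]),
            standardization={k: (float(v[0]), float(v[1])) for k, v in d["standardization"].items()},
        )


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = RIDGE_ALPHA):
    """Newton–Raphson logistic fit with a tiny ridge penalty.

    Fallback when maximum likelihood fails (perfect separation); the penalty
    keeps the Hessian invertible. Returns (params, p_values).
    """
    n, k = X.shape
    beta = np.zeros(k)
    pen = alpha * np.eye(k)
    pen[0, 0] = 0.0  # intercept unpenalized
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        grad = X.T @ (y - p) - pen @ beta
        hess = (X.T * w) @ X + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1 - p), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X + pen)
    se = np.sqrt(np.diag(cov))
    zval = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zval))
    # under separation the Wald statistic collapses (Hauck-Donner); a
    # quasi-infinite standardized coefficient is treated as significant
    pvals = np.where(np.abs(beta) > 15.0, 0.0, pvals)
    return beta, pvals


def _fit_wald(X: np.ndarray, y: np.ndarray):
    """ML logistic fit; returns (params, Wald p-values). Ridge fallback on failure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", False) or not np.all(
                np.isfinite(res.bse)
            ):
                raise np.linalg.LinAlgError("non-converged fit")
            return np.asarray(res.params), np.asarray(res.pvalues)
        except Exception:
            log.warning("ML logistic fit failed (likely separation); ridge fallback")
            return _ridge_logit(X, y)


def fit_logistic(
    landuse: LandUseMap, drivers: DriverStack, class_code: int
) -> LogisticModel:
    """Forward-stepwise binary logistic regression for one class.

    Drivers are standardized over unmasked cells before fitting. At each
    forward step the candidate with the smallest Wald p-value enters if
    p < 0.05; after every entry, any included driver with p > 0.10 is
    removed; iteration stops at a fixpoint. In-sample ROC is recorded on the
    fitted surface.
    """
    names = drivers.names
    y = (landuse.unmasked() == class_code).astype(float)
    share = y.mean()
    if not 0.01 <= share <= 0.99:
        raise DegenerateClassError(
            f"class {class_code} covers {share:.1%} of cells; need 1%-99%"
        )
    raw = drivers.matrix(names)
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (raw - mu) / sd_safe

    selected: list[int] = []
    remaining = [i for i in range(len(names)) if sd[i] > 0]
    prev_sets: set[frozenset[int]] = set()
    for _ in range(4 * len(names)):
        changed = False
        # forward entry
        best_p, best_i = np.inf, None
        for i in remaining:
            cols = selected + [i]
            X = np.column_stack([np.ones_like(y)] + [Z[:, c] for c in cols])
            _, pv = _fit_wald(X, y)
            if pv[-1] < best_p:
                best_p, best_i = pv[-1], i
        if best_i is not None and best_p < ENTRY_P:
            selected.append(best_i)
            remaining.remove(best_i)
            changed = True
        # backward removal
        while selected:
            X = np.column_stack([np.ones_like(y)] + [Z[:, c] for c in selected])
            _, pv = _fit_wald(X, y)
            worst = int(np.argmax(pv[1:]))
            if pv[1 + worst] > REMOVAL_P:
                remaining.append(selected.pop(worst))
                changed = True
            else:
                break
        key = frozenset(selected)
        if not changed or key in prev_sets:
            break
        prev_sets.add(key)

    X = np.column_stack([np.ones_like(y)] + [Z[:, c] for c in selected])
    params, _ = _fit_wald(X, y)
    sel_names = [names[i] for i in selected]
    eta = X @ params
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    auc = roc_auc_values(prob, y > 0.5)
    return LogisticModel(
        class_code=class_code,
        intercept=float(params[0]),
        coefficients={n: float(b) for n, b in zip(sel_names, params[1:])},
        selected_drivers=sel_names,
        roc=auc,
        standardization={names[i]: (float(mu[i]), float(sd_safe[i])) for i in selected},
    )


def fit_all_classes(
    landuse: LandUseMap, drivers: DriverStack, class_codes=(1, 2, 3, 4, 5, 6)
) -> dict[int, LogisticModel]:
    return {c: fit_logistic(landuse, drivers, c) for c in class_codes}


def probability_surface(model: LogisticModel, drivers: DriverStack) -> GridRaster:
    """Per-cell inverse-logit suitability in [0, 1]."""
    eta = model.linear_predictor(drivers)
    ref = drivers.reference
    return ref.like(1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700))))


def roc_auc_values(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: P(random positive outranks random negative), ties ½."""
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both label values must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(scores: GridRaster, labels: GridRaster) -> float:
    """AUC of a score raster against a binary label raster (unmasked cells)."""
    if not scores.aligned_with(labels):
        raise ValueError("score and label rasters must be aligned")
    return roc_auc_values(scores.unmasked(), labels.unmasked() > 0.5)
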