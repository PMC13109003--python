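"""Weighted point-treatment estimators for competing-events data.

Two inverse-probability weighted estimators of a treatment effect on the
event of interest, both driven by a fitted model for the competing-event
probability pi~(A, L) = Pr(D=1 | A, L):

* The IPCW estimator treats records with a competing event as censored and
  reweights the uncensored by 1 / (1 - pi~(A, L)); it converges to the
  statistical target of a controlled direct effect.
* The separable-effect estimator reweights by the survivor-probability
  ratio (1 - pi~(aD, L)) / (1 - pi~(A, L)); it converges to the
  statistical target of a separable direct effect with the
  competing-event-acting treatment component held at aD.

Both use the plain sample-average (Horvitz-Thompson) form — no weight
normalization, no truncation by default — so estimates match the
estimating equations exactly as written.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .dgp import PointDataset

__all__ = [
    "NuisanceSpec",
    "FittedNuisance",
    "EstimateResult",
    "InestimableCellError",
    "PositivityError",
    "fit_nuisance",
    "ipcw_cde_hat",
    "ipw_sde_hat",
    "weight_summary",
]

_LOGISTIC_TERMS = ("intercept", "a", "l", "a:l")


class InestimableCellError(ValueError):
    """A (a,l) cell needed for prediction contains no records."""


class PositivityError(ValueError):
    """A needed cell has estimated competing-event probability 1."""


@dataclass(frozen=True)
class NuisanceSpec:
    """Specification of the model for pi~(A, L).

    ``saturated`` fits one parameter per (a,l) cell — cell proportions of
    D=1, algebraically identical to a logistic fit with all four terms.
    ``logistic`` fits maximum-likelihood logistic regression of D on the
    stated linear-predictor terms (subset of intercept, a, l, a:l),
    enabling deliberate misspecification experiments.
    """

    kind: str = "saturated"
    terms: tuple[str, ...] = _LOGISTIC_TERMS

    def __post_init__(self):
        if self.kind not in ("saturated", "logistic"):
            raise ValueError(f"kind must be 'saturated' or 'logistic', got {self.kind!r}")
        object.__setattr__(self, "terms", tuple(self.terms))
        unknown = set(self.terms) - set(_LOGISTIC_TERMS)
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}; allowed: {_LOGISTIC_TERMS}")


@dataclass
class FittedNuisance:
    """Predicted pi~(a,l) on the four cells, with per-cell record counts.

    ``pi_hat`` entries are NaN for cells with no records under a saturated
    fit; using such a cell downstream raises InestimableCellError.
    """

    pi_hat: np.ndarray           # shape (2,2), indexed [a, l]
    counts: np.ndarray           # shape (2,2), records per cell
    coefficients: dict = field(default_factory=dict)
    spec: NuisanceSpec = field(default_factory=NuisanceSpec)

    def predict(self, a, l) -> np.ndarray:
        """pi~-hat for vectors of cell indices; NaN cells raise."""
        a = np.asarray(a, dtype=np.intp)
        l = np.asarray(l, dtype=np.intp)
        p = self.pi_hat[a, l]
        if np.isnan(np.atleast_1d(p)).any():
            bad = sorted(
                {(int(ai), int(li)) for ai, li, pi in
                 zip(np.atleast_1d(a), np.atleast_1d(l), np.atleast_1d(p))
                 if np.isnan(pi)}
            )
            raise InestimableCellError(
                f"no records in cell(s) {bad}: pi~(a,l) inestimable under a saturated fit"
            )
        return p


def _design(a: np.ndarray, l: np.ndarray, terms: tuple[str, ...]) -> np.ndarray:
    cols = {"intercept": np.ones_like(a, dtype=float), "a": a.astype(float),
            "l": l.astype(float), "a:l": (a * l).astype(float)}
    return np.column_stack([cols[t] for t in terms])


def fit_nuisance(data: PointDataset, spec: NuisanceSpec | None = None) -> FittedNuisance:
    """Fit the competing-event model pi~(A, L) to point-treatment data."""
    if spec is None:
        spec = NuisanceSpec()
    if len(data) == 0:
        raise ValueError("cannot fit a nuisance model on an empty dataset")
    a, l, d = data.a, data.l, data.d

    counts = np.zeros((2, 2), dtype=int)
    events = np.zeros((2, 2), dtype=int)
    np.add.at(counts, (a, l), 1)
    np.add.at(events, (a, l), d)

    if spec.kind == "saturated":
        with np.errstate(invalid="ignore"):
            pi_hat = np.where(counts > 0, events / np.maximum(counts, 1), np.nan)
        coefs = {}
    else:
        X = _design(a, l, spec.terms)
        model = sm.GLM(d.astype(float), X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=200)
        except Exception as exc:  # separation / singular design
            raise RuntimeError(f"nuisance logistic fit failed to converge: {exc}") from exc
        if not res.converged:
            raise RuntimeError("nuisance logistic fit did not converge")
        coefs = dict(zip(spec.terms, res.params))
        grid_a = np.array([0, 0, 1, 1])
        grid_l = np.array([0, 1, 0, 1])
        preds = res.predict(_design(grid_a, grid_l, spec.terms))
        pi_hat = np.full((2, 2), np.nan)
        pi_hat[grid_a, grid_l] = preds
    return FittedNuisance(pi_hat=pi_hat, counts=counts, coefficients=coefs, spec=spec)


@dataclass
class EstimateResult:
    """A single weighted point estimate with weight diagnostics."""

    estimator: str               # "IPCW-CDE" or "IPW-SDE"
    aD: int | None
    estimate: float
    arm_means: dict              # a -> weighted mean component
    arm_n: dict                  # a -> records in arm
    max_weight: float
    mean_weight: float

    def to_row(self) -> dict:
        return {
            "estimator": self.estimator,
            "aD": self.aD,
            "estimate": self.estimate,
            "arm0_mean": self.arm_means[0],
            "arm1_mean": self.arm_means[1],
            "arm0_n": self.arm_n[0],
            "arm1_n": self.arm_n[1],
            "max_weight": self.max_weight,
            "mean_weight": self.mean_weight,
        }


def _check_positivity(data: PointDataset, fit: FittedNuisance) -> None:
    """Every populated (a,l) cell must have estimated survivor prob > 0."""
    populated = np.argwhere(fit.counts > 0)
    for a, l in populated:
        p = fit.pi_hat[a, l]
        if not np.isnan(p) and p >= 1.0:
            raise PositivityError(
                f"estimated pi~({a},{l}) = 1: all records in cell (a={a}, l={l}) "
                "experienced the competing event; IP weights are infinite"
            )


def _arm_masks(data: PointDataset):
    masks = {a: data.a == a for a in (0, 1)}
    for a, m in masks.items():
        if not m.any():
            raise ValueError(f"no records in treatment arm A={a}")
    return masks


def ipcw_cde_hat(data: PointDataset, fit: FittedNuisance) -> EstimateResult:
    """Inverse-probability-of-censoring-weighted contrast (competing events censored).

    Arm component: average over A=a records of Y * I(D=0) / (1 - pi~(a, L));
    estimate = arm-1 component minus arm-0 component.
    """
    _check_positivity(data, fit)
    masks = _arm_masks(data)
    surv = 1.0 - fit.predict(data.a, data.l)
    uncens = data.d == 0
    contrib = np.where(uncens, data.y / np.where(surv > 0, surv, np.nan), 0.0)
    arm_means = {a: float(contrib[m].mean()) for a, m in masks.items()}
    w = 1.0 / surv[uncens]
    return EstimateResult(
        estimator="IPCW-CDE",
        aD=None,
        estimate=arm_means[1] - arm_means[0],
        arm_means=arm_means,
        arm_n={a: int(m.sum()) for a, m in masks.items()},
        max_weight=float(w.max()) if w.size else float("nan"),
        mean_weight=float(w.mean()) if w.size else float("nan"),
    )


def ipw_sde_hat(data: PointDataset, fit: FittedNuisance, aD: int) -> EstimateResult:
    """Separable-effect weighted contrast with the D-acting component at aD.

    Arm component: average over A=a records of
    Y * (1 - pi~(aD, L)) / (1 - pi~(a, L)).  Records with D=1 necessarily
    have Y=0 so no explicit censoring indicator is needed.
    """
    if aD not in (0, 1):
        raise ValueError(f"aD must be 0 or 1, got {aD!r}")
    if np.any((data.d == 1) & (data.y == 1)):
        raise ValueError("dataset violates competing-event determinism (D=1 with Y=1)")
    _check_positivity(data, fit)
    masks = _arm_masks(data)
    surv_own = 1.0 - fit.predict(data.a, data.l)
    surv_aD = 1.0 - fit.predict(np.full(len(data), aD), data.l)
    w = surv_aD / surv_own
    contrib = data.y * w
    arm_means = {a: float(contrib[m].mean()) for a, m in masks.items()}
    return EstimateResult(
        estimator="IPW-SDE",
        aD=aD,
        estimate=arm_means[1] - arm_means[0],
        arm_means=arm_means,
        arm_n={a: int(m.sum()) for a, m in masks.items()},
        max_weight=float(w.max()),
        mean_weight=float(w.mean()),
    )


def weight_summary(
    data: PointDataset,
    fit: FittedNuisance,
    estimator: str,
    aD: int | None = None,
) -> dict:
    """Max / mean / 99th-percentile weight over contributing records.

    For the IPCW estimator the contributing records are the uncensored
    (D=0) ones with weight 1/(1 - pi~(A,L)); for the separable-effect
    estimator every record carries the ratio weight
    (1 - pi~(aD,L)) / (1 - pi~(A,L)).
    """
    _check_positivity(data, fit)
    surv_own = 1.0 - fit.predict(data.a, data.l)
    if estimator == "IPCW-CDE":
        w = 1.0 / surv_own[data.d == 0]
    elif estimator == "IPW-SDE":
        if aD not in (0, 1):
            raise ValueError("aD required for the separable-effect estimator")
        surv_aD = 1.0 - fit.predict(np.full(len(data), aD), data.l)
        w = surv_aD / surv_own
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if w.size == 0:
        return {"max": float("nan"), "mean": float("nan"), "p99": float("nan")}
    return {
        "max": float(w.max()),
        "mean": float(w.mean()),
        "p99": float(np.quantile(w, 0.99)),
    }
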