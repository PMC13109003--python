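"""Three-way error decomposition against the actual causal target.

Premise: the quantity the analysis is truly after is a separable direct
effect SDE0^{aD}.  The bias of an estimator with Monte Carlo mean m then
splits exactly into three parts:

    m - SDE0^{aD} = (ostensible - actual)        estimand error
                  + (statistical - ostensible)   non-identification error
                  + (m - statistical)            statistical error

For the IPCW estimator the ostensible target is CDE0 and the statistical
target is CDE_obs; for the separable-effect estimator the ostensible
target IS the actual target (estimand error is identically zero) and the
statistical target is SDE_obs^{aD}.  MSE = total bias^2 + variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dgp import DGPParams
from .estimands import TargetValues, UndefinedFunctional, all_targets, sign_discordant

__all__ = ["ErrorDecomposition", "decompose", "grid_scan"]


@dataclass
class ErrorDecomposition:
    estimator: str                 # "IPCW-CDE" or "IPW-SDE"
    aD: int                        # indexes the actual target SDE0^{aD}
    actual_target: float
    ostensible_target: float
    statistical_target: float
    estimator_mean: float
    estimand_error: float
    nonidentification_error: float
    statistical_error: float
    total_bias: float
    variance: float
    mse: float
    mc_se_mean: float | None = None       # MC standard error of estimator_mean
    mc_se_variance: float | None = None   # MC standard error of variance

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in (
            "estimator", "aD", "actual_target", "ostensible_target",
            "statistical_target", "estimator_mean", "estimand_error",
            "nonidentification_error", "statistical_error", "total_bias",
            "variance", "mse", "mc_se_mean", "mc_se_variance",
        )}


def decompose(
    estimator_mean: float,
    estimator_variance: float,
    targets: TargetValues,
    estimator: str,
    aD: int,
    reps: int | None = None,
) -> ErrorDecomposition:
    """Assemble the exact bias decomposition and MSE for one estimator.

    ``reps`` (Monte Carlo replicate count) is optional; when given, MC
    standard errors for the mean and variance are attached.
    """
    if aD not in (0, 1):
        raise ValueError(f"aD must be 0 or 1, got {aD!r}")
    actual = targets.sde0(aD)
    if estimator == "IPCW-CDE":
        ostensible = targets.cde0
        statistical = targets.cdeobs
    elif estimator == "IPW-SDE":
        ostensible = targets.sde0(aD)
        statistical = targets.sdeobs(aD)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if statistical is None or isinstance(statistical, UndefinedFunctional):
        reason = statistical.reason if isinstance(statistical, UndefinedFunctional) else "missing"
        raise ValueError(
            f"statistical target for {estimator} is undefined ({reason}); "
            "the decomposition requires the positivity condition for this estimator"
        )
    estimand_error = ostensible - actual
    nonid_error = statistical - ostensible
    stat_error = estimator_mean - statistical
    total_bias = estimator_mean - actual
    mse = total_bias**2 + estimator_variance
    mc_se_mean = mc_se_var = None
    if reps is not None and reps > 1:
        mc_se_mean = math.sqrt(estimator_variance / reps)
        # sampling SD of a sample variance under approximate normality
        mc_se_var = estimator_variance * math.sqrt(2.0 / (reps - 1))
    return ErrorDecomposition(
        estimator=estimator,
        aD=aD,
        actual_target=actual,
        ostensible_target=ostensible,
        statistical_target=statistical,
        estimator_mean=estimator_mean,
        estimand_error=estimand_error,
        nonidentification_error=nonid_error,
        statistical_error=stat_error,
        total_bias=total_bias,
        variance=estimator_variance,
        mse=mse,
        mc_se_mean=mc_se_mean,
        mc_se_variance=mc_se_var,
    )


def grid_scan(param_grid, aD: int = 0) -> pd.DataFrame:
    """Analytic targets and error components over a list of parameter sets.

    One row per DGPParams with the true contrasts, both statistical
    targets, both non-identification errors, the estimand error of a
    censoring analysis, and the sign-discordance flag.  Rows where a
    statistical target is undefined by positivity carry None there (never
    dropped).  Everything is exact enumeration — no simulation.
    """
    param_grid = list(param_grid)
    if not param_grid:
        raise ValueError("param_grid must be nonempty")
    rows = []
    for i, params in enumerate(param_grid):
        tv = all_targets(params)
        sde0 = tv.sde0(aD)
        cdeobs = tv.cdeobs
        sdeobs = tv.sdeobs(aD)
        cde_def = not isinstance(cdeobs, UndefinedFunctional)
        sde_def = not isinstance(sdeobs, UndefinedFunctional)
        rows.append({
            "index": i,
            "aD": aD,
            "cde0": tv.cde0,
            "sde0": sde0,
            "cdeobs": cdeobs if cde_def else None,
            "sdeobs": sdeobs if sde_def else None,
            "estimand_error": tv.cde0 - sde0,
            "nonid_error_cde": (cdeobs - tv.cde0) if cde_def else None,
            "nonid_error_sde": (sdeobs - sde0) if sde_def else None,
            "sign_discordant": sign_discordant(tv, aD),
            "theta": list(params.theta),
            "beta": list(params.beta),
        })
    return pd.DataFrame(rows)


def factorial_subsample(
    coef_values=(-1.0, -0.5, 0.5, 1.0),
    theta0: float = -1.0,
    beta0: float = -1.0,
    pL: float = 0.5,
    pU: float = 0.5,
    n_points: int = 1000,
    seed: int = 0,
) -> list[DGPParams]:
    """Seeded random subsample of the factorial over theta1..6, beta1..6.

    The full factorial over six theta and six beta slots each taking four
    values has 4^12 points — combinatorially infeasible to scan whole, so
    a reproducible random subset is drawn.  Intercepts are held fixed
    (beta0 controls competing-event rarity).
    """
    rng = np.random.default_rng(seed)
    vals = np.asarray(coef_values, dtype=float)
    draws = vals[rng.integers(0, len(vals), size=(n_points, 12))]
    grid = []
    for row in draws:
        grid.append(DGPParams(
            pL=pL, pU=pU,
            theta=(theta0, *row[:6]),
            beta=(beta0, *row[6:]),
        ))
    return grid
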