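"""Point-treatment data-generating process for competing-events analyses.

The observed data are i.i.d. records (U, L, A, D, Y): a binary unmeasured
common cause U, a binary measured baseline covariate L, randomized binary
treatment A, a competing-event indicator D, and the event-of-interest
indicator Y.  The competing event is deterministic for the event of
interest: a record with D=1 has Y=0 by construction (the competing event
precludes the event of interest within the follow-up window).

Two logistic models parameterize the joint law:

    mu0(a,l,u; theta) = Pr(Y=1 | A=a, L=l, U=u, D=0)
                      = expit(th0 + th1*a + th2*l + th3*a*l
                              + th4*u + th5*a*u + th6*l*u)
    pi0(a,l,u; beta)  = Pr(D=1 | A=a, L=l, U=u)
                      = expit(b0 + b1*a + b2*l + b3*a*l
                              + b4*u + b5*a*u + b6*l*u)

U, L and A are mutually independent Bernoulli draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "DGPParams",
    "Scenario",
    "PointDataset",
    "mu0",
    "pi0",
    "generate_point_data",
    "scenario_presets",
]

_N_COEF = 7


@dataclass(frozen=True)
class DGPParams:
    """Full parameterization of the point-treatment data-generating law.

    Parameters
    ----------
    pL, pU, pA
        Marginal Bernoulli probabilities of L=1, U=1 and A=1.  A is the
        randomization probability and defaults to 0.5 (a 1:1 trial).
    theta
        The 7 coefficients (th0..th6) of the event-of-interest model.
    beta
        The 7 coefficients (b0..b6) of the competing-event model.
    """

    pL: float
    pU: float
    theta: tuple[float, ...]
    beta: tuple[float, ...]
    pA: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", tuple(float(t) for t in self.theta))
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        for name in ("pL", "pU", "pA"):
            p = getattr(self, name)
            if not (np.isfinite(p) and 0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {p!r}")
        for name in ("theta", "beta"):
            v = getattr(self, name)
            if len(v) != _N_COEF:
                raise ValueError(f"{name} must have exactly {_N_COEF} coefficients, got {len(v)}")
            if not all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values: {v}")

    def replace(self, **kw) -> "DGPParams":
        return dataclasses.replace(self, **kw)


def _check_binary(*vals: int) -> None:
    for v in vals:
        if v not in (0, 1):
            raise ValueError(f"inputs must be binary 0/1, got {v!r}")


def _linpred(coef, a, l, u):
    c0, c1, c2, c3, c4, c5, c6 = coef
    return c0 + c1 * a + c2 * l + c3 * a * l + c4 * u + c5 * a * u + c6 * l * u


def mu0(a: int, l: int, u: int, params: DGPParams) -> float:
    """Conditional event-of-interest probability Pr(Y=1 | A=a, L=l, U=u, D=0)."""
    _check_binary(a, l, u)
    return float(expit(_linpred(params.theta, a, l, u)))


def pi0(a: int, l: int, u: int, params: DGPParams) -> float:
    """Conditional competing-event probability Pr(D=1 | A=a, L=l, U=u)."""
    _check_binary(a, l, u)
    return float(expit(_linpred(params.beta, a, l, u)))


@dataclass
class PointDataset:
    """i.i.d. point-treatment records.

    All fields are 0/1 integer arrays of common length.  ``u`` is carried
    for diagnostics but must never be used by estimators (it plays the role
    of an unmeasured variable).  The competing-event determinism Y=0
    whenever D=1 is enforced at construction.
    """

    u: np.ndarray
    l: np.ndarray
    a: np.ndarray
    d: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        arrs = [np.asarray(getattr(self, f), dtype=np.int8) for f in "ulady"]
        n = len(arrs[0])
        for f, arr in zip("ulady", arrs):
            if len(arr) != n:
                raise ValueError("all record columns must have equal length")
            if arr.size and not np.isin(arr, (0, 1)).all():
                raise ValueError(f"column {f!r} must be binary 0/1")
            setattr(self, f, arr)
        if np.any((self.d == 1) & (self.y == 1)):
            raise ValueError("competing-event determinism violated: D=1 record with Y=1")

    def __len__(self) -> int:
        return len(self.a)

    def to_frame(self, include_u: bool = True) -> pd.DataFrame:
        cols = {"u": self.u, "l": self.l, "a": self.a, "d": self.d, "y": self.y}
        if not include_u:
            cols.pop("u")
        return pd.DataFrame(cols)

    def to_csv(self, path, include_u: bool = True) -> None:
        self.to_frame(include_u=include_u).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PointDataset":
        cols = {c.lower(): c for c in df.columns}
        for required in ("l", "a", "d", "y"):
            if required not in cols:
                raise ValueError(f"missing required column {required!r}")
        n = len(df)
        u = df[cols["u"]].to_numpy() if "u" in cols else np.zeros(n, dtype=np.int8)
        return cls(
            u=u,
            l=df[cols["l"]].to_numpy(),
            a=df[cols["a"]].to_numpy(),
            d=df[cols["d"]].to_numpy(),
            y=df[cols["y"]].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path) -> "PointDataset":
        return cls.from_frame(pd.read_csv(path))


def generate_point_data(params: DGPParams, n: int, seed: int) -> PointDataset:
    """Sample ``n`` i.i.d. records from the point-treatment law.

    U, L, A are independent Bernoulli draws; D ~ Bernoulli(pi0(A,L,U));
    Y ~ Bernoulli(mu0(A,L,U)) when D=0 and Y=0 when D=1.  The draw is a
    pure function of (params, n, seed).
    """
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    rng = np.random.default_rng(seed)
    u = rng.random(n) < params.pU
    l = rng.random(n) < params.pL
    a = rng.random(n) < params.pA
    p_d = expit(_linpred(params.beta, a, l, u))
    d = rng.random(n) < p_d
    p_y = expit(_linpred(params.theta, a, l, u))
    y = (rng.random(n) < p_y) & ~d
    return PointDataset(
        u=u.astype(np.int8),
        l=l.astype(np.int8),
        a=a.astype(np.int8),
        d=d.astype(np.int8),
        y=y.astype(np.int8),
    )


@dataclass(frozen=True)
class Scenario:
    """A named data-generating scenario with its qualitative flags.

    Flags mirror the three factorial axes of the variance study: whether a
    near positivity violation is present, whether Y and D depend on the
    unmeasured U, and whether the competing event is marginally rare
    (Pr(D=1) < 10%).
    """

    name: str
    params: DGPParams
    near_positivity_violation: bool
    u_dependence: bool
    rare_competing_event: bool

    def validate(self, eps: float = 0.05, rare_threshold: float = 0.10) -> None:
        """Check flag/parameter consistency; raise ValueError on mismatch."""
        # local import: estimands depends on dgp, keep module graph acyclic
        from .estimands import marginal_pr_d, min_survivor_probability

        p = self.params
        u_terms = p.theta[4:] + p.beta[4:]
        udep = any(t != 0.0 for t in u_terms)
        if udep != self.u_dependence:
            raise ValueError(
                f"scenario {self.name!r}: u_dependence flag {self.u_dependence} "
                f"inconsistent with U coefficients {u_terms}"
            )
        rare = marginal_pr_d(p) < rare_threshold
        if rare != self.rare_competing_event:
            raise ValueError(
                f"scenario {self.name!r}: rare flag {self.rare_competing_event} "
                f"inconsistent with marginal Pr(D=1)={marginal_pr_d(p):.4f}"
            )
        near = min_survivor_probability(p) < eps
        if near != self.near_positivity_violation:
            raise ValueError(
                f"scenario {self.name!r}: near-violation flag "
                f"{self.near_positivity_violation} inconsistent with min "
                f"survivor probability {min_survivor_probability(p):.4f} at eps={eps}"
            )


def _scenario_from_dict(name: str, spec: dict) -> Scenario:
    for key in ("theta", "beta"):
        if len(spec[key]) != _N_COEF:
            raise ValueError(
                f"scenario {name!r}: {key} must have {_N_COEF} entries, got {len(spec[key])}"
            )
    params = DGPParams(
        pL=spec.get("pL", 0.1),
        pU=spec.get("pU", 0.5),
        theta=tuple(spec["theta"]),
        beta=tuple(spec["beta"]),
        pA=spec.get("pA", 0.5),
    )
    flags = spec["flags"]
    return Scenario(
        name=name,
        params=params,
        near_positivity_violation=bool(flags["near_positivity_violation"]),
        u_dependence=bool(flags["u_dependence"]),
        rare_competing_event=bool(flags["rare_competing_event"]),
    )


def scenario_presets(config_path: str | Path | None = None, validate: bool = True) -> list[Scenario]:
    """Load the six variance-study scenarios.

    Without ``config_path`` the packaged configuration is used.  Its
    coefficients are documented stand-ins satisfying each row's flags
    (near violation x U dependence x rarity); a user config with the same
    schema can override them, e.g. with exact published values.
    """
    if config_path is None:
        text = resources.files("sepeffects.data").joinpath("scenarios.yaml").read_text()
    else:
        text = Path(config_path).read_text()
    raw = yaml.safe_load(text)
    scenarios = [_scenario_from_dict(name, spec) for name, spec in raw["scenarios"].items()]
    if validate:
        for sc in scenarios:
            sc.validate()
    return scenarios
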