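"""Exact causal and statistical targets under a known point-treatment law.

Everything here is computed analytically by enumeration over the discrete
(L, U) support — no simulation.  Two families of quantities are produced
for a given parameterization:

*True causal targets.*  The controlled direct effect contrasts risks under
joint interventions setting treatment and eliminating the competing event,

    CDE0 = Pr(Y^{a=1,d=0}=1) - Pr(Y^{a=0,d=0}=1),

with Pr(Y^{a,d=0}=1) = sum_{l,u} mu0(a,l,u) Pr(L=l) Pr(U=u).  The
separable direct effect contrasts risks under joint interventions on the
treatment components acting on the event of interest (aY) and on the
competing event (aD),

    SDE0^{aD} = Pr(Y^{aY=1,aD}=1) - Pr(Y^{aY=0,aD}=1),

with Pr(Y^{aY,aD}=1) = sum_{l,u} mu0(aY,l,u) (1-pi0(aD,l,u)) Pr(L=l) Pr(U=u).

*Observed-data statistical targets.*  The functionals of the observable
law (L, A, D, Y) that the two weighted estimators converge to:

    psi~(a, d=0)   = sum_l Pr(Y=1|A=a, D=0, L=l) Pr(L=l)
    psi~(aY, aD)   = sum_l Pr(Y=1|A=aY, D=0, L=l) (1 - pi~(aD,l)) Pr(L=l)

where pi~(a,l) = Pr(D=1|A=a,L=l).  When the unmeasured U influences both
processes these differ from the causal targets — the gap is the
non-identification error.  L and U are independent throughout (the law
specifies only their marginals and samples them independently).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .dgp import DGPParams, mu0, pi0

__all__ = [
    "UndefinedFunctional",
    "TargetValues",
    "PositivityReport",
    "pi_tilde_true",
    "marginal_pr_d",
    "min_survivor_probability",
    "true_targets",
    "observed_targets",
    "all_targets",
    "positivity_report",
    "sign_discordant",
]


class UndefinedFunctional:
    """Marker for an observed-data functional undefined due to positivity.

    Used instead of NaN so that undefinedness can never leak silently into
    arithmetic: any numeric operation raises.
    """

    def __init__(self, reason: str):
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"UndefinedFunctional({self.reason!r})"

    def __bool__(self) -> bool:
        return False


def _marginals(params: DGPParams):
    """(value, probability) pairs for the L and U marginals, zero-prob levels kept."""
    pl = [(0, 1.0 - params.pL), (1, params.pL)]
    pu = [(0, 1.0 - params.pU), (1, params.pU)]
    return pl, pu


def pi_tilde_true(a: int, l: int, params: DGPParams) -> float:
    """U-marginalized competing-event probability Pr(D=1 | A=a, L=l)."""
    _, pu = _marginals(params)
    return sum(pi0(a, l, u, params) * w for u, w in pu)


def marginal_pr_d(params: DGPParams) -> float:
    """Marginal competing-event probability Pr(D=1)."""
    pl, pu = _marginals(params)
    pa = [(0, 1.0 - params.pA), (1, params.pA)]
    return sum(
        pi0(a, l, u, params) * wa * wl * wu
        for (a, wa), (l, wl), (u, wu) in product(pa, pl, pu)
    )


def min_survivor_probability(params: DGPParams) -> float:
    """min over reachable (a,l) of 1 - pi~(a,l), the positivity margin."""
    pl, _ = _marginals(params)
    probs = [
        1.0 - pi_tilde_true(a, l, params)
        for a in (0, 1)
        for l, wl in pl
        if wl > 0 and (params.pA if a else 1 - params.pA) > 0
    ]
    return min(probs)


@dataclass
class TargetValues:
    """The causal targets, statistical targets and their contrasts.

    True-risk fields are plain floats.  Observed-functional fields may hold
    an :class:`UndefinedFunctional` when positivity fails for the cells the
    functional needs.
    """

    # true counterfactual risks
    psi0_cde: dict = field(default_factory=dict)        # a -> Pr(Y^{a,d=0}=1)
    psi0_sde: dict = field(default_factory=dict)        # (aY,aD) -> Pr(Y^{aY,aD}=1)
    # observed-data functionals
    psi_tilde_cde: dict = field(default_factory=dict)   # a -> psi~(a,d=0)
    psi_tilde_sde: dict = field(default_factory=dict)   # (aY,aD) -> psi~(aY,aD)
    # contrasts
    cde0: float | None = None
    sde0_aD0: float | None = None
    sde0_aD1: float | None = None
    cdeobs: float | UndefinedFunctional | None = None
    sdeobs_aD0: float | UndefinedFunctional | None = None
    sdeobs_aD1: float | UndefinedFunctional | None = None
    total_effect_obs: float | None = None

    def sde0(self, aD: int) -> float:
        return self.sde0_aD1 if aD else self.sde0_aD0

    def sdeobs(self, aD: int):
        return self.sdeobs_aD1 if aD else self.sdeobs_aD0

    def to_row(self, name: str = "") -> dict:
        """Flat dict (CSV row) with undefined functionals rendered as None."""
        def _v(x):
            return None if isinstance(x, UndefinedFunctional) else x

        return {
            "name": name,
            "cde0": self.cde0,
            "sde0_aD0": self.sde0_aD0,
            "sde0_aD1": self.sde0_aD1,
            "cdeobs": _v(self.cdeobs),
            "sdeobs_aD0": _v(self.sdeobs_aD0),
            "sdeobs_aD1": _v(self.sdeobs_aD1),
            "total_effect_obs": self.total_effect_obs,
        }


def true_targets(params: DGPParams) -> TargetValues:
    """Controlled and separable direct-effect risks by exact enumeration."""
    pl, pu = _marginals(params)
    tv = TargetValues()
    for a in (0, 1):
        tv.psi0_cde[a] = sum(
            mu0(a, l, u, params) * wl * wu for (l, wl), (u, wu) in product(pl, pu)
        )
    for aY, aD in product((0, 1), (0, 1)):
        tv.psi0_sde[(aY, aD)] = sum(
            mu0(aY, l, u, params) * (1.0 - pi0(aD, l, u, params)) * wl * wu
            for (l, wl), (u, wu) in product(pl, pu)
        )
    tv.cde0 = tv.psi0_cde[1] - tv.psi0_cde[0]
    tv.sde0_aD0 = tv.psi0_sde[(1, 0)] - tv.psi0_sde[(0, 0)]
    tv.sde0_aD1 = tv.psi0_sde[(1, 1)] - tv.psi0_sde[(0, 1)]
    return tv


def _pr_y_given_a_d0_l(a: int, l: int, params: DGPParams):
    """Pr(Y=1 | A=a, D=0, L=l), or an UndefinedFunctional when Pr(D=0|a,l)=0."""
    _, pu = _marginals(params)
    num = sum(mu0(a, l, u, params) * (1.0 - pi0(a, l, u, params)) * wu for u, wu in pu)
    den = sum((1.0 - pi0(a, l, u, params)) * wu for u, wu in pu)
    if den <= 0.0:
        return UndefinedFunctional(
            f"Pr(D=0|A={a},L={l}) = 0: conditioning event has probability zero"
        )
    return num / den


def observed_targets(params: DGPParams) -> TargetValues:
    """Statistical targets of the IPCW and separable-effect estimators.

    Functionals needing a survivor stratum of probability zero are marked
    with :class:`UndefinedFunctional` rather than computed.  Per the weaker
    separable-effect positivity condition, a stratum with survivor
    probability zero under aD contributes exactly zero to psi~(aY,aD) and
    does not make it undefined.
    """
    pl, _ = _marginals(params)
    tv = TargetValues()

    cond = {(a, l): _pr_y_given_a_d0_l(a, l, params) for a in (0, 1) for l, _ in pl}

    for a in (0, 1):
        total, undef = 0.0, None
        for l, wl in pl:
            if wl == 0:
                continue
            c = cond[(a, l)]
            if isinstance(c, UndefinedFunctional):
                undef = c
                break
            total += c * wl
        tv.psi_tilde_cde[a] = undef if undef is not None else total

    for aY, aD in product((0, 1), (0, 1)):
        total, undef = 0.0, None
        for l, wl in pl:
            if wl == 0:
                continue
            surv_aD = 1.0 - pi_tilde_true(aD, l, params)
            if surv_aD <= 0.0:
                continue  # weight is exactly zero; Eq-(11)-style reachability
            c = cond[(aY, l)]
            if isinstance(c, UndefinedFunctional):
                undef = UndefinedFunctional(
                    f"survivor stratum (A={aY},L={l}) has probability zero but "
                    f"carries positive weight under aD={aD}"
                )
                break
            total += c * surv_aD * wl
        tv.psi_tilde_sde[(aY, aD)] = undef if undef is not None else total

    def _contrast(v1, v0):
        for v in (v1, v0):
            if isinstance(v, UndefinedFunctional):
                return v
        return v1 - v0

    tv.cdeobs = _contrast(tv.psi_tilde_cde[1], tv.psi_tilde_cde[0])
    tv.sdeobs_aD0 = _contrast(tv.psi_tilde_sde[(1, 0)], tv.psi_tilde_sde[(0, 0)])
    tv.sdeobs_aD1 = _contrast(tv.psi_tilde_sde[(1, 1)], tv.psi_tilde_sde[(0, 1)])

    pl_, pu = _marginals(params)
    pr_y = {
        a: sum(
            mu0(a, l, u, params) * (1.0 - pi0(a, l, u, params)) * wl * wu
            for (l, wl), (u, wu) in product(pl_, pu)
        )
        for a in (0, 1)
    }
    tv.total_effect_obs = pr_y[1] - pr_y[0]
    return tv


def all_targets(params: DGPParams) -> TargetValues:
    """True and observed targets merged into one TargetValues."""
    tv = true_targets(params)
    obs = observed_targets(params)
    tv.psi_tilde_cde = obs.psi_tilde_cde
    tv.psi_tilde_sde = obs.psi_tilde_sde
    tv.cdeobs = obs.cdeobs
    tv.sdeobs_aD0 = obs.sdeobs_aD0
    tv.sdeobs_aD1 = obs.sdeobs_aD1
    tv.total_effect_obs = obs.total_effect_obs
    return tv


@dataclass
class PositivityReport:
    """Diagnostics for the two competing-event positivity conditions.

    The strong condition (required by the controlled direct effect): every
    reachable (a,l) stratum has survivor probability 1 - pi~(a,l) > 0.  The
    weak condition (separable direct effect, per aD): strata only need a
    positive survivor probability if they carry positive weight, i.e. if
    1 - pi~(aD,l) > 0.  The strong condition implies the weak one.
    """

    pi_tilde: dict                    # (a,l) -> Pr(D=1|A=a,L=l)
    cde_condition_holds: bool
    sde_condition_holds: dict         # aD -> bool
    min_survivor_prob: float
    near_violation: bool
    eps: float


def positivity_report(params: DGPParams, eps: float = 0.05) -> PositivityReport:
    """Evaluate both positivity conditions and the near-violation margin."""
    if not (0.0 < eps < 1.0):
        raise ValueError(f"eps must be in (0,1), got {eps}")
    pl, _ = _marginals(params)
    reachable_l = [l for l, wl in pl if wl > 0]
    reachable_a = [a for a in (0, 1) if (params.pA if a else 1 - params.pA) > 0]
    pt = {(a, l): pi_tilde_true(a, l, params) for a in (0, 1) for l in (0, 1)}

    cde_ok = all(1.0 - pt[(a, l)] > 0.0 for a in reachable_a for l in reachable_l)
    sde_ok = {}
    for aD in (0, 1):
        sde_ok[aD] = all(
            1.0 - pt[(a, l)] > 0.0
            for a in reachable_a
            for l in reachable_l
            if 1.0 - pt[(aD, l)] > 0.0
        )
    min_surv = min(1.0 - pt[(a, l)] for a in reachable_a for l in reachable_l)
    return PositivityReport(
        pi_tilde=pt,
        cde_condition_holds=cde_ok,
        sde_condition_holds=sde_ok,
        min_survivor_prob=min_surv,
        near_violation=min_surv < eps,
        eps=eps,
    )


def sign_discordant(tv: TargetValues, aD: int) -> bool:
    """True iff CDE0 and SDE0^{aD} have strictly opposite signs.

    Zero is concordant with everything (points on an axis belong to no
    quadrant).
    """
    s = tv.sde0(aD)
    if tv.cde0 is None or s is None:
        raise ValueError("TargetValues must carry the true contrasts")
    return (tv.cde0 > 0 and s < 0) or (tv.cde0 < 0 and s > 0)
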