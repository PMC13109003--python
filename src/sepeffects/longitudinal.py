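"""Discrete-time extension: cumulative incidence under competing events.

Person-period (long-format) trial data: one row per person-month while at
risk, with randomized baseline treatment A, fixed baseline covariates, a
competing-event indicator D_k and an event-of-interest indicator Y_k for
interval k.  The competing event is evaluated first within an interval, so
a row with D_k=1 terminates follow-up with Y_k=0; a row with Y_k=1 is the
person's last row.

Only the competing-event process is modeled parametrically — a pooled
logistic discrete-hazard model with a second-degree polynomial in month —
while event-of-interest increments enter nonparametrically through
indicator sums.  Two weighted cumulative-incidence estimators generalize
the point-treatment pair:

* IPCW: persons are censored at a competing event and surviving
  person-months are weighted by the cumulative product of
  1 / (1 - hazard_D(j, a, L)) — the "competing events eliminated" curve.
* Separable-effect: person-months are weighted by the cumulative product
  of (1 - hazard_D(j, aD, L)) / (1 - hazard_D(j, aY, L)), targeting the
  curve under the D-acting treatment component held at aD.

At a single interval (K=1) both collapse exactly to the point-treatment
estimators.  Percentile bootstrap confidence intervals resample persons
and refit the hazard model in every resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PersonPeriodTable",
    "HazardModelSpec",
    "FittedHazard",
    "TrialHazardCoefficients",
    "fit_discrete_hazard",
    "ipcw_risk_curve",
    "sde_risk_curve",
    "bootstrap_contrasts",
    "RiskCurveResult",
    "generate_synthetic_trial",
]

_CORE_COLS = ("id", "month", "a", "d", "y")


@dataclass
class PersonPeriodTable:
    """Validated long-format person-period data.

    ``df`` must contain columns id, month, a, d, y; every other column is
    treated as a baseline covariate and must be constant within person.
    Months are consecutive integers starting at 1, and a person's rows end
    at (and include) the first row with an event.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        missing = [c for c in _CORE_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"person-period table missing columns {missing}")
        df = df.sort_values(["id", "month"]).reset_index(drop=True)
        if df.empty:
            raise ValueError("person-period table is empty")
        if ((df["d"] == 1) & (df["y"] == 1)).any():
            raise ValueError("a row has both D_k=1 and Y_k=1; the competing event "
                             "precedes the event of interest within an interval")
        ids = df["id"].to_numpy()
        month = df["month"].to_numpy()
        first = np.ones(len(df), dtype=bool)
        first[1:] = ids[1:] != ids[:-1]
        last = np.roll(first, -1)
        if (month[first] != 1).any():
            raise ValueError("each person's rows must start at month 1")
        within = ~first
        if (month[within] - np.roll(month, 1)[within] != 1).any():
            raise ValueError("each person's months must be consecutive")
        # rows must stop at the first event: an event row is the person's last
        event = (df["d"].to_numpy() + df["y"].to_numpy()) > 0
        if (event & ~last).any():
            raise ValueError("rows continue past a person's first event")
        for c in self.covariate_columns(df):
            v = df[c].to_numpy()
            if (~first & (v != np.roll(v, 1))).any():
                raise ValueError(f"baseline covariate {c!r} varies within a person")
        if not df["a"].isin((0, 1)).all():
            raise ValueError("treatment a must be binary")
        self.df = df

    @staticmethod
    def covariate_columns(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c not in _CORE_COLS]

    @property
    def covariates(self) -> list[str]:
        return self.covariate_columns(self.df)

    @property
    def n_persons(self) -> int:
        return self.df["id"].nunique()

    @property
    def max_month(self) -> int:
        return int(self.df["month"].max())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, column_map: dict | None = None) -> "PersonPeriodTable":
        """Read a person-period CSV; ``column_map`` renames source columns
        to the canonical names (e.g. for externally published datasets)."""
        df = pd.read_csv(path)
        if column_map:
            df = df.rename(columns=column_map)
        return cls(df)


@dataclass(frozen=True)
class HazardModelSpec:
    """Pooled logistic discrete-hazard model specification.

    Time enters as a polynomial in month (degree 2 by default — the
    standard smooth-hazard choice; degree 0 gives a time-constant hazard,
    useful for single-interval data).  ``covariates`` are baseline column
    names; a column named ``age_group`` (coded 0/1/2) is expanded into two
    indicator terms.  ``interactions`` are (treatment-column, covariate)
    pairs entered as products; by default the competing-event model
    includes a x hist_cvd when that covariate exists.
    """

    outcome: str = "competing-event"
    time_degree: int = 2
    covariates: tuple[str, ...] | None = None   # None -> all baseline columns + a
    interactions: tuple[tuple[str, str], ...] | None = None  # None -> default

    def __post_init__(self):
        if self.outcome not in ("competing-event", "event-of-interest"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.time_degree < 0:
            raise ValueError("time_degree must be >= 0")

    def resolve(self, table: PersonPeriodTable) -> "HazardModelSpec":
        cov = self.covariates
        if cov is None:
            cov = tuple(["a"] + table.covariates)
        inter = self.interactions
        if inter is None:
            inter = (("a", "hist_cvd"),) if (
                self.outcome == "competing-event" and "hist_cvd" in table.covariates
            ) else ()
        return HazardModelSpec(self.outcome, self.time_degree, tuple(cov), tuple(inter))


def _design_matrix(df: pd.DataFrame, spec: HazardModelSpec) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    m = df["month"].to_numpy(dtype=float)
    for p in range(1, spec.time_degree + 1):
        cols.append(m**p)
        names.append(f"month^{p}" if p > 1 else "month")
    for c in spec.covariates:
        if c == "age_group":
            ag = df[c].to_numpy()
            cols += [(ag == 1).astype(float), (ag == 2).astype(float)]
            names += ["age_60_75", "age_75p"]
        else:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
    for c1, c2 in spec.interactions:
        cols.append(df[c1].to_numpy(dtype=float) * df[c2].to_numpy(dtype=float))
        names.append(f"{c1}:{c2}")
    return np.column_stack(cols), names


@dataclass
class FittedHazard:
    """A fitted (or degenerate all-zero) discrete-hazard model."""

    spec: HazardModelSpec
    params: np.ndarray | None
    term_names: list[str]
    bse: np.ndarray | None = None
    degenerate_zero: bool = False    # no events at all: hazard is exactly 0

    def coefficients(self) -> dict:
        if self.params is None:
            return {}
        return dict(zip(self.term_names, self.params))

    def predict(self, df: pd.DataFrame, a: int | np.ndarray | None = None) -> np.ndarray:
        """Predicted discrete hazard for each row; ``a`` overrides the
        treatment column (to evaluate the hazard under a set arm)."""
        if self.degenerate_zero:
            return np.zeros(len(df))
        if a is not None:
            df = df.assign(a=a)
        X, _ = _design_matrix(df, self.spec)
        lin = X @ self.params
        return 1.0 / (1.0 + np.exp(-lin))


def fit_discrete_hazard(
    data: PersonPeriodTable, spec: HazardModelSpec | None = None
) -> FittedHazard:
    """Maximum-likelihood pooled logistic fit on at-risk person-months.

    Every row of the table is an at-risk person-month for the
    competing-event process (the table format drops rows after an event,
    so no explicit risk-set filter is needed).  For the event-of-interest
    outcome, person-months with a competing event are excluded (the event
    of interest was never evaluated in those intervals).  A dataset with
    no events of the modeled type yields an exact all-zero hazard fit.
    """
    if spec is None:
        spec = HazardModelSpec()
    spec = spec.resolve(data)
    df = data.df
    if spec.outcome == "competing-event":
        out = df["d"].to_numpy(dtype=float)
    else:
        df = df[df["d"] == 0]
        out = df["y"].to_numpy(dtype=float)
    X, names = _design_matrix(df, spec)
    if out.sum() == 0:
        return FittedHazard(spec=spec, params=None, term_names=names, degenerate_zero=True)
    model = sm.GLM(out, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:
        raise RuntimeError(f"pooled logistic hazard fit failed: {exc}") from exc
    if not res.converged:
        raise RuntimeError("pooled logistic hazard fit did not converge "
                           "(possible separation)")
    return FittedHazard(spec=spec, params=np.asarray(res.params),
                        term_names=names, bse=np.asarray(res.bse))


def _cum_weights(df: pd.DataFrame, hazfit: FittedHazard, aY: int, aD: int | None):
    """Per-row cumulative IP weight within person for arm-aY rows.

    aD=None gives IPCW weights prod 1/(1-h(j,aY,L)); otherwise the
    separable-effect ratio prod (1-h(j,aD,L))/(1-h(j,aY,L)).
    """
    h_own = hazfit.predict(df, a=aY)
    if np.any(h_own >= 1.0):
        k = int(df["month"].to_numpy()[h_own >= 1.0][0])
        raise ValueError(f"predicted competing-event hazard is 1 at month {k}, arm {aY}: "
                         "infinite inverse-probability weight")
    if aD is None:
        ratio = 1.0 / (1.0 - h_own)
    else:
        h_aD = hazfit.predict(df, a=aD)
        ratio = (1.0 - h_aD) / (1.0 - h_own)
    return pd.Series(ratio, index=df.index).groupby(df["id"]).cumprod().to_numpy()


def ipcw_risk_curve(
    data: PersonPeriodTable, hazfit: FittedHazard, arm: int, months
) -> pd.Series:
    """IPCW cumulative incidence of the event of interest in one arm.

    risk(t) = (1/n_arm) * sum over persons in arm, intervals k <= t of
    I(Y_k=1) * prod_{j<=k} 1/(1 - hazard_D(j, arm, L)).  Persons are
    censored at a competing event.  The returned Series carries the max
    cumulative weight in ``.attrs['max_weight']``.
    """
    months = list(months)
    sub = data.df[data.df["a"] == arm]
    if sub.empty:
        raise ValueError(f"no persons in arm A={arm}")
    n_arm = sub["id"].nunique()
    if not months:
        s = pd.Series(dtype=float)
        s.attrs["max_weight"] = float("nan")
        return s
    w = _cum_weights(sub, hazfit, aY=arm, aD=None)
    # weights are defined for uncensored person-months (all rows up to exit;
    # a D_k=1 row exits as censored and contributes nothing to the numerator)
    uncens = sub["d"].to_numpy() == 0
    contrib = sub["y"].to_numpy() * w * uncens
    k = sub["month"].to_numpy()
    risks = {t: float(contrib[k <= t].sum() / n_arm) for t in months}
    s = pd.Series(risks).sort_index()
    s.attrs["max_weight"] = float(w[uncens].max()) if uncens.any() else float("nan")
    return s


def sde_risk_curve(
    data: PersonPeriodTable, hazfit: FittedHazard, aY: int, aD: int, months
) -> pd.Series:
    """Separable-effect weighted cumulative incidence.

    risk(t) = (1/n_aY) * sum over persons in arm aY, intervals k <= t of
    I(Y_k=1) * prod_{j<=k} (1-hazard_D(j,aD,L)) / (1-hazard_D(j,aY,L)).
    With aD=aY the weights cancel to 1 and this is the crude cumulative
    incidence.
    """
    months = list(months)
    sub = data.df[data.df["a"] == aY]
    if sub.empty:
        raise ValueError(f"no persons in arm A={aY}")
    n_arm = sub["id"].nunique()
    if not months:
        s = pd.Series(dtype=float)
        s.attrs["max_weight"] = float("nan")
        return s
    if aY == aD:
        w = np.ones(len(sub))
    else:
        w = _cum_weights(sub, hazfit, aY=aY, aD=aD)
    contrib = sub["y"].to_numpy() * w
    k = sub["month"].to_numpy()
    risks = {t: float(contrib[k <= t].sum() / n_arm) for t in months}
    s = pd.Series(risks).sort_index()
    s.attrs["max_weight"] = float(w.max())
    return s


@dataclass
class RiskCurveResult:
    """Point curves, contrast and percentile bootstrap CIs by month."""

    estimator: str
    aD: int | None
    months: list[int]
    risk_arm1: pd.Series
    risk_arm0: pd.Series
    contrast: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    max_weight: float
    n_boot: int
    n_boot_failed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "month": self.months,
            "risk_arm1": self.risk_arm1.values,
            "risk_arm0": self.risk_arm0.values,
            "contrast": self.contrast.values,
            "ci_lower": self.ci_lower.values,
            "ci_upper": self.ci_upper.values,
        })


def _contrast_curves(table, spec, estimator, aD, months):
    hazfit = fit_discrete_hazard(table, spec)
    if estimator == "ipcw":
        r1 = ipcw_risk_curve(table, hazfit, 1, months)
        r0 = ipcw_risk_curve(table, hazfit, 0, months)
    elif estimator == "sde":
        r1 = sde_risk_curve(table, hazfit, 1, aD, months)
        r0 = sde_risk_curve(table, hazfit, 0, aD, months)
    else:
        raise ValueError(f"unknown estimator {estimator!r}; use 'ipcw' or 'sde'")
    mw = np.nanmax([r1.attrs["max_weight"], r0.attrs["max_weight"]])
    return r1, r0, float(mw)


def bootstrap_contrasts(
    data: PersonPeriodTable,
    estimator: str,
    aD: int | None = None,
    months=(12, 24, 36, 48),
    B: int = 1000,
    seed: int = 0,
    spec: HazardModelSpec | None = None,
) -> RiskCurveResult:
    """Arm contrast of a weighted risk curve with percentile bootstrap CIs.

    Resampling unit is the person; the competing-event hazard model is
    refit within every resample.  Resamples whose fit fails are skipped
    and counted.  The 2.5th / 97.5th percentiles of the B contrast
    estimates form the interval.
    """
    if estimator == "sde" and aD not in (0, 1):
        raise ValueError("aD must be 0 or 1 for the separable-effect estimator")
    if B < 2:
        raise ValueError("B must be >= 2")
    months = list(months)
    r1, r0, max_w = _contrast_curves(data, spec, estimator, aD, months)
    point = r1 - r0

    rng = np.random.default_rng(seed)
    ids = data.df["id"].unique()
    id_arr = data.df["id"].to_numpy()
    row_ix = {pid: np.flatnonzero(id_arr == pid) for pid in ids}
    boot = []
    failed = 0
    for _ in range(B):
        pick = rng.choice(ids, size=len(ids), replace=True)
        ix = np.concatenate([row_ix[p] for p in pick])
        sample_df = data.df.take(ix).reset_index(drop=True)
        # relabel so persons drawn multiple times stay distinct
        sample_df["id"] = np.repeat(np.arange(len(pick)),
                                    [len(row_ix[p]) for p in pick])
        sample = PersonPeriodTable(sample_df)
        try:
            b1, b0, _ = _contrast_curves(sample, spec, estimator, aD, months)
        except (RuntimeError, ValueError):
            failed += 1
            continue
        boot.append((b1 - b0).values)
    if not boot:
        raise RuntimeError("all bootstrap resamples failed to fit")
    arr = np.vstack(boot)
    lower = pd.Series(np.percentile(arr, 2.5, axis=0), index=months)
    upper = pd.Series(np.percentile(arr, 97.5, axis=0), index=months)
    return RiskCurveResult(
        estimator=estimator,
        aD=aD,
        months=months,
        risk_arm1=r1,
        risk_arm0=r0,
        contrast=point,
        ci_lower=lower,
        ci_upper=upper,
        max_weight=max_w,
        n_boot=len(boot),
        n_boot_failed=failed,
    )


@dataclass(frozen=True)
class TrialHazardCoefficients:
    """Pooled logistic coefficients for one event process.

    Linear predictor: intercept + month*m + month2*m^2 + a*A
    + hgb_low + age_60_75 + age_75p + in_bed + hist_cvd (+ a:hist_cvd).
    Defaults emulate an elderly prostate-cancer trial: a baseline monthly
    other-cause-death hazard near 1%, elevated by age, bed-bound status
    and cardiovascular history, with treatment raising cardiovascular
    mortality more in men with prior cardiovascular disease.
    """

    intercept: float
    month: float = 0.0
    month2: float = 0.0
    a: float = 0.0
    hgb_low: float = 0.0
    age_60_75: float = 0.0
    age_75p: float = 0.0
    in_bed: float = 0.0
    hist_cvd: float = 0.0
    a_hist_cvd: float = 0.0

    def hazard(self, month, a, hgb_low, age_group, in_bed, hist_cvd) -> np.ndarray:
        lin = (self.intercept + self.month * month + self.month2 * month**2
               + self.a * a + self.hgb_low * hgb_low
               + self.age_60_75 * (age_group == 1) + self.age_75p * (age_group == 2)
               + self.in_bed * in_bed + self.hist_cvd * hist_cvd
               + self.a_hist_cvd * a * hist_cvd)
        return 1.0 / (1.0 + np.exp(-lin))


DEFAULT_D_COEFS = TrialHazardCoefficients(
    intercept=-4.9, month=0.015, month2=-0.0002, a=0.35, hgb_low=0.25,
    age_60_75=0.3, age_75p=0.8, in_bed=0.6, hist_cvd=0.5, a_hist_cvd=0.45,
)
DEFAULT_Y_COEFS = TrialHazardCoefficients(
    intercept=-4.4, month=0.025, month2=-0.0003, a=-0.45, hgb_low=0.35,
    age_60_75=0.1, age_75p=0.25, in_bed=0.8, hist_cvd=0.0, a_hist_cvd=0.0,
)
DEFAULT_COVARIATE_PREVALENCES = {
    "hgb_low": 0.25,
    "age_group": (0.15, 0.55, 0.30),
    "in_bed": 0.05,
    "hist_cvd": 0.35,
}


def generate_synthetic_trial(
    arms: tuple[int, int] = (125, 127),
    K: int = 50,
    d_coefs: TrialHazardCoefficients = DEFAULT_D_COEFS,
    y_coefs: TrialHazardCoefficients = DEFAULT_Y_COEFS,
    prevalences: dict | None = None,
    seed: int = 0,
) -> PersonPeriodTable:
    """Simulate a two-arm trial as a person-period table.

    SYNTHETIC stand-in for the historical estrogen-therapy trial data:
    per person, baseline covariates are drawn from their marginal
    prevalences; each month the competing event is drawn first from its
    discrete hazard, then (if no competing event) the event of interest
    from its hazard; follow-up stops at the first event or month K
    (administrative censoring).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n1, n0 = arms
    n = n1 + n0
    if prevalences is None:
        prevalences = DEFAULT_COVARIATE_PREVALENCES
    rng = np.random.default_rng(seed)
    a = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    hgb = (rng.random(n) < prevalences["hgb_low"]).astype(int)
    age = rng.choice(3, size=n, p=np.asarray(prevalences["age_group"], dtype=float))
    bed = (rng.random(n) < prevalences["in_bed"]).astype(int)
    cvd = (rng.random(n) < prevalences["hist_cvd"]).astype(int)

    rows = []
    alive = np.ones(n, dtype=bool)
    for k in range(1, K + 1):
        idx = np.where(alive)[0]
        if idx.size == 0:
            break
        h_d = d_coefs.hazard(k, a[idx], hgb[idx], age[idx], bed[idx], cvd[idx])
        d_k = rng.random(idx.size) < h_d
        h_y = y_coefs.hazard(k, a[idx], hgb[idx], age[idx], bed[idx], cvd[idx])
        y_k = (rng.random(idx.size) < h_y) & ~d_k
        rows.append(pd.DataFrame({
            "id": idx, "month": k, "a": a[idx], "hgb_low": hgb[idx],
            "age_group": age[idx], "in_bed": bed[idx], "hist_cvd": cvd[idx],
            "d": d_k.astype(int), "y": y_k.astype(int),
        }))
        alive[idx[d_k | y_k]] = False
    return PersonPeriodTable(pd.concat(rows, ignore_index=True))
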