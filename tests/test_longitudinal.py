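import numpy as np
import pandas as pd
import pytest

from sepeffects import (
    HazardModelSpec,
    PersonPeriodTable,
    TrialHazardCoefficients,
    bootstrap_contrasts,
    fit_discrete_hazard,
    generate_synthetic_trial,
    ipcw_risk_curve,
    sde_risk_curve,
)
from sepeffects.longitudinal import FittedHazard


class FixedHazard:
    """Hand-set discrete hazard h(month, arm) for toy oracles."""

    def __init__(self, table):  # {(month, a): hazard}
        self.table = table

    def predict(self, df, a=None):
        arm = df["a"].to_numpy() if a is None else np.full(len(df), a)
        return np.array([self.table[(m, ai)] for m, ai in zip(df["month"], arm)])


def small_trial(seed=0, n=300, K=10):
    return generate_synthetic_trial(arms=(n // 2, n - n // 2), K=K, seed=seed)


class TestPersonPeriodValidation:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["id", "month", "a", "d", "y"])

    def test_rows_after_event_rejected(self):
        with pytest.raises(ValueError, match="first event"):
            PersonPeriodTable(self._frame([(1, 1, 0, 0, 1), (1, 2, 0, 0, 0)]))

    def test_nonconsecutive_months_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            PersonPeriodTable(self._frame([(1, 1, 0, 0, 0), (1, 3, 0, 0, 0)]))

    def test_must_start_at_month_one(self):
        with pytest.raises(ValueError, match="month 1"):
            PersonPeriodTable(self._frame([(1, 2, 0, 0, 0)]))

    def test_simultaneous_events_rejected(self):
        with pytest.raises(ValueError, match="competing event"):
            PersonPeriodTable(self._frame([(1, 1, 0, 1, 1)]))

    def test_time_varying_covariate_rejected(self):
        df = pd.DataFrame({"id": [1, 1], "month": [1, 2], "a": [0, 0],
                           "d": [0, 0], "y": [0, 0], "hgb_low": [0, 1]})
        with pytest.raises(ValueError, match="varies"):
            PersonPeriodTable(df)

    def test_csv_roundtrip_with_column_map(self, tmp_path):
        tr = small_trial(n=40, K=4)
        path = tmp_path / "trial.csv"
        tr.df.rename(columns={"a": "treat"}).to_csv(path, index=False)
        back = PersonPeriodTable.from_csv(path, column_map={"treat": "a"})
        assert back.df.equals(tr.df[back.df.columns])


class TestSyntheticTrialGenerator:
    def test_zero_hazards_give_full_followup(self):
        z = TrialHazardCoefficients(intercept=-40)
        tr = generate_synthetic_trial(arms=(10, 10), K=6, d_coefs=z, y_coefs=z, seed=1)
        assert len(tr.df) == 20 * 6
        assert tr.df["d"].sum() == 0 and tr.df["y"].sum() == 0

    def test_zero_d_hazard_gives_no_competing_events(self):
        z = TrialHazardCoefficients(intercept=-40)
        y = TrialHazardCoefficients(intercept=-3)
        tr = generate_synthetic_trial(arms=(50, 50), K=10, d_coefs=z, y_coefs=y, seed=2)
        assert tr.df["d"].sum() == 0
        assert tr.df["y"].sum() > 0

    def test_determinism(self):
        t1 = generate_synthetic_trial(seed=4, K=10)
        t2 = generate_synthetic_trial(seed=4, K=10)
        assert t1.df.equals(t2.df)

    def test_empirical_hazards_match_specification(self):
        d = TrialHazardCoefficients(intercept=-3.0, a=0.5)
        y = TrialHazardCoefficients(intercept=-2.5, a=-0.5)
        tr = generate_synthetic_trial(arms=(5000, 5000), K=3, d_coefs=d, y_coefs=y,
                                      seed=6)
        df = tr.df
        for k in (1, 2, 3):
            for a in (0, 1):
                at_risk = df[(df["month"] == k) & (df["a"] == a)]
                h = 1 / (1 + np.exp(3.0 - 0.5 * a))
                se = np.sqrt(h * (1 - h) / len(at_risk))
                assert abs(at_risk["d"].mean() - h) < 4 * se
                surv = at_risk[at_risk["d"] == 0]
                hy = 1 / (1 + np.exp(2.5 + 0.5 * a))
                sey = np.sqrt(hy * (1 - hy) / len(surv))
                assert abs(surv["y"].mean() - hy) < 4 * sey


class TestDiscreteHazardFit:
    def test_no_events_yields_exact_zero_hazard(self):
        z = TrialHazardCoefficients(intercept=-40)
        y = TrialHazardCoefficients(intercept=-3)
        tr = generate_synthetic_trial(arms=(30, 30), K=5, d_coefs=z, y_coefs=y, seed=3)
        fit = fit_discrete_hazard(tr)
        assert fit.degenerate_zero
        assert np.all(fit.predict(tr.df) == 0.0)

    def test_intercept_only_fit_is_pooled_event_fraction(self):
        tr = small_trial(seed=9)
        spec = HazardModelSpec(time_degree=0, covariates=(), interactions=())
        fit = fit_discrete_hazard(tr, spec)
        assert fit.predict(tr.df)[0] == pytest.approx(tr.df["d"].mean(), abs=1e-8)

    def test_parameter_recovery_on_large_trial(self):
        """Fitted pooled-logistic coefficients recover the generating values,
        including the treatment x cardiovascular-history interaction."""
        true_d = TrialHazardCoefficients(
            intercept=-4.0, month=0.02, month2=-0.0003, a=0.4, hgb_low=0.3,
            age_60_75=0.2, age_75p=0.6, in_bed=0.5, hist_cvd=0.4, a_hist_cvd=0.5)
        tr = generate_synthetic_trial(arms=(2500, 2500), K=50, d_coefs=true_d, seed=12)
        fit = fit_discrete_hazard(tr)
        coefs = fit.coefficients()
        ses = dict(zip(fit.term_names, fit.bse))
        truth = {"intercept": -4.0, "month": 0.02, "month^2": -0.0003, "a": 0.4,
                 "hgb_low": 0.3, "age_60_75": 0.2, "age_75p": 0.6, "in_bed": 0.5,
                 "hist_cvd": 0.4, "a:hist_cvd": 0.5}
        for term, val in truth.items():
            assert abs(coefs[term] - val) < 4 * ses[term], term


class TestRiskCurves:
    def test_k2_toy_matches_hand_computation(self):
        # arm 1: person A has Y at month 1; person B censored by D at month 2
        # arm 0: person C has Y at month 2; person D event-free both months
        df = pd.DataFrame({
            "id": [1, 2, 2, 3, 3, 4, 4],
            "month": [1, 1, 2, 1, 2, 1, 2],
            "a": [1, 1, 1, 0, 0, 0, 0],
            "d": [0, 0, 1, 0, 0, 0, 0],
            "y": [1, 0, 0, 0, 1, 0, 0],
        })
        table = PersonPeriodTable(df)
        haz = FixedHazard({(1, 1): 0.3, (2, 1): 0.35, (1, 0): 0.1, (2, 0): 0.15})
        r1 = ipcw_risk_curve(table, haz, arm=1, months=[1, 2])
        # person A: w = 1/(1-0.3); risk(1) = (1/0.7)/2
        assert r1[1] == pytest.approx((1 / 0.7) / 2)
        assert r1[2] == pytest.approx((1 / 0.7) / 2)  # B censored, adds nothing
        r0 = ipcw_risk_curve(table, haz, arm=0, months=[1, 2])
        assert r0[1] == 0.0
        assert r0[2] == pytest.approx((1 / (0.9 * 0.85)) / 2)
        s1 = sde_risk_curve(table, haz, aY=1, aD=0, months=[1, 2])
        # person A: w = (1-0.1)/(1-0.3) = 0.9/0.7
        assert s1[2] == pytest.approx((0.9 / 0.7) / 2)
        s0 = sde_risk_curve(table, haz, aY=0, aD=1, months=[1, 2])
        # person C: w = (0.7/0.9) * (0.65/0.85)
        assert s0[2] == pytest.approx((0.7 / 0.9) * (0.65 / 0.85) / 2)

    def test_own_arm_sde_curve_is_crude_cumulative_incidence(self):
        tr = small_trial(seed=20)
        fit = fit_discrete_hazard(tr)
        months = [3, 6, 10]
        for a in (0, 1):
            crude = sde_risk_curve(tr, fit, aY=a, aD=a, months=months)
            df = tr.df[tr.df["a"] == a]
            n = df["id"].nunique()
            for t in months:
                events = df[(df["y"] == 1) & (df["month"] <= t)]
                assert crude[t] == pytest.approx(len(events) / n)
            assert crude.attrs["max_weight"] == 1.0

    def test_no_competing_events_equivalence_chain(self):
        z = TrialHazardCoefficients(intercept=-40)
        y = TrialHazardCoefficients(intercept=-2.5, a=-0.4)
        tr = generate_synthetic_trial(arms=(150, 150), K=8, d_coefs=z, y_coefs=y,
                                      seed=21)
        fit = fit_discrete_hazard(tr)
        months = [2, 5, 8]
        for a in (0, 1):
            ipcw = ipcw_risk_curve(tr, fit, a, months)
            crude = sde_risk_curve(tr, fit, aY=a, aD=a, months=months)
            for aD in (0, 1):
                sde = sde_risk_curve(tr, fit, aY=a, aD=aD, months=months)
                assert np.allclose(sde.values, ipcw.values)
            assert np.allclose(ipcw.values, crude.values)

    def test_curves_monotone_nondecreasing(self):
        tr = small_trial(seed=22)
        fit = fit_discrete_hazard(tr)
        months = list(range(1, 11))
        for a in (0, 1):
            for curve in (ipcw_risk_curve(tr, fit, a, months),
                          sde_risk_curve(tr, fit, a, 1 - a, months)):
                assert (np.diff(curve.values) >= -1e-12).all()
                assert ((curve.values >= 0) & (curve.values <= 1.5)).all()

    def test_empty_month_list(self):
        tr = small_trial(n=40, K=3)
        fit = fit_discrete_hazard(tr)
        assert len(ipcw_risk_curve(tr, fit, 1, [])) == 0


class TestPointTreatmentCollapse:
    """At a single interval the longitudinal estimators reduce exactly to
    the point-treatment weighted estimators."""

    def test_k1_reproduces_point_estimators(self, base_params):
        from sepeffects import (fit_nuisance, generate_point_data, ipcw_cde_hat,
                                ipw_sde_hat)
        data = generate_point_data(base_params, 4000, seed=30)
        table = PersonPeriodTable(pd.DataFrame({
            "id": np.arange(len(data)), "month": 1, "a": data.a,
            "l": data.l, "d": data.d, "y": data.y,
        }))
        spec = HazardModelSpec(time_degree=0, covariates=("a", "l"),
                               interactions=(("a", "l"),))
        hazfit = fit_discrete_hazard(table, spec)
        nuis = fit_nuisance(data)
        ipcw_long = (ipcw_risk_curve(table, hazfit, 1, [1])
                     - ipcw_risk_curve(table, hazfit, 0, [1]))
        assert ipcw_long[1] == pytest.approx(ipcw_cde_hat(data, nuis).estimate,
                                             abs=1e-7)
        for aD in (0, 1):
            sde_long = (sde_risk_curve(table, hazfit, 1, aD, [1])
                        - sde_risk_curve(table, hazfit, 0, aD, [1]))
            assert sde_long[1] == pytest.approx(
                ipw_sde_hat(data, nuis, aD).estimate, abs=1e-7)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        tr = small_trial(n=80, K=5)
        kw = dict(estimator="ipcw", months=[2, 5], B=8, seed=99)
        r1 = bootstrap_contrasts(tr, **kw)
        r2 = bootstrap_contrasts(tr, **kw)
        assert np.array_equal(r1.ci_lower.values, r2.ci_lower.values)
        assert np.array_equal(r1.ci_upper.values, r2.ci_upper.values)

    def test_degenerate_data_gives_zero_width_interval(self):
        z = TrialHazardCoefficients(intercept=-40)
        tr = generate_synthetic_trial(arms=(20, 20), K=3, d_coefs=z, y_coefs=z, seed=1)
        res = bootstrap_contrasts(tr, "sde", aD=0, months=[3], B=5, seed=0)
        assert res.ci_lower[3] == res.ci_upper[3] == res.contrast[3] == 0.0

    def test_interval_covers_statistical_target(self):
        """Percentile bootstrap CIs cover the generator's analytic statistical
        target at roughly nominal rate over outer replications."""
        d = TrialHazardCoefficients(intercept=-2.8, a=0.5, hist_cvd=0.4, a_hist_cvd=0.4)
        y = TrialHazardCoefficients(intercept=-2.5, a=-0.5, hist_cvd=0.2)
        p_cvd = 0.4
        K, t = 4, 4

        # path-enumeration oracle for the IPCW statistical target:
        # sum_k h_y(k,a,l) prod_{j<k} (1-h_y(j,a,l)), marginalized over l
        def ipcw_target(a):
            total = 0.0
            for cvd, w in ((0, 1 - p_cvd), (1, p_cvd)):
                surv = 1.0
                risk = 0.0
                for k in range(1, t + 1):
                    hy = float(y.hazard(k, a, 0, 0, 0, cvd))
                    risk += surv * hy
                    surv *= 1 - hy
                total += w * risk
            return total

        target = ipcw_target(1) - ipcw_target(0)
        prev = {"hgb_low": 0.0, "age_group": (1.0, 0.0, 0.0), "in_bed": 0.0,
                "hist_cvd": p_cvd}
        covered = 0
        n_outer = 30
        for i in range(n_outer):
            tr = generate_synthetic_trial(arms=(150, 150), K=K, d_coefs=d, y_coefs=y,
                                          prevalences=prev, seed=1000 + i)
            res = bootstrap_contrasts(tr, "ipcw", months=[t], B=80, seed=i,
                                      spec=HazardModelSpec(
                                          time_degree=1,
                                          covariates=("a", "hist_cvd"),
                                          interactions=(("a", "hist_cvd"),)))
            if res.ci_lower[t] <= target <= res.ci_upper[t]:
                covered += 1
        # Binomial(30, .95): P(X < 24) ~ 1e-4
        assert covered >= 24
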