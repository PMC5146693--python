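"""Survival engine: Cox fits against a hand-coded partial-likelihood oracle,
Breslow baseline hazard, model-based 10-year risks, delayed-entry KM,
Aalen–Johansen identities and interaction tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from grslife import (
    aj_cif,
    age_at_crossing,
    baseline_cumhaz,
    fit_cox,
    interaction_test,
    km_curve,
    predict_risk10,
)
from grslife.survival import CoxFit, SurvCurve
from conftest import make_survival_frame


def six_record_fixture():
    """No ties, one binary covariate, delayed entry."""
    return make_survival_frame(
        entry=[50.0, 51.0, 52.0, 50.5, 53.0, 54.0],
        exit_=[55.0, 57.0, 59.5, 61.0, 63.0, 66.0],
        event=["chd", "censored", "chd", "chd", "censored", "chd"],
        x=[1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
    )


def partial_likelihood_score(beta, df, cov="x"):
    """Hand-written Cox score U(beta) with (entry, exit] risk sets, no ties."""
    entry = df["entry_age"].to_numpy()
    exit_ = df["exit_age"].to_numpy()
    ev = (df["event"] == "chd").to_numpy()
    x = df[cov].to_numpy(float)
    u = 0.0
    for i in np.flatnonzero(ev):
        t = exit_[i]
        risk = (entry < t) & (t <= exit_)
        w = np.exp(beta * x[risk])
        u += x[i] - np.sum(w * x[risk]) / np.sum(w)
    return u


class TestFitCox:
    def test_matches_score_equation_root_on_fixture(self):
        df = six_record_fixture()
        fit = fit_cox(df, ["x"], strata=None)
        root = brentq(partial_likelihood_score, -5, 5, args=(df,))
        assert fit.params["x"] == pytest.approx(root, abs=1e-5)

    def test_two_group_weibull_recovery(self, rng):
        """True log-HR 0.5 recovered within 3 SEs at n=2000."""
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        entry = rng.uniform(40, 60, n)
        u = rng.random(n)
        lam, k = 90.0, 5.0
        t = lam * ((entry / lam) ** k - np.log(u) * np.exp(-0.5 * x)) ** (1 / k)
        cens = entry + rng.uniform(5, 15, n)
        df = make_survival_frame(
            entry=entry, exit_=np.minimum(t, cens),
            event=np.where(t <= cens, "chd", "censored"), x=x,
        )
        fit = fit_cox(df, ["x"], strata=None)
        assert abs(fit.params["x"] - 0.5) < 3 * fit.se["x"]

    def test_null_covariate_ci_coverage(self, rng):
        """A covariate independent of the hazard: 95% CI covers 0 in most
        replicates (binomial slack at 40 reps)."""
        cover = 0
        reps = 40
        for _ in range(reps):
            n = 300
            entry = rng.uniform(40, 60, n)
            t = entry + rng.exponential(8, n)
            cens = entry + rng.uniform(4, 12, n)
            df = make_survival_frame(
                entry=entry, exit_=np.minimum(t, cens),
                event=np.where(t <= cens, "chd", "censored"),
                x=rng.standard_normal(n),
            )
            fit = fit_cox(df, ["x"], strata=None)
            b, se = fit.params["x"], fit.se["x"]
            cover += (b - 1.96 * se) <= 0 <= (b + 1.96 * se)
        assert cover / reps >= 0.85

    def test_constant_covariate_rejected(self):
        df = six_record_fixture()
        df["c"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, ["c"], strata=None)

    def test_stratum_without_events_rejected(self):
        df = six_record_fixture()
        df["sex"] = ["male"] * 3 + ["female"] * 3
        df.loc[df["sex"] == "female", "event"] = "censored"
        with pytest.raises(ValueError, match="events"):
            fit_cox(df, ["x"], strata="sex")

    def test_cause_specific_equals_relabelled_censoring(self):
        """Competing events are treated exactly as censoring."""
        df = six_record_fixture()
        df.loc[1, "event"] = "death_other"
        fit_cs = fit_cox(df, ["x"], strata=None, cause="chd")
        df2 = df.copy()
        df2.loc[1, "event"] = "censored"
        fit_std = fit_cox(df2, ["x"], strata=None, cause="chd")
        assert fit_cs.params["x"] == pytest.approx(fit_std.params["x"], abs=1e-12)

    def test_common_age_shift_preserves_coefficients(self):
        """Shifting every entry/exit age by a constant leaves risk sets, and
        hence the partial-likelihood estimate, unchanged."""
        df = six_record_fixture()
        shifted = df.copy()
        shifted["entry_age"] += 7.0
        shifted["exit_age"] += 7.0
        f1 = fit_cox(df, ["x"], strata=None)
        f2 = fit_cox(shifted, ["x"], strata=None)
        assert f1.params["x"] == pytest.approx(f2.params["x"], abs=1e-6)


class TestBaselineCumhaz:
    def test_null_lp_equals_nelson_aalen(self):
        df = six_record_fixture()
        df["z"] = [0.1, -0.1, 0.05, -0.05, 0.2, -0.2]
        fit = fit_cox(df, ["z"], strata=None)
        fit.params["z"] = 0.0  # force lp = 0
        base = baseline_cumhaz(fit)[None]
        entry = df["entry_age"].to_numpy()
        exit_ = df["exit_age"].to_numpy()
        ev = (df["event"] == "chd").to_numpy()
        na = 0.0
        for k, a in enumerate(base["age"]):
            n_at = np.sum((entry < a) & (a <= exit_))
            d = np.sum(ev & (exit_ == a))
            na += d / n_at
            assert base["cumhaz"].iloc[k] == pytest.approx(na, abs=1e-12)

    def test_hand_computed_breslow_terms(self):
        df = make_survival_frame(
            entry=[0.0, 0.0, 0.0, 0.0, 0.0],
            exit_=[1.0, 2.0, 3.0, 4.0, 5.0],
            event=["chd", "censored", "chd", "censored", "censored"],
            x=[1.0, 0.0, 1.0, 0.0, 0.0],
        )
        fit = fit_cox(df, ["x"], strata=None)
        b = float(fit.params["x"])
        base = baseline_cumhaz(fit)[None]
        e = np.exp(b)
        inc1 = 1.0 / (2 * e + 3)       # risk set at t=1: all 5
        inc2 = 1.0 / (e + 2)           # at t=3: subjects 3,4,5
        np.testing.assert_allclose(base["cumhaz"], [inc1, inc1 + inc2], atol=1e-10)
        assert np.all(np.diff(base["cumhaz"]) >= 0)


def toy_fit(baseline_df, beta=0.5):
    """Hand-assembled CoxFit for predict_risk10 arithmetic."""
    return CoxFit(
        params=pd.Series({"x": beta}),
        cov=pd.DataFrame([[0.01]], index=["x"], columns=["x"]),
        n=10, n_events=2, converged=True, cause="chd",
        strata_col=None, covariates=["x"],
        baseline={None: baseline_df}, _data=None,
    )


class TestPredictRisk10:
    def test_flat_hazard_gives_zero_risk(self):
        fit = toy_fit(pd.DataFrame({"age": [40.0], "cumhaz": [0.3]}))
        subj = pd.DataFrame({"entry_age": [45.0], "x": [1.0]})
        assert predict_risk10(fit, subj).iloc[0] == pytest.approx(0.0)

    def test_two_increment_hand_value(self):
        base = pd.DataFrame({"age": [52.0, 58.0], "cumhaz": [0.05, 0.12]})
        fit = toy_fit(base, beta=0.5)
        subj = pd.DataFrame({"entry_age": [50.0], "x": [2.0]})
        expected = 1 - np.exp(-0.12 * np.exp(1.0))
        assert predict_risk10(fit, subj).iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_large_lp_limit(self):
        base = pd.DataFrame({"age": [52.0], "cumhaz": [0.05]})
        fit = toy_fit(base, beta=1.0)
        subj = pd.DataFrame({"entry_age": [50.0], "x": [50.0]})
        assert predict_risk10(fit, subj).iloc[0] == pytest.approx(1.0)


class TestKaplanMeier:
    def test_no_events_survival_is_one(self):
        df = make_survival_frame([0, 0], [5.0, 6.0], ["censored", "censored"])
        curve = km_curve(df)
        assert len(curve.ages) == 0
        assert curve.value_at(4.0) == 1.0

    def test_hand_product_limit(self):
        df = make_survival_frame(
            [0.0, 0.0, 0.0], [1.0, 2.0, 3.0], ["chd", "censored", "chd"]
        )
        curve = km_curve(df)
        np.testing.assert_allclose(curve.estimate, [2 / 3, 0.0])
        np.testing.assert_allclose(curve.ages, [1.0, 3.0])

    def test_matches_lifelines_with_delayed_entry(self, rng):
        from lifelines import KaplanMeierFitter

        n = 300
        entry = rng.uniform(40, 55, n)
        t = entry + rng.exponential(8, n)
        cens = entry + rng.uniform(2, 14, n)
        exit_ = np.minimum(t, cens)
        ev = t <= cens
        df = make_survival_frame(entry, exit_, np.where(ev, "chd", "censored"))
        curve = km_curve(df)
        kmf = KaplanMeierFitter()
        kmf.fit(exit_, ev, entry=entry)
        ours = {a: s for a, s in zip(curve.ages, curve.estimate)}
        for a, s in ours.items():
            assert kmf.predict(a) == pytest.approx(s, abs=1e-10)

    def test_band_contains_estimate(self, rng):
        df = make_survival_frame(
            np.zeros(50), rng.uniform(1, 10, 50),
            rng.choice(["chd", "censored"], 50),
        )
        c = km_curve(df)
        assert np.all(c.lower <= c.estimate + 1e-12)
        assert np.all(c.upper >= c.estimate - 1e-12)


class TestAalenJohansen:
    def test_equals_one_minus_km_without_competing(self, rng):
        n = 200
        entry = rng.uniform(40, 55, n)
        exit_ = entry + rng.uniform(1, 15, n)
        ev = rng.choice(["chd", "censored"], n, p=[0.4, 0.6])
        df = make_survival_frame(entry, exit_, ev)
        cif = aj_cif(df, cause="chd")
        km = km_curve(df)
        np.testing.assert_allclose(cif.estimate, 1.0 - km.estimate, atol=1e-12)

    def test_cause_conservation(self, rng):
        n = 300
        entry = rng.uniform(40, 55, n)
        exit_ = entry + rng.uniform(1, 15, n)
        ev = rng.choice(["chd", "death_other", "censored"], n, p=[0.3, 0.2, 0.5])
        df = make_survival_frame(entry, exit_, ev)
        cif1 = aj_cif(df, cause="chd")
        cif2 = aj_cif(df, cause="death_other")
        km_all = km_curve(df, event_types=("chd", "death_other"))
        total = cif1.estimate + cif2.estimate
        np.testing.assert_allclose(total, 1.0 - km_all.estimate, atol=1e-12)

    def test_hand_computed_two_cause_fixture(self):
        df = make_survival_frame(
            entry=[0.0] * 6,
            exit_=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            event=["chd", "death_other", "censored", "chd", "censored", "censored"],
        )
        cif = aj_cif(df, cause="chd")
        # steps: t=1 S(0-)=1, d/n = 1/6 -> 1/6
        # t=2 (competing) flat for chd; S(2) = (5/6)(4/5) = 2/3
        # t=4: S(4-)=2/3, n=3 -> step (2/3)(1/3) = 2/9
        np.testing.assert_allclose(cif.ages, [1.0, 2.0, 4.0])
        np.testing.assert_allclose(
            cif.estimate, [1 / 6, 1 / 6, 1 / 6 + 2 / 9], atol=1e-12
        )
        assert np.all(cif.lower <= cif.estimate) and np.all(cif.upper >= cif.estimate)


class TestAgeAtCrossing:
    def test_never_attained_returns_none(self):
        c = SurvCurve(np.array([50.0, 60.0]), np.array([0.05, 0.08]),
                      np.zeros(2), np.ones(2), np.array([10, 5]), kind="incidence")
        assert age_at_crossing(c, 0.10) is None

    def test_step_crossing(self):
        c = SurvCurve(np.array([45.0, 52.0]), np.array([0.06, 0.12]),
                      np.zeros(2), np.ones(2), np.array([10, 5]), kind="incidence")
        assert age_at_crossing(c, 0.10) == 52.0

    def test_quintile_gap_sign(self):
        """Top-vs-bottom score groups: with HR/SD > 1 the top group reaches a
        10% cumulative risk earlier (simulation sign property)."""
        from grslife import SimConfig, simulate_dataset, apply_cohort_filters

        cfg = SimConfig(n_samples=4000, n_snps=100, target_hr_per_sd=2.5, seed=31)
        geno, truth, _, cohort = simulate_dataset(cfg)
        cohort = apply_cohort_filters(cohort, censor_age=75.0)
        z = pd.Series(truth.true_score, index=pd.Index(geno.sample_ids))
        cohort["z"] = z.loc[cohort["sample_id"]].to_numpy()
        lo, hi = cohort["z"].quantile([0.2, 0.8])
        top = aj_cif(cohort[cohort["z"] > hi], cause="chd")
        bottom = aj_cif(cohort[cohort["z"] <= lo], cause="chd")
        a_top = age_at_crossing(top, 0.10)
        a_bot = age_at_crossing(bottom, 0.10)
        assert a_top is not None
        assert a_bot is None or a_top < a_bot


class TestInteraction:
    def test_constant_product_is_error(self):
        df = six_record_fixture()
        df["g"] = [1.0, 2.0, 0.5, 1.5, 0.7, 1.2]
        df["f"] = 0.0
        with pytest.raises(ValueError, match="constant"):
            interaction_test(df, "g", "f", strata=None)

    def test_detects_strong_interaction(self, rng):
        """Product-term log-HR 0.5 at n=4000: Wald p < 0.05 in most draws."""
        hits = 0
        for _ in range(5):
            n = 4000
            g = rng.standard_normal(n)
            f = rng.integers(0, 2, n).astype(float)
            entry = rng.uniform(40, 60, n)
            lp = 0.2 * g + 0.2 * f + 0.5 * g * f
            t = entry + rng.exponential(10.0 * np.exp(-lp))
            cens = entry + rng.uniform(5, 15, n)
            df = make_survival_frame(
                entry, np.minimum(t, cens),
                np.where(t <= cens, "chd", "censored"), g=g, f=f,
            )
            res = interaction_test(df, "g", "f", strata=None)
            hits += res["p"] < 0.05
        assert hits >= 4
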