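"""Age-timescale survival models: Cox fits, baseline hazards, KM and
Aalen–Johansen curves, risk-crossing ages, and interaction tests.

All estimators use attained age as the time axis with delayed entry at the
baseline age, so risk sets are age-matched: a subject is at risk at age
``a`` iff ``entry_age < a <= exit_age``.  Cause-specific models treat
competing events as censoring.  Partial-likelihood maximization (with sex
strata, left truncation and Efron tie handling) is delegated to lifelines;
the Breslow baseline hazard, product-limit and Aalen–Johansen estimators
are computed here directly from their defining formulas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from grslife.sim import EVENT_CHD, EVENT_CENSORED

logger = logging.getLogger(__name__)

_Z95 = sps.norm.ppf(0.975)


@dataclass
class CoxFit:
    """Stratified cause-specific Cox model on the age scale."""

    params: pd.Series
    cov: pd.DataFrame
    n: int
    n_events: int
    converged: bool
    cause: str
    strata_col: str | None
    covariates: list
    baseline: dict = field(repr=False)  # stratum -> DataFrame(age, cumhaz)
    _data: pd.DataFrame = field(repr=False, default=None)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def hazard_ratios(self) -> pd.DataFrame:
        """HR with Wald 95% CI, exp(beta +/- 1.96 SE), and two-sided p."""
        se = self.se
        z = self.params / se
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "hr": np.exp(self.params),
                "hr_lo": np.exp(self.params - _Z95 * se),
                "hr_hi": np.exp(self.params + _Z95 * se),
                "z": z,
                "p": 2 * sps.norm.sf(np.abs(z)),
            }
        )

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.covariates].to_numpy(dtype=float)
        return X @ self.params.to_numpy()


@dataclass
class SurvCurve:
    """Step-function estimate with pointwise 95% band and at-risk counts.

    ``kind`` is ``"survival"`` (non-increasing from 1) or ``"incidence"``
    (non-decreasing from 0); ``ages`` are the jump ages.
    """

    ages: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    at_risk: np.ndarray
    kind: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
                "at_risk": self.at_risk,
            }
        )

    def value_at(self, age: float) -> float:
        """Right-continuous step evaluation; baseline value before first jump."""
        idx = np.searchsorted(self.ages, age, side="right") - 1
        if idx < 0:
            return 1.0 if self.kind == "survival" else 0.0
        return float(self.estimate[idx])


def _check_survival_frame(records: pd.DataFrame) -> None:
    need = {"entry_age", "exit_age", "event"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"survival records missing columns: {sorted(missing)}")
    if (records["exit_age"] <= records["entry_age"]).any():
        raise ValueError("all records must have exit_age > entry_age")


def fit_cox(
    records: pd.DataFrame,
    covariates,
    strata: str | None = "sex",
    cause: str = EVENT_CHD,
) -> CoxFit:
    """Stratified Cox PH fit with age as time scale and delayed entry.

    Non-target event types are treated as censoring (cause-specific model).
    Ties are handled by the Efron approximation.  Raises on constant
    covariates, strata without events of the target cause, or
    non-convergence / complete separation.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    _check_survival_frame(records)
    covariates = list(covariates)
    df = records[
        ["entry_age", "exit_age", "event"]
        + ([strata] if strata else [])
        + covariates
    ].copy()
    df["event_ind"] = (df["event"] == cause).astype(int)
    df = df.drop(columns=["event"])

    for c in covariates:
        if df[c].nunique(dropna=False) < 2:
            raise ValueError(f"covariate {c!r} is constant")
    if strata:
        per = df.groupby(strata)["event_ind"].sum()
        if (per < 1).any():
            empty = per.index[per < 1].tolist()
            raise ValueError(f"no {cause!r} events in strata {empty}")
    elif df["event_ind"].sum() < 1:
        raise ValueError(f"no events of cause {cause!r}")

    cph = CoxPHFitter(penalizer=0.0)
    try:
        cph.fit(
            df,
            duration_col="exit_age",
            event_col="event_ind",
            entry_col="entry_age",
            strata=[strata] if strata else None,
            show_progress=False,
        )
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err

    params = cph.params_.copy()
    params.index = [i if isinstance(i, str) else i[-1] for i in params.index]
    cov = pd.DataFrame(
        cph.variance_matrix_.to_numpy(), index=params.index, columns=params.index
    )

    fit = CoxFit(
        params=params[covariates],
        cov=cov.loc[covariates, covariates],
        n=len(df),
        n_events=int(df["event_ind"].sum()),
        converged=True,
        cause=cause,
        strata_col=strata,
        covariates=covariates,
        baseline={},
        _data=df,
    )
    fit.baseline = baseline_cumhaz(fit)
    return fit


def baseline_cumhaz(fit: CoxFit) -> dict:
    """Breslow baseline cumulative hazard per stratum on the age scale.

    At each event age ``a`` the increment is ``d(a) / sum_{risk set} exp(lp)``
    with the risk set ``entry < a <= exit``; a stratum with no events gets an
    identically-zero step function.
    """
    df = fit._data
    lp = fit.linear_predictor(df)
    out: dict = {}
    groups = df.groupby(fit.strata_col) if fit.strata_col else [(None, df)]
    for label, g in groups:
        idx = g.index.to_numpy()
        gi = df.index.get_indexer(idx)
        entry = g["entry_age"].to_numpy(float)
        exit_ = g["exit_age"].to_numpy(float)
        ev = g["event_ind"].to_numpy() == 1
        elp = np.exp(lp[gi])
        ages = np.unique(exit_[ev])
        inc = np.zeros(len(ages))
        for k, a in enumerate(ages):
            at_risk = (entry < a) & (a <= exit_)
            d = np.sum(ev & (exit_ == a))
            inc[k] = d / elp[at_risk].sum()
        out[label] = pd.DataFrame({"age": ages, "cumhaz": np.cumsum(inc)})
    return out


def _cumhaz_at(base: pd.DataFrame, ages: np.ndarray) -> np.ndarray:
    """Step-function evaluation of a baseline cumulative hazard (flat
    extrapolation beyond the last observed event age)."""
    if len(base) == 0:
        return np.zeros(np.shape(ages))
    grid = base["age"].to_numpy()
    ch = base["cumhaz"].to_numpy()
    idx = np.searchsorted(grid, ages, side="right") - 1
    return np.where(idx < 0, 0.0, ch[np.clip(idx, 0, len(ch) - 1)])


def predict_risk10(
    fit: CoxFit, subjects: pd.DataFrame, horizon: float = 10.0
) -> pd.Series:
    """Model-based ``horizon``-year risk from a subject's entry age.

    ``risk = 1 - exp(-[H0_s(a0 + horizon) - H0_s(a0)] * exp(lp))`` with the
    subject's stratum baseline.  Ages beyond the last observed event age use
    the last cumulative-hazard value (flat extrapolation), with a logged
    flag.
    """
    lp = fit.linear_predictor(subjects)
    a0 = subjects["entry_age"].to_numpy(float)
    a1 = a0 + horizon
    risk = np.empty(len(subjects))
    groups = (
        subjects.groupby(fit.strata_col).groups.items()
        if fit.strata_col
        else [(None, subjects.index)]
    )
    for label, idx in groups:
        base = fit.baseline.get(label, pd.DataFrame({"age": [], "cumhaz": []}))
        gi = subjects.index.get_indexer(idx)
        if len(base) and np.any(a1[gi] > base["age"].iloc[-1]):
            logger.info(
                "predict_risk10: %d subjects in stratum %r extend beyond the last "
                "observed event age; flat extrapolation used",
                int(np.sum(a1[gi] > base["age"].iloc[-1])), label,
            )
        dh = _cumhaz_at(base, a1[gi]) - _cumhaz_at(base, a0[gi])
        risk[gi] = 1.0 - np.exp(-dh * np.exp(lp[gi]))
    return pd.Series(risk, index=subjects.index, name="risk10")


def _event_table(entry, exit_, is_event):
    """Unique exit ages with at-risk counts, all-cause removals and events."""
    ages = np.unique(exit_[is_event])
    n_at_risk = np.array([np.sum((entry < a) & (a <= exit_)) for a in ages])
    d = np.array([np.sum(is_event & (exit_ == a)) for a in ages])
    return ages, n_at_risk, d


def km_curve(records: pd.DataFrame, event_types=(EVENT_CHD,)) -> SurvCurve:
    """Product-limit survival on the age scale with delayed entry.

    ``event_types`` lists the event labels counted as failures (everything
    else is censoring).  The 95% band is Greenwood on the log scale:
    ``S * exp(±1.96 * sqrt(sum d / (n (n - d))))``.
    """
    _check_survival_frame(records)
    entry = records["entry_age"].to_numpy(float)
    exit_ = records["exit_age"].to_numpy(float)
    is_event = records["event"].isin(event_types).to_numpy()

    ages, n, d = _event_table(entry, exit_, is_event)
    if len(ages) == 0:
        return SurvCurve(
            ages=np.array([]), estimate=np.array([]), lower=np.array([]),
            upper=np.array([]), at_risk=np.array([]), kind="survival",
        )
    frac = 1.0 - d / n
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n > d, d / (n * (n - d)), np.inf)
    var_log = np.cumsum(gw_terms)
    se_log = np.sqrt(var_log)
    with np.errstate(invalid="ignore", over="ignore"):
        lower = surv * np.exp(-_Z95 * se_log)
        upper = np.minimum(surv * np.exp(_Z95 * se_log), 1.0)
    lower = np.where(np.isfinite(lower), lower, 0.0)
    upper = np.where(np.isfinite(upper), upper, 1.0)
    return SurvCurve(ages=ages, estimate=surv, lower=lower, upper=upper,
                     at_risk=n, kind="survival")


def aj_cif(records: pd.DataFrame, cause: str = EVENT_CHD) -> SurvCurve:
    """Aalen–Johansen cumulative incidence of one cause under competing risks.

    ``CIF(t) = sum_{ages a <= t} S(a-) d_cause(a) / n(a)`` with ``S`` the
    all-cause Kaplan–Meier.  The 95% band uses the standard counting-process
    variance estimator (Klein & Moeschberger form), clipped to [0, 1].
    """
    _check_survival_frame(records)
    entry = records["entry_age"].to_numpy(float)
    exit_ = records["exit_age"].to_numpy(float)
    any_event = (records["event"] != EVENT_CENSORED).to_numpy()
    cause_event = (records["event"] == cause).to_numpy()
    if not any_event.any():
        return SurvCurve(np.array([]), np.array([]), np.array([]), np.array([]),
                         np.array([]), kind="incidence")

    ages, n, d_all = _event_table(entry, exit_, any_event)
    d_cause = np.array([np.sum(cause_event & (exit_ == a)) for a in ages])
    frac = 1.0 - d_all / n
    surv = np.cumprod(frac)
    s_minus = np.concatenate([[1.0], surv[:-1]])
    inc = s_minus * d_cause / n
    cif = np.cumsum(inc)

    # Klein & Moeschberger variance of the AJ estimator
    var = np.empty(len(ages))
    with np.errstate(divide="ignore", invalid="ignore"):
        g1 = np.where(n > d_all, d_all / (n * (n - d_all)), 0.0)
    g2 = s_minus**2 * ((n - d_cause) / n) * d_cause / n**2
    g3 = s_minus * d_cause / n**2
    for k in range(len(ages)):
        diff = cif[k] - cif[: k + 1]
        var[k] = (
            np.sum(diff**2 * g1[: k + 1])
            + np.sum(g2[: k + 1])
            - 2.0 * np.sum(diff * g3[: k + 1])
        )
    se = np.sqrt(np.maximum(var, 0.0))
    lower = np.clip(cif - _Z95 * se, 0.0, 1.0)
    upper = np.clip(cif + _Z95 * se, 0.0, 1.0)
    return SurvCurve(ages=ages, estimate=cif, lower=lower, upper=upper,
                     at_risk=n, kind="incidence")


def age_at_crossing(curve: SurvCurve, level: float):
    """Smallest age at which cumulative incidence reaches ``level``.

    Returns None if the curve never attains the level (e.g. a low-risk group
    that never reaches 10% cumulative risk by the censoring age).
    """
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    if curve.kind == "incidence":
        est = curve.estimate
    else:
        est = 1.0 - curve.estimate
    hit = np.flatnonzero(est >= level)
    if len(hit) == 0:
        return None
    return float(curve.ages[hit[0]])


def interaction_test(
    records: pd.DataFrame,
    grs_col: str,
    factor_col: str,
    adjust=(),
    strata: str | None = "sex",
    cause: str = EVENT_CHD,
) -> dict:
    """Wald test of a GRS × factor product term in a Cox model.

    Fits ``grs + factor + grs:factor`` (plus adjustments) and returns the
    product-term coefficient, SE, z and two-sided p.  A constant product
    column (factor or score constant) raises.
    """
    df = records.copy()
    prod_col = f"{grs_col}_x_{factor_col}"
    df[prod_col] = df[grs_col] * df[factor_col]
    if df[prod_col].nunique(dropna=False) < 2:
        raise ValueError("interaction product column is constant")
    fit = fit_cox(
        df, [grs_col, factor_col, prod_col] + list(adjust), strata=strata, cause=cause
    )
    hr = fit.hazard_ratios().loc[prod_col]
    return {
        "term": prod_col,
        "coef": float(hr["coef"]),
        "se": float(hr["se"]),
        "z": float(hr["z"]),
        "p": float(hr["p"]),
        "fit": fit,
    }
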