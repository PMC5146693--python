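"""Discrimination metrics: truncated Harrell's C-index, the correlated
jackknife test for a difference in C between two models on the same data,
Mann–Whitney AUC with a DeLong interval, and per-SD logistic odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

_Z95 = sps.norm.ppf(0.975)
_CHUNK = 512


@dataclass
class CIndexResult:
    c: float
    n_pairs: int
    se: float
    label: str = ""


@dataclass
class DeltaCResult:
    """C_B - C_A with leave-one-out jackknife inference."""

    delta_c: float
    se: float
    z: float
    p: float
    c_a: float
    c_b: float


@dataclass
class AucResult:
    auc: float
    se: float
    ci: tuple


@dataclass
class OrResult:
    odds_ratio: float
    ci: tuple
    beta: float
    se: float
    p: float


def _pair_sums(durations, events, scores, horizon):
    """Totals and per-subject sums of comparable / concordant pair weights.

    Pair (i, j) is comparable iff subject i has the event at follow-up time
    t_i <= horizon and t_i < t_j (j still at risk when i fails); the pair is
    concordant when score_i > score_j, and score ties count 0.5.
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n = len(t)
    comp_row = np.zeros(n)
    conc_row = np.zeros(n)
    comp_col = np.zeros(n)
    conc_col = np.zeros(n)
    idx_i = np.flatnonzero(e & (t <= horizon))
    for start in range(0, len(idx_i), _CHUNK):
        ii = idx_i[start : start + _CHUNK]
        comp = t[ii][:, None] < t[None, :]  # i fails strictly before j exits
        gt = s[ii][:, None] > s[None, :]
        eq = s[ii][:, None] == s[None, :]
        conc = comp * (gt + 0.5 * eq)
        comp_row[ii] += comp.sum(axis=1)
        conc_row[ii] += conc.sum(axis=1)
        comp_col += comp.sum(axis=0)
        conc_col += conc.sum(axis=0)
    return comp_row, conc_row, comp_col, conc_col


def cindex_truncated(
    durations,
    events,
    scores,
    horizon: float = 10.0,
    label: str = "",
) -> CIndexResult:
    """Harrell's C restricted to events within ``horizon`` of follow-up.

    ``durations`` are follow-up times from entry; ``events`` marks the event
    of interest.  The SE is a leave-one-out jackknife.  Raises if no
    comparable pairs exist.
    """
    comp_row, conc_row, comp_col, conc_col = _pair_sums(
        durations, events, scores, horizon
    )
    n_pairs = comp_row.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs; truncated C-index undefined")
    c = float(conc_row.sum() / n_pairs)

    comp_i = comp_row + comp_col
    conc_i = conc_row + conc_col
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = (conc_row.sum() - conc_i) / (n_pairs - comp_i)
    c_loo = np.where(np.isfinite(c_loo), c_loo, c)
    n = len(c_loo)
    se = float(np.sqrt((n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)))
    return CIndexResult(c=c, n_pairs=int(n_pairs), se=se, label=label)


def delta_c_jackknife(
    durations,
    events,
    scores_a,
    scores_b,
    horizon: float = 10.0,
) -> DeltaCResult:
    """Correlated jackknife test for ΔC = C_B − C_A on the same subjects.

    Leave-one-out ΔC pseudo-values give the variance
    ``(n-1)/n * sum (ΔC_(−i) − mean)²``; z = ΔC / se with a normal two-sided
    p.  ΔC exactly 0 (e.g. identical scores) is reported with p = 1.
    Antisymmetric under swapping the two models.
    """
    n = len(np.asarray(durations))
    if n < 3:
        raise ValueError("need at least 3 subjects for the jackknife")

    res = {}
    for key, s in (("a", scores_a), ("b", scores_b)):
        comp_row, conc_row, comp_col, conc_col = _pair_sums(
            durations, events, s, horizon
        )
        n_pairs = comp_row.sum()
        if n_pairs == 0:
            raise ValueError("no comparable pairs; truncated C-index undefined")
        c = conc_row.sum() / n_pairs
        comp_i = comp_row + comp_col
        conc_i = conc_row + conc_col
        with np.errstate(invalid="ignore", divide="ignore"):
            c_loo = (conc_row.sum() - conc_i) / (n_pairs - comp_i)
        res[key] = (float(c), np.where(np.isfinite(c_loo), c_loo, c))

    c_a, loo_a = res["a"]
    c_b, loo_b = res["b"]
    delta = c_b - c_a
    d_loo = loo_b - loo_a
    var = (n - 1) / n * np.sum((d_loo - d_loo.mean()) ** 2)
    se = float(np.sqrt(var))
    if delta == 0.0:
        return DeltaCResult(delta_c=0.0, se=se, z=0.0, p=1.0, c_a=c_a, c_b=c_b)
    if se == 0.0:
        z = np.inf if delta > 0 else -np.inf
        return DeltaCResult(delta_c=delta, se=0.0, z=z, p=0.0, c_a=c_a, c_b=c_b)
    z = delta / se
    return DeltaCResult(
        delta_c=float(delta), se=se, z=float(z),
        p=float(2 * sps.norm.sf(abs(z))), c_a=c_a, c_b=c_b,
    )


def auc_binary(labels, scores) -> AucResult:
    """Mann–Whitney AUC with tie correction and a DeLong-style 95% CI."""
    y = np.asarray(labels).astype(float)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute AUC")

    # structural components (DeLong): psi(x, y) = 1[x>y] + 0.5*1[x==y]
    order = np.argsort(neg, kind="mergesort")
    neg_sorted = neg[order]
    lt = np.searchsorted(neg_sorted, pos, side="left")
    le = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lt + 0.5 * (le - lt)) / n  # per-positive
    order = np.argsort(pos, kind="mergesort")
    pos_sorted = pos[order]
    gt = m - np.searchsorted(pos_sorted, neg, side="right")
    ge = m - np.searchsorted(pos_sorted, neg, side="left")
    v01 = (gt + 0.5 * (ge - gt)) / m  # per-negative

    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    ci = (max(0.0, auc - _Z95 * se), min(1.0, auc + _Z95 * se))
    return AucResult(auc=auc, se=se, ci=ci)


def logistic_per_sd(labels, score, covariates: pd.DataFrame | None = None) -> OrResult:
    """Per-SD odds ratio from a maximum-likelihood logistic fit.

    The score is standardized (denominator n−1) before fitting so the OR is
    invariant to linear rescaling of the raw score.  Optional adjustment
    covariates enter additively.  Complete separation raises.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(labels).astype(float)
    s = np.asarray(score, dtype=float)
    sd = s.std(ddof=1)
    if not sd > 0:
        raise ValueError("score has zero SD")
    z = (s - s.mean()) / sd

    X = pd.DataFrame({"score_sd": z})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise ValueError(f"logistic fit failed (separation?): {err}") from err
    if not np.isfinite(fit.bse["score_sd"]) or fit.bse["score_sd"] > 1e3:
        raise ValueError("logistic fit unstable; possible complete separation")
    beta = float(fit.params["score_sd"])
    se = float(fit.bse["score_sd"])
    return OrResult(
        odds_ratio=float(np.exp(beta)),
        ci=(float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))),
        beta=beta,
        se=se,
        p=float(fit.pvalues["score_sd"]),
    )
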