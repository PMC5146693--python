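"""Fixed-effect inverse-variance meta-analysis with heterogeneity statistics.

Per-cohort estimates on an additive scale (log HR, ΔC, NRI, IDI) are pooled
with weights ``w_i = 1/se_i²``; heterogeneity is summarized by Cochran's Q
(chi-square with k−1 df) and ``I² = max(0, (Q − df)/Q) × 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

_Z95 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class StudyEstimate:
    label: str
    estimate: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"study {self.label!r}: se must be positive")


@dataclass
class MetaResult:
    estimate: float
    se: float
    ci: tuple
    k: int
    q: float | None = None
    df: int | None = None
    i2: float | None = None
    p_q: float | None = None

    @property
    def p(self) -> float:
        return float(2 * sps.norm.sf(abs(self.estimate / self.se)))


def se_from_ci(lo: float, hi: float, log_scale: bool = True) -> float:
    """Recover an SE from a printed 95% CI, (hi − lo)/(2·1.96); ratio-scale
    bounds (HR, OR) are log-transformed first."""
    if log_scale:
        lo, hi = np.log(lo), np.log(hi)
    if hi <= lo:
        raise ValueError("upper CI bound must exceed lower")
    return float((hi - lo) / (2 * _Z95))


def fixed_effect_meta(studies) -> MetaResult:
    """Inverse-variance pooled estimate; heterogeneity attached when k >= 2."""
    studies = list(studies)
    if not studies:
        raise ValueError("need at least one study")
    theta = np.array([s.estimate for s in studies], dtype=float)
    w = np.array([1.0 / s.se**2 for s in studies])
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    res = MetaResult(
        estimate=pooled,
        se=se,
        ci=(pooled - _Z95 * se, pooled + _Z95 * se),
        k=len(studies),
    )
    if len(studies) >= 2:
        q, df, i2, p_q = heterogeneity(studies, pooled)
        res.q, res.df, res.i2, res.p_q = q, df, i2, p_q
    return res


def heterogeneity(studies, pooled: float | None = None):
    """Cochran's Q, df, I² (percent) and the chi-square p-value.

    ``Q = sum w_i (theta_i − pooled)²`` with inverse-variance weights.
    Raises for fewer than two studies, where heterogeneity is undefined.
    """
    studies = list(studies)
    if len(studies) < 2:
        raise ValueError("heterogeneity undefined for fewer than two studies")
    theta = np.array([s.estimate for s in studies], dtype=float)
    w = np.array([1.0 / s.se**2 for s in studies])
    if pooled is None:
        pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(studies) - 1
    i2, p_q = i2_from_q(q, df)
    return q, df, i2, p_q


def i2_from_q(q: float, df: int):
    """I² (percent) and chi-square p implied by a Q statistic and its df."""
    if df < 1:
        raise ValueError("df must be >= 1")
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    p_q = float(sps.chi2.sf(q, df)) if q > 0 else 1.0
    return i2, p_q
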