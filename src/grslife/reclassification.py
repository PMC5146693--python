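"""Risk reclassification between two 10-year risk models.

Subjects are cross-tabulated by risk category under the old and new model,
separately for those who do and do not experience the event within the
horizon; categorical and continuous net reclassification improvement (NRI)
and integrated discrimination improvement (IDI) summarize the movement.
Standard-normal (Pencina-style) variance approximations are used for CIs
and p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

_Z95 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class RiskBins:
    """Risk-category cut points in percent; default (0, 7.5, 10, 20, 100).

    Categories are half-open ``[lo, hi)`` with the last bin closed at 100%,
    so a risk of exactly 7.5% falls in the second category.
    """

    cuts: tuple = (0.0, 7.5, 10.0, 20.0, 100.0)

    def __post_init__(self) -> None:
        c = np.asarray(self.cuts, dtype=float)
        if len(c) < 2 or np.any(np.diff(c) <= 0):
            raise ValueError("cut points must be strictly increasing")
        if c[0] != 0.0 or c[-1] != 100.0:
            raise ValueError("cut points must start at 0 and end at 100")

    @property
    def n_bins(self) -> int:
        return len(self.cuts) - 1

    @property
    def labels(self) -> list:
        return [
            f"{lo:g}–{hi:g}%" for lo, hi in zip(self.cuts[:-1], self.cuts[1:])
        ]


@dataclass
class ReclassTable:
    """Paired event and non-event old × new category cross-tabulations."""

    events: np.ndarray
    nonevents: np.ndarray
    bins: RiskBins = field(default_factory=RiskBins)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        k = self.bins.n_bins
        self.events = np.asarray(self.events, dtype=float)
        self.nonevents = np.asarray(self.nonevents, dtype=float)
        for m in (self.events, self.nonevents):
            if m.shape != (k, k):
                raise ValueError(f"count tables must be {k}x{k}")
            if np.any(m < 0):
                raise ValueError("counts must be non-negative")

    @property
    def all_individuals(self) -> np.ndarray:
        return self.events + self.nonevents

    @property
    def n_events(self) -> float:
        return float(self.events.sum())

    @property
    def n_nonevents(self) -> float:
        return float(self.nonevents.sum())

    def reclassified_pct(self, which: str = "events") -> np.ndarray:
        """Per-old-category percent reclassified, 100*(1 − diagonal/row)."""
        m = {"events": self.events, "nonevents": self.nonevents,
             "all": self.all_individuals}[which]
        row = m.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * (1.0 - np.diag(m) / row)
        return np.where(row > 0, pct, 0.0)

    def to_frame(self, which: str = "events") -> pd.DataFrame:
        m = {"events": self.events, "nonevents": self.nonevents,
             "all": self.all_individuals}[which]
        labels = self.bins.labels
        df = pd.DataFrame(m, index=labels, columns=labels)
        df["Total"] = m.sum(axis=1)
        df["Reclassified %"] = np.round(self.reclassified_pct(which), 1)
        return df


@dataclass
class NriResult:
    nri_events: float
    nri_nonevents: float
    nri_total: float
    se_events: float
    se_nonevents: float
    se_total: float

    def _ci(self, est, se):
        return (est - _Z95 * se, est + _Z95 * se)

    @property
    def ci_total(self):
        return self._ci(self.nri_total, self.se_total)

    @property
    def ci_events(self):
        return self._ci(self.nri_events, self.se_events)

    @property
    def ci_nonevents(self):
        return self._ci(self.nri_nonevents, self.se_nonevents)

    def p_value(self, which: str = "total") -> float:
        est, se = {
            "total": (self.nri_total, self.se_total),
            "events": (self.nri_events, self.se_events),
            "nonevents": (self.nri_nonevents, self.se_nonevents),
        }[which]
        if se == 0:
            return 1.0 if est == 0 else 0.0
        return float(2 * sps.norm.sf(abs(est / se)))


def assign_bins(risk, bins: RiskBins = RiskBins()) -> np.ndarray:
    """Risk category (1-based) per subject; risks are probabilities in [0,1].

    Intervals are ``[lo, hi)`` with the final bin closed at 100%.  NaN risks
    yield category 0 (caller excludes them).
    """
    r = np.asarray(risk, dtype=float)
    finite = np.isfinite(r)
    if np.any((r[finite] < 0) | (r[finite] > 1)):
        raise ValueError("risks must lie in [0, 1]")
    edges = np.asarray(bins.cuts, dtype=float) / 100.0
    cat = np.searchsorted(edges, r, side="right")
    cat = np.minimum(cat, bins.n_bins)  # risk == 1.0 belongs to the last bin
    return np.where(finite, cat, 0).astype(int)


def reclass_table(
    old_risk,
    new_risk,
    event10,
    bins: RiskBins = RiskBins(),
) -> ReclassTable:
    """Cross-tabulate old vs new risk categories for events and non-events.

    ``event10`` indicates the event within the classification horizon;
    subjects with missing risks or status are excluded with a logged count.
    """
    old_risk = np.asarray(old_risk, dtype=float)
    new_risk = np.asarray(new_risk, dtype=float)
    ev = np.asarray(event10, dtype=float)
    if not (len(old_risk) == len(new_risk) == len(ev)):
        raise ValueError("old_risk, new_risk and event10 must have equal length")

    ok = np.isfinite(old_risk) & np.isfinite(new_risk) & np.isfinite(ev)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluding %d subjects with missing inputs from reclassification",
                    n_excluded)
    old_cat = assign_bins(old_risk[ok], bins) - 1
    new_cat = assign_bins(new_risk[ok], bins) - 1
    is_event = ev[ok] == 1

    k = bins.n_bins
    events = np.zeros((k, k))
    nonevents = np.zeros((k, k))
    np.add.at(events, (old_cat[is_event], new_cat[is_event]), 1)
    np.add.at(nonevents, (old_cat[~is_event], new_cat[~is_event]), 1)
    return ReclassTable(events=events, nonevents=nonevents, bins=bins,
                        n_excluded=n_excluded)


def _updown(m: np.ndarray) -> tuple:
    ups = float(np.triu(m, k=1).sum())
    downs = float(np.tril(m, k=-1).sum())
    return ups, downs


def _nri_component(p_up, p_down, n):
    """Estimate and SE of p_up − p_down from sign proportions."""
    est = p_up - p_down
    var = (p_up + p_down) / n - est**2 / n
    return est, float(np.sqrt(max(var, 0.0)))


def categorical_nri(table: ReclassTable) -> NriResult:
    """Categorical NRI from paired cross-tabs.

    ``NRI_events = (ups − downs)/n_events`` over the event table (upward
    movement is correct for events), ``NRI_nonevents = (downs − ups)/
    n_nonevents`` over the non-event table, total their sum.
    """
    n_e, n_ne = table.n_events, table.n_nonevents
    if n_e < 1 or n_ne < 1:
        raise ValueError("need at least one event and one non-event")
    ups_e, downs_e = _updown(table.events)
    ups_ne, downs_ne = _updown(table.nonevents)
    nri_e, se_e = _nri_component(ups_e / n_e, downs_e / n_e, n_e)
    nri_ne, se_ne = _nri_component(downs_ne / n_ne, ups_ne / n_ne, n_ne)
    return NriResult(
        nri_events=nri_e,
        nri_nonevents=nri_ne,
        nri_total=nri_e + nri_ne,
        se_events=se_e,
        se_nonevents=se_ne,
        se_total=float(np.sqrt(se_e**2 + se_ne**2)),
    )


def continuous_nri(old_risk, new_risk, event10) -> NriResult:
    """Category-free NRI from the signs of risk changes; ties contribute 0."""
    old_risk = np.asarray(old_risk, dtype=float)
    new_risk = np.asarray(new_risk, dtype=float)
    ev = np.asarray(event10, dtype=float)
    ok = np.isfinite(old_risk) & np.isfinite(new_risk) & np.isfinite(ev)
    d = new_risk[ok] - old_risk[ok]
    is_event = ev[ok] == 1
    n_e = int(is_event.sum())
    n_ne = int((~is_event).sum())
    if n_e < 1 or n_ne < 1:
        raise ValueError("need at least one event and one non-event")
    nri_e, se_e = _nri_component(
        np.mean(d[is_event] > 0), np.mean(d[is_event] < 0), n_e
    )
    nri_ne, se_ne = _nri_component(
        np.mean(d[~is_event] < 0), np.mean(d[~is_event] > 0), n_ne
    )
    return NriResult(
        nri_events=nri_e,
        nri_nonevents=nri_ne,
        nri_total=nri_e + nri_ne,
        se_events=se_e,
        se_nonevents=se_ne,
        se_total=float(np.sqrt(se_e**2 + se_ne**2)),
    )


@dataclass
class IdiResult:
    idi: float
    se: float

    @property
    def ci(self):
        return (self.idi - _Z95 * self.se, self.idi + _Z95 * self.se)

    @property
    def p(self) -> float:
        if self.se == 0:
            return 1.0 if self.idi == 0 else 0.0
        return float(2 * sps.norm.sf(abs(self.idi / self.se)))


def idi(old_risk, new_risk, event10) -> IdiResult:
    """Integrated discrimination improvement: the change in discrimination
    slope, ``(mean Δrisk | events) − (mean Δrisk | non-events)``, with SE
    from the two independent paired-mean differences.
    """
    old_risk = np.asarray(old_risk, dtype=float)
    new_risk = np.asarray(new_risk, dtype=float)
    ev = np.asarray(event10, dtype=float)
    ok = np.isfinite(old_risk) & np.isfinite(new_risk) & np.isfinite(ev)
    d = new_risk[ok] - old_risk[ok]
    is_event = ev[ok] == 1
    n_e = int(is_event.sum())
    n_ne = int((~is_event).sum())
    if n_e < 1 or n_ne < 1:
        raise ValueError("need at least one event and one non-event")
    de, dne = d[is_event], d[~is_event]
    est = float(de.mean() - dne.mean())
    var = (de.var(ddof=1) / n_e if n_e > 1 else 0.0) + (
        dne.var(ddof=1) / n_ne if n_ne > 1 else 0.0
    )
    return IdiResult(idi=est, se=float(np.sqrt(var)))
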