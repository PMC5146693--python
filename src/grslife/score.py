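"""Construction of the genomic risk score (GRS).

A GRS is the weighted sum of effect-allele dosages, ``raw_i = sum_j w_j g_ij``,
with weights ``w_j`` taken as per-allele log odds from an external GWAS
meta-analysis.  Before scoring, summary statistics and cohort genotypes are
harmonized to count the same allele; the SNP set is thinned by linkage
disequilibrium (greedy, p-value-priority clumping) at a grid of r² thresholds,
and the threshold maximizing case/control AUC is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default r² grid for threshold selection (descending; 0.7 is the
#: conventionally reported optimum for CHD scores of this kind)
DEFAULT_R2_GRID = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.3, 0.1)

STATS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "weight", "se", "pvalue", "eaf",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G SNPs cannot be oriented across strands by alleles alone."""
    return _COMPLEMENT.get(str(a1).upper()) == str(a2).upper()


@dataclass
class GenotypeDosage:
    """Sample × SNP effect-allele dosage matrix with values in [0, 2].

    ``snps`` is a DataFrame with columns snp_id, chrom, pos, effect_allele
    (the counted / ALT allele) and other_allele (REF).  Missing dosages are
    represented as NaN.
    """

    sample_ids: np.ndarray
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad & ~np.isnan(self.dosage)):
            raise ValueError("dosages must lie in [0, 2] where present")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(self, snp_ids) -> "GenotypeDosage":
        idx = pd.Index(self.snps["snp_id"])
        locs = idx.get_indexer(list(snp_ids))
        if np.any(locs < 0):
            missing = [s for s, l in zip(snp_ids, locs) if l < 0]
            raise KeyError(f"SNPs not present in genotypes: {missing[:5]}")
        return GenotypeDosage(
            sample_ids=self.sample_ids,
            snps=self.snps.iloc[locs].reset_index(drop=True),
            dosage=self.dosage[:, locs],
        )

    def allele_frequencies(self) -> np.ndarray:
        """Effect-allele frequency per SNP: column mean dosage / 2."""
        return np.nanmean(self.dosage, axis=0) / 2.0


@dataclass
class ScoreVector:
    """Per-sample GRS on raw and standardized (mean 0, SD 1) scales."""

    sample_ids: np.ndarray
    raw: np.ndarray
    standardized: np.ndarray | None
    n_snps_used: int
    coverage: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw": self.raw,
                "standardized": self.standardized,
            }
        )


@dataclass
class ThinningResult:
    """Outcome of r² threshold selection over a grid."""

    r2_threshold: float
    kept_snp_ids: list
    report: pd.DataFrame = field(repr=False)


def validate_summary_stats(stats: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STATS_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if stats["snp_id"].duplicated().any():
        dups = stats.loc[stats["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_ids in summary statistics: {dups[:5]}")
    pv = stats["pvalue"].dropna()
    if ((pv <= 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    same = stats["effect_allele"].astype(str) == stats["other_allele"].astype(str)
    if same.any():
        raise ValueError("effect and other allele identical for some SNPs")
    return stats


def harmonize_alleles(
    stats: pd.DataFrame,
    geno: GenotypeDosage,
    ambiguity_margin: float = 0.08,
) -> tuple[pd.DataFrame, GenotypeDosage, dict]:
    """Align summary statistics and genotypes to count the same allele.

    SNPs are matched by id.  Where the cohort's counted (ALT) allele equals
    the statistics' *other* allele, the dosage column is reflected
    ``g <- 2 - g``.  Strand-ambiguous SNPs (A/T, C/G) are dropped unless
    |eaf - 0.5| > ``ambiguity_margin`` and the cohort frequency is concordant
    with the reported eaf; SNPs whose allele pairs cannot be reconciled are
    dropped.  Returns aligned (stats, geno) in matched order plus a log of
    counts.
    """
    validate_summary_stats(stats)
    stats = stats.reset_index(drop=True)
    geno_idx = pd.Index(geno.snps["snp_id"])
    locs = geno_idx.get_indexer(stats["snp_id"])
    matched = locs >= 0

    keep_stats_rows: list[int] = []
    keep_geno_cols: list[int] = []
    flip: list[bool] = []
    n_flipped = n_ambiguous_dropped = n_mismatch = 0

    g_ea = geno.snps["effect_allele"].astype(str).str.upper().to_numpy()
    g_oa = geno.snps["other_allele"].astype(str).str.upper().to_numpy()
    cohort_freq = geno.allele_frequencies()

    for i in np.flatnonzero(matched):
        j = locs[i]
        s_ea = str(stats.at[i, "effect_allele"]).upper()
        s_oa = str(stats.at[i, "other_allele"]).upper()
        direct = (g_ea[j] == s_ea) and (g_oa[j] == s_oa)
        swapped = (g_ea[j] == s_oa) and (g_oa[j] == s_ea)
        if not (direct or swapped):
            n_mismatch += 1
            continue
        if is_strand_ambiguous(s_ea, s_oa):
            eaf = stats.at[i, "eaf"]
            if not np.isfinite(eaf) or abs(eaf - 0.5) <= ambiguity_margin:
                n_ambiguous_dropped += 1
                continue
            # orient by frequency: the cohort ALT frequency should sit on the
            # same side of 0.5 as the reported eaf (possibly after reflection)
            direct = abs(cohort_freq[j] - eaf) <= abs(cohort_freq[j] - (1 - eaf))
            swapped = not direct
        keep_stats_rows.append(i)
        keep_geno_cols.append(j)
        flip.append(bool(swapped))
        n_flipped += int(swapped)

    if not keep_stats_rows:
        raise ValueError("no SNPs could be harmonized between summary stats and genotypes")

    stats_h = stats.iloc[keep_stats_rows].reset_index(drop=True)
    dosage = geno.dosage[:, keep_geno_cols].copy()
    snps_h = geno.snps.iloc[keep_geno_cols].reset_index(drop=True).copy()
    flip_arr = np.asarray(flip)
    if flip_arr.any():
        dosage[:, flip_arr] = 2.0 - dosage[:, flip_arr]
        snps_h.loc[flip_arr, ["effect_allele", "other_allele"]] = snps_h.loc[
            flip_arr, ["other_allele", "effect_allele"]
        ].to_numpy()

    log = {
        "n_input": len(stats),
        "n_matched": int(matched.sum()),
        "n_kept": len(keep_stats_rows),
        "n_flipped": n_flipped,
        "n_ambiguous_dropped": n_ambiguous_dropped,
        "n_allele_mismatch": n_mismatch,
        "n_unmatched": int((~matched).sum()),
    }
    logger.info("harmonized alleles: %s", log)
    geno_h = GenotypeDosage(sample_ids=geno.sample_ids, snps=snps_h, dosage=dosage)
    return stats_h, geno_h, log


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns.

    Computed over pairwise-complete samples; returns NaN (with a warning) if
    fewer than two complete pairs remain or either column has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        logger.warning("ld_r2: fewer than two complete pairs; undefined")
        return np.nan
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        logger.warning("ld_r2: zero variance column; r^2 undefined")
        return np.nan
    sxy = float(dx @ dy)
    return (sxy * sxy) / (sxx * syy)


def _thin_order(stats: pd.DataFrame) -> np.ndarray:
    """Visit order for greedy thinning: ascending p, ties by (chrom, pos)."""
    key = stats[["pvalue", "chrom", "pos"]].copy()
    key["chrom"] = key["chrom"].astype(str)
    return np.asarray(
        key.sort_values(["pvalue", "chrom", "pos"], kind="mergesort").index
    )


def ld_thin(
    stats: pd.DataFrame,
    geno: GenotypeDosage,
    r2_threshold: float,
    window_bp: int = 1_000_000,
) -> list:
    """Greedy LD thinning ("clumping") of SNPs at an r² threshold.

    SNPs are visited in ascending p-value order (ties broken by chromosome
    then position); a SNP is kept unless its dosage r² with an already-kept
    SNP within ``window_bp`` exceeds the threshold.  Undefined r² (degenerate
    columns) is treated as 0.  Returns kept snp_ids in the order of the input
    summary statistics.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in (0, 1]")
    stats = stats.reset_index(drop=True)
    geno = geno.subset(stats["snp_id"])

    D = geno.dosage
    has_nan = np.isnan(D).any()
    if not has_nan:
        # precenter once for fast vectorized r^2 against kept columns
        Dc = D - D.mean(axis=0)
        ss = np.einsum("ij,ij->j", Dc, Dc)

    chrom = stats["chrom"].astype(str).to_numpy()
    pos = stats["pos"].to_numpy()
    order = _thin_order(stats)

    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for j in order:
        neighbours = [
            k
            for k in kept_by_chrom.get(chrom[j], [])
            if abs(pos[k] - pos[j]) <= window_bp
        ]
        keep = True
        if neighbours:
            if has_nan:
                r2s = np.array([ld_r2(D[:, j], D[:, k]) for k in neighbours])
            else:
                if ss[j] == 0.0:
                    r2s = np.zeros(len(neighbours))
                else:
                    num = Dc[:, neighbours].T @ Dc[:, j]
                    den = ss[neighbours] * ss[j]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        r2s = np.where(den > 0, (num * num) / den, np.nan)
            r2s = np.nan_to_num(r2s, nan=0.0)
            keep = not np.any(r2s > r2_threshold)
        if keep:
            kept.append(j)
            kept_by_chrom.setdefault(chrom[j], []).append(j)

    kept_sorted = sorted(kept)
    return stats.loc[kept_sorted, "snp_id"].tolist()


def compute_grs(
    stats: pd.DataFrame,
    geno: GenotypeDosage,
    snp_subset=None,
) -> ScoreVector:
    """Weighted per-sample score ``raw_i = sum_j w_j g_ij`` over a SNP subset.

    Missing dosages are mean-imputed as ``2 * eaf_j`` so scores remain
    comparable across samples with different missingness.  SNPs with missing
    weights (e.g. flagged monomorphic) are skipped and counted against
    coverage.  Inputs are assumed harmonized.
    """
    stats = stats.reset_index(drop=True)
    if snp_subset is None:
        requested = stats["snp_id"].tolist()
    else:
        requested = list(snp_subset)
    if len(requested) == 0:
        raise ValueError("empty SNP subset: cannot compute a score")

    sub = stats.set_index("snp_id")
    present = [
        s
        for s in requested
        if s in sub.index
        and np.isfinite(sub.at[s, "weight"])
        and s in set(geno.snps["snp_id"])
    ]
    if not present:
        raise ValueError("no requested SNPs with usable weights found in genotypes")

    g = geno.subset(present)
    w = sub.loc[present, "weight"].to_numpy(dtype=float)
    eaf = sub.loc[present, "eaf"].to_numpy(dtype=float)

    D = g.dosage
    if np.isnan(D).any():
        fill = np.where(np.isfinite(eaf), 2.0 * eaf, 2.0 * g.allele_frequencies())
        D = np.where(np.isnan(D), fill[None, :], D)
    raw = D @ w

    sd = raw.std(ddof=1) if len(raw) > 1 else 0.0
    standardized = (raw - raw.mean()) / sd if sd > 0 else None
    return ScoreVector(
        sample_ids=g.sample_ids,
        raw=raw,
        standardized=standardized,
        n_snps_used=len(present),
        coverage=len(present) / len(requested),
    )


def standardize_score(score: ScoreVector) -> ScoreVector:
    """Centre and scale the raw score to mean 0, SD 1 (denominator n-1)."""
    raw = np.asarray(score.raw, dtype=float)
    sd = raw.std(ddof=1)
    if not sd > 0:
        raise ValueError("raw score is constant across samples; SD is zero so the score cannot be standardized")
    return ScoreVector(
        sample_ids=score.sample_ids,
        raw=raw,
        standardized=(raw - raw.mean()) / sd,
        n_snps_used=score.n_snps_used,
        coverage=score.coverage,
    )


def select_r2_threshold(
    stats: pd.DataFrame,
    geno: GenotypeDosage,
    outcome: np.ndarray,
    grid=DEFAULT_R2_GRID,
    window_bp: int = 1_000_000,
) -> ThinningResult:
    """Thin, score and evaluate at each r² threshold; pick the AUC maximizer.

    For each threshold the kept set is scored, and discrimination of the
    binary ``outcome`` is measured by AUC together with the per-SD logistic
    odds ratio.  Ties in AUC are broken toward the larger threshold (fewer
    SNPs removed).
    """
    from grslife.discrimination import auc_binary, logistic_per_sd

    grid = sorted(set(grid), reverse=True)
    if not grid:
        raise ValueError("empty threshold grid")
    outcome = np.asarray(outcome)
    if len(np.unique(outcome[~pd.isna(outcome)])) < 2:
        raise ValueError("outcome must contain both classes")

    rows = []
    best = None
    kept_best: list = []
    for thr in grid:
        kept = ld_thin(stats, geno, thr, window_bp=window_bp)
        sv = standardize_score(compute_grs(stats, geno, kept))
        auc = auc_binary(outcome, sv.standardized)
        orr = logistic_per_sd(outcome, sv.raw)
        rows.append(
            {
                "r2_threshold": thr,
                "n_kept": len(kept),
                "auc": auc.auc,
                "auc_lo": auc.ci[0],
                "auc_hi": auc.ci[1],
                "or_per_sd": orr.odds_ratio,
                "or_lo": orr.ci[0],
                "or_hi": orr.ci[1],
            }
        )
        if best is None or auc.auc > best:
            best = auc.auc
            best_thr = thr
            kept_best = kept
    report = pd.DataFrame(rows)
    return ThinningResult(r2_threshold=best_thr, kept_snp_ids=kept_best, report=report)
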