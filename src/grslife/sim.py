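"""Synthetic cohorts with the structure the GRS survival analysis assumes.

The generator produces three linked artifacts from one seeded config:

* genotype dosages with block-wise linkage disequilibrium — two haplotypes
  per person, each obtained by thresholding a latent AR(1) Gaussian at
  ``Phi^-1(1 - MAF)``, so dosages are exact {0,1,2} and adjacent within-block
  r² is tunable through ``rho``;
* GWAS-style summary statistics — per-SNP weights equal to the true log
  hazard effects plus Gaussian noise with the standard log-odds standard
  error ``1 / sqrt(2 p (1-p) N)`` at an effective sample size ``gwas_n``;
* a survival cohort — entry ages from a truncated-normal baseline-age
  distribution, CHD event ages from a Weibull proportional-hazards model on
  the age scale (sampled conditionally on surviving to entry, so delayed
  entry / left truncation is always exercised), an independent competing
  non-CHD mortality process, administrative censoring, and clinical
  covariates with configurable means/prevalences and log-hazard effects.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, logit

from grslife.score import GenotypeDosage, STATS_COLUMNS

logger = logging.getLogger(__name__)

EVENT_CHD = "chd"
EVENT_COMPETING = "death_other"
EVENT_CENSORED = "censored"

#: population-style defaults for baseline covariates: (mean, SD) for
#: continuous, prevalence for binary.  Units: years, mmHg, mmol/L.
DEFAULT_BASELINE_COVARIATES = {
    "age": (45.97, 12.7),
    "sbp": (134.93, 19.7),
    "total_chol": (5.58, 1.11),
    "hdl_chol": (1.45, 0.38),
    "smoking": 0.26,
    "diabetes": 0.05,
    "male": 0.46,
    "lipid_treatment": 0.03,
    "bp_treatment": 0.11,
}

#: log hazard ratios of baseline covariates on the CHD cause-specific hazard;
#: continuous covariates act per SD, binary covariates per indicator.
DEFAULT_COVARIATE_LOG_HRS = {
    "smoking": 0.6,
    "sbp": 0.3,
    "total_chol": 0.25,
    "hdl_chol": -0.25,
    "diabetes": 0.6,
    "male": 0.7,
}

COHORT_COLUMNS = [
    "sample_id", "sex", "entry_age", "exit_age", "event", "prevalent_cvd",
    "smoking", "sbp", "total_chol", "hdl_chol", "diabetes",
    "lipid_treatment", "bp_treatment", "family_history", "cohort", "region",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Baseline-hazard defaults are calibrated so that, with the default
    covariate structure, roughly 6% of subjects have an incident CHD event
    within follow-up before attained age 75 and roughly 20% would die of
    other causes before 75.
    """

    n_samples: int = 5000
    n_snps: int = 2000
    block_size: int = 20
    rho: float = 0.8
    maf_range: tuple = (0.05, 0.5)
    prop_causal: float = 0.1
    causal_beta_sd: float = 0.08
    target_hr_per_sd: float = 1.74
    gwas_n: float = 200_000.0
    baseline_covariates: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_COVARIATES)
    )
    covariate_log_hrs: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LOG_HRS)
    )
    weibull_shape: float = 6.0
    weibull_scale: float = 110.0
    competing_shape: float = 8.0
    competing_scale: float = 90.5
    competing_log_hrs: dict = field(
        default_factory=lambda: {"smoking": 0.35, "male": 0.4}
    )
    admin_censor_years: float = 15.0
    prevalent_fraction: float = 0.03
    family_history_beta: float = 0.3
    family_history_prevalence: float = 0.15
    entry_age_range: tuple = (25.0, 74.0)
    pos_spacing_bp: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_snps < 1 or self.block_size < 1:
            raise ValueError("invalid simulation dimensions")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 < self.prop_causal <= 1):
            raise ValueError("prop_causal must lie in (0, 1]")
        for name in ("weibull_shape", "weibull_scale", "competing_shape",
                     "competing_scale", "admin_censor_years", "target_hr_per_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per generation stage."""
        return np.random.default_rng([int(self.seed), stream])

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("maf_range", "entry_age_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["entry_age_range"] = list(self.entry_age_range)
        return d


@dataclass
class TrueModel:
    """Generative truth the pipeline should recover."""

    causal_betas: np.ndarray
    true_score: np.ndarray
    covariate_betas: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "causal_betas": np.asarray(self.causal_betas).tolist(),
                "true_score": np.asarray(self.true_score).tolist(),
                "covariate_betas": self.covariate_betas,
            }
        )


def _simulate_haplotype_latents(rng, n, n_snps, block_size, rho):
    """Latent AR(1) Gaussians for one haplotype set, block-diagonal LD."""
    z = rng.standard_normal((n, n_snps))
    if rho > 0 and block_size > 1:
        c = np.sqrt(1.0 - rho * rho)
        for start in range(0, n_snps, block_size):
            stop = min(start + block_size, n_snps)
            for j in range(start + 1, stop):
                z[:, j] = rho * z[:, j - 1] + c * z[:, j]
    return z


def simulate_genotypes(config: SimConfig) -> GenotypeDosage:
    """Dosages in {0,1,2}: two latent-Gaussian-thresholded haplotypes summed.

    Within a block, adjacent latent variables follow an AR(1) with parameter
    ``rho``; across blocks SNPs are independent, so dosage r² decays within
    blocks and vanishes between them.
    """
    rng = config.rng(0)
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    thresh = sps.norm.ppf(1.0 - maf)  # latent > thresh -> carries effect allele
    hap = np.zeros((config.n_samples, config.n_snps), dtype=np.int8)
    for _ in range(2):
        z = _simulate_haplotype_latents(
            rng, config.n_samples, config.n_snps, config.block_size, config.rho
        )
        hap += (z > thresh[None, :]).astype(np.int8)

    alleles_ref = rng.choice(np.array(["A", "C"]), size=config.n_snps)
    alt = np.where(alleles_ref == "A", "G", "T")  # never strand-ambiguous
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(config.n_snps)],
            "chrom": "1",
            "pos": 1 + np.arange(config.n_snps) * config.pos_spacing_bp,
            "effect_allele": alt,
            "other_allele": alleles_ref,
        }
    )
    sample_ids = np.array([f"S{i:06d}" for i in range(config.n_samples)])
    return GenotypeDosage(sample_ids=sample_ids, snps=snps, dosage=hap.astype(float))


def simulate_true_model(geno: GenotypeDosage, config: SimConfig) -> TrueModel:
    """Draw sparse causal effects and the implied per-sample true score."""
    rng = config.rng(1)
    m = geno.n_snps
    n_causal = max(1, int(round(config.prop_causal * m)))
    causal_idx = rng.choice(m, size=n_causal, replace=False)
    betas = np.zeros(m)
    betas[causal_idx] = rng.normal(0.0, config.causal_beta_sd, size=n_causal)
    true_score = geno.dosage @ betas
    return TrueModel(
        causal_betas=betas,
        true_score=true_score,
        covariate_betas=dict(config.covariate_log_hrs),
    )


def simulate_summary_stats(
    geno: GenotypeDosage, truth: TrueModel, config: SimConfig
) -> pd.DataFrame:
    """GWAS-style weights: true effect + noise at the log-odds standard error.

    ``SE_j = 1 / sqrt(2 p_j (1 - p_j) gwas_n)`` with ``p_j`` the empirical
    effect-allele frequency; p-values are two-sided Wald.  Monomorphic SNPs
    are flagged and given missing weight/SE.
    """
    if len(truth.causal_betas) != geno.n_snps:
        raise ValueError("truth dimensions do not match genotypes")
    rng = config.rng(2)
    p = geno.allele_frequencies()
    poly = (p > 0) & (p < 1)
    se = np.full(geno.n_snps, np.nan)
    if np.isfinite(config.gwas_n):
        se[poly] = 1.0 / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]) * config.gwas_n)
    else:
        se[poly] = 0.0
    weight = np.where(poly, truth.causal_betas + se * rng.standard_normal(geno.n_snps), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, weight / se, np.where(weight == 0, 0.0, np.inf))
    pvalue = np.where(poly, 2.0 * sps.norm.sf(np.abs(z)), np.nan)
    pvalue = np.where(np.isfinite(pvalue), np.maximum(pvalue, 5e-324), pvalue)

    out = geno.snps.copy()
    out["weight"] = weight
    out["se"] = se
    out["pvalue"] = pvalue
    out["eaf"] = p
    out["flag"] = np.where(poly, "", "monomorphic")
    if (~poly).any():
        logger.warning("%d monomorphic SNPs flagged with missing weights", int((~poly).sum()))
    return out[STATS_COLUMNS + ["flag"]]


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _left_truncated_weibull(rng, entry, lp, shape, scale):
    """Sample T from S(t) = exp(-(t/scale)^shape * e^lp) given T > entry."""
    u = rng.random(len(entry))
    u = np.clip(u, np.finfo(float).tiny, 1.0 - 1e-16)
    return scale * ((entry / scale) ** shape - np.log(u) * np.exp(-lp)) ** (1.0 / shape)


def simulate_phenotypes(
    geno: GenotypeDosage, truth: TrueModel, config: SimConfig
) -> pd.DataFrame:
    """Survival records plus clinical covariates under a Weibull PH model.

    The CHD log hazard is ``log(target_hr_per_sd) * z`` (z = standardized
    true score) plus covariate terms; competing non-CHD death is drawn
    independently from its own Weibull.  The observed record is
    ``(entry age, min(event ages, entry + admin_censor_years), event type)``.
    Censoring at attained age 75 is *not* applied here — that is the job of
    :func:`apply_cohort_filters`.
    """
    rng = config.rng(3)
    n = geno.n_samples
    bc = config.baseline_covariates

    entry = _truncnorm(rng, *bc["age"], *config.entry_age_range, n)
    sbp = np.maximum(rng.normal(*bc["sbp"], n), 70.0)
    tc = np.maximum(rng.normal(*bc["total_chol"], n), 1.5)
    hdl = np.maximum(rng.normal(*bc["hdl_chol"], n), 0.3)
    smoking = (rng.random(n) < bc["smoking"]).astype(int)
    diabetes = (rng.random(n) < bc["diabetes"]).astype(int)
    male = (rng.random(n) < bc["male"]).astype(int)
    lipid_tx = (rng.random(n) < bc["lipid_treatment"]).astype(int)
    bp_tx = (rng.random(n) < bc["bp_treatment"]).astype(int)

    ts = np.asarray(truth.true_score, dtype=float)
    sd_ts = ts.std(ddof=1)
    z = (ts - ts.mean()) / sd_ts if sd_ts > 0 else np.zeros(n)

    cb = truth.covariate_betas
    std = {
        "sbp": (sbp - bc["sbp"][0]) / bc["sbp"][1],
        "total_chol": (tc - bc["total_chol"][0]) / bc["total_chol"][1],
        "hdl_chol": (hdl - bc["hdl_chol"][0]) / bc["hdl_chol"][1],
        "smoking": smoking,
        "diabetes": diabetes,
        "male": male,
    }
    lp_chd = np.log(config.target_hr_per_sd) * z
    for name, beta in cb.items():
        lp_chd = lp_chd + beta * std[name]
    lp_death = np.zeros(n)
    for name, beta in config.competing_log_hrs.items():
        lp_death = lp_death + beta * std[name]

    t_chd = _left_truncated_weibull(rng, entry, lp_chd, config.weibull_shape, config.weibull_scale)
    t_death = _left_truncated_weibull(
        rng, entry, lp_death, config.competing_shape, config.competing_scale
    )
    t_admin = entry + config.admin_censor_years

    exit_age = np.minimum.reduce([t_chd, t_death, t_admin])
    exit_age = np.maximum(exit_age, entry + 1e-6)
    event = np.full(n, EVENT_CENSORED, dtype=object)
    event[(exit_age == t_death)] = EVENT_COMPETING
    event[(exit_age == t_chd)] = EVENT_CHD

    fh_logit = logit(config.family_history_prevalence) + config.family_history_beta * z
    family_history = (rng.random(n) < expit(fh_logit)).astype(int)
    prevalent = (rng.random(n) < config.prevalent_fraction).astype(int)
    cohort = rng.choice(np.array(["c92", "c97", "c02"]), size=n)
    region = rng.choice(np.array(["east", "west"]), size=n)

    return pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "sex": np.where(male == 1, "male", "female"),
            "entry_age": entry,
            "exit_age": exit_age,
            "event": event,
            "prevalent_cvd": prevalent,
            "smoking": smoking,
            "sbp": sbp,
            "total_chol": tc,
            "hdl_chol": hdl,
            "diabetes": diabetes,
            "lipid_treatment": lipid_tx,
            "bp_treatment": bp_tx,
            "family_history": family_history,
            "cohort": cohort,
            "region": region,
        }
    )


def simulate_dataset(config: SimConfig):
    """Convenience: (genotypes, truth, summary stats, cohort) from one config."""
    geno = simulate_genotypes(config)
    truth = simulate_true_model(geno, config)
    stats = simulate_summary_stats(geno, truth, config)
    cohort = simulate_phenotypes(geno, truth, config)
    return geno, truth, stats, cohort


def apply_cohort_filters(
    cohort: pd.DataFrame,
    min_baseline_age: float | None = None,
    censor_age: float = 75.0,
) -> pd.DataFrame:
    """Study exclusion and censoring rules; input left unchanged.

    Removes subjects with prevalent cardiovascular disease at baseline and,
    when ``min_baseline_age`` is given, subjects younger than it at entry.
    Exit ages are truncated at ``censor_age`` with events after truncation
    recoded as censored.  Records whose exit would not exceed their entry
    after truncation are dropped with a logged warning.  Idempotent.
    """
    if min_baseline_age is not None and censor_age <= min_baseline_age:
        raise ValueError("censor_age must exceed min_baseline_age")
    out = cohort.copy()
    if len(out) == 0:
        return out

    if "prevalent_cvd" in out.columns:
        n_prev = int((out["prevalent_cvd"] == 1).sum())
        if n_prev:
            logger.info("excluding %d subjects with prevalent CVD at baseline", n_prev)
        out = out[out["prevalent_cvd"] != 1]
    if min_baseline_age is not None:
        n_young = int((out["entry_age"] < min_baseline_age).sum())
        if n_young:
            logger.info("excluding %d subjects younger than %.0f at baseline",
                        n_young, min_baseline_age)
        out = out[out["entry_age"] >= min_baseline_age]

    over = out["exit_age"] > censor_age
    out.loc[over, "event"] = EVENT_CENSORED
    out.loc[over, "exit_age"] = censor_age

    degenerate = out["exit_age"] <= out["entry_age"]
    if degenerate.any():
        logger.warning(
            "dropping %d records with exit age <= entry age after censoring at %.0f",
            int(degenerate.sum()), censor_age,
        )
        out = out[~degenerate]
    return out.reset_index(drop=True)
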