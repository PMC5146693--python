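"""Clinical 10-year risk equations as coefficient-table engines.

Cox-equation risk scores of the Framingham family have the common form

    risk = 1 − S0 ^ exp(LP − LPbar)

with a sex-stratified linear predictor ``LP = Σ_k β_k · Π_f transform(scale·x)``
over (possibly interacted) covariate terms, a per-stratum baseline 10-year
survival ``S0`` and mean linear predictor ``LPbar``.  Coefficients ship as
versioned data files (a JSON manifest plus a TSV term table); two scores are
bundled: a Framingham general-CVD variant ("frs") and the ACC/AHA 2013
pooled-cohort equations, white strata ("accaha13" — populations without a
recorded race are mapped to the white stratum, which is logged).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BUILTIN_SCORES = {
    "frs": "frs_general_cvd_2008",
    "accaha13": "pce_accaha_2013_white",
}

_TRANSFORMS = {
    "identity": lambda x: x,
    "log": np.log,
    "complement": lambda x: 1.0 - x,
}


@dataclass(frozen=True)
class Term:
    """One additive term: coefficient times a product of transformed covariates."""

    name: str
    covariates: tuple
    transforms: tuple
    scales: tuple
    coefficient: float

    def evaluate(self, cohort: pd.DataFrame) -> np.ndarray:
        val = np.full(len(cohort), self.coefficient, dtype=float)
        for cov, tr, sc in zip(self.covariates, self.transforms, self.scales):
            x = cohort[cov].to_numpy(dtype=float) * sc
            if tr == "log":
                with np.errstate(invalid="ignore", divide="ignore"):
                    t = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
            else:
                t = _TRANSFORMS[tr](x)
            val = val * t
        return val


@dataclass
class Stratum:
    s0: float
    lp_mean: float
    terms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.s0 < 1):
            raise ValueError("baseline 10-year survival S0 must lie in (0, 1)")


@dataclass
class ClinicalScoreConfig:
    name: str
    version: str
    strata: dict  # stratum label -> Stratum

    def required_covariates(self) -> set:
        out = set()
        for s in self.strata.values():
            for t in s.terms:
                out.update(t.covariates)
        return out


@dataclass
class Risk10Vector:
    sample_ids: np.ndarray
    risk: np.ndarray
    linear_predictor: np.ndarray


def load_clinical_score(source) -> ClinicalScoreConfig:
    """Load a score from a bundled name ('frs', 'accaha13') or manifest path."""
    if isinstance(source, str) and source in BUILTIN_SCORES:
        base = BUILTIN_SCORES[source]
        pkg = resources.files("grslife.data")
        manifest = json.loads(pkg.joinpath(f"{base}.manifest.json").read_text())
        terms = pd.read_csv(
            pkg.joinpath(f"{base}.terms.tsv").open("r"), sep="\t"
        )
    else:
        from pathlib import Path

        path = Path(source)
        manifest = json.loads(path.read_text())
        terms = pd.read_csv(path.with_suffix("").with_suffix(".terms.tsv"), sep="\t")
    return _build_config(manifest, terms)


def _build_config(manifest: dict, terms: pd.DataFrame) -> ClinicalScoreConfig:
    strata = {}
    for label, meta in manifest["strata"].items():
        rows = terms[terms["stratum"] == label]
        tl = []
        for _, r in rows.iterrows():
            covs = tuple(str(r["covariates"]).split("|"))
            trs = tuple(str(r["transforms"]).split("|"))
            scales = tuple(float(v) for v in str(r["scales"]).split("|"))
            bad = set(trs) - set(_TRANSFORMS)
            if bad:
                raise ValueError(f"unknown transforms {bad} in term {r['term']!r}")
            if not (len(covs) == len(trs) == len(scales)):
                raise ValueError(f"inconsistent factor lists in term {r['term']!r}")
            tl.append(
                Term(
                    name=str(r["term"]),
                    covariates=covs,
                    transforms=trs,
                    scales=scales,
                    coefficient=float(r["coefficient"]),
                )
            )
        strata[label] = Stratum(s0=float(meta["s0"]), lp_mean=float(meta["lp_mean"]), terms=tl)
    return ClinicalScoreConfig(
        name=manifest["name"], version=manifest.get("version", ""), strata=strata
    )


def _stratum_labels(cohort: pd.DataFrame, config: ClinicalScoreConfig) -> pd.Series:
    labels = cohort["sex"].astype(str)
    unknown = set(labels.unique()) - set(config.strata)
    if unknown:
        raise ValueError(f"cohort strata {sorted(unknown)} not defined for {config.name}")
    return labels


def linear_predictor(cohort: pd.DataFrame, config: ClinicalScoreConfig) -> pd.Series:
    """Per-subject LP within the subject's sex stratum.

    Subjects with a missing or non-positive-under-log covariate get NaN and
    are thereby excluded from downstream reclassification; the count is
    logged.
    """
    need = config.required_covariates()
    missing = need - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort lacks covariates required by {config.name}: {sorted(missing)}")
    labels = _stratum_labels(cohort, config)
    lp = np.full(len(cohort), np.nan)
    for label, stratum in config.strata.items():
        mask = (labels == label).to_numpy()
        if not mask.any():
            continue
        sub = cohort.loc[mask]
        total = np.zeros(mask.sum())
        for term in stratum.terms:
            total = total + term.evaluate(sub)
        lp[mask] = total
    n_bad = int(np.sum(~np.isfinite(lp)))
    if n_bad:
        logger.warning(
            "%s: %d subjects flagged with missing/invalid covariates (LP = NaN)",
            config.name, n_bad,
        )
    return pd.Series(lp, index=cohort.index, name=f"{config.name}_lp")


def risk10_from_equation(
    lp: pd.Series, config: ClinicalScoreConfig, strata_labels: pd.Series
) -> Risk10Vector:
    """10-year risk ``1 − S0^exp(LP − LPbar)`` with per-stratum S0, LPbar."""
    risk = np.full(len(lp), np.nan)
    lp_arr = np.asarray(lp, dtype=float)
    labels = strata_labels.astype(str)
    for label, stratum in config.strata.items():
        mask = (labels == label).to_numpy()
        risk[mask] = 1.0 - stratum.s0 ** np.exp(lp_arr[mask] - stratum.lp_mean)
    return Risk10Vector(
        sample_ids=np.asarray(lp.index), risk=risk, linear_predictor=lp_arr
    )


def clinical_risk10(cohort: pd.DataFrame, score="frs") -> pd.Series:
    """Convenience: 10-year clinical risk for every cohort subject."""
    config = score if isinstance(score, ClinicalScoreConfig) else load_clinical_score(score)
    if config.name.startswith("pce"):
        logger.info("%s: cohort has no race variable; white stratum applied", config.name)
    lp = linear_predictor(cohort, config)
    rv = risk10_from_equation(lp, config, _stratum_labels(cohort, config))
    return pd.Series(rv.risk, index=cohort.index, name=f"{config.name}_risk10")
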