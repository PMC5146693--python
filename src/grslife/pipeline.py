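"""End-to-end orchestration: data → GRS → clinical scores → survival models
→ discrimination, reclassification, lifetime risk, meta-analysis → report.

The pipeline is deterministic given the config seed; every number in the
report is regenerable from the intermediate files written next to it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logit

import grslife
from grslife import io as gio
from grslife.clinical import clinical_risk10
from grslife.discrimination import cindex_truncated, delta_c_jackknife, logistic_per_sd
from grslife.meta import StudyEstimate, fixed_effect_meta
from grslife.reclassification import (
    NriResult,
    ReclassTable,
    RiskBins,
    categorical_nri,
    continuous_nri,
    idi,
    reclass_table,
)
from grslife.score import (
    DEFAULT_R2_GRID,
    compute_grs,
    harmonize_alleles,
    select_r2_threshold,
    standardize_score,
)
from grslife.sim import EVENT_CHD, SimConfig, apply_cohort_filters, simulate_dataset
from grslife.survival import (
    age_at_crossing,
    aj_cif,
    fit_cox,
    interaction_test,
    km_curve,
    predict_risk10,
)

logger = logging.getLogger(__name__)

_PACKAGED_COUNTS = {
    "table3_frs_finrisk": (
        "reclass_frs_grs_finrisk_events.tsv",
        "reclass_frs_grs_finrisk_nonevents.tsv",
    ),
    "table4_accaha13_finrisk": (
        "reclass_accaha13_grs_finrisk_events.tsv",
        "reclass_accaha13_grs_finrisk_nonevents.tsv",
    ),
}


@dataclass
class PipelineConfig:
    """Everything one run needs; simulate when no input paths are given."""

    sim: SimConfig = field(default_factory=SimConfig)
    stats_path: str | None = None
    geno_path: str | None = None
    cohort_path: str | None = None
    r2_grid: tuple = DEFAULT_R2_GRID
    window_bp: int = 1_000_000
    bin_cuts: tuple = (0.0, 7.5, 10.0, 20.0, 100.0)
    horizon: float = 10.0
    censor_age: float = 75.0
    min_baseline_age: float | None = None
    age_split: float = 60.0
    clinical_scores: tuple = ("frs", "accaha13")
    risk_level: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.seed is not None:
            self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        for k in ("r2_grid", "bin_cuts", "clinical_scores"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                **{k: v for k, v in dataclasses.asdict(self).items() if k != "sim"},
                "sim": self.sim.to_dict(),
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_or_simulate(config: PipelineConfig):
    if config.stats_path or config.geno_path or config.cohort_path:
        if not (config.stats_path and config.geno_path and config.cohort_path):
            raise ValueError("stats_path, geno_path and cohort_path must be given together")
        stats = gio.read_summary_stats(config.stats_path)
        geno = (
            gio.read_vcf(config.geno_path)
            if str(config.geno_path).endswith(".vcf")
            else gio.read_dosage_tsv(config.geno_path)
        )
        cohort = gio.read_cohort(config.cohort_path)
        return geno, stats, cohort
    geno, _, stats, cohort = simulate_dataset(config.sim)
    return geno, stats, cohort


def _event10(cohort: pd.DataFrame, horizon: float) -> np.ndarray:
    """Event within ``horizon`` years of entry; earlier censoring counts as
    non-event (no censoring-weighted correction is applied)."""
    t = cohort["exit_age"] - cohort["entry_age"]
    return ((cohort["event"] == EVENT_CHD) & (t <= horizon)).to_numpy().astype(int)


def _adjustment_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort/region indicators standing in for study-design adjustments."""
    cols = {}
    for name in ("cohort", "region"):
        if name in cohort.columns and cohort[name].nunique() > 1:
            dummies = pd.get_dummies(cohort[name], prefix=name, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def _hr_block(fit, term: str) -> dict:
    row = fit.hazard_ratios().loc[term]
    return {
        "hr": float(row["hr"]),
        "ci": [float(row["hr_lo"]), float(row["hr_hi"])],
        "log_hr": float(row["coef"]),
        "se": float(row["se"]),
        "p": float(row["p"]),
        "n": int(fit.n),
        "n_events": int(fit.n_events),
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages in dependency order and write the run report.

    Returns the report dict; artifacts (scores, kept SNPs, per-threshold
    report, curves, reclassification tables, report.json) are written under
    ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package": "grslife",
            "version": grslife.__version__,
            "seed": int(config.sim.seed),
            "config_hash": config.config_hash(),
            "combined_model": "Cox(age scale, sex strata) on logit(clinical 10y risk) + standardized GRS",
        }
    }

    stage = "input"
    try:
        geno, stats, cohort_raw = _load_or_simulate(config)

        stage = "cohort_filters"
        cohort = apply_cohort_filters(
            cohort_raw, min_baseline_age=config.min_baseline_age,
            censor_age=config.censor_age,
        )
        keep = pd.Index(geno.sample_ids).get_indexer(cohort["sample_id"])
        geno = dataclasses.replace(
            geno.subset(geno.snps["snp_id"]),
            sample_ids=geno.sample_ids[keep],
            dosage=geno.dosage[keep],
        )
        cohort = cohort.reset_index(drop=True)
        report["cohort"] = {
            "n_input": int(len(cohort_raw)),
            "n_analyzed": int(len(cohort)),
            "n_events_chd": int((cohort["event"] == EVENT_CHD).sum()),
            "n_events_competing": int((cohort["event"] == "death_other").sum()),
        }
        logger.info("cohort: %s", report["cohort"])

        stage = "score_construction"
        stats_h, geno_h, harm_log = harmonize_alleles(stats, geno)
        event10 = _event10(cohort, config.horizon)
        thin = select_r2_threshold(
            stats_h, geno_h, event10, grid=config.r2_grid, window_bp=config.window_bp
        )
        sv = standardize_score(compute_grs(stats_h, geno_h, thin.kept_snp_ids))
        cohort["grs_std"] = sv.standardized
        thin.report.to_csv(outdir / "threshold_report.tsv", sep="\t", index=False)
        pd.Series(thin.kept_snp_ids, name="snp_id").to_csv(
            outdir / "kept_snps.tsv", sep="\t", index=False
        )
        sv.to_frame().to_csv(outdir / "scores.csv", index=False)
        report["score"] = {
            "harmonization": harm_log,
            "r2_threshold": float(thin.r2_threshold),
            "n_snps_kept": int(len(thin.kept_snp_ids)),
            "coverage": float(sv.coverage),
            "per_threshold": thin.report.to_dict(orient="records"),
        }
        logger.info("score: r2=%.2f, %d SNPs kept", thin.r2_threshold, len(thin.kept_snp_ids))

        stage = "clinical_scores"
        for name in config.clinical_scores:
            cohort[f"{name}_risk10"] = clinical_risk10(cohort, name).to_numpy()

        stage = "survival_models"
        adj = _adjustment_frame(cohort)
        df = pd.concat([cohort, adj], axis=1)
        adj_cols = list(adj.columns)
        fit_grs = fit_cox(df, ["grs_std"] + adj_cols, strata="sex", cause=EVENT_CHD)
        report["cox"] = {"grs_per_sd": _hr_block(fit_grs, "grs_std")}
        risk_cols = ["smoking", "diabetes"]
        df["log_sbp"] = np.log(df["sbp"])
        df["log_total_chol"] = np.log(df["total_chol"])
        df["log_hdl_chol"] = np.log(df["hdl_chol"])
        fit_adj = fit_cox(
            df,
            ["grs_std", "log_sbp", "log_total_chol", "log_hdl_chol",
             "family_history"] + risk_cols + adj_cols,
            strata="sex",
        )
        report["cox"]["grs_per_sd_risk_factor_adjusted"] = _hr_block(fit_adj, "grs_std")
        fit_fh = fit_cox(df, ["family_history"] + adj_cols, strata="sex")
        report["cox"]["family_history"] = _hr_block(fit_fh, "family_history")

        q = np.quantile(df["grs_std"], [0.2, 0.8])  # type-7 sample quantiles
        df["grs_quintile"] = 1 + np.searchsorted(
            np.quantile(df["grs_std"], [0.2, 0.4, 0.6, 0.8]), df["grs_std"], side="right"
        )
        extremes = df[(df["grs_std"] <= q[0]) | (df["grs_std"] > q[1])].copy()
        extremes["top_quintile"] = (extremes["grs_std"] > q[1]).astype(float)
        fit_tb = fit_cox(extremes, ["top_quintile"], strata="sex")
        report["cox"]["top_vs_bottom_quintile"] = _hr_block(fit_tb, "top_quintile")

        stage = "discrimination"
        t_follow = (df["exit_age"] - df["entry_age"]).to_numpy()
        is_chd = (df["event"] == EVENT_CHD).to_numpy()
        disc: dict = {}
        or_grs = logistic_per_sd(event10, df["grs_std"].to_numpy())
        report["logistic_or_per_sd"] = {
            "or": or_grs.odds_ratio, "ci": list(or_grs.ci), "p": or_grs.p,
        }
        c_grs = cindex_truncated(t_follow, is_chd, df["grs_std"].to_numpy(),
                                 config.horizon, label="grs")
        disc["grs"] = {"c": c_grs.c, "se": c_grs.se, "n_pairs": c_grs.n_pairs}
        c_fh = cindex_truncated(t_follow, is_chd, df["family_history"].to_numpy(),
                                config.horizon, label="family_history")
        disc["family_history"] = {"c": c_fh.c, "se": c_fh.se, "n_pairs": c_fh.n_pairs}

        stage = "reclassification"
        reclass: dict = {}
        combined_risks: dict = {}
        for name in config.clinical_scores:
            risk_old = df[f"{name}_risk10"].to_numpy()
            ok = np.isfinite(risk_old) & (risk_old > 0) & (risk_old < 1)
            dfx = df.copy()
            dfx["clin_logit"] = np.where(ok, logit(np.clip(risk_old, 1e-12, 1 - 1e-12)), np.nan)
            dfit = dfx[np.isfinite(dfx["clin_logit"])]
            fit_comb = fit_cox(dfit, ["clin_logit", "grs_std"], strata="sex")
            risk_new = np.full(len(df), np.nan)
            risk_new[dfit.index] = predict_risk10(fit_comb, dfit, config.horizon).to_numpy()
            combined_risks[name] = risk_new

            # C-index difference compares nested fitted models (clinical-only
            # Cox vs clinical+GRS Cox) so a null GRS gives delta C centred on
            # 0; the published-equation risk itself is what gets binned in the
            # reclassification tables below.
            fit_clin = fit_cox(dfit, ["clin_logit"], strata="sex")
            risk_clin_model = np.full(len(df), np.nan)
            risk_clin_model[dfit.index] = predict_risk10(
                fit_clin, dfit, config.horizon
            ).to_numpy()

            c_old = cindex_truncated(t_follow[ok], is_chd[ok], risk_old[ok],
                                     config.horizon, label=name)
            dc = delta_c_jackknife(t_follow[ok], is_chd[ok], risk_clin_model[ok],
                                   risk_new[ok], config.horizon)
            disc[name] = {"c": c_old.c, "se": c_old.se, "n_pairs": c_old.n_pairs,
                          "c_fitted_model": dc.c_a}
            disc[f"{name}_grs"] = {
                "c": dc.c_b,
                "delta_c_vs_clinical": dc.delta_c,
                "delta_c_se": dc.se,
                "delta_c_p": dc.p,
            }

            bins = RiskBins(config.bin_cuts)
            table = reclass_table(risk_old, risk_new, event10, bins)
            cat = categorical_nri(table)
            cont = continuous_nri(risk_old, risk_new, event10)
            idi_res = idi(risk_old, risk_new, event10)
            for which in ("events", "nonevents", "all"):
                table.to_frame(which).to_csv(
                    outdir / f"reclass_{name}_{which}.tsv", sep="\t"
                )
            reclass[name] = {
                "n_excluded": table.n_excluded,
                "categorical_nri": _nri_dict(cat),
                "continuous_nri": _nri_dict(cont),
                "idi": {"idi": idi_res.idi, "se": idi_res.se,
                        "ci": list(idi_res.ci), "p": idi_res.p},
                "reclassified_pct_events": table.reclassified_pct("events").tolist(),
            }
        report["discrimination"] = disc
        report["reclassification"] = reclass

        stage = "age_subgroups"
        sub: dict = {}
        for label, mask in (
            (f"lt{config.age_split:g}", df["entry_age"] < config.age_split),
            (f"ge{config.age_split:g}", df["entry_age"] >= config.age_split),
        ):
            d = df[mask]
            if (d["event"] == EVENT_CHD).sum() >= 5:
                fit_s = fit_cox(d, ["grs_std"] + adj_cols, strata="sex")
                sub[label] = {"n": int(len(d)), "grs_per_sd": _hr_block(fit_s, "grs_std")}
        report["age_subgroups"] = sub

        stage = "curves"
        curves_dir = outdir / "curves"
        curves_dir.mkdir(exist_ok=True)
        crossing: dict = {}
        for sex in ("male", "female"):
            for quint in (1, 5):
                grp = df[(df["sex"] == sex) & (df["grs_quintile"] == quint)]
                if len(grp) == 0:
                    continue
                cif = aj_cif(grp, cause=EVENT_CHD)
                cif.to_frame().to_csv(
                    curves_dir / f"cif_{sex}_q{quint}.tsv", sep="\t", index=False
                )
                age = age_at_crossing(cif, config.risk_level)
                crossing[f"{sex}_q{quint}"] = None if age is None else float(age)
        km_all = km_curve(df)
        km_all.to_frame().to_csv(curves_dir / "km_all.tsv", sep="\t", index=False)
        aj_all = aj_cif(df, cause=EVENT_CHD)
        aj_all.to_frame().to_csv(curves_dir / "cif_all.tsv", sep="\t", index=False)
        report["lifetime_risk"] = {
            "age_at_risk_level": crossing,
            "risk_level": config.risk_level,
        }

        stage = "interactions"
        inter: dict = {}
        for factor in ("smoking", "sbp", "total_chol"):
            res = interaction_test(df, "grs_std", factor, adjust=adj_cols)
            inter[factor] = {"coef": res["coef"], "se": res["se"],
                             "z": res["z"], "p": res["p"]}
        report["interactions"] = inter

        stage = "meta_analysis"
        studies = []
        for label, d in df.groupby("cohort"):
            if (d["event"] == EVENT_CHD).sum() < 5:
                continue
            try:
                f = fit_cox(d, ["grs_std"], strata="sex")
            except (ValueError, RuntimeError):
                continue
            hr = f.hazard_ratios().loc["grs_std"]
            studies.append(StudyEstimate(str(label), float(hr["coef"]), float(hr["se"])))
        if len(studies) >= 2:
            mr = fixed_effect_meta(studies)
            report["meta_analysis"] = {
                "per_cohort_log_hr": [dataclasses.asdict(s) for s in studies],
                "pooled_hr": float(np.exp(mr.estimate)),
                "pooled_ci": [float(np.exp(mr.ci[0])), float(np.exp(mr.ci[1]))],
                "q": mr.q, "df": mr.df, "i2_pct": mr.i2, "p_q": mr.p_q,
            }
    except Exception as err:
        (outdir / "report.json").write_text(_dump(report))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    gio.write_cohort(df, outdir / "cohort_analyzed.csv")
    (outdir / "report.json").write_text(_dump(report))
    return report


def _nri_dict(r: NriResult) -> dict:
    return {
        "events": r.nri_events,
        "nonevents": r.nri_nonevents,
        "total": r.nri_total,
        "ci_total": list(r.ci_total),
        "p_total": r.p_value("total"),
    }


def _dump(obj: dict) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def validate_inputs(
    stats_path=None, geno_path=None, cohort_path=None
) -> list:
    """Schema, range and duplicate checks; returns a machine-readable error
    list (empty when all supplied inputs are well-formed)."""
    errors: list = []

    if stats_path is not None:
        try:
            stats = pd.read_csv(stats_path, sep="\t")
            disk_cols = ["snp_id", "chrom", "pos", "ea", "oa", "weight", "se", "pvalue", "eaf"]
            missing = [c for c in disk_cols if c not in stats.columns]
            if missing:
                errors.append({"file": str(stats_path), "error": "missing_columns",
                               "detail": missing})
            else:
                dup = stats.loc[stats["snp_id"].duplicated(), "snp_id"]
                for s in dup:
                    errors.append({"file": str(stats_path), "error": "duplicate_snp_id",
                                   "detail": str(s)})
                bad_p = stats[(stats["pvalue"] <= 0) | (stats["pvalue"] > 1)]
                for i in bad_p.index:
                    errors.append({"file": str(stats_path), "error": "pvalue_out_of_range",
                                   "detail": f"row {int(i)}"})
                same = stats[stats["ea"].astype(str) == stats["oa"].astype(str)]
                for i in same.index:
                    errors.append({"file": str(stats_path), "error": "identical_alleles",
                                   "detail": f"row {int(i)}"})
        except OSError as err:
            errors.append({"file": str(stats_path), "error": "unreadable", "detail": str(err)})

    if geno_path is not None:
        try:
            geno = (
                gio.read_vcf(geno_path)
                if str(geno_path).endswith(".vcf")
                else pd.read_csv(geno_path, sep="\t", index_col="sample_id")
            )
            mat = geno.dosage if hasattr(geno, "dosage") else geno.to_numpy(float)
            with np.errstate(invalid="ignore"):
                bad = np.argwhere((mat < 0) | (mat > 2))
            for r, c in bad[:50]:
                errors.append({"file": str(geno_path), "error": "dosage_out_of_range",
                               "detail": f"row {int(r)}, column {int(c)}"})
        except OSError as err:
            errors.append({"file": str(geno_path), "error": "unreadable", "detail": str(err)})

    if cohort_path is not None:
        try:
            cohort = pd.read_csv(cohort_path)
            need = ["sample_id", "sex", "entry_age", "exit_age", "event"]
            missing = [c for c in need if c not in cohort.columns]
            if missing:
                errors.append({"file": str(cohort_path), "error": "missing_columns",
                               "detail": missing})
            else:
                bad = cohort[cohort["exit_age"] <= cohort["entry_age"]]
                for i in bad.index:
                    errors.append({"file": str(cohort_path), "error": "exit_before_entry",
                                   "detail": f"row {int(i)}"})
                allowed = {EVENT_CHD, "death_other", "censored"}
                bad_ev = cohort[~cohort["event"].isin(allowed)]
                for i in bad_ev.index:
                    errors.append({"file": str(cohort_path), "error": "unknown_event_type",
                                   "detail": f"row {int(i)}"})
        except OSError as err:
            errors.append({"file": str(cohort_path), "error": "unreadable", "detail": str(err)})

    return errors


def packaged_counts(name: str):
    """Bundled published reclassification cross-tab counts.

    ``name`` is ``table3_frs_finrisk`` or ``table4_accaha13_finrisk``;
    returns (events 4x4, nonevents 4x4) arrays.
    """
    if name not in _PACKAGED_COUNTS:
        raise KeyError(f"unknown packaged table {name!r}; options: {sorted(_PACKAGED_COUNTS)}")
    ev_name, ne_name = _PACKAGED_COUNTS[name]
    pkg = resources.files("grslife.data")
    with resources.as_file(pkg.joinpath(ev_name)) as p:
        events = gio.read_counts_tsv(p)
    with resources.as_file(pkg.joinpath(ne_name)) as p:
        nonevents = gio.read_counts_tsv(p)
    return events, nonevents


def reproduce_tables(events, nonevents, bins: RiskBins = RiskBins()):
    """Categorical NRI directly from supplied cross-tab counts.

    ``events`` / ``nonevents`` may be file paths to count TSVs or arrays.
    Returns (ReclassTable, NriResult).
    """
    if not isinstance(events, np.ndarray):
        events = gio.read_counts_tsv(events)
    if not isinstance(nonevents, np.ndarray):
        nonevents = gio.read_counts_tsv(nonevents)
    table = ReclassTable(events=events, nonevents=nonevents, bins=bins)
    return table, categorical_nri(table)
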