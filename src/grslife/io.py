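"""Readers and writers for the pipeline's on-disk formats.

Summary statistics travel as TSV (columns: snp_id, chrom, pos, ea, oa,
weight, se, pvalue, eaf), genotype dosages as VCF 4.2 with a per-genotype
``DS`` FORMAT field or as a plain sample × SNP TSV matrix (with a
``.snps.tsv`` sidecar carrying alleles and positions), cohorts as CSV and
the generative truth as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from grslife.score import GenotypeDosage, STATS_COLUMNS, validate_summary_stats

_DISK_STATS_COLS = {"effect_allele": "ea", "other_allele": "oa"}
_MEM_STATS_COLS = {v: k for k, v in _DISK_STATS_COLS.items()}


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    out = stats[STATS_COLUMNS + (["flag"] if "flag" in stats.columns else [])]
    out = out.rename(columns=_DISK_STATS_COLS)
    out.to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").rename(columns=_MEM_STATS_COLS)
    return validate_summary_stats(df)


def write_dosage_tsv(geno: GenotypeDosage, path) -> None:
    path = Path(path)
    mat = pd.DataFrame(
        geno.dosage, index=pd.Index(geno.sample_ids, name="sample_id"),
        columns=geno.snps["snp_id"],
    )
    mat.to_csv(path, sep="\t")
    geno.snps.to_csv(path.with_suffix(path.suffix + ".snps.tsv"), sep="\t", index=False)


def read_dosage_tsv(path, snps: pd.DataFrame | None = None) -> GenotypeDosage:
    path = Path(path)
    mat = pd.read_csv(path, sep="\t", index_col="sample_id")
    if snps is None:
        sidecar = path.with_suffix(path.suffix + ".snps.tsv")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"SNP metadata required: pass `snps` or provide {sidecar}"
            )
        snps = pd.read_csv(sidecar, sep="\t")
    snps = snps.set_index("snp_id").loc[mat.columns].reset_index()
    return GenotypeDosage(
        sample_ids=mat.index.to_numpy(), snps=snps, dosage=mat.to_numpy(float)
    )


def write_vcf(geno: GenotypeDosage, path) -> None:
    """VCF 4.2 with the effect (counted) allele as ALT and dosage in DS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description='
            '"Dosage of the ALT (effect) allele">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.sample_ids))
            + "\n"
        )
        gt_for = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in geno.snps.iterrows():
            ds = geno.dosage[:, j]
            cells = []
            for v in ds:
                if np.isnan(v):
                    cells.append("./.:.")
                else:
                    gt = gt_for.get(int(round(v)), "./.") if float(v).is_integer() else "./."
                    cells.append(f"{gt}:{v:g}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['snp_id']}\t"
                f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path) -> GenotypeDosage:
    """Read a dosage VCF (DS FORMAT field; GT used as fallback)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.array(vcf.samples)
    snp_rows = []
    cols = []
    for var in vcf:
        snp_rows.append(
            {
                "snp_id": var.ID,
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "effect_allele": var.ALT[0],
                "other_allele": var.REF,
            }
        )
        try:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gts = np.asarray(var.gt_types, dtype=float)
            ds = np.where(gts == 3, np.nan, np.where(gts == 2, 2.0, gts))
        ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
        cols.append(ds)
    vcf.close()
    snps = pd.DataFrame(snp_rows)
    dosage = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return GenotypeDosage(sample_ids=sample_ids, snps=snps, dosage=dosage)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(truth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_counts_tsv(path) -> np.ndarray:
    """Read a 4x4 (or k x k) reclassification count table with row labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"count table at {path} is not square: {m.shape}")
    if np.any(m < 0):
        raise ValueError(f"negative counts in {path}")
    return m


def read_config_file(path) -> dict:
    """JSON or YAML key-value config."""
    import yaml

    text = Path(path).read_text()
    return yaml.safe_load(text)
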