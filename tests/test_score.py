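"""Score construction: allele harmonization, LD r², greedy thinning against
an exhaustive oracle, weighted scores and threshold selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grslife import (
    GenotypeDosage,
    compute_grs,
    harmonize_alleles,
    ld_r2,
    ld_thin,
    select_r2_threshold,
    standardize_score,
)
from grslife.score import ScoreVector


def make_stats(n, weights=None, pvals=None, eaf=None, ea="G", oa="A", pos=None):
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": "1",
            "pos": pos if pos is not None else 1 + np.arange(n) * 1000,
            "effect_allele": [ea] * n if isinstance(ea, str) else ea,
            "other_allele": [oa] * n if isinstance(oa, str) else oa,
            "weight": weights if weights is not None else np.ones(n),
            "se": 0.1,
            "pvalue": pvals if pvals is not None else np.linspace(0.01, 0.5, n),
            "eaf": eaf if eaf is not None else np.full(n, 0.3),
        }
    )


def make_geno(dosage, stats):
    dosage = np.asarray(dosage, dtype=float)
    return GenotypeDosage(
        sample_ids=np.array([f"S{i}" for i in range(dosage.shape[0])]),
        snps=stats[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]].copy(),
        dosage=dosage,
    )


class TestHarmonize:
    def test_identical_alleles_noop(self):
        stats = make_stats(3)
        geno = make_geno(np.array([[0, 1, 2], [2, 1, 0]]), stats)
        sh, gh, log = harmonize_alleles(stats, geno)
        np.testing.assert_array_equal(gh.dosage, geno.dosage)
        assert log["n_flipped"] == 0 and log["n_kept"] == 3

    def test_swapped_alleles_reflect_dosage(self):
        stats = make_stats(1)
        geno = make_geno(np.array([[2.0], [1.0], [0.0]]), stats)
        geno.snps.loc[0, ["effect_allele", "other_allele"]] = ["A", "G"]
        _, gh, log = harmonize_alleles(stats, geno)
        np.testing.assert_array_equal(gh.dosage[:, 0], [0.0, 1.0, 2.0])
        assert log["n_flipped"] == 1

    def test_score_matches_manually_preflipped_fixture(self, rng):
        stats = make_stats(5, weights=rng.normal(size=5))
        dosage = rng.integers(0, 3, size=(8, 5)).astype(float)
        geno = make_geno(dosage.copy(), stats)
        # flip SNPs 1 and 3 in the cohort representation
        for j in (1, 3):
            geno.snps.loc[j, ["effect_allele", "other_allele"]] = ["A", "G"]
            geno.dosage[:, j] = 2.0 - geno.dosage[:, j]
        sh, gh, _ = harmonize_alleles(stats, geno)
        got = compute_grs(sh, gh).raw
        expected = dosage @ stats["weight"].to_numpy()
        np.testing.assert_allclose(got, expected)

    def test_ambiguous_snp_dropped_near_half_frequency(self):
        stats = make_stats(2, ea=["A", "G"], oa=["T", "A"], eaf=np.array([0.5, 0.3]))
        geno = make_geno(np.array([[1, 1], [1, 0], [0, 2]]), stats)
        sh, gh, log = harmonize_alleles(stats, geno)
        assert log["n_ambiguous_dropped"] == 1
        assert sh["snp_id"].tolist() == ["rs1"]

    def test_zero_overlap_is_hard_error(self):
        stats = make_stats(2)
        geno = make_geno(np.array([[0, 1]]), stats)
        geno.snps["snp_id"] = ["x1", "x2"]
        with pytest.raises(ValueError, match="harmonized"):
            harmonize_alleles(stats, geno)


class TestLdR2:
    def test_identical_columns(self):
        assert ld_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_orthogonal_columns(self):
        assert ld_r2([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # sum(dx*dy)^2 / (sum dx^2 * sum dy^2) = 2^2 / (2.75 * 2) = 4/5.5
        assert ld_r2([0, 1, 2, 0], [1, 1, 2, 0]) == pytest.approx(4 / 5.5)

    def test_zero_variance_is_missing(self):
        assert np.isnan(ld_r2([1, 1, 1, 1], [0, 1, 2, 1]))

    def test_pairwise_complete(self):
        full = ld_r2([0, 1, 2, 0], [1, 1, 2, 0])
        padded = ld_r2([0, 1, 2, 0, np.nan], [1, 1, 2, 0, 2])
        assert padded == pytest.approx(full)


def greedy_thin_oracle(stats, dosage, threshold, window_bp):
    """Naive reimplementation: explicit loops, same visiting rule."""
    order = stats.sort_values(["pvalue", "chrom", "pos"], kind="mergesort").index
    kept = []
    for j in order:
        ok = True
        for k in kept:
            if (
                stats.loc[j, "chrom"] == stats.loc[k, "chrom"]
                and abs(stats.loc[j, "pos"] - stats.loc[k, "pos"]) <= window_bp
            ):
                r2 = ld_r2(dosage[:, j], dosage[:, k])
                if not np.isnan(r2) and r2 > threshold:
                    ok = False
                    break
        if ok:
            kept.append(j)
    return sorted(stats.loc[sorted(kept), "snp_id"])


class TestLdThin:
    def test_all_below_threshold_keeps_everything(self, rng):
        stats = make_stats(6)
        geno = make_geno(rng.integers(0, 3, size=(400, 6)).astype(float), stats)
        kept = ld_thin(stats, geno, 1.0)
        assert sorted(kept) == sorted(stats["snp_id"])

    def test_duplicate_snp_keeps_smaller_p(self):
        stats = make_stats(2, pvals=np.array([0.4, 0.01]))
        col = np.array([0.0, 1, 2, 1, 0, 2])
        geno = make_geno(np.column_stack([col, col]), stats)
        assert ld_thin(stats, geno, 0.7) == ["rs1"]

    def test_matches_exhaustive_oracle_on_small_fixtures(self, rng):
        for trial in range(10):
            n_snps = 6
            stats = make_stats(n_snps, pvals=rng.permutation(np.linspace(0.01, 0.2, n_snps)))
            base = rng.integers(0, 3, size=(60, 2)).astype(float)
            cols = [base[:, rng.integers(0, 2)].copy() for _ in range(n_snps)]
            for c in cols:  # jitter to create intermediate r^2
                flip = rng.random(60) < 0.2
                c[flip] = rng.integers(0, 3, size=flip.sum())
            dosage = np.column_stack(cols)
            geno = make_geno(dosage, stats)
            for thr in (0.2, 0.5, 0.8):
                assert sorted(ld_thin(stats, geno, thr)) == greedy_thin_oracle(
                    stats, dosage, thr, 1_000_000
                )

    def test_tie_break_by_position(self):
        stats = make_stats(2, pvals=np.array([0.05, 0.05]))
        col = np.array([0.0, 1, 2, 1, 0, 2])
        geno = make_geno(np.column_stack([col, col]), stats)
        # equal p: rs0 at smaller pos is visited first and kept
        assert ld_thin(stats, geno, 0.7) == ["rs0"]

    def test_kept_pairwise_r2_below_threshold(self, small_dataset):
        geno, _, stats, _ = small_dataset
        kept = ld_thin(stats, geno, 0.5, window_bp=10_000_000)
        sub = geno.subset(kept)
        d = sub.dosage
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                r2 = ld_r2(d[:, a], d[:, b])
                assert np.isnan(r2) or r2 <= 0.5 + 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_lowering_threshold_never_keeps_more(self, seed):
        rng = np.random.default_rng(seed)
        stats = make_stats(8, pvals=rng.uniform(0.001, 0.5, 8))
        base = rng.integers(0, 3, size=(80, 8)).astype(float)
        base[:, 1] = base[:, 0]
        base[:, 4] = np.clip(base[:, 3] + rng.integers(-1, 2, 80), 0, 2)
        geno = make_geno(base, stats)
        counts = [len(ld_thin(stats, geno, t)) for t in (1.0, 0.8, 0.5, 0.2)]
        assert counts == sorted(counts, reverse=True)


class TestComputeGrs:
    def test_zero_weights_zero_score(self):
        stats = make_stats(3, weights=np.zeros(3))
        geno = make_geno(np.array([[0, 1, 2], [2, 2, 2]]), stats)
        np.testing.assert_array_equal(compute_grs(stats, geno).raw, [0.0, 0.0])

    def test_hand_arithmetic(self):
        w = np.array([np.log(2), -np.log(2)])
        stats = make_stats(2, weights=w)
        geno = make_geno(np.array([[2.0, 1.0]]), stats)
        assert compute_grs(stats, geno).raw[0] == pytest.approx(np.log(2))

    def test_allele_flip_invariance_of_standardized_score(self, rng):
        stats = make_stats(4, weights=rng.normal(size=4))
        dosage = rng.integers(0, 3, size=(30, 4)).astype(float)
        geno = make_geno(dosage.copy(), stats)
        s1 = standardize_score(compute_grs(stats, geno))
        flipped = stats.copy()
        flipped.loc[2, "weight"] = -flipped.loc[2, "weight"]
        flipped.loc[2, ["effect_allele", "other_allele"]] = ["A", "G"]
        flipped.loc[2, "eaf"] = 1 - flipped.loc[2, "eaf"]
        geno2 = make_geno(dosage.copy(), flipped)
        geno2.dosage[:, 2] = 2.0 - geno2.dosage[:, 2]
        geno2.snps.loc[2, ["effect_allele", "other_allele"]] = ["A", "G"]
        s2 = standardize_score(compute_grs(flipped, geno2))
        np.testing.assert_allclose(s1.standardized, s2.standardized, atol=1e-12)
        # raw scores shift by the constant 2w
        np.testing.assert_allclose(
            s2.raw - s1.raw, np.full(30, 2 * flipped.loc[2, "weight"])
        )

    def test_score_linearity_over_disjoint_subsets(self, small_dataset):
        geno, _, stats, _ = small_dataset
        ids = stats["snp_id"].tolist()
        a, b = ids[:100], ids[100:250]
        full = compute_grs(stats, geno, a + b).raw
        parts = compute_grs(stats, geno, a).raw + compute_grs(stats, geno, b).raw
        np.testing.assert_allclose(full, parts, atol=1e-10)

    def test_missing_dosage_mean_imputed(self):
        stats = make_stats(1, weights=np.array([2.0]), eaf=np.array([0.25]))
        geno = make_geno(np.array([[1.0], [np.nan]]), stats)
        raw = compute_grs(stats, geno).raw
        assert raw[1] == pytest.approx(2.0 * 2 * 0.25)

    def test_empty_subset_is_error(self, small_dataset):
        geno, _, stats, _ = small_dataset
        with pytest.raises(ValueError, match="empty"):
            compute_grs(stats, geno, [])


class TestStandardize:
    def test_hand_values_and_idempotence(self):
        sv = ScoreVector(
            sample_ids=np.array(["a", "b", "c"]), raw=np.array([1.0, 2.0, 3.0]),
            standardized=None, n_snps_used=1, coverage=1.0,
        )
        out = standardize_score(sv)
        np.testing.assert_allclose(out.standardized, [-1.0, 0.0, 1.0])
        again = standardize_score(out)
        np.testing.assert_allclose(again.standardized, out.standardized)
        assert abs(out.standardized.mean()) < 1e-10
        assert out.standardized.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_constant_score_error_names_cause(self):
        sv = ScoreVector(
            sample_ids=np.array(["a", "b"]), raw=np.array([1.0, 1.0]),
            standardized=None, n_snps_used=1, coverage=1.0,
        )
        with pytest.raises(ValueError, match="constant"):
            standardize_score(sv)


class TestSelectThreshold:
    def test_single_element_grid(self, small_dataset, rng):
        geno, _, stats, _ = small_dataset
        outcome = rng.integers(0, 2, geno.n_samples)
        res = select_r2_threshold(stats, geno, outcome, grid=(0.7,))
        assert res.r2_threshold == 0.7

    def test_tie_broken_toward_larger_threshold(self, rng):
        # independent SNPs: every threshold keeps the full set -> identical AUC
        stats = make_stats(5, weights=rng.normal(size=5))
        geno = make_geno(rng.integers(0, 3, size=(200, 5)).astype(float), stats)
        outcome = rng.integers(0, 2, 200)
        res = select_r2_threshold(stats, geno, outcome, grid=(0.5, 0.9))
        assert res.r2_threshold == 0.9
        aucs = res.report.set_index("r2_threshold")["auc"]
        assert aucs[0.5] == pytest.approx(aucs[0.9])

    def test_reported_auc_matches_naive_oracle(self, small_dataset):
        geno, truth, stats, cohort = small_dataset
        outcome = (cohort["event"] == "chd").astype(int).to_numpy()
        res = select_r2_threshold(stats, geno, outcome, grid=(1.0, 0.5))
        for _, row in res.report.iterrows():
            kept = ld_thin(stats, geno, row["r2_threshold"])
            score = compute_grs(stats, geno, kept).raw
            pos, neg = score[outcome == 1], score[outcome == 0]
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
                pos[:, None] == neg[None, :]
            ).sum()
            assert row["auc"] == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_degenerate_outcome_is_error(self, small_dataset):
        geno, _, stats, _ = small_dataset
        with pytest.raises(ValueError, match="both classes"):
            select_r2_threshold(stats, geno, np.zeros(geno.n_samples), grid=(0.7,))
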