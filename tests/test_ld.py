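import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from cnvpop.ld import (
    filter_variants_for_ld,
    hwe_exact_test,
    ld_decay_profile,
    mask_snps_in_cnvrs,
    pair_cnvr_qtl,
    pairwise_r2,
    r2,
    taggability,
)
from cnvpop.types import Cnvr, QtlRecord, VariantGenotypes


def hwe_oracle(n_aa, n_ab, n_bb):
    """Closed-form exact HWE p by direct enumeration (log-factorials)."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    n_rare = min(na, nb)

    def logp(h):
        hom_r = (n_rare - h) // 2
        hom_c = n - hom_r - h
        return (
            h * np.log(2)
            - gammaln(hom_r + 1)
            - gammaln(h + 1)
            - gammaln(hom_c + 1)
        )

    hs = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    logs = np.array([logp(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(n_ab)]
    return min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum())


class TestHweExact:
    def test_matches_enumeration_oracle_up_to_n200(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 201))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            got = hwe_exact_test(n_aa, n_ab, n_bb)
            want = hwe_oracle(n_aa, n_ab, n_bb)
            assert got == pytest.approx(want, rel=1e-9)

    def test_extreme_het_deficit_tiny_p(self):
        # (AA=50, Aa=0, aa=50): total heterozygote deficit at n=100
        assert hwe_exact_test(50, 0, 50) < 1e-9

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(30, 0, 0) == 1.0


def make_geno(dosage_rows, kinds=None, positions=None, phase=None, chrom="chr1"):
    n_var = len(dosage_rows)
    n_samp = len(dosage_rows[0])
    positions = positions or [100 * (i + 1) for i in range(n_var)]
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(n_var)],
            "chrom": chrom,
            "pos": positions,
            "end": positions,
            "kind": kinds or ["snp"] * n_var,
        }
    )
    return VariantGenotypes(
        variants,
        [f"s{j}" for j in range(n_samp)],
        np.array(dosage_rows, dtype=float),
        phase,
    )


class TestVariantFilters:
    def test_monomorphic_removed_for_maf(self):
        g = make_geno([[0, 0, 0, 0]])
        kept, removed = filter_variants_for_ld(g)
        assert len(kept) == 0 and removed["v0"] == ["maf"]

    def test_low_call_rate_removed_snp_only(self):
        rng = np.random.default_rng(5)
        row = list(rng.binomial(2, 0.4, size=89).astype(float)) + [np.nan] * 11
        g = make_geno([row, row], kinds=["snp", "cnvr"])  # 89% call rate
        kept, removed = filter_variants_for_ld(g)
        assert "call_rate" in removed["v0"]
        assert 1 in kept  # CNVRs are exempt from the call-rate criterion

    def test_hwe_failure_removed(self):
        row = [0.0] * 50 + [2.0] * 50
        g = make_geno([row])
        kept, removed = filter_variants_for_ld(g)
        assert removed["v0"] == ["hwe"]

    def test_passing_variant_kept(self):
        rng = np.random.default_rng(3)
        row = rng.binomial(2, 0.3, size=200).astype(float)
        g = make_geno([row])
        kept, removed = filter_variants_for_ld(g)
        assert list(kept) == [0] and not removed


class TestMasking:
    def test_boundaries_inclusive(self):
        snps = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [1000, 2000, 2001]})
        cnvrs = [Cnvr("c", "chr1", 1000, 2000, "deletion")]
        keep = mask_snps_in_cnvrs(snps, cnvrs)
        assert list(keep) == [False, False, True]

    def test_matches_brute_force_oracle(self, rng):
        snps = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=300),
                "pos": rng.integers(1, 100_000, size=300),
            }
        )
        cnvrs = [
            Cnvr(f"c{i}", ch, int(s), int(s + l), "deletion")
            for i, (ch, s, l) in enumerate(
                zip(
                    rng.choice(["chr1", "chr2"], size=20),
                    rng.integers(1, 90_000, size=20),
                    rng.integers(100, 8_000, size=20),
                )
            )
        ]
        keep = mask_snps_in_cnvrs(snps, cnvrs)
        oracle = [
            not any(
                r.chrom == ch and r.start <= p <= r.end for r in cnvrs
            )
            for ch, p in zip(snps["chrom"], snps["pos"])
        ]
        assert list(keep) == oracle


class TestR2:
    def test_self_pair_is_one(self):
        d = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert r2(d, d).r2 == pytest.approx(1.0)

    def test_phased_hand_case(self):
        # haplotype counts AB=40, Ab=10, aB=10, ab=40 of 100:
        # D = 0.4 - 0.25 = 0.15, r2 = 0.15^2 / 0.5^4 = 0.36
        hap_a = [1] * 40 + [1] * 10 + [0] * 10 + [0] * 40
        hap_b = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        pa = np.array(hap_a).reshape(50, 2)
        pb = np.array(hap_b).reshape(50, 2)
        val = r2(pa.sum(axis=1).astype(float), pb.sum(axis=1).astype(float), pa, pb)
        assert val.mode == "phased"
        assert val.r2 == pytest.approx(0.36)

    def test_allele_label_swap_invariance(self):
        d_a = np.array([0, 1, 2, 2, 1, 0, 1, 2], dtype=float)
        d_b = np.array([0, 0, 2, 1, 1, 0, 2, 2], dtype=float)
        assert r2(d_a, d_b).r2 == pytest.approx(r2(2 - d_a, d_b).r2)

    def test_monomorphic_pair_undefined(self):
        a = np.array([1, 1, 1, 1], dtype=float)
        b = np.array([0, 1, 2, 1], dtype=float)
        assert np.isnan(r2(a, b).r2)

    def test_phased_equals_composite_when_all_homozygous(self):
        # phase carries no extra information when every sample is homozygous
        pa = np.array([[1, 1]] * 4 + [[0, 0]] * 4)
        pb = np.array([[1, 1]] * 2 + [[0, 0]] * 2 + [[1, 1]] * 2 + [[0, 0]] * 2)
        da = pa.sum(axis=1).astype(float)
        db = pb.sum(axis=1).astype(float)
        assert r2(da, db, pa, pb).r2 == pytest.approx(r2(da, db).r2)


class TestProfilesAndTaggability:
    def _pairs(self, rows):
        return pd.DataFrame(
            rows, columns=["id_a", "id_b", "distance", "r2", "maf_a", "maf_b", "mode", "class"]
        )

    def test_constant_r2_constant_bins(self):
        rows = [
            ("a", f"s{i}", d, 0.25, 0.2, 0.2, "composite", "snp")
            for i, d in enumerate(range(0, 100_000, 7_000))
        ]
        prof = ld_decay_profile(self._pairs(rows))
        filled = prof.dropna(subset=["mean_r2"])
        assert (filled["mean_r2"] == 0.25).all()

    def test_empty_bin_is_missing_not_zero(self):
        rows = [("a", "s1", 95_000, 0.5, 0.2, 0.2, "composite", "snp")]
        prof = ld_decay_profile(self._pairs(rows))
        first = prof[(prof["bin_left"] == 0)].iloc[0]
        assert np.isnan(first["mean_r2"]) and first["n_pairs"] == 0

    def test_best_r2_and_tagged(self):
        rows = [
            ("a", "s1", 10, 0.2, 0.1, 0.1, "composite", "cnvr"),
            ("a", "s2", 20, 0.9, 0.1, 0.1, "composite", "cnvr"),
            ("a", "s3", 30, 0.5, 0.1, 0.1, "composite", "cnvr"),
        ]
        records, bins = taggability(self._pairs(rows))
        assert records.loc[0, "best_r2"] == pytest.approx(0.9)
        assert bool(records.loc[0, "tagged"])

    def test_no_partner_absent_from_records(self):
        records, bins = taggability(self._pairs([]))
        assert records.empty and bins.empty

    def test_best_r2_monotone_in_window(self, small_cohort):
        g = small_cohort.snp_genotypes
        anchors = [10]
        partners = list(range(0, 60))
        small = pairwise_r2(g, anchors, partners, window=20_000)
        large = pairwise_r2(g, anchors, partners, window=80_000)
        if not small.empty:
            assert large["r2"].max() >= small["r2"].max() - 1e-12


class TestCnvrQtl:
    def _pairs_df(self):
        return pd.DataFrame(
            {
                "id_a": ["c1"] * 3,
                "id_b": ["s1", "s2", "s3"],
                "distance": [10, 20, 30],
                "r2": [0.5, 0.74, 0.53],
                "maf_a": [0.2] * 3,
                "maf_b": [0.2] * 3,
                "mode": ["phased"] * 3,
                "class": ["cnvr"] * 3,
            }
        )

    def _snp_positions(self):
        return pd.DataFrame(
            {
                "variant_id": ["s1", "s2", "s3"],
                "chrom": ["chr1"] * 3,
                "pos": [9_000, 52_000, 61_000],
            }
        )

    def test_aggregation_mean_and_max(self):
        cnvr = Cnvr("c1", "chr1", 20_000, 40_000, "deletion")
        qtls = [
            QtlRecord("q1", "chr1", 9_500, 9_500, "milk"),
            QtlRecord("q2", "chr1", 50_000, 50_000, "milk"),
            QtlRecord("q3", "chr1", 60_000, 60_000, "fat"),
        ]
        out = pair_cnvr_qtl(
            self._pairs_df(), qtls, [cnvr], window=100_000,
            snp_match_bp=10_000, snp_positions=self._snp_positions(),
        )
        row = out.iloc[0]
        assert row["n_qtls"] == 3
        assert round(row["mean_r2"], 2) == 0.59
        assert round(row["max_r2"], 2) == 0.74

    def test_no_qtl_in_window_absent(self):
        cnvr = Cnvr("c1", "chr1", 20_000, 40_000, "deletion")
        qtls = [QtlRecord("q1", "chr2", 30_000, 30_000, "milk")]
        out = pair_cnvr_qtl(
            self._pairs_df(), qtls, [cnvr], window=100_000,
            snp_positions=self._snp_positions(),
        )
        assert out.empty

    def test_zero_window_only_inside_qtls(self):
        cnvr = Cnvr("c1", "chr1", 20_000, 40_000, "deletion")
        inside = QtlRecord("q1", "chr1", 30_000, 30_000, "milk")
        outside = QtlRecord("q2", "chr1", 41_000, 41_000, "milk")
        pairs = self._pairs_df()
        pos = pd.DataFrame(
            {"variant_id": ["s1", "s2", "s3"], "chrom": ["chr1"] * 3,
             "pos": [29_000, 35_000, 45_000]}
        )
        out = pair_cnvr_qtl(pairs, [inside, outside], [cnvr], window=0,
                            snp_positions=pos)
        assert out.iloc[0]["n_qtls"] == 1
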