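import numpy as np
import pandas as pd
import pytest

from cnvpop.popgen import (
    filter_min_copies,
    fst_outlier_scan,
    fst_vst_concordance,
    fst_wc,
    vst,
    FstResult,
    VstResult,
)
from cnvpop.types import Cnvr, CnvCall, LrrMatrix


def wc_theta_oracle(alt1, n1, alt2, n2):
    """Independent Weir-Cockerham theta: literal one-way ANOVA on allele
    indicator vectors (coded before the main implementation)."""
    g1 = np.array([1] * alt1 + [0] * (n1 - alt1), dtype=float)
    g2 = np.array([1] * alt2 + [0] * (n2 - alt2), dtype=float)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    grand = np.concatenate([g1, g2]).mean()
    ssp = n1 * (g1.mean() - grand) ** 2 + n2 * (g2.mean() - grand) ** 2
    ssg = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
    msp = ssp / (r - 1)
    msg = ssg / (n1 + n2 - r)
    denom = msp + (nc - 1) * msg
    return np.nan if denom == 0 else (msp - msg) / denom


class TestFstWc:
    def test_fixed_difference_is_one(self):
        assert fst_wc((100, 100), (0, 100)).fst == pytest.approx(1.0)

    def test_null_is_nonpositive(self):
        assert fst_wc((30, 100), (30, 100)).fst <= 0

    def test_monomorphic_in_both_undefined(self):
        assert np.isnan(fst_wc((0, 80), (0, 40)).fst)
        assert np.isnan(fst_wc((80, 80), (40, 40)).fst)

    def test_against_anova_oracle_on_random_configurations(self, rng):
        for _ in range(100):
            n1 = int(rng.integers(4, 300))
            n2 = int(rng.integers(4, 300))
            alt1 = int(rng.integers(0, n1 + 1))
            alt2 = int(rng.integers(0, n2 + 1))
            got = fst_wc((alt1, n1), (alt2, n2)).fst
            want = wc_theta_oracle(alt1, n1, alt2, n2)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)
                assert got <= 1.0

    def test_allele_label_swap_invariance(self):
        a = fst_wc((10, 40), (30, 40)).fst
        b = fst_wc((30, 40), (10, 40)).fst
        assert a == pytest.approx(b)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fst_wc((0, 0), (5, 10))

    def test_increasing_divergence_increases_fst(self):
        vals = [fst_wc((int(200 * (0.1 + d)), 200), (20, 200)).fst
                for d in (0.0, 0.1, 0.2, 0.4)]
        assert vals == sorted(vals)


class TestOutlierScan:
    def test_value_above_threshold_flagged(self):
        base = [FstResult(f"c{i}", 0.01 + 0.001 * (i % 7), 0, 2, 0, 2) for i in range(50)]
        vals = np.array([f.fst for f in base])
        m, s = vals.mean(), vals.std(ddof=1)
        # far enough out to remain > mean + 3 SD after its own inclusion
        hi = FstResult("hi", m + 10 * s, 0, 2, 0, 2)
        outliers, thr, table = fst_outlier_scan(base + [hi])
        assert "hi" in outliers
        assert table.loc[table.cnvr_id == "hi", "outlier"].item()

    def test_threshold_is_strict(self):
        # with k=0 the threshold is the mean itself: a value exactly at the
        # threshold must not be flagged, one above it must
        base = [FstResult(f"c{i}", v, 0, 2, 0, 2) for i, v in enumerate([0.1, 0.2, 0.3])]
        outliers, thr, _ = fst_outlier_scan(base, k=0.0)
        assert thr == pytest.approx(0.2)
        assert outliers == {"c2"}

    def test_nan_values_ignored_all_nan_rejected(self):
        base = [FstResult("a", np.nan, 0, 2, 0, 2), FstResult("b", np.nan, 0, 2, 0, 2)]
        with pytest.raises(ValueError):
            fst_outlier_scan(base)


def make_lrr(sample_vals, chrom="chr1", positions=(100, 200)):
    samples = list(sample_vals)
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{p}" for p in positions],
            "chrom": chrom,
            "pos": list(positions),
        }
    )
    vals = np.tile(np.array([sample_vals[s] for s in samples], dtype=float), (len(positions), 1))
    return LrrMatrix(snps, samples, vals)


class TestVst:
    def test_zero_within_population_variance_gives_one(self):
        lrr = make_lrr({"a": 0.0, "b": 0.0, "c": -0.5, "d": -0.5})
        r = vst(lrr, Cnvr("c", "chr1", 50, 250, "deletion"), ["a", "b"], ["c", "d"])
        assert r.vst == pytest.approx(1.0)

    def test_identical_pooled_values_give_zero(self):
        lrr = make_lrr({"a": 0.1, "b": 0.3, "c": 0.1, "d": 0.3})
        r = vst(lrr, Cnvr("c", "chr1", 50, 250, "deletion"), ["a", "b"], ["c", "d"])
        assert r.vst == pytest.approx(0.0)

    def test_hand_computed_case(self):
        # pop1 {0.0, 0.2}, pop2 {-0.6, -0.4}: VT = 0.10, within = 0.01 -> 0.9
        lrr = make_lrr({"a": 0.0, "b": 0.2, "c": -0.6, "d": -0.4})
        r = vst(lrr, Cnvr("c", "chr1", 50, 250, "deletion"), ["a", "b"], ["c", "d"])
        assert r.v_total == pytest.approx(0.10)
        assert r.vst == pytest.approx(0.9)
        assert r.n_snps == 2

    def test_constant_shift_invariance(self):
        base = {"a": 0.0, "b": 0.2, "c": -0.6, "d": -0.4}
        shifted = {k: v + 5.0 for k, v in base.items()}
        r1 = vst(make_lrr(base), Cnvr("c", "chr1", 50, 250, "deletion"), ["a", "b"], ["c", "d"])
        r2 = vst(make_lrr(shifted), Cnvr("c", "chr1", 50, 250, "deletion"), ["a", "b"], ["c", "d"])
        assert r1.vst == pytest.approx(r2.vst)

    def test_bounds_zero_one(self, rng):
        for _ in range(25):
            vals = {f"s{i}": float(rng.normal()) for i in range(10)}
            r = vst(
                make_lrr(vals), Cnvr("c", "chr1", 50, 250, "deletion"),
                [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 10)],
            )
            assert 0.0 <= r.vst <= 1.0 + 1e-12

    def test_no_snp_in_span_rejected(self):
        lrr = make_lrr({"a": 0.0, "b": 0.1})
        with pytest.raises(ValueError, match="no LRR SNP"):
            vst(lrr, Cnvr("cX", "chr1", 300, 400, "deletion"), ["a"], ["b"])


def region_with_calls(cnvr_id, pop1_calls, pop2_calls):
    members = [
        CnvCall(f"P1_{i}", "chr1", 1, 100, 1, 5) for i in range(pop1_calls)
    ] + [CnvCall(f"P2_{i}", "chr1", 1, 100, 1, 5) for i in range(pop2_calls)]
    return Cnvr(cnvr_id, "chr1", 1, 100, "deletion", members)


class TestMinCopies:
    def _popmap(self, n1=20, n2=20):
        m = {f"P1_{i}": "pop1" for i in range(n1)}
        m.update({f"P2_{i}": "pop2" for i in range(n2)})
        return m

    def test_either_mode_removes_low_population(self):
        r = region_with_calls("c", 4, 10)
        assert filter_min_copies([r], self._popmap(), ("pop1", "pop2"), mode="either") == []

    def test_both_mode_retains_one_sided(self):
        r = region_with_calls("c", 4, 10)
        kept = filter_min_copies([r], self._popmap(), ("pop1", "pop2"), mode="both")
        assert kept == [r]

    def test_exactly_five_retained_strict(self):
        r = region_with_calls("c", 5, 5)
        kept = filter_min_copies([r], self._popmap(), ("pop1", "pop2"), mode="either")
        assert kept == [r]

    def test_unknown_population_rejected(self):
        r = region_with_calls("c", 5, 5)
        with pytest.raises(ValueError, match="population"):
            filter_min_copies([r], self._popmap(), ("pop1", "nope"))


class TestConcordance:
    def _pairs(self, fvals, vvals):
        fsts = [FstResult(f"c{i}", v, 0, 2, 0, 2) for i, v in enumerate(fvals)]
        vsts = [VstResult(f"c{i}", v, 1, 1, 1, 2, 2, 3) for i, v in enumerate(vvals)]
        return fsts, vsts

    def test_identity_gives_one(self):
        f, v = self._pairs([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        r, n = fst_vst_concordance(f, v)
        assert r == pytest.approx(1.0) and n == 4

    def test_negated_gives_minus_one(self):
        f, v = self._pairs([0.1, 0.2, 0.3], [0.4, 0.3, 0.2])
        r, _ = fst_vst_concordance(f, v)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self, rng):
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        f, v = self._pairs(x, y)
        r, n = fst_vst_concordance(f, v)
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert n == 50
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        f, v = self._pairs([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(ValueError):
            fst_vst_concordance(f, v)
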