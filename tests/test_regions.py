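import numpy as np
import pytest

from cnvpop.regions import (
    MAF_COMMON,
    MAF_INTERMEDIATE,
    MAF_RARE,
    allele_frequency,
    build_cnvrs,
    classify_maf,
    genotype_cnvr,
    site_frequency_spectrum,
    summarize_cnvrs,
)
from cnvpop.types import CnvCall, Cnvr


def call(sample, start, end, cn, chrom="chr1"):
    return CnvCall(sample, chrom, start, end, cn, 5)


class TestBuildCnvrs:
    def test_two_overlapping_deletions_union(self):
        (r,) = build_cnvrs([call("a", 1, 100, 1), call("b", 50, 150, 1)])
        assert (r.chrom, r.start, r.end, r.type) == ("chr1", 1, 150, "deletion")

    def test_mixed_states_complex(self):
        (r,) = build_cnvrs([call("a", 1, 100, 1), call("b", 80, 200, 3)])
        assert (r.start, r.end, r.type) == (1, 200, "complex")

    def test_bookended_calls_stay_separate(self):
        rs = build_cnvrs([call("a", 1, 100, 1), call("b", 101, 200, 1)])
        assert len(rs) == 2

    def test_all_duplications_typed_duplication(self):
        (r,) = build_cnvrs([call("a", 1, 100, 3), call("b", 50, 150, 4)])
        assert r.type == "duplication"

    def test_matches_union_find_oracle_on_random_intervals(self, rng):
        # brute-force union-find over all pairwise >=1 bp overlaps
        n = 500
        starts = rng.integers(1, 200_000, size=n)
        lengths = rng.integers(1, 5_000, size=n)
        chroms = rng.choice(["chr1", "chr2"], size=n)
        cns = rng.choice([0, 1, 3, 4], size=n)
        calls = [
            call(f"s{i}", int(s), int(s + l - 1), int(c), chrom=ch)
            for i, (s, l, c, ch) in enumerate(zip(starts, lengths, cns, chroms))
        ]
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = calls[i], calls[j]
                if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                    parent[find(i)] = find(j)
        oracle_groups = {}
        for i in range(n):
            oracle_groups.setdefault(find(i), set()).add(calls[i].sample_id)
        oracle = sorted(map(frozenset, oracle_groups.values()), key=sorted)

        cnvrs = build_cnvrs(calls)
        got = sorted(
            (frozenset(c.sample_id for c in r.member_calls) for r in cnvrs), key=sorted
        )
        assert got == oracle

    def test_every_call_in_exactly_one_cnvr_and_spans_disjoint(self, clean_calls, clean_cnvrs):
        assigned = [c for r in clean_cnvrs for c in r.member_calls]
        assert sorted(assigned, key=id) is not None
        assert len(assigned) == len(clean_calls)
        by_chrom = {}
        for r in clean_cnvrs:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2


class TestGenotyping:
    def _deletion_cnvr(self, members):
        return Cnvr("c1", "chr1", 1, 1000, "deletion", members)

    def test_deletion_coding(self):
        r = self._deletion_cnvr([call("het", 1, 1000, 1), call("hom", 1, 1000, 0)])
        t = genotype_cnvr(r, ["het", "hom", "none"])
        assert dict(zip(t.sample_ids, t.dosage)) == {"het": 1, "hom": 2, "none": 0}
        assert t.genotype_labels == ["+/-", "-/-", "+/+"]

    def test_duplication_cn4_is_dosage_2(self):
        r = Cnvr("c1", "chr1", 1, 1000, "duplication", [call("s", 1, 1000, 4)])
        t = genotype_cnvr(r, ["s"])
        assert t.dosage[0] == 2

    def test_multiple_calls_take_most_extreme(self):
        r = self._deletion_cnvr([call("s", 1, 400, 1), call("s", 500, 1000, 0)])
        t = genotype_cnvr(r, ["s"])
        assert t.dosage[0] == 2

    def test_cn5_clamped_with_warning(self, caplog):
        r = Cnvr("c1", "chr1", 1, 1000, "duplication", [call("s", 1, 1000, 5)])
        with caplog.at_level("WARNING"):
            t = genotype_cnvr(r, ["s"])
        assert t.dosage[0] == 2 and "clamped" in caplog.text

    def test_complex_rejected(self):
        r = Cnvr("c1", "chr1", 1, 1000, "complex", [])
        with pytest.raises(ValueError, match="not bi-allelic"):
            genotype_cnvr(r, ["s"])


class TestFrequencies:
    def test_allele_frequency_and_empty_pop(self):
        r = Cnvr("c1", "chr1", 1, 1000, "deletion", [call("a", 1, 1000, 1)])
        t = genotype_cnvr(r, ["a", "b"])
        assert allele_frequency(t, ["a", "b"]) == 0.25
        with pytest.raises(ValueError, match="empty"):
            allele_frequency(t, [])

    @pytest.mark.parametrize(
        "maf,label",
        [
            (0.05, MAF_COMMON),
            (0.049, MAF_INTERMEDIATE),
            (0.01, MAF_INTERMEDIATE),
            (0.009, MAF_RARE),
            (0.0, MAF_RARE),
            (0.95, MAF_COMMON),  # folded: MAF = 0.05
        ],
    )
    def test_maf_class_boundaries(self, maf, label):
        assert classify_maf(maf) == label


class TestSfs:
    def test_small_example(self):
        sfs = site_frequency_spectrum({"deletion": [0.02, 0.03, 0.12]})
        assert sfs["deletion"].sum() == 3
        assert sfs.loc[0, "deletion"] == 2  # [0, 0.05)
        assert sfs.loc[2, "deletion"] == 1  # [0.10, 0.15)

    def test_empty_input_all_zero(self):
        sfs = site_frequency_spectrum({"deletion": []})
        assert sfs["deletion"].sum() == 0

    def test_matches_direct_histogram_oracle(self, rng):
        freqs = rng.uniform(0, 0.5, size=1000)
        sfs = site_frequency_spectrum({"duplication": freqs})
        edges = np.arange(0, 0.525, 0.05)
        oracle, _ = np.histogram(freqs, bins=edges)
        np.testing.assert_array_equal(sfs["duplication"].values, oracle)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            site_frequency_spectrum({"deletion": [0.7]})


class TestSummary:
    def test_full_chromosome_coverage(self):
        c = call("s", 1, 1_000_000, 1)
        (r,) = build_cnvrs([c])
        s = summarize_cnvrs([c], [r], {"chr1": 1_000_000})
        assert s["coverage_pct_by_chrom"]["chr1"] == 100.0
        assert s["genome_coverage_pct"] == 100.0

    def test_missing_chrom_length_rejected(self):
        c = call("s", 1, 100, 1)
        (r,) = build_cnvrs([c])
        with pytest.raises(ValueError, match="chromosome length"):
            summarize_cnvrs([c], [r], {"chr2": 500})

    def test_coverage_invariant_to_splitting_calls(self, clean_calls, clean_cohort):
        from cnvpop.qc import merge_adjacent_calls

        split = []
        for c in clean_calls:
            if c.length > 10 and c.num_snps > 1:
                mid = (c.start + c.end) // 2
                split.append(CnvCall(c.sample_id, c.chrom, c.start, mid, c.cn_state, 1))
                split.append(CnvCall(c.sample_id, c.chrom, mid + 1, c.end, c.cn_state,
                                     c.num_snps - 1))
            else:
                split.append(c)
        remerged = merge_adjacent_calls(split)
        lens = clean_cohort.chrom_lengths
        s1 = summarize_cnvrs(clean_calls, build_cnvrs(clean_calls), lens)
        s2 = summarize_cnvrs(remerged, build_cnvrs(remerged), lens)
        assert s1["genome_coverage_pct"] == s2["genome_coverage_pct"]
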