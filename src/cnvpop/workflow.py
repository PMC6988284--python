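"""End-to-end orchestration of the pipeline stages.

Thin glue used by the analysis drivers and the acceptance script: call
emission + QC + merging + CNVR construction, the two-population
differentiation scan (Fst/Vst), the functional-impact scan, and the LD /
taggability scan. All computation lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ld as ld_mod
from .functional import (
    GeneIndex,
    PermutationResult,
    assign_functional_category,
    permutation_overlap_test,
)
from .popgen import (
    FstResult,
    VstResult,
    filter_min_copies,
    fst_from_dosages,
    fst_outlier_scan,
    fst_vst_concordance,
    vst,
)
from .qc import filter_outlier_samples, filter_samples, merge_adjacent_calls
from .regions import (
    allele_frequency,
    build_cnvrs,
    classify_maf,
    genotype_all_biallelic,
    summarize_cnvrs,
)
from .simulate import SyntheticCohort, emit_calls
from .types import Cnvr, CnvCall, VariantGenotypes


@dataclass
class CallSet:
    """QC'd and merged calls with the surviving sample set."""

    calls_raw: list[CnvCall]
    samples: list[str]  # post-QC, in cohort order
    removed_signal: dict[str, list[str]]
    removed_outlier: dict[str, list[str]]
    calls: list[CnvCall]  # QC'd + merged
    cnvrs: list[Cnvr]
    tables: dict  # cnvr_id -> CnvrGenotypeTable over `samples`
    summary: dict


def call_and_aggregate(cohort: SyntheticCohort) -> CallSet:
    calls_raw = emit_calls(cohort.truth, cohort.config, lrr=cohort.lrr)
    kept_signal, removed_signal = filter_samples(cohort.qc_metrics)
    calls_q = [c for c in calls_raw if c.sample_id in set(kept_signal)]
    _, removed_outlier = filter_outlier_samples(calls_q)
    bad = set(removed_outlier)
    samples = [s for s in cohort.truth.sample_ids if s in set(kept_signal) and s not in bad]
    calls_q = [c for c in calls_q if c.sample_id not in bad]
    calls = merge_adjacent_calls(calls_q)
    cnvrs = build_cnvrs(calls)
    tables = genotype_all_biallelic(cnvrs, samples)
    summary = summarize_cnvrs(calls, cnvrs, cohort.chrom_lengths)
    return CallSet(
        calls_raw, samples, removed_signal, removed_outlier, calls, cnvrs, tables, summary
    )


@dataclass
class DifferentiationScan:
    fsts: list[FstResult]
    vsts: list[VstResult]
    outliers: set[str]
    threshold: float
    manhattan: pd.DataFrame
    corr_unfiltered: float
    n_unfiltered: int
    corr_min5_both: float
    n_min5_both: int


def differentiation_scan(
    cohort: SyntheticCohort, cs: CallSet, min_copies: int = 5
) -> DifferentiationScan:
    t = cohort.truth
    popmap = dict(zip(t.sample_ids, t.populations))
    pop1 = [s for s in cs.samples if popmap[s] == "pop1"]
    pop2 = [s for s in cs.samples if popmap[s] == "pop2"]
    sample_pos = {s: j for j, s in enumerate(cs.samples)}
    i1 = np.array([sample_pos[s] for s in pop1])
    i2 = np.array([sample_pos[s] for s in pop2])
    fsts, vsts = [], []
    for r in cs.cnvrs:
        if r.cnvr_id not in cs.tables:
            continue
        d = cs.tables[r.cnvr_id].dosage.astype(float)
        fsts.append(fst_from_dosages(d[i1], d[i2], r.cnvr_id))
        vsts.append(vst(cohort.lrr, r, pop1, pop2))
    outliers, threshold, manhattan = fst_outlier_scan(fsts)
    corr_all, n_all = fst_vst_concordance(fsts, vsts)
    kept = filter_min_copies(
        [r for r in cs.cnvrs if r.cnvr_id in cs.tables],
        popmap, ("pop1", "pop2"), min_copies=min_copies, mode="both",
    )
    kept_ids = {r.cnvr_id for r in kept}
    corr_b, n_b = fst_vst_concordance(
        [f for f in fsts if f.cnvr_id in kept_ids],
        [v for v in vsts if v.cnvr_id in kept_ids],
    )
    return DifferentiationScan(
        fsts, vsts, outliers, threshold, manhattan, corr_all, n_all, corr_b, n_b
    )


@dataclass
class FunctionalScan:
    labels: dict[str, str]  # cnvr_id -> category label
    genic_pct: float
    permutation: PermutationResult


def functional_scan(
    cohort: SyntheticCohort, cs: CallSet, n_perm: int = 1000, seed: int = 0
) -> FunctionalScan:
    index = GeneIndex(cohort.genes)
    labels = {
        r.cnvr_id: assign_functional_category(r, index).label for r in cs.cnvrs
    }
    genic = sum(1 for l in labels.values() if l != "intergenic")
    features = [(g.chrom, g.start, g.end) for g in cohort.genes]
    perm = permutation_overlap_test(
        cs.cnvrs, features, cohort.chrom_lengths, n_perm=n_perm, seed=seed
    )
    return FunctionalScan(
        labels, 100.0 * genic / len(labels) if labels else float("nan"), perm
    )


@dataclass
class LdScan:
    pairs_cnvr: pd.DataFrame
    pairs_snp: pd.DataFrame
    profile: pd.DataFrame
    tag_cnvr: pd.DataFrame
    tag_snp: pd.DataFrame
    qtl_summary: pd.DataFrame


def _subset_samples(geno: VariantGenotypes, samples: Sequence[str]) -> VariantGenotypes:
    idx = geno.sample_indices(samples)
    return VariantGenotypes(
        geno.variants, list(samples), geno.dosage[:, idx],
        None if geno.phase is None else geno.phase[:, idx],
    )


def ld_scan(
    cohort: SyntheticCohort,
    cs: CallSet,
    population: str = "pop1",
    window: int = 100_000,
    common_maf: float = 0.05,
    max_snp_anchors: int = 200,
    seed: int = 0,
) -> LdScan:
    """CNVR-SNP and frequency-matched SNP-SNP LD within one population.

    SNPs are pre-filtered (MAF, call rate, Hardy-Weinberg) and masked when
    inside a CNVR; common bi-allelic CNVRs (MAF >= common_maf in the
    population) are the CNVR anchors, and SNP anchors are drawn from the
    same MAF range (at most ``max_snp_anchors``, seeded subsample).
    """
    t = cohort.truth
    popmap = dict(zip(t.sample_ids, t.populations))
    pop = [s for s in cs.samples if popmap[s] == population]
    snp_geno = _subset_samples(cohort.snp_genotypes, pop)
    kept_rows, _ = ld_mod.filter_variants_for_ld(snp_geno)
    snp_tab = snp_geno.variants.iloc[kept_rows][["variant_id", "chrom", "pos"]]
    keep_mask = ld_mod.mask_snps_in_cnvrs(snp_tab, cs.cnvrs)
    snp_rows = kept_rows[keep_mask]

    sample_pos = {s: j for j, s in enumerate(cs.samples)}
    idx = np.array([sample_pos[s] for s in pop])
    cnvr_rows_meta, cnvr_dosage = [], []
    cnvr_class = {}
    for r in cs.cnvrs:
        if r.cnvr_id not in cs.tables:
            continue
        d = cs.tables[r.cnvr_id].dosage.astype(float)[idx]
        f = d.sum() / (2 * len(d))
        if min(f, 1 - f) < common_maf:
            continue
        cnvr_rows_meta.append(
            {"variant_id": r.cnvr_id, "chrom": r.chrom, "pos": r.start,
             "end": r.end, "kind": "cnvr"}
        )
        cnvr_dosage.append(d)
        cnvr_class[len(cnvr_rows_meta) - 1] = f"{r.type}_cnvr"
    n_cnvr = len(cnvr_rows_meta)
    variants = pd.concat(
        [pd.DataFrame(cnvr_rows_meta,
                      columns=["variant_id", "chrom", "pos", "end", "kind"]),
         snp_geno.variants],
        ignore_index=True,
    )
    dosage = np.vstack([np.array(cnvr_dosage).reshape(n_cnvr, len(pop)), snp_geno.dosage])
    phase = None
    if snp_geno.phase is not None:
        pad = np.full((n_cnvr, len(pop), 2), -1, dtype=np.int8)
        phase = np.concatenate([pad, snp_geno.phase])
    combined = VariantGenotypes(variants, pop, dosage, phase)

    partner_rows = snp_rows + n_cnvr
    pairs_cnvr = ld_mod.pairwise_r2(
        combined, list(range(n_cnvr)), partner_rows, window=window,
        anchor_class=cnvr_class,
    )

    cnvr_mafs = [
        ld_mod.variant_maf(dosage[i]) for i in range(n_cnvr)
    ]
    maf_hi = max(cnvr_mafs) if cnvr_mafs else 0.5
    snp_mafs = np.array([ld_mod.variant_maf(dosage[r]) for r in partner_rows])
    matched = partner_rows[(snp_mafs >= common_maf) & (snp_mafs <= maf_hi)]
    rng = np.random.default_rng(seed)
    if len(matched) > max_snp_anchors:
        matched = rng.choice(matched, size=max_snp_anchors, replace=False)
    pairs_snp = ld_mod.pairwise_r2(
        combined, sorted(int(m) for m in matched), partner_rows, window=window,
        anchor_class={int(m): "snp" for m in matched},
    )

    profile = ld_mod.ld_decay_profile(
        pd.concat([pairs_cnvr, pairs_snp], ignore_index=True), window=window
    )
    tag_cnvr, _ = ld_mod.taggability(pairs_cnvr)
    tag_snp, _ = ld_mod.taggability(pairs_snp)
    qtl_summary = ld_mod.pair_cnvr_qtl(
        pairs_cnvr, cohort.qtls, cs.cnvrs, window=window,
        snp_positions=combined.variants[["variant_id", "chrom", "pos"]],
    )
    return LdScan(pairs_cnvr, pairs_snp, profile, tag_cnvr, tag_snp, qtl_summary)


def cnvr_population_frequencies(cohort: SyntheticCohort, cs: CallSet) -> pd.DataFrame:
    """Per-CNVR allele frequency and MAF class in each population."""
    t = cohort.truth
    popmap = dict(zip(t.sample_ids, t.populations))
    pop1 = [s for s in cs.samples if popmap[s] == "pop1"]
    pop2 = [s for s in cs.samples if popmap[s] == "pop2"]
    rows = []
    for r in cs.cnvrs:
        if r.cnvr_id not in cs.tables:
            continue
        tab = cs.tables[r.cnvr_id]
        f1 = allele_frequency(tab, pop1)
        f2 = allele_frequency(tab, pop2)
        rows.append(
            {
                "cnvr_id": r.cnvr_id, "chrom": r.chrom, "start": r.start,
                "end": r.end, "type": r.type,
                "af_pop1": f1, "af_pop2": f2,
                "maf_class_pop1": classify_maf(f1), "maf_class_pop2": classify_maf(f2),
            }
        )
    return pd.DataFrame(rows)
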