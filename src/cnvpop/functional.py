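"""Functional impact of CNVRs: gene-overlap categories, permutation
enrichment test, and chi-square association of category with CNVR features.

Each CNVR receives exactly one category by a fixed priority: whole_gene >
stop_codon > promoter > intronic > exonic, with intergenic for regions
touching no gene body and no promoter window. Promoter windows are the
strand-aware 500 bp immediately upstream of a transcription start site.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict
from typing import Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .types import Cnvr, GeneModel

CATEGORIES = ("intergenic", "intronic", "whole_gene", "stop_codon", "promoter", "exonic")

DEFAULT_PROMOTER_BP = 500


@dataclass(frozen=True)
class FunctionalCategory:
    label: str
    gene_ids: tuple[str, ...]

    @property
    def genic(self) -> bool:
        return self.label != "intergenic"


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def promoter_window(tss: int, strand: str, promoter_bp: int = DEFAULT_PROMOTER_BP):
    """Strand-aware upstream window: [TSS-500, TSS-1] on +, [TSS+1, TSS+500] on -."""
    if strand == "+":
        return max(1, tss - promoter_bp), tss - 1
    return tss + 1, tss + promoter_bp


class GeneIndex:
    """Interval lookups over gene bodies, exons, stop codons and promoters."""

    def __init__(self, genes: Sequence[GeneModel], promoter_bp: int = DEFAULT_PROMOTER_BP):
        self.genes = {g.gene_id: g for g in genes}
        self.promoter_bp = promoter_bp
        self._body: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._promoter: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            # IntervalTree is half-open; store [start, end+1)
            self._body[g.chrom].addi(g.start, g.end + 1, g.gene_id)
            for t in g.transcripts:
                ps, pe = promoter_window(t.tss, g.strand, promoter_bp)
                if ps <= pe:
                    self._promoter[g.chrom].addi(ps, pe + 1, g.gene_id)

    def body_hits(self, chrom: str, start: int, end: int) -> set[str]:
        return {iv.data for iv in self._body.get(chrom, IntervalTree()).overlap(start, end + 1)}

    def promoter_hits(self, chrom: str, start: int, end: int) -> set[str]:
        return {iv.data for iv in self._promoter.get(chrom, IntervalTree()).overlap(start, end + 1)}


def assign_functional_category(
    cnvr: Cnvr,
    genes: Sequence[GeneModel] | GeneIndex,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
) -> FunctionalCategory:
    """Assign the single functional category of a CNVR.

    Priority: intergenic (no gene-body or promoter overlap); whole_gene
    (>=1 gene fully contained); stop_codon; promoter; intronic (every
    gene-body overlap avoids all exons); exonic (residual genic class).
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, promoter_bp)
    body = index.body_hits(cnvr.chrom, cnvr.start, cnvr.end)
    promoter = index.promoter_hits(cnvr.chrom, cnvr.start, cnvr.end)
    if not body and not promoter:
        return FunctionalCategory("intergenic", ())
    contained = tuple(
        sorted(
            gid for gid in body
            if cnvr.start <= index.genes[gid].start and index.genes[gid].end <= cnvr.end
        )
    )
    if contained:
        return FunctionalCategory("whole_gene", contained)
    stop_hits = tuple(
        sorted(
            gid for gid in body
            for t in index.genes[gid].transcripts
            if t.stop_codon is not None
            and _overlaps(cnvr.start, cnvr.end, t.stop_codon[0], t.stop_codon[1])
        )
    )
    if stop_hits:
        return FunctionalCategory("stop_codon", tuple(dict.fromkeys(stop_hits)))
    if promoter:
        return FunctionalCategory("promoter", tuple(sorted(promoter)))
    exon_hits = set()
    for gid in body:
        for t in index.genes[gid].transcripts:
            if any(_overlaps(cnvr.start, cnvr.end, s, e) for s, e in t.exons):
                exon_hits.add(gid)
                break
    if not exon_hits:
        return FunctionalCategory("intronic", tuple(sorted(body)))
    return FunctionalCategory("exonic", tuple(sorted(body)))


@dataclass(frozen=True)
class PermutationResult:
    observed_overlap: int
    perm_mean: float
    perm_sd: float
    z_score: float  # NaN when the permutation distribution is degenerate
    empirical_p: float
    n_perm: int
    seed: int


class _FeatureLookup:
    """Sorted-array overlap queries: any feature overlapping [start, end]?"""

    def __init__(self, features: Sequence[tuple[str, int, int]]):
        self._starts: dict[str, np.ndarray] = {}
        self._prefix_max_end: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for chrom, s, e in features:
            by_chrom[chrom].append((s, e))
        for chrom, spans in by_chrom.items():
            spans.sort()
            starts = np.array([s for s, _ in spans])
            ends = np.array([e for _, e in spans])
            self._starts[chrom] = starts
            self._prefix_max_end[chrom] = np.maximum.accumulate(ends)

    def any_overlap(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        if chrom not in self._starts:
            return np.zeros(len(starts), dtype=bool)
        fs = self._starts[chrom]
        pme = self._prefix_max_end[chrom]
        idx = np.searchsorted(fs, ends, side="right")
        out = np.zeros(len(starts), dtype=bool)
        nz = idx > 0
        out[nz] = pme[idx[nz] - 1] >= starts[nz]
        return out


def permutation_overlap_test(
    cnvrs: Sequence[Cnvr],
    features: Sequence[tuple[str, int, int]],
    chrom_lengths: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for CNVR-feature overlap enrichment.

    Each permutation re-places every CNVR uniformly at random on the
    genome, preserving its length: the chromosome is drawn with probability
    proportional to the number of valid start positions, then the start is
    uniform among them. The statistic is the number of CNVRs overlapping
    >= 1 feature by >= 1 bp. Enrichment p is (#{perm >= obs} + 1)/(n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths, key=lambda c: c)
    clens = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    lookup = _FeatureLookup(features)

    obs = 0
    for r in cnvrs:
        if bool(lookup.any_overlap(r.chrom, np.array([r.start]), np.array([r.end]))[0]):
            obs += 1

    lengths = np.array([r.length for r in cnvrs], dtype=np.int64)
    placeable = clens[None, :] - lengths[:, None] + 1  # (n_regions, n_chroms)
    placeable = np.maximum(placeable, 0)
    totals = placeable.sum(axis=1)
    if (totals == 0).any():
        bad = [cnvrs[i].cnvr_id for i in np.nonzero(totals == 0)[0]]
        raise ValueError(f"regions longer than every chromosome: {bad}")
    probs = placeable / totals[:, None]

    counts = np.zeros(n_perm, dtype=np.int64)
    for p in range(n_perm):
        u = rng.random(len(cnvrs))
        chrom_idx = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
        n_pos = placeable[np.arange(len(cnvrs)), chrom_idx]
        starts = rng.integers(1, n_pos + 1)
        ends = starts + lengths - 1
        hit = np.zeros(len(cnvrs), dtype=bool)
        for ci, chrom in enumerate(chroms):
            m = chrom_idx == ci
            if m.any():
                hit[m] = lookup.any_overlap(chrom, starts[m], ends[m])
        counts[p] = int(hit.sum())

    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n_perm > 1 else 0.0
    z = (obs - mean) / sd if sd > 0 else float("nan")
    emp_p = (int((counts >= obs).sum()) + 1) / (n_perm + 1)
    return PermutationResult(obs, mean, sd, z, emp_p, n_perm, seed)


def chisq_category_association(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table of counts.

    Returns (chi2, df, p). Zero marginals raise; expected cells < 5 warn.
    """
    import warnings

    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row or column")
    res = stats.chi2_contingency(t, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("some expected cell counts are below 5", stacklevel=2)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def category_counts(
    labels: Sequence[str], by: Optional[Sequence[str]] = None
) -> "np.ndarray | dict":
    """Tally category labels, optionally cross-classified by a second factor."""
    if by is None:
        out = {c: 0 for c in CATEGORIES}
        for l in labels:
            out[l] += 1
        return out
    table: dict[str, dict[str, int]] = defaultdict(lambda: {c: 0 for c in CATEGORIES})
    for l, b in zip(labels, by):
        table[b][l] += 1
    return dict(table)
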