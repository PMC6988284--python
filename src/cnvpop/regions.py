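"""CNV-region (CNVR) construction, genotyping, frequencies and summaries.

Calls from all samples are aggregated into regions by transitive >=1 bp
overlap (the Redon-style union rule). Pure deletion and pure duplication
regions are treated as bi-allelic loci and genotyped as +/+, +/- and -/-
(dosage 0/1/2 of the alternate, non-diploid allele); mixed regions are
"complex" and not genotyped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    CNVR_COMPLEX,
    CNVR_DELETION,
    CNVR_DUPLICATION,
    Cnvr,
    CnvCall,
    natural_chrom_key,
)

logger = logging.getLogger(__name__)

MAF_COMMON = "common"
MAF_INTERMEDIATE = "intermediate"
MAF_RARE = "rare"

COMMON_MIN_MAF = 0.05
INTERMEDIATE_MIN_MAF = 0.01


def build_cnvrs(calls: Sequence[CnvCall]) -> list[Cnvr]:
    """Aggregate calls into CNVRs by transitive >= 1 bp overlap.

    The region span is the union of member spans; bookended calls
    (start2 == end1 + 1) share no base pair and stay separate. Region type
    is deletion if all member states < 2, duplication if all > 2, else
    complex. Ids are assigned in (chrom, start) order.
    """
    by_chrom: dict[str, list[CnvCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)
    clusters: list[tuple[str, int, int, list[CnvCall]]] = []
    for chrom in sorted(by_chrom, key=natural_chrom_key):
        seq = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cur_start, cur_end, members = None, None, []
        for c in seq:
            if cur_start is None:
                cur_start, cur_end, members = c.start, c.end, [c]
            elif c.start <= cur_end:  # >= 1 bp overlap with the running union
                cur_end = max(cur_end, c.end)
                members.append(c)
            else:
                clusters.append((chrom, cur_start, cur_end, members))
                cur_start, cur_end, members = c.start, c.end, [c]
        if cur_start is not None:
            clusters.append((chrom, cur_start, cur_end, members))
    width = max(4, len(str(len(clusters))))
    out = []
    for i, (chrom, start, end, members) in enumerate(clusters, start=1):
        states = {m.cn_state for m in members}
        if all(s < 2 for s in states):
            rtype = CNVR_DELETION
        elif all(s > 2 for s in states):
            rtype = CNVR_DUPLICATION
        else:
            rtype = CNVR_COMPLEX
        out.append(Cnvr(f"cnvr_{i:0{width}d}", chrom, start, end, rtype, list(members)))
    return out


@dataclass
class CnvrGenotypeTable:
    """Per-sample bi-allelic genotypes for one CNVR."""

    cnvr_id: str
    sample_ids: list[str]
    dosage: np.ndarray  # int, 0/1/2 alternate-allele copies

    @property
    def genotype_labels(self) -> list[str]:
        return [{0: "+/+", 1: "+/-", 2: "-/-"}[int(d)] for d in self.dosage]


def genotype_cnvr(cnvr: Cnvr, samples: Sequence[str]) -> CnvrGenotypeTable:
    """Genotype a bi-allelic CNVR from its member calls.

    Deletions: cn=1 -> dosage 1, cn=0 -> dosage 2; duplications: cn=3 -> 1,
    cn=4 -> 2. Samples with no member call are dosage 0 (+/+). A sample with
    several member calls takes the most extreme state; cn >= 5 is clamped to
    dosage 2 with a warning (the bi-allelic model caps at two alt alleles).
    """
    if not cnvr.is_biallelic:
        raise ValueError(f"{cnvr.cnvr_id} is {cnvr.type}: not bi-allelic")
    per_sample_cn: dict[str, int] = {}
    for c in cnvr.member_calls:
        cur = per_sample_cn.get(c.sample_id)
        if cur is None or abs(c.cn_state - 2) > abs(cur - 2):
            per_sample_cn[c.sample_id] = c.cn_state
    dosage = np.zeros(len(samples), dtype=int)
    for j, s in enumerate(samples):
        cn = per_sample_cn.get(s)
        if cn is None:
            continue
        if cnvr.type == CNVR_DELETION:
            dosage[j] = 2 - cn
        else:
            if cn >= 5:
                logger.warning(
                    "%s: sample %s has cn=%d, clamped to dosage 2", cnvr.cnvr_id, s, cn
                )
                dosage[j] = 2
            else:
                dosage[j] = cn - 2
    return CnvrGenotypeTable(cnvr.cnvr_id, list(samples), dosage)


def allele_frequency(table: CnvrGenotypeTable, pop: Sequence[str]) -> float:
    """Alternate-allele frequency of a CNVR in a sample subset."""
    pop = list(pop)
    if not pop:
        raise ValueError("empty population")
    idx = {s: j for j, s in enumerate(table.sample_ids)}
    d = np.array([table.dosage[idx[s]] for s in pop], dtype=float)
    return float(d.sum() / (2 * len(pop)))


def classify_maf(freq: float) -> str:
    """MAF class: common (>=0.05), intermediate ([0.01, 0.05)), rare (<0.01)."""
    maf = min(freq, 1.0 - freq)
    if maf >= COMMON_MIN_MAF:
        return MAF_COMMON
    if maf >= INTERMEDIATE_MIN_MAF:
        return MAF_INTERMEDIATE
    return MAF_RARE


def site_frequency_spectrum(
    freqs_by_type: Mapping[str, Sequence[float]], bin_width: float = 0.05
) -> pd.DataFrame:
    """Histogram of allele frequencies in [0, 0.5], split by CNVR type.

    Bins are left-closed right-open; the last bin is closed at 0.5.
    """
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    if edges[-1] < 0.5:
        edges = np.append(edges, 0.5)
    rows = {}
    for rtype, freqs in freqs_by_type.items():
        f = np.asarray(list(freqs), dtype=float)
        if f.size and (f.min() < 0 or f.max() > 0.5):
            raise ValueError("SFS frequencies must lie in [0, 0.5]")
        counts, _ = np.histogram(f, bins=edges)
        rows[rtype] = counts
    out = pd.DataFrame(rows if rows else None)
    out.insert(0, "bin_left", edges[:-1])
    out.insert(1, "bin_right", edges[1:])
    return out


def summarize_cnvrs(
    calls: Sequence[CnvCall],
    cnvrs: Sequence[Cnvr],
    chrom_lengths: Mapping[str, int],
) -> dict:
    """Cohort-level CNV/CNVR summary.

    Reports per-type CNVR counts and mean lengths, calls per sample, the
    deletion:duplication call ratio, and per-chromosome plus genome-wide
    coverage (% of bp under the CNVR union).
    """
    for r in cnvrs:
        if r.chrom not in chrom_lengths:
            raise ValueError(f"{r.cnvr_id} on {r.chrom}: no chromosome length given")
    n_samples = len({c.sample_id for c in calls})
    n_del_calls = sum(1 for c in calls if c.cn_state < 2)
    n_dup_calls = sum(1 for c in calls if c.cn_state > 2)
    per_type: dict[str, dict] = {}
    for rtype in (CNVR_DELETION, CNVR_DUPLICATION, CNVR_COMPLEX):
        lens = [r.length for r in cnvrs if r.type == rtype]
        per_type[rtype] = {
            "n": len(lens),
            "mean_length_bp": float(np.mean(lens)) if lens else float("nan"),
        }
    cov_by_chrom = {}
    covered_total = 0
    for chrom in sorted(chrom_lengths, key=natural_chrom_key):
        bp = sum(r.length for r in cnvrs if r.chrom == chrom)
        covered_total += bp
        cov_by_chrom[chrom] = 100.0 * bp / chrom_lengths[chrom]
    genome_bp = sum(chrom_lengths.values())
    return {
        "n_calls": len(calls),
        "n_samples": n_samples,
        "calls_per_sample": len(calls) / n_samples if n_samples else float("nan"),
        "n_deletion_calls": n_del_calls,
        "n_duplication_calls": n_dup_calls,
        "del_dup_call_ratio": n_del_calls / n_dup_calls if n_dup_calls else float("nan"),
        "n_cnvrs": len(cnvrs),
        "cnvrs_by_type": per_type,
        "coverage_pct_by_chrom": cov_by_chrom,
        "genome_coverage_pct": 100.0 * covered_total / genome_bp if genome_bp else float("nan"),
        "cnvr_bp": covered_total,
        "genome_bp": genome_bp,
    }


def genotype_all_biallelic(
    cnvrs: Sequence[Cnvr], samples: Sequence[str]
) -> dict[str, CnvrGenotypeTable]:
    """Genotype every bi-allelic CNVR; complex regions are skipped."""
    return {
        r.cnvr_id: genotype_cnvr(r, samples) for r in cnvrs if r.is_biallelic
    }
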