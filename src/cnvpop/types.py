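"""Core domain containers shared across the pipeline.

Coordinates are 1-based and inclusive throughout the package (the convention
of the rawcnv and GFF3 inputs); conversion to 0-based half-open BED happens
only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MIN_CN = 0
MAX_CN = 6


@dataclass(frozen=True)
class CnvCall:
    """One copy-number segment called in one sample.

    ``cn_state`` is the integer copy number (0–6, never 2: the diploid
    state is not a call). ``num_snps`` is the number of array SNPs
    supporting the call.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cn_state: int
    num_snps: int
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1 (1-based), got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if not (MIN_CN <= self.cn_state <= MAX_CN):
            raise ValueError(f"cn_state {self.cn_state} outside {MIN_CN}..{MAX_CN}")
        if self.cn_state == 2:
            raise ValueError("cn_state 2 is the diploid state, not a CNV call")
        if self.num_snps < 1:
            raise ValueError("num_snps must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_deletion(self) -> bool:
        return self.cn_state < 2


CNVR_DELETION = "deletion"
CNVR_DUPLICATION = "duplication"
CNVR_COMPLEX = "complex"


@dataclass
class Cnvr:
    """A CNV region: the union of calls overlapping by >= 1 bp across samples."""

    cnvr_id: str
    chrom: str
    start: int
    end: int
    type: str
    member_calls: list[CnvCall] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_biallelic(self) -> bool:
        return self.type in (CNVR_DELETION, CNVR_DUPLICATION)

    def carrier_samples(self) -> set[str]:
        return {c.sample_id for c in self.member_calls}


@dataclass(frozen=True)
class Transcript:
    tx_id: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    stop_codon: Optional[tuple[int, int]]
    tss: int


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcripts; source of the functional categories."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def start(self) -> int:
        return min(e[0] for t in self.transcripts for e in t.exons)

    @property
    def end(self) -> int:
        return max(e[1] for t in self.transcripts for e in t.exons)


@dataclass(frozen=True)
class QtlRecord:
    qtl_id: str
    chrom: str
    start: int
    end: int
    trait: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid QTL span {self.start}-{self.end}")


class LrrMatrix:
    """Per-SNP x per-sample log-R-ratio values.

    ``snps`` is a DataFrame with columns snp_id, chrom, pos (sorted within
    chromosome); ``values`` is a float array of shape (n_snps, n_samples).
    """

    def __init__(self, snps: pd.DataFrame, sample_ids: Sequence[str], values: np.ndarray):
        snps = snps.reset_index(drop=True)
        required = {"snp_id", "chrom", "pos"}
        if not required.issubset(snps.columns):
            raise ValueError(f"snps must have columns {sorted(required)}")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(snps), len(sample_ids)):
            raise ValueError(
                f"values shape {values.shape} != (n_snps={len(snps)}, n_samples={len(sample_ids)})"
            )
        for _, grp in snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("SNP positions must be sorted within chromosome")
        self.snps = snps
        self.sample_ids = list(sample_ids)
        self.values = values
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        return np.array([self._sample_index[s] for s in samples], dtype=int)

    def snps_in_span(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of SNPs with chrom==chrom and start <= pos <= end."""
        mask = (self.snps["chrom"].values == chrom)
        pos = self.snps["pos"].values
        return np.nonzero(mask & (pos >= start) & (pos <= end))[0]


VARIANT_SNP = "snp"
VARIANT_CNVR = "cnvr"


class VariantGenotypes:
    """Bi-allelic dosages (0/1/2 alternate-allele copies) for SNPs and CNVRs.

    ``variants`` is a DataFrame with columns variant_id, chrom, pos, end,
    kind ('snp' or 'cnvr'); ``dosage`` is float (n_variants, n_samples) with
    NaN for missing. ``phase``, when present, is an int8 array of shape
    (n_variants, n_samples, 2) with haploid alleles (0/1, -1 missing) whose
    sum equals the dosage wherever both are defined.
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        sample_ids: Sequence[str],
        dosage: np.ndarray,
        phase: Optional[np.ndarray] = None,
    ):
        variants = variants.reset_index(drop=True)
        required = {"variant_id", "chrom", "pos", "end", "kind"}
        if not required.issubset(variants.columns):
            raise ValueError(f"variants must have columns {sorted(required)}")
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(variants), len(sample_ids)):
            raise ValueError("dosage shape does not match variants x samples")
        if phase is not None:
            phase = np.asarray(phase, dtype=np.int8)
            if phase.shape != (len(variants), len(sample_ids), 2):
                raise ValueError("phase shape must be (n_variants, n_samples, 2)")
            defined = (phase >= 0).all(axis=2) & ~np.isnan(dosage)
            if not np.array_equal(phase.sum(axis=2)[defined], dosage[defined]):
                raise ValueError("phase alleles must sum to dosage where both defined")
        self.variants = variants
        self.sample_ids = list(sample_ids)
        self.dosage = dosage
        self.phase = phase
        self._variant_index = {v: i for i, v in enumerate(variants["variant_id"])}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def variant_row(self, variant_id: str) -> int:
        return self._variant_index[variant_id]

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        return np.array([self._sample_index[s] for s in samples], dtype=int)

    def subset_variants(self, rows: Sequence[int]) -> "VariantGenotypes":
        rows = np.asarray(rows, dtype=int)
        return VariantGenotypes(
            self.variants.iloc[rows],
            self.sample_ids,
            self.dosage[rows],
            None if self.phase is None else self.phase[rows],
        )


def natural_chrom_key(chrom: str):
    """Sort chromosomes numerically where possible: chr2 before chr10."""
    stem = chrom[3:] if chrom.lower().startswith("chr") else chrom
    try:
        return (0, int(stem), "")
    except ValueError:
        return (1, 0, stem)
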