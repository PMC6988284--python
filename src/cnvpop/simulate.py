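"""Synthetic two-population SNP-array cohort generator.

Emulates the statistical structure of a two-breed dairy-cattle array
dataset: LD-structured SNP haplotypes, CNV loci with a rare-skewed allele
frequency spectrum (deletions more frequent but shorter than duplications),
per-sample log-R-ratio signal shifted by copy-number state, PennCNV-style
calls with boundary jitter and false-positive singletons, plus gene and QTL
annotations. Everything is deterministic under a fixed seed, so every
downstream stage is testable without external data.

Haplotypes follow a latent Gaussian AR(1) (first-order Markov) model: the
latent correlation between neighbouring SNPs is exp(-d/L), thresholded to
alleles at each SNP's target frequency, which yields SNP-SNP r2 that decays
with distance while preserving the per-SNP frequencies exactly. Each CNV
locus is anchored to a nearby SNP haplotype background so true CNV-SNP LD
exists; a configurable fraction of duplication loci is instead "dispersed"
onto random backgrounds (weaker LD, mimicking dispersed duplications).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as cio
from .qc import SampleQcMetrics
from .types import (
    CnvCall,
    GeneModel,
    LrrMatrix,
    QtlRecord,
    Transcript,
    VariantGenotypes,
)

DEFAULT_LRR_SHIFT = {0: -2.0, 1: -0.5, 3: 0.3, 4: 0.6}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the post-QC analysis sets of a two-breed dairy cohort
    (315 + 107 animals) with ~30-55 CNV calls per sample, a 1.8:1
    deletion:duplication call ratio, deletion loci shorter than
    duplications, and a rare-skewed CNV frequency spectrum, on a genome
    scaled to 5 x 20 Mb autosomes at BovineHD-like SNP density.
    """

    n_pop1: int = 315
    n_pop2: int = 107
    n_chroms: int = 5
    chrom_length: int = 20_000_000
    snp_spacing_mean: int = 3_400
    n_cnv_loci: int = 200
    deletion_fraction: float = 0.64
    maf_distribution: str = "beta_rare"  # or "uniform"
    n_diverged_loci: int = 5
    diverged_delta_af: float = 0.4
    lrr_noise_sd: float = 0.16
    fp_singleton_rate: float = 2.0
    boundary_jitter_sd: float = 2_000.0
    seed: int = 0
    # secondary knobs
    ld_decay_length: float = 60_000.0
    deletion_mean_len: float = 44_200.0
    duplication_mean_len: float = 74_600.0
    min_locus_snps: int = 5
    locus_margin: int = 100_000
    dispersed_dup_fraction: float = 0.25
    lrr_shift: dict = field(default_factory=lambda: dict(DEFAULT_LRR_SHIFT))
    gene_spacing_mean: float = 120_000.0
    n_qtls: int = 120

    def __post_init__(self) -> None:
        counts = dict(
            n_pop1=self.n_pop1, n_pop2=self.n_pop2, n_chroms=self.n_chroms,
            n_cnv_loci=self.n_cnv_loci, n_diverged_loci=self.n_diverged_loci,
        )
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, v in dict(
            deletion_fraction=self.deletion_fraction,
            diverged_delta_af=self.diverged_delta_af,
            dispersed_dup_fraction=self.dispersed_dup_fraction,
        ).items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.chrom_length <= self.snp_spacing_mean:
            raise ValueError("chrom_length must exceed snp_spacing_mean")
        if self.n_diverged_loci > self.n_cnv_loci:
            raise ValueError("n_diverged_loci > n_cnv_loci")
        if self.maf_distribution not in ("beta_rare", "uniform"):
            raise ValueError(f"unknown maf_distribution {self.maf_distribution!r}")


@dataclass
class TruthSet:
    """Ground truth of the generated cohort."""

    loci: pd.DataFrame  # locus_id, chrom, start, end, type, af_pop1, af_pop2, ...
    carrier_cn: np.ndarray  # (n_loci, n_samples) integer copy number
    carrier_hap: np.ndarray  # (n_loci, n_samples, 2) bool: CNV allele per haplotype
    sample_ids: list[str]
    populations: list[str]  # per-sample population label

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in zip(self.sample_ids, self.populations) if p == pop]

    def realized_af(self, locus_row: int, pop: str) -> float:
        idx = [i for i, p in enumerate(self.populations) if p == pop]
        return float(self.carrier_hap[locus_row][idx].mean())


@dataclass
class SyntheticCohort:
    config: CohortConfig
    truth: TruthSet
    lrr: LrrMatrix
    snp_genotypes: VariantGenotypes  # phased truth SNP genotypes
    genes: list[GeneModel]
    qtls: list[QtlRecord]
    qc_metrics: list[SampleQcMetrics]
    chrom_lengths: dict[str, int]

    def write(self, outdir) -> None:
        """Write every external file the pipeline consumes (seed-stamped)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seed = self.config.seed
        calls = emit_calls(self.truth, self.config, lrr=self.lrr)
        cio.write_cnv_calls(calls, outdir / "calls.rawcnv", seed=seed)
        cio.write_lrr_matrix(self.lrr, outdir / "lrr.tsv", seed=seed)
        cio.write_vcf(self.snp_genotypes, outdir / "snps.vcf", seed=seed)
        cio.write_gff3(self.genes, outdir / "genes.gff3", seed=seed)
        cio.write_qtl_tsv(self.qtls, outdir / "qtls.tsv", seed=seed)
        with open(outdir / "samples.tsv", "w") as fh:
            fh.write(f"# seed={seed}\nsample_id\tpopulation\n")
            for s, p in zip(self.truth.sample_ids, self.truth.populations):
                fh.write(f"{s}\t{p}\n")
        with open(outdir / "qc_metrics.tsv", "w") as fh:
            fh.write(f"# seed={seed}\nsample_id\tlrr_sd\tbaf_sd\twaviness_factor\n")
            for m in self.qc_metrics:
                fh.write(f"{m.sample_id}\t{m.lrr_sd:.4f}\t{m.baf_sd:.6f}\t{m.waviness_factor:.4f}\n")
        truth_payload = {
            "seed": seed,
            "loci": self.loci_records(),
            "gene_exon_counts": {
                g.gene_id: sum(len(t.exons) for t in g.transcripts) for g in self.genes
            },
            "chrom_lengths": self.chrom_lengths,
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth_payload, fh, indent=1)

    def loci_records(self) -> list[dict]:
        recs = self.truth.loci.to_dict(orient="records")
        for i, r in enumerate(recs):
            r["realized_af_pop1"] = self.truth.realized_af(i, "pop1")
            r["realized_af_pop2"] = self.truth.realized_af(i, "pop2")
        return recs


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _snp_map(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = 1 + rng.integers(0, config.snp_spacing_mean)
        k = 0
        while pos <= config.chrom_length:
            k += 1
            rows.append((f"{chrom}_snp{k:06d}", chrom, int(pos)))
            gap = max(1, int(rng.exponential(config.snp_spacing_mean)))
            pos += gap
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def _haplotypes(
    snps: pd.DataFrame, n_haploids: int, config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent-AR(1) haplotypes: returns (alleles (n_snps, n_haploids), snp freqs)."""
    n = len(snps)
    freqs = rng.uniform(0.05, 0.5, size=n)
    thresholds = sps.norm.ppf(freqs)
    alleles = np.empty((n, n_haploids), dtype=np.int8)
    chroms = snps["chrom"].values
    pos = snps["pos"].values
    z = None
    prev_chrom = None
    for i in range(n):
        eps = rng.standard_normal(n_haploids)
        if chroms[i] != prev_chrom:
            z = eps
            prev_chrom = chroms[i]
        else:
            rho = np.exp(-(pos[i] - pos[i - 1]) / config.ld_decay_length)
            z = rho * z + np.sqrt(1.0 - rho * rho) * eps
        alleles[i] = (z < thresholds[i]).astype(np.int8)
    return alleles, freqs


def _draw_locus_af(config: CohortConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    if config.maf_distribution == "beta_rare":
        af = rng.beta(0.6, 6.0, size=size)
    else:
        af = rng.uniform(0.0, 0.5, size=size)
    return np.clip(af, 0.002, 0.45)


def _place_loci(
    config: CohortConfig, snps: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Place non-overlapping CNV loci (margin-separated) with enough SNPs."""
    chrom_pos = {
        c: snps.loc[snps["chrom"] == c, "pos"].values for c in snps["chrom"].unique()
    }
    chroms = list(chrom_pos)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    n_del = int(round(config.n_cnv_loci * config.deletion_fraction))
    types = ["deletion"] * n_del + ["duplication"] * (config.n_cnv_loci - n_del)
    rng.shuffle(types)
    for li, ltype in enumerate(types):
        mean_len = (
            config.deletion_mean_len if ltype == "deletion" else config.duplication_mean_len
        )
        ok = False
        for _ in range(2000):
            length = int(np.clip(rng.exponential(mean_len), 15_000, 400_000))
            chrom = chroms[rng.integers(0, len(chroms))]
            if length + 2 >= config.chrom_length:
                continue
            start = int(rng.integers(1, config.chrom_length - length))
            end = start + length - 1
            if any(
                start - config.locus_margin <= e and s <= end + config.locus_margin
                for s, e in placed[chrom]
            ):
                continue
            pos = chrom_pos[chrom]
            inside = np.searchsorted(pos, end, "right") - np.searchsorted(pos, start)
            if inside < config.min_locus_snps:
                continue
            placed[chrom].append((start, end))
            rows.append((f"locus_{li + 1:04d}", chrom, start, end, ltype))
            ok = True
            break
        if not ok:
            raise RuntimeError("could not place CNV loci; genome too small for config")
    loci = pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end", "type"])
    loci = loci.sort_values(["chrom", "start"]).reset_index(drop=True)

    af1 = _draw_locus_af(config, rng, len(loci))
    af2 = af1.copy()
    diverged = np.zeros(len(loci), dtype=bool)
    if config.n_diverged_loci > 0:
        pick = rng.choice(len(loci), size=config.n_diverged_loci, replace=False)
        diverged[pick] = True
        for i in pick:
            up = af1[i] + config.diverged_delta_af
            down = af1[i] - config.diverged_delta_af
            if up <= 1.0:
                af2[i] = up
            elif down >= 0.0:
                af2[i] = down
            else:
                raise ValueError(
                    "diverged_delta_af pushes allele frequency outside [0, 1]"
                )
    loci["af_pop1"] = af1
    loci["af_pop2"] = af2
    loci["diverged"] = diverged
    return loci


def _assign_carriers(
    loci: pd.DataFrame,
    snps: pd.DataFrame,
    haplotypes: np.ndarray,
    populations: list[str],
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-haplotype CNV alleles anchored to local SNP backgrounds.

    For each locus an anchor SNP just outside the span is chosen; within
    each population, haplotypes carrying the anchor allele are preferred
    carriers so that CNV-SNP LD exists, while the expected carrier
    frequency matches the target allele frequency. Dispersed duplication
    loci ignore the anchor (random background).
    """
    n_hap = haplotypes.shape[1]
    n_samples = n_hap // 2
    pop_arr = np.repeat(populations, 2)
    carrier = np.zeros((len(loci), n_hap), dtype=bool)
    anchors: list[int] = []
    chrom_all = snps["chrom"].values
    pos_all = snps["pos"].values
    for i, row in loci.iterrows():
        m = chrom_all == row["chrom"]
        pos = pos_all[m]
        rows_m = np.nonzero(m)[0]
        # nearest SNP outside the span, within 30 kb of a boundary
        left = rows_m[(pos < row["start"]) & (pos >= row["start"] - 30_000)]
        right = rows_m[(pos > row["end"]) & (pos <= row["end"] + 30_000)]
        cand = np.concatenate([left, right])
        anchor = int(cand[rng.integers(0, len(cand))]) if len(cand) else -1
        dispersed = row["type"] == "duplication" and rng.random() < config.dispersed_dup_fraction
        anchors.append(-1 if dispersed else anchor)
        for pop, af in (("pop1", row["af_pop1"]), ("pop2", row["af_pop2"])):
            hsel = np.nonzero(pop_arr == pop)[0]
            if anchor >= 0 and not dispersed:
                a = haplotypes[anchor, hsel].astype(bool)
                fa = a.mean()
                if 0.0 < fa < 1.0:
                    q1 = min(af / fa, 1.0)
                    q0 = max(0.0, (af - fa) / (1.0 - fa))
                else:
                    q1 = q0 = af
                u = rng.random(len(hsel))
                carrier[i, hsel] = np.where(a, u < q1, u < q0)
                continue
            carrier[i, hsel] = rng.random(len(hsel)) < af
    carrier_hap = carrier.reshape(len(loci), n_samples, 2)
    sign = np.where(loci["type"].values == "deletion", -1, 1)
    carrier_cn = 2 + sign[:, None] * carrier_hap.sum(axis=2)
    return carrier_cn.astype(int), carrier_hap, anchors


def _make_genes(
    config: CohortConfig, rng: np.random.Generator
) -> list[GeneModel]:
    genes = []
    gi = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = 1 + int(rng.exponential(config.gene_spacing_mean))
        while True:
            length = int(rng.uniform(5_000, 40_000))
            if pos + length - 1 > config.chrom_length:
                break
            gi += 1
            start, end = pos, pos + length - 1
            n_exons = int(rng.integers(2, 9))
            cuts = np.sort(rng.choice(np.arange(1, length - 1), size=2 * n_exons, replace=False))
            exons = tuple(
                (start + int(cuts[2 * k]), start + int(cuts[2 * k + 1])) for k in range(n_exons)
            )
            exons = ((start, exons[0][1]),) + exons[1:-1] + ((exons[-1][0], end),)
            strand = "+" if rng.random() < 0.5 else "-"
            cds = exons
            if strand == "+":
                stop = (max(exons[-1][0], exons[-1][1] - 2), exons[-1][1])
                tss = start
            else:
                stop = (exons[0][0], min(exons[0][1], exons[0][0] + 2))
                tss = end
            tx = Transcript(f"tx_{gi:05d}", exons, cds, stop, tss)
            genes.append(GeneModel(f"gene_{gi:05d}", chrom, strand, (tx,)))
            pos = end + 1 + max(1000, int(rng.exponential(config.gene_spacing_mean)))
    return genes


_TRAITS = ["milk_yield", "protein_pct", "fat_pct", "stature", "fertility", "scs"]


def _make_qtls(config: CohortConfig, rng: np.random.Generator) -> list[QtlRecord]:
    out = []
    for qi in range(config.n_qtls):
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        pos = int(rng.integers(1, config.chrom_length))
        out.append(
            QtlRecord(
                f"qtl_{qi + 1:04d}", chrom, pos, pos,
                _TRAITS[int(rng.integers(0, len(_TRAITS)))],
            )
        )
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort (truth, signal, genotypes, annotation)."""
    n_samples = config.n_pop1 + config.n_pop2
    sample_ids = [f"P1_{i + 1:04d}" for i in range(config.n_pop1)] + [
        f"P2_{i + 1:04d}" for i in range(config.n_pop2)
    ]
    populations = ["pop1"] * config.n_pop1 + ["pop2"] * config.n_pop2
    chrom_lengths = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}

    snps = _snp_map(config, _rng(config, 1))
    haplotypes, _ = _haplotypes(snps, 2 * n_samples, config, _rng(config, 2))
    loci = _place_loci(config, snps, _rng(config, 3))
    carrier_cn, carrier_hap, anchors = _assign_carriers(
        loci, snps, haplotypes, populations, config, _rng(config, 4)
    )
    loci = loci.copy()
    loci["anchor_snp_row"] = anchors

    truth = TruthSet(loci, carrier_cn, carrier_hap, sample_ids, populations)

    rng_sig = _rng(config, 5)
    sample_sd = np.clip(
        rng_sig.normal(config.lrr_noise_sd, 0.01, size=n_samples), 0.05, None
    )
    values = rng_sig.standard_normal((len(snps), n_samples)) * sample_sd[None, :]
    pos_by_chrom = {c: snps.loc[snps["chrom"] == c, "pos"].values for c in chrom_lengths}
    row0_by_chrom = {
        c: int(np.nonzero((snps["chrom"] == c).values)[0][0]) for c in chrom_lengths
    }
    for i, row in loci.iterrows():
        pos = pos_by_chrom[row["chrom"]]
        base = row0_by_chrom[row["chrom"]]
        lo = base + np.searchsorted(pos, row["start"])
        hi = base + np.searchsorted(pos, row["end"], "right")
        for j in range(n_samples):
            cn = carrier_cn[i, j]
            if cn != 2:
                values[lo:hi, j] += config.lrr_shift[int(cn)]
    lrr = LrrMatrix(snps, sample_ids, values)

    phase = haplotypes.T.reshape(n_samples, 2, len(snps)).transpose(2, 0, 1).astype(np.int8)
    dosage = phase.sum(axis=2).astype(float)
    variants = pd.DataFrame(
        {
            "variant_id": snps["snp_id"],
            "chrom": snps["chrom"],
            "pos": snps["pos"],
            "end": snps["pos"],
            "kind": "snp",
        }
    )
    snp_geno = VariantGenotypes(variants, sample_ids, dosage, phase)

    rng_qc = _rng(config, 6)
    metrics = []
    for j, s in enumerate(sample_ids):
        metrics.append(
            SampleQcMetrics(
                s,
                lrr_sd=float(values[:, j].std()),
                baf_sd=float(abs(rng_qc.normal(4e-4, 1e-4))),
                waviness_factor=float(abs(rng_qc.normal(0.02, 0.008))),
            )
        )

    genes = _make_genes(config, _rng(config, 7))
    qtls = _make_qtls(config, _rng(config, 8))
    return SyntheticCohort(
        config, truth, lrr, snp_geno, genes, qtls, metrics, chrom_lengths
    )


def emit_calls(
    truth: TruthSet, config: CohortConfig, lrr: Optional[LrrMatrix] = None
) -> list[CnvCall]:
    """PennCNV-style calls from the truth: one call per carried locus per
    sample with boundary jitter, plus Poisson false-positive singletons
    placed uniformly outside the true loci."""
    rng = _rng(config, 9)
    loci = truth.loci
    if lrr is not None:
        pos_by_chrom = {
            c: lrr.snps.loc[lrr.snps["chrom"] == c, "pos"].values
            for c in lrr.snps["chrom"].unique()
        }
    else:
        pos_by_chrom = {}

    def n_snps_in(chrom: str, start: int, end: int) -> int:
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            return max(1, (end - start + 1) // max(1, config.snp_spacing_mean))
        return int(np.searchsorted(pos, end, "right") - np.searchsorted(pos, start))

    spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, row in loci.iterrows():
        spans_by_chrom.setdefault(row["chrom"], []).append((row["start"], row["end"]))

    calls: list[CnvCall] = []
    n_samples = len(truth.sample_ids)
    for j, sample in enumerate(truth.sample_ids):
        for i, row in loci.iterrows():
            cn = int(truth.carrier_cn[i, j])
            if cn == 2:
                continue
            if config.boundary_jitter_sd > 0:
                start = int(row["start"] + round(rng.normal(0, config.boundary_jitter_sd)))
                end = int(row["end"] + round(rng.normal(0, config.boundary_jitter_sd)))
            else:
                start, end = int(row["start"]), int(row["end"])
            start = max(1, start)
            end = min(config.chrom_length, end)
            if start > end or n_snps_in(row["chrom"], start, end) < 1:
                start, end = int(row["start"]), int(row["end"])
            calls.append(
                CnvCall(
                    sample, row["chrom"], start, end, cn,
                    n_snps_in(row["chrom"], start, end),
                    confidence=float(np.round(rng.uniform(10, 100), 1)),
                )
            )
        n_fp = rng.poisson(config.fp_singleton_rate)
        for _ in range(n_fp):
            for _try in range(500):
                chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
                length = int(np.clip(rng.exponential(20_000), 5_000, 60_000))
                if length >= config.chrom_length:
                    continue
                start = int(rng.integers(1, config.chrom_length - length))
                end = start + length - 1
                if any(
                    s <= end and start <= e for s, e in spans_by_chrom.get(chrom, [])
                ):
                    continue
                ns = n_snps_in(chrom, start, end)
                if ns < 1:
                    continue
                cn = 1 if rng.random() < config.deletion_fraction else 3
                calls.append(
                    CnvCall(
                        sample, chrom, start, end, cn, ns,
                        confidence=float(np.round(rng.uniform(10, 40), 1)),
                    )
                )
                break
    return calls


def config_to_json(config: CohortConfig) -> str:
    return json.dumps(asdict(config), indent=1, sort_keys=True)
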