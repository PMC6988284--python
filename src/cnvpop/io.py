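"""Readers and writers for the external formats the pipeline touches.

Formats: PennCNV-style rawcnv (read/write), GFF3 (read), BED (write/read),
LRR matrix TSV (read/write), genotype dosage TSV and VCF (read/write),
QTL TSV (read). Internal coordinates are 1-based inclusive; BED output is
converted to 0-based half-open at this boundary only.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CnvCall,
    GeneModel,
    LrrMatrix,
    QtlRecord,
    Transcript,
    VariantGenotypes,
    natural_chrom_key,
)

logger = logging.getLogger(__name__)

_LOCUS_RE = re.compile(r"^(\S+):(\d+)-(\d+)$")
_STATE_RE = re.compile(r"^state\d+,cn=(\d+)$")


class RawcnvParseError(ValueError):
    pass


def read_cnv_calls(path) -> list[CnvCall]:
    """Parse a PennCNV-style rawcnv file into CnvCall records.

    Each line carries a locus token ``chrN:start-end``, ``numsnp=``,
    ``length=`` (thousands separators tolerated), ``stateK,cn=K``, the
    sample identifier, and optionally ``conf=``.
    """
    calls: list[CnvCall] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            calls.append(_parse_rawcnv_line(line, lineno))
    if not calls:
        logger.warning("no CNV calls parsed from %s", path)
    return calls


def _parse_rawcnv_line(line: str, lineno: int) -> CnvCall:
    tokens = line.split()
    locus = _LOCUS_RE.match(tokens[0])
    if locus is None:
        raise RawcnvParseError(f"line {lineno}: malformed locus token {tokens[0]!r}")
    chrom, start, end = locus.group(1), int(locus.group(2)), int(locus.group(3))
    num_snps = cn = None
    confidence = None
    sample_id = None
    for tok in tokens[1:]:
        if tok.startswith("numsnp="):
            num_snps = int(tok[len("numsnp="):].replace(",", ""))
        elif tok.startswith("length="):
            pass  # redundant with the locus span; parsed for validation only
        elif _STATE_RE.match(tok):
            cn = int(_STATE_RE.match(tok).group(1))
        elif tok.startswith("conf="):
            confidence = float(tok[len("conf="):])
        elif tok.startswith(("startsnp=", "endsnp=")):
            pass
        elif sample_id is None:
            sample_id = tok
    if num_snps is None or cn is None or sample_id is None:
        raise RawcnvParseError(f"line {lineno}: missing numsnp/state/sample field")
    if not (0 <= cn <= 6):
        raise RawcnvParseError(f"line {lineno}: cn={cn} outside 0..6")
    try:
        return CnvCall(sample_id, chrom, start, end, cn, num_snps, confidence)
    except ValueError as exc:
        raise RawcnvParseError(f"line {lineno}: {exc}") from exc


def write_cnv_calls(calls: Iterable[CnvCall], path, seed: Optional[int] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for c in calls:
            conf = f" conf={c.confidence:g}" if c.confidence is not None else ""
            fh.write(
                f"{c.chrom}:{c.start}-{c.end} numsnp={c.num_snps} "
                f"length={c.length:,} state{c.cn_state},cn={c.cn_state} "
                f"{c.sample_id}{conf}\n"
            )


# --- GFF3 -------------------------------------------------------------------

class Gff3Error(ValueError):
    pass


def _gff_attrs(col: str) -> dict[str, str]:
    out = {}
    for part in col.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path) -> list[GeneModel]:
    """Read a GFF3 gene/mRNA/exon/CDS hierarchy into GeneModel records.

    The stop-codon span defaults to the last CDS codon on the coding strand
    when no explicit stop_codon feature is present. Orphan child features
    (Parent pointing at an unknown ID) raise Gff3Error listing the IDs.
    """
    genes: dict[str, dict] = {}
    tx: dict[str, dict] = {}
    children: list[tuple[str, str, int, int, str]] = []  # (type, parent, start, end, own_id)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise Gff3Error(f"expected 9 GFF3 columns, got {len(cols)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            start, end = int(start), int(end)
            if start < 1:
                raise Gff3Error("GFF3 coordinates are 1-based; got start 0")
            a = _gff_attrs(attrs)
            if ftype == "gene":
                genes[a["ID"]] = {"chrom": chrom, "strand": strand, "tx": []}
            elif ftype in ("mRNA", "transcript"):
                tx[a["ID"]] = {
                    "parent": a.get("Parent"),
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "exons": [],
                    "cds": [],
                    "stop": None,
                }
            elif ftype in ("exon", "CDS", "stop_codon"):
                children.append((ftype, a.get("Parent"), start, end, a.get("ID", "")))
    orphans = []
    for ftype, parent, start, end, own in children:
        if parent not in tx:
            orphans.append(own or f"{ftype}:{parent}")
            continue
        if ftype == "exon":
            tx[parent]["exons"].append((start, end))
        elif ftype == "CDS":
            tx[parent]["cds"].append((start, end))
        else:
            tx[parent]["stop"] = (start, end)
    for tid, t in tx.items():
        if t["parent"] not in genes:
            orphans.append(tid)
    if orphans:
        raise Gff3Error(f"orphan child features: {sorted(orphans)}")

    models = []
    for gid, g in genes.items():
        transcripts = []
        for tid, t in tx.items():
            if t["parent"] != gid:
                continue
            exons = tuple(sorted(t["exons"]))
            cds = tuple(sorted(t["cds"]))
            stop = t["stop"]
            if stop is None and cds:
                # last codon of the coding sequence, strand-aware
                if t["strand"] == "+":
                    last = cds[-1]
                    stop = (max(last[0], last[1] - 2), last[1])
                else:
                    first = cds[0]
                    stop = (first[0], min(first[1], first[0] + 2))
            tss = t["start"] if t["strand"] == "+" else t["end"]
            transcripts.append(Transcript(tid, exons, cds, stop, tss))
        if not transcripts:
            continue
        transcripts.sort(key=lambda t: t.tx_id)
        models.append(GeneModel(gid, g["chrom"], g["strand"], tuple(transcripts)))
    models.sort(key=lambda m: (natural_chrom_key(m.chrom), m.start))
    return models


def write_gff3(genes: Sequence[GeneModel], path, seed: Optional[int] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tcnvpop\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                ts = min(e[0] for e in t.exons)
                te = max(e[1] for e in t.exons)
                fh.write(
                    f"{g.chrom}\tcnvpop\tmRNA\t{ts}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={t.tx_id};Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.chrom}\tcnvpop\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={t.tx_id}.e{i};Parent={t.tx_id}\n"
                    )
                for i, (s, e) in enumerate(t.cds, 1):
                    fh.write(
                        f"{g.chrom}\tcnvpop\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                        f"ID={t.tx_id}.c{i};Parent={t.tx_id}\n"
                    )
                if t.stop_codon is not None:
                    s, e = t.stop_codon
                    fh.write(
                        f"{g.chrom}\tcnvpop\tstop_codon\t{s}\t{e}\t.\t{g.strand}\t0\t"
                        f"ID={t.tx_id}.stop;Parent={t.tx_id}\n"
                    )


# --- BED --------------------------------------------------------------------

def write_regions_bed(regions, path) -> None:
    """Write regions (objects with chrom/start/end and an id) as BED.

    Internal 1-based inclusive spans become 0-based half-open (start-1, end).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in regions:
        name = getattr(r, "cnvr_id", None) or getattr(r, "qtl_id", None) or ""
        rows.append((r.chrom, r.start - 1, r.end, name))
    rows.sort(key=lambda r: (natural_chrom_key(r[0]), r[1]))
    with open(path, "w") as fh:
        fh.write("# chrom\tstart0\tend\tname\n")
        for chrom, s0, e, name in rows:
            fh.write(f"{chrom}\t{s0}\t{e}\t{name}\n")


def read_regions_bed(path) -> pd.DataFrame:
    """Read a BED file back to internal 1-based inclusive coordinates."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start0", "end", "name"],
        dtype={"chrom": str, "name": str},
    )
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["start0"] + 1, "end": df["end"], "name": df["name"]}
    )
    return out


# --- LRR matrix -------------------------------------------------------------

def write_lrr_matrix(lrr: LrrMatrix, path, seed: Optional[int] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("snp_id\tchrom\tpos\t" + "\t".join(lrr.sample_ids) + "\n")
        for i in range(lrr.n_snps):
            row = lrr.snps.iloc[i]
            vals = "\t".join(f"{v:.4f}" for v in lrr.values[i])
            fh.write(f"{row.snp_id}\t{row.chrom}\t{row.pos}\t{vals}\n")


def read_lrr_matrix(path) -> LrrMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    snps = df[["snp_id", "chrom", "pos"]].copy()
    snps["chrom"] = snps["chrom"].astype(str)
    sample_ids = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
    values = df[sample_ids].to_numpy(dtype=float)
    return LrrMatrix(snps, sample_ids, values)


# --- genotypes --------------------------------------------------------------

_DOSAGE_LEGEND = {0: "+/+", 1: "+/-", 2: "-/-"}


def write_dosage_tsv(geno: VariantGenotypes, path, seed: Optional[int] = None) -> None:
    """Dosage TSV: one variant per row, NA for missing, with a genotype legend."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("# dosage legend: 0=+/+ 1=+/- 2=-/-\n")
        fh.write("variant_id\tchrom\tpos\tend\tkind\t" + "\t".join(geno.sample_ids) + "\n")
        for i in range(geno.n_variants):
            v = geno.variants.iloc[i]
            vals = "\t".join(
                "NA" if np.isnan(d) else str(int(d)) for d in geno.dosage[i]
            )
            fh.write(f"{v.variant_id}\t{v.chrom}\t{v.pos}\t{v.end}\t{v.kind}\t{vals}\n")


def read_dosage_tsv(path) -> VariantGenotypes:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    meta = ["variant_id", "chrom", "pos", "end", "kind"]
    variants = df[meta].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    sample_ids = [c for c in df.columns if c not in meta]
    dosage = df[sample_ids].to_numpy(dtype=float)
    return VariantGenotypes(variants, sample_ids, dosage)


def write_vcf(geno: VariantGenotypes, path, seed: Optional[int] = None) -> None:
    """Minimal VCF 4.2 with GT; phased (|) when truth phase is present."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    order = sorted(
        range(geno.n_variants),
        key=lambda i: (
            natural_chrom_key(geno.variants.iloc[i]["chrom"]),
            int(geno.variants.iloc[i]["pos"]),
        ),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if seed is not None:
            fh.write(f"##cnvpop_seed={seed}\n")
        chroms = geno.variants["chrom"].unique()
        for c in sorted(chroms, key=natural_chrom_key):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids) + "\n"
        )
        for i in order:
            v = geno.variants.iloc[i]
            gts = []
            for j in range(geno.n_samples):
                if geno.phase is not None and (geno.phase[i, j] >= 0).all():
                    gts.append(f"{geno.phase[i, j, 0]}|{geno.phase[i, j, 1]}")
                elif np.isnan(geno.dosage[i, j]):
                    gts.append("./.")
                else:
                    d = int(geno.dosage[i, j])
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
            fh.write(
                f"{v.chrom}\t{int(v.pos)}\t{v.variant_id}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> VariantGenotypes:
    """Read GT genotypes from a VCF via cyvcf2 into VariantGenotypes."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows = []
    dosages = []
    phases = []
    any_phased = False
    for rec in vcf:
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "end": rec.POS,
                "kind": "snp",
            }
        )
        gt = np.array(rec.genotype.array(), dtype=int)  # (n_samples, 3): a, b, phased
        a, b = gt[:, 0], gt[:, 1]
        miss = (a < 0) | (b < 0)
        d = (a + b).astype(float)
        d[miss] = np.nan
        dosages.append(d)
        ph = np.stack([a, b], axis=1).astype(np.int8)
        ph[miss] = -1
        ph[~(gt[:, 2].astype(bool)) & ~miss] = -1  # unphased entries carry no phase
        phases.append(ph)
        if (gt[~miss, 2] != 0).any():
            any_phased = True
    variants = pd.DataFrame(rows)
    dosage = np.array(dosages, dtype=float)
    phase = np.array(phases, dtype=np.int8) if any_phased else None
    if phase is not None:
        # keep phase only where fully defined and consistent
        ok = (phase >= 0).all(axis=2)
        phase[~ok] = -1
    return VariantGenotypes(variants, sample_ids, dosage, phase)


# --- QTL --------------------------------------------------------------------

def read_qtl_tsv(path) -> list[QtlRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    out = []
    for _, r in df.iterrows():
        end = int(r["end"]) if "end" in df.columns and not pd.isna(r.get("end")) else int(r["start"])
        out.append(QtlRecord(str(r["qtl_id"]), str(r["chrom"]), int(r["start"]), end, str(r["trait"])))
    return out


def write_qtl_tsv(qtls: Sequence[QtlRecord], path, seed: Optional[int] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("qtl_id\tchrom\tstart\tend\ttrait\n")
        for q in qtls:
            fh.write(f"{q.qtl_id}\t{q.chrom}\t{q.start}\t{q.end}\t{q.trait}\n")
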