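"""Linkage disequilibrium of CNVRs and SNPs.

Variant filtering (MAF, call rate, Hardy-Weinberg exact test), masking of
SNPs inside CNVRs, r-squared from truth haplotypes (phased) or dosage
correlation (composite), distance-binned LD decay, taggability (best r2
against SNPs within a window), and CNVR-QTL pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import Cnvr, QtlRecord, VariantGenotypes

DEFAULT_WINDOW = 100_000
DEFAULT_BIN = 10_000
HIGH_LD = 0.8


# --- Hardy-Weinberg exact test ------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test on genotype counts.

    Conditional enumeration of the heterozygote-count distribution given
    the observed allele counts (Wigginton et al. style, computed by
    recurrence); p = sum of probabilities of heterozygote counts no more
    likely than the observed one. Monomorphic sites return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    h_obs = n_het
    h_min = n_rare % 2
    h_max = n_rare if n_rare <= n else 2 * n - n_rare
    probs = {}
    # start from the maximal het count and recurse downward:
    # P(h-2)/P(h) = h*(h-1) / ((n_rare-h+2)/2 * (2n-n_rare-h+2)/2) inverted
    h = h_max
    probs[h] = 1.0
    while h - 2 >= h_min:
        probs[h - 2] = probs[h] * (h * (h - 1)) / (
            (n_rare - h + 2) * (2 * n - n_rare - h + 2)
        )
        h -= 2
    total = sum(probs.values())
    p_obs = probs.get(h_obs)
    if p_obs is None:
        raise ValueError("observed het count inconsistent with allele counts")
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


# --- variant filtering --------------------------------------------------------

def variant_maf(dosage_row: np.ndarray) -> float:
    d = dosage_row[~np.isnan(dosage_row)]
    if d.size == 0:
        return float("nan")
    f = d.sum() / (2 * d.size)
    return float(min(f, 1 - f))


def filter_variants_for_ld(
    geno: VariantGenotypes,
    maf_min: float = 0.001,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-9,
) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Pre-LD variant filters; returns (kept row indices, {variant: reasons}).

    SNPs are removed for MAF < maf_min, call rate < call_rate_min, or
    Hardy-Weinberg exact p < hwe_p_min. CNVR variants are exempt from the
    call-rate criterion.
    """
    kept = []
    removed: dict[str, list[str]] = {}
    kinds = geno.variants["kind"].values
    ids = geno.variants["variant_id"].values
    for i in range(geno.n_variants):
        row = geno.dosage[i]
        obs = ~np.isnan(row)
        reasons = []
        call_rate = obs.mean()
        if kinds[i] != "cnvr" and call_rate < call_rate_min:
            reasons.append("call_rate")
        maf = variant_maf(row)
        if np.isnan(maf) or maf < maf_min:
            reasons.append("maf")
        d = row[obs].astype(int)
        n0 = int((d == 0).sum())
        n1 = int((d == 1).sum())
        n2 = int((d == 2).sum())
        if n0 + n1 + n2 > 0 and hwe_exact_test(n0, n1, n2) < hwe_p_min:
            reasons.append("hwe")
        if reasons:
            removed[ids[i]] = reasons
        else:
            kept.append(i)
    return np.array(kept, dtype=int), removed


def mask_snps_in_cnvrs(
    snps: pd.DataFrame, cnvrs: Sequence[Cnvr]
) -> np.ndarray:
    """Boolean keep-mask over SNP rows: False for SNPs inside any CNVR span.

    Span boundaries are inclusive. ``snps`` needs columns chrom and pos.
    """
    keep = np.ones(len(snps), dtype=bool)
    spans: dict[str, list[tuple[int, int]]] = {}
    for r in cnvrs:
        spans.setdefault(r.chrom, []).append((r.start, r.end))
    chroms = snps["chrom"].values
    pos = snps["pos"].values.astype(np.int64)
    for chrom, sp in spans.items():
        sp.sort()
        starts = np.array([s for s, _ in sp], dtype=np.int64)
        max_end = np.maximum.accumulate(np.array([e for _, e in sp], dtype=np.int64))
        m = chroms == chrom
        if not m.any():
            continue
        idx = np.searchsorted(starts, pos[m], side="right")
        inside = np.zeros(int(m.sum()), dtype=bool)
        nz = idx > 0
        inside[nz] = max_end[idx[nz] - 1] >= pos[m][nz]
        keep[np.nonzero(m)[0][inside]] = False
    return keep


# --- r-squared ----------------------------------------------------------------

@dataclass(frozen=True)
class R2Value:
    r2: float  # NaN when undefined (monomorphic in the joint sample)
    mode: str  # 'phased' or 'composite'


def r2(
    dosage_a: np.ndarray,
    dosage_b: np.ndarray,
    phase_a: Optional[np.ndarray] = None,
    phase_b: Optional[np.ndarray] = None,
) -> R2Value:
    """LD r2 between two bi-allelic variants.

    Phased mode (both phase arrays given, shape (n_samples, 2)):
    r2 = D^2 / (pA qA pB qB) from haplotype frequencies. Unphased mode:
    squared Pearson correlation of dosages (composite LD). Pairs
    monomorphic in the joint non-missing sample are undefined (NaN).
    """
    if phase_a is not None and phase_b is not None:
        ok = (phase_a >= 0).all(axis=1) & (phase_b >= 0).all(axis=1)
        if ok.sum() < 2:
            raise ValueError("need >= 2 jointly phased samples")
        ha = phase_a[ok].ravel().astype(float)
        hb = phase_b[ok].ravel().astype(float)
        pa, pb = ha.mean(), hb.mean()
        if pa in (0.0, 1.0) or pb in (0.0, 1.0):
            return R2Value(float("nan"), "phased")
        pab = (ha * hb).mean()
        d = pab - pa * pb
        return R2Value(float(d * d / (pa * (1 - pa) * pb * (1 - pb))), "phased")
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        raise ValueError("need >= 2 jointly genotyped samples")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return R2Value(float("nan"), "composite")
    c = np.corrcoef(a, b)[0, 1]
    return R2Value(float(c * c), "composite")


def _row_phase_ok(phase: Optional[np.ndarray], row: int) -> bool:
    return phase is not None and (phase[row] >= 0).all()


def pairwise_r2(
    geno: VariantGenotypes,
    anchor_rows: Sequence[int],
    partner_rows: Sequence[int],
    window: int = DEFAULT_WINDOW,
    phased: bool = True,
    anchor_class: Optional[Mapping[int, str]] = None,
) -> pd.DataFrame:
    """All anchor-partner r2 pairs within ``window`` bp, as an LdPair table.

    Distance is from the partner SNP position to the nearest anchor
    boundary (anchors may be spans; 0 if inside). Pairs with undefined r2
    are dropped. Falls back to composite r2 per pair when truth phase is
    unavailable for either variant.
    """
    v = geno.variants
    rows = []
    partner_rows = np.asarray(partner_rows, dtype=int)
    p_chrom = v["chrom"].values[partner_rows]
    p_pos = v["pos"].values[partner_rows].astype(np.int64)
    order = np.lexsort((p_pos, p_chrom))
    partner_rows = partner_rows[order]
    p_chrom, p_pos = p_chrom[order], p_pos[order]
    for ar in anchor_rows:
        a = v.iloc[ar]
        a_start, a_end = int(a["pos"]), int(a["end"])
        m = p_chrom == a["chrom"]
        lo = np.searchsorted(p_pos[m], a_start - window)
        hi = np.searchsorted(p_pos[m], a_end + window, side="right")
        cand = partner_rows[m][lo:hi]
        cand_pos = p_pos[m][lo:hi]
        maf_a = variant_maf(geno.dosage[ar])
        for pr, pp in zip(cand, cand_pos):
            if pr == ar:
                continue
            dist = max(a_start - pp, pp - a_end, 0)
            use_phase = (
                phased and _row_phase_ok(geno.phase, ar) and _row_phase_ok(geno.phase, pr)
            )
            val = r2(
                geno.dosage[ar],
                geno.dosage[pr],
                geno.phase[ar] if use_phase else None,
                geno.phase[pr] if use_phase else None,
            )
            if math.isnan(val.r2):
                continue
            rows.append(
                {
                    "id_a": a["variant_id"],
                    "id_b": v.iloc[int(pr)]["variant_id"],
                    "distance": int(dist),
                    "r2": val.r2,
                    "maf_a": maf_a,
                    "maf_b": variant_maf(geno.dosage[pr]),
                    "mode": val.mode,
                    "class": (anchor_class or {}).get(int(ar), "anchor"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "distance", "r2", "maf_a", "maf_b", "mode", "class"],
    )


# --- profiles and taggability ---------------------------------------------------

def ld_decay_profile(
    pairs: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    bin_size: int = DEFAULT_BIN,
) -> pd.DataFrame:
    """Mean r2 per distance bin, stratified by the pairs' class column.

    Bins are [k*bin, (k+1)*bin); empty bins report NaN, not zero.
    """
    edges = np.arange(0, window + bin_size, bin_size)
    recs = []
    classes = pairs["class"].unique() if len(pairs) else []
    for cls in classes:
        sub = pairs[pairs["class"] == cls]
        which = np.digitize(sub["distance"].values, edges) - 1
        for b in range(len(edges) - 1):
            sel = sub["r2"].values[which == b]
            recs.append(
                {
                    "class": cls,
                    "bin_left": int(edges[b]),
                    "bin_right": int(edges[b + 1]),
                    "mean_r2": float(sel.mean()) if sel.size else float("nan"),
                    "n_pairs": int(sel.size),
                }
            )
    return pd.DataFrame(recs, columns=["class", "bin_left", "bin_right", "mean_r2", "n_pairs"])


def taggability(
    pairs: pd.DataFrame,
    high_ld: float = HIGH_LD,
    maf_bin: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best r2 per anchor variant and per-MAF-bin mean taggability.

    Returns (records, bin_means). ``records`` has one row per anchor with a
    defined partner: best_r2, tagged (best_r2 > high_ld, strict), maf and
    its bin. Anchors without partners are simply absent (undefined).
    """
    if pairs.empty:
        return (
            pd.DataFrame(columns=["variant_id", "best_r2", "tagged", "maf", "maf_bin"]),
            pd.DataFrame(columns=["maf_bin", "mean_best_r2", "tagged_fraction", "n"]),
        )
    grp = pairs.groupby("id_a")
    records = pd.DataFrame(
        {
            "variant_id": grp.size().index,
            "best_r2": grp["r2"].max().values,
            "maf": grp["maf_a"].first().values,
        }
    )
    records["tagged"] = records["best_r2"] > high_ld
    records["maf_bin"] = np.floor(records["maf"] / maf_bin).astype(int) * maf_bin
    bins = (
        records.groupby("maf_bin")
        .agg(
            mean_best_r2=("best_r2", "mean"),
            tagged_fraction=("tagged", "mean"),
            n=("best_r2", "size"),
        )
        .reset_index()
    )
    return records.reset_index(drop=True), bins


def pair_cnvr_qtl(
    pairs: pd.DataFrame,
    qtls: Sequence[QtlRecord],
    cnvrs: Sequence[Cnvr],
    window: int = DEFAULT_WINDOW,
    snp_match_bp: int = 10_000,
    snp_positions: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-CNVR summary of LD with nearby QTLs.

    A CNVR-QTL pair exists when the QTL lies within ``window`` bp of the
    CNVR span and the CNVR has an r2-bearing partner SNP within
    ``snp_match_bp`` of the QTL position (QTLs are matched to SNPs by
    position, not identity). Output: cnvr_id, n_qtls, mean_r2, max_r2,
    sorted by max_r2 descending. ``snp_positions`` (variant_id, chrom, pos)
    locates the partner SNPs; required when pairs are non-empty.
    """
    out_cols = ["cnvr_id", "n_qtls", "mean_r2", "max_r2"]
    if pairs.empty:
        return pd.DataFrame(columns=out_cols)
    if snp_positions is None:
        raise ValueError("snp_positions required to match QTLs to partner SNPs")
    pos_of = dict(
        zip(snp_positions["variant_id"], zip(snp_positions["chrom"], snp_positions["pos"]))
    )
    rows = []
    for cnvr in cnvrs:
        sub = pairs[pairs["id_a"] == cnvr.cnvr_id]
        if sub.empty:
            continue
        qtl_r2 = []
        for q in qtls:
            if q.chrom != cnvr.chrom:
                continue
            dist = max(cnvr.start - q.end, q.start - cnvr.end, 0)
            if dist > window:
                continue
            qpos = (q.start + q.end) // 2
            best = None
            for _, p in sub.iterrows():
                chrom_pos = pos_of.get(p["id_b"])
                if chrom_pos is None or chrom_pos[0] != q.chrom:
                    continue
                d = abs(int(chrom_pos[1]) - qpos)
                if d <= snp_match_bp and (best is None or d < best[0]):
                    best = (d, p["r2"])
            if best is not None:
                qtl_r2.append(best[1])
        if qtl_r2:
            rows.append(
                {
                    "cnvr_id": cnvr.cnvr_id,
                    "n_qtls": len(qtl_r2),
                    "mean_r2": float(np.mean(qtl_r2)),
                    "max_r2": float(np.max(qtl_r2)),
                }
            )
    out = pd.DataFrame(rows, columns=out_cols)
    return out.sort_values("max_r2", ascending=False).reset_index(drop=True)
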