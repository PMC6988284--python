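"""Two-population differentiation statistics for CNVRs.

Fst is the Weir-Cockerham (1984) per-locus estimator in its allele-count
(ANOVA) form; Vst is the intensity analogue, computed from per-sample mean
log-R ratios over the SNPs inside a CNVR span:

    Vst = (V_T - (V_1 n_1 + V_2 n_2) / (n_1 + n_2)) / V_T

with population variances (denominator n), which bounds Vst in [0, 1] by
the law of total variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import Cnvr, LrrMatrix


@dataclass(frozen=True)
class FstResult:
    cnvr_id: str
    fst: float  # NaN when undefined (monomorphic in both populations)
    alt1: int
    total1: int
    alt2: int
    total2: int


@dataclass(frozen=True)
class VstResult:
    cnvr_id: str
    vst: float
    v_total: float
    v_pop1: float
    v_pop2: float
    n1: int
    n2: int
    n_snps: int


def fst_wc(
    pop1: tuple[int, int], pop2: tuple[int, int], cnvr_id: str = ""
) -> FstResult:
    """Weir-Cockerham (1984) per-locus theta-hat from two allele-count samples.

    ``pop1``/``pop2`` are (alt allele count, total alleles). With allele
    counts as the sampling unit the estimator is the ANOVA form

        theta = (MSP - MSG) / (MSP + (n_c - 1) * MSG)

    where MSP/MSG are the among/within-population mean squares of the
    allele indicator and n_c the variance-corrected mean sample size.
    Loci monomorphic in both populations return NaN. Estimates may be
    slightly negative under the null; they are not clamped.
    """
    alt1, n1 = pop1
    alt2, n2 = pop2
    if n1 == 0 or n2 == 0:
        raise ValueError("allele_total must be > 0 in both populations")
    if n1 < 2 or n2 < 2:
        raise ValueError("allele_total must be >= 2 in each population")
    if not (0 <= alt1 <= n1 and 0 <= alt2 <= n2):
        raise ValueError("alt count outside [0, total]")
    p1, p2 = alt1 / n1, alt2 / n2
    pbar = (alt1 + alt2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        return FstResult(cnvr_id, float("nan"), alt1, n1, alt2, n2)
    r = 2
    nbar = (n1 + n2) / r
    n_c = ((n1 + n2) - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / ((n1 - 1) + (n2 - 1))
    denom = msp + (n_c - 1) * msg
    if denom == 0:
        return FstResult(cnvr_id, float("nan"), alt1, n1, alt2, n2)
    return FstResult(cnvr_id, float((msp - msg) / denom), alt1, n1, alt2, n2)


def fst_from_dosages(
    dosage1: Sequence[float], dosage2: Sequence[float], cnvr_id: str = ""
) -> FstResult:
    """Fst from per-sample alternate-allele dosages (0/1/2, NaN missing)."""
    d1 = np.asarray(dosage1, dtype=float)
    d2 = np.asarray(dosage2, dtype=float)
    d1, d2 = d1[~np.isnan(d1)], d2[~np.isnan(d2)]
    return fst_wc(
        (int(d1.sum()), 2 * len(d1)), (int(d2.sum()), 2 * len(d2)), cnvr_id
    )


def fst_outlier_scan(
    fsts: Sequence[FstResult], k: float = 3.0
) -> tuple[set[str], float, pd.DataFrame]:
    """Flag loci with Fst strictly above mean + k*SD of defined values.

    Returns (outlier ids, threshold, table) where the table is a
    Manhattan-style frame (cnvr_id, fst, outlier flag).
    """
    vals = np.array([f.fst for f in fsts], dtype=float)
    defined = ~np.isnan(vals)
    if defined.sum() < 2:
        raise ValueError("need >= 2 defined Fst values")
    mean = float(vals[defined].mean())
    sd = float(vals[defined].std(ddof=1))
    threshold = mean + k * sd
    flags = defined & (vals > threshold)
    table = pd.DataFrame(
        {
            "cnvr_id": [f.cnvr_id for f in fsts],
            "fst": vals,
            "outlier": flags,
        }
    )
    return {f.cnvr_id for f, fl in zip(fsts, flags) if fl}, threshold, table


def vst(
    lrr: LrrMatrix,
    cnvr: Cnvr,
    pop1: Sequence[str],
    pop2: Sequence[str],
) -> VstResult:
    """Vst of a CNVR from LRR signal.

    Per-sample summary = mean LRR over SNPs inside the CNVR span; variances
    use denominator n. Vst = 0 is reported when the pooled variance is 0
    (degenerate: no signal variation at all).
    """
    if not pop1 or not pop2:
        raise ValueError("both populations must be non-empty")
    rows = lrr.snps_in_span(cnvr.chrom, cnvr.start, cnvr.end)
    if rows.size == 0:
        raise ValueError(f"no LRR SNP inside {cnvr.cnvr_id} ({cnvr.chrom}:{cnvr.start}-{cnvr.end})")
    i1 = lrr.sample_indices(pop1)
    i2 = lrr.sample_indices(pop2)
    s1 = lrr.values[np.ix_(rows, i1)].mean(axis=0)
    s2 = lrr.values[np.ix_(rows, i2)].mean(axis=0)
    pooled = np.concatenate([s1, s2])
    v_t = float(pooled.var(ddof=0))
    v1 = float(s1.var(ddof=0))
    v2 = float(s2.var(ddof=0))
    n1, n2 = len(s1), len(s2)
    if v_t == 0.0:
        value = 0.0
    else:
        value = (v_t - (v1 * n1 + v2 * n2) / (n1 + n2)) / v_t
    return VstResult(cnvr.cnvr_id, value, v_t, v1, v2, n1, n2, int(rows.size))


def filter_min_copies(
    cnvrs: Sequence[Cnvr],
    pop_of_sample: Mapping[str, str],
    pops: tuple[str, str],
    min_copies: int = 5,
    mode: str = "either",
) -> list[Cnvr]:
    """Keep CNVRs with enough supporting calls per population.

    ``mode='either'`` drops a CNVR when any of the two populations has
    fewer than ``min_copies`` member calls (strict <); ``mode='both'``
    drops only when both do.
    """
    if mode not in ("either", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    known = set(pop_of_sample.values())
    for p in pops:
        if p not in known:
            raise ValueError(f"unknown population label {p!r}")
    out = []
    for r in cnvrs:
        counts = {p: 0 for p in pops}
        for c in r.member_calls:
            p = pop_of_sample.get(c.sample_id)
            if p is None:
                raise ValueError(f"sample {c.sample_id!r} has no population label")
            if p in counts:
                counts[p] += 1
        low = [p for p in pops if counts[p] < min_copies]
        drop = bool(low) if mode == "either" else len(low) == len(pops)
        if not drop:
            out.append(r)
    return out


def fst_vst_concordance(
    fsts: Sequence[FstResult], vsts: Sequence[VstResult]
) -> tuple[float, int]:
    """Pearson correlation of Fst and Vst over CNVRs defined in both."""
    fmap = {f.cnvr_id: f.fst for f in fsts if not math.isnan(f.fst)}
    pairs = [(fmap[v.cnvr_id], v.vst) for v in vsts if v.cnvr_id in fmap]
    if len(pairs) < 3:
        raise ValueError("need >= 3 paired values")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in Fst or Vst vector")
    r = stats.pearsonr(x, y).statistic
    return float(r), len(pairs)
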