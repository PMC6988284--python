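"""Sample-level quality control and within-sample adjacent-call merging.

Poor-quality samples are removed on array-signal metrics (LRR SD, BAF SD,
waviness factor), outlier samples on per-sample call count and total called
length, and split calls are re-joined when the gap between two same-state
neighbours is small relative to the merged span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import CnvCall, natural_chrom_key

logger = logging.getLogger(__name__)

# PennCNV-style default sample QC thresholds (remove when strictly exceeded)
DEFAULT_LRR_SD = 0.30
DEFAULT_BAF_SD = 0.001
DEFAULT_WAVINESS = 0.05
DEFAULT_MAX_CNVS = 100
DEFAULT_GAP_FRACTION = 0.10


@dataclass(frozen=True)
class SampleQcMetrics:
    sample_id: str
    lrr_sd: float
    baf_sd: float
    waviness_factor: float
    n_cnvs: int = 0
    total_cnv_length: int = 0

    def __post_init__(self) -> None:
        if min(self.lrr_sd, self.baf_sd, self.waviness_factor) < 0:
            raise ValueError("QC metrics must be >= 0")


def filter_samples(
    metrics: Sequence[SampleQcMetrics],
    lrr_sd_max: float = DEFAULT_LRR_SD,
    baf_sd_max: float = DEFAULT_BAF_SD,
    waviness_max: float = DEFAULT_WAVINESS,
) -> tuple[list[str], dict[str, list[str]]]:
    """Partition samples into (kept ids, {removed id: reasons}).

    A sample is removed iff any metric strictly exceeds its threshold;
    boundary values pass.
    """
    seen = set()
    kept: list[str] = []
    removed: dict[str, list[str]] = {}
    for m in metrics:
        if m.sample_id in seen:
            raise ValueError(f"duplicate sample_id {m.sample_id!r}")
        seen.add(m.sample_id)
        reasons = []
        if m.lrr_sd > lrr_sd_max:
            reasons.append("lrr_sd")
        if m.baf_sd > baf_sd_max:
            reasons.append("baf_sd")
        if m.waviness_factor > waviness_max:
            reasons.append("waviness_factor")
        if reasons:
            removed[m.sample_id] = reasons
        else:
            kept.append(m.sample_id)
    return kept, removed


def filter_outlier_samples(
    calls: Sequence[CnvCall],
    max_cnvs: int = DEFAULT_MAX_CNVS,
    max_total_length: Optional[float] = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Remove samples with excessive call counts or total called length.

    ``max_total_length=None`` ("auto") sets the length threshold to
    Q3 + 3*IQR of the per-sample totals, a deterministic stand-in for
    visual QQ-plot inspection. Strict ">" in both rules.
    """
    per_sample: dict[str, list[CnvCall]] = defaultdict(list)
    for c in calls:
        per_sample[c.sample_id].append(c)
    totals = {s: sum(c.length for c in cs) for s, cs in per_sample.items()}
    if max_total_length is None and totals:
        arr = np.array(list(totals.values()), dtype=float)
        q1, q3 = np.percentile(arr, [25, 75])
        max_total_length = q3 + 3 * (q3 - q1)
    kept: list[str] = []
    removed: dict[str, list[str]] = {}
    for s in sorted(per_sample):
        reasons = []
        if len(per_sample[s]) > max_cnvs:
            reasons.append("n_cnvs")
        if max_total_length is not None and totals[s] > max_total_length:
            reasons.append("total_cnv_length")
        if reasons:
            removed[s] = reasons
        else:
            kept.append(s)
    return kept, removed


def merge_adjacent_calls(
    calls: Iterable[CnvCall],
    gap_fraction: float = DEFAULT_GAP_FRACTION,
) -> list[CnvCall]:
    """Merge consecutive same-sample, same-chromosome, same-state calls.

    Two neighbours merge iff gap/(merged span) < gap_fraction, with
    gap = start2 - end1 - 1 and merged span = end2 - start1 + 1; applied
    left-to-right to a fixed point. The merged call's num_snps is the sum
    over members. Overlapping same-sample calls of different state are
    warned about and never merged.
    """
    groups: dict[tuple[str, str], list[CnvCall]] = defaultdict(list)
    for c in calls:
        groups[(c.sample_id, c.chrom)].append(c)
    out: list[CnvCall] = []
    for key in sorted(groups, key=lambda k: (k[0], natural_chrom_key(k[1]))):
        seq = sorted(groups[key], key=lambda c: (c.start, c.end))
        while True:  # a merge can widen a span and enable earlier merges
            merged: list[CnvCall] = []
            for c in seq:
                if merged:
                    prev = merged[-1]
                    gap = c.start - prev.end - 1
                    span = max(c.end, prev.end) - prev.start + 1
                    if gap < 0 and c.cn_state != prev.cn_state:
                        logger.warning(
                            "overlapping calls with different states in %s %s:%d-%d vs %d-%d",
                            c.sample_id, c.chrom, prev.start, prev.end, c.start, c.end,
                        )
                    if c.cn_state == prev.cn_state and gap / span < gap_fraction:
                        conf = None
                        if prev.confidence is not None and c.confidence is not None:
                            conf = prev.confidence + c.confidence
                        merged[-1] = CnvCall(
                            prev.sample_id, prev.chrom, prev.start, max(c.end, prev.end),
                            prev.cn_state, prev.num_snps + c.num_snps, conf,
                        )
                        continue
                merged.append(c)
            if len(merged) == len(seq):
                break
            seq = merged
        out.extend(merged)
    return out
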