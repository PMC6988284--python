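#!/usr/bin/env python
"""Sample QC and adjacent-call merging on the simulated call set.

Reads the rawcnv calls and per-sample metrics written by 01 (regenerating
them if absent), applies the signal-quality thresholds (LRR SD > 0.30,
BAF SD > 0.001, waviness > 0.05), the >100-calls-per-sample outlier rule
with the Q3+3*IQR total-length rule, and re-joins split calls (gap < 10%
of the merged span). Writes the surviving calls and a removal report.
"""

from pathlib import Path

import pandas as pd

from cnvpop import io as cio
from cnvpop.qc import (
    SampleQcMetrics,
    filter_outlier_samples,
    filter_samples,
    merge_adjacent_calls,
)
from cnvpop.simulate import CohortConfig, emit_calls, generate_cohort

SEED = 2026
ROOT = Path(__file__).resolve().parents[1]


def load_inputs():
    src = ROOT / "scratch" / "cohort"
    if (src / "calls.rawcnv").exists() and (src / "qc_metrics.tsv").exists():
        calls = cio.read_cnv_calls(src / "calls.rawcnv")
        mdf = pd.read_csv(src / "qc_metrics.tsv", sep="\t", comment="#")
        metrics = [
            SampleQcMetrics(r.sample_id, r.lrr_sd, r.baf_sd, r.waviness_factor)
            for r in mdf.itertuples()
        ]
        return calls, metrics
    cohort = generate_cohort(CohortConfig(seed=SEED))
    return emit_calls(cohort.truth, cohort.config, lrr=cohort.lrr), cohort.qc_metrics


def main() -> None:
    calls, metrics = load_inputs()
    kept_sig, removed_sig = filter_samples(metrics)
    calls_q = [c for c in calls if c.sample_id in set(kept_sig)]
    _, removed_out = filter_outlier_samples(calls_q)
    calls_q = [c for c in calls_q if c.sample_id not in removed_out]
    merged = merge_adjacent_calls(calls_q)

    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    cio.write_cnv_calls(merged, ROOT / "scratch" / "cohort" / "calls.qc.rawcnv", seed=SEED)
    report = [
        {"sample_id": s, "stage": "signal", "reasons": ";".join(r)}
        for s, r in removed_sig.items()
    ] + [
        {"sample_id": s, "stage": "outlier", "reasons": ";".join(r)}
        for s, r in removed_out.items()
    ]
    pd.DataFrame(report, columns=["sample_id", "stage", "reasons"]).to_csv(
        res / "02_removed_samples.tsv", sep="\t", index=False
    )
    n_samples = len({c.sample_id for c in merged})
    print(f"input calls: {len(calls)}; removed samples: "
          f"{len(removed_sig)} signal, {len(removed_out)} outlier")
    print(f"after QC + merging: {len(merged)} calls from {n_samples} samples "
          f"({len(merged) / n_samples:.1f} calls/sample)")
    print(f"merging joined {len(calls_q) - len(merged)} split calls")


if __name__ == "__main__":
    main()
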