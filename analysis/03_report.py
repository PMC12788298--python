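#!/usr/bin/env python
"""Summarize an experiment: metric tables, fold-level tests, ROC exports.

Reads the prediction table from 02_run_experiment.py and writes pooled and
per-task metric tables (mean, SD, 95% CI over folds), paired Wilcoxon tests
against the audio-only baseline with Holm adjustment, and pooled ROC point
sets for plotting.
"""

import argparse
import os

import pandas as pd

from voiceimu.reporting import (compare_to_baseline, export_roc, metric_table,
                                per_task_metrics)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--predictions", required=True)
    ap.add_argument("--baseline", default="audio_only")
    ap.add_argument("--holm-family", choices=("all", "per-metric"), default="all")
    ap.add_argument("--out", default="results/report")
    args = ap.parse_args()

    preds = pd.read_csv(args.predictions)
    os.makedirs(args.out, exist_ok=True)

    pooled = metric_table(preds)
    pooled.to_csv(os.path.join(args.out, "metrics_pooled.csv"), index=False)
    per_task = per_task_metrics(preds)
    per_task.to_csv(os.path.join(args.out, "metrics_per_task.csv"), index=False)

    cols = [c for c in pooled.columns if c.endswith("_mean")]
    print("pooled fold-mean metrics:")
    print(pooled[["method"] + cols].round(3).to_string(index=False))

    if args.baseline in set(preds["method"]):
        tests = compare_to_baseline(preds, baseline=args.baseline,
                                    holm_family=args.holm_family)
        tests.to_csv(os.path.join(args.out, "wilcoxon_holm.csv"), index=False)
        print(f"\npaired Wilcoxon vs. {args.baseline} (Holm family: {args.holm_family}):")
        print(tests.round(4).to_string(index=False))

    roc = export_roc(preds)
    roc.to_csv(os.path.join(args.out, "roc_pooled.csv"), index=False)
    print(f"\nwrote tables and ROC points to {args.out}")


if __name__ == "__main__":
    main()
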