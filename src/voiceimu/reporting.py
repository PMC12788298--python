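"""Pooled and per-task metrics, fold summaries and paired fold-level tests.

AUC is computed on calibrated probabilities (rank statistic, ties counted
half); F1/accuracy/precision/recall at each fold's operating threshold with
PD as the positive class.  Fold means carry sample SD and a Student-t 95%
confidence interval.  Method-vs-baseline comparisons use the exact paired
two-sided Wilcoxon signed-rank test (full sign-assignment enumeration,
mean ranks for ties, zero differences dropped) with Holm adjustment.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score, roc_curve)

METRICS = ("AUC", "F1", "Accuracy", "Precision", "Recall")


def binary_metrics(probs, labels, threshold: float) -> dict[str, float]:
    """AUC / F1 / Accuracy / Precision / Recall for one set of predictions.

    AUC is NaN when only one class is present.  Predictions are
    probability >= threshold; the positive class is PD (label 1).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(probs) == 0:
        raise ValueError("empty input")
    preds = probs >= threshold
    auc = (float(roc_auc_score(labels, probs))
           if len(np.unique(labels)) == 2 else float("nan"))
    return {
        "AUC": auc,
        "F1": float(f1_score(labels, preds, zero_division=0)),
        "Accuracy": float(accuracy_score(labels, preds)),
        "Precision": float(precision_score(labels, preds, zero_division=0)),
        "Recall": float(recall_score(labels, preds, zero_division=0)),
    }


def summarize_folds(values) -> dict[str, float]:
    """Mean, sample SD and Student-t 95% CI over per-fold metric values."""
    v = np.asarray([x for x in values if not np.isnan(x)], dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 fold values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    tcrit = float(stats.t.ppf(0.975, len(v) - 1))
    half = tcrit * sd / np.sqrt(len(v))
    return {"mean": mean, "sd": sd, "ci_lo": mean - half, "ci_hi": mean + half,
            "n_folds": int(len(v))}


def fold_metrics(records: pd.DataFrame, by_task: bool = False) -> pd.DataFrame:
    """Per-(method, scope[, task], fold) metric cells from prediction rows.

    Each cell uses that fold's ensembled operating threshold.  Cells whose
    test episodes are single-class get AUC = NaN (excluded from fold means
    downstream, with the exclusion countable from this table).
    """
    keys = ["method", "scope", "fold"] + (["task_id"] if by_task else [])
    rows = []
    for key_vals, grp in records.groupby(keys, sort=True):
        m = binary_metrics(grp["prob"], grp["label"], float(grp["threshold"].iloc[0]))
        rows.append(dict(zip(keys, key_vals)) | m | {"n_episodes": len(grp)})
    return pd.DataFrame(rows)


def metric_table(records: pd.DataFrame, by_task: bool = False) -> pd.DataFrame:
    """Fold-averaged metric table (mean, SD, 95% CI per metric)."""
    cells = fold_metrics(records, by_task=by_task)
    keys = ["method", "scope"] + (["task_id"] if by_task else [])
    rows = []
    for key_vals, grp in cells.groupby(keys, sort=True):
        row = dict(zip(keys, key_vals))
        for metric in METRICS:
            vals = grp[metric].to_numpy()
            valid = vals[~np.isnan(vals)]
            row[f"{metric}_mean"] = float(valid.mean()) if len(valid) else float("nan")
            if len(valid) >= 2:
                s = summarize_folds(valid)
                row[f"{metric}_sd"] = s["sd"]
                row[f"{metric}_ci_lo"] = s["ci_lo"]
                row[f"{metric}_ci_hi"] = s["ci_hi"]
            else:
                row[f"{metric}_sd"] = row[f"{metric}_ci_lo"] = row[f"{metric}_ci_hi"] = float("nan")
            row[f"{metric}_n_missing"] = int(np.isnan(vals).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def per_task_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Metrics grouped by task (fold cells averaged within each task)."""
    return metric_table(records, by_task=True)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def wilcoxon_paired(method_folds, baseline_folds) -> float:
    """Exact two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; tied absolute differences receive mean
    ranks; the p-value enumerates all 2^m sign assignments of the m nonzero
    differences.  All-zero differences give p = 1.
    """
    a = np.asarray(method_folds, dtype=float)
    b = np.asarray(baseline_folds, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    m = len(d)
    if m == 0:
        return 1.0
    if m > 20:
        raise ValueError("exact enumeration limited to 20 nonzero differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w_obs = min(w_plus, total - w_plus)
    # enumerate all sign assignments
    count = 0
    for signs in product((0.0, 1.0), repeat=m):
        w = float(np.dot(signs, ranks))
        if min(w, total - w) <= w_obs + 1e-12:
            count += 1
    return count / 2**m


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving.

    adjusted_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) over the ascending
    order, mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, j in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[j]))
        adj_sorted[i] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def compare_to_baseline(records: pd.DataFrame, baseline: str = "audio_only",
                        metrics: tuple[str, ...] = ("AUC", "F1", "Accuracy"),
                        holm_family: str = "all") -> pd.DataFrame:
    """Paired Wilcoxon tests of every method vs. the baseline across folds.

    ``holm_family`` = "all" adjusts over the full methods x metrics family
    (the default); "per-metric" adjusts within each metric separately.
    """
    if holm_family not in ("all", "per-metric"):
        raise ValueError(f"unknown holm_family {holm_family!r}")
    cells = fold_metrics(records)
    methods = [m for m in cells["method"].unique() if m != baseline]
    base = cells[cells["method"] == baseline].set_index(["scope", "fold"])
    rows = []
    for method in methods:
        cur = cells[cells["method"] == method].set_index(["scope", "fold"])
        folds = sorted(set(base.index) & set(cur.index))
        for metric in metrics:
            p = wilcoxon_paired(cur.loc[folds, metric].to_numpy(),
                                base.loc[folds, metric].to_numpy())
            rows.append({"comparison": f"{method} vs. {baseline}",
                         "metric": metric, "p_raw": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(p_holm=[])
    if holm_family == "all":
        df["p_holm"] = holm_adjust(df["p_raw"].to_numpy())
    else:
        df["p_holm"] = np.nan
        for metric in metrics:
            mask = df["metric"] == metric
            df.loc[mask, "p_holm"] = holm_adjust(df.loc[mask, "p_raw"].to_numpy())
    return df


def export_roc(records: pd.DataFrame, by_task: bool = False) -> pd.DataFrame:
    """ROC point sets per method (probabilities pooled across folds).

    Returns a long table (method, scope[, task], fpr, tpr, threshold)
    suitable for plotting; raises when a grouping is single-class.
    """
    keys = ["method", "scope"] + (["task_id"] if by_task else [])
    frames = []
    for key_vals, grp in records.groupby(keys, sort=True):
        if len(np.unique(grp["label"])) < 2:
            raise ValueError(f"single-class input for {key_vals}")
        fpr, tpr, thr = roc_curve(grp["label"], grp["prob"])
        df = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        for k, v in zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)):
            df[k] = v
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
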