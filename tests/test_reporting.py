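"""Metrics, fold summaries and fold-level statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from voiceimu.reporting import (
    binary_metrics,
    compare_to_baseline,
    export_roc,
    fold_metrics,
    holm_adjust,
    metric_table,
    per_task_metrics,
    summarize_folds,
    wilcoxon_paired,
)


def brute_force_auc(probs, labels):
    """Concordant-pair counting with ties worth one half."""
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBinaryMetrics:
    def test_perfect_separation(self):
        m = binary_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.5)
        assert m["AUC"] == m["F1"] == m["Accuracy"] == 1.0

    def test_complete_ties_give_half_auc(self):
        m = binary_metrics([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5)
        assert m["AUC"] == 0.5

    def test_pairwise_counting_example(self):
        m = binary_metrics([0.7, 0.4, 0.6, 0.2], [1, 0, 0, 1], 0.5)
        assert m["AUC"] == 0.5  # 2 concordant, 2 discordant of 4 pairs

    def test_auc_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                labels[0], labels[1] = 0, 1
            probs = np.round(rng.uniform(size=n), 2)  # force some ties
            m = binary_metrics(probs, labels, 0.5)
            assert np.isclose(m["AUC"], brute_force_auc(probs, labels), atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics([], [], 0.5)


class TestFoldSummary:
    def test_constant_folds(self):
        s = summarize_folds([1, 1, 1, 1, 1])
        assert s["mean"] == 1 and s["sd"] == 0
        assert s["ci_lo"] == s["ci_hi"] == 1

    def test_closed_form_example(self):
        s = summarize_folds([0.8, 0.85, 0.9, 0.95, 1.0])
        assert np.isclose(s["mean"], 0.9)
        assert np.isclose(s["sd"], 0.0790569, atol=1e-6)
        half = 2.7764451 * s["sd"] / np.sqrt(5)
        assert np.isclose(s["ci_hi"] - s["mean"], half, atol=1e-6)

    def test_translation_invariance(self):
        a = summarize_folds([0.1, 0.2, 0.3, 0.4, 0.5])
        b = summarize_folds([0.3, 0.4, 0.5, 0.6, 0.7])
        assert np.isclose(b["mean"] - a["mean"], 0.2)
        assert np.isclose(a["sd"], b["sd"])

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            summarize_folds([0.5])


def enumeration_wilcoxon(d):
    """Independent oracle: direct enumeration over sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = min(ranks[d > 0].sum(), total - ranks[d > 0].sum())
    count = 0
    m = len(d)
    for mask in range(2**m):
        w = sum(ranks[i] for i in range(m) if mask >> i & 1)
        if min(w, total - w) <= w_obs + 1e-12:
            count += 1
    return count / 2**m


class TestWilcoxon:
    def test_five_same_signed_differences(self):
        """Five same-signed distinct differences give the exact two-sided
        floor p = 2/32 = 0.0625."""
        p = wilcoxon_paired([0.9, 0.8, 0.7, 0.85, 0.95],
                            [0.5, 0.45, 0.6, 0.4, 0.55])
        assert p == 0.0625

    def test_identical_vectors_give_one(self):
        assert wilcoxon_paired([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mixed_signs_match_enumeration(self):
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0])
        p = wilcoxon_paired(a, np.zeros(5))
        assert np.isclose(p, enumeration_wilcoxon(a))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=2, max_size=9))
    def test_exact_p_matches_direct_enumeration(self, d):
        d = [x for x in d if x != 0]
        if not d:
            return
        assert np.isclose(wilcoxon_paired(d, np.zeros(len(d))),
                          enumeration_wilcoxon(d))

    def test_matches_scipy_exact_on_tie_free_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            d = rng.normal(size=n)
            d = d[np.abs(d) > 1e-6]
            if len(d) < 2:
                continue
            ours = wilcoxon_paired(d, np.zeros_like(d))
            ref = stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue
            assert np.isclose(ours, ref, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1, 2], [1, 2, 3])


class TestHolm:
    def test_twelve_way_family_maps_floor_to_075(self):
        """Three p=0.0625 values in a 12-comparison family adjust to 0.75."""
        p = [0.0625, 0.3125, 0.8125, 0.6250,
             0.0625, 0.1875, 1.0000, 0.6250,
             0.0625, 0.1875, 0.6250, 1.0000]
        adj = holm_adjust(p)
        for i in (0, 4, 8):
            assert np.isclose(adj[i], 0.75)
        assert np.all(adj <= 1.0)

    def test_single_p_unchanged(self):
        assert holm_adjust([0.04])[0] == 0.04

    def test_dominates_raw_and_bonferroni(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1.0, size=8)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= np.minimum(1.0, len(p) * p) + 1e-12)

    def test_order_invariance(self):
        p = [0.2, 0.01, 0.6, 0.05]
        adj = holm_adjust(p)
        perm = [2, 0, 3, 1]
        adj_perm = holm_adjust([p[i] for i in perm])
        assert np.allclose([adj[i] for i in perm], adj_perm)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=12))
    def test_holm_bracketed_by_raw_and_bonferroni(self, p):
        adj = holm_adjust(p)
        p = np.asarray(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= np.minimum(1.0, len(p) * p) + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1.0, size=12)
        _, ref, _, _ = multipletests(p, method="holm")
        assert np.allclose(holm_adjust(p), ref)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.0, 0.5])


def _pred_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "task_id", "session_index",
                                       "method", "scope", "fold", "raw_logit",
                                       "prob", "threshold", "label"])


def synthetic_predictions(rng, methods=("audio_only", "gated_early"),
                          tasks=("T03", "T04"), folds=3, n=8, shift=0.0):
    rows = []
    for method in methods:
        for fold in range(folds):
            for task in tasks:
                for i in range(n):
                    label = i % 2
                    base = 0.3 + 0.4 * label + rng.normal(0, 0.12)
                    if method != "audio_only":
                        base += shift * label
                    rows.append([f"P{fold}{i}", task, 1, method, "ALL", fold,
                                 0.0, float(np.clip(base, 0, 1)), 0.5, label])
    return _pred_frame(rows)


class TestTables:
    def test_single_task_per_task_equals_pooled(self):
        rng = np.random.default_rng(4)
        preds = synthetic_predictions(rng, tasks=("T06",))
        pooled = metric_table(preds)
        per_task = per_task_metrics(preds)
        merged = per_task.merge(pooled, on=["method", "scope"], suffixes=("_t", "_p"))
        assert np.allclose(merged["AUC_mean_t"], merged["AUC_mean_p"])

    def test_cell_count_bookkeeping(self):
        rng = np.random.default_rng(5)
        preds = synthetic_predictions(rng, tasks=("T02", "T03", "T04", "T05", "T06"),
                                      folds=5)
        cells = fold_metrics(preds, by_task=True)
        assert len(cells) <= 5 * 5 * 2

    def test_single_class_cell_excluded_from_fold_mean(self):
        rng = np.random.default_rng(6)
        preds = synthetic_predictions(rng, methods=("audio_only",),
                                      tasks=("T03",), folds=5)
        # make fold 0 single-class for the task
        mask = (preds["fold"] == 0)
        preds.loc[mask, "label"] = 0
        table = per_task_metrics(preds)
        row = table.iloc[0]
        assert row["AUC_n_missing"] == 1
        cells = fold_metrics(preds, by_task=True)
        good = cells[~np.isnan(cells["AUC"])]
        assert np.isclose(row["AUC_mean"], good["AUC"].mean())

    def test_compare_to_baseline_families(self):
        rng = np.random.default_rng(7)
        preds = synthetic_predictions(rng, methods=("audio_only", "gated_early",
                                                    "imu_only"), folds=5, shift=0.1)
        out_all = compare_to_baseline(preds, holm_family="all")
        out_pm = compare_to_baseline(preds, holm_family="per-metric")
        assert len(out_all) == 2 * 3
        assert np.all(out_all["p_holm"] >= out_all["p_raw"] - 1e-12)
        assert np.all(out_pm["p_holm"] <= out_all["p_holm"] + 1e-12)


class TestRoc:
    def test_export_consistent_with_auc(self):
        rng = np.random.default_rng(8)
        preds = synthetic_predictions(rng, methods=("audio_only",), folds=5)
        roc = export_roc(preds)
        grp = roc[roc["method"] == "audio_only"].sort_values("fpr")
        area = np.trapezoid(grp["tpr"], grp["fpr"])
        auc = binary_metrics(preds["prob"], preds["label"], 0.5)["AUC"]
        assert np.isclose(area, auc, atol=1e-9)

    def test_monotone_and_through_corners(self):
        rng = np.random.default_rng(9)
        preds = synthetic_predictions(rng, methods=("audio_only",))
        roc = export_roc(preds)
        assert np.all(np.diff(roc["fpr"]) >= -1e-12)
        assert np.all(np.diff(roc["tpr"]) >= -1e-12)
        assert roc["tpr"].iloc[-1] == 1.0 and roc["fpr"].iloc[-1] == 1.0

    def test_single_class_rejected(self):
        preds = _pred_frame([["P1", "T03", 1, "m", "ALL", 0, 0, 0.5, 0.5, 1]])
        with pytest.raises(ValueError):
            export_roc(preds)
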