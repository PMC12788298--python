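"""Nested subject-grouped cross-validation with calibration.

Protocol: an outer 5-fold participant-grouped, label-stratified split; within
each training fold, 3 participant-grouped 70/30 train/validation repetitions
used only for early stopping, temperature calibration and threshold
selection.  Per repetition a model is trained with class-weighted
cross-entropy (AdamW, gradient clipping, early stopping on a smoothed
validation AUC), calibrated with guard-railed temperature scaling, and the
three repetitions are ensembled by averaging calibrated probabilities.
Held-out episodes are predicted with K-crop test-time augmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.metrics import f1_score, roc_auc_score

from . import signals
from .cohort import EpisodeRecord, EpisodeParams, read_manifest, synth_imu, synth_speech
from .models import FusionModel, ModelConfig, build_model, weighted_bce_with_logits
from .nn import AdamW, clip_grad_norm

POSITIVE = "PD"

TEMP_BOUNDS = (0.300, 3.000)
THRESH_BOUNDS = (0.200, 0.800)
MIN_VAL_N = 20


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 32
    max_epochs: int = 50
    clip_norm: float = 1.0
    patience: int = 4
    smoothing_window: int = 3
    seed: int = 42
    crop_s: float = 15.0
    tta_k: int = 3

    def validate(self) -> None:
        if min(self.lr, self.weight_decay, self.batch_size, self.max_epochs,
               self.clip_norm, self.patience, self.smoothing_window) <= 0:
            raise ValueError("all training settings must be positive")
        if self.smoothing_window > self.max_epochs:
            raise ValueError("smoothing window longer than the epoch budget")

    def scaled_down(self) -> "TrainConfig":
        """Reduced regime for CPU-bound runs: 3 s crops, 15-epoch cap."""
        return replace(self, crop_s=3.0, max_epochs=15)


@dataclass
class CalibrationResult:
    temperature: float
    threshold: float
    n_val: int
    fallback: bool
    red_flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# dataset access
# ---------------------------------------------------------------------------

class EpisodeDataset:
    """Episode records plus lazily computed, cached model-ready features.

    Features per episode: a log-mel sequence (audio) and a normalized 100 Hz
    six-channel IMU stream; either may be absent.  Two constructions exist:
    from a written dataset directory (manifest + WAV/CSV files) or directly
    from generation parameters (signals synthesized in memory, bypassing
    disk — numerically equivalent up to WAV quantization).
    """

    def __init__(self, records: list[EpisodeRecord]):
        self.records = list(records)
        self._cache: dict[tuple, dict] = {}

    # construction -------------------------------------------------------
    @classmethod
    def from_files(cls, manifest_path: str, root_dir: str) -> "EpisodeDataset":
        ds = cls(read_manifest(manifest_path))
        ds._root = root_dir
        ds._params = None
        return ds

    @classmethod
    def from_params(cls, records: list[EpisodeRecord],
                    params: dict[tuple, EpisodeParams]) -> "EpisodeDataset":
        ds = cls(records)
        ds._root = None
        ds._params = params
        return ds

    # availability -------------------------------------------------------
    @staticmethod
    def has_modalities(rec: EpisodeRecord, uses_audio: bool, uses_imu: bool) -> bool:
        if uses_audio and not rec.wav_path:
            return False
        if uses_imu and not (rec.acc_path and rec.gyr_path):
            return False
        return True

    def record(self, key: tuple) -> EpisodeRecord:
        for r in self.records:
            if r.key == key:
                return r
        raise KeyError(key)

    def features(self, rec: EpisodeRecord) -> dict:
        if rec.key in self._cache:
            return self._cache[rec.key]
        import os

        mel = imu = None
        if self._params is not None:
            ep = self._params[rec.key]
            rng = np.random.default_rng(ep.signal_seed)
            wav = synth_speech(ep.speech, rng)
            acc, gyr = synth_imu(ep.imu, rng)
            if rec.wav_path:
                mel = signals.compute_logmel(signals.Waveform(wav))
            if rec.acc_path and rec.gyr_path:
                acc_t = signals.load_imu_table(acc)
                gyr_t = signals.load_imu_table(gyr)
                stream = signals.to_100hz_six_channel(acc_t, gyr_t)
                imu = signals.normalize_channels(stream)
        else:
            if rec.wav_path:
                w = signals.load_audio(os.path.join(self._root, rec.wav_path))
                mel = signals.compute_logmel(w)
            if rec.acc_path and rec.gyr_path:
                acc_t = signals.load_imu_table(os.path.join(self._root, rec.acc_path))
                gyr_t = signals.load_imu_table(os.path.join(self._root, rec.gyr_path))
                stream = signals.to_100hz_six_channel(acc_t, gyr_t)
                imu = signals.normalize_channels(stream)
        feats = {"mel": mel, "imu": imu}
        self._cache[rec.key] = feats
        return feats


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def make_outer_splits(records: list[EpisodeRecord], k: int = 5,
                      seed: int = 42) -> list[set[str]]:
    """Participant-grouped, label-stratified k folds (test participant sets).

    Greedy stratification: participants of each class are shuffled with the
    seed and dealt round-robin across folds, so per-fold class counts are as
    balanced as the integer constraints allow.
    """
    by_class: dict[str, list[str]] = {}
    group_of: dict[str, str] = {}
    for r in records:
        if r.participant_id in group_of:
            if group_of[r.participant_id] != r.group:
                raise ValueError(f"participant {r.participant_id} has two groups")
            continue
        group_of[r.participant_id] = r.group
        by_class.setdefault(r.group, []).append(r.participant_id)
    if len(by_class) < 2:
        raise ValueError("both diagnostic classes must be present")
    if len(group_of) < k:
        raise ValueError("fewer participants than folds")
    rng = np.random.default_rng(seed)
    folds: list[set[str]] = [set() for _ in range(k)]
    offset = 0
    for cls in sorted(by_class):
        pids = sorted(by_class[cls])
        rng.shuffle(pids)
        for i, pid in enumerate(pids):
            folds[(i + offset) % k].add(pid)
        offset += len(pids) % k
    return folds


def make_inner_splits(train_participants: list[tuple[str, str]], reps: int = 3,
                      seed: int = 42, val_frac: float = 0.3
                      ) -> list[tuple[set[str], set[str]]]:
    """``reps`` participant-grouped train/validation splits (70/30).

    Each repetition holds out ~``val_frac`` of the participants; when
    feasible both classes are represented on each side (a single swap
    repairs a one-class draw).
    """
    pids = [p for p, _ in train_participants]
    labels = dict(train_participants)
    classes = set(labels.values())
    if len(pids) < 3:
        raise ValueError("degenerate training fold")
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(val_frac * len(pids))))
    splits = []
    for _ in range(reps):
        order = list(pids)
        rng.shuffle(order)
        val = order[:n_val]
        train = order[n_val:]
        for side_a, side_b in ((val, train), (train, val)):
            present = {labels[p] for p in side_a}
            missing = classes - present
            if missing and len(side_a) < len(pids):
                want = next(iter(missing))
                for j, p in enumerate(side_b):
                    if labels[p] == want and len({labels[q] for q in side_b} |
                                                 {labels[side_a[-1]]}) >= 1:
                        side_a[-1], side_b[j] = side_b[j], side_a[-1]
                        break
        splits.append((set(train), set(val)))
    return splits


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Inverse-frequency class weights, normalized so the two weights mean 1."""
    labels = np.asarray(labels)
    n = len(labels)
    w = {}
    for c in (0, 1):
        nc = int(np.sum(labels == c))
        if nc == 0:
            raise ValueError("single-class training data")
        w[c] = n / (2.0 * nc)
    scale = 2.0 / (w[0] + w[1])
    return {c: v * scale for c, v in w.items()}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class EarlyStopper:
    """Early stopping on a smoothed metric (mean of the last few epochs)."""

    def __init__(self, patience: int, window: int):
        self.patience = patience
        self.window = window
        self.history: list[float] = []
        self.best = -np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, value: float) -> tuple[float, bool]:
        """Feed one epoch's metric; returns (smoothed value, should_stop)."""
        self.history.append(value)
        smoothed = float(np.mean(self.history[-self.window:]))
        if smoothed > self.best + 1e-12:
            self.best = smoothed
            self.best_epoch = len(self.history) - 1
            self.stale = 0
        else:
            self.stale += 1
        return smoothed, self.stale >= self.patience


def _episode_crops(feats: dict, uses_audio: bool, uses_imu: bool, mode: str,
                   K: int, rng: np.random.Generator, crop_s: float):
    """Aligned (X_a, X_i) crops honouring the variant's modality needs.

    Single-modality episodes are cropped on their own duration; the missing
    side is None.  IMU-only crops are still expressed on the 20 ms mel-frame
    grid so every variant sees the same temporal resolution.
    """
    mel, imu = feats["mel"], feats["imu"]
    if uses_audio and uses_imu:
        crops = signals.make_crops(mel, imu, mode, K, rng, crop_s)
        return [(c.X_a, c.X_i) for c in crops]
    n = 1 if mode == "train" else K
    out = []
    if uses_audio:
        D = mel.duration_s
        T = min(int(round(min(crop_s, D) * signals.FRAMES_PER_SECOND)), mel.n_frames)
        for _ in range(n):
            s0 = 0
            if D > crop_s:
                start = float(rng.uniform(0.0, D - crop_s))
                s0 = min(int(round(start * signals.FRAMES_PER_SECOND)), mel.n_frames - T)
            out.append((mel.values[s0:s0 + T], None))
    else:
        D = imu.duration_s
        T = int(round(min(crop_s, D) * signals.FRAMES_PER_SECOND))
        for _ in range(n):
            start = 0.0
            if D > crop_s:
                start = float(rng.uniform(0.0, D - crop_s))
            ft = start + np.arange(T) / signals.FRAMES_PER_SECOND
            xi = signals.align_to_mel_grid(imu, ft).astype(np.float32)
            out.append((None, xi))
    return out


def _predict_batch(model: FusionModel, items: list[tuple]) -> np.ndarray:
    """Deterministic (eval-mode) logits for a list of (xa, xi) pairs."""
    logits = np.empty(len(items))
    # bucket by T so equal-length crops share one forward pass
    buckets: dict[int, list[int]] = {}
    for i, (xa, xi) in enumerate(items):
        T = xa.shape[0] if xa is not None else xi.shape[0]
        buckets.setdefault(T, []).append(i)
    for idxs in buckets.values():
        xa = np.stack([items[i][0] for i in idxs]) if items[idxs[0]][0] is not None else None
        xi = np.stack([items[i][1] for i in idxs]) if items[idxs[0]][1] is not None else None
        out = model.forward(xa, xi, training=False)
        for j, i in enumerate(idxs):
            logits[i] = out[j]
    return logits


def train_model(model: FusionModel, dataset: EpisodeDataset,
                train_recs: list[EpisodeRecord], val_recs: list[EpisodeRecord],
                cfg: TrainConfig, rng: np.random.Generator) -> dict:
    """Train one model with early stopping on smoothed validation AUC.

    One random crop per training episode per epoch; validation uses a fixed
    crop per episode (drawn once) so epoch AUCs are comparable.  The weights
    of the best smoothed-AUC epoch are restored before returning.
    """
    cfg.validate()
    y_train = np.array([1 if r.group == POSITIVE else 0 for r in train_recs])
    if len(np.unique(y_train)) < 2:
        raise ValueError("single-class training data")
    cw = class_weights(y_train)
    ua, ui = model.uses_audio, model.uses_imu

    val_rng = np.random.default_rng(rng.integers(2**31 - 1))
    val_items = [_episode_crops(dataset.features(r), ua, ui, "test", 1,
                                val_rng, cfg.crop_s)[0] for r in val_recs]
    y_val = np.array([1 if r.group == POSITIVE else 0 for r in val_recs])

    opt = AdamW(model, lr=cfg.lr, weight_decay=cfg.weight_decay)
    stopper = EarlyStopper(cfg.patience, cfg.smoothing_window)
    best_state = model.state_dict()
    history = {"train_loss": [], "val_auc": [], "val_auc_smoothed": []}

    order = np.arange(len(train_recs))
    for _epoch in range(cfg.max_epochs):
        rng.shuffle(order)
        # draw this epoch's crops, then bucket by length for batching
        crops = [(_episode_crops(dataset.features(train_recs[i]), ua, ui,
                                 "train", 1, rng, cfg.crop_s)[0], y_train[i])
                 for i in order]
        buckets: dict[int, list[int]] = {}
        for j, ((xa, xi), _) in enumerate(crops):
            T = xa.shape[0] if xa is not None else xi.shape[0]
            buckets.setdefault(T, []).append(j)
        epoch_loss, n_batches = 0.0, 0
        for idxs in buckets.values():
            for s in range(0, len(idxs), cfg.batch_size):
                chunk = idxs[s:s + cfg.batch_size]
                xa = (np.stack([crops[j][0][0] for j in chunk])
                      if crops[chunk[0]][0][0] is not None else None)
                xi = (np.stack([crops[j][0][1] for j in chunk])
                      if crops[chunk[0]][0][1] is not None else None)
                y = np.array([crops[j][1] for j in chunk], dtype=np.float64)
                w = np.array([cw[int(v)] for v in y])
                model.zero_grad()
                logits = model.forward(xa, xi, training=True, rng=rng)
                loss, dl = weighted_bce_with_logits(logits, y, w)
                model.backward(dl)
                clip_grad_norm(model, cfg.clip_norm)
                opt.step()
                epoch_loss += loss
                n_batches += 1

        val_logits = _predict_batch(model, val_items)
        if len(np.unique(y_val)) < 2:
            auc = 0.5
        else:
            auc = float(roc_auc_score(y_val, val_logits))
        smoothed, stop = stopper.update(auc)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_auc"].append(auc)
        history["val_auc_smoothed"].append(smoothed)
        if stopper.best_epoch == len(stopper.history) - 1:
            best_state = model.state_dict()
        if stop:
            break

    model.load_state_dict(best_state)
    history["best_epoch"] = stopper.best_epoch
    return history


def tta_predict(model: FusionModel, dataset: EpisodeDataset, rec: EpisodeRecord,
                K: int, rng: np.random.Generator, crop_s: float = 15.0) -> float:
    """Mean raw logit over K independent test crops of one episode."""
    if not EpisodeDataset.has_modalities(rec, model.uses_audio, model.uses_imu):
        raise ValueError("episode lacks a modality required by the variant")
    feats = dataset.features(rec)
    if (model.uses_audio and feats["mel"] is None) or \
       (model.uses_imu and feats["imu"] is None):
        raise ValueError("episode lacks a modality required by the variant")
    items = _episode_crops(feats, model.uses_audio, model.uses_imu,
                           "test", K, rng, crop_s)
    return float(np.mean(_predict_batch(model, items)))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _nll(T: float, logits: np.ndarray, y: np.ndarray) -> float:
    p = 1.0 / (1.0 + np.exp(-logits / T))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def calibrate(val_logits: np.ndarray, val_labels: np.ndarray) -> CalibrationResult:
    """Guard-railed temperature scaling plus F1-optimal threshold selection.

    Small (< 20) or single-class validation sets fall back to T=1, t*=0.5
    with a red flag; a fitted temperature or threshold at a guard-rail bound
    is clipped there and flagged.
    """
    logits = np.asarray(val_logits, dtype=np.float64)
    y = np.asarray(val_labels, dtype=np.float64)
    n = len(logits)
    if n < MIN_VAL_N:
        return CalibrationResult(1.0, 0.5, n, True, ["fallback_small_val"])
    if len(np.unique(y)) < 2:
        return CalibrationResult(1.0, 0.5, n, True, ["single_class_val"])

    flags: list[str] = []
    res = minimize_scalar(_nll, bounds=TEMP_BOUNDS, args=(logits, y),
                          method="bounded", options={"xatol": 1e-4})
    T = float(res.x)
    for bound in TEMP_BOUNDS:
        if abs(T - bound) <= 1e-3:
            T = bound
            flags.append("temperature_clipped")
            break

    probs = 1.0 / (1.0 + np.exp(-logits / T))
    grid = np.unique(np.concatenate([
        probs[(probs >= THRESH_BOUNDS[0]) & (probs <= THRESH_BOUNDS[1])],
        np.round(np.arange(20, 81) / 100.0, 2),
    ]))
    best_f1, best_t = -1.0, THRESH_BOUNDS[0]
    for t in grid:  # ascending: first maximizer = smallest threshold
        f1 = f1_score(y, probs >= t, zero_division=0)
        if f1 > best_f1 + 1e-12:
            best_f1, best_t = f1, float(t)
    if best_t in THRESH_BOUNDS:
        flags.append("threshold_clipped")
    return CalibrationResult(T, best_t, n, False, flags)


def ensemble_repetitions(rep_outputs: list[dict]) -> dict:
    """Average calibrated probabilities and thresholds; union the red flags."""
    if not rep_outputs:
        raise ValueError("need at least one repetition")
    keys = list(rep_outputs[0]["probs"])
    probs = {k: float(np.mean([r["probs"][k] for r in rep_outputs])) for k in keys}
    threshold = float(np.mean([r["threshold"] for r in rep_outputs]))
    flags = sorted(set().union(*[set(r["red_flags"]) for r in rep_outputs]))
    return {"probs": probs, "threshold": threshold, "red_flags": flags}


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def _assert_disjoint(*sets: set) -> None:
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            leaked = sets[i] & sets[j]
            if leaked:
                raise AssertionError(f"participant leakage: {sorted(leaked)}")


def run_experiment(dataset: EpisodeDataset, variants: list[str],
                   regime: str = "pooled", cfg: TrainConfig | None = None,
                   k_outer: int = 5, n_reps: int = 3
                   ) -> tuple[pd.DataFrame, list[dict]]:
    """Train/calibrate/ensemble every variant over the outer folds.

    Returns one prediction row per (variant, scope, fold, test episode) plus
    a per-repetition calibration log.  All randomness derives from
    ``cfg.seed`` with the variant, scope, fold and repetition indices, so a
    rerun with the same seed reproduces the table exactly.
    """
    if regime not in ("pooled", "taskwise"):
        raise ValueError(f"unknown regime {regime!r}")
    cfg = cfg or TrainConfig()
    cfg.validate()
    folds = make_outer_splits(dataset.records, k=k_outer, seed=cfg.seed)
    group_of = {r.participant_id: r.group for r in dataset.records}

    rows: list[dict] = []
    cal_log: list[dict] = []
    for vi, variant in enumerate(variants):
        mcfg = ModelConfig(variant=variant)
        uses_audio = variant != "imu_only"
        uses_imu = variant != "audio_only"
        eligible = [r for r in dataset.records
                    if EpisodeDataset.has_modalities(r, uses_audio, uses_imu)]
        if not eligible:
            warnings.warn(f"variant {variant}: no eligible episodes; skipped")
            continue
        scopes = [None] if regime == "pooled" else sorted({r.task_id for r in eligible})
        for si, scope in enumerate(scopes):
            scoped = eligible if scope is None else [r for r in scoped_list(eligible, scope)]
            if not scoped:
                warnings.warn(f"variant {variant}, task {scope}: no episodes; skipped")
                continue
            for fold, test_pids in enumerate(folds):
                test_recs = [r for r in scoped if r.participant_id in test_pids]
                pool_recs = [r for r in scoped if r.participant_id not in test_pids]
                pool_pids = sorted({r.participant_id for r in pool_recs})
                pool_labeled = [(p, group_of[p]) for p in pool_pids]
                per_class = {c: sum(1 for _, g in pool_labeled if g == c)
                             for c in ("PD", "HC")}
                if min(per_class.values()) < 2 or not test_recs:
                    warnings.warn(f"variant {variant} fold {fold}: degenerate fold; skipped")
                    continue
                inner_seed = int(np.random.SeedSequence(
                    [cfg.seed, vi, si, fold]).generate_state(1)[0] % (2**31))
                inner = make_inner_splits(pool_labeled, reps=n_reps, seed=inner_seed)
                rep_outputs = []
                for rep, (tr_pids, va_pids) in enumerate(inner):
                    _assert_disjoint(tr_pids, va_pids, set(test_pids))
                    tr = [r for r in pool_recs if r.participant_id in tr_pids]
                    va = [r for r in pool_recs if r.participant_id in va_pids]
                    ss = np.random.SeedSequence([cfg.seed, vi, si, fold, rep])
                    rng = np.random.default_rng(ss)
                    model = build_model(mcfg, rng)
                    history = train_model(model, dataset, tr, va, cfg, rng)
                    tta_rng = np.random.default_rng(
                        np.random.SeedSequence([cfg.seed, vi, si, fold, rep, 7]))
                    val_logits = np.array([
                        tta_predict(model, dataset, r, cfg.tta_k, tta_rng, cfg.crop_s)
                        for r in va])
                    y_val = np.array([1 if r.group == POSITIVE else 0 for r in va])
                    cal = calibrate(val_logits, y_val)
                    cal_log.append({
                        "variant": variant, "scope": scope or "ALL", "fold": fold,
                        "rep": rep, "temperature": cal.temperature,
                        "threshold": cal.threshold, "n_val": cal.n_val,
                        "fallback": cal.fallback, "red_flags": list(cal.red_flags),
                        "history": {k: (list(map(float, v)) if isinstance(v, list)
                                        else int(v))
                                    for k, v in history.items()},
                    })
                    test_logits = np.array([
                        tta_predict(model, dataset, r, cfg.tta_k, tta_rng, cfg.crop_s)
                        for r in test_recs])
                    probs = 1.0 / (1.0 + np.exp(-test_logits / cal.temperature))
                    rep_outputs.append({
                        "probs": {r.key: p for r, p in zip(test_recs, probs)},
                        "raw": {r.key: l for r, l in zip(test_recs, test_logits)},
                        "threshold": cal.threshold,
                        "red_flags": cal.red_flags,
                    })
                ens = ensemble_repetitions(rep_outputs)
                for r in test_recs:
                    rows.append({
                        "participant_id": r.participant_id,
                        "task_id": r.task_id,
                        "session_index": r.session_index,
                        "method": variant,
                        "scope": scope or "ALL",
                        "fold": fold,
                        "raw_logit": float(np.mean([ro["raw"][r.key]
                                                    for ro in rep_outputs])),
                        "prob": ens["probs"][r.key],
                        "threshold": ens["threshold"],
                        "label": 1 if r.group == POSITIVE else 0,
                    })
    columns = ["participant_id", "task_id", "session_index", "method", "scope",
               "fold", "raw_logit", "prob", "threshold", "label"]
    return pd.DataFrame(rows, columns=columns), cal_log


def scoped_list(records: list[EpisodeRecord], task: str) -> list[EpisodeRecord]:
    return [r for r in records if r.task_id == task]
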