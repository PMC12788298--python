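"""Synthetic multi-task voice + head-IMU cohort generator.

Emulates the statistical structure of a mixed-reality Parkinson's disease
(PD) vs. healthy control (HC) study: each participant contributes task-level
"episodes" (speech waveform + tri-axial accelerometer + tri-axial gyroscope,
referenced from a manifest).  The PD group differs from HC through a small
set of clinically motivated knobs — reduced pitch variability (monopitch),
reduced loudness modulation (monoloudness), amplitude tremor on the voice,
and elevated 3-7 Hz tremor-band power on the head IMU — each scaled by a
per-task effect magnitude so that separability can be audio-dominated on
some tasks and IMU-informative on others.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

TASKS = ("T02", "T03", "T04", "T05", "T06")
AUDIO_RATE = 16_000
TICKS_PER_SECOND = 10_000_000  # 100 ns ticks

#: Default per-task group-effect magnitudes.  Audio effects are strong on
#: every task (the speech channel is the dominant marker); IMU effects
#: default to zero — head motion carries no group signal unless enabled.
DEFAULT_AUDIO_EFFECT = {"T02": 1.0, "T03": 1.0, "T04": 1.2, "T05": 1.2, "T06": 1.0}
DEFAULT_IMU_EFFECT = {t: 0.0 for t in TASKS}
#: Preset marking T03/T06 as IMU-informative (movement-engaging tasks).
IMU_INFORMATIVE_EFFECT = {"T02": 0.0, "T03": 1.0, "T04": 0.0, "T05": 0.0, "T06": 1.0}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n_pd: int = 16
    n_hc: int = 16
    tasks: tuple[str, ...] = ("T03", "T04", "T06")
    sessions_per_participant: int = 1
    duration_range_s: tuple[float, float] = (10.0, 22.0)
    missing_modality_rate: float = 0.0
    audio_effect: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AUDIO_EFFECT))
    imu_effect: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_IMU_EFFECT))
    seed: int = 0

    def validate(self) -> None:
        if self.n_pd < 0 or self.n_hc < 0:
            raise ValueError("participant counts must be non-negative")
        if not self.tasks:
            raise ValueError("task list must be non-empty")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task id {t!r}")
            if t not in self.audio_effect or t not in self.imu_effect:
                raise ValueError(f"task {t!r} missing from an effect map")
        if not (0.0 <= self.missing_modality_rate <= 1.0):
            raise ValueError("missing_modality_rate must lie in [0, 1]")
        lo, hi = self.duration_range_s
        if lo <= 0 or hi < lo:
            raise ValueError("invalid duration range")
        if self.sessions_per_participant < 1:
            raise ValueError("sessions_per_participant must be >= 1")


@dataclass(frozen=True)
class EpisodeRecord:
    """One task-level recording: file references plus identity metadata."""

    participant_id: str
    group: str  # "PD" or "HC"
    task_id: str
    session_index: int
    wav_path: str | None = None
    acc_path: str | None = None
    gyr_path: str | None = None
    age: float | None = None
    sex: str | None = None

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.participant_id, self.task_id, self.session_index)


@dataclass(frozen=True)
class SpeechParams:
    f0_mean: float  # Hz
    f0_sd: float  # Hz, slow pitch variability
    intensity_mod_depth: float  # syllabic loudness modulation, [0, 1]
    amp_tremor_freq: float  # Hz
    amp_tremor_depth: float  # [0, 1]
    syllable_rate: float  # Hz; 0 for sustained vowel
    noise_snr_db: float
    duration_s: float

    def validate(self) -> None:
        if self.f0_mean <= 0:
            raise ValueError("f0_mean must be positive")
        if not (0 <= self.intensity_mod_depth <= 1 and 0 <= self.amp_tremor_depth <= 1):
            raise ValueError("modulation depths must lie in [0, 1]")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class ImuParams:
    acc_rate: float = 1100.0  # Hz (HoloLens-like accelerometer)
    gyr_rate: float = 3800.0  # Hz (HoloLens-like gyroscope)
    tremor_freq: float = 5.0  # Hz, within the 3-7 Hz parkinsonian band
    tremor_power: float = 0.0  # variance units
    drift_rate: float = 0.05  # units/s
    noise_sd: float = 1.0
    duration_s: float = 15.0

    def validate(self) -> None:
        if self.acc_rate <= 200 or self.gyr_rate <= 200:
            raise ValueError("IMU rates must exceed 200 Hz")
        if not (3.0 <= self.tremor_freq <= 7.0):
            raise ValueError("tremor_freq must lie in [3, 7] Hz")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.tremor_power < 0:
            raise ValueError("tremor_power must be non-negative")


@dataclass(frozen=True)
class EpisodeParams:
    """Generation parameters attached to one episode."""

    speech: SpeechParams
    imu: ImuParams
    signal_seed: int


_SYLLABLE_RATE_RANGE = {
    "T02": (2.5, 4.5),  # picture description
    "T03": (2.5, 4.5),  # daily activity monologue
    "T04": (2.5, 4.5),  # story recall
    "T05": (4.0, 7.0),  # diadochokinesis
    "T06": (0.0, 0.0),  # sustained vowel
}


def _draw_params(rng: np.random.Generator, group: str, task: str,
                 audio_effect: float, imu_effect: float,
                 duration_s: float) -> EpisodeParams:
    """Draw one episode's generation parameters.

    Baseline draws are identical for both groups; PD applies multiplicative /
    additive shifts scaled by the per-task effect magnitudes, so zero effects
    make the groups statistically indistinguishable.
    """
    f0_mean = float(np.exp(rng.normal(np.log(140.0), 0.18)))
    f0_sd = float(rng.uniform(8.0, 15.0))
    mod_depth = float(rng.uniform(0.35, 0.60))
    amp_tremor_freq = float(rng.uniform(4.0, 7.0))
    amp_tremor_depth = float(rng.uniform(0.0, 0.05))
    lo, hi = _SYLLABLE_RATE_RANGE[task]
    syllable_rate = float(rng.uniform(lo, hi)) if hi > 0 else 0.0
    snr = float(rng.uniform(15.0, 25.0))
    tremor_freq = float(rng.uniform(3.5, 6.5))
    tremor_gain = float(rng.uniform(0.5, 1.5))
    signal_seed = int(rng.integers(0, 2**31 - 1))

    tremor_power = 0.02  # faint physiological baseline, identical across groups
    if group == "PD":
        f0_sd *= max(0.0, 1.0 - 0.6 * audio_effect)
        mod_depth *= max(0.0, 1.0 - 0.5 * audio_effect)
        amp_tremor_depth = min(1.0, amp_tremor_depth + 0.2 * audio_effect)
        snr -= 8.0 * audio_effect  # breathiness: reduced harmonics-to-noise ratio
        tremor_power += 0.5 * imu_effect * tremor_gain

    speech = SpeechParams(
        f0_mean=f0_mean,
        f0_sd=f0_sd,
        intensity_mod_depth=min(1.0, mod_depth),
        amp_tremor_freq=amp_tremor_freq,
        amp_tremor_depth=amp_tremor_depth,
        syllable_rate=syllable_rate,
        noise_snr_db=snr,
        duration_s=duration_s,
    )
    imu = ImuParams(
        tremor_freq=tremor_freq,
        tremor_power=tremor_power,
        duration_s=duration_s,
    )
    return EpisodeParams(speech=speech, imu=imu, signal_seed=signal_seed)


def generate_cohort(spec: CohortSpec) -> tuple[list[EpisodeRecord], dict[tuple, EpisodeParams]]:
    """Draw the full cohort: episode records plus per-episode parameters.

    Deterministic for a fixed ``spec`` (including its seed).  File-path
    fields are filled with the relative paths :func:`write_dataset` will
    use; modalities dropped by ``missing_modality_rate`` are ``None``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[EpisodeRecord] = []
    params: dict[tuple, EpisodeParams] = {}

    participants = [("PD", f"PD{i:03d}") for i in range(spec.n_pd)]
    participants += [("HC", f"HC{i:03d}") for i in range(spec.n_hc)]

    for group, pid in participants:
        age = float(rng.uniform(55.0, 75.0))
        sex = "M" if rng.uniform() < 0.5 else "F"
        for session in range(1, spec.sessions_per_participant + 1):
            for task in spec.tasks:
                duration = float(rng.uniform(*spec.duration_range_s))
                ep = _draw_params(rng, group, task,
                                  spec.audio_effect[task], spec.imu_effect[task],
                                  duration)
                # one presence draw per modality, consumed unconditionally to
                # keep the parameter stream independent of the missing rate
                present = rng.uniform(size=3) >= spec.missing_modality_rate
                stem = f"{pid}_{task}_s{session:02d}"
                rec = EpisodeRecord(
                    participant_id=pid,
                    group=group,
                    task_id=task,
                    session_index=session,
                    wav_path=f"{stem}.wav" if present[0] else None,
                    acc_path=f"{stem}_acc.csv" if present[1] else None,
                    gyr_path=f"{stem}_gyr.csv" if present[2] else None,
                    age=round(age, 1),
                    sex=sex,
                )
                records.append(rec)
                params[rec.key] = ep
    return records, params


def make_cohort_manifest(spec: CohortSpec) -> list[EpisodeRecord]:
    """Episode records only (see :func:`generate_cohort` for parameters)."""
    return generate_cohort(spec)[0]


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

_FORMANTS = ((500.0, 90.0), (1500.0, 140.0), (2500.0, 220.0))  # (centre Hz, bandwidth Hz)


def synth_speech(params: SpeechParams, rng: np.random.Generator,
                 rate: int = AUDIO_RATE) -> np.ndarray:
    """Synthesize a vowel-like speech waveform (mono, peak <= 1).

    Glottal-like impulse train following a slowly drifting F0 contour,
    shaped by fixed second-order formant resonators, with syllabic and
    tremor amplitude modulation plus additive noise at the requested SNR.
    """
    params.validate()
    n = int(round(params.duration_s * rate))
    t = np.arange(n) / rate

    # F0 contour: random walk at 100 Hz control rate, standardized to the
    # requested SD so f0_sd=0 yields an exactly constant contour.
    n_ctrl = max(2, int(np.ceil(params.duration_s * 100)))
    walk = np.cumsum(rng.normal(size=n_ctrl))
    walk -= walk.mean()
    sd = walk.std()
    if sd > 0 and params.f0_sd > 0:
        walk *= params.f0_sd / sd
    else:
        walk[:] = 0.0
    f0_ctrl = np.maximum(50.0, params.f0_mean + walk)
    f0 = np.interp(t, np.arange(n_ctrl) / 100.0, f0_ctrl)

    # impulse train at the instantaneous F0
    phase = np.cumsum(f0) / rate
    pulses = np.diff(np.floor(phase), prepend=0.0)
    src = pulses.astype(np.float64)

    x = src
    for fc, bw in _FORMANTS:
        r = np.exp(-np.pi * bw / rate)
        theta = 2 * np.pi * fc / rate
        a = np.array([1.0, -2 * r * np.cos(theta), r * r])
        b = np.array([1.0 - r])
        x = sps.lfilter(b, a, x)

    env = np.ones_like(t)
    if params.syllable_rate > 0 and params.intensity_mod_depth > 0:
        phi = rng.uniform(0, 2 * np.pi)
        env *= (1.0 - params.intensity_mod_depth) + params.intensity_mod_depth * 0.5 * (
            1.0 - np.cos(2 * np.pi * params.syllable_rate * t + phi))
    if params.amp_tremor_depth > 0:
        phi = rng.uniform(0, 2 * np.pi)
        env *= 1.0 - params.amp_tremor_depth * 0.5 * (
            1.0 + np.sin(2 * np.pi * params.amp_tremor_freq * t + phi))
    x = x * env

    p_sig = float(np.mean(x**2))
    if p_sig > 0:
        noise_sd = np.sqrt(p_sig / 10 ** (params.noise_snr_db / 10))
        x = x + rng.normal(scale=noise_sd, size=n)

    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x = x / peak
    return x.astype(np.float32)


def synth_imu(params: ImuParams, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize accelerometer and gyroscope tables at their native rates.

    Each axis is low-frequency drift + white noise + a tremor sinusoid at
    ``tremor_freq`` with variance ``tremor_power`` (amplitude sqrt(2 P))
    and a random phase per axis.
    """
    params.validate()

    def one_stream(rate: float) -> pd.DataFrame:
        n = int(round(params.duration_s * rate))
        t = np.arange(n) / rate
        cols = {}
        amp = np.sqrt(2.0 * params.tremor_power)
        for axis in ("x", "y", "z"):
            drift = rng.normal(scale=params.drift_rate) * t
            noise = rng.normal(scale=params.noise_sd, size=n)
            phi = rng.uniform(0, 2 * np.pi)
            tremor = amp * np.sin(2 * np.pi * params.tremor_freq * t + phi)
            cols[axis] = (drift + noise + tremor).astype(np.float32)
        return pd.DataFrame({"timestamp": t, **cols})

    return one_stream(params.acc_rate), one_stream(params.gyr_rate)


# ---------------------------------------------------------------------------
# dataset serialization
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["participant_id", "group", "task_id", "session_index",
                    "wav_path", "acc_path", "gyr_path", "age", "sex"]


def write_dataset(records: list[EpisodeRecord],
                  params_per_record: dict[tuple, EpisodeParams],
                  out_dir: str,
                  dialect: str = "seconds",
                  wav_format: str = "float32",
                  audio_rate: int = AUDIO_RATE) -> str:
    """Materialize a cohort to disk: WAV + IMU CSV files and a manifest CSV.

    ``dialect`` selects the IMU time column: ``seconds`` (float seconds,
    header ``timestamp``) or ``ticks`` (integer 100 ns units, header
    ``ticks``).  ``audio_rate`` defaults to the pipeline's 16 kHz working
    rate; a 48 kHz mode exists to exercise the loader's resampling path.
    Returns the manifest path.
    """
    if dialect not in ("seconds", "ticks"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if wav_format not in ("float32", "pcm16"):
        raise ValueError(f"unknown wav_format {wav_format!r}")
    os.makedirs(out_dir, exist_ok=True)

    for rec in records:
        ep = params_per_record[rec.key]
        rng = np.random.default_rng(ep.signal_seed)
        # draw both modalities from the same stream in a fixed order so the
        # written signals match an in-memory regeneration exactly
        wav = synth_speech(ep.speech, rng, rate=audio_rate)
        acc, gyr = synth_imu(ep.imu, rng)
        if rec.wav_path:
            if wav_format == "pcm16":
                wavfile.write(os.path.join(out_dir, rec.wav_path), audio_rate,
                              np.round(wav * 32767.0).astype(np.int16))
            else:
                wavfile.write(os.path.join(out_dir, rec.wav_path), audio_rate, wav)
        for path, table in ((rec.acc_path, acc), (rec.gyr_path, gyr)):
            if not path:
                continue
            out = table.copy()
            if dialect == "ticks":
                out.insert(0, "ticks",
                           np.round(out.pop("timestamp") * TICKS_PER_SECOND).astype(np.int64))
            out.to_csv(os.path.join(out_dir, path), index=False)

    manifest = records_to_frame(records)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def records_to_frame(records: list[EpisodeRecord]) -> pd.DataFrame:
    rows = [{
        "participant_id": r.participant_id, "group": r.group, "task_id": r.task_id,
        "session_index": r.session_index,
        "wav_path": r.wav_path or "", "acc_path": r.acc_path or "",
        "gyr_path": r.gyr_path or "", "age": r.age, "sex": r.sex,
    } for r in records]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def read_manifest(path: str) -> list[EpisodeRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(EpisodeRecord(
            participant_id=str(row["participant_id"]),
            group=str(row["group"]),
            task_id=str(row["task_id"]),
            session_index=int(row["session_index"]),
            wav_path=str(row["wav_path"]) or None,
            acc_path=str(row["acc_path"]) or None,
            gyr_path=str(row["gyr_path"]) or None,
            age=float(row["age"]) if str(row["age"]) != "" else None,
            sex=str(row["sex"]) or None,
        ))
    return records


def summarize_completeness(records: list[EpisodeRecord]) -> tuple[pd.DataFrame, float]:
    """Per-group modality availability table plus overall tri-modal fraction.

    A record counts as *complete* iff all three modality paths are present;
    the fraction is complete sessions over all sessions, pooled over groups.
    """
    rows = []
    by_group: dict[str, list[EpisodeRecord]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    total_sessions = 0
    total_complete = 0
    for group in sorted(by_group):
        recs = by_group[group]
        complete = sum(1 for r in recs if r.wav_path and r.acc_path and r.gyr_path)
        rows.append({
            "group": group,
            "participants": len({r.participant_id for r in recs}),
            "sessions": len(recs),
            "audio": sum(1 for r in recs if r.wav_path),
            "accel": sum(1 for r in recs if r.acc_path),
            "gyro": sum(1 for r in recs if r.gyr_path),
            "complete": complete,
        })
        total_sessions += len(recs)
        total_complete += complete
    frac = total_complete / total_sessions if total_sessions else 0.0
    return pd.DataFrame(rows), frac
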