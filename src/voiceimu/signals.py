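"""Signal preprocessing and temporal alignment.

Audio: load at 16 kHz mono, peak-normalize, extract 56-band log-mel
spectrograms (NFFT=1024, hop=320, Hann, centered; natural log with a 1e-10
floor).  IMU: heuristic CSV parsing, linear resampling of accelerometer and
gyroscope to a shared 100 Hz six-channel stream, per-channel median/SD
normalization.  The two modalities are aligned by interpolating the IMU
stream onto the mel-frame timestamp grid, then cropped to 15 s windows
(random crops in training, K-crop test-time augmentation at inference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

TARGET_RATE = 16_000
N_FFT = 1024
HOP = 320
N_MELS = 56
LOG_FLOOR = 1e-10
FRAMES_PER_SECOND = TARGET_RATE / HOP  # 50
IMU_RATE = 100.0
TICKS_PER_SECOND = 10_000_000
CROP_SECONDS = 15.0


@dataclass
class Waveform:
    samples: np.ndarray  # mono, peak-normalized
    rate: int = TARGET_RATE

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class MelSequence:
    values: np.ndarray  # (T, N_MELS) natural-log power
    frame_times: np.ndarray  # seconds, frame k at k*HOP/rate

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / FRAMES_PER_SECOND


@dataclass
class ImuStream:
    values: np.ndarray  # (T, 6): ACC x,y,z then GYR x,y,z
    times: np.ndarray  # uniform 10 ms grid from 0
    rate: float = IMU_RATE

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_steps / self.rate


@dataclass
class AlignedCrop:
    """Paired sequences on a shared mel-frame grid."""

    X_a: np.ndarray  # (T, 56)
    X_i: np.ndarray  # (T, 6)
    crop_start: float  # seconds

    @property
    def T(self) -> int:
        return self.X_a.shape[0]


def load_audio(path: str) -> Waveform:
    """Read a WAV file -> 16 kHz mono peak-normalized waveform.

    Resampling uses a polyphase FIR (anti-aliasing low-pass built in);
    multichannel input is averaged to mono; an all-zero signal is returned
    unnormalized.
    """
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    x = data.astype(np.float64)
    if np.issubdtype(data.dtype, np.integer):
        x = x / float(np.iinfo(data.dtype).max + 1)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != TARGET_RATE:
        frac = Fraction(TARGET_RATE, int(rate))
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x = x / peak
    return Waveform(samples=x.astype(np.float32), rate=TARGET_RATE)


def _hz_to_mel(f):
    """Slaney mel scale: linear below 1 kHz, logarithmic above."""
    f = np.asarray(f, dtype=np.float64)
    mel = f / (200.0 / 3.0)
    log_step = np.log(6.4) / 27.0
    above = f >= 1000.0
    mel = np.where(above, 15.0 + np.log(np.maximum(f, 1e-12) / 1000.0) / log_step, mel)
    return mel


def _mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    log_step = np.log(6.4) / 27.0
    f = m * (200.0 / 3.0)
    return np.where(m >= 15.0, 1000.0 * np.exp(log_step * (m - 15.0)), f)


def mel_filterbank(n_mels: int = N_MELS, n_fft: int = N_FFT,
                   rate: int = TARGET_RATE, fmin: float = 0.0,
                   fmax: float | None = None) -> np.ndarray:
    """Slaney-style area-normalized triangular mel filterbank, (n_mels, n_fft//2+1)."""
    if fmax is None:
        fmax = rate / 2
    fft_freqs = np.linspace(0, rate / 2, n_fft // 2 + 1)
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        fb[i] *= 2.0 / (hi - lo)  # area normalization
    return fb


_FB_CACHE: dict[tuple, np.ndarray] = {}
_WIN = sps.get_window("hann", N_FFT, fftbins=True)


def compute_logmel(w: Waveform) -> MelSequence:
    """Log-mel spectrogram: centered power STFT x mel filterbank, ln(. + 1e-10).

    Frame count is truncated to floor(n_samples / hop) so a 15 s crop yields
    exactly 750 frames; frame k is timestamped at k*hop/rate.
    """
    x = np.asarray(w.samples, dtype=np.float64)
    if len(x) < HOP:
        raise ValueError("waveform shorter than one hop")
    n_frames = len(x) // HOP
    pad = N_FFT // 2
    xp = np.pad(x, (pad, pad + N_FFT))
    idx = np.arange(n_frames)[:, None] * HOP + np.arange(N_FFT)[None, :]
    frames = xp[idx] * _WIN
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    key = (N_MELS, N_FFT, w.rate)
    if key not in _FB_CACHE:
        _FB_CACHE[key] = mel_filterbank(N_MELS, N_FFT, w.rate, 0.0, w.rate / 2)
    mel = spec @ _FB_CACHE[key].T
    values = np.log(mel + LOG_FLOOR).astype(np.float32)
    frame_times = np.arange(n_frames) * (HOP / w.rate)
    return MelSequence(values=values, frame_times=frame_times)


_TIME_NAMES = ("time", "timestamp", "ticks", "t")


def load_imu_table(path_or_df) -> pd.DataFrame:
    """Parse a raw IMU CSV into a table with columns t (seconds), x, y, z.

    The time column is the first header matching {time, timestamp, ticks, t}
    case-insensitively; a ``ticks`` column is converted from 100 ns units.
    The axes are the first three remaining numeric columns in file order.
    Missing samples are forward- then back-filled; time is re-based to 0.
    """
    df = pd.read_csv(path_or_df) if isinstance(path_or_df, str) else path_or_df.copy()
    time_col = None
    for c in df.columns:
        if str(c).strip().lower() in _TIME_NAMES:
            time_col = c
            break
    if time_col is None:
        raise ValueError("no time-like column found")
    t = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=np.float64)
    if str(time_col).strip().lower() == "ticks":
        t = t / TICKS_PER_SECOND
    axes = []
    for c in df.columns:
        if c == time_col:
            continue
        col = pd.to_numeric(df[c], errors="coerce")
        if col.notna().any():
            axes.append(col)
        if len(axes) == 3:
            break
    if len(axes) < 3:
        raise ValueError("fewer than 3 numeric axis columns")
    out = pd.DataFrame({"t": t})
    for name, col in zip(("x", "y", "z"), axes):
        out[name] = col.to_numpy(dtype=np.float64)
    out = out.ffill().bfill()
    out["t"] = out["t"] - out["t"].iloc[0]
    if np.any(np.diff(out["t"].to_numpy()) < 0):
        raise ValueError("non-monotone time after rebase")
    return out


def to_100hz_six_channel(acc_table: pd.DataFrame, gyr_table: pd.DataFrame) -> ImuStream:
    """Resample both streams to a uniform 100 Hz grid and stack (ACC first).

    Each stream is linearly interpolated independently from 0 to its last
    timestamp; the two grids are truncated to their common length.
    """
    streams = []
    lengths = []
    for table in (acc_table, gyr_table):
        if len(table) < 2:
            raise ValueError("IMU table needs at least 2 samples")
        t = table["t"].to_numpy()
        n = int(math.floor(t[-1] * IMU_RATE)) + 1
        grid = np.arange(n) / IMU_RATE
        chans = [np.interp(grid, t, table[a].to_numpy()) for a in ("x", "y", "z")]
        streams.append(np.stack(chans, axis=1))
        lengths.append(n)
    n = min(lengths)
    values = np.concatenate([s[:n] for s in streams], axis=1)
    return ImuStream(values=values.astype(np.float64), times=np.arange(n) / IMU_RATE)


def normalize_channels(s: ImuStream) -> ImuStream:
    """Per-channel median centering and SD scaling (1e-6 floor), episode-wide."""
    v = s.values
    med = np.median(v, axis=0, keepdims=True)
    sd = np.maximum(v.std(axis=0, keepdims=True), 1e-6)
    return ImuStream(values=(v - med) / sd, times=s.times, rate=s.rate)


def align_to_mel_grid(s: ImuStream, frame_times: np.ndarray) -> np.ndarray:
    """Linearly interpolate each IMU channel at the mel-frame timestamps.

    Times beyond the stream's support are clamped to the edge values.
    """
    if s.n_steps == 0:
        raise ValueError("empty IMU stream")
    frame_times = np.asarray(frame_times, dtype=np.float64)
    out = np.empty((len(frame_times), s.values.shape[1]))
    for c in range(s.values.shape[1]):
        out[:, c] = np.interp(frame_times, s.times, s.values[:, c])
    return out


def make_crops(mel: MelSequence, imu: ImuStream, mode: str, K: int,
               rng: np.random.Generator,
               crop_s: float = CROP_SECONDS) -> list[AlignedCrop]:
    """Cut aligned 15 s (default) windows from one episode.

    The usable overlap D is the minimum of the two modality durations.  If
    D exceeds the crop length, starts are drawn uniformly in [0, D - crop]
    (one crop in training, K crops at test time); otherwise the full
    overlap is used and all test crops are identical.
    """
    if mel.n_frames == 0 or imu.n_steps == 0:
        raise ValueError("both modalities must be non-empty")
    if mode not in ("train", "test"):
        raise ValueError(f"unknown mode {mode!r}")
    D = min(mel.duration_s, imu.duration_s)
    if D <= 0:
        raise ValueError("empty overlap")
    n_crops = 1 if mode == "train" else K
    crops = []
    full_T = min(int(round(min(crop_s, D) * FRAMES_PER_SECOND)), mel.n_frames)
    for _ in range(n_crops):
        if D > crop_s:
            start = float(rng.uniform(0.0, D - crop_s))
            s0 = int(round(start * FRAMES_PER_SECOND))
            s0 = min(s0, mel.n_frames - full_T)
        else:
            start, s0 = 0.0, 0
        xa = mel.values[s0:s0 + full_T]
        ft = mel.frame_times[s0:s0 + full_T]
        xi = align_to_mel_grid(imu, ft)
        crops.append(AlignedCrop(X_a=xa, X_i=xi.astype(np.float32),
                                 crop_start=s0 / FRAMES_PER_SECOND))
    return crops
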