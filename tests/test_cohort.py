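"""Synthetic cohort generator: manifests, signal models, serialization."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps
from scipy.io import wavfile

from voiceimu.cohort import (
    AUDIO_RATE,
    CohortSpec,
    EpisodeRecord,
    ImuParams,
    SpeechParams,
    generate_cohort,
    make_cohort_manifest,
    read_manifest,
    records_to_frame,
    summarize_completeness,
    synth_imu,
    synth_speech,
    write_dataset,
)


def small_spec(**kw):
    base = dict(n_pd=2, n_hc=2, tasks=("T06",), sessions_per_participant=1,
                duration_range_s=(2.0, 3.0), missing_modality_rate=0.0, seed=7)
    base.update(kw)
    return CohortSpec(**base)


class TestManifest:
    def test_complete_small_cohort(self):
        recs = make_cohort_manifest(small_spec())
        assert len(recs) == 4
        assert all(r.wav_path and r.acc_path and r.gyr_path for r in recs)
        assert len({r.key for r in recs}) == 4

    def test_all_modalities_dropped_at_rate_one(self):
        recs = make_cohort_manifest(small_spec(missing_modality_rate=1.0))
        assert all(r.wav_path is None and r.acc_path is None and r.gyr_path is None
                   for r in recs)

    def test_missing_rate_tally(self):
        """Presence fraction matches the binomial expectation 1 - rate."""
        recs = make_cohort_manifest(small_spec(n_pd=50, n_hc=50,
                                               missing_modality_rate=0.3, seed=0))
        n = len(recs)
        for attr in ("wav_path", "acc_path", "gyr_path"):
            frac = sum(1 for r in recs if getattr(r, attr)) / n
            assert abs(frac - 0.7) < 0.05

    @pytest.mark.parametrize("kw", [dict(tasks=()), dict(n_pd=-1),
                                    dict(missing_modality_rate=1.5)])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            make_cohort_manifest(small_spec(**kw))

    def test_determinism(self):
        a_recs, a_params = generate_cohort(small_spec(n_pd=5, n_hc=5))
        b_recs, b_params = generate_cohort(small_spec(n_pd=5, n_hc=5))
        assert records_to_frame(a_recs).to_csv() == records_to_frame(b_recs).to_csv()
        assert a_params == b_params

    def test_group_constant_per_participant(self):
        recs = make_cohort_manifest(small_spec(n_pd=4, n_hc=4,
                                               tasks=("T03", "T06"),
                                               sessions_per_participant=2))
        groups = {}
        for r in recs:
            groups.setdefault(r.participant_id, set()).add(r.group)
        assert all(len(g) == 1 for g in groups.values())


class TestGroupStructure:
    def test_zero_effects_make_groups_indistinguishable(self):
        """With all effect magnitudes at zero the generated parameter
        distributions are identical across groups (two-sample KS)."""
        zero = {t: 0.0 for t in ("T06",)}
        hits = 0
        for seed in range(10):
            spec = small_spec(n_pd=200, n_hc=200, audio_effect=zero,
                              imu_effect=zero, seed=seed)
            _, params = generate_cohort(spec)
            pd_v = [p.speech.f0_sd for k, p in params.items() if k[0].startswith("PD")]
            hc_v = [p.speech.f0_sd for k, p in params.items() if k[0].startswith("HC")]
            from scipy.stats import ks_2samp
            if ks_2samp(pd_v, hc_v).pvalue > 0.01:
                hits += 1
        assert hits >= 9

    def test_pd_shifts_follow_effect_direction(self):
        _, params = generate_cohort(small_spec(n_pd=100, n_hc=100, seed=3))
        pd_sd = np.mean([p.speech.f0_sd for k, p in params.items() if k[0][:2] == "PD"])
        hc_sd = np.mean([p.speech.f0_sd for k, p in params.items() if k[0][:2] == "HC"])
        assert pd_sd < hc_sd


class TestSpeechSynthesis:
    def test_sample_count(self):
        p = SpeechParams(140, 0, 0, 5, 0, 0, 30, duration_s=10)
        x = synth_speech(p, np.random.default_rng(0))
        assert len(x) == 160_000

    def test_peak_normalized(self):
        p = SpeechParams(120, 10, 0.5, 5, 0.3, 3, 15, duration_s=2)
        x = synth_speech(p, np.random.default_rng(1))
        assert np.isclose(np.max(np.abs(x)), 1.0, atol=1e-6)

    def test_f0_recoverable_by_autocorrelation(self):
        """A steady vowel's pitch estimate lands within 2% of f0_mean."""
        f0 = 130.0
        p = SpeechParams(f0, 0, 0, 5, 0, 0, 40, duration_s=2)
        x = synth_speech(p, np.random.default_rng(2)).astype(np.float64)
        seg = x[AUDIO_RATE // 2:AUDIO_RATE // 2 + AUDIO_RATE]
        ac = np.correlate(seg, seg, mode="full")[len(seg) - 1:]
        lo, hi = int(AUDIO_RATE / 300), int(AUDIO_RATE / 60)
        lag = lo + int(np.argmax(ac[lo:hi]))
        est = AUDIO_RATE / lag
        assert abs(est - f0) / f0 < 0.02

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            synth_speech(SpeechParams(140, 0, 0, 5, 0, 0, 30, duration_s=0),
                         np.random.default_rng(0))


class TestImuSynthesis:
    def test_sample_counts(self):
        p = ImuParams(acc_rate=1100, duration_s=15)
        acc, gyr = synth_imu(p, np.random.default_rng(0))
        assert abs(len(acc) - 16_500) <= 1
        assert abs(len(gyr) - 57_000) <= 1
        assert np.all(np.diff(acc["timestamp"]) > 0)

    def test_no_tremor_gives_flat_band_spectrum(self):
        p = ImuParams(tremor_power=0.0, drift_rate=0.0, duration_s=20)
        acc, _ = synth_imu(p, np.random.default_rng(3))
        f, pxx = sps.welch(acc["x"].to_numpy(), fs=1100, nperseg=4096)
        band = pxx[(f >= 3) & (f <= 7)].mean()
        ref = pxx[(f >= 8) & (f <= 12)].mean()
        assert abs(10 * np.log10(band / ref)) < 3

    def test_strong_tremor_peaks_at_its_frequency(self):
        p = ImuParams(tremor_freq=5.0, tremor_power=50.0, noise_sd=0.5,
                      drift_rate=0.0, duration_s=20)
        acc, _ = synth_imu(p, np.random.default_rng(4))
        f, pxx = sps.welch(acc["x"].to_numpy(), fs=1100, nperseg=8192)
        assert 4.5 <= f[np.argmax(pxx)] <= 5.5

    def test_band_power_monotone_in_tremor_power(self):
        """Estimated 3-7 Hz band power is nondecreasing in the tremor knob."""
        grid = [0.0, 0.25, 0.5, 1.0, 2.0]
        means = []
        for power in grid:
            vals = []
            for seed in range(20):
                p = ImuParams(tremor_freq=5.0, tremor_power=power,
                              drift_rate=0.0, duration_s=8)
                acc, _ = synth_imu(p, np.random.default_rng(seed))
                f, pxx = sps.welch(acc["x"].to_numpy(), fs=1100, nperseg=2048)
                vals.append(pxx[(f >= 3) & (f <= 7)].mean())
            means.append(np.mean(vals))
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestSerialization:
    def test_round_trip_and_manifest(self, tmp_path):
        recs, params = generate_cohort(small_spec())
        manifest = write_dataset(recs, params, str(tmp_path), dialect="seconds")
        df = pd.read_csv(manifest)
        assert len(df) == len(recs)
        back = read_manifest(manifest)
        assert [r.key for r in back] == [r.key for r in recs]
        rate, wav = wavfile.read(tmp_path / recs[0].wav_path)
        assert rate == AUDIO_RATE and wav.dtype == np.float32

    def test_pcm16_quantization_bound(self, tmp_path):
        recs, params = generate_cohort(small_spec(n_pd=1, n_hc=0))
        write_dataset(recs, params, str(tmp_path), wav_format="pcm16")
        ep = params[recs[0].key]
        rng = np.random.default_rng(ep.signal_seed)
        original = synth_speech(ep.speech, rng)
        _, wav = wavfile.read(tmp_path / recs[0].wav_path)
        assert np.max(np.abs(wav / 32767.0 - original)) <= 1.0 / 32767.0

    def test_ticks_dialect(self, tmp_path):
        recs, params = generate_cohort(small_spec(n_pd=1, n_hc=0,
                                                  duration_range_s=(1.5, 1.5)))
        write_dataset(recs, params, str(tmp_path), dialect="ticks")
        df = pd.read_csv(tmp_path / recs[0].acc_path)
        assert list(df.columns)[:1] == ["ticks"]
        # one second of samples at 1100 Hz -> tick 10,000,000
        row = df.iloc[1100]
        assert row["ticks"] == 10_000_000

    def test_48k_mode_resamples_on_load(self, tmp_path):
        recs, params = generate_cohort(small_spec(n_pd=1, n_hc=0,
                                                  duration_range_s=(2.0, 2.0)))
        write_dataset(recs, params, str(tmp_path), audio_rate=48_000)
        from voiceimu.signals import load_audio
        w = load_audio(str(tmp_path / recs[0].wav_path))
        assert w.rate == AUDIO_RATE and len(w.samples) == 2 * AUDIO_RATE

    def test_unknown_dialect_rejected(self, tmp_path):
        recs, params = generate_cohort(small_spec(n_pd=1, n_hc=0))
        with pytest.raises(ValueError):
            write_dataset(recs, params, str(tmp_path), dialect="minutes")


def _records_with_counts(group, n, complete, audio, accel, gyro):
    recs = []
    extras = [audio - complete, accel - complete, gyro - complete]
    for i in range(n):
        has = [False, False, False]
        if i < complete:
            has = [True, True, True]
        else:
            j = i - complete
            if j < extras[0]:
                has[0] = True
            elif j < extras[0] + extras[1]:
                has[1] = True
            elif j < extras[0] + extras[1] + extras[2]:
                has[2] = True
        recs.append(EpisodeRecord(
            participant_id=f"{group}{i % 93}", group=group, task_id="T02",
            session_index=i,
            wav_path="a.wav" if has[0] else None,
            acc_path="a.csv" if has[1] else None,
            gyr_path="g.csv" if has[2] else None))
    return recs


class TestCompleteness:
    def test_cohort_style_counts_give_47_percent(self):
        """Session counts shaped like the clinical inventory (HC 464/211
        complete, PD 358/175) yield a tri-modal fraction that rounds to 47%."""
        recs = _records_with_counts("HC", 464, 211, 216, 218, 218)
        recs += _records_with_counts("PD", 358, 175, 175, 182, 181)
        table, frac = summarize_completeness(recs)
        hc = table[table["group"] == "HC"].iloc[0]
        assert (hc["sessions"], hc["audio"], hc["accel"], hc["gyro"], hc["complete"]) \
            == (464, 216, 218, 218, 211)
        assert round(frac * 100) == 47

    def test_all_complete(self):
        recs = make_cohort_manifest(small_spec())
        _, frac = summarize_completeness(recs)
        assert frac == 1.0

    def test_missing_gyro_means_zero_complete(self):
        recs = [EpisodeRecord("P1", "PD", "T02", i, "w.wav", "a.csv", None)
                for i in range(5)]
        table, frac = summarize_completeness(recs)
        assert frac == 0.0 and table["complete"].sum() == 0
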