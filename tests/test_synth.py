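"""Synthetic ECG generator: rhythm statistics, morphology, noise, datasets."""

import numpy as np
import pytest
from scipy import signal

from afnet import (
    ECGSynthConfig,
    RhythmClass,
    add_noise,
    generate_dataset,
    render_waveform,
    sample_rr_intervals,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestRRIntervals:
    def test_same_seed_identical(self, default_config):
        a = sample_rr_intervals(RhythmClass.AF, 50, default_config, _rng(3))
        b = sample_rr_intervals(RhythmClass.AF, 50, default_config, _rng(3))
        np.testing.assert_array_equal(a, b)

    def test_af_more_irregular_than_nsr(self, default_config):
        nsr = sample_rr_intervals(RhythmClass.NSR, 10_000, default_config, _rng(1))
        af = sample_rr_intervals(RhythmClass.AF, 10_000, default_config, _rng(2))
        cv = lambda x: np.std(x) / np.mean(x)  # noqa: E731
        assert cv(nsr) < cv(af)

    def test_af_mean_matches_gamma_parameters(self, default_config):
        n = 10_000
        af = sample_rr_intervals(RhythmClass.AF, n, default_config, _rng(4))
        se = default_config.af_rr_mean * default_config.af_rr_cv / np.sqrt(n)
        assert abs(af.mean() - default_config.af_rr_mean) < 3 * se

    def test_all_positive_and_nsr_truncated(self, default_config):
        for rhythm in (RhythmClass.NSR, RhythmClass.AF):
            rr = sample_rr_intervals(rhythm, 5000, default_config, _rng(5))
            assert np.all(rr > 0)
        nsr = sample_rr_intervals(RhythmClass.NSR, 5000, default_config, _rng(6))
        assert np.all(nsr >= 0.3)

    def test_rejects_nonpositive_n_beats(self, default_config):
        with pytest.raises(ValueError):
            sample_rr_intervals(RhythmClass.NSR, 0, default_config, _rng(0))


class TestWaveform:
    def test_output_length_is_rr_sum_times_fs(self, default_config):
        out = render_waveform(np.ones(5), RhythmClass.NSR, default_config, _rng(0))
        assert out.size == 2500

    def test_peak_count_equals_beat_count(self, default_config):
        rr = sample_rr_intervals(RhythmClass.NSR, 12, default_config, _rng(1))
        clean = render_waveform(rr, RhythmClass.NSR, default_config, _rng(1))
        r_amp = default_config.morphology.bumps["R"][0]
        peaks, _ = signal.find_peaks(clean, height=r_amp / 2)
        assert peaks.size == 12

    def test_af_suppresses_p_wave_energy(self, default_config):
        """Energy 60-200 ms before each R peak drops when P bumps vanish."""
        rr = np.full(10, 0.8)
        nsr = render_waveform(rr, RhythmClass.NSR, default_config, _rng(2))
        af = render_waveform(rr, RhythmClass.AF, default_config, _rng(2))
        fs = default_config.fs
        r_times = np.cumsum(rr) - rr[0] / 2
        def window_energy(x):
            total = 0.0
            for rt in r_times[1:]:
                lo, hi = int((rt - 0.2) * fs), int((rt - 0.06) * fs)
                total += float(np.sum(x[lo:hi] ** 2))
            return total
        assert window_energy(af) < window_energy(nsr)

    def test_af_adds_fibrillatory_oscillation(self, default_config):
        rr = np.full(10, 0.8)
        af = render_waveform(rr, RhythmClass.AF, default_config, _rng(3))
        f, p = signal.periodogram(af, fs=default_config.fs)
        nsr = render_waveform(rr, RhythmClass.NSR, default_config, _rng(3))
        _, p_nsr = signal.periodogram(nsr, fs=default_config.fs)
        i_fib = np.argmin(np.abs(f - default_config.fib_wave_freq))
        assert p[i_fib] > 100 * p_nsr[i_fib]

    def test_rejects_empty_or_nonpositive_rr(self, default_config):
        with pytest.raises(ValueError):
            render_waveform(np.array([]), RhythmClass.NSR, default_config, _rng(0))
        with pytest.raises(ValueError):
            render_waveform(np.array([0.8, -0.1]), RhythmClass.NSR, default_config, _rng(0))


class TestNoise:
    def test_zero_amplitudes_identity(self):
        cfg = ECGSynthConfig(noise_amplitudes=(0.0, 0.0, 0.0))
        x = np.sin(np.linspace(0, 10, 1000))
        out = add_noise(x, cfg.fs, cfg, _rng(0))
        np.testing.assert_array_equal(out, x)

    def test_powerline_peak_in_periodogram(self, default_config):
        x = np.zeros(5000)
        out = add_noise(x, default_config.fs, default_config, _rng(1))
        f, p = signal.periodogram(out, fs=default_config.fs)
        i50 = np.argmin(np.abs(f - default_config.powerline_freq))
        _, p_clean = signal.periodogram(x, fs=default_config.fs)
        assert p[i50] > p_clean[i50]

    def test_emg_variance_monotone(self):
        x = np.zeros(20_000)
        lo = ECGSynthConfig(noise_amplitudes=(0.0, 0.0, 0.03))
        hi = ECGSynthConfig(noise_amplitudes=(0.0, 0.0, 0.06))
        v_lo = np.var(add_noise(x, lo.fs, lo, _rng(2)) - x)
        v_hi = np.var(add_noise(x, hi.fs, hi, _rng(2)) - x)
        assert v_hi > v_lo

    def test_rejects_negative_amplitude(self):
        with pytest.raises(ValueError):
            ECGSynthConfig(noise_amplitudes=(-0.1, 0.0, 0.0))


class TestConfigInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fs": 0}, {"duration_s": -1}, {"af_fraction": 0.0}, {"af_fraction": 1.0},
            {"af_rr_cv": 0.01},  # not more irregular than NSR
            {"fib_wave_freq": 12.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ECGSynthConfig(**kwargs)


class TestDataset:
    def test_exact_class_counts(self):
        cfg = ECGSynthConfig(duration_s=2.0, fs=100.0, seed=0)
        records = generate_dataset(600, cfg)
        n_af = sum(r.label is RhythmClass.AF for r in records)
        assert n_af == 100 and len(records) == 600

    def test_two_record_balanced(self):
        cfg = ECGSynthConfig(duration_s=2.0, fs=100.0, af_fraction=0.5, seed=0)
        labels = sorted(r.label.value for r in generate_dataset(2, cfg))
        assert labels == ["AF", "NSR"]

    def test_seeded_determinism(self):
        cfg = ECGSynthConfig(duration_s=2.0, fs=100.0, seed=9)
        a = generate_dataset(10, cfg)
        b = generate_dataset(10, cfg)
        for ra, rb in zip(a, b):
            assert ra.label is rb.label
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_record_invariants(self, small_dataset, default_config):
        for rec in small_dataset:
            assert np.all(np.isfinite(rec.samples))
            assert rec.fs > 0
            assert rec.samples.size == default_config.n_samples

    def test_rejects_too_few_records(self, default_config):
        with pytest.raises(ValueError):
            generate_dataset(1, default_config)

    def test_four_class_mode(self):
        cfg = ECGSynthConfig(duration_s=2.0, fs=100.0, seed=3)
        records = generate_dataset(40, cfg, four_class=True,
                                   other_fraction=0.2, noise_fraction=0.1)
        counts = {c: sum(r.label is c for r in records) for c in RhythmClass}
        assert counts[RhythmClass.AF] == round(40 * cfg.af_fraction)
        assert counts[RhythmClass.OTHER] == 8
        assert counts[RhythmClass.NOISE] == 4
        assert sum(counts.values()) == 40


def test_rr_irregularity_separates_classes(small_dataset):
    """A single RR-sd threshold achieves >= 90% accuracy on default data."""
    from afnet.baseline import best_threshold_accuracy

    acc, thr = best_threshold_accuracy(small_dataset)
    assert acc >= 0.90
    assert thr > 0
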