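"""Cleaning-chain tests: high-pass, notch, resampling, code standardization."""

import numpy as np
import pytest

from afdet.io import AFIB, AFL, NSR, OTHER, EcgRecord, RecordTooShortError
from afdet.preprocess import (PreprocessConfig, highpass, powerline_filter,
                              preprocess_record, resample_to,
                              standardize_diagnosis)


def tone(freq, fs, duration=10.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestHighpass:
    def test_dc_rejection(self):
        out = highpass(np.full(2000, 3.0), fs=125.0)
        assert np.abs(out).max() < 1e-6

    def test_zero_phase_symmetry(self):
        """A symmetric pulse stays symmetric: forward-backward filtering adds
        no group delay."""
        n = 4001
        x = np.zeros(n)
        c = n // 2
        ramp = np.linspace(0, 1, 200)
        x[c - 199:c + 1] = ramp
        x[c:c + 200] = ramp[::-1]
        out = highpass(x, fs=125.0)
        assert np.abs(out - out[::-1]).max() < 1e-6 * np.abs(out).max()

    def test_stopband_attenuation_matches_butterworth_squared_magnitude(self):
        """A sub-cutoff tone is attenuated by the squared order-5 Butterworth
        magnitude (squared because of the forward and backward passes)."""
        fs, f0, fc, order = 125.0, 0.35, 0.5, 5
        x = tone(f0, fs, duration=600.0)
        out = highpass(x, fs)
        # closed-form |H(f)|^2 for a Butterworth high-pass, one pass
        ratio = (f0 / fc) ** (2 * order)
        expected = ratio / (1 + ratio)          # power gain = two-pass amplitude
        # steady-state amplitude by projection onto the tone's quadratures
        core = slice(len(x) // 3, -len(x) // 3)
        t = np.arange(len(x))[core] / fs
        c = np.cos(2 * np.pi * f0 * t)
        s = np.sin(2 * np.pi * f0 * t)
        amp = 2 * np.hypot(np.dot(out[core], c), np.dot(out[core], s)) / len(t)
        assert amp == pytest.approx(expected, rel=0.10)

    def test_too_short_signal_raises(self):
        with pytest.raises(RecordTooShortError):
            highpass(np.ones(10), fs=125.0)

    def test_passband_idempotence(self):
        """Filtering a 5-40 Hz band-limited signal twice changes it < 1% RMS."""
        rng = np.random.default_rng(0)
        fs = 125.0
        x = sum(tone(f, fs, 30.0, rng.uniform(0.5, 1))
                for f in rng.uniform(5, 40, size=8))
        once = highpass(x, fs)
        twice = highpass(once, fs)
        core = slice(int(5 * fs), -int(5 * fs))  # steady state, past edge transients
        rms = (np.sqrt(np.mean((twice - once)[core] ** 2))
               / np.sqrt(np.mean(once[core] ** 2)))
        assert rms < 0.01


class TestPowerline:
    def test_mains_tone_suppressed(self):
        fs = 500.0
        x = tone(50.0, fs)
        out = powerline_filter(x, fs)
        assert np.sqrt(np.mean(out ** 2)) < 0.1 * np.sqrt(np.mean(x ** 2))

    def test_suppression_at_least_20db(self):
        fs = 500.0
        x = tone(50.0, fs, duration=20.0)
        out = powerline_filter(x, fs)
        core = slice(len(x) // 4, -len(x) // 4)
        db = 20 * np.log10(np.sqrt(np.mean(out[core] ** 2))
                           / np.sqrt(np.mean(x[core] ** 2)))
        assert db < -20.0

    def test_passband_tone_preserved(self):
        fs = 500.0
        x = tone(10.0, fs)
        out = powerline_filter(x, fs)
        assert np.sqrt(np.mean(out ** 2)) == pytest.approx(
            np.sqrt(np.mean(x ** 2)), rel=0.05)

    def test_zero_in_zero_out(self):
        assert np.allclose(powerline_filter(np.zeros(1000), 500.0), 0.0)

    def test_low_rate_skips_filter(self, caplog):
        x = tone(10.0, 80.0)
        with caplog.at_level("WARNING"):
            out = powerline_filter(x, 80.0)  # 80 <= 2*50: cannot notch
        assert np.array_equal(out, x)
        assert "skipped" in caplog.text


class TestResample:
    def test_length_arithmetic(self):
        assert len(resample_to(np.zeros(2500), 250.0)) == 1250

    def test_identity_at_target_rate(self):
        x = np.arange(100.0)
        assert np.array_equal(resample_to(x, 125.0), x)

    def test_tone_survives_with_correct_shape(self):
        fs_in = 500.0
        x = tone(5.0, fs_in, duration=20.0)
        y = resample_to(x, fs_in, 125.0)
        ref = tone(5.0, 125.0, duration=20.0)
        core = slice(50, -50)
        corr = np.corrcoef(y[core], ref[core])[0, 1]
        assert corr > 0.999

    def test_duration_preserved_within_one_sample(self):
        for fs_in, n in [(360.0, 6500), (257.0, 10001), (1000.0, 12345)]:
            y = resample_to(np.zeros(n), fs_in, 125.0)
            assert abs(len(y) / 125.0 - n / fs_in) <= 1.0 / 125.0

    def test_sub_40hz_amplitude_error_below_2pct(self):
        fs_in = 500.0
        x = tone(35.0, fs_in, duration=20.0)
        y = resample_to(x, fs_in, 125.0)
        core = slice(100, -100)
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.02)


class TestStandardizeDiagnosis:
    @pytest.mark.parametrize("code,expected", [
        ("atrial fibrillation", AFIB),
        ("AFIB", AFIB),
        ("Atrial Flutter", AFL),
        ("Sinus Tachycardia", OTHER),
        ("sinus bradycardia", OTHER),
        ("Sinus Arrhythmia", OTHER),
        ("Normal sinus rhythm", NSR),
    ])
    def test_known_codes(self, code, expected):
        assert standardize_diagnosis(code) == expected

    def test_unknown_and_empty_codes_warn_to_other(self, caplog):
        with caplog.at_level("WARNING"):
            assert standardize_diagnosis("") == OTHER
            assert standardize_diagnosis("ventricular bigeminy") == OTHER
        assert "unknown diagnosis" in caplog.text


class TestFullChain:
    def test_preprocess_record_resamples_and_keeps_rhythms(self):
        rng = np.random.default_rng(3)
        fs = 250.0
        sig = rng.normal(0, 0.2, size=(1, int(60 * fs)))
        from afdet.io import EpisodeLabel

        rec = EcgRecord("r", sig, fs,
                        rhythms=[EpisodeLabel(0, 30, NSR),
                                 EpisodeLabel(30, 60, AFIB)])
        out = preprocess_record(rec)
        assert out.fs == 125.0
        assert out.n_samples == int(60 * 125)
        assert [r.label for r in out.rhythms] == [NSR, AFIB]

    def test_exclusion_rule(self):
        rec = EcgRecord("r", np.zeros((1, 2000)), 250.0)  # 8 s -> 1000 samples
        with pytest.raises(RecordTooShortError):
            preprocess_record(rec)
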