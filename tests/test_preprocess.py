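"""Filter chain, bad-segment rejection, referencing, epoching."""

import numpy as np
import pytest

from neurocog.io import Recording, ValidationError
from neurocog.preprocess import (
    EpochSet,
    PreprocessConfig,
    average_reference,
    bandpass,
    epoch,
    notch,
    preprocess_chain,
    reject_bad_segments,
)
from oracles import reject_windows_oracle


def _rec(signal, fs=500.0):
    return Recording(
        subject_id="s", session=1, device="other",
        channel_labels=[f"ch{i}" for i in range(signal.shape[0])],
        fs=fs, signal=signal,
    )


def _tone(freq, fs, dur, amp=1.0):
    t = np.arange(int(fs * dur)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestFilters:
    def test_notch_attenuates_mains_by_20_db(self):
        fs = 500.0
        rec = _rec(_tone(50, fs, 10)[None], fs)
        out = notch(rec, 50.0, 35.0)
        mid = slice(1000, -1000)  # ignore edge transients
        rms_in = np.sqrt((rec.signal[0, mid] ** 2).mean())
        rms_out = np.sqrt((out.signal[0, mid] ** 2).mean())
        assert 20 * np.log10(rms_in / rms_out) >= 20.0

    def test_passband_gain_within_half_db(self):
        fs = 500.0
        rec = _rec(_tone(10, fs, 10)[None], fs)
        out = bandpass(rec, 0.5, 100.0)
        mid = slice(1000, -1000)
        gain = np.sqrt((out.signal[0, mid] ** 2).mean()
                       / (rec.signal[0, mid] ** 2).mean())
        assert abs(20 * np.log10(gain)) <= 0.5

    def test_empirical_transfer_function_matches_design(self):
        """White-noise FFT ratio vs the designed filter response."""
        from scipy import signal as sps

        fs = 500.0
        n = 32768          # long signal so filter transients stay negligible
        rng = np.random.default_rng(0)
        num = np.zeros(n // 2 + 1)
        den = np.zeros(n // 2 + 1)
        for _ in range(100):
            x = rng.standard_normal(n)
            y = bandpass(_rec(x[None], fs), 0.5, 100.0).signal[0]
            num += np.abs(np.fft.rfft(y)) ** 2
            den += np.abs(np.fft.rfft(x)) ** 2
        emp = np.sqrt(num / den)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        sos = sps.butter(4, [0.5, 100.0], btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
        design = np.abs(h) ** 2          # forward-backward: magnitude squared
        mid = (freqs > 4) & (freqs < 90)
        assert np.allclose(emp[mid], design[mid], atol=0.05)

    def test_zero_phase_keeps_pulse_peak_index(self):
        fs = 500.0
        n = 5000
        x = np.zeros(n)
        # band-limited pulse well inside the passband
        t = np.arange(n) / fs
        x = np.exp(-0.5 * ((t - 5.0) / 0.05) ** 2) * np.cos(2 * np.pi * 10 * (t - 5.0))
        out = bandpass(_rec(x[None], fs), 0.5, 100.0).signal[0]
        assert abs(int(np.argmax(np.abs(out))) - int(np.argmax(np.abs(x)))) <= 1

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValidationError):
            preprocess_chain(_rec(np.zeros((1, 1000)), fs=150.0))


class TestRejection:
    def test_clean_input_identity(self):
        rng = np.random.default_rng(1)
        rec = _rec(10 * rng.standard_normal((3, 5000)))
        out, mask = reject_bad_segments(rec, 100.0, 1.0)
        assert mask.all()
        assert np.array_equal(out.signal, rec.signal)

    def test_single_spike_window_removed(self):
        rng = np.random.default_rng(2)
        fs = 500.0
        rec_arr = 10 * rng.standard_normal((2, 5000))
        rec_arr[1, 1750] = 500.0       # inside window [1500, 2000) = [3 s..4 s)
        out, mask = reject_bad_segments(_rec(rec_arr, fs), 100.0, 1.0)
        w = int(fs)
        assert not mask[1500:2000].any()
        assert mask[:1500].all() and mask[2000:].all()
        assert out.n_samples == 5000 - w

    def test_retained_duration_matches_window_scan_oracle(self):
        rng = np.random.default_rng(3)
        fs = 250.0
        sig = 20 * rng.standard_normal((2, 11 * int(fs)))
        spikes = rng.choice(sig.shape[1], size=8, replace=False)
        sig[0, spikes] += 400.0
        w = int(fs)
        out, mask = reject_bad_segments(_rec(sig, fs), 100.0, 1.0)
        assert out.n_samples == reject_windows_oracle(sig, 100.0, w) * w
        assert int(mask.sum()) == out.n_samples

    def test_everything_rejected_raises(self):
        rec = _rec(np.full((1, 1000), 300.0))
        with pytest.raises(ValidationError, match="no clean data"):
            reject_bad_segments(rec, 100.0, 1.0)


class TestReference:
    def test_symmetric_pair_unchanged(self):
        rec = _rec(np.vstack([np.ones(100), -np.ones(100)]))
        out = average_reference(rec)
        assert np.allclose(out.signal, rec.signal)

    def test_identical_channels_zeroed(self):
        rec = _rec(np.tile(np.sin(np.arange(200) / 7), (4, 1)))
        assert np.allclose(average_reference(rec).signal, 0.0)

    def test_column_means_zero(self):
        rng = np.random.default_rng(4)
        out = average_reference(_rec(rng.standard_normal((7, 300))))
        assert np.abs(out.signal.mean(axis=0)).max() < 1e-9


class TestEpoching:
    def test_50_two_second_epochs_at_1000_hz(self):
        rng = np.random.default_rng(5)
        rec = _rec(rng.standard_normal((4, 150_000)), fs=1000.0)
        es = epoch(rec, 50, 2.0)
        assert es.epochs.shape == (50, 4, 2000)

    def test_identical_epochs_average_equals_any(self):
        base = np.random.default_rng(6).standard_normal((2, 200))
        rec = _rec(np.tile(base, (1, 5)), fs=100.0)
        es = epoch(rec, 5, 2.0, policy="average_waveform")
        assert np.allclose(es.mean_epoch(), base)

    def test_alternating_sign_epochs_cancel(self):
        base = np.random.default_rng(7).standard_normal((2, 200))
        sig = np.concatenate([base, -base, base, -base], axis=1)
        es = epoch(_rec(sig, fs=100.0), 4, 2.0, policy="average_waveform")
        assert np.abs(es.mean_epoch()).max() < 1e-12

    def test_insufficient_data_reports_duration(self):
        rec = _rec(np.zeros((1, 900)), fs=100.0)
        with pytest.raises(ValidationError, match="insufficient"):
            epoch(rec, 5, 2.0)


def test_chain_is_deterministic_and_ordered():
    rng = np.random.default_rng(8)
    sig = 15 * rng.standard_normal((4, 4000))
    sig[2, 1200] = 400.0
    rec = _rec(sig, fs=500.0)
    cfg = PreprocessConfig()
    a = preprocess_chain(rec, cfg)
    b = preprocess_chain(rec, cfg)
    assert np.array_equal(a.signal, b.signal)
    assert [s.split()[0] for s in a.log] == [
        "reject_bad_segments", "notch", "bandpass", "average"
    ]
    # final stage is the average reference: channel means are zero
    assert np.abs(a.signal.mean(axis=0)).max() < 1e-9
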