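import numpy as np
import pytest
from scipy import signal as sps

from qeeg import (
    BAND_BY_NAME,
    DEFAULT_BANDS,
    BandDefinition,
    band_psd,
    coherence,
    sliding_cross_spectrum,
)
from qeeg.errors import InsufficientDataError, UndefinedCoherenceError, ValidationError
from qeeg.montage import ChannelMontage
from qeeg.recording import Recording, reject_artifact_windows

from conftest import make_recording, white_recording

RATE = 128.0
ALPHA = BAND_BY_NAME["alpha"]


def two_channel_recording(x, y, rate=RATE):
    m = ChannelMontage(("FP1", "FP2"))
    return Recording("pair", np.vstack([x, y]), rate, montage=m)


class TestBands:
    def test_default_band_edges(self):
        edges = {b.name: (b.low, b.high) for b in DEFAULT_BANDS}
        assert edges == {
            "delta": (1, 4), "theta": (4, 8), "alpha": (8, 12),
            "beta": (12, 25), "high_beta": (25, 30), "gamma": (30, 40),
        }

    def test_bands_are_half_open_so_shared_edges_belong_to_one_band(self):
        freqs = np.arange(0.5, 40.5, 0.5)
        counts = sum(b.bin_mask(freqs).astype(int) for b in DEFAULT_BANDS)
        # every bin in [1, 40) covered exactly once; 0.5 and 40.0 by none
        assert counts[0] == 0 and counts[-1] == 0
        assert np.all(counts[1:-1] == 1)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 10, 8)


class TestSlidingCrossSpectrum:
    def test_window_count_and_bin_grid_for_60s_at_128hz(self):
        cs = sliding_cross_spectrum(white_recording(seed=0))
        assert cs.n_windows == (7680 - 256) // 64 + 1 == 117
        assert np.allclose(np.diff(cs.bin_freqs), 0.5)
        assert cs.bin_freqs[0] == 0.5 and cs.bin_freqs[-1] == 40.0
        assert len(cs.bin_freqs) == 80

    def test_zero_signal_gives_zero_sums(self):
        cs = sliding_cross_spectrum(make_recording(np.zeros((19, 7680))))
        assert cs.n_windows == 117
        assert np.all(cs.auto_power == 0)
        assert np.all(cs.cross_real == 0) and np.all(cs.cross_imag == 0)
        assert band_psd(cs, "O1", ALPHA) == 0.0

    def test_too_short_recording_raises(self):
        with pytest.raises(InsufficientDataError):
            sliding_cross_spectrum(make_recording(np.zeros((19, 128))))

    def test_windows_restart_at_accepted_spans(self):
        rec = white_recording(seed=8, scale=10.0, duration_s=70.0)
        rec.data[0, 256 * 10 : 256 * 11] = 500.0
        clean, _ = reject_artifact_windows(rec)
        cs = sliding_cross_spectrum(clean)
        # spans of 10 and 24 epochs: per-span window counts, not pooled
        n1 = (2560 - 256) // 64 + 1
        n2 = (70 * 128 - 2816 - 256) // 64 + 1
        assert cs.n_windows == n1 + n2

    def test_cauchy_schwarz_bound_on_cross_sums(self):
        cs = sliding_cross_spectrum(white_recording(seed=9))
        iu, ju = np.triu_indices(19, k=1)
        lhs = cs.cross_real[iu, ju] ** 2 + cs.cross_imag[iu, ju] ** 2
        rhs = cs.auto_power[iu] * cs.auto_power[ju]
        assert np.all(lhs <= rhs * (1 + 1e-9))


class TestBandPower:
    def test_sinusoid_power_is_amplitude_squared_over_two(self):
        t = np.arange(300 * RATE) / RATE
        tone = 2.0 * np.sin(2 * np.pi * 10 * t)
        cs = sliding_cross_spectrum(make_recording(np.tile(tone, (19, 1))))
        alpha = band_psd(cs, "O1", ALPHA)
        assert alpha == pytest.approx(2.0**2 / 2, rel=0.05)
        for b in DEFAULT_BANDS:
            if b.name != "alpha":
                assert band_psd(cs, "O1", b) < 0.01 * alpha

    def test_white_noise_band_sum_matches_filtered_variance_oracle(self):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((19, int(300 * RATE)))
        cs = sliding_cross_spectrum(make_recording(data))
        total = sum(band_psd(cs, "Cz", b) for b in DEFAULT_BANDS)
        # oracle: variance of an ideal [1, 40) Hz band-pass copy
        spec = np.fft.rfft(data[9])
        freqs = np.fft.rfftfreq(data.shape[1], 1 / RATE)
        keep = (freqs >= 1.0) & (freqs < 40.0)
        oracle = np.fft.irfft(np.where(keep, spec, 0), data.shape[1]).var()
        assert total == pytest.approx(oracle, rel=0.05)
        assert total == pytest.approx((40 - 1) / 64, rel=0.05)

    def test_power_scales_quadratically_with_amplitude(self):
        rec = white_recording(seed=13, duration_s=60)
        cs1 = sliding_cross_spectrum(rec)
        cs2 = sliding_cross_spectrum(make_recording(2.0 * rec.data))
        for b in DEFAULT_BANDS:
            p1 = band_psd(cs1, "F3", b)
            p2 = band_psd(cs2, "F3", b)
            assert p2 == pytest.approx(4.0 * p1, rel=1e-6)

    def test_band_outside_grid_rejected(self):
        cs = sliding_cross_spectrum(white_recording(seed=0))
        with pytest.raises(ValidationError):
            band_psd(cs, "O1", BandDefinition("hf", 40, 60))

    def test_psd_agrees_with_welch_oracle(self):
        """Independent route: scipy's Welch estimator with matched windowing."""
        rec = white_recording(seed=14)
        cs = sliding_cross_spectrum(rec)
        f, pxx = sps.welch(
            rec.data[0], fs=RATE, window="hann", nperseg=256, noverlap=192,
            detrend=False, scaling="density",
        )
        for b in DEFAULT_BANDS:
            mask = (f >= b.low) & (f < b.high)
            assert band_psd(cs, "FP1", b) == pytest.approx(pxx[mask].sum() * 0.5, rel=1e-8)


class TestCoherence:
    def test_duplicated_signal_has_unit_coherence(self):
        x = np.random.default_rng(1).standard_normal(7680)
        cs = sliding_cross_spectrum(two_channel_recording(x, x.copy()))
        for b in DEFAULT_BANDS:
            assert coherence(cs, ("FP1", "FP2"), b) == pytest.approx(1.0, abs=1e-12)

    def test_single_window_coherence_is_identically_one(self):
        # algebraic identity (au+bv)^2 + (av-bu)^2 = (a^2+b^2)(u^2+v^2)
        rng = np.random.default_rng(2)
        rec = two_channel_recording(rng.standard_normal(256), rng.standard_normal(256))
        cs = sliding_cross_spectrum(rec)
        assert cs.n_windows == 1
        for b in DEFAULT_BANDS:
            assert coherence(cs, ("FP1", "FP2"), b) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_gain_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 7680))
        cs = sliding_cross_spectrum(two_channel_recording(x, y))
        cs_scaled = sliding_cross_spectrum(two_channel_recording(5.0 * x, y))
        for b in DEFAULT_BANDS:
            c = coherence(cs, ("FP1", "FP2"), b)
            assert c == coherence(cs, ("FP2", "FP1"), b)
            assert coherence(cs_scaled, ("FP1", "FP2"), b) == pytest.approx(c, rel=1e-9)

    def test_self_pair_rejected(self):
        cs = sliding_cross_spectrum(white_recording(seed=0))
        with pytest.raises(ValidationError):
            coherence(cs, ("O1", "O1"), ALPHA)

    def test_zero_power_band_is_undefined_not_zero(self):
        t = np.arange(7680) / RATE
        tone = np.sin(2 * np.pi * 10 * t)
        cs = sliding_cross_spectrum(two_channel_recording(tone, np.zeros_like(tone)))
        with pytest.raises(UndefinedCoherenceError):
            coherence(cs, ("FP1", "FP2"), BAND_BY_NAME["gamma"])

    def test_shared_component_monotonically_increases_coherence(self):
        rng = np.random.default_rng(4)
        x, y, s_raw = rng.standard_normal((3, 7680))
        sos = sps.butter(4, [8, 12], btype="bandpass", fs=RATE, output="sos")
        shared = sps.sosfiltfilt(sos, s_raw)
        vals = []
        for w in (0.0, 1.0, 2.0):
            cs = sliding_cross_spectrum(
                two_channel_recording(x + w * shared, y + w * shared)
            )
            vals.append(coherence(cs, ("FP1", "FP2"), ALPHA))
        assert vals[0] < vals[1] < vals[2]

    def test_independent_channels_agree_with_welch_coherence_oracle(self):
        """Per-bin agreement with scipy's magnitude-squared coherence."""
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 7680))
        cs = sliding_cross_spectrum(two_channel_recording(x, y))
        f, cxy = sps.coherence(
            x, y, fs=RATE, window="hann", nperseg=256, noverlap=192, detrend=False
        )
        for b in DEFAULT_BANDS:
            mask = (f >= b.low) & (f < b.high)
            assert coherence(cs, ("FP1", "FP2"), b) == pytest.approx(
                cxy[mask].mean(), rel=1e-8
            )

    def test_finite_window_bias_matches_monte_carlo_oracle(self):
        """Independent white-noise channels keep a small positive bias ~1/N_eff;
        the implementation's mean over replicates must match a brute-force
        oracle computed directly from the definition."""
        n_rep = 60
        ours, oracle = [], []
        w = sps.get_window("hann", 256, fftbins=True)
        for k in range(n_rep):
            rng = np.random.default_rng(1000 + k)
            x, y = rng.standard_normal((2, 7680))
            cs = sliding_cross_spectrum(two_channel_recording(x, y))
            ours.append(coherence(cs, ("FP1", "FP2"), ALPHA))
            # brute force from the definition: tapered DFT coefficients per window
            starts = np.arange(0, 7680 - 256 + 1, 64)
            Fx = np.array([np.fft.rfft(w * x[s : s + 256]) for s in starts])
            Fy = np.array([np.fft.rfft(w * y[s : s + 256]) for s in starts])
            freqs = np.fft.rfftfreq(256, 1 / RATE)
            bins = np.flatnonzero((freqs >= 8) & (freqs < 12))
            num = np.abs((Fx[:, bins] * np.conj(Fy[:, bins])).sum(0)) ** 2
            den = (np.abs(Fx[:, bins]) ** 2).sum(0) * (np.abs(Fy[:, bins]) ** 2).sum(0)
            oracle.append(float(np.mean(num / den)))
        np.testing.assert_allclose(ours, oracle, rtol=1e-10)
        se = np.std(ours, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(ours) - np.mean(oracle)) < 3 * se
        assert 0 < np.mean(ours) < 0.2  # small positive finite-N bias


class TestAggregationAndExport:
    def test_pooled_aggregate_stays_in_unit_interval_and_differs(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 7680))
        s = sps.sosfiltfilt(
            sps.butter(4, [8, 12], btype="bandpass", fs=RATE, output="sos"),
            rng.standard_normal(7680),
        )
        cs = sliding_cross_spectrum(two_channel_recording(x + s, y + s))
        mean_c = coherence(cs, ("FP1", "FP2"), ALPHA, aggregate="mean")
        pooled_c = coherence(cs, ("FP1", "FP2"), ALPHA, aggregate="pooled")
        assert 0 <= pooled_c <= 1
        assert mean_c != pooled_c  # different estimators, same ballpark
        assert abs(mean_c - pooled_c) < 0.3

    def test_cross_spectrum_long_table_export(self):
        m = ChannelMontage(("FP1", "FP2"))
        rng = np.random.default_rng(7)
        cs = sliding_cross_spectrum(Recording("s9", rng.standard_normal((2, 512)), RATE, m))
        table = cs.to_table("s9")
        assert set(table.columns) == {"subject", "element", "bin_hz", "statistic", "value"}
        assert set(table["statistic"]) == {"auto_power", "cross_real", "cross_imag"}
        # 2 channels x 80 bins auto + 1 pair x 80 bins x 2 statistics
        assert len(table) == 2 * 80 + 80 * 2
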