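"""Band power, differential entropy and asymmetry features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emokan.bands import (
    ALPHA,
    BETA,
    CHANNELS,
    DEFAULT_BANDS,
    GAMMA,
    THETA,
    Band,
    EEGWindow,
    asi,
    band_de,
    bandpass_filter,
    de_from_variance,
    evi,
    extract_features,
    feature_names,
    welch_band_power,
)
from emokan.errors import BandRangeError, DegenerateSignalError

from conftest import make_window


def dft_band_variance(x: np.ndarray, fs: float, band: Band) -> float:
    """Oracle: variance of the band content via direct DFT masking."""
    spectrum = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    spectrum[(freqs < band.f_low) | (freqs > band.f_high)] = 0.0
    return float(np.var(np.fft.irfft(spectrum, n=len(x))))


class TestBandpassFilter:
    def test_zero_signal_stays_zero(self):
        win = make_window({})
        out = bandpass_filter(win, ALPHA)
        assert np.allclose(out.samples, 0.0)

    def test_in_band_sine_passes(self, sine_window):
        win = sine_window(10.0)
        out = bandpass_filter(win, ALPHA)
        expected = dft_band_variance(win.samples[:, 0], 128.0, ALPHA)
        got = float(np.var(out.samples[:, 0]))
        assert got == pytest.approx(expected, rel=0.05)
        assert got == pytest.approx(float(np.var(win.samples[:, 0])), rel=0.05)

    def test_out_of_band_sine_rejected(self, sine_window):
        win = sine_window(10.0)
        out = bandpass_filter(win, GAMMA)
        assert float(np.var(out.samples[:, 0])) < 0.01 * float(np.var(win.samples[:, 0]))

    def test_band_above_nyquist_rejected(self, sine_window):
        win = sine_window(10.0, fs=64.0)
        with pytest.raises(BandRangeError):
            bandpass_filter(win, GAMMA)  # 45 Hz edge > 32 Hz Nyquist

    def test_invalid_band_edges_rejected(self):
        with pytest.raises(BandRangeError):
            Band("bad", 10.0, 5.0)


class TestWelchBandPower:
    def test_zero_signal_has_zero_power(self):
        win = make_window({})
        for band in DEFAULT_BANDS:
            assert welch_band_power(win, "FP1", band) == 0.0

    def test_unit_sine_power_is_half(self, sine_window):
        # A^2/2 = 0.5 for a unit sine; Welch leakage bounds the tolerance
        win = sine_window(10.0)
        assert welch_band_power(win, "FP1", ALPHA) == pytest.approx(0.5, rel=0.15)

    def test_unknown_channel_is_lookup_error(self, sine_window):
        with pytest.raises(KeyError):
            welch_band_power(sine_window(10.0), "CZ", ALPHA)

    def test_white_noise_band_share(self):
        # sum of powers over 4-45 Hz ~ (45-4)/(fs/2) * sigma^2 for white noise
        fs, total = 128.0, 0.0
        n_draws = 100
        rng = np.random.default_rng(99)
        for _ in range(n_draws):
            win = EEGWindow(rng.standard_normal((128, 4)), fs)
            total += sum(welch_band_power(win, "FP1", b) for b in DEFAULT_BANDS)
        assert total / n_draws == pytest.approx((45 - 4) / (fs / 2), rel=0.10)

    def test_parseval_partition(self):
        # a partition of (0, fs/2] recovers the window variance on white noise
        fs = 128.0
        partition = [Band("p1", 1e-6, 16.0), Band("p2", 16.0, 32.0),
                     Band("p3", 32.0, 48.0), Band("p4", 48.0, 64.0 + 1e-6)]
        rng = np.random.default_rng(5)
        ratio = 0.0
        for _ in range(100):
            win = EEGWindow(rng.standard_normal((128, 4)), fs)
            power = sum(welch_band_power(win, "FP1", b) for b in partition)
            ratio += power / float(np.var(win.samples[:, 0]))
        assert ratio / 100 == pytest.approx(1.0, rel=0.10)


class TestDifferentialEntropy:
    def test_closed_form_values(self):
        assert de_from_variance(1.0) == pytest.approx(0.5 * math.log(2 * math.pi * math.e), abs=1e-9)
        assert de_from_variance(1.0 / (2 * math.pi * math.e)) == pytest.approx(0.0, abs=1e-9)

    def test_quadrupling_variance_adds_ln2(self):
        v = 0.37
        assert de_from_variance(4 * v) - de_from_variance(v) == pytest.approx(math.log(2), abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_variance_rejected(self, bad):
        with pytest.raises(DegenerateSignalError):
            de_from_variance(bad)

    def test_band_de_amplitude_scaling(self, noise_window):
        win = noise_window(seed=7)
        doubled = EEGWindow(2.0 * win.samples, win.fs)
        for band in DEFAULT_BANDS:
            delta = band_de(doubled, "AF3", band) - band_de(win, "AF3", band)
            assert delta == pytest.approx(math.log(2), abs=1e-9)

    def test_band_de_matches_two_step_oracle(self, noise_window):
        win = noise_window(seed=11)
        for band in (THETA, BETA):
            filtered = bandpass_filter(win, band)
            expected = 0.5 * math.log(2 * math.pi * math.e * np.var(filtered.channel("FP2")))
            assert band_de(win, "FP2", band) == pytest.approx(expected, abs=1e-12)

    def test_zero_signal_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            band_de(make_window({}), "FP1", ALPHA)

    def test_monotone_in_amplitude(self, noise_window):
        win = noise_window(seed=3)
        values = [band_de(EEGWindow(s * win.samples, win.fs), "FP1", ALPHA)
                  for s in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(values) > 0)


class TestAsymmetryIndices:
    def test_evi_examples(self):
        assert evi(3.0, 3.0) == 0.0
        assert evi(math.e * 2.0, 2.0) == pytest.approx(1.0, abs=1e-12)

    def test_asi_examples(self):
        assert asi(2.0, 2.0) == 0.0
        assert asi(3.0, 1.0) == pytest.approx(0.5)
        assert asi(2.0, 0.0) == 1.0

    @given(a=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_and_bounds(self, a, b):
        assert evi(a, b) == pytest.approx(-evi(b, a), rel=1e-12, abs=1e-12)
        assert asi(a, b) == -asi(b, a)
        assert -1.0 <= asi(a, b) <= 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateSignalError):
            evi(0.0, 1.0)
        with pytest.raises(DegenerateSignalError):
            asi(0.0, 0.0)
        with pytest.raises(DegenerateSignalError):
            asi(-1.0, 2.0)


class TestExtractFeatures:
    def test_48_finite_values(self, noise_window):
        fw = extract_features(noise_window(seed=21))
        assert fw.values.shape == (48,)
        assert np.all(np.isfinite(fw.values))
        assert len(feature_names()) == 48

    def test_identical_channels_zero_spatial(self, rng):
        x = rng.standard_normal(128)
        win = EEGWindow(np.column_stack([x] * 4), 128.0)
        fw = extract_features(win)
        assert np.allclose(fw.spatial, 0.0, atol=1e-12)

    def test_lateralized_alpha_hits_asi_half(self):
        # alpha power on FP1 three times FP2 -> ASI(alpha, FP1-FP2) ~ 0.5,
        # and exactly asi() of the measured Welch powers
        t = np.arange(128) / 128.0
        alpha_wave = np.sin(2 * np.pi * 10.0 * t)
        win = EEGWindow(np.column_stack([
            np.sqrt(3.0) * alpha_wave, alpha_wave, alpha_wave, alpha_wave]), 128.0)
        fw = extract_features(win)
        i = feature_names().index("asi_alpha_FP1-FP2")
        p1 = welch_band_power(win, "FP1", ALPHA)
        p2 = welch_band_power(win, "FP2", ALPHA)
        assert fw.values[i] == pytest.approx(asi(p1, p2), abs=1e-12)
        assert fw.values[i] == pytest.approx(0.5, abs=0.05)

    def test_channel_relabeling_equivariance(self, rng):
        samples = rng.standard_normal((128, 4))
        win = EEGWindow(samples, 128.0)
        perm = [2, 0, 3, 1]
        win_p = EEGWindow(samples[:, perm], 128.0,
                          tuple(np.array(win.channel_names)[perm]))
        assert np.allclose(extract_features(win).values,
                           extract_features(win_p).values, atol=1e-12)
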