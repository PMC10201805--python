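import numpy as np
import pytest

import seizeeg as sz
from seizeeg.segments import EEGSegment
from seizeeg.wavelets import band_edges, truncate_hz

FS = 173.61


def _tone(hz, fs=FS, n=4096, amp=1.0):
    t = np.arange(n) / fs
    return EEGSegment(amp * np.sin(2 * np.pi * hz * t), fs=fs)


class TestBandpass:
    def test_zero_in_zero_out(self):
        seg = EEGSegment(np.zeros(512), fs=FS)
        out = sz.bandpass(seg, 0.5, 40.0)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_midband_tone_preserved(self):
        seg = _tone(10.0)
        with pytest.warns(UserWarning, match="Nyquist"):
            out = sz.bandpass(seg, 0.01, 86.8)
        rms_in = np.sqrt(np.mean(seg.samples**2))
        rms_out = np.sqrt(np.mean(out.samples**2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_slow_drift_attenuated(self):
        t = np.arange(4096) / FS
        drift = EEGSegment(np.sin(2 * np.pi * 0.001 * t), fs=FS)
        with pytest.warns(UserWarning, match="Nyquist"):
            out = sz.bandpass(drift, 0.01, 86.8)
        assert np.sqrt(np.mean(out.samples**2)) < 0.2 * np.sqrt(np.mean(drift.samples**2))

    def test_invalid_band_rejected(self):
        seg = _tone(10.0, n=512)
        with pytest.raises(ValueError):
            sz.bandpass(seg, 40.0, 10.0)


class TestDenoise:
    def test_noise_reduced(self):
        rng = np.random.default_rng(0)
        t = np.arange(2048) / FS
        clean = np.sin(2 * np.pi * 5.0 * t)
        # SNR 5 dB: noise power = signal power / 10^0.5
        noise_sd = np.sqrt(np.mean(clean**2) / 10**0.5)
        noisy = clean + noise_sd * rng.standard_normal(clean.size)
        den = sz.wavelet_denoise(EEGSegment(noisy, fs=FS)).samples
        rmse_den = np.sqrt(np.mean((den - clean) ** 2))
        rmse_noisy = np.sqrt(np.mean((noisy - clean) ** 2))
        assert rmse_den < rmse_noisy

    def test_clean_input_nearly_unchanged(self):
        seg = _tone(5.0, n=2048)
        den = sz.wavelet_denoise(seg).samples
        rms = np.sqrt(np.mean(seg.samples**2))
        assert np.sqrt(np.mean((den - seg.samples) ** 2)) < 0.05 * rms

    def test_zero_in_zero_out(self):
        seg = EEGSegment(np.zeros(256), fs=FS)
        np.testing.assert_allclose(sz.wavelet_denoise(seg).samples, 0.0, atol=1e-12)


class TestDecompose:
    @pytest.mark.parametrize("seed", range(5))
    def test_perfect_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        seg = EEGSegment(rng.standard_normal(1024), fs=FS)
        sb = sz.dwt_decompose(seg, representation="reconstructed")
        total = sum(sb[name] for name in sb.subbands)
        np.testing.assert_allclose(total, seg.samples, rtol=0, atol=1e-8 * np.abs(seg.samples).max())

    @pytest.mark.parametrize("seed", range(5))
    def test_energy_conservation(self, seed):
        rng = np.random.default_rng(100 + seed)
        seg = EEGSegment(rng.standard_normal(2048), fs=FS)
        sb = sz.dwt_decompose(seg, representation="coefficients")
        coef_energy = sum(float(np.sum(c**2)) for c in sb.subbands.values())
        sig_energy = float(np.sum(seg.samples**2))
        assert abs(coef_energy - sig_energy) / sig_energy < 1e-6

    def test_constant_input(self):
        seg = EEGSegment(np.full(512, 3.7), fs=FS)
        sb = sz.dwt_decompose(seg, representation="coefficients")
        for name in ("D1", "D2", "D3", "D4"):
            assert np.abs(sb[name]).max() < 1e-10
        # A4 carries the signal mean (scaled by the analysis gain)
        assert np.abs(sb["A4"]).max() > 1.0

    def test_3hz_energy_in_a4(self):
        sb = sz.dwt_decompose(_tone(3.0), representation="reconstructed")
        energies = {n: float(np.sum(v**2)) for n, v in sb.subbands.items()}
        assert energies["A4"] / sum(energies.values()) >= 0.80

    @pytest.mark.parametrize(
        "hz,band", [(60.0, "D1"), (30.0, "D2"), (15.0, "D3"), (8.0, "D4"), (2.0, "A4")]
    )
    def test_frequency_selectivity(self, hz, band):
        """A tone inside band B lands the plurality of its energy in B."""
        sb = sz.dwt_decompose(_tone(hz), representation="reconstructed")
        energies = {n: float(np.sum(v**2)) for n, v in sb.subbands.items()}
        assert max(energies, key=energies.get) == band

    def test_too_short_rejected(self):
        seg = EEGSegment(np.arange(8.0), fs=FS)
        with pytest.raises(ValueError, match="short"):
            sz.dwt_decompose(seg)

    def test_five_names(self):
        sb = sz.dwt_decompose(_tone(10.0, n=512))
        assert set(sb.subbands) == {"D1", "D2", "D3", "D4", "A4"}
        assert sb.representation == "reconstructed"


class TestBandEdges:
    def test_bonn_rate_truncated_values(self):
        edges = band_edges(173.61, 4)
        assert truncate_hz(edges["A4"][1]) == 5.4
        assert truncate_hz(edges["D4"][1]) == 10.8
        assert truncate_hz(edges["D3"][1]) == 21.7
        assert truncate_hz(edges["D2"][1]) == 43.4
        assert truncate_hz(edges["D1"][1]) == 86.8
        assert edges["A4"][0] == 0.0

    def test_powers_of_two(self):
        edges = band_edges(64.0, 2)
        assert edges == {"D1": (16.0, 32.0), "D2": (8.0, 16.0), "A2": (0.0, 8.0)}

    def test_successive_halving(self):
        edges = band_edges(200.0, 4)
        for k in range(1, 4):
            lo, hi = edges[f"D{k}"]
            lo2, hi2 = edges[f"D{k+1}"]
            assert hi2 == pytest.approx(lo)
            assert lo2 == pytest.approx(lo / 2)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            band_edges(-1.0, 4)
        with pytest.raises(ValueError):
            band_edges(100.0, 0)
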