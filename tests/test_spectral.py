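"""Filtering, envelope, band power, and spectrum-comparison behavior."""

import numpy as np
import pytest
from scipy import stats
from scipy.signal import periodogram

from tcd.spectral import (
    PowerSpectrum,
    band_log_power,
    bandpass_filter,
    group_spectrum_comparison,
    hilbert_envelope,
    whole_spectrum,
)

FS = 128.0
T = np.arange(int(60 * FS)) / FS


def test_inband_sinusoid_passes_unchanged():
    x = np.sin(2 * np.pi * 10 * T)
    y = bandpass_filter(x, 8, 12, FS)
    c = slice(int(0.05 * x.size), int(0.95 * x.size))
    assert np.corrcoef(x[c], y[c])[0, 1] > 0.99


def test_stopband_sinusoid_suppressed():
    x = np.sin(2 * np.pi * 20 * T)
    y = bandpass_filter(x, 4, 7.5, FS)
    assert y.var() < 0.01 * x.var()


def test_white_noise_band_mass_confined():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(T.size)
    y = bandpass_filter(x, 30.5, 44, FS)
    f, p = periodogram(y, fs=FS)
    inside = (f >= 30.0) & (f <= 44.5)
    assert p[inside].sum() >= 0.99 * p.sum()


def test_filter_idempotent_on_band_limited_signal():
    # signal strictly inside the flat pass band (its transition skirts end at
    # 8 and 12 Hz, where the outer filter's gain is still 1)
    rng = np.random.default_rng(4)
    x = bandpass_filter(rng.standard_normal(T.size), 8.5, 11.5, FS)
    y = bandpass_filter(x, 8, 12, FS)
    assert np.sqrt(np.mean((x - y) ** 2)) < 0.01 * np.sqrt(np.mean(x**2))


def test_filter_rejects_bad_band_and_nonfinite():
    with pytest.raises(ValueError):
        bandpass_filter(np.zeros(int(10 * FS)), 30, 70, FS)
    bad = np.zeros(int(10 * FS))
    bad[5] = np.nan
    with pytest.raises(ValueError):
        bandpass_filter(bad, 8, 12, FS)


def test_envelope_constant_tone():
    env = hilbert_envelope(2 * np.sin(2 * np.pi * 40 * T))
    c = slice(int(0.05 * T.size), int(0.95 * T.size))
    assert np.all(np.abs(env[c] - 2) < 0.05)


def test_envelope_recovers_am_modulator():
    mod = 1 + 0.5 * np.sin(2 * np.pi * 6 * T)
    env = hilbert_envelope(mod * np.sin(2 * np.pi * 40 * T))
    c = slice(int(0.05 * T.size), int(0.95 * T.size))
    assert np.corrcoef(env[c], mod[c])[0, 1] > 0.95


def test_envelope_zero_and_sign_invariance():
    assert np.allclose(hilbert_envelope(np.zeros(100)), 0)
    x = np.sin(2 * np.pi * 9 * T) + 0.3 * np.sin(2 * np.pi * 17 * T)
    np.testing.assert_allclose(hilbert_envelope(x), hilbert_envelope(-x), atol=1e-12)


class _FakeRoi:
    def __init__(self, comps, fs=FS):
        self.components = np.asarray(comps)
        self.fs = fs


def test_band_power_tone_dominates_own_band():
    roi = _FakeRoi(np.vstack([np.sin(2 * np.pi * 10 * T)] * 3))
    alpha = band_log_power(roi, "alpha")
    for other in ("delta", "theta", "beta", "gamma"):
        assert alpha > band_log_power(roi, other)


def test_band_power_amplitude_scaling():
    rng = np.random.default_rng(7)
    comps = rng.standard_normal((3, T.size))
    roi1, roi2 = _FakeRoi(comps), _FakeRoi(2 * comps)
    assert band_log_power(roi2, "alpha") - band_log_power(roi1, "alpha") == pytest.approx(
        np.log10(4), abs=1e-9
    )


def test_band_power_component_permutation_and_shift_invariance():
    rng = np.random.default_rng(8)
    comps = rng.standard_normal((3, T.size))
    v1 = band_log_power(_FakeRoi(comps), "beta")
    assert band_log_power(_FakeRoi(comps[[2, 0, 1]]), "beta") == v1
    shifted = np.roll(comps, T.size // 3, axis=1)
    assert abs(band_log_power(_FakeRoi(shifted), "beta") - v1) < 0.01 * abs(v1)


def test_whole_spectrum_length_and_parseval():
    rng = np.random.default_rng(9)
    comps = rng.standard_normal((3, T.size))
    sp = whole_spectrum(_FakeRoi(comps), log_scale=False)
    assert sp.freqs.size == 43
    band_limited = np.vstack([bandpass_filter(c, 2, 44, FS, transition=0.0) for c in comps])
    var = band_limited.var(axis=1).mean()
    assert sp.power.sum() == pytest.approx(var, rel=0.05)


def test_group_comparison_identical_groups_give_zero_F():
    rng = np.random.default_rng(10)
    spectra = [PowerSpectrum(np.arange(2, 45.0), rng.standard_normal(43)) for _ in range(4)]
    spectra = spectra + spectra  # second group copies the first
    comp = group_spectrum_comparison(spectra, ["a"] * 4 + ["b"] * 4, omnibus=False)
    np.testing.assert_allclose(comp.F, 0.0, atol=1e-20)


def test_group_comparison_F_equals_t_squared():
    rng = np.random.default_rng(11)
    spectra = [PowerSpectrum(np.arange(2, 45.0), rng.standard_normal(43)) for _ in range(12)]
    labels = ["a"] * 5 + ["b"] * 7
    comp = group_spectrum_comparison(spectra, labels, omnibus=False)
    mat = np.vstack([s.power for s in spectra])
    for j in [0, 21, 42]:
        t = stats.ttest_ind(mat[:5, j], mat[5:, j]).statistic
        assert comp.F[j] == pytest.approx(t**2, abs=1e-8)


def test_group_comparison_rejects_singleton_group():
    spectra = [PowerSpectrum(np.arange(2, 45.0), np.ones(43))] * 3
    with pytest.raises(ValueError):
        group_spectrum_comparison(spectra, ["a", "a", "b"])
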