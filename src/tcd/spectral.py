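"""Filtering, envelopes, band power, and per-frequency group comparison.

All spectral analysis operates on source-space ROI current time series in
the 2–44 Hz range at 128 Hz sampling. The canonical frequency bands are

    delta 2–3.5, theta 4–7.5, alpha 8–12, beta 13–30, gamma 30.5–44 Hz

(with beta1 12.5–30 Hz used by the cross-frequency-coupling analysis).
Band-pass filtering is done in the frequency domain — zero-phase FFT
multiplication with raised-cosine (Hann-shaped) transition edges — which is
the natural choice for offline resting-state analysis and is exactly
invertible in the pass band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

__all__ = [
    "BandDefinition",
    "BANDS",
    "CFC_BANDS",
    "PowerSpectrum",
    "SpectrumComparison",
    "bandpass_filter",
    "hilbert_envelope",
    "band_log_power",
    "band_log_powers",
    "whole_spectrum",
    "group_spectrum_comparison",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"invalid band {self.name}: [{self.f_low}, {self.f_high}]")


BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 2.0, 3.5),
    "theta": BandDefinition("theta", 4.0, 7.5),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.5, 44.0),
}

#: Bands used by the phase–amplitude nesting statistic.
CFC_BANDS: dict[str, BandDefinition] = {
    "theta": BANDS["theta"],
    "beta1": BandDefinition("beta1", 12.5, 30.0),
    "gamma": BANDS["gamma"],
}

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: 1-Hz analysis grid for whole-record spectra (43 bins, 2..44 Hz inclusive).
SPECTRUM_FREQS: np.ndarray = np.arange(2, 45, dtype=float)


@dataclass
class PowerSpectrum:
    """Power on the 1-Hz 2–44 Hz grid; log10 scale when ``log_scale``."""

    freqs: np.ndarray
    power: np.ndarray
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if not self.log_scale and np.any(self.power < 0):
            raise ValueError("linear-scale power must be non-negative")


@dataclass
class SpectrumComparison:
    """Per-frequency ANOVA across groups, with an optional MANOVA omnibus."""

    freqs: np.ndarray
    F: np.ndarray
    p: np.ndarray
    alpha: float
    significant: np.ndarray = field(init=False)
    omnibus_stat: float | None = None  # Pillai's trace
    omnibus_p: float | None = None

    def __post_init__(self) -> None:
        self.significant = np.asarray(self.p) < self.alpha


def _check_signal(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return x


def bandpass_filter(
    x: np.ndarray,
    f_low: float,
    f_high: float,
    fs: float,
    transition: float = 0.5,
) -> np.ndarray:
    """Zero-phase FFT band-pass with Hann-shaped transition edges.

    The gain is 1 on [f_low, f_high], falls as a raised cosine over
    ``transition`` Hz on either side, and is 0 elsewhere. Output length
    equals input length.
    """
    x = _check_signal(x)
    if not 0 < f_low < f_high < fs / 2:
        raise ValueError(f"band [{f_low}, {f_high}] outside (0, Nyquist={fs / 2})")
    if x.size < 8 * fs:
        raise ValueError(f"signal too short: need >= {int(8 * fs)} samples, got {x.size}")
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[(freqs >= f_low) & (freqs <= f_high)] = 1.0
    if transition > 0:
        lo = (freqs >= f_low - transition) & (freqs < f_low)
        gain[lo] = 0.5 * (1 - np.cos(np.pi * (freqs[lo] - (f_low - transition)) / transition))
        hi = (freqs > f_high) & (freqs <= f_high + transition)
        gain[hi] = 0.5 * (1 + np.cos(np.pi * (freqs[hi] - f_high) / transition))
    return np.fft.irfft(np.fft.rfft(x) * gain, n=x.size)


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (instantaneous amplitude)."""
    x = _check_signal(x)
    return np.abs(sps.hilbert(x))


def _welch_psd(x: np.ndarray, fs: float, window_s: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(int(window_s * fs), x.size)
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def band_log_powers(
    components: np.ndarray, fs: float, window_s: float = 4.0
) -> dict[str, float]:
    """log10 band power for every canonical band from one Welch pass.

    Welch PSD (default 4 s Hann windows, 50% overlap) per component, mean
    PSD over the band's frequencies, averaged across the 3 components, then
    log10 — mirroring the log-transformed current density averaged over an
    ROI's voxels.
    """
    comps = np.atleast_2d(np.asarray(components, dtype=float))
    psds = []
    for c in comps:
        f, p = _welch_psd(_check_signal(c), fs, window_s)
        psds.append(p)
    psd = np.mean(psds, axis=0)
    out: dict[str, float] = {}
    for name, band in BANDS.items():
        sel = (f >= band.f_low) & (f <= band.f_high)
        if not np.any(sel):
            raise ValueError(f"band {name} is empty at the available frequency resolution")
        out[name] = float(np.log10(np.mean(psd[sel])))
    return out


def band_log_power(roi_ts, band: str | BandDefinition, window_s: float = 4.0) -> float:
    """log10 mean Welch PSD of one canonical band, averaged over components."""
    name = band if isinstance(band, str) else band.name
    if name not in BANDS:
        raise ValueError(f"unknown band {name!r}; canonical bands: {list(BANDS)}")
    return band_log_powers(roi_ts.components, roi_ts.fs, window_s)[name]


def whole_spectrum(obj, log_scale: bool = True) -> PowerSpectrum:
    """1-Hz-binned 2–44 Hz power spectrum of an ROI series or a subject.

    Welch PSD with 1 s windows (1 Hz resolution) averaged across the 3
    current components, and across all ROIs for a subject-level spectrum.
    Power is averaged on the linear scale, then log10-transformed.
    """
    series = list(obj.roi_series.values()) if hasattr(obj, "roi_series") else [obj]
    acc = np.zeros_like(SPECTRUM_FREQS)
    n = 0
    for ts in series:
        if ts.fs < 128:
            raise ValueError(f"sampling rate {ts.fs} Hz too low; need >= 128")
        for c in ts.components:
            f, p = _welch_psd(_check_signal(c), ts.fs, window_s=1.0)
            idx = np.searchsorted(f, SPECTRUM_FREQS)
            if not np.allclose(f[idx], SPECTRUM_FREQS):
                raise ValueError("1-Hz grid not representable at this fs/window")
            acc += p[idx]
            n += 1
    power = acc / n
    return PowerSpectrum(SPECTRUM_FREQS.copy(), np.log10(power) if log_scale else power,
                         log_scale=log_scale)


def group_spectrum_comparison(
    spectra: list[PowerSpectrum],
    labels: list[str],
    alpha: float = 0.05,
    omnibus: bool = True,
) -> SpectrumComparison:
    """Per-frequency one-way ANOVA across groups, plus a MANOVA omnibus.

    The omnibus (Pillai's trace over all 43 frequency bins) is computed only
    when there are enough subjects for a non-singular covariance; otherwise
    it is reported as None. Per-frequency F tests are always computed and the
    significance mask is uncorrected at ``alpha``, matching simple-contrast
    reporting.
    """
    if len(spectra) != len(labels):
        raise ValueError("one label per spectrum required")
    mat = np.vstack([s.power for s in spectra])
    labels_arr = np.asarray(labels)
    uniq = np.unique(labels_arr)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    groups = [mat[labels_arr == g] for g in uniq]
    for g, block in zip(uniq, groups):
        if block.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    nf = mat.shape[1]
    F = np.empty(nf)
    p = np.empty(nf)
    for j in range(nf):
        cols = [block[:, j] for block in groups]
        if all(np.ptp(c) == 0 for c in cols) and np.ptp([c[0] for c in cols]) == 0:
            F[j], p[j] = 0.0, 1.0
        else:
            F[j], p[j] = stats.f_oneway(*cols)
    comp = SpectrumComparison(SPECTRUM_FREQS.copy(), F, p, alpha=alpha)
    if omnibus and mat.shape[0] > nf + uniq.size:
        from statsmodels.multivariate.manova import MANOVA

        try:
            mv = MANOVA(mat, np.column_stack([np.ones(len(labels_arr)),
                                              (labels_arr[:, None] == uniq[1:]).astype(float)]))
            tab = mv.mv_test().results["x1"]["stat"]
            comp.omnibus_stat = float(tab.loc["Pillai's trace", "Value"])
            comp.omnibus_p = float(tab.loc["Pillai's trace", "Pr > F"])
        except Exception:
            comp.omnibus_stat = comp.omnibus_p = None
    return comp
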