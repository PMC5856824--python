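"""Phase–amplitude nesting and power–power comodulograms.

The nesting statistic operationalizes thalamocortical "edge-effect"
coupling: per ROI, the three orthogonal current components are band-passed
in theta (4–7.5 Hz), beta1 (12.5–30 Hz), and gamma (30.5–44 Hz); each band
is reduced to its first principal component (recovering the shared dipole
waveform); the Hilbert envelope of the beta1 and gamma components is taken;
and the Pearson correlation between the theta component and each fast-band
envelope is the per-subject coupling score.

Note this is a *linear* theta-waveform-to-envelope covariation measure, not
a phase-binned modulation index: a positive r means the fast amplitude
rises with the theta waveform itself. Significance for an individual score
is assessed against circular-shift surrogates, which keep both spectra but
destroy the temporal alignment.

The power–power comodulogram is the correlation matrix of mean-removed
multitaper spectral amplitude time courses on a 1-Hz grid (2–44 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import windows

from .spectral import CFC_BANDS, SPECTRUM_FREQS, bandpass_filter, hilbert_envelope

__all__ = [
    "CouplingResult",
    "Comodulogram",
    "first_pc",
    "pac_nesting",
    "surrogate_threshold",
    "group_compare_cfc",
    "comodulogram",
]


@dataclass
class CouplingResult:
    subject_id: str
    roi: str
    r_theta_beta: float
    r_theta_gamma: float

    def __post_init__(self) -> None:
        for r in (self.r_theta_beta, self.r_theta_gamma):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation {r} outside [-1, 1]")


@dataclass
class Comodulogram:
    freqs: np.ndarray
    matrix: np.ndarray
    window_s: float
    step_s: float
    n_tapers: int


def first_pc(components: np.ndarray) -> np.ndarray:
    """Projection onto the leading eigenvector of the 3×3 component covariance.

    Sign convention: the output correlates positively with the component of
    largest variance, so repeated calls on rotated versions of the same data
    agree up to numerical noise rather than up to sign.
    """
    comps = np.asarray(components, dtype=float)
    if comps.ndim != 2 or comps.shape[0] != 3:
        raise ValueError("expected 3 equal-length component signals")
    centered = comps - comps.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / centered.shape[1]
    if np.allclose(cov, 0):
        raise ValueError("zero-variance input")
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, -1]
    pc = v @ centered
    dominant = centered[int(np.argmax(np.diag(cov)))]
    if np.dot(pc, dominant) < 0:
        pc = -pc
    return pc


def _band_pc(comps: np.ndarray, fs: float, band) -> np.ndarray:
    filtered = np.vstack(
        [bandpass_filter(c, band.f_low, band.f_high, fs) for c in comps]
    )
    return first_pc(filtered)


def pac_nesting(roi_ts, fs: float | None = None, edge_s: float = 1.0) -> CouplingResult:
    """Theta-to-beta1 and theta-to-gamma nesting correlations for one ROI.

    The first and last ``edge_s`` seconds are excluded from the correlation
    to avoid filter and Hilbert edge transients.
    """
    fs = fs or roi_ts.fs
    comps = roi_ts.components
    if comps.shape[1] / fs < 30.0:
        raise ValueError("need >= 30 s of signal for a stable nesting estimate")
    theta = _band_pc(comps, fs, CFC_BANDS["theta"])
    env_beta = hilbert_envelope(_band_pc(comps, fs, CFC_BANDS["beta1"]))
    env_gamma = hilbert_envelope(_band_pc(comps, fs, CFC_BANDS["gamma"]))
    edge = int(edge_s * fs)
    sl = slice(edge, comps.shape[1] - edge)
    r_tb = float(stats.pearsonr(theta[sl], env_beta[sl]).statistic)
    r_tg = float(stats.pearsonr(theta[sl], env_gamma[sl]).statistic)
    sid = getattr(roi_ts, "subject_id", "")
    return CouplingResult(sid, roi_ts.roi.name, r_tb, r_tg)


def surrogate_threshold(
    roi_ts, n_surr: int = 200, seed: int = 0, edge_s: float = 1.0
) -> dict[str, float]:
    """95th percentile of |r| under circular-shift surrogates.

    The fast-band envelope is circularly shifted by >= 2 s random offsets,
    which preserves both marginal spectra while destroying phase alignment.
    """
    fs = roi_ts.fs
    comps = roi_ts.components
    theta = _band_pc(comps, fs, CFC_BANDS["theta"])
    env_beta = hilbert_envelope(_band_pc(comps, fs, CFC_BANDS["beta1"]))
    env_gamma = hilbert_envelope(_band_pc(comps, fs, CFC_BANDS["gamma"]))
    n = comps.shape[1]
    edge = int(edge_s * fs)
    sl = slice(edge, n - edge)
    min_shift = int(2 * fs)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift, size=n_surr)
    r_b = np.empty(n_surr)
    r_g = np.empty(n_surr)
    for i, s in enumerate(shifts):
        r_b[i] = abs(stats.pearsonr(theta[sl], np.roll(env_beta, s)[sl]).statistic)
        r_g[i] = abs(stats.pearsonr(theta[sl], np.roll(env_gamma, s)[sl]).statistic)
    return {
        "q95_beta": float(np.quantile(r_b, 0.95)),
        "q95_gamma": float(np.quantile(r_g, 0.95)),
    }


def group_compare_cfc(
    results: list[CouplingResult],
    groups: dict[str, str],
    roi: str,
    pair: str = "theta_gamma",
) -> dict:
    """One-way ANOVA of nesting r across groups at one ROI, with Bonferroni
    pairwise contrasts (correction factor = number of group pairs)."""
    if pair not in ("theta_beta", "theta_gamma"):
        raise ValueError("pair must be 'theta_beta' or 'theta_gamma'")
    attr = "r_" + pair
    by_group: dict[str, list[float]] = {}
    for res in results:
        if res.roi != roi:
            continue
        g = groups[res.subject_id]
        by_group.setdefault(g, []).append(getattr(res, attr))
    if len(by_group) < 2:
        raise ValueError(f"need >= 2 groups with data at ROI {roi}")
    for g, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects at ROI {roi}")
    names = sorted(by_group)
    samples = [np.asarray(by_group[g]) for g in names]
    if np.ptp(np.concatenate(samples)) == 0:
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*samples)
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.ptp(np.concatenate([samples[i], samples[j]])) == 0:
                praw = 1.0
            else:
                praw = stats.ttest_ind(samples[i], samples[j]).pvalue
            pairwise[f"{names[i]} vs {names[j]}"] = float(min(1.0, praw * n_pairs))
    return {"F": float(F), "p": float(p), "pairwise": pairwise, "groups": names}


def comodulogram(
    roi_ts,
    fs: float | None = None,
    window_s: float = 2.0,
    step_s: float = 0.25,
    n_tapers: int = 3,
) -> Comodulogram:
    """Power-power coupling: correlations of multitaper amplitude time courses.

    The broadband first principal component is run through a sliding
    multitaper spectrogram (DPSS tapers, NW = (n_tapers + 1)/2); spectral
    amplitudes on the 1-Hz 2–44 Hz grid are mean-removed and correlated
    across window positions for every frequency pair.
    """
    fs = fs or roi_ts.fs
    comps = roi_ts.components
    n = comps.shape[1]
    if n / fs < 20 * window_s:
        raise ValueError(f"need >= {20 * window_s:.0f} s of signal")
    if SPECTRUM_FREQS[-1] >= fs / 2:
        raise ValueError("analysis grid extends beyond Nyquist")
    pc = first_pc(comps)
    nw = int(window_s * fs)
    step = int(step_s * fs)
    tapers = windows.dpss(nw, NW=(n_tapers + 1) / 2, Kmax=n_tapers)
    fft_freqs = np.fft.rfftfreq(nw, d=1.0 / fs)
    idx = np.searchsorted(fft_freqs, SPECTRUM_FREQS)
    starts = np.arange(0, n - nw + 1, step)
    amps = np.empty((starts.size, SPECTRUM_FREQS.size))
    for i, s in enumerate(starts):
        seg = pc[s : s + nw]
        spec = np.abs(np.fft.rfft(tapers * seg[None, :], axis=1)) ** 2
        amps[i] = np.sqrt(spec.mean(axis=0)[idx])
    amps -= amps.mean(axis=0)
    mat = np.corrcoef(amps.T)
    np.fill_diagonal(mat, 1.0)
    return Comodulogram(SPECTRUM_FREQS.copy(), mat, window_s, step_s, n_tapers)
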