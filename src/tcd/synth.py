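"""Synthetic source-space cohorts carrying the thalamocortical-dysrhythmia signature.

Real inputs to this kind of analysis are per-ROI current time series from an
EEG inverse solution (three orthogonal current components per ROI). This
module generates seeded surrogates with the statistical structure the
downstream analyses assume:

* healthy subjects — a dominant alpha (8–12 Hz) oscillation over a 1/f
  background, no cross-frequency coupling anywhere;
* patients — in disorder-specific ROIs (plus the dACC/sgACC common areas)
  the alpha rhythm is slowed to theta (4–7.5 Hz) and surrounded by beta and
  gamma carriers whose amplitude is linearly modulated by the theta
  waveform ("nesting"); all remaining ROIs look healthy.

All three components of an ROI share one core waveform through a random
unit direction vector, emulating a fixed current dipole orientation — this
is what the downstream principal-component reduction recovers.

Coupling is injected as linear amplitude modulation of the fast carriers by
the rescaled theta waveform, so the Pearson nesting statistic is monotone in
the modulation depth ``m`` and exactly zero in expectation at ``m = 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .rois import CANONICAL_ROIS, GROUPS, PATIENT_GROUPS, RoiSpec, disorder_roi_map

__all__ = [
    "GeneratorParams",
    "RoiTimeSeries",
    "SubjectRecord",
    "PAPER_COUNTS",
    "default_counts",
    "pink_noise",
    "generate_subject",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
    "export_roi_csv",
]

#: Study-scale group sizes (total 541 subjects).
PAPER_COUNTS: dict[str, int] = {
    "healthy": 264,
    "tinnitus": 153,
    "pain": 78,
    "parkinson": 31,
    "depression": 15,
}


def default_counts(scale: float = 1.0) -> dict[str, int]:
    """Group sizes scaled from the study's 264/153/78/31/15 (>=1 per group)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return {g: max(1, round(n * scale)) for g, n in PAPER_COUNTS.items()}


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable parameters of the synthetic cohort generator.

    ``modulation_depth`` (m) scales the theta-phase modulation of the beta
    and gamma carriers; m=0 produces no coupling by construction.
    ``amp_jitter`` is the log-normal sd of per-subject amplitude variation,
    which gives band-power features realistic between-subject spread.
    ``spectral_shift=False`` disables the TCD injection entirely (patients
    become spectrally identical to controls) — the non-TCD control cohort.
    """

    duration_s: float = 300.0
    fs: float = 128.0
    alpha_freq: float = 10.0
    theta_freq: float = 6.0
    osc_amplitude: float = 0.8
    hf_amplitude: float = 0.4
    modulation_depth: float = 0.8
    noise_sigma: float = 0.4
    pink_exponent: float = 1.0
    amp_jitter: float = 0.5
    spectral_shift: bool = True
    depression_phc_alpha: bool = False  # optional left-PHC alpha boost, off by default

    def __post_init__(self) -> None:
        if not 8.0 <= self.alpha_freq <= 12.0:
            raise ValueError("alpha_freq must lie in [8, 12] Hz")
        if not 4.0 <= self.theta_freq <= 7.5:
            raise ValueError("theta_freq must lie in [4, 7.5] Hz")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if self.fs <= 2 * 44.0:
            raise ValueError("fs must exceed twice the 44 Hz band edge")
        if self.duration_s < 8.0:
            raise ValueError("duration_s must be >= 8 s (filter transients)")


@dataclass
class RoiTimeSeries:
    """Three orthogonal current-component signals for one ROI."""

    roi: RoiSpec
    components: np.ndarray  # shape (3, T)
    fs: float

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 2 or self.components.shape[0] != 3:
            raise ValueError("components must have shape (3, T)")
        if not np.all(np.isfinite(self.components)):
            raise ValueError("components contain non-finite values")
        if self.fs <= 2 * 44.0:
            raise ValueError("fs must exceed twice the 44 Hz band edge")

    @property
    def n_samples(self) -> int:
        return self.components.shape[1]


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    roi_series: dict[str, RoiTimeSeries]
    seed: int
    params: GeneratorParams = field(repr=False, default=GeneratorParams())

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        expected = {r.name for r in CANONICAL_ROIS}
        if set(self.roi_series) != expected:
            missing = expected - set(self.roi_series)
            extra = set(self.roi_series) - expected
            raise ValueError(f"ROI set mismatch: missing={sorted(missing)}, extra={sorted(extra)}")


def pink_noise(
    n: int, exponent: float = 1.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via frequency-domain shaping."""
    rng = rng or np.random.default_rng()
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _core_waveforms(group, roi, t, params, rng, j_osc, j_hf, f_beta, f_gamma):
    """Core (shared-dipole) waveform for one ROI; phases drawn from rng.

    Draw order is fixed and identical for every ROI so that signal content
    depends only on the seed, not on which ROIs carry the TCD effect.
    """
    phi, phi_b, phi_g = rng.uniform(0, 2 * np.pi, size=3)
    is_tcd = (
        params.spectral_shift
        and group in PATIENT_GROUPS
        and roi in {r.name for r in disorder_roi_map(group)}
    )
    amp = params.osc_amplitude * j_osc
    if not is_tcd:
        if (
            params.depression_phc_alpha
            and group == "depression"
            and roi == "PHC_L"
        ):
            amp *= 1.5
        return amp * np.sin(2 * np.pi * params.alpha_freq * t + phi)
    theta = np.sin(2 * np.pi * params.theta_freq * t + phi)  # already in [-1, 1]
    envelope = 1.0 + params.modulation_depth * theta
    carriers = np.sin(2 * np.pi * f_beta * t + phi_b) + np.sin(2 * np.pi * f_gamma * t + phi_g)
    return amp * theta + params.hf_amplitude * j_hf * envelope * carriers


def generate_subject(group: str, params: GeneratorParams, seed: int) -> SubjectRecord:
    """Generate one subject's 13 ROI time series, deterministically from ``seed``."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs
    # Per-subject draws: amplitude jitter and carrier frequencies.
    j_osc, j_hf = np.exp(rng.normal(0.0, params.amp_jitter, size=2))
    f_beta = rng.uniform(13.0, 30.0)
    f_gamma = rng.uniform(30.5, 44.0)
    roi_series: dict[str, RoiTimeSeries] = {}
    for roi in CANONICAL_ROIS:
        core = _core_waveforms(group, roi.name, t, params, rng, j_osc, j_hf, f_beta, f_gamma)
        w = rng.standard_normal(3)
        w /= np.linalg.norm(w)
        # A dipole orientation is sign-ambiguous (w, core) == (-w, -core);
        # canonicalize to the hemisphere with a positive dominant component so
        # the downstream PCA sign convention recovers core with positive sign.
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        noise = params.noise_sigma * np.vstack(
            [pink_noise(n, params.pink_exponent, rng) for _ in range(3)]
        )
        comps = w[:, None] * core[None, :] + noise
        roi_series[roi.name] = RoiTimeSeries(roi, comps, params.fs)
    return SubjectRecord(f"{group}", group, roi_series, seed, params)


def _subject_seeds(master_seed: int, n: int) -> np.ndarray:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return (state & 0x7FFFFFFF).astype(np.int64)


def generate_cohort(
    counts: dict[str, int], params: GeneratorParams, master_seed: int
) -> list[SubjectRecord]:
    """Generate independent subjects; per-subject seeds derive from ``master_seed``."""
    for g, c in counts.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
        if c < 0:
            raise ValueError("counts must be >= 0")
    order = [(g, i) for g in GROUPS for i in range(counts.get(g, 0))]
    seeds = _subject_seeds(master_seed, len(order))
    cohort = []
    for (g, i), s in zip(order, seeds):
        rec = generate_subject(g, params, int(s))
        rec.subject_id = f"{g}_{i:03d}"
        cohort.append(rec)
    return cohort


def save_cohort(cohort: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write one NPZ signal container plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {
        f"{rec.subject_id}/{name}": ts.components
        for rec in cohort
        for name, ts in rec.roi_series.items()
    }
    np.savez_compressed(out / "signals.npz", **arrays)
    manifest = {
        "n_subjects": len(cohort),
        "fs": cohort[0].params.fs if cohort else None,
        "params": asdict(cohort[0].params) if cohort else None,
        "subjects": [
            {"subject_id": r.subject_id, "group": r.group, "seed": r.seed} for r in cohort
        ],
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_cohort(in_dir: str | Path) -> list[SubjectRecord]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    params = GeneratorParams(**manifest["params"])
    data = np.load(in_dir / "signals.npz")
    cohort = []
    for meta in manifest["subjects"]:
        roi_series = {
            roi.name: RoiTimeSeries(roi, data[f"{meta['subject_id']}/{roi.name}"], params.fs)
            for roi in CANONICAL_ROIS
        }
        cohort.append(
            SubjectRecord(meta["subject_id"], meta["group"], roi_series, meta["seed"], params)
        )
    return cohort


def export_roi_csv(rec: SubjectRecord, roi_name: str, path: str | Path) -> None:
    """CSV dump of one ROI's three components for inspection."""
    ts = rec.roi_series[roi_name]
    t = np.arange(ts.n_samples) / ts.fs
    header = f"subject={rec.subject_id} group={rec.group} roi={roi_name} fs={ts.fs}"
    np.savetxt(
        path,
        np.column_stack([t, ts.components.T]),
        delimiter=",",
        header=header + "\ntime_s,comp_x,comp_y,comp_z",
        comments="",
    )
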