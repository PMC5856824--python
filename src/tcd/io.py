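"""Readers and writers: EDF ingestion, CSV/JSON exports.

EDF ingestion stops at the channel level: mapping scalp channels to ROI
current sources requires an inverse solution, which is out of scope here —
channel signals must not be mistaken for sources. Recordings are brought to
the analysis convention on read: resampled to 128 Hz and band-passed to
2–44 Hz with the zero-phase FFT filter.

EDF *writing* is a minimal single-purpose implementation (fixed-layout
ASCII header + 16-bit integer records) sufficient for interchange and
round-trip testing; reading goes through MNE.
"""

from __future__ import annotations

import json
from dataclasses import is_dataclass, asdict
from pathlib import Path

import numpy as np

from .spectral import bandpass_filter

__all__ = ["read_edf", "write_edf", "write_json"]

TARGET_FS = 128.0
ANALYSIS_BAND = (2.0, 44.0)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    path: str | Path,
    signals: np.ndarray,
    fs: float,
    ch_names: list[str] | None = None,
) -> None:
    """Write channels × samples to a minimal EDF file (16-bit, 1 s records).

    Signals are truncated to a whole number of 1-second data records. Each
    channel gets a symmetric physical range covering its extremes, so the
    quantization step is (phys_max − phys_min) / (2^16 − 1).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_sig, n_samp = signals.shape
    spr = int(round(fs))  # samples per 1 s record
    n_rec = n_samp // spr
    if n_rec < 1:
        raise ValueError("need at least one second of data")
    ch_names = ch_names or [f"ch{i}" for i in range(n_sig)]
    phys_max = np.maximum(np.abs(signals).max(axis=1), 1e-9)
    dig_min, dig_max = -32768, 32767
    header = b"".join(
        [
            _pad("0", 8),
            _pad("synthetic", 80),
            _pad("tcd export", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_sig)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(n_sig), 4),
        ]
    )
    fields = [
        [_pad(n, 16) for n in ch_names],
        [_pad("", 80)] * n_sig,
        [_pad("uV", 8)] * n_sig,
        [_pad(f"{-p:.6g}"[:8], 8) for p in phys_max],
        [_pad(f"{p:.6g}"[:8], 8) for p in phys_max],
        [_pad(str(dig_min), 8)] * n_sig,
        [_pad(str(dig_max), 8)] * n_sig,
        [_pad("", 80)] * n_sig,
        [_pad(str(spr), 8)] * n_sig,
        [_pad("", 32)] * n_sig,
    ]
    header += b"".join(b"".join(f) for f in fields)
    # parse the physical extremes back so stored data match the 8-char header
    pmin = np.array([float(f"{-p:.6g}"[:8]) for p in phys_max])
    pmax = np.array([float(f"{p:.6g}"[:8]) for p in phys_max])
    scale = (dig_max - dig_min) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for s in range(n_sig):
                seg = signals[s, r * spr : (r + 1) * spr]
                dig = np.clip(
                    np.round((seg - pmin[s]) * scale[s]) + dig_min, dig_min, dig_max
                ).astype("<i2")
                fh.write(dig.tobytes())


def read_edf(
    path: str | Path,
    resample_to: float = TARGET_FS,
    band: tuple[float, float] | None = ANALYSIS_BAND,
) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF recording and bring it to the analysis convention.

    Returns (channels × samples array, sampling rate, channel names) after
    resampling to ``resample_to`` Hz and, when ``band`` is given and the
    record is long enough, zero-phase band-pass filtering.
    """
    import mne

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"EDF file {path} is missing or empty")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if raw.info["sfreq"] != resample_to:
        raw = raw.resample(resample_to, verbose="error")
    data = raw.get_data()
    fs = float(raw.info["sfreq"])
    if band is not None and data.shape[1] >= 8 * fs:
        data = np.vstack([bandpass_filter(ch, band[0], band[1], fs) for ch in data])
    return data, fs, list(raw.ch_names)


def write_json(obj, path: str | Path) -> None:
    """JSON writer tolerant of numpy scalars/arrays and dataclasses."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if is_dataclass(o):
            return asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
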