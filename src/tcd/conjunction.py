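"""Contrast z-maps over (ROI, band) and minimum-statistic conjunction.

Each disorder-vs-healthy contrast is summarized as a z-map: per (ROI, band)
cell, a two-sample t statistic on log current density mapped through the
normal quantile of its t cumulative probability (positive when the first
group exceeds the second). A conjunction across several contrasts keeps, per
cell, the minimum z; a cell is declared common to all contrasts when that
minimum exceeds the one-sided normal threshold — the "conjunction null"
reading, under which every individual contrast must show the effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable
from .rois import CANONICAL_ROIS
from .spectral import BAND_ORDER

__all__ = ["ZMap", "contrast_zmap", "conjunction_z"]

_ROI_NAMES = tuple(r.name for r in CANONICAL_ROIS)
_Z_CAP = 37.0  # |z| beyond double-precision normal quantiles


@dataclass
class ZMap:
    """13 x 5 grid of z-scores for one group contrast."""

    values: pd.DataFrame  # index: ROI, columns: band
    contrast: str

    def __post_init__(self) -> None:
        if tuple(self.values.index) != _ROI_NAMES or tuple(self.values.columns) != BAND_ORDER:
            raise ValueError("z-map must be on the canonical 13 ROI x 5 band grid")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("z-map contains non-finite values")

    def to_long(self) -> pd.DataFrame:
        out = self.values.stack().rename("z").reset_index()
        out.columns = ["roi", "band", "z"]
        return out


def _t_to_z(t: float, df: int) -> float:
    """Normal quantile of the t cumulative probability, sign-symmetric."""
    if t >= 0:
        z = stats.norm.isf(stats.t.sf(t, df))
    else:
        z = -stats.norm.isf(stats.t.sf(-t, df))
    return float(np.clip(z, -_Z_CAP, _Z_CAP))


def contrast_zmap(table: FeatureTable, group_a: str, group_b: str) -> ZMap:
    """Two-sample t per (ROI, band) converted to z; positive when a > b."""
    la = table.labels == group_a
    lb = table.labels == group_b
    if la.sum() < 2 or lb.sum() < 2:
        raise ValueError("both groups need >= 2 subjects")
    A = table.data[la]
    B = table.data[lb]
    df = int(la.sum() + lb.sum() - 2)
    grid = np.empty((len(_ROI_NAMES), len(BAND_ORDER)))
    for i, roi in enumerate(_ROI_NAMES):
        for j, band in enumerate(BAND_ORDER):
            col = f"{roi}:{band}"
            a, b = A[col].to_numpy(), B[col].to_numpy()
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                if a.mean() == b.mean():
                    grid[i, j] = 0.0
                    continue
                raise ValueError(f"degenerate variance in cell {col}")
            t = stats.ttest_ind(a, b).statistic
            grid[i, j] = _t_to_z(float(t), df)
    values = pd.DataFrame(grid, index=list(_ROI_NAMES), columns=list(BAND_ORDER))
    return ZMap(values, f"{group_a}-{group_b}")


def conjunction_z(zmaps: list[ZMap], alpha: float = 0.05) -> tuple[ZMap, list[tuple[str, str]]]:
    """Cellwise minimum over maps; significant cells exceed the one-sided
    normal threshold (z > Phi^-1(1 - alpha)) in *every* contrast."""
    if len(zmaps) < 2:
        raise ValueError("need >= 2 z-maps to conjoin")
    ref = zmaps[0].values
    for zm in zmaps[1:]:
        if not (zm.values.index.equals(ref.index) and zm.values.columns.equals(ref.columns)):
            raise ValueError("z-map grids do not match")
    stacked = np.stack([zm.values.to_numpy() for zm in zmaps])
    conj = pd.DataFrame(stacked.min(axis=0), index=ref.index, columns=ref.columns)
    label = "conj(" + ", ".join(zm.contrast for zm in zmaps) + ")"
    thresh = float(stats.norm.isf(alpha))
    sig = [
        (roi, band)
        for roi in conj.index
        for band in conj.columns
        if conj.loc[roi, band] > thresh
    ]
    return ZMap(conj, label), sig
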