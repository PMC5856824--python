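"""Subjects × (ROI × band) log current-density feature tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .rois import CANONICAL_ROIS, GROUPS
from .spectral import BAND_ORDER, band_log_powers

__all__ = ["FEATURE_NAMES", "FeatureTable", "build_feature_table"]

#: Canonical 65 feature columns, "ROI:band" (13 ROIs x 5 bands).
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{roi.name}:{band}" for roi in CANONICAL_ROIS for band in BAND_ORDER
)


@dataclass
class FeatureTable:
    """Feature matrix (rows: subjects, columns "ROI:band") with group labels.

    ``data`` is indexed by subject_id; ``labels`` holds one group name per
    subject. ``meta`` carries provenance (generator parameters, seeds).
    """

    data: pd.DataFrame
    labels: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(FEATURE_NAMES):
            raise ValueError("feature columns must be the canonical 65 'ROI:band' names")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not self.data.index.equals(self.labels.index):
            raise ValueError("labels must be indexed like the feature matrix")
        unknown = set(self.labels) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def binary_task(self, disorder: str) -> "FeatureTable":
        """Restrict to one disorder vs healthy (labels unchanged)."""
        mask = self.labels.isin(["healthy", disorder])
        return FeatureTable(self.data[mask].copy(), self.labels[mask].copy(), dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.labels)
        out.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject_id")
        labels = df.pop("group")
        return cls(df[list(FEATURE_NAMES)], labels)


def build_feature_table(cohort) -> FeatureTable:
    """One row per subject, one column per ROI:band log power.

    Band powers come from a single Welch pass per (subject, ROI), identical
    to calling ``band_log_power`` per band.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    rows, labels, index = [], [], []
    for rec in cohort:
        row = {}
        for roi in CANONICAL_ROIS:
            if roi.name not in rec.roi_series:
                raise ValueError(f"subject {rec.subject_id} is missing ROI {roi.name}")
            ts = rec.roi_series[roi.name]
            powers = band_log_powers(ts.components, ts.fs)
            for band in BAND_ORDER:
                row[f"{roi.name}:{band}"] = powers[band]
        rows.append(row)
        labels.append(rec.group)
        index.append(rec.subject_id)
    data = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"), columns=FEATURE_NAMES)
    meta = {"n_subjects": len(cohort)}
    if cohort and getattr(cohort[0], "params", None) is not None:
        from dataclasses import asdict

        meta["params"] = asdict(cohort[0].params)
    return FeatureTable(data, pd.Series(labels, index=data.index, name="group"), meta)
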