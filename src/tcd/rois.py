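"""Canonical regions of interest for the thalamocortical-dysrhythmia (TCD) analysis.

The pipeline works at the level of 13 cortical regions of interest (ROIs):
bilateral auditory (BA41), somatosensory (BA1/2/3), and motor (BA4) cortex,
bilateral parahippocampus (BA27) and insula (BA13), and three midline
cingulate regions — dorsal ACC (BA24), subgenual ACC (BA25), and posterior
cingulate (BA23) — which are not lateralized because volume conduction makes
left/right separation unreliable near the midline.

Each patient group carries the TCD signature (alpha slowed to theta, with
theta-phase-modulated beta/gamma) in a disorder-specific subset of these
ROIs, plus the two cingulate "common areas" shared by all disorders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet


@dataclass(frozen=True)
class RoiSpec:
    """One region of interest: name, Brodmann area, and hemisphere."""

    name: str
    brodmann: str
    side: str  # "left" | "right" | "midline"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "midline"):
            raise ValueError(f"invalid side {self.side!r} for ROI {self.name!r}")


CANONICAL_ROIS: tuple[RoiSpec, ...] = (
    RoiSpec("AUD_L", "BA41", "left"),
    RoiSpec("AUD_R", "BA41", "right"),
    RoiSpec("So_L", "BA1/2/3", "left"),
    RoiSpec("So_R", "BA1/2/3", "right"),
    RoiSpec("Mo_L", "BA4", "left"),
    RoiSpec("Mo_R", "BA4", "right"),
    RoiSpec("PHC_L", "BA27", "left"),
    RoiSpec("PHC_R", "BA27", "right"),
    RoiSpec("INS_L", "BA13", "left"),
    RoiSpec("INS_R", "BA13", "right"),
    RoiSpec("dACC", "BA24", "midline"),
    RoiSpec("sgACC", "BA25", "midline"),
    RoiSpec("PCC", "BA23", "midline"),
)

ROI_BY_NAME: dict[str, RoiSpec] = {r.name: r for r in CANONICAL_ROIS}

GROUPS: tuple[str, ...] = ("healthy", "tinnitus", "pain", "parkinson", "depression")
PATIENT_GROUPS: tuple[str, ...] = GROUPS[1:]

#: Cingulate regions showing TCD in every disorder.
COMMON_ROIS: FrozenSet[str] = frozenset({"dACC", "sgACC"})

_DISORDER_SPECIFIC: dict[str, FrozenSet[str]] = {
    "tinnitus": frozenset({"AUD_L", "AUD_R"}),
    "pain": frozenset({"So_L", "So_R", "Mo_L", "Mo_R"}),
    "parkinson": frozenset({"Mo_L", "Mo_R"}),
    "depression": frozenset({"sgACC"}),
}


def disorder_roi_map(group: str) -> FrozenSet[RoiSpec]:
    """ROIs in which the TCD signature is injected for a patient group.

    Each disorder has its spatially specific target (tinnitus: auditory
    cortex; pain: somatosensory + motor; Parkinson: motor; depression:
    subgenual ACC) and every disorder additionally involves the dorsal and
    subgenual ACC common areas.

    Raises
    ------
    ValueError
        If ``group`` is not a patient group (including ``healthy``).
    """
    if group not in _DISORDER_SPECIFIC:
        raise ValueError(
            f"{group!r} is not a patient group; expected one of {sorted(_DISORDER_SPECIFIC)}"
        )
    names = _DISORDER_SPECIFIC[group] | COMMON_ROIS
    return frozenset(ROI_BY_NAME[n] for n in names)
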