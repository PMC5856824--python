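"""Group-mean 2-44 Hz spectra and per-frequency disorder-vs-healthy ANOVAs.

Patients slow their alpha peak toward theta and gain beta/gamma power in
affected ROIs, so each disorder's whole-head spectrum should differ from
healthy controls at low (theta) and high (beta/gamma) frequencies while the
healthy spectrum peaks at 10 Hz. Writes:
    results/group_spectra.csv     — per-frequency mean log power per group
    results/spectrum_anovas.csv   — per-frequency F and p per disorder
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, get_cohort  # noqa: E402

from tcd.rois import PATIENT_GROUPS  # noqa: E402
from tcd.spectral import SPECTRUM_FREQS, group_spectrum_comparison, whole_spectrum  # noqa: E402


def main() -> None:
    cohort = get_cohort()
    spectra = [whole_spectrum(rec) for rec in cohort]
    labels = [rec.group for rec in cohort]
    mat = np.vstack([s.power for s in spectra])
    arr = np.asarray(labels)
    means = pd.DataFrame(
        {g: mat[arr == g].mean(axis=0) for g in sorted(set(labels))}, index=SPECTRUM_FREQS
    )
    means.to_csv(RESULTS / "group_spectra.csv", index_label="freq_hz")
    healthy_peak = means.index[means["healthy"].to_numpy().argmax()]
    print(f"healthy group spectrum peaks at {healthy_peak:.0f} Hz")

    rows = []
    for d in PATIENT_GROUPS:
        sel = [i for i, l in enumerate(labels) if l in ("healthy", d)]
        comp = group_spectrum_comparison(
            [spectra[i] for i in sel], [labels[i] for i in sel], omnibus=False
        )
        for f, F, p in zip(comp.freqs, comp.F, comp.p):
            rows.append({"disorder": d, "freq_hz": f, "F": F, "p": p})
        sig = comp.freqs[comp.significant]
        print(f"{d:10s}: {comp.significant.sum():2d}/43 frequencies differ from healthy "
              f"(p<0.05), e.g. {sig[:4].astype(int).tolist()} Hz")
    pd.DataFrame(rows).to_csv(RESULTS / "spectrum_anovas.csv", index=False)


if __name__ == "__main__":
    main()
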