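"""Theta-phase nesting per ROI and group, plus a power-power comodulogram.

Computes the theta-to-beta1 and theta-to-gamma nesting correlations for the
disorder-target and common-area ROIs of every subject, compares groups per
ROI by one-way ANOVA with Bonferroni pairwise contrasts, and saves one
example comodulogram (a coupled tinnitus auditory ROI). Writes:
    results/cfc_nesting.csv
    results/cfc_anovas.json
    results/comodulogram_aud_tinnitus.csv
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, get_cohort  # noqa: E402

from tcd.cfc import CouplingResult, comodulogram, group_compare_cfc, pac_nesting  # noqa: E402
from tcd.pipeline import CFC_ROIS  # noqa: E402


def main() -> None:
    cohort = get_cohort()
    rows, results, groups = [], [], {}
    for rec in cohort:
        groups[rec.subject_id] = rec.group
        for roi in CFC_ROIS:
            res = pac_nesting(rec.roi_series[roi])
            results.append(CouplingResult(rec.subject_id, roi, res.r_theta_beta, res.r_theta_gamma))
            rows.append({"subject_id": rec.subject_id, "group": rec.group, "roi": roi,
                         "r_theta_beta": res.r_theta_beta, "r_theta_gamma": res.r_theta_gamma})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "cfc_nesting.csv", index=False)

    aud = df[df.roi == "AUD_L"].groupby("group").r_theta_gamma.mean()
    print("mean theta-gamma nesting in left auditory cortex:")
    for g, v in aud.items():
        print(f"  {g:10s} {v:+.3f}")

    anovas = {}
    for roi in CFC_ROIS:
        anovas[roi] = {
            pair: group_compare_cfc(results, groups, roi, pair)
            for pair in ("theta_beta", "theta_gamma")
        }
        F = anovas[roi]["theta_gamma"]["F"]
        print(f"{roi:6s} theta-gamma group ANOVA F = {F:8.1f}")
    (RESULTS / "cfc_anovas.json").write_text(json.dumps(anovas, indent=2))

    tin = next(r for r in cohort if r.group == "tinnitus")
    com = comodulogram(tin.roi_series["AUD_L"])
    pd.DataFrame(com.matrix, index=com.freqs, columns=com.freqs).to_csv(
        RESULTS / "comodulogram_aud_tinnitus.csv", index_label="freq_hz"
    )
    i6, i40 = int(np.searchsorted(com.freqs, 6)), int(np.searchsorted(com.freqs, 40))
    print(f"comodulogram (tinnitus AUD_L): r(6 Hz, 40 Hz amplitude) = {com.matrix[i6, i40]:.2f}")


if __name__ == "__main__":
    main()
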