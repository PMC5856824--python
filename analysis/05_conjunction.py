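"""Minimum-statistic conjunction of the four disorder-vs-healthy z-maps.

Each disorder contrast is a 13 ROI x 5 band z-map (two-sample t mapped to
the normal quantile). The conjunction keeps, per cell, the smallest z across
the four contrasts; cells exceeding the one-sided 5% normal threshold in
every contrast are the candidate disorder-general ("common") areas. Writes:
    results/conjunction_zmap.csv
    results/conjunction_cells.json
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, get_cohort  # noqa: E402

from tcd.conjunction import conjunction_z, contrast_zmap  # noqa: E402
from tcd.features import build_feature_table  # noqa: E402
from tcd.rois import PATIENT_GROUPS  # noqa: E402


def main() -> None:
    table = build_feature_table(get_cohort())
    zmaps = [contrast_zmap(table, d, "healthy") for d in PATIENT_GROUPS]
    conj, sig = conjunction_z(zmaps, alpha=0.05)
    conj.to_long().to_csv(RESULTS / "conjunction_zmap.csv", index=False)
    (RESULTS / "conjunction_cells.json").write_text(
        json.dumps({"alpha": 0.05, "significant_cells": [list(c) for c in sig]}, indent=2)
    )
    print(f"{len(sig)} conjunction-significant cells (one-sided alpha = 0.05):")
    for roi, band in sig:
        print(f"  {roi:6s} {band:6s} z_conj = {conj.values.loc[roi, band]:.2f}")


if __name__ == "__main__":
    main()
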