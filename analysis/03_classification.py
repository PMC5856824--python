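"""Cross-validated classification of each disorder vs healthy, with nulls.

For each disorder: stratified ten-fold CV of the linear logistic model on
the 65 band-power features (10 repeats), a 100-permutation label-shuffled
null, the real-vs-null ANOVA, the calibrated permutation p-value, and the
features the model leans on. Also fits the five-class full model. Writes:
    results/classification.json
"""

import dataclasses
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import MASTER_SEED, RESULTS, get_cohort  # noqa: E402

from tcd.classify import (  # noqa: E402
    CvConfig,
    compare_real_vs_null,
    evaluate_cv,
    permutation_null,
    permutation_pvalue,
    selected_features,
    train_linear,
)
from tcd.features import build_feature_table  # noqa: E402
from tcd.rois import PATIENT_GROUPS  # noqa: E402


def main() -> None:
    table = build_feature_table(get_cohort())
    out = {}
    for i, d in enumerate(PATIENT_GROUPS):
        sub = table.binary_task(d)
        cfg = CvConfig(k=10, n_repeats=10, seed=i)
        rep = evaluate_cv(sub, cfg)
        null = permutation_null(
            sub, dataclasses.replace(cfg, n_repeats=1), n_perm=100, master_seed=MASTER_SEED + i
        )
        model = train_linear(sub.data.to_numpy(), sub.labels.to_numpy(), cfg)
        picks = selected_features(model)[:8]
        out[d] = {
            "cv_mean": rep.mean,
            "cv_sd": rep.sd,
            "null_mean": null.mean,
            "anova_accuracy": compare_real_vs_null(rep, null, "accuracy"),
            "perm_p_accuracy": permutation_pvalue(rep, null, "accuracy"),
            "selected_features": picks,
        }
        print(
            f"{d:10s}: acc {100 * rep.mean['accuracy']:5.1f}% (null "
            f"{100 * null.mean['accuracy']:4.1f}%), kappa {rep.mean['kappa']:.2f}, "
            f"perm p {out[d]['perm_p_accuracy']:.3f}, top features {picks[:3]}"
        )
    cfg = CvConfig(k=10, n_repeats=10, seed=99)
    rep = evaluate_cv(table, cfg)
    null = permutation_null(
        table, dataclasses.replace(cfg, n_repeats=1), n_perm=100, master_seed=MASTER_SEED + 99
    )
    out["full_model"] = {
        "cv_mean": rep.mean,
        "null_mean": null.mean,
        "anova_accuracy": compare_real_vs_null(rep, null, "accuracy"),
    }
    print(f"full model : acc {100 * rep.mean['accuracy']:5.1f}% "
          f"(null {100 * null.mean['accuracy']:4.1f}%)")
    (RESULTS / "classification.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
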