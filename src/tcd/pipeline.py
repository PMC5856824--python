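"""End-to-end driver: simulate → spectra → classification → CFC → conjunction.

``run_all`` replays the study's analysis sequence on a synthetic cohort and
writes one JSON report bundle plus CSV tables. Every artifact embeds the
configuration hash and master seed, so two runs with the same configuration
are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .cfc import group_compare_cfc, pac_nesting
from .classify import (
    CvConfig,
    compare_real_vs_null,
    evaluate_cv,
    permutation_null,
    permutation_pvalue,
)
from .conjunction import conjunction_z, contrast_zmap
from .features import FeatureTable, build_feature_table
from .io import write_json
from .rois import PATIENT_GROUPS
from .spectral import SPECTRUM_FREQS, group_spectrum_comparison, whole_spectrum
from .synth import GeneratorParams, generate_cohort, save_cohort

log = logging.getLogger("tcd")

__all__ = ["RunConfig", "simulate", "run_all", "validate_report", "config_hash"]

#: ROIs for which nesting is computed (the spatially specific disorder
#: targets plus the cingulate common areas).
CFC_ROIS: tuple[str, ...] = ("AUD_L", "AUD_R", "So_L", "So_R", "Mo_L", "Mo_R", "dACC", "sgACC")


@dataclass(frozen=True)
class RunConfig:
    counts: dict[str, int] = field(default_factory=lambda: {g: 20 for g in synth.PAPER_COUNTS})
    params: GeneratorParams = GeneratorParams(duration_s=60.0)
    cv: CvConfig = CvConfig()
    n_perm: int = 100
    null_repeats: int = 1  # CV repeats inside each permutation
    cfc_rois: tuple[str, ...] = CFC_ROIS
    master_seed: int = 0
    out_dir: str = "results/run"
    log_level: str = "INFO"


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def simulate(config: RunConfig, out_dir: str | Path | None = None) -> list:
    """Generate the cohort and (optionally) persist it with its manifest."""
    cohort = generate_cohort(config.counts, config.params, config.master_seed)
    if out_dir is not None:
        save_cohort(cohort, out_dir)
    return cohort


def _classification_block(table: FeatureTable, config: RunConfig, seed_offset: int) -> dict:
    cv_cfg = replace(config.cv, seed=config.cv.seed + seed_offset)
    report = evaluate_cv(table, cv_cfg)
    null_cfg = replace(cv_cfg, n_repeats=config.null_repeats)
    null = permutation_null(
        table, null_cfg, n_perm=config.n_perm, master_seed=config.master_seed + seed_offset
    )
    return {
        "cv_mean": report.mean,
        "cv_sd": report.sd,
        "null_mean": null.mean,
        "null_sd": null.sd,
        "n_perm": null.n_perm,
        "anova_accuracy": compare_real_vs_null(report, null, "accuracy"),
        "anova_kappa": compare_real_vs_null(report, null, "kappa"),
        "perm_p_accuracy": permutation_pvalue(report, null, "accuracy"),
        "perm_p_kappa": permutation_pvalue(report, null, "kappa"),
        "classes": report.classes,
    }


def run_all(config: RunConfig, cohort=None, table: FeatureTable | None = None) -> dict:
    """Run every analysis stage; write the report bundle under ``config.out_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    bundle: dict = {"config_hash": chash, "master_seed": config.master_seed}

    t0 = _stage("simulate")
    if cohort is None:
        cohort = simulate(config)
    bundle["n_subjects"] = len(cohort)
    log.info("simulate: %d subjects in %.1f s", len(cohort), time.perf_counter() - t0)

    t0 = _stage("features")
    if table is None:
        table = build_feature_table(cohort)
    table.to_csv(out / "features.csv")
    log.info("features: %s in %.1f s", table.data.shape, time.perf_counter() - t0)

    t0 = _stage("spectra")
    spectra = [whole_spectrum(rec) for rec in cohort]
    labels = [rec.group for rec in cohort]
    spec_block: dict = {"freqs": SPECTRUM_FREQS.tolist()}
    mat = np.vstack([s.power for s in spectra])
    means = pd.DataFrame(
        {g: mat[np.asarray(labels) == g].mean(axis=0) for g in sorted(set(labels))},
        index=SPECTRUM_FREQS,
    )
    means.to_csv(out / "group_spectra.csv", index_label="freq_hz")
    for disorder in PATIENT_GROUPS:
        sel = [i for i, l in enumerate(labels) if l in ("healthy", disorder)]
        comp = group_spectrum_comparison(
            [spectra[i] for i in sel], [labels[i] for i in sel], omnibus=False
        )
        spec_block[disorder] = {
            "F": comp.F.tolist(),
            "p": comp.p.tolist(),
            "n_significant": int(comp.significant.sum()),
        }
    bundle["spectra"] = spec_block
    log.info("spectra in %.1f s", time.perf_counter() - t0)

    t0 = _stage("classification")
    cls_block: dict = {}
    for i, disorder in enumerate(PATIENT_GROUPS):
        cls_block[disorder] = _classification_block(table.binary_task(disorder), config, i)
        log.info(
            "%s: acc=%.3f null=%.3f p=%.2g",
            disorder,
            cls_block[disorder]["cv_mean"]["accuracy"],
            cls_block[disorder]["null_mean"]["accuracy"],
            cls_block[disorder]["anova_accuracy"]["p"],
        )
    cls_block["full_model"] = _classification_block(table, config, len(PATIENT_GROUPS))
    bundle["classification"] = cls_block
    log.info("classification in %.1f s", time.perf_counter() - t0)

    t0 = _stage("cfc")
    rows = []
    groups = {}
    for rec in cohort:
        groups[rec.subject_id] = rec.group
        for roi in config.cfc_rois:
            res = pac_nesting(rec.roi_series[roi])
            res.subject_id = rec.subject_id
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "roi": roi,
                    "r_theta_beta": res.r_theta_beta,
                    "r_theta_gamma": res.r_theta_gamma,
                }
            )
    cfc_df = pd.DataFrame(rows)
    cfc_df.to_csv(out / "cfc_nesting.csv", index=False)
    from .cfc import CouplingResult

    results = [
        CouplingResult(r["subject_id"], r["roi"], r["r_theta_beta"], r["r_theta_gamma"])
        for r in rows
    ]
    cfc_block = {}
    for roi in config.cfc_rois:
        cfc_block[roi] = {
            pair: group_compare_cfc(results, groups, roi, pair)
            for pair in ("theta_beta", "theta_gamma")
        }
    bundle["cfc"] = cfc_block
    log.info("cfc in %.1f s", time.perf_counter() - t0)

    t0 = _stage("conjunction")
    zmaps = [contrast_zmap(table, d, "healthy") for d in PATIENT_GROUPS]
    conj, sig = conjunction_z(zmaps)
    conj.to_long().to_csv(out / "conjunction_zmap.csv", index=False)
    bundle["conjunction"] = {
        "significant_cells": [list(c) for c in sig],
        "threshold_alpha": 0.05,
        "max_z": float(conj.values.to_numpy().max()),
    }
    log.info("conjunction in %.1f s: %d significant cells", time.perf_counter() - t0, len(sig))

    cfg = asdict(config)
    cfg["config_hash"] = chash
    write_json(cfg, out / "config.json")
    write_json(bundle, out / "report.json")
    validate_report(bundle)
    return bundle


def _lookup(bundle: dict, dotted: str):
    cur = bundle
    for part in dotted.split("."):
        if not isinstance(cur, dict) or part not in cur:
            raise KeyError(dotted)
        cur = cur[part]
    return cur


def validate_report(bundle: dict, schema_path: str | Path | None = None) -> None:
    """Structural validation of a report bundle against the shipped schema.

    Raises ValueError naming the first missing or mistyped entry.
    """
    if schema_path is None:
        schema = json.loads(
            resources.files("tcd").joinpath("report_schema.json").read_text()
        )
    else:
        schema = json.loads(Path(schema_path).read_text())
    types = {"str": str, "int": int, "float": float, "dict": dict, "list": list}
    required = dict(schema["required"])
    for disorder in PATIENT_GROUPS:
        for key, typ in schema["per_disorder_required"].items():
            required[key.replace("<disorder>", disorder)] = typ
    for dotted, typ in required.items():
        try:
            val = _lookup(bundle, dotted)
        except KeyError:
            raise ValueError(f"report bundle missing required entry {dotted!r}")
        if not isinstance(val, types[typ]):
            raise ValueError(f"report entry {dotted!r} has type {type(val).__name__}, expected {typ}")
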