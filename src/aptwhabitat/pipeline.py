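"""End-to-end pipeline: simulate -> aptw -> habitat -> features -> select ->
fit -> evaluate, with a single global seed fanned out deterministically to
per-stage seeds and every artifact written with a manifest.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .aptw import compute_aptw_map
from .evaluation import auc_ci_delong, delong_test, roc_auc, youden_threshold
from .habitat import extract_voxel_features, select_habitats
from .modeling import MODEL_NAMES, ModelSpec, fit_cv
from .radiomics import FeatureBankConfig, extract_feature_table
from .selection import SelectionConfig
from .synthetic import CohortConfig, cohort_table, generate_cohort, perturb_feature_table

log = logging.getLogger("aptwhabitat")

#: order of the seed fan-out (index into the spawned seed sequences)
_STAGES = ("simulate", "aptw", "habitat", "features", "select", "fit", "evaluate")


@dataclass
class PipelineConfig:
    out_dir: str = "runs/default"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    feature_bank: FeatureBankConfig = field(default_factory=FeatureBankConfig)
    selection: SelectionConfig = field(
        default_factory=lambda: SelectionConfig(n_lambdas=40, lambda_min_ratio=1e-2)
    )
    k_range: tuple[int, int] = (3, 10)
    kmeans_n_init: int = 10
    n_habitats: int = 3
    cv_folds: int = 5
    reader2_rel_sd: float = 0.05
    use_zspectra: bool = False
    write_volumes: bool = False

    def stage_seed(self, stage: str) -> int:
        idx = _STAGES.index(stage)
        return int(
            np.random.SeedSequence(self.seed).spawn(len(_STAGES))[idx].generate_state(1)[0]
            % (2**31 - 1)
        )


@dataclass
class PipelineResult:
    run_dir: Path
    cohort: pd.DataFrame
    feature_table: pd.DataFrame
    cv_results: dict
    eval_report: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- simulate ---------------------------------------------------------
    cohort_cfg = config.cohort
    if cohort_cfg.seed != config.stage_seed("simulate"):
        cohort_cfg = type(cohort_cfg)(
            **{**asdict(cohort_cfg), "seed": config.stage_seed("simulate"),
               "make_zspectra": config.use_zspectra}
        )
    patients = generate_cohort(cohort_cfg)
    clin = cohort_table(patients)
    io.write_table(run_dir / "cohort.csv", clin)
    log.info("simulate: %d patients in %.1fs", len(patients), time.time() - t0)

    # --- aptw -------------------------------------------------------------
    for p in patients:
        if config.use_zspectra and p.zspectrum is not None:
            p.volume_aptw = compute_aptw_map(p.zspectrum, p.mask).values
    if config.write_volumes:
        vol_dir = run_dir / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for p in patients:
            io.write_volume(vol_dir / f"{p.patient_id}_aptw.nii", p.volume_aptw, p.spacing)
            io.write_volume(vol_dir / f"{p.patient_id}_mask.nii", p.mask, p.spacing)

    # --- habitat ----------------------------------------------------------
    t1 = time.time()
    habitat_maps = {}
    ch_rows = []
    for p in patients:
        fmap = extract_voxel_features(p.volume_aptw, p.mask)
        hm = select_habitats(
            fmap,
            p.volume_aptw,
            p.mask,
            k_range=config.k_range,
            seed=config.stage_seed("habitat"),
            n_init=config.kmeans_n_init,
        )
        habitat_maps[p.patient_id] = hm
        for k, ch in hm.ch_scores.items():
            ch_rows.append({"patient_id": p.patient_id, "k": k, "ch": ch, "selected": k == hm.k})
    io.write_table(run_dir / "ch_scores.csv", pd.DataFrame(ch_rows).set_index("patient_id"))
    log.info("habitat: clustered %d patients in %.1fs", len(patients), time.time() - t1)

    # --- features ---------------------------------------------------------
    t2 = time.time()
    table, flagged = extract_feature_table(
        {p.patient_id: p.volume_aptw for p in patients},
        {p.patient_id: habitat_maps[p.patient_id].labels for p in patients},
        {p.patient_id: p.spacing for p in patients},
        config=config.feature_bank,
        n_habitats=config.n_habitats,
    )
    io.write_table(run_dir / "features.csv", table)
    reader2 = perturb_feature_table(table, config.reader2_rel_sd, config.stage_seed("features"))
    log.info("features: %d columns in %.1fs (flagged: %s)", table.shape[1],
             time.time() - t2, flagged or "none")

    # --- fit (selection happens inside the outer folds) -------------------
    t3 = time.time()
    labels = clin["lvsi"]
    sel_cfg = config.selection
    if sel_cfg.seed != config.stage_seed("select"):
        sel_cfg = type(sel_cfg)(**{**asdict(sel_cfg), "seed": config.stage_seed("select")})
    cv_results = {}
    for name in MODEL_NAMES:
        spec = ModelSpec(name=name, seed=config.stage_seed("fit"))
        cv_results[name] = fit_cv(
            spec,
            clin,
            labels,
            feature_table=table,
            reader2_table=reader2,
            selection_config=sel_cfg,
            folds=config.cv_folds,
        )
    preds = pd.DataFrame(
        {name: r.oof_probability for name, r in cv_results.items()}
    )
    preds["fold"] = cv_results[MODEL_NAMES[0]].fold_assignment
    preds["lvsi"] = labels
    io.write_table(run_dir / "predictions.csv", preds)
    log.info("fit: 3 models in %.1fs", time.time() - t3)

    # --- evaluate ---------------------------------------------------------
    y = labels.to_numpy()
    report = {"models": {}, "comparisons": {}}
    for name, r in cv_results.items():
        roc = roc_auc(r.oof_probability.to_numpy(), y)
        thr, j = youden_threshold(roc.curve)
        auc, lo, hi = auc_ci_delong(r.oof_probability.to_numpy(), y)
        report["models"][name] = {
            "mean_fold_auc": r.mean_auc,
            "mean_fold_accuracy": r.mean_accuracy,
            "mean_fold_f1": r.mean_f1,
            "pooled_auc": auc,
            "pooled_auc_ci95": [lo, hi],
            "threshold": thr,
            "youden": j,
            "z_vs_chance": roc.z_vs_chance,
            "p_vs_chance": roc.p_vs_chance,
        }
    for a, b in (("combined", "aptw_h3"), ("combined", "clinical_radiological"),
                 ("aptw_h3", "clinical_radiological")):
        d = delong_test(
            cv_results[a].oof_probability.to_numpy(),
            cv_results[b].oof_probability.to_numpy(),
            y,
        )
        report["comparisons"][f"{a}_vs_{b}"] = {
            "auc1": d.auc1, "auc2": d.auc2, "diff": d.diff,
            "diff_ci95": list(d.diff_ci95), "z": d.z, "p": d.p,
        }
    io.write_json(run_dir / "eval_report.json", report)
    io.write_manifest(
        run_dir,
        {"cohort": run_dir / "cohort.csv", "features": run_dir / "features.csv"},
        config.seed,
        list(_STAGES),
    )
    log.info("pipeline done in %.1fs", time.time() - t0)
    return PipelineResult(
        run_dir=run_dir,
        cohort=clin,
        feature_table=table,
        cv_results=cv_results,
        eval_report=report,
    )
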