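"""End-to-end orchestration: simulate → meta-ROI → train → explain → Θ → evaluate.

Each stage reads/writes delimited tables under one output directory, so any
stage can be resumed from existing intermediates.  A single seed fans out to
named per-stage sub-seeds; identical config + seed reproduces every output
byte-for-byte.  A JSON manifest records the config hash, seed, stage
timings, and the files each stage produced.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import ShapMatrix, attribution_matrix
from .classifier import (
    TrainedClassifier,
    load_model,
    save_model,
    stratified_split,
    train_ensemble,
)
from .cohort import (
    CohortTable,
    load_cohort,
    read_scores,
    write_cohort,
    write_scores,
)
from .config import RunConfig, config_hash, load_config
from .errors import ThetaPetError
from .metaroi import classify_meta_roi
from .simulate import generate_cohort, label_concordance
from .stats import classification_metrics, confusion_rates
from .theta import batch_theta

log = logging.getLogger(__name__)

STAGES = ("simulate", "train", "predict", "explain", "score", "evaluate")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _stage_seed(seed: int, stage: str) -> int:
    # named substream per stage, kept below 2**31
    return int(np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0] % (2**31))


def run_full_pipeline(
    config_path=None,
    out_dir="theta_run",
    seed=None,
    config: RunConfig | None = None,
    resume: bool = False,
) -> RunManifest:
    """Execute all stages in order; returns the populated manifest.

    ``resume=True`` skips any stage whose output files already exist.
    Failures abort with the stage name; the partial manifest is still
    written to ``manifest.json``.
    """
    cfg = config if config is not None else load_config(config_path)
    if seed is not None:
        cfg = load_config(config_path, overrides={"seed": int(seed)})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(cfg), seed=cfg.seed)
    paths = {
        "suvr": out / "cohort_suvr.csv",
        "meta": out / "cohort_metadata.csv",
        "model": out / "model.pkl",
        "shap": out / "attributions.csv",
        "scores": out / "scores.csv",
        "metrics": out / "metrics.csv",
        "manifest": out / "manifest.json",
        "log": out / "run.log",
    }
    try:
        _run_stages(cfg, paths, manifest, resume)
    except ThetaPetError as exc:
        manifest.write(paths["manifest"])
        raise ThetaPetError(f"pipeline aborted: {exc}") from exc
    manifest.write(paths["manifest"])
    with open(paths["log"], "a", encoding="utf-8") as fh:
        fh.write(
            f"{time.strftime('%Y-%m-%dT%H:%M:%S')} completed seed={cfg.seed} "
            f"config={manifest.config_hash} version={__version__}\n"
        )
    return manifest


def _timed(manifest: RunManifest, stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()

        def __exit__(self, *exc):
            manifest.stage_seconds[stage] = round(time.perf_counter() - self.t0, 3)

    return _Timer()


def _run_stages(cfg: RunConfig, paths, manifest: RunManifest, resume: bool) -> None:
    atlas = cfg.atlas

    with _timed(manifest, "simulate"):
        if resume and paths["suvr"].exists() and paths["meta"].exists():
            cohort = load_cohort(paths["suvr"], paths["meta"], atlas, cfg.delimiter)
        else:
            sim_cfg = cfg.simulation
            cohort = generate_cohort(sim_cfg, atlas)
            write_cohort(cohort, paths["suvr"], paths["meta"], cfg.delimiter)
        manifest.outputs["simulate"] = [str(paths["suvr"]), str(paths["meta"])]

    meta = {
        rec.participant_id: classify_meta_roi(panel, atlas, cfg.meta_roi)
        for rec, panel in cohort.records
    }
    concordance = {
        pid: lab.label for pid, lab in label_concordance(cohort, meta).items()
    }

    with _timed(manifest, "train"):
        if resume and paths["model"].exists():
            model, _ = load_model(paths["model"])
            split = stratified_split(
                cohort, concordance, cfg.classifier.test_fraction,
                seed=_stage_seed(cfg.seed, "train"),
            )
        else:
            split = stratified_split(
                cohort, concordance, cfg.classifier.test_fraction,
                seed=_stage_seed(cfg.seed, "train"),
            )
            model = train_ensemble(
                cohort, split, k=cfg.classifier.k, repeats=cfg.classifier.repeats,
                seed=_stage_seed(cfg.seed, "train"), atlas=atlas,
            )
            save_model(model, paths["model"], manifest.config_hash)
        manifest.outputs["train"] = [str(paths["model"])]

    with _timed(manifest, "predict"):
        proba = model.predict_proba_matrix(cohort.suvr_matrix(model.feature_order))
        status = proba > cfg.classifier.threshold

    with _timed(manifest, "explain"):
        if resume and paths["shap"].exists():
            matrix = _read_attributions(paths["shap"], cohort)
        else:
            train_cohort = cohort.subset(split.train_ids)
            matrix = attribution_matrix(
                model, cohort, train_cohort,
                method=cfg.attribution.method,
                n_background=cfg.attribution.n_background,
                n_permutations=cfg.attribution.n_permutations,
                seed=_stage_seed(cfg.seed, "explain"),
            )
            _write_attributions(matrix, paths["shap"])
        manifest.outputs["explain"] = [str(paths["shap"])]

    with _timed(manifest, "score"):
        theta_table = batch_theta(matrix, cohort, cfg.theta)
        results = {}
        for i, pid in enumerate(cohort.participant_ids):
            row = theta_table.iloc[i]
            r = meta[pid]
            entry = {
                "temporal_suvr": r.temporal_suvr,
                "mtl_suvr": r.mtl_suvr,
                "neo_suvr": r.neo_suvr,
                "temporal_pos": int(r.temporal_pos),
                "mtl_pos": int(r.mtl_pos),
                "neo_pos": int(r.neo_pos),
                "probability": float(proba[i]),
                "predicted_status": int(status[i]),
                "theta": float(row["theta"]),
            }
            entry.update(
                {c: float(row[c]) for c in theta_table.columns if c.startswith("theta_")}
            )
            results[pid] = entry
        write_scores(cohort, results, paths["scores"], cfg.delimiter)
        manifest.outputs["score"] = [str(paths["scores"])]

    with _timed(manifest, "evaluate"):
        _evaluate(cohort, meta, proba, status, split, paths["metrics"])
        manifest.outputs["evaluate"] = [str(paths["metrics"])]


def _write_attributions(matrix: ShapMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.insert(1, "base_value", matrix.base_value)
    frame.to_csv(path, index=False, float_format="%.17g")  # exact round-trip


def _read_attributions(path, cohort: CohortTable) -> ShapMatrix:
    frame = pd.read_csv(
        path, dtype={"participant_id": str}, float_precision="round_trip"
    )
    regions = [c for c in frame.columns if c not in ("participant_id", "base_value")]
    return ShapMatrix(
        values=frame[regions].to_numpy(),
        base_value=float(frame["base_value"].iloc[0]),
        participant_ids=tuple(frame["participant_id"]),
        region_names=tuple(regions),
        method="loaded",
    )


def _evaluate(cohort, meta, proba, status, split, out_path) -> None:
    """Table-2-style comparison block: visual vs each meta-ROI vs model."""
    vis = cohort.visual_ratings().astype(int)
    ids = cohort.participant_ids
    rows = []
    comparators = {
        "temporal": np.array([int(meta[p].temporal_pos) for p in ids]),
        "mtl": np.array([int(meta[p].mtl_pos) for p in ids]),
        "neo": np.array([int(meta[p].neo_pos) for p in ids]),
        "model": status.astype(int),
    }
    for name, comp in comparators.items():
        rep = confusion_rates(vis, comp)
        rows.append(
            {
                "comparison": f"visual_vs_{name}",
                "tpr": rep.tpr, "tnr": rep.tnr, "tp": rep.tp, "tn": rep.tn,
                "pos_mismatch_pct": rep.pos_mismatch_pct(),
                "neg_mismatch_pct": rep.neg_mismatch_pct(),
            }
        )
    test_idx = [i for i, p in enumerate(ids) if p in set(split.test_ids)]
    test_rep = classification_metrics(
        vis[test_idx], status.astype(int)[test_idx], proba[test_idx]
    )
    rows.append(
        {
            "comparison": "model_test_set",
            "tpr": test_rep.tpr, "tnr": test_rep.tnr,
            "tp": test_rep.tp, "tn": test_rep.tn,
            "pos_mismatch_pct": test_rep.pos_mismatch_pct(),
            "neg_mismatch_pct": test_rep.neg_mismatch_pct(),
            "balanced_accuracy": test_rep.balanced_accuracy,
            "mcc": test_rep.mcc, "f1": test_rep.f1, "roc_auc": test_rep.roc_auc,
        }
    )
    pd.DataFrame(rows).to_csv(out_path, index=False, float_format="%.6g")
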