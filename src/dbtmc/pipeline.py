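"""End-to-end pipeline: phantom cohort -> preprocessing -> both branches ->
ensembles -> metrics at view and lesion level.

Every run directory receives the resolved configuration, the seed, the
library versions, per-stage logs, training histories, per-model prediction
CSVs and one metrics JSON per (model, level) — enough to re-run the
experiment exactly.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, dump_config
from .evaluation import PredictionRecord, evaluate_predictions
from .io import save_cohort, write_metrics, write_predictions
from .networks import (
    build_aniso_resnet3d,
    build_resnet34_2d,
    decision_ensemble,
)
from .phantom import generate_cohort
from .training import (
    build_branch_data,
    feature_ensemble_predictions,
    predictions_for,
    set_global_seed,
    train_branch,
    train_feature_ensemble,
)

__all__ = ["run_pipeline", "decision_ensemble_predictions"]


def decision_ensemble_predictions(
    preds2d: list[PredictionRecord],
    preds3d: list[PredictionRecord],
    weight_2d: float = 0.5,
) -> list[PredictionRecord]:
    """Combine matching view-level predictions of the two branches."""
    by_key = {(p.lesion_id, p.view): p for p in preds3d}
    out = []
    for p2 in preds2d:
        p3 = by_key.get((p2.lesion_id, p2.view))
        if p3 is None:
            raise ValueError(f"no 3D prediction for {(p2.lesion_id, p2.view)}")
        if p3.label != p2.label:
            raise ValueError(f"label mismatch for {(p2.lesion_id, p2.view)}")
        prob = decision_ensemble(
            np.array([1.0 - p2.p_malignant, p2.p_malignant]),
            np.array([1.0 - p3.p_malignant, p3.p_malignant]),
            weight_2d,
        )
        out.append(
            PredictionRecord(
                lesion_id=p2.lesion_id,
                view=p2.view,
                label=p2.label,
                p_malignant=float(prob[1]),
            )
        )
    return out


def _stage(log, out_dir, name, t0):
    elapsed = time.time() - t0
    log.append(f"{name}: {elapsed:.1f}s")
    (Path(out_dir) / "run.log").write_text("\n".join(log) + "\n")
    return time.time()


def run_pipeline(cfg: RunConfig, out_dir, save_volumes: bool = False) -> dict:
    """Execute generate -> preprocess -> train -> predict -> ensemble ->
    evaluate and return {model: {level: metrics dict}}.

    ``save_volumes`` additionally writes the cohort NIfTI files (slower;
    the manifest is always written).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = [
        f"dbtmc {__version__}",
        f"python {sys.version.split()[0]} numpy {np.__version__}",
        f"seed {cfg.seed}",
    ]
    dump_config(cfg, out_dir / "config.yaml")
    set_global_seed(cfg.seed)
    t0 = time.time()

    phantom_params = dataclasses.replace(cfg.phantom, seed=cfg.seed)
    cohort = generate_cohort(phantom_params)
    if save_volumes:
        save_cohort(cohort, out_dir / "cohort")
    else:
        from .io import write_manifest

        write_manifest(cohort.records, out_dir / "manifest.csv")
    t0 = _stage(log, out_dir, "generate", t0)

    data = {
        split: build_branch_data(cohort, split, cfg.slab, cfg.use_oracle_focus)
        for split in ("train", "val", "test")
    }
    t0 = _stage(log, out_dir, "preprocess", t0)

    model2d = build_resnet34_2d(
        block_modules=cfg.net2d.block_modules,
        block_channels=cfg.net2d.block_channels,
        dropout_p=cfg.net2d.dropout_p,
        seed=cfg.seed,
    )
    model2d, hist2d = train_branch(model2d, data["train"], data["val"],
                                   cfg.train, arch="2d")
    pd.DataFrame(hist2d).to_csv(out_dir / "history_2d.csv", index=False)
    model2d.save(out_dir / "checkpoint_2d.npz")
    t0 = _stage(log, out_dir, "train_2d", t0)

    model3d = build_aniso_resnet3d(cfg.net3d, seed=cfg.seed + 1)
    model3d, hist3d = train_branch(model3d, data["train"], data["val"],
                                   cfg.train, arch="3d")
    pd.DataFrame(hist3d).to_csv(out_dir / "history_3d.csv", index=False)
    model3d.save(out_dir / "checkpoint_3d.npz")
    t0 = _stage(log, out_dir, "train_3d", t0)

    head = train_feature_ensemble(model2d, model3d, data["train"], data["val"],
                                  cfg.train)
    t0 = _stage(log, out_dir, "train_feature_ensemble", t0)

    preds = {
        "2d-resnet": predictions_for(model2d, data["test"], "2d"),
        "3d-aniso-resnet": predictions_for(model3d, data["test"], "3d"),
        "feature-ensemble": feature_ensemble_predictions(
            model2d, model3d, head, data["test"]
        ),
    }
    for w in cfg.ensemble_weights:
        name = "decision-ua" if w == 0.5 else f"decision-wa-{w:g}"
        preds[name] = decision_ensemble_predictions(
            preds["2d-resnet"], preds["3d-aniso-resnet"], w
        )
    t0 = _stage(log, out_dir, "predict", t0)

    results: dict = {}
    for model_name, model_preds in preds.items():
        write_predictions(model_preds, out_dir / f"predictions_{model_name}.csv")
        results[model_name] = {}
        for level in ("view", "lesion"):
            report = evaluate_predictions(model_preds, level=level)
            results[model_name][level] = report.as_dict()
            write_metrics(
                report.as_dict(), out_dir / f"metrics_{model_name}_{level}.json"
            )
    _stage(log, out_dir, "evaluate", t0)
    with open(out_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return results
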