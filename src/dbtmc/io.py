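"""Standard-format I/O: CSV manifests, NIfTI volumes, JSON metrics.

Volumes are stored as NIfTI (.nii.gz) with uint16 intensities in [0, 1023]
and the voxel spacing in the affine/header; masks share the geometry with
values {0, 1}.  The manifest is a CSV with one row per (lesion, view) and
0-based slice indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import Cohort, LesionRecord, PhantomParams
from .preprocess import DbtRoi

__all__ = [
    "MANIFEST_COLUMNS",
    "write_manifest",
    "read_manifest",
    "write_volume",
    "read_volume",
    "write_metrics",
    "save_cohort",
    "load_cohort",
    "write_predictions",
    "read_predictions",
]

MANIFEST_COLUMNS = [
    "lesion_id",
    "patient_id",
    "view",
    "label",
    "split",
    "volume_path",
    "mask_path",
    "focus_slice_gt",
]


def write_manifest(records: list[LesionRecord], path) -> None:
    rows = [
        {
            "lesion_id": r.lesion_id,
            "patient_id": r.patient_id,
            "view": r.view,
            "label": r.label,
            "split": r.split,
            "volume_path": r.volume_path,
            "mask_path": r.mask_path,
            "focus_slice_gt": "" if r.focus_slice_gt is None else r.focus_slice_gt,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> list[LesionRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            focus = row["focus_slice_gt"]
            records.append(
                LesionRecord(
                    lesion_id=row["lesion_id"],
                    patient_id=row["patient_id"],
                    view=row["view"],
                    label=row["label"],
                    split=row["split"],
                    volume_path=row["volume_path"],
                    mask_path=row["mask_path"],
                    focus_slice_gt=None if focus == "" else int(focus),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed manifest row {i + 2} in {path}: {exc}")
    return records


def write_volume(array: np.ndarray, path,
                 spacing: tuple[float, float, float] = (0.1, 0.1, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def write_metrics(metrics: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=float)


def save_cohort(cohort: Cohort, out_dir) -> Path:
    """Write all volumes/masks as NIfTI plus the manifest CSV."""
    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    updated: list[LesionRecord] = []
    for rec in cohort.records:
        roi, mask, focus = cohort.volumes[(rec.lesion_id, rec.view)]
        vol_rel = f"volumes/{rec.lesion_id}_{rec.view}.nii.gz"
        mask_rel = f"volumes/{rec.lesion_id}_{rec.view}_mask.nii.gz"
        write_volume(roi.intensities.astype(np.uint16), out_dir / vol_rel,
                     roi.spacing)
        write_volume(mask.astype(np.uint8), out_dir / mask_rel, roi.spacing)
        updated.append(
            LesionRecord(
                lesion_id=rec.lesion_id,
                patient_id=rec.patient_id,
                view=rec.view,
                label=rec.label,
                split=rec.split,
                volume_path=vol_rel,
                mask_path=mask_rel,
                focus_slice_gt=focus,
            )
        )
    cohort.records = updated
    manifest = out_dir / "manifest.csv"
    write_manifest(updated, manifest)
    return manifest


def load_cohort(cohort_dir, params: PhantomParams | None = None) -> Cohort:
    """Rebuild an in-memory cohort from a saved manifest + volumes."""
    cohort_dir = Path(cohort_dir)
    records = read_manifest(cohort_dir / "manifest.csv")
    volumes = {}
    for rec in records:
        vol, spacing = read_volume(cohort_dir / rec.volume_path)
        mask, mask_spacing = read_volume(cohort_dir / rec.mask_path)
        if mask.shape != vol.shape:
            raise ValueError(
                f"mask/volume geometry mismatch for {rec.lesion_id} {rec.view}"
            )
        roi = DbtRoi(intensities=vol.astype(np.uint16), spacing=spacing)
        volumes[(rec.lesion_id, rec.view)] = (roi, mask, rec.focus_slice_gt)
    return Cohort(params=params or PhantomParams(), records=records,
                  volumes=volumes)


def write_predictions(preds, path) -> None:
    pd.DataFrame(
        [
            {
                "lesion_id": p.lesion_id,
                "view": p.view,
                "label": p.label,
                "p_malignant": f"{p.p_malignant:.8f}",
            }
            for p in preds
        ]
    ).to_csv(path, index=False)


def read_predictions(path):
    from .evaluation import PredictionRecord

    df = pd.read_csv(path)
    required = {"lesion_id", "view", "label", "p_malignant"}
    if not required.issubset(df.columns):
        raise ValueError(f"predictions CSV missing columns {required - set(df.columns)}")
    return [
        PredictionRecord(
            lesion_id=str(r.lesion_id),
            view=str(r.view),
            label=int(r.label),
            p_malignant=float(r.p_malignant),
        )
        for r in df.itertuples()
    ]
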