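"""Cohort and artifact I/O: NIfTI volumes, JSON annotations, CSV manifests.

A cohort directory contains one NIfTI volume per patient plus ``cohort.json``
(schema: generator config; per patient: patient_id, volume file, nodule
records with nodule_id, center, bbox, ratings, true_label, true_volume,
true_diameter) and ``split.csv`` mapping patient_id to train/test.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import CTVolume, NoduleGroundTruth
from .errors import StageDependencyError
from .synthetic import Cohort, SyntheticConfig


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = []
    for vol in cohort.volumes:
        fname = f"{vol.patient_id}.nii.gz"
        affine = np.diag(list(vol.spacing) + [1.0])
        nib.save(nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), affine), out / fname)
        patients.append(
            {
                "patient_id": vol.patient_id,
                "volume_file": fname,
                "spacing": list(vol.spacing),
                "nodules": [
                    {
                        "nodule_id": n.nodule_id,
                        "center": list(n.center),
                        "bbox": list(n.bbox),
                        "ratings": list(n.ratings),
                        "true_label": n.true_label,
                        "true_volume": n.true_volume,
                        "true_diameter": n.true_diameter,
                    }
                    for n in cohort.nodules_of(vol.patient_id)
                ],
            }
        )
    (out / "cohort.json").write_text(
        json.dumps(
            {"config": dataclasses.asdict(cohort.config), "patients": patients}, indent=1
        )
    )
    pd.DataFrame(
        [(p, "train") for p in cohort.train_patients]
        + [(p, "test") for p in cohort.test_patients],
        columns=["patient_id", "partition"],
    ).to_csv(out / "split.csv", index=False)
    return out


def load_cohort(cohort_dir: str | Path) -> Cohort:
    d = Path(cohort_dir)
    meta_path = d / "cohort.json"
    if not meta_path.exists():
        raise StageDependencyError(
            f"{meta_path} not found: run the 'simulate' stage before loading a cohort"
        )
    meta = json.loads(meta_path.read_text())
    cfg_dict = dict(meta["config"])
    for k, v in cfg_dict.items():
        if isinstance(v, list):
            cfg_dict[k] = tuple(v)
    config = SyntheticConfig(**cfg_dict)
    volumes, nodules = [], []
    for rec in meta["patients"]:
        img = nib.load(d / rec["volume_file"])
        volumes.append(
            CTVolume(
                np.asarray(img.dataobj, dtype=np.float32),
                spacing=tuple(rec.get("spacing", (1, 1, 1))),
                patient_id=rec["patient_id"],
            )
        )
        for n in rec["nodules"]:
            nodules.append(
                NoduleGroundTruth(
                    nodule_id=n["nodule_id"],
                    patient_id=rec["patient_id"],
                    center=tuple(n["center"]),
                    bbox=tuple(n["bbox"]),
                    true_label=n["true_label"],
                    true_volume=n["true_volume"],
                    true_diameter=n["true_diameter"],
                    ratings=list(n["ratings"]),
                )
            )
    split_path = d / "split.csv"
    if not split_path.exists():
        raise StageDependencyError(f"{split_path} not found: cohort directory incomplete")
    split = pd.read_csv(split_path)
    train = sorted(split.loc[split.partition == "train", "patient_id"])
    test = sorted(split.loc[split.partition == "test", "patient_id"])
    return Cohort(config, volumes, nodules, train, test)
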