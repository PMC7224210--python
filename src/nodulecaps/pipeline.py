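"""Staged pipeline: simulate -> extract -> train -> fuse -> predict -> evaluate.

Each stage reads its inputs from the run directory and writes its artifacts
back there, so stages are idempotent given identical inputs and seed, and a
missing upstream artifact raises a :class:`StageDependencyError` naming the
stage to run first. ``run_pipeline`` chains all stages and writes a manifest
of every resolved configuration value.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baseline import train_baseline
from .capsule import load_capsnet, save_capsnet, train_single_scale
from .config import RunConfig
from .containers import NoduleAnnotation
from .errors import StageDependencyError
from .evaluation import (
    HAND_CRAFTED_NAMES,
    confusion_metrics,
    correlate_features,
    patient_level_report,
    roc_auc,
)
from .fusion import (
    load_fusion,
    mask_and_concat_batch,
    save_fusion,
    train_fusion,
)
from .io import load_cohort, save_cohort
from .labeling import MalignancyLabel, RatingSet, labels_table
from .patches import all_flips, default_scale_specs, extract_multiscale
from .synthetic import generate_cohort

log = logging.getLogger("nodulecaps")

DISCARD_SENTINEL = -1


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageDependencyError(f"missing artifact {path}; run the '{stage}' stage first")
    return path


def stage_simulate(cfg: RunConfig, run_dir: Path) -> Path:
    cohort = generate_cohort(dataclasses.replace(cfg.cohort, seed=cfg.seed))
    out = save_cohort(cohort, run_dir / "cohort")
    log.info("simulate: %d patients, %d nodules", cfg.cohort.n_patients, len(cohort.nodules))
    return out


def stage_extract(cfg: RunConfig, run_dir: Path) -> Path:
    """Labels CSV plus the three-scale patch arrays for every nodule."""
    cohort = load_cohort(_require(run_dir / "cohort", "simulate"))
    table = labels_table(
        RatingSet(n.ratings, n.nodule_id, n.patient_id) for n in cohort.nodules
    )
    table.to_csv(run_dir / "labels.csv", index=False)
    specs = default_scale_specs(out_size=cfg.out_size)
    xs: dict[int, list[np.ndarray]] = {1: [], 2: [], 3: []}
    labels, nodule_ids, patient_ids, partitions = [], [], [], []
    train_ids = set(cohort.train_patients)
    label_by_id = dict(zip(table.nodule_id, table.label))
    for n in cohort.nodules:
        msp = extract_multiscale(
            cohort.volume_of(n.patient_id), NoduleAnnotation.from_truth(n), specs
        )
        lab = label_by_id[n.nodule_id]
        for i, p in enumerate(msp.patches, start=1):
            xs[i].append(p.values)
        labels.append(DISCARD_SENTINEL if lab == MalignancyLabel.DISCARD.value else int(lab))
        nodule_ids.append(n.nodule_id)
        patient_ids.append(n.patient_id)
        partitions.append("train" if n.patient_id in train_ids else "test")
    np.savez_compressed(
        run_dir / "patches.npz",
        scale1=np.array(xs[1]), scale2=np.array(xs[2]), scale3=np.array(xs[3]),
        labels=np.array(labels),
        nodule_ids=np.array(nodule_ids), patient_ids=np.array(patient_ids),
        partitions=np.array(partitions),
        true_labels=np.array([n.true_label for n in cohort.nodules]),
        hand_crafted=np.array(
            [[n.true_volume, n.true_diameter, n.center[0], n.center[1]] for n in cohort.nodules]
        ),
    )
    (run_dir / "patches.json").write_text(
        json.dumps({"out_size": cfg.out_size, "scales": [dataclasses.asdict(s) for s in specs]})
    )
    log.info("extract: %d nodules at out_size %d", len(labels), cfg.out_size)
    return run_dir / "patches.npz"


def _load_patches(run_dir: Path) -> dict:
    with np.load(_require(run_dir / "patches.npz", "extract"), allow_pickle=False) as z:
        return {k: z[k] for k in z.files}


def _training_arrays(data: dict, scale: int) -> tuple[np.ndarray, np.ndarray]:
    """Flip-augmented labeled training patches for one scale."""
    keep = (data["partitions"] == "train") & (data["labels"] != DISCARD_SENTINEL)
    x = data[f"scale{scale}"][keep]
    y = data["labels"][keep]
    xa, ya = [], []
    for xi, yi in zip(x, y):
        for fr in (False, True):
            for fc in (False, True):
                v = xi
                if fr:
                    v = v[:, ::-1, :]
                if fc:
                    v = v[:, :, ::-1]
                xa.append(v.copy())
                ya.append(yi)
    return np.array(xa), np.array(ya)


def stage_train_scale(cfg: RunConfig, run_dir: Path, scale: int) -> Path:
    data = _load_patches(run_dir)
    x, y = _training_arrays(data, scale)
    net = train_single_scale(
        x, y, cfg.capsnet,
        epochs=cfg.train.epochs_scale, batch_size=cfg.train.batch_size,
        lr=cfg.train.lr, seed=cfg.seed * 10 + scale, margin_params=cfg.margin,
    )
    path = run_dir / f"capsnet_scale{scale}.npz"
    save_capsnet(net, str(path))
    log.info("train-scale %d: final loss %.4f", scale, net.loss_trace[-1])
    return path


def stage_fuse(cfg: RunConfig, run_dir: Path) -> Path:
    """Masked 96-dim fused vectors for every nodule, from frozen scale nets."""
    data = _load_patches(run_dir)
    nets = [
        load_capsnet(str(_require(run_dir / f"capsnet_scale{s}.npz", f"train-scale {s}")))
        for s in (1, 2, 3)
    ]
    vs = [nets[s - 1].forward_batch(data[f"scale{s}"]) for s in (1, 2, 3)]
    fused = mask_and_concat_batch(*vs)
    np.savez_compressed(run_dir / "fused.npz", fused=fused,
                        scale_norms=np.stack([np.linalg.norm(v, axis=-1) for v in vs], axis=1))
    return run_dir / "fused.npz"


def stage_train_fusion(cfg: RunConfig, run_dir: Path) -> Path:
    data = _load_patches(run_dir)
    with np.load(_require(run_dir / "fused.npz", "fuse-features")) as z:
        fused = z["fused"]
    keep = (data["partitions"] == "train") & (data["labels"] != DISCARD_SENTINEL)
    net = train_fusion(
        fused[keep], data["labels"][keep], cfg.bce, cfg.fusion,
        epochs=cfg.train.epochs_fusion, batch_size=cfg.train.batch_size,
        lr=cfg.train.lr, seed=cfg.seed * 10 + 7,
    )
    save_fusion(net, str(run_dir / "fusion.npz"))
    log.info("train-fusion: final loss %.4f", net.loss_trace[-1])
    return run_dir / "fusion.npz"


def stage_train_baseline(cfg: RunConfig, run_dir: Path) -> Path:
    data = _load_patches(run_dir)
    xs, y = zip(*[_training_arrays(data, s) for s in (1, 2, 3)])  # type: ignore[assignment]
    model = train_baseline(
        tuple(xs), y[0], cfg.baseline,
        epochs=cfg.train.epochs_scale, batch_size=cfg.train.batch_size,
        lr=cfg.train.lr, seed=cfg.seed * 10 + 50,
    )
    test = tuple(data[f"scale{s}"] for s in (1, 2, 3))
    probs = model.predict_proba(test)
    pd.DataFrame(
        {
            "nodule_id": data["nodule_ids"],
            "p_benign": probs[:, 0],
            "p_malignant": probs[:, 1],
        }
    ).to_csv(run_dir / "baseline_predictions.csv", index=False)
    return run_dir / "baseline_predictions.csv"


def stage_predict(cfg: RunConfig, run_dir: Path) -> Path:
    data = _load_patches(run_dir)
    with np.load(_require(run_dir / "fused.npz", "fuse-features")) as z:
        fused = z["fused"]
    net = load_fusion(str(_require(run_dir / "fusion.npz", "train-fusion")))
    probs = net.forward_batch(fused)
    label = probs.argmax(axis=1)
    pd.DataFrame(
        {
            "nodule_id": data["nodule_ids"],
            "patient_id": data["patient_ids"],
            "partition": data["partitions"],
            "label_rated": data["labels"],
            "true_label": data["true_labels"],
            "p_benign": probs[:, 0],
            "p_malignant": probs[:, 1],
            "predicted": label,
            "confidence": probs.max(axis=1),
        }
    ).to_csv(run_dir / "predictions.csv", index=False)
    return run_dir / "predictions.csv"


def stage_evaluate(cfg: RunConfig, run_dir: Path) -> Path:
    preds = pd.read_csv(_require(run_dir / "predictions.csv", "predict"))
    test = preds[(preds.partition == "test") & (preds.label_rated != DISCARD_SENTINEL)]
    if len(test) == 0:
        raise ValueError("no labeled test nodules to evaluate")
    report = confusion_metrics(test.predicted, test.label_rated)
    try:
        report.roc_points, report.auc = roc_auc(test.p_malignant, test.label_rated)
    except ValueError:   # single-class test set: AUC undefined, flagged None
        report.roc_points, report.auc = [], None
    report.per_nodule = [
        dict(nodule_id=r.nodule_id, confidence=float(r.confidence),
             predicted=int(r.predicted), true=int(r.label_rated))
        for r in test.itertuples()
    ]
    patient = patient_level_report(test.predicted, test.patient_id, test.label_rated)

    data = _load_patches(run_dir)
    with np.load(_require(run_dir / "fused.npz", "fuse-features")) as z:
        fused = z["fused"]
    corr = correlate_features(fused, data["hand_crafted"])
    pd.DataFrame(corr, columns=list(HAND_CRAFTED_NAMES)).to_csv(
        run_dir / "feature_correlation.csv", index=False
    )
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
        run_dir / "roc_points.csv", index=False
    )
    out = {
        "nodule_level": report.to_dict(),
        "patient_level": patient.to_dict(),
    }
    (run_dir / "report.json").write_text(json.dumps(out, indent=1))
    log.info(
        "evaluate: accuracy %.3f auc %s (n=%d test nodules)",
        report.accuracy, report.auc, len(test),
    )
    return run_dir / "report.json"


def run_pipeline(cfg: RunConfig, run_dir: str | Path) -> Path:
    """Run every stage and write a manifest; returns the run directory."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stage_simulate(cfg, run_dir)
    stage_extract(cfg, run_dir)
    for s in (1, 2, 3):
        stage_train_scale(cfg, run_dir, s)
    stage_fuse(cfg, run_dir)
    stage_train_fusion(cfg, run_dir)
    if cfg.with_baseline:
        stage_train_baseline(cfg, run_dir)
    stage_predict(cfg, run_dir)
    stage_evaluate(cfg, run_dir)
    digest = hashlib.sha256((run_dir / "patches.npz").read_bytes()).hexdigest()
    (run_dir / "manifest.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "config": cfg.resolved(),
                "patches_sha256": digest,
            },
            indent=1,
            default=str,
        )
    )
    return run_dir
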