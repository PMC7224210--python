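"""In-memory end-to-end experiments on synthetic cohorts.

This is the evaluation harness behind the acceptance checks and the worked
examples: generate a seeded cohort, extract three-scale patches, train the
three single-scale capsule networks and the fusion stack, and score the
held-out patients at nodule and patient level. Everything runs in memory;
the staged, file-based pipeline in :mod:`nodulecaps.pipeline` exposes the
same computation as a CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .capsule import CapsNetConfig, MarginLossParams, TINY_CAPSNET, train_single_scale
from .containers import NoduleAnnotation
from .evaluation import (
    confusion_metrics,
    correlate_features,
    patient_level_report,
    roc_auc,
)
from .fusion import (
    FusionSpec,
    TINY_FUSION,
    WeightedBCEParams,
    mask_and_concat_batch,
    train_fusion,
)
from .labeling import MalignancyLabel, label_from_ratings
from .patches import default_scale_specs, extract_multiscale
from .synthetic import Cohort, SyntheticConfig, generate_cohort


@dataclass
class PatchTable:
    """Per-nodule patch arrays and metadata for one cohort."""

    x: tuple[np.ndarray, np.ndarray, np.ndarray]   # each (N, 3, H, W)
    labels: np.ndarray                              # 0/1, or -1 for indeterminate
    true_labels: np.ndarray
    patient_ids: np.ndarray
    is_train: np.ndarray                            # bool, by patient split
    hand_crafted: np.ndarray                        # (N, 4): volume, diameter, cx, cy

    def subset(self, mask: np.ndarray) -> "PatchTable":
        return PatchTable(
            tuple(xi[mask] for xi in self.x), self.labels[mask], self.true_labels[mask],
            self.patient_ids[mask], self.is_train[mask], self.hand_crafted[mask],
        )


def build_patch_table(cohort: Cohort, out_size: int = 40) -> PatchTable:
    specs = default_scale_specs(out_size=out_size)
    xs: list[list[np.ndarray]] = [[], [], []]
    labels, true_labels, pids = [], [], []
    train_ids = set(cohort.train_patients)
    hc = []
    for n in cohort.nodules:
        msp = extract_multiscale(
            cohort.volume_of(n.patient_id), NoduleAnnotation.from_truth(n), specs
        )
        for i, p in enumerate(msp.patches):
            xs[i].append(p.values)
        lab = label_from_ratings(n.ratings)
        labels.append(-1 if lab == MalignancyLabel.DISCARD else lab.value)
        true_labels.append(n.true_label)
        pids.append(n.patient_id)
        hc.append([n.true_volume, n.true_diameter, n.center[0], n.center[1]])
    pids_arr = np.array(pids)
    return PatchTable(
        x=tuple(np.array(a) for a in xs),
        labels=np.array(labels),
        true_labels=np.array(true_labels),
        patient_ids=pids_arr,
        is_train=np.isin(pids_arr, sorted(train_ids)),
        hand_crafted=np.array(hc),
    )


def _augment_flips(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    outs = [x, x[:, :, ::-1, :], x[:, :, :, ::-1], x[:, :, ::-1, ::-1]]
    return np.concatenate([np.ascontiguousarray(o) for o in outs]), np.tile(y, 4)


@dataclass
class ExperimentResult:
    """Metrics and reusable artifacts of one end-to-end seeded run."""

    seed: int
    n_train: int
    n_test: int
    single_scale_acc: tuple[float, float, float]
    fused_accuracy: float
    fused_auc: float
    sensitivity: float | None
    specificity: float | None
    patient_accuracy: float
    patient_sensitivity: float | None
    patient_specificity: float | None
    fused_train: np.ndarray = field(repr=False, default=None)
    y_train: np.ndarray = field(repr=False, default=None)
    fused_test: np.ndarray = field(repr=False, default=None)
    y_test: np.ndarray = field(repr=False, default=None)
    test_patient_ids: np.ndarray = field(repr=False, default=None)
    fused_all: np.ndarray = field(repr=False, default=None)
    hand_crafted: np.ndarray = field(repr=False, default=None)
    confidence_clear: np.ndarray = field(repr=False, default=None)
    confidence_indeterminate: np.ndarray = field(repr=False, default=None)


def run_experiment(
    seed: int,
    *,
    cohort_config: SyntheticConfig | None = None,
    out_size: int = 40,
    capsnet: CapsNetConfig = TINY_CAPSNET,
    fusion_spec: FusionSpec = TINY_FUSION,
    bce: WeightedBCEParams = WeightedBCEParams(),
    margin: MarginLossParams = MarginLossParams(),
    epochs_scale: int = 25,
    epochs_fusion: int = 200,
    batch_size: int = 16,
    lr: float = 1e-3,
) -> ExperimentResult:
    """Full tiny-scale experiment: cohort -> patches -> training -> metrics."""
    cfg = cohort_config or SyntheticConfig(seed=seed)
    cohort = generate_cohort(cfg)
    table = build_patch_table(cohort, out_size=out_size)

    tr = table.is_train & (table.labels >= 0)
    te = ~table.is_train & (table.labels >= 0)
    y_tr, y_te = table.labels[tr], table.labels[te]

    nets, single_acc = [], []
    for s in range(3):
        x_aug, y_aug = _augment_flips(table.x[s][tr], y_tr)
        net = train_single_scale(
            x_aug, y_aug, capsnet, epochs=epochs_scale, batch_size=batch_size,
            lr=lr, seed=seed * 10 + s + 1, margin_params=margin,
        )
        nets.append(net)
        norms = np.linalg.norm(net.forward_batch(table.x[s][te]), axis=-1)
        single_acc.append(float(np.mean(norms.argmax(axis=1) == y_te)))

    v_all = [nets[s].forward_batch(table.x[s]) for s in range(3)]
    fused_all = mask_and_concat_batch(*v_all)
    fnet = train_fusion(
        fused_all[tr], y_tr, bce, fusion_spec,
        epochs=epochs_fusion, batch_size=batch_size, lr=lr, seed=seed * 10 + 7,
    )
    probs_all = fnet.forward_batch(fused_all)
    pred_te = probs_all[te].argmax(axis=1)

    report = confusion_metrics(pred_te, y_te)
    try:
        _, auc = roc_auc(probs_all[te, 1], y_te)
    except ValueError:
        auc = float("nan")
    patient = patient_level_report(pred_te, table.patient_ids[te], y_te)

    conf_all = probs_all.max(axis=1)
    return ExperimentResult(
        seed=seed,
        n_train=int(tr.sum()),
        n_test=int(te.sum()),
        single_scale_acc=tuple(single_acc),
        fused_accuracy=report.accuracy,
        fused_auc=auc,
        sensitivity=report.sensitivity,
        specificity=report.specificity,
        patient_accuracy=patient.accuracy,
        patient_sensitivity=patient.sensitivity,
        patient_specificity=patient.specificity,
        fused_train=fused_all[tr],
        y_train=y_tr,
        fused_test=fused_all[te],
        y_test=y_te,
        test_patient_ids=table.patient_ids[te],
        fused_all=fused_all,
        hand_crafted=table.hand_crafted,
        confidence_clear=conf_all[table.labels >= 0],
        confidence_indeterminate=conf_all[table.labels < 0],
    )


def weight_sweep(
    result: ExperimentResult,
    settings: dict[str, WeightedBCEParams],
    *,
    fusion_spec: FusionSpec = TINY_FUSION,
    epochs: int = 200,
    seed_offset: int = 100,
) -> dict[str, dict[str, float | None]]:
    """Retrain the fusion stack under several loss weightings, same features.

    The single-scale networks stay frozen, so any sensitivity/specificity
    shift is attributable to the loss weights alone.
    """
    out: dict[str, dict[str, float | None]] = {}
    for name, params in settings.items():
        fnet = train_fusion(
            result.fused_train, result.y_train, params, fusion_spec,
            epochs=epochs, seed=result.seed * 10 + seed_offset,
        )
        pred = fnet.forward_batch(result.fused_test).argmax(axis=1)
        rep = confusion_metrics(pred, result.y_test)
        out[name] = {
            "accuracy": rep.accuracy,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
        }
    return out


def feature_correlations(result: ExperimentResult) -> dict[str, float]:
    """Max |r| of the fused capsule features against each descriptor."""
    r = correlate_features(result.fused_all, result.hand_crafted)
    with np.errstate(invalid="ignore"):
        m = np.nanmax(np.abs(r), axis=0)
    return dict(zip(("volume", "diameter", "x_center", "y_center"), m.tolist()))
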