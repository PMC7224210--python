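"""Shared data containers for volumes, annotations and patches.

Axis convention: volumes are indexed ``(x, y, z)`` where ``z`` is the slice
(axial) axis. Patches are indexed ``(slice, row, col)`` with the 3 slices
being the nodule's central slice and its two immediate z-neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CTVolume:
    """A 3D voxel array with spacing metadata and a patient identifier."""

    voxels: np.ndarray                # (nx, ny, nz) float array
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)   # mm / voxel
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume.voxels must be 3-dimensional")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CTVolume.voxels must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]


@dataclass
class NoduleGroundTruth:
    """Generator-side truth for one synthetic nodule.

    ``bbox`` is the axis-aligned integer box ``(x0, x1, y0, y1, z0, z1)``
    with inclusive low and exclusive high bounds, guaranteed to contain the
    blob. ``ratings`` are the simulated 1-5 rater scores (1-4 raters).
    """

    nodule_id: str
    patient_id: str
    center: tuple[int, int, int]
    bbox: tuple[int, int, int, int, int, int]
    true_label: int                   # 0 benign, 1 malignant
    true_volume: float                # voxels^3, of the generating blob
    true_diameter: float              # voxels, equivalent-sphere diameter
    ratings: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        x0, x1, y0, y1, z0, z1 = self.bbox
        cx, cy, cz = self.center
        if not (x0 <= cx < x1 and y0 <= cy < y1 and z0 <= cz < z1):
            raise ValueError(f"bbox {self.bbox} does not contain center {self.center}")
        if self.true_label not in (0, 1):
            raise ValueError("true_label must be 0 or 1")


@dataclass
class NoduleAnnotation:
    """What a reader module needs about a nodule: where it is and its ratings."""

    nodule_id: str
    patient_id: str
    center: tuple[int, int, int]
    bbox: tuple[int, int, int, int, int, int]
    ratings: list[int] = field(default_factory=list)

    @classmethod
    def from_truth(cls, gt: NoduleGroundTruth) -> "NoduleAnnotation":
        return cls(gt.nodule_id, gt.patient_id, gt.center, gt.bbox, list(gt.ratings))


@dataclass
class Patch3D:
    """One nodule patch at one scale: 3 axial slices of size out x out."""

    values: np.ndarray                # (3, H, W)
    scale_index: int                  # 1, 2 or 3

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != 3:
            raise ValueError(f"Patch3D.values must be (3, H, W), got {self.values.shape}")
        if self.scale_index not in (1, 2, 3):
            raise ValueError("scale_index must be 1, 2 or 3")


@dataclass
class MultiScalePatch:
    """Aligned triple of patches for one nodule, sharing a single label.

    ``label`` is 0 (benign), 1 (malignant) or None for nodules whose
    rater-averaged rating is indeterminate and which are excluded from
    training and scoring but kept for confidence analysis.
    """

    scale1: Patch3D
    scale2: Patch3D
    scale3: Patch3D
    nodule_id: str
    label: int | None = None

    @property
    def patches(self) -> tuple[Patch3D, Patch3D, Patch3D]:
        return (self.scale1, self.scale2, self.scale3)
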