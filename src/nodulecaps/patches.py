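"""Three-scale 3D nodule patch extraction.

Each nodule yields three aligned patches built from its central axial slice
and the two immediate z-neighbours. Scale 1 crops the annotated bounding box
exactly and zero-pads to 80x80; scale 2 adds a 10-pixel margin per side and
pads to 100x100; scale 3 adds 20 pixels and pads to 120x120. Scales 2 and 3
are then bilinearly down-sampled to the common 80x80 grid so all scales are
comparable, and every patch is min-max normalized to [0, 1].

Down-sampling is separable linear interpolation (one axis, then the other)
with output sample centers on the align-corners-false grid
``(i + 0.5) * n_in / n_out - 0.5``, clamped at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CTVolume, MultiScalePatch, NoduleAnnotation, Patch3D
from .errors import ExtractionError


@dataclass(frozen=True)
class ScaleSpec:
    """Margin, pre-down-sampling pad size and output size for one scale."""

    margin_px: int
    pad_to: int
    out_size: int = 80

    def __post_init__(self) -> None:
        if self.margin_px < 0:
            raise ValueError("margin_px must be >= 0")
        if self.pad_to < self.out_size or self.out_size < 1:
            raise ValueError("need pad_to >= out_size >= 1")


def default_scale_specs(out_size: int = 80) -> tuple[ScaleSpec, ScaleSpec, ScaleSpec]:
    """The three canonical scales: margins 0/10/20, pads 80/100/120."""
    return (
        ScaleSpec(0, 80, out_size),
        ScaleSpec(10, 100, out_size),
        ScaleSpec(20, 120, out_size),
    )


def _axis_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) linear-interpolation matrix for one axis."""
    pos = np.clip((np.arange(n_out) + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    w = np.zeros((n_out, n_in))
    np.add.at(w, (np.arange(n_out), lo), 1.0 - frac)
    np.add.at(w, (np.arange(n_out), hi), frac)
    return w


def bilinear_downsample(img: np.ndarray, out: tuple[int, int]) -> np.ndarray:
    """Separable linear down-sampling of a 2D image to shape ``out``.

    Exact on images that are linear in the pixel coordinates; raises on an
    up-sampling request, which is outside this function's contract.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("bilinear_downsample expects a 2D array")
    h, w = out
    if h > img.shape[0] or w > img.shape[1]:
        raise ValueError(
            f"requested output {out} exceeds input {img.shape}; this is a down-sampler"
        )
    return _axis_weights(img.shape[0], h) @ img @ _axis_weights(img.shape[1], w).T


def _pad_centered(img: np.ndarray, size: int) -> np.ndarray:
    """Zero-pad to size x size, centered; odd remainders go to the high side."""
    py, px = size - img.shape[0], size - img.shape[1]
    return np.pad(img, ((py // 2, py - py // 2), (px // 2, px - px // 2)))


def extract_patch(vol: CTVolume, ann: NoduleAnnotation, spec: ScaleSpec,
                  scale_index: int = 1) -> Patch3D:
    """Crop, pad and down-sample one nodule at one scale.

    The annotated in-plane bounding box is expanded by ``margin_px`` per
    side on the central slice and its two immediate z-neighbours, zero-padded
    (centered) to ``pad_to`` and down-sampled to ``out_size`` if needed.
    """
    x0, x1, y0, y1, _, _ = ann.bbox
    cz = ann.center[2]
    nx, ny, nz = vol.shape
    if cz - 1 < 0 or cz + 1 >= nz:
        raise ExtractionError(
            f"nodule {ann.nodule_id}: central slice {cz} lacks a z-neighbour in "
            f"a volume of {nz} slices"
        )
    ex0, ex1 = x0 - spec.margin_px, x1 + spec.margin_px
    ey0, ey1 = y0 - spec.margin_px, y1 + spec.margin_px
    if ex0 < 0 or ey0 < 0 or ex1 > nx or ey1 > ny:
        raise ExtractionError(
            f"nodule {ann.nodule_id}: crop [{ex0}:{ex1}, {ey0}:{ey1}] with margin "
            f"{spec.margin_px} exceeds the {nx}x{ny} slice bounds"
        )
    if ex1 - ex0 > spec.pad_to or ey1 - ey0 > spec.pad_to:
        raise ExtractionError(
            f"nodule {ann.nodule_id}: extent {(ex1 - ex0, ey1 - ey0)} exceeds the "
            f"padded size {spec.pad_to}"
        )
    slices = []
    for z in (cz - 1, cz, cz + 1):
        crop = np.asarray(vol.voxels[ex0:ex1, ey0:ey1, z], dtype=float)
        padded = _pad_centered(crop, spec.pad_to)
        if spec.pad_to > spec.out_size:
            padded = bilinear_downsample(padded, (spec.out_size, spec.out_size))
        slices.append(padded)
    return Patch3D(np.stack(slices), scale_index=scale_index)


def normalize_unit(p: Patch3D) -> Patch3D:
    """Min-max scale a patch to [0, 1]; a constant patch maps to all zeros."""
    v = p.values
    if not np.all(np.isfinite(v)):
        raise ValueError("patch contains non-finite values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return Patch3D(np.zeros_like(v), p.scale_index)
    return Patch3D((v - lo) / (hi - lo), p.scale_index)


def extract_multiscale(
    vol: CTVolume,
    ann: NoduleAnnotation,
    specs: tuple[ScaleSpec, ScaleSpec, ScaleSpec] | None = None,
    label: int | None = None,
    normalize: bool = True,
) -> MultiScalePatch:
    """Extract the aligned three-scale patch triple for one nodule."""
    specs = specs if specs is not None else default_scale_specs()
    out = []
    for i, spec in enumerate(specs, start=1):
        patch = extract_patch(vol, ann, spec, scale_index=i)
        out.append(normalize_unit(patch) if normalize else patch)
    return MultiScalePatch(out[0], out[1], out[2], nodule_id=ann.nodule_id, label=label)


_FLIPS = ((False, False), (True, False), (False, True), (True, True))


def _apply_flip(p: Patch3D, flip_rows: bool, flip_cols: bool) -> Patch3D:
    v = p.values
    if flip_rows:
        v = np.flip(v, axis=1)
    if flip_cols:
        v = np.flip(v, axis=2)
    return Patch3D(v.copy(), p.scale_index)


def flip_multiscale(p: MultiScalePatch, flip_rows: bool, flip_cols: bool) -> MultiScalePatch:
    """Apply one in-plane flip identically to all scales and slices."""
    s1, s2, s3 = (_apply_flip(s, flip_rows, flip_cols) for s in p.patches)
    return MultiScalePatch(s1, s2, s3, nodule_id=p.nodule_id, label=p.label)


def random_flip(p: MultiScalePatch, rng_seed: int) -> MultiScalePatch:
    """Draw one of {identity, row flip, column flip, both} uniformly, seeded."""
    rng = np.random.default_rng(rng_seed)
    fr, fc = _FLIPS[int(rng.integers(0, 4))]
    return flip_multiscale(p, fr, fc)


def all_flips(p: MultiScalePatch) -> list[MultiScalePatch]:
    """The four deterministic flip variants, used for training augmentation."""
    return [flip_multiscale(p, fr, fc) for fr, fc in _FLIPS]
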