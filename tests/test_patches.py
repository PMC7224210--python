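"""Patch extraction: crops, padding, bilinear down-sampling, normalization."""

import numpy as np
import pytest

from nodulecaps.containers import CTVolume, NoduleAnnotation, Patch3D
from nodulecaps.errors import ExtractionError
from nodulecaps.patches import (
    ScaleSpec,
    all_flips,
    bilinear_downsample,
    default_scale_specs,
    extract_multiscale,
    extract_patch,
    flip_multiscale,
    normalize_unit,
    random_flip,
)


def _downsample_oracle(img: np.ndarray, out: tuple[int, int]) -> np.ndarray:
    """Brute-force two-pass separable linear interpolation, pixel by pixel."""
    def one_axis(a: np.ndarray, n_out: int) -> np.ndarray:
        n_in = a.shape[0]
        res = np.empty((n_out,) + a.shape[1:])
        for i in range(n_out):
            p = min(max((i + 0.5) * n_in / n_out - 0.5, 0.0), n_in - 1.0)
            lo = int(np.floor(p))
            hi = min(lo + 1, n_in - 1)
            f = p - lo
            res[i] = (1 - f) * a[lo] + f * a[hi]
        return res

    return one_axis(one_axis(img, out[0]).T, out[1]).T


def _volume_with_box(box_value=1.0, shape=(160, 160, 32), bbox=(60, 100, 60, 100)):
    vox = np.zeros(shape, dtype=float)
    x0, x1, y0, y1 = bbox
    vox[x0:x1, y0:y1, 14:19] = box_value
    vol = CTVolume(vox, patient_id="p")
    ann = NoduleAnnotation("n", "p", center=(80, 80, 16), bbox=(x0, x1, y0, y1, 14, 19))
    return vol, ann


class TestBilinearDownsample:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            img = rng.standard_normal((6, 6))
            np.testing.assert_allclose(
                bilinear_downsample(img, (4, 4)), _downsample_oracle(img, (4, 4)),
                atol=1e-12,
            )

    def test_rectangular_sizes_against_oracle(self, rng):
        img = rng.standard_normal((10, 7))
        np.testing.assert_allclose(
            bilinear_downsample(img, (5, 6)), _downsample_oracle(img, (5, 6)), atol=1e-12
        )

    def test_constant_preserved(self):
        img = np.full((100, 100), 3.25)
        out = bilinear_downsample(img, (80, 80))
        np.testing.assert_allclose(out, 3.25, atol=1e-12)

    def test_exact_on_coordinate_ramp(self):
        # output samples of f(x) = x sit exactly on the (clamped) sample grid
        img = np.tile(np.arange(100.0), (100, 1)).T
        out = bilinear_downsample(img, (80, 100))
        expected = np.clip((np.arange(80) + 0.5) * 100 / 80 - 0.5, 0, 99)
        np.testing.assert_allclose(out[:, 0], expected, atol=1e-12)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="down-sampler"):
            bilinear_downsample(np.zeros((4, 4)), (8, 4))


class TestExtraction:
    def test_scale1_pads_to_80_with_zero_border(self):
        vol, ann = _volume_with_box()
        p = extract_patch(vol, ann, ScaleSpec(0, 80, 80))
        assert p.values.shape == (3, 80, 80)
        assert np.all(p.values[:, :20, :] == 0) and np.all(p.values[:, :, -20:] == 0)
        assert np.all(p.values[:, 20:60, 20:60] == 1.0)

    def test_scale2_crop_pad_downsample_chain(self):
        vol, ann = _volume_with_box()
        p = extract_patch(vol, ann, ScaleSpec(10, 100, 80))
        assert p.values.shape == (3, 80, 80)
        # 40px box + 2*10 margin = 60px crop inside 100 -> downsampled by 0.8
        assert p.values[1].sum() > 0

    def test_all_zero_volume_gives_all_zero_patches(self):
        vol, ann = _volume_with_box(box_value=0.0)
        for spec in default_scale_specs():
            assert not extract_patch(vol, ann, spec).values.any()

    def test_default_specs_give_3x80x80_triple(self):
        vol, ann = _volume_with_box()
        msp = extract_multiscale(vol, ann, label=1)
        for p in msp.patches:
            assert p.values.shape == (3, 80, 80)
        assert msp.label == 1

    def test_context_ring_visible_only_at_coarse_scale(self):
        vol, ann = _volume_with_box(bbox=(72, 89, 72, 89))
        x, y, z = np.meshgrid(
            np.arange(160.0) - 80, np.arange(160.0) - 80, np.arange(32.0) - 16,
            indexing="ij",
        )
        shell = np.abs(np.sqrt(x**2 + y**2 + z**2) - 20) < 1.0
        vol.voxels[shell] = 0.5
        s1 = extract_patch(vol, ann, ScaleSpec(0, 80, 80))
        s3 = extract_patch(vol, ann, ScaleSpec(20, 120, 80))
        # the tight crop sees only box (1.0) and background (0.0)
        assert set(np.unique(s1.values)) <= {0.0, 1.0}
        # the coarse crop contains the (down-sampled, hence blurred) ring
        assert ((s3.values > 0.1) & (s3.values < 0.9)).sum() > 20

    def test_crop_outside_bounds_raises(self):
        vol, ann = _volume_with_box(bbox=(0, 40, 0, 40))
        with pytest.raises(ExtractionError, match="exceeds"):
            extract_patch(vol, ann, ScaleSpec(10, 100, 80))

    def test_oversize_nodule_names_nodule(self):
        vol, ann = _volume_with_box(bbox=(30, 130, 30, 130))
        with pytest.raises(ExtractionError, match="n"):
            extract_patch(vol, ann, ScaleSpec(0, 80, 80))

    def test_missing_z_neighbour_raises(self):
        vox = np.zeros((60, 60, 5))
        vol = CTVolume(vox, patient_id="p")
        ann = NoduleAnnotation("edge", "p", center=(30, 30, 0), bbox=(20, 40, 20, 40, 0, 2))
        with pytest.raises(ExtractionError, match="z-neighbour"):
            extract_patch(vol, ann, ScaleSpec(0, 80, 80))

    def test_nested_fields_of_view(self):
        # a marker 5px outside the bbox is invisible at scale 1, visible at 2 and 3
        vol, ann = _volume_with_box(bbox=(70, 91, 70, 91))
        vol.voxels[65, 80, 16] = 9.0
        raw = [
            extract_patch(vol, ann, spec) for spec in default_scale_specs()
        ]
        assert raw[0].values.max() < 9.0
        assert raw[1].values.max() > 5.0 and raw[2].values.max() > 5.0


class TestNormalize:
    def test_min_max_closed_form(self):
        p = Patch3D(np.array([[[0.0, 50.0], [100.0, 50.0]]] * 3), 1)
        out = normalize_unit(p)
        np.testing.assert_allclose(out.values[0], [[0.0, 0.5], [1.0, 0.5]])

    def test_constant_patch_maps_to_zero(self):
        p = Patch3D(np.full((3, 4, 4), 7.0), 1)
        assert not normalize_unit(p).values.any()

    def test_idempotent_and_order_preserving(self, rng):
        p = Patch3D(rng.standard_normal((3, 8, 8)), 2)
        once = normalize_unit(p)
        twice = normalize_unit(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-15)
        assert once.values.min() == 0.0 and once.values.max() == 1.0
        flat_in, flat_out = p.values.ravel(), once.values.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= 0)

    def test_non_finite_rejected(self):
        p = Patch3D(np.full((3, 2, 2), np.nan), 1)
        with pytest.raises(ValueError):
            normalize_unit(p)


class TestFlips:
    def _patch(self, rng):
        vol, ann = _volume_with_box()
        vol.voxels += rng.standard_normal(vol.voxels.shape) * 0.1
        return extract_multiscale(vol, ann, label=0)

    def test_seeded_determinism(self, rng):
        msp = self._patch(rng)
        a, b = random_flip(msp, 99), random_flip(msp, 99)
        for pa, pb in zip(a.patches, b.patches):
            np.testing.assert_array_equal(pa.values, pb.values)

    def test_involution(self, rng):
        msp = self._patch(rng)
        flipped = flip_multiscale(msp, True, True)
        back = flip_multiscale(flipped, True, True)
        for pa, pb in zip(msp.patches, back.patches):
            np.testing.assert_array_equal(pa.values, pb.values)

    def test_flip_preserves_multiset_and_label(self, rng):
        msp = self._patch(rng)
        for variant in all_flips(msp):
            assert variant.label == msp.label
            for pa, pb in zip(msp.patches, variant.patches):
                np.testing.assert_allclose(
                    np.sort(pa.values.ravel()), np.sort(pb.values.ravel())
                )

    def test_same_flip_across_scales(self, rng):
        msp = self._patch(rng)
        flipped = flip_multiscale(msp, True, False)
        for orig, flip in zip(msp.patches, flipped.patches):
            np.testing.assert_array_equal(flip.values, orig.values[:, ::-1, :])
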