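"""Overlap geometry, constrained center sampling, and patch extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofactor.atlas import BinaryMask, ROISpec
from neurofactor.sampling import (
    GeometryError,
    SamplingConfig,
    SamplingError,
    extract_patch,
    extract_subject_patches,
    max_overlap_for_roi,
    overlap_fraction,
    sample_patch_centers,
)


def brute_force_overlap(a, b, size):
    """Oracle: explicit voxel-set intersection of two cubes."""
    half = size // 2

    def voxels(c):
        return {
            (x, y, z)
            for x in range(c[0] - half, c[0] - half + size)
            for y in range(c[1] - half, c[1] - half + size)
            for z in range(c[2] - half, c[2] - half + size)
        }

    return len(voxels(a) & voxels(b)) / size**3


def _mask_from_array(arr, abbrev="T01"):
    roi = ROISpec(abbrev, "test region", "left", frozenset({1}), "g")
    return BinaryMask(mask=np.asarray(arr, dtype=bool), roi=roi)


class TestOverlapFraction:
    @pytest.mark.parametrize("a,b,size,expected", [
        ((10, 10, 10), (10, 10, 10), 32, 1.0),     # identical centers
        ((0, 0, 0), (32, 0, 0), 32, 0.0),          # disjoint cubes
        ((0, 0, 0), (16, 0, 0), 32, 0.5),          # half overlap on one axis
    ])
    def test_exact_cases(self, a, b, size, expected):
        assert overlap_fraction(a, b, size) == expected

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            size = int(rng.integers(2, 9))
            a = rng.integers(0, 12, 3)
            b = rng.integers(0, 12, 3)
            assert overlap_fraction(a, b, size) == pytest.approx(
                brute_force_overlap(tuple(a), tuple(b), size), abs=1e-12)

    @given(st.tuples(*[st.integers(-50, 50)] * 3), st.tuples(*[st.integers(-50, 50)] * 3),
           st.integers(1, 40))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_symmetry_and_identity(self, a, b, size):
        assert overlap_fraction(a, b, size) == overlap_fraction(b, a, size)
        assert overlap_fraction(a, a, size) == 1.0


class TestOverlapCap:
    def test_bounds_at_size_extremes(self):
        cfg = SamplingConfig()
        assert max_overlap_for_roi(100, cfg, size_range=(100, 5000)) == 0.50
        assert max_overlap_for_roi(5000, cfg, size_range=(100, 5000)) == 0.75

    def test_equal_sizes_equal_caps(self):
        cfg = SamplingConfig()
        a = max_overlap_for_roi(700, cfg, size_range=(100, 5000))
        b = max_overlap_for_roi(700, cfg, size_range=(100, 5000))
        assert a == b

    def test_monotone_in_voxel_count(self):
        cfg = SamplingConfig()
        caps = [max_overlap_for_roi(n, cfg, size_range=(10, 10000))
                for n in (10, 100, 1000, 5000, 10000)]
        assert caps == sorted(caps)
        assert all(0.50 <= c <= 0.75 for c in caps)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            max_overlap_for_roi(0, SamplingConfig())


class TestSampleCenters:
    def _blob_mask(self, shape=(40, 40, 40), radius=10):
        g = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
        c = [(s - 1) / 2 for s in shape]
        d = sum((gi - ci) ** 2 for gi, ci in zip(g, c))
        return _mask_from_array(d <= radius**2)

    def test_default_count_is_five(self, rng):
        mask = self._blob_mask()
        cfg = SamplingConfig(patch_size=16, max_attempts=500)
        centers = sample_patch_centers(mask, (40, 40, 40), cfg, rng, max_overlap=0.75)
        assert len(centers) == 5
        for c in centers:
            assert mask.mask[c.sampled_center]

    def test_single_patch_needs_no_constraint(self, rng):
        mask = _mask_from_array(np.ones((20, 20, 20), dtype=bool))
        cfg = SamplingConfig(patch_size=16, patches_per_roi=1)
        centers = sample_patch_centers(mask, (20, 20, 20), cfg, rng)
        assert len(centers) == 1

    def test_pairwise_overlaps_below_cap_brute_force(self, rng):
        mask = self._blob_mask()
        cfg = SamplingConfig(patch_size=16, max_attempts=2000)
        centers = sample_patch_centers(mask, (40, 40, 40), cfg, rng, max_overlap=0.75)
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                ov = brute_force_overlap(centers[i].center, centers[j].center, 16)
                assert ov <= 0.75 + 1e-12

    def test_seed_determinism(self):
        mask = self._blob_mask()
        cfg = SamplingConfig(patch_size=16, max_attempts=500)
        a = sample_patch_centers(mask, (40, 40, 40), cfg,
                                 np.random.default_rng(5), max_overlap=0.6)
        b = sample_patch_centers(mask, (40, 40, 40), cfg,
                                 np.random.default_rng(5), max_overlap=0.6)
        assert [c.center for c in a] == [c.center for c in b]

    def test_infeasible_roi_reports_its_name(self, rng):
        mask_arr = np.zeros((40, 40, 40), dtype=bool)
        mask_arr[20, 20, 20] = True  # single voxel cannot host 5 distinct cubes
        cfg = SamplingConfig(patch_size=16, max_attempts=50)
        with pytest.raises(SamplingError, match="T01"):
            sample_patch_centers(_mask_from_array(mask_arr), (40, 40, 40), cfg, rng,
                                 max_overlap=0.5)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(SamplingError):
            sample_patch_centers(_mask_from_array(np.zeros((20, 20, 20))),
                                 (20, 20, 20), SamplingConfig(patch_size=8), rng)

    def test_random_masks_satisfy_contract(self, rng):
        """100 random synthetic masks: in-mask centers, caps verified by oracle."""
        cfg = SamplingConfig(patch_size=8, patches_per_roi=3, max_attempts=500)
        for _ in range(100):
            shape = tuple(int(s) for s in rng.integers(16, 33, 3))
            arr = np.zeros(shape, dtype=bool)
            lo = [int(rng.integers(0, s - 6)) for s in shape]
            ext = [int(rng.integers(4, min(10, s - l))) for s, l in zip(shape, lo)]
            arr[lo[0]:lo[0] + ext[0], lo[1]:lo[1] + ext[1], lo[2]:lo[2] + ext[2]] = True
            mask = _mask_from_array(arr)
            centers = sample_patch_centers(mask, shape, cfg, rng, max_overlap=0.75)
            assert len(centers) == 3
            for c in centers:
                assert mask.mask[c.sampled_center]
            active_cap = centers[0].overlap_cap
            assert active_cap >= 0.75
            for i, a in enumerate(centers):
                for b in centers[i + 1:]:
                    assert brute_force_overlap(a.center, b.center, 8) <= active_cap + 1e-12


class TestExtractPatch:
    def _center(self, c, subject="S1", roi="T01"):
        from neurofactor.sampling import PatchCenter

        return PatchCenter(subject_id=subject, roi_abbreviation=roi, center=c)

    def test_constant_volume_normalizes_to_zero(self):
        vol = np.full((24, 24, 24), 7.0)
        cfg = SamplingConfig(patch_size=8)
        patch = extract_patch(vol, self._center((12, 12, 12)), cfg)
        assert patch.values.shape == (8, 8, 8)
        assert np.allclose(patch.values, 0.0)

    def test_boundary_center_is_clamped_and_recorded(self, rng):
        vol = rng.standard_normal((24, 24, 24))
        cfg = SamplingConfig(patch_size=16)
        patch = extract_patch(vol, self._center((1, 12, 23)), cfg)
        assert patch.values.shape == (16, 16, 16)
        assert patch.center.clamped
        # cube spans [c-8, c+8): valid centers lie in [8, 16] on a 24-axis
        assert patch.center.center == (8, 12, 16)

    def test_patch_matches_manual_slice(self, rng):
        vol = rng.standard_normal((32, 32, 32)).astype(np.float32)
        cfg = SamplingConfig(patch_size=8)
        patch = extract_patch(vol, self._center((16, 10, 20)), cfg)
        norm = (vol - vol.mean()) / vol.std()
        assert np.allclose(patch.values, norm[12:20, 6:14, 16:24], atol=1e-6)

    def test_volume_smaller_than_patch_rejected(self, rng):
        with pytest.raises(GeometryError):
            extract_patch(rng.standard_normal((8, 8, 8)), self._center((4, 4, 4)),
                          SamplingConfig(patch_size=16))


class TestExtractSubjectPatches:
    def test_count_is_rois_times_patches(self, tiny_atlas, tiny_sampling_config, rng):
        vol = rng.standard_normal(tiny_atlas.shape)
        patches = extract_subject_patches(vol, tiny_atlas, tiny_sampling_config,
                                          np.random.default_rng(0), subject_id="S1")
        assert len(patches) == tiny_atlas.n_rois * tiny_sampling_config.patches_per_roi
        rois = {p.center.roi_abbreviation for p in patches}
        assert rois == {r.abbreviation for r in tiny_atlas.roi_table}

    def test_same_seed_identical_centers(self, tiny_atlas, tiny_sampling_config, rng):
        vol = rng.standard_normal(tiny_atlas.shape)
        a = extract_subject_patches(vol, tiny_atlas, tiny_sampling_config,
                                    np.random.default_rng(3))
        b = extract_subject_patches(vol, tiny_atlas, tiny_sampling_config,
                                    np.random.default_rng(3))
        assert [p.center.center for p in a] == [p.center.center for p in b]

    def test_shape_mismatch_rejected(self, tiny_atlas, tiny_sampling_config, rng):
        with pytest.raises(GeometryError):
            extract_subject_patches(rng.standard_normal((10, 10, 10)), tiny_atlas,
                                    tiny_sampling_config, rng)
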