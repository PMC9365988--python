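"""Atlas splitting, mask warping, boundary refinement and recombination."""

import itertools

import numpy as np
import pytest

from ratparc import atlas_ops as ao
from ratparc import phantom as ph
from ratparc.errors import EmptyAtlasError, GeometryError
from ratparc.evaluation import dice
from ratparc.image_core import BinaryMask, LabelAtlas, Series4D, Volume3D
from ratparc.transforms import AffineTransform


def _atlas(labels: np.ndarray) -> LabelAtlas:
    lut = {int(i): f"roi_{i}" for i in np.unique(labels) if i != 0}
    return LabelAtlas(Volume3D(labels.astype(np.int32), np.eye(4)), lut)


def _mask(arr: np.ndarray, idx: int = 1) -> BinaryMask:
    return BinaryMask(Volume3D(arr.astype(np.uint8), np.eye(4)), source_index=idx)


class TestSplitAtlas:
    def test_three_labels_give_three_binary_masks(self, rng):
        labels = rng.integers(0, 4, size=(8, 8, 4))
        masks = ao.split_atlas(_atlas(labels))
        assert len(masks) == 3
        for m in masks:
            assert set(np.unique(m.array)) <= {0, 1}

    def test_66_label_atlas_gives_66_masks(self):
        spec = ph.PhantomSpec(seed=5, n_rois=66)
        _, atlas, _, _ = ph.make_template(spec)
        masks = ao.split_atlas(atlas)
        assert len(masks) == 66

    def test_union_equals_support_and_masks_disjoint(self, rng):
        labels = rng.integers(0, 6, size=(10, 10, 6))
        atlas = _atlas(labels)
        masks = ao.split_atlas(atlas)
        union = np.zeros(labels.shape, dtype=int)
        for m in masks:
            union += m.array
        assert union.max() == 1  # pairwise disjoint
        np.testing.assert_array_equal(union > 0, labels > 0)
        for m in masks:  # voxel-count oracle
            assert m.voxel_count == int((labels == m.source_index).sum())

    def test_empty_atlas_rejected(self):
        with pytest.raises(EmptyAtlasError):
            ao.split_atlas(_atlas(np.zeros((4, 4, 4))))


class TestWarpMask:
    def test_identity_reproduces_mask(self, rng):
        arr = rng.integers(0, 2, size=(10, 10, 6))
        m = _mask(arr)
        fz = ao.warp_mask(m, AffineTransform.identity(), target=m.data)
        np.testing.assert_allclose(fz.data.data, arr, atol=1e-6)

    def test_integer_translation_shifts_mask(self):
        arr = np.zeros((12, 12, 6))
        arr[4:8, 4:8, 2:4] = 1
        m = _mask(arr)
        t = np.eye(4)
        t[0, 3] = 2.0  # individual -> standard: +2 mm = +2 voxels
        fz = ao.warp_mask(m, AffineTransform(t), target=m.data)
        vals = fz.data.data
        assert np.abs(vals[2:6, 4:8, 2:4] - 1).max() < 1e-6
        assert np.abs(vals[8:, :, :]).max() < 1e-6

    def test_half_voxel_shift_gives_intermediate_boundary(self):
        arr = np.zeros((16, 8, 8))
        arr[4:12] = 1.0  # slab
        m = _mask(arr)
        t = np.eye(4)
        t[0, 3] = 0.5
        fz = ao.warp_mask(m, AffineTransform(t), target=m.data)
        boundary = fz.data.data[3, 4, 4]  # half in, half out
        assert 0.0 < boundary < 1.0

    def test_geometry_mismatch_rejected(self, small_bundle):
        m = _mask(np.ones((4, 4, 4)))
        with pytest.raises(GeometryError):
            ao.warp_mask(m, small_bundle.truth_inverse, target=m.data)

    def test_affine_without_target_rejected(self):
        with pytest.raises(GeometryError):
            ao.warp_mask(_mask(np.ones((4, 4, 4))), AffineTransform.identity())


class TestBinarize:
    def test_high_membership_everywhere(self):
        fz = ao.FuzzyMask(Volume3D(np.full((4, 4, 4), 0.9), np.eye(4)), 1)
        assert ao.binarize(fz).array.min() == 1

    def test_threshold_semantics(self):
        vals = np.array([0.49, 0.5, 0.51]).reshape(3, 1, 1)
        fz = ao.FuzzyMask(Volume3D(vals, np.eye(4)), 1)
        np.testing.assert_array_equal(ao.binarize(fz).array.ravel(), [0, 1, 1])

    def test_identity_roundtrip(self, rng):
        arr = rng.integers(0, 2, size=(8, 8, 6))
        m = _mask(arr)
        fz = ao.warp_mask(m, AffineTransform.identity(), target=m.data)
        np.testing.assert_array_equal(ao.binarize(fz).array, arr)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_threshold_range(self, bad):
        fz = ao.FuzzyMask(Volume3D(np.zeros((2, 2, 2)), np.eye(4)), 1)
        with pytest.raises(ValueError):
            ao.binarize(fz, threshold=bad)


def brute_force_opening(arr: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Exhaustive erosion-then-dilation by explicit structuring-element scans."""
    offs = np.argwhere(element) - (np.array(element.shape) - 1) // 2
    shape = arr.shape

    def inside(p):
        return all(0 <= p[a] < shape[a] for a in range(3))

    # border counts as empty for erosion (scipy border_value=0)
    eroded = np.zeros_like(arr)
    for p in itertools.product(*map(range, shape)):
        eroded[p] = all(inside(p + o) and arr[tuple(p + o)] for o in offs)
    dilated = np.zeros_like(arr)
    for p in itertools.product(*map(range, shape)):
        dilated[p] = any(inside(p + o) and eroded[tuple(p + o)] for o in offs)
    return dilated


class TestRefineBoundary:
    def test_empty_mask_stays_empty(self):
        m = _mask(np.zeros((6, 6, 4)))
        assert ao.refine_boundary(m).voxel_count == 0

    @pytest.mark.parametrize("element", ["disc2D", "ball3D"])
    def test_isolated_voxel_removed(self, element):
        arr = np.zeros((3, 3, 3))
        arr[1, 1, 1] = 1
        assert ao.refine_boundary(_mask(arr), element=element).voxel_count == 0

    @pytest.mark.parametrize("element", ["disc2D", "ball3D"])
    def test_matches_exhaustive_oracle(self, rng, element):
        st = ao.structuring_element(element)
        for _ in range(5):
            arr = (rng.random((7, 7, 3)) > 0.4).astype(np.uint8)
            got = ao.refine_boundary(_mask(arr), element=element).array
            want = brute_force_opening(arr, st).astype(np.uint8)
            np.testing.assert_array_equal(got, want)

    def test_solid_block(self):
        arr = np.zeros((9, 9, 5))
        arr[1:8, 1:8, 1:4] = 1
        got = ao.refine_boundary(_mask(arr)).array
        want = brute_force_opening(arr, ao.structuring_element("disc2D"))
        np.testing.assert_array_equal(got, want.astype(np.uint8))

    def test_idempotent_and_bounded(self, rng):
        arr = (rng.random((10, 10, 6)) > 0.5).astype(np.uint8)
        once = ao.refine_boundary(_mask(arr))
        twice = ao.refine_boundary(once)
        np.testing.assert_array_equal(once.array, twice.array)
        # opening with a symmetric element is anti-extensive
        assert not np.any(once.array.astype(bool) & ~arr.astype(bool))


class TestCombine:
    def _fuzzy(self, arr, idx):
        return ao.FuzzyMask(Volume3D(np.asarray(arr, dtype=float), np.eye(4)), idx)

    def test_disjoint_masks_preserved(self):
        a = np.zeros((8, 8, 4))
        b = np.zeros((8, 8, 4))
        a[1:3, 1:3, 1:3] = 1
        b[5:7, 5:7, 1:3] = 1
        res = ao.combine_rois(
            [_mask(a, 3), _mask(b, 7)],
            [self._fuzzy(a, 3), self._fuzzy(b, 7)],
            {3: "x", 7: "y"},
        )
        assert set(np.unique(res.labels.data)) == {0, 3, 7}
        assert int((res.labels.data == 3).sum()) == int(a.sum())
        assert int((res.labels.data == 7).sum()) == int(b.sum())

    def test_conflict_goes_to_higher_membership(self):
        m = np.zeros((4, 4, 4))
        m[1, 1, 1] = 1
        f1, f2 = m * 0.9, m * 0.6
        res = ao.combine_rois(
            [_mask(m, 1), _mask(m, 2)],
            [self._fuzzy(f1, 1), self._fuzzy(f2, 2)],
            {1: "a", 2: "b"},
        )
        assert res.labels.data[1, 1, 1] == 1

    def test_membership_tie_goes_to_smaller_roi(self):
        big = np.zeros((10, 10, 4))
        big[0:5, 0:5, :] = 1  # 100 voxels
        small = np.zeros((10, 10, 4))
        small[4, 4, :] = 1  # 4 voxels, all contested
        fz = np.where(big + small > 0, 0.8, 0.0)
        res = ao.combine_rois(
            [_mask(big, 2), _mask(small, 9)],
            [self._fuzzy(np.where(big, 0.8, 0), 2), self._fuzzy(np.where(small, 0.8, 0), 9)],
            {2: "big", 9: "small"},
        )
        assert (res.labels.data[4, 4, :] == 9).all()

    def test_full_tie_goes_to_lower_index(self):
        m = np.zeros((4, 4, 4))
        m[1, 1, 1] = 1
        res = ao.combine_rois(
            [_mask(m, 5), _mask(m, 2)],
            [self._fuzzy(m * 0.7, 5), self._fuzzy(m * 0.7, 2)],
            {5: "a", 2: "b"},
        )
        assert res.labels.data[1, 1, 1] == 2

    def test_duplicate_indices_rejected(self):
        m = np.zeros((4, 4, 4))
        m[1, 1, 1] = 1
        with pytest.raises(ValueError):
            ao.combine_rois(
                [_mask(m, 1), _mask(m, 1)],
                [self._fuzzy(m, 1), self._fuzzy(m, 1)],
                {1: "a"},
            )

    def test_counts_never_exceed_refined(self, rng):
        masks, fuzz = [], []
        for idx in (1, 2, 3):
            arr = (rng.random((8, 8, 4)) > 0.6).astype(np.uint8)
            masks.append(_mask(arr, idx))
            fuzz.append(self._fuzzy(rng.random((8, 8, 4)) * arr, idx))
        res = ao.combine_rois(masks, fuzz, {1: "a", 2: "b", 3: "c"})
        for m in masks:
            final = int((res.labels.data == m.source_index).sum())
            assert final <= m.voxel_count
        row = res.per_roi.set_index("index")
        assert (row["voxel_count"] <= row["refined_count"]).all()


class TestParcellatePipeline:
    def test_identity_pipeline_reproduces_atlas(self):
        spec = ph.PhantomSpec(seed=3, n_rois=8, amplitude=0.0, noise_sd=0.0)
        tpl, atlas, _, _ = ph.make_template(spec)
        res = ao.parcellate_individual(
            tpl, None, atlas, transform=AffineTransform.identity()
        )
        for idx in atlas.indices:
            a = BinaryMask(tpl.with_data((res.labels.data == idx).astype(np.uint8)))
            b = BinaryMask(tpl.with_data((atlas.labels.data == idx).astype(np.uint8)))
            assert dice(a, b).value >= 0.95

    def test_known_warp_per_roi_dice(self, bundle8):
        # ground-truth inverse, registration bypassed
        b = bundle8
        res = ao.parcellate_individual(
            b.individual, None, b.atlas, transform=b.truth_forward
        )
        truth = b.truth_individual_labels.labels.data
        for idx in b.atlas.indices:
            if int((truth == idx).sum()) < 100:
                continue
            a = BinaryMask(b.individual.with_data((res.labels.data == idx).astype(np.uint8)))
            t = BinaryMask(b.individual.with_data((truth == idx).astype(np.uint8)))
            assert dice(a, t).value >= 0.9

    def test_series_input_equivalent_to_mean_volume(self, small_bundle):
        b = small_bundle
        series = Series4D([b.individual, b.individual])
        res_series = ao.parcellate_individual(
            series, None, b.atlas, transform=b.truth_forward
        )
        res_vol = ao.parcellate_individual(
            b.individual, None, b.atlas, transform=b.truth_forward
        )
        np.testing.assert_array_equal(res_series.labels.data, res_vol.labels.data)

    def test_tpm_path_recovers_brain_outline(self, small_bundle):
        b = small_bundle
        res = ao.parcellate_individual(
            b.individual, (b.individual_tpms, b.tpms), b.atlas, path="tpm"
        )
        assert dice(res.union_mask, b.truth_individual_brain).value >= 0.8

    def test_stage_name_in_errors(self, small_bundle):
        b = small_bundle
        empty = LabelAtlas(
            Volume3D(np.zeros(b.atlas.labels.shape, dtype=np.int32),
                     b.atlas.labels.affine), {}
        )
        with pytest.raises(EmptyAtlasError, match="stage: split"):
            ao.parcellate_individual(
                b.individual, None, empty, transform=b.truth_forward
            )
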