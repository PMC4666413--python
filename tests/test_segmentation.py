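import numpy as np
import pytest

from pvsquant import errors
from pvsquant.image_io import IntensityVolume
from pvsquant.intensity_adjust import AdjustmentParams, saturate_rescale_array
from pvsquant.segmentation import (
    CaseCharacteristics,
    SizeFilter,
    ThresholdPolicy,
    apply_threshold,
    filter_objects,
    label_objects,
    quantify,
    segment_case,
    select_threshold,
)
from pvsquant.synthetic import LacuneSpec, SyntheticSpec, generate_phantom

from .oracles import flood_fill_components

T2W_SPACING = (0.47, 0.47, 6.0)


class TestSelectThreshold:
    def test_benign_pattern_gets_low(self):
        chars = CaseCharacteristics(
            scattered_pvs=True, uniform_background=True, few_focal_lesions=True
        )
        policy = select_threshold(chars)
        assert policy.level == "low" and policy.fraction_of_max == 0.075

    @pytest.mark.parametrize(
        "flag", ["grouped_pvs", "high_background", "many_lesions", "poor_quality"]
    )
    def test_any_severe_flag_forces_high(self, flag):
        policy = select_threshold(CaseCharacteristics(**{flag: True}))
        assert policy.level == "high" and policy.fraction_of_max == 0.15

    def test_default_is_medium(self):
        policy = select_threshold(CaseCharacteristics())
        assert policy.level == "medium" and policy.fraction_of_max == 0.1125

    def test_severe_flag_overrides_benign_pattern(self):
        chars = CaseCharacteristics(
            scattered_pvs=True, uniform_background=True, few_focal_lesions=True,
            high_background=True,
        )
        assert select_threshold(chars).level == "high"

    def test_named_policy_fractions_are_pinned(self):
        with pytest.raises(ValueError):
            ThresholdPolicy("low", 0.1)
        with pytest.raises(ValueError):
            ThresholdPolicy("high", 0.10)
        assert ThresholdPolicy.named("high", 0.25).fraction_of_max == 0.25


class TestApplyThreshold:
    def _roi(self, shape):
        roi = np.zeros(shape, bool)
        roi[2:-2, 2:-2] = True
        return roi

    def test_tiny_fraction_recovers_roi_minus_exclusions(self):
        slice_ = np.full((8, 8), 10.0)
        roi = self._roi((8, 8))
        excl = np.zeros((8, 8), bool)
        excl[4, 4] = True
        policy = ThresholdPolicy.named("custom", 1e-9)
        mask = apply_threshold(slice_, roi, policy, excl)
        np.testing.assert_array_equal(mask, roi & ~excl)

    def test_fraction_one_keeps_only_out_max_pixels(self):
        slice_ = np.zeros((8, 8))
        slice_[3, 3] = 255.0
        slice_[4, 4] = 254.9
        mask = apply_threshold(slice_, self._roi((8, 8)), ThresholdPolicy.named("custom", 1.0))
        assert mask.sum() == 1 and mask[3, 3]

    def test_counts_pixels_at_or_above_threshold(self):
        slice_ = np.zeros((8, 8))
        coords = [(2, 2), (3, 5), (4, 4), (5, 2), (5, 5)]
        for r, c in coords:
            slice_[r, c] = 0.1125 * 255  # ties included (>= rule)
        slice_[2, 5] = 0.1124 * 255
        mask = apply_threshold(slice_, self._roi((8, 8)), ThresholdPolicy.named("medium"))
        assert mask.sum() == 5

    def test_shape_mismatch_raises(self):
        with pytest.raises(errors.ShapeMismatchError):
            apply_threshold(np.zeros((8, 8)), np.ones((9, 9), bool), ThresholdPolicy.named("low"))

    def test_empty_roi_raises(self):
        with pytest.raises(errors.EmptyMaskError):
            apply_threshold(np.zeros((8, 8)), np.zeros((8, 8), bool), ThresholdPolicy.named("low"))

    def test_candidate_masks_nest_across_thresholds(self, rng):
        roi = self._roi((32, 32))
        for _ in range(100):
            raw = rng.uniform(0, 1000, (32, 32))
            adjusted = saturate_rescale_array(raw, AdjustmentParams(0.01, 1.0, 255.0))
            masks = {
                level: apply_threshold(adjusted, roi, ThresholdPolicy.named(level))
                for level in ("low", "medium", "high")
            }
            assert np.all(masks["high"] <= masks["medium"])
            assert np.all(masks["medium"] <= masks["low"])


class TestLabelObjects:
    def test_empty_mask_gives_no_components(self):
        assert label_objects(np.zeros((5, 5), bool)) == []

    def test_diagonal_pair_depends_on_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_objects(mask, 8)) == 1
        assert len(label_objects(mask, 4)) == 2

    def test_three_disjoint_squares(self):
        mask = np.zeros((12, 12), bool)
        for r0 in (0, 4, 8):
            mask[r0 : r0 + 2, r0 : r0 + 2] = True
        comps = label_objects(mask, 8)
        assert len(comps) == 3
        assert all(c.shape[0] == 4 for c in comps)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_masks(self, rng, connectivity):
        for _ in range(500):
            mask = rng.random((32, 32)) < rng.uniform(0.05, 0.6)
            got = sorted(
                frozenset(map(tuple, comp.tolist())) for comp in label_objects(mask, connectivity)
            )
            want = sorted(frozenset(c) for c in flood_fill_components(mask, connectivity))
            assert got == want


class TestFilterAndQuantify:
    def test_single_pixel_kept_under_three_mm(self):
        comps = [np.array([[3, 3]])]
        records = filter_objects(comps, SizeFilter(), T2W_SPACING)
        assert len(records) == 1
        assert records[0].equivalent_diameter_mm == pytest.approx(0.530, abs=0.001)

    def test_sixty_pixel_blob_removed_as_over_three_mm(self):
        comps = [np.array([[r, c] for r in range(6) for c in range(10)])]
        # 60 px * 0.47^2 mm^2 -> equivalent diameter ~4.11 mm > 3 mm
        assert filter_objects(comps, SizeFilter(), T2W_SPACING) == []
        kept = filter_objects(comps, SizeFilter(max_equivalent_diameter_mm=5.0), T2W_SPACING)
        assert kept[0].equivalent_diameter_mm == pytest.approx(4.11, abs=0.01)

    def test_min_voxels_two_removes_singletons(self):
        comps = [np.array([[0, 0]]), np.array([[5, 5], [5, 6]])]
        records = filter_objects(comps, SizeFilter(min_voxels=2), T2W_SPACING)
        assert len(records) == 1 and records[0].voxel_count == 2

    def test_no_limits_is_identity(self, rng):
        comps = [
            np.argwhere(rng.random((20, 20)) < 0.2) for _ in range(5)
        ]
        comps = [c for c in comps if len(c)]
        records = filter_objects(comps, SizeFilter(1, np.inf), T2W_SPACING)
        assert [r.voxel_count for r in records] == [len(c) for c in comps]

    def test_record_geometry_invariants(self):
        comps = [np.array([[1, 1], [1, 2], [2, 1]])]
        rec = filter_objects(comps, SizeFilter(), T2W_SPACING)[0]
        assert rec.area_mm2 == pytest.approx(rec.voxel_count * 0.47 * 0.47)
        assert rec.equivalent_diameter_mm == pytest.approx(2 * np.sqrt(rec.area_mm2 / np.pi))
        assert rec.volume_ml == pytest.approx(rec.voxel_count * 0.47 * 0.47 * 6.0 / 1000.0)

    def test_quantify_totals(self):
        comps = [np.array([[r, c] for c in range(7)]) for r in range(10)]
        records = filter_objects(comps, SizeFilter(), T2W_SPACING)
        count, total, volumes = quantify(records)
        assert count == 10
        # 70 voxels at 0.47*0.47*6 mm^3 = 1.3254 mm^3 each
        assert total == pytest.approx(0.092778, abs=1e-6)
        assert len(volumes) == 10

    def test_quantify_empty(self):
        assert quantify([]) == (0, 0.0, [])

    def test_doubling_dz_doubles_volume_not_count(self):
        comps = [np.array([[0, 0], [0, 1]]), np.array([[5, 5]])]
        r1 = filter_objects(comps, SizeFilter(), (0.47, 0.47, 6.0))
        r2 = filter_objects(comps, SizeFilter(), (0.47, 0.47, 12.0))
        assert len(r1) == len(r2)
        assert quantify(r2)[1] == pytest.approx(2 * quantify(r1)[1])


@pytest.fixture(scope="module")
def phantom(default_roi):
    spec = SyntheticSpec(seed=42, n_pvs=12)
    volume, truth = generate_phantom(spec, default_roi)
    return spec, volume, truth


class TestSegmentCase:
    def test_recovers_planted_dot_count(self, phantom, default_roi):
        _, volume, truth = phantom
        result = segment_case(
            volume, 0, default_roi, policy=ThresholdPolicy.named("medium")
        )
        assert result.count == truth.n_pvs_true == 12
        assert result.total_volume_ml > 0
        assert result.provenance["connectivity"] == 8

    def test_exclusion_mask_removes_one_dot(self, phantom, default_roi):
        _, volume, truth = phantom
        excl = np.zeros(volume.shape[:2], bool)
        r, c = truth.dot_centers[0]
        excl[r - 4 : r + 5, c - 4 : c + 5] = True
        result = segment_case(
            volume, 0, default_roi, policy=ThresholdPolicy.named("medium"),
            exclusion_mask=excl,
        )
        assert result.count == 11

    def test_count_non_increasing_in_threshold(self, default_roi):
        volume, _ = generate_phantom(
            SyntheticSpec(seed=11, n_pvs=20), default_roi
        )
        # neutralise the diameter filter: at very permissive thresholds
        # footprints grow past 3 mm, which would remove (not merge) objects
        counts = []
        for frac in (0.05, 0.075, 0.1125, 0.15, 0.25, 0.5):
            res = segment_case(
                volume, 0, default_roi,
                policy=ThresholdPolicy.named("custom", frac),
                size_filter=SizeFilter(1, np.inf),
            )
            counts.append(res.count)
        assert counts == sorted(counts, reverse=True)

    def test_translation_invariance_of_count_and_volume(self, default_roi):
        volume, _ = generate_phantom(SyntheticSpec(seed=5, n_pvs=8), default_roi)
        res = segment_case(volume, 0, default_roi, policy=ThresholdPolicy.named("medium"))
        shift = 7
        shifted_img = np.roll(volume.data, shift, axis=0)
        shifted_vol = IntensityVolume(shifted_img, volume.spacing)
        shifted_roi = np.roll(default_roi.mask, shift, axis=0)
        res_shift = segment_case(
            shifted_vol, 0, shifted_roi, policy=ThresholdPolicy.named("medium")
        )
        assert res_shift.count == res.count
        assert res_shift.total_volume_ml == pytest.approx(res.total_volume_ml)

    def test_lacune_rejected_by_diameter_filter(self, default_roi):
        volume, truth = generate_phantom(
            SyntheticSpec(seed=3, n_pvs=5, lacunes=LacuneSpec(n=1)), default_roi
        )
        result = segment_case(volume, 0, default_roi, policy=ThresholdPolicy.named("medium"))
        assert result.count == 5
        lr, lc = truth.lacune_centers[0]
        for obj in result.objects:
            d = np.hypot((obj.centroid[0] - lr) * 0.47, (obj.centroid[1] - lc) * 0.47)
            assert d > 2.5

    def test_requires_policy_or_characteristics(self, phantom, default_roi):
        _, volume, _ = phantom
        with pytest.raises(ValueError):
            segment_case(volume, 0, default_roi)

    def test_score_attached_from_count(self, phantom, default_roi):
        _, volume, _ = phantom
        res = segment_case(volume, 0, default_roi, policy=ThresholdPolicy.named("medium"))
        assert res.score == 2  # 12 dots -> category 2 (11-20)
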