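import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwayfat import (
    DixonSet,
    LabelMask,
    VolumeImage,
    compute_fat_fraction_map,
    fat_fraction_histogram,
    mask_structure,
    tissue_fat_metrics,
)
from airwayfat.errors import EmptyStructureError, LabelError
from airwayfat.fat_fraction import fat_percent_ratio_of_sums, write_fat_fraction_map
from airwayfat.volume_io import read_volume
from conftest import random_dixon


def dixon_from_fw(fat, water, spacing=(1.0, 1.0, 1.0)):
    fat = np.asarray(fat, dtype=float)
    water = np.asarray(water, dtype=float)
    return DixonSet(
        in_phase=VolumeImage(fat + water, spacing),
        out_phase=VolumeImage(np.abs(water - fat), spacing),
        fat=VolumeImage(fat, spacing),
        water=VolumeImage(water, spacing),
    )


def full_mask(shape, structure="tongue", spacing=(1.0, 1.0, 1.0)):
    return LabelMask(np.ones(shape, dtype=np.int16), {structure: 1}, spacing)


class TestFatFractionMap:
    def test_single_voxel_ratio(self):
        dixon = dixon_from_fw(np.full((1, 1, 1), 30.0), np.full((1, 1, 1), 70.0))
        ffmap = compute_fat_fraction_map(dixon)
        assert ffmap.fraction[0, 0, 0] == pytest.approx(30.0)

    def test_zero_signal_voxel_undefined(self):
        dixon = dixon_from_fw(np.zeros((2, 1, 1)), np.zeros((2, 1, 1)))
        ffmap = compute_fat_fraction_map(dixon, background_threshold=0.0)
        assert not ffmap.defined_mask.any()
        assert np.isnan(ffmap.fraction).all()

    def test_matches_per_voxel_loop_oracle(self, rng):
        dixon = random_dixon(rng, shape=(4, 4, 4))
        ffmap = compute_fat_fraction_map(dixon)
        F, W = dixon.fat.data, dixon.water.data
        for idx in np.ndindex(*F.shape):
            expected = 100.0 * F[idx] / (F[idx] + W[idx])
            assert ffmap.fraction[idx] == expected  # exact: same fp operations

    def test_defined_fractions_bounded(self, rng):
        dixon = random_dixon(rng, shape=(6, 6, 6))
        ffmap = compute_fat_fraction_map(dixon)
        vals = ffmap.fraction[ffmap.defined_mask]
        assert np.all((vals >= 0.0) & (vals <= 100.0))

    def test_background_threshold_masks_low_signal(self):
        fat = np.array([[[1.0, 30.0]]])
        water = np.array([[[1.0, 70.0]]])
        ffmap = compute_fat_fraction_map(dixon_from_fw(fat, water), background_threshold=10.0)
        assert not ffmap.defined_mask[0, 0, 0]
        assert ffmap.defined_mask[0, 0, 1]

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_fat_percent_invariant_under_common_rescaling(self, scale):
        rng = np.random.default_rng(7)
        fat = rng.uniform(1, 50, (3, 3, 3))
        water = rng.uniform(1, 50, (3, 3, 3))
        mask = full_mask((3, 3, 3))
        base = tissue_fat_metrics(compute_fat_fraction_map(dixon_from_fw(fat, water)), mask, "tongue")
        scaled = tissue_fat_metrics(
            compute_fat_fraction_map(dixon_from_fw(fat * scale, water * scale)), mask, "tongue"
        )
        assert scaled.fat_percent == pytest.approx(base.fat_percent, abs=1e-9)

    def test_raising_fat_never_decreases_fractions(self, rng):
        fat = rng.uniform(1, 50, (4, 4, 4))
        water = rng.uniform(1, 50, (4, 4, 4))
        bump = rng.uniform(0, 10, (4, 4, 4))
        mask = full_mask((4, 4, 4))
        lo = compute_fat_fraction_map(dixon_from_fw(fat, water))
        hi = compute_fat_fraction_map(dixon_from_fw(fat + bump, water))
        assert np.all(hi.fraction >= lo.fraction - 1e-12)
        assert (
            tissue_fat_metrics(hi, mask, "tongue").fat_percent
            >= tissue_fat_metrics(lo, mask, "tongue").fat_percent
        )


class TestMaskStructure:
    def test_zero_voxel_structure_gives_empty_collection(self):
        mask = LabelMask(np.ones((3, 3, 3), dtype=np.int16), {"tongue": 1, "airway": 2})
        dixon = dixon_from_fw(np.ones((3, 3, 3)), np.ones((3, 3, 3)))
        voxels = mask_structure(compute_fat_fraction_map(dixon), mask, "airway")
        assert voxels.count == 0
        assert voxels.values.size == 0

    def test_full_structure_collects_every_voxel(self):
        mask = full_mask((3, 3, 3))
        dixon = dixon_from_fw(np.ones((3, 3, 3)), np.ones((3, 3, 3)))
        voxels = mask_structure(compute_fat_fraction_map(dixon), mask, "tongue")
        assert voxels.count == 27

    def test_unknown_structure_rejected(self):
        mask = full_mask((2, 2, 2))
        dixon = dixon_from_fw(np.ones((2, 2, 2)), np.ones((2, 2, 2)))
        with pytest.raises(LabelError):
            mask_structure(compute_fat_fraction_map(dixon), mask, "soft_palate")

    def test_phantom_counts_match_ground_truth(self, noiseless_phantom):
        dixon, mask, truth = noiseless_phantom
        ffmap = compute_fat_fraction_map(dixon)
        for name, count in truth.voxel_counts.items():
            assert mask_structure(ffmap, mask, name).count == count


class TestTissueFatMetrics:
    def test_uniform_quarter_fat_tissue(self):
        shape = (10, 10, 10)  # 1000 voxels at 1 mm^3
        dixon = dixon_from_fw(np.full(shape, 25.0), np.full(shape, 75.0))
        m = tissue_fat_metrics(compute_fat_fraction_map(dixon), full_mask(shape), "tongue")
        assert m.tissue_volume_cm3 == pytest.approx(1.0)
        assert m.fat_volume_cm3 == pytest.approx(0.25)
        assert m.fat_percent == pytest.approx(25.0)

    def test_two_voxel_extremes_average_to_half(self):
        fat = np.array([[[0.0, 100.0]]])
        water = np.array([[[100.0, 0.0]]])
        m = tissue_fat_metrics(compute_fat_fraction_map(dixon_from_fw(fat, water)), full_mask((1, 1, 2)), "tongue")
        assert m.fat_percent == pytest.approx(50.0)
        assert m.median_fat_percent == pytest.approx(50.0)

    def test_noiseless_phantom_recovers_truth(self, noiseless_phantom):
        dixon, mask, truth = noiseless_phantom
        ffmap = compute_fat_fraction_map(dixon)
        for name, f_true in truth.fat_fractions.items():
            m = tissue_fat_metrics(ffmap, mask, name)
            assert m.fat_percent == pytest.approx(f_true, abs=1e-9)

    def test_fat_volume_bounded_by_tissue_volume(self, rng):
        dixon = random_dixon(rng, shape=(5, 5, 5))
        m = tissue_fat_metrics(compute_fat_fraction_map(dixon), full_mask((5, 5, 5)), "tongue")
        assert 0.0 <= m.fat_volume_cm3 <= m.tissue_volume_cm3
        assert m.fat_percent == pytest.approx(100.0 * m.fat_volume_cm3 / m.tissue_volume_cm3)

    def test_structure_with_no_defined_voxels_rejected(self):
        dixon = dixon_from_fw(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))
        with pytest.raises(EmptyStructureError):
            tissue_fat_metrics(compute_fat_fraction_map(dixon), full_mask((2, 2, 2)), "tongue")

    def test_ratio_of_sums_agrees_on_uniform_signal(self, noiseless_phantom):
        # uniform amplitude per tissue -> mean-of-fractions == ratio-of-sums
        dixon, mask, truth = noiseless_phantom
        ffmap = compute_fat_fraction_map(dixon)
        for name in ("tongue", "fat_pads"):
            mean_based = tissue_fat_metrics(ffmap, mask, name).fat_percent
            ratio_based = fat_percent_ratio_of_sums(dixon, mask, name)
            assert ratio_based == pytest.approx(mean_based, abs=1e-9)


class TestHistogram:
    def test_constant_half_fraction_lands_in_bin_five(self):
        shape = (3, 3, 3)
        dixon = dixon_from_fw(np.full(shape, 50.0), np.full(shape, 50.0))
        hist, median = fat_fraction_histogram(
            compute_fat_fraction_map(dixon), full_mask(shape), "tongue", n_bins=10
        )
        assert median == pytest.approx(50.0)
        assert hist.counts[5] == 27  # [50, 60) per the half-open convention
        assert hist.counts.sum() == 27

    def test_pure_fat_voxel_counted_in_last_bin(self):
        dixon = dixon_from_fw(np.full((1, 1, 1), 80.0), np.zeros((1, 1, 1)))
        hist, _ = fat_fraction_histogram(
            compute_fat_fraction_map(dixon), full_mask((1, 1, 1)), "tongue", n_bins=50
        )
        assert hist.counts[-1] == 1

    def test_counts_match_sort_and_count_oracle(self, rng):
        dixon = random_dixon(rng, shape=(6, 6, 6))
        ffmap = compute_fat_fraction_map(dixon)
        n_bins = 50
        hist, median = fat_fraction_histogram(ffmap, full_mask((6, 6, 6)), "tongue", n_bins=n_bins)
        values = np.sort(ffmap.fraction[ffmap.defined_mask])
        width = 100.0 / n_bins
        oracle = np.zeros(n_bins, dtype=int)
        for v in values:  # independent per-value binning
            b = min(int(v // width), n_bins - 1)
            oracle[b] += 1
        np.testing.assert_array_equal(hist.counts, oracle)
        assert median == pytest.approx(np.median(values))
        assert hist.counts.sum() == values.size

    def test_invalid_bin_count_rejected(self, noiseless_phantom):
        dixon, mask, _ = noiseless_phantom
        with pytest.raises(ValueError):
            fat_fraction_histogram(compute_fat_fraction_map(dixon), mask, "tongue", n_bins=0)


def test_map_round_trip_with_nan_sentinel(tmp_path, noiseless_phantom):
    dixon, _, _ = noiseless_phantom
    ffmap = compute_fat_fraction_map(dixon)
    back = read_volume(write_fat_fraction_map(ffmap, tmp_path / "ff.nii.gz"))
    np.testing.assert_array_equal(np.isnan(back.data), ~ffmap.defined_mask)
    np.testing.assert_array_equal(back.data[ffmap.defined_mask], ffmap.fraction[ffmap.defined_mask])
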