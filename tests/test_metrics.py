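"""Probability-weighted volumetry, partitioning and diffusivity means."""

import math

import numpy as np
import pytest

from tractmetrics import (
    DiffusivitySet,
    EmptyRegion,
    GridMismatch,
    VoxelGrid,
    compute_tract_metrics,
    lesion_frequency_map,
    partition_lesional,
    weighted_lesion_volume,
    weighted_mean_diffusivity,
)

from .conftest import make_map, make_mask
from .oracles import loop_weighted_mean


def grid_of(data, dims=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(data, dtype=float), dims, np.eye(4), "test")


class TestWeightedLesionVolume:
    def test_no_lesions_is_zero(self):
        lesions = make_mask(np.zeros((3, 3, 3)))
        tract = make_map(np.full((3, 3, 3), 0.8))
        assert weighted_lesion_volume(lesions, tract) == 0.0

    def test_binary_tract_reduces_to_overlap_count(self):
        """50 overlapping voxels at 8 mm^3 each -> 0.4 mL."""
        lesions = np.zeros((5, 5, 5)); lesions.ravel()[:50] = 1
        tract = np.ones((5, 5, 5))
        v = weighted_lesion_volume(make_mask(lesions, voxel_dims=(2, 2, 2)),
                                   make_map(tract, voxel_dims=(2, 2, 2)))
        assert v == pytest.approx(0.4)

    def test_weighted_hand_example(self):
        """Lesion voxels with tract weights 0.5 and 0.25 at 1 mm^3 -> 7.5e-4 mL."""
        lesions = np.zeros((1, 1, 3)); lesions[0, 0, :2] = 1
        tract = np.array([0.5, 0.25, 0.9]).reshape(1, 1, 3)
        v = weighted_lesion_volume(make_mask(lesions), make_map(tract))
        assert v == pytest.approx(7.5e-4)

    def test_grid_mismatch(self):
        with pytest.raises(GridMismatch):
            weighted_lesion_volume(make_mask(np.zeros((2, 2, 2))),
                                   make_map(np.zeros((3, 3, 3))))


class TestPartitionLesional:
    def test_full_lesion_coverage_empties_nonlesional(self, rng):
        tract = make_map(rng.random((4, 4, 4)))
        les, nonles = partition_lesional(tract, make_mask(np.ones((4, 4, 4))))
        assert nonles.weight_sum == 0.0
        assert np.array_equal(les.data, tract.data)

    def test_no_lesions_keeps_everything_nonlesional(self, rng):
        tract = make_map(rng.random((4, 4, 4)))
        les, nonles = partition_lesional(tract, make_mask(np.zeros((4, 4, 4))))
        assert les.weight_sum == 0.0
        assert np.array_equal(nonles.data, tract.data)

    def test_checkerboard_splits_uniform_weight_in_half(self):
        tract = make_map(np.full((4, 4, 4), 0.5))
        board = np.indices((4, 4, 4)).sum(axis=0) % 2
        les, nonles = partition_lesional(tract, make_mask(board.astype(float)))
        assert les.weight_sum == pytest.approx(tract.weight_sum / 2)
        assert nonles.weight_sum == pytest.approx(tract.weight_sum / 2)

    def test_partition_is_exact_decomposition(self, rng):
        tract = make_map(rng.random((5, 5, 5)))
        lesions = make_mask((rng.random((5, 5, 5)) < 0.3).astype(float))
        les, nonles = partition_lesional(tract, lesions)
        assert np.array_equal(les.data + nonles.data, tract.data)


class TestWeightedMeanDiffusivity:
    def test_uniform_weights_give_arithmetic_mean(self, rng):
        vals = rng.random((3, 3, 3))
        mean = weighted_mean_diffusivity(grid_of(vals), make_map(np.ones((3, 3, 3))))
        assert mean == pytest.approx(vals.mean())

    def test_hand_example(self):
        """D={1,3}, w={1,3} -> (1+9)/4 = 2.5."""
        d = grid_of(np.array([1.0, 3.0]).reshape(1, 1, 2))
        w = make_map(np.array([0.25, 0.75]).reshape(1, 1, 2))
        # weights scale-invariant in the ratio: use {0.25, 0.75} ∝ {1, 3}
        assert weighted_mean_diffusivity(d, w) == pytest.approx(2.5)

    def test_zero_weight_raises_empty_region(self):
        with pytest.raises(EmptyRegion):
            weighted_mean_diffusivity(grid_of(np.ones((2, 2, 2))),
                                      make_map(np.zeros((2, 2, 2))))

    def test_nan_voxels_dropped_pairwise(self):
        vals = np.array([1.0, np.nan, 5.0]).reshape(1, 1, 3)
        w = make_map(np.array([0.5, 0.9, 0.5]).reshape(1, 1, 3))
        assert weighted_mean_diffusivity(grid_of(vals), w) == pytest.approx(3.0)

    def test_all_nan_under_weight_raises(self):
        vals = np.full((2, 2, 2), np.nan)
        with pytest.raises(EmptyRegion):
            weighted_mean_diffusivity(grid_of(vals), make_map(np.ones((2, 2, 2))))

    def test_matches_loop_oracle(self, rng):
        vals = rng.normal(1.0, 0.2, (6, 6, 6))
        vals[rng.random((6, 6, 6)) < 0.1] = np.nan
        w = rng.random((6, 6, 6))
        got = weighted_mean_diffusivity(grid_of(vals), make_map(w))
        assert got == pytest.approx(loop_weighted_mean(vals, w), rel=1e-12)

    def test_scaling_equivariance(self, rng):
        vals = rng.normal(1.0, 0.1, (4, 4, 4))
        w = make_map(rng.random((4, 4, 4)))
        base = weighted_mean_diffusivity(grid_of(vals), w)
        scaled = weighted_mean_diffusivity(grid_of(3.5 * vals), w)
        assert scaled == pytest.approx(3.5 * base, rel=1e-12)


def uniform_diffusivity(shape, ad=1.17, rd=0.63, md=0.81, fa=0.38):
    return DiffusivitySet(
        ad=grid_of(np.full(shape, ad)), rd=grid_of(np.full(shape, rd)),
        md=grid_of(np.full(shape, md)), fa=grid_of(np.full(shape, fa)))


class TestDiffusivitySet:
    def test_rejects_fa_out_of_range(self):
        with pytest.raises(ValueError, match="FA"):
            uniform_diffusivity((2, 2, 2), fa=1.2)

    def test_rejects_rd_above_ad(self):
        with pytest.raises(ValueError, match="AD"):
            uniform_diffusivity((2, 2, 2), ad=0.5, rd=0.9)

    def test_rejects_grid_mismatch(self):
        with pytest.raises(GridMismatch):
            DiffusivitySet(ad=grid_of(np.ones((2, 2, 2))),
                           rd=grid_of(np.ones((3, 3, 3))),
                           md=grid_of(np.ones((2, 2, 2))),
                           fa=grid_of(np.full((2, 2, 2), 0.4)))


class TestComputeTractMetrics:
    def test_no_lesions_whole_equals_nonlesional_and_lesional_nan(self):
        shape = (4, 4, 4)
        m = compute_tract_metrics(
            "s1", make_map(np.full(shape, 0.6)), make_mask(np.zeros(shape)),
            diffusivity=uniform_diffusivity(shape))
        assert m.mean_ad_whole == pytest.approx(m.mean_ad_nonlesional)
        assert math.isnan(m.mean_ad_lesional)
        assert m.lesion_volume_ml == 0.0

    def test_volume_conservation_and_normalization(self, rng):
        shape = (5, 5, 5)
        tract = make_map(rng.random(shape), voxel_dims=(2, 2, 2))
        lesions = make_mask((rng.random(shape) < 0.3).astype(float),
                            voxel_dims=(2, 2, 2))
        m = compute_tract_metrics("s1", tract, lesions, scaling_factor=1.3,
                                  brain_volume_ml=1200.0)
        assert m.lesional_volume_ml + m.nonlesional_volume_ml == pytest.approx(
            m.tract_volume_ml, rel=1e-12)
        assert m.normalized_tract_volume_ml == pytest.approx(1.3 * m.tract_volume_ml)
        assert m.tract_volume_fraction_of_brain == pytest.approx(
            m.tract_volume_ml / 1200.0 * 100.0)
        # weighted lesion volume coincides with the lesional compartment volume
        assert m.lesion_volume_ml == pytest.approx(m.lesional_volume_ml, rel=1e-12)

    def test_mixture_identity(self, rng):
        """Whole-tract mean is the weight-mixture of compartment means."""
        shape = (6, 6, 6)
        tract = make_map(rng.random(shape))
        lesions = make_mask((rng.random(shape) < 0.4).astype(float))
        vals = rng.normal(1.0, 0.2, shape)
        d = DiffusivitySet(ad=grid_of(vals + 1), rd=grid_of(vals),
                           md=grid_of(vals + 0.5),
                           fa=grid_of(np.full(shape, 0.4)))
        m = compute_tract_metrics("s1", tract, lesions, diffusivity=d)
        les, nonles = partition_lesional(tract, lesions)
        wl, wn = les.weight_sum, nonles.weight_sum
        mixed = (wl * m.mean_md_lesional + wn * m.mean_md_nonlesional) / (wl + wn)
        assert m.mean_md_whole == pytest.approx(mixed, rel=1e-12)

    def test_exclusion_applied_before_everything(self):
        shape = (4, 4, 4)
        excl = np.zeros(shape); excl[0] = 1
        tract = np.full(shape, 1.0)
        lesions = np.zeros(shape); lesions[0] = 1  # lesions only inside exclusion
        m = compute_tract_metrics(
            "s1", make_map(tract), make_mask(lesions),
            exclusion=make_mask(excl))
        assert m.lesion_volume_ml == 0.0
        assert m.tract_volume_ml == pytest.approx((64 - 16) / 1000.0)

    def test_binary_tract_accepted(self):
        shape = (3, 3, 3)
        m = compute_tract_metrics("s1", make_mask(np.ones(shape)),
                                  make_mask(np.zeros(shape)))
        assert m.tract_volume_ml == pytest.approx(27 / 1000.0)

    def test_nonpositive_scaling_factor_rejected(self):
        shape = (2, 2, 2)
        with pytest.raises(ValueError):
            compute_tract_metrics("s1", make_map(np.ones(shape)),
                                  make_mask(np.zeros(shape)), scaling_factor=0.0)


class TestLesionFrequencyMap:
    def test_single_subject_is_intersection_with_support(self, rng):
        tract = make_map((rng.random((4, 4, 4)) < 0.5) * 0.7)
        lesions = make_mask((rng.random((4, 4, 4)) < 0.5).astype(float))
        f = lesion_frequency_map([lesions], tract)
        expected = lesions.data * (tract.data > 0)
        assert np.array_equal(f.data, expected)

    def test_no_lesions_gives_zero_map(self):
        tract = make_map(np.full((3, 3, 3), 0.5))
        masks = [make_mask(np.zeros((3, 3, 3))) for _ in range(3)]
        assert lesion_frequency_map(masks, tract).weight_sum == 0.0

    def test_counting_fraction(self):
        """A voxel lesioned in 3 of 4 subjects scores 0.75."""
        tract = make_map(np.ones((1, 1, 2)))
        masks = []
        for i in range(4):
            arr = np.zeros((1, 1, 2))
            if i < 3:
                arr[0, 0, 0] = 1
            masks.append(make_mask(arr))
        f = lesion_frequency_map(masks, tract)
        assert f.data[0, 0, 0] == pytest.approx(0.75)
        assert f.data[0, 0, 1] == 0.0

    def test_empty_subject_list_rejected(self):
        with pytest.raises(ValueError):
            lesion_frequency_map([], make_map(np.ones((2, 2, 2))))
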