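"""Confocal morphometry: MIPs, consensus ROI, thresholding, skeleton metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.ndimage import distance_transform_edt

from speckleflow.errors import DegenerateInputError
from speckleflow.morphometry import (
    ConfocalStack,
    analyze_mip,
    consensus_roi,
    diameter_histogram,
    iterative_threshold,
    make_mips,
    segment_skeleton,
    size_filter,
    skeletonize_mask,
    vessel_density,
    vessel_diameters,
)


def exhaustive_isodata(values):
    """Independent oracle: test every midpoint between distinct intensity
    levels for the fixed-point condition t = (mean below + mean at/above)/2."""
    values = np.asarray(values, float).ravel()
    levels = np.unique(values)
    best, best_err = None, np.inf
    for lo, hi in zip(levels[:-1], levels[1:]):
        t = 0.5 * (lo + hi)
        mid = 0.5 * (values[values < t].mean() + values[values >= t].mean())
        err = abs(mid - t)
        if (lo <= mid < hi) and err < best_err:
            best, best_err = mid, err
    return best


class TestMakeMips:
    def _stack(self, volume, z_step=7.0):
        return ConfocalStack(volume=np.asarray(volume, float), voxel_size_um=(z_step, 1.0, 1.0))

    def test_single_block_is_max_of_all_slices(self, rng):
        vol = rng.uniform(size=(10, 8, 8))
        mips = make_mips(self._stack(vol), slab_um=70.0)
        assert len(mips.mips) == 1
        np.testing.assert_array_equal(mips.mips[0], vol.max(axis=0))

    def test_max_semantics_per_block(self):
        vol = np.arange(10).reshape(-1, 1, 1) * np.ones((1, 4, 4))
        mips = make_mips(self._stack(vol), 70.0)
        assert np.all(mips.mips[0] == 9)

    def test_hundred_slices_make_ten_mips(self):
        vol = np.zeros((100, 4, 4))
        mips = make_mips(self._stack(vol), 70.0)  # floor(70/7) = 10 slices/block
        assert len(mips.mips) == 10
        assert all(b - a == 10 for a, b in mips.z_ranges)

    def test_small_remainder_discarded_large_kept(self):
        # 24 slices at 7 um: blocks of 10, remainder 4 < 5 discarded
        assert len(make_mips(self._stack(np.zeros((24, 2, 2))), 70.0).mips) == 2
        # remainder 6 >= 5 kept as a thin MIP
        assert len(make_mips(self._stack(np.zeros((26, 2, 2))), 70.0).mips) == 3

    def test_slab_thinner_than_slice_rejected(self):
        with pytest.raises(ValueError):
            make_mips(self._stack(np.zeros((5, 2, 2))), 3.0)


class TestConsensusROI:
    def test_three_identical_masks(self, rng):
        m = rng.random((20, 20)) > 0.5
        assert np.array_equal(consensus_roi([m, m, m]).mask, m)

    def test_two_of_three_vote(self, rng):
        a = rng.random((15, 15)) > 0.5
        empty = np.zeros_like(a)
        assert np.array_equal(consensus_roi([a, a, empty]).mask, a)

    def test_matches_brute_force_tally(self, rng):
        masks = [rng.random((12, 12)) > 0.5 for _ in range(3)]
        cons = consensus_roi(masks).mask
        for i in range(12):
            for j in range(12):
                votes = sum(m[i, j] for m in masks)
                assert cons[i, j] == (votes >= 2)

    @settings(max_examples=25, deadline=None)
    @given(
        data=hnp.arrays(np.bool_, (3, 10, 10), elements=st.booleans()),
    )
    def test_sandwich_invariant(self, data):
        """intersection <= consensus <= union for any reader masks."""
        masks = list(data)
        cons = consensus_roi(masks).mask
        inter = masks[0] & masks[1] & masks[2]
        union = masks[0] | masks[1] | masks[2]
        assert np.all(inter <= cons) and np.all(cons <= union)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_roi([np.ones((3, 3), bool), np.ones((4, 4), bool)])


class TestIterativeThreshold:
    def test_two_equal_classes_split_at_midpoint(self):
        img = np.array([10.0] * 50 + [20.0] * 50).reshape(10, 10)
        assert iterative_threshold(img) == pytest.approx(15.0)

    def test_unequal_classes_iterate_to_fifteen(self):
        # 300 pixels of 10 and 100 of 20: t0 = 12.5, class means 10 and 20,
        # fixed point at 15 after one step
        img = np.array([10] * 300 + [20] * 100, dtype=np.uint8).reshape(20, 20)
        assert iterative_threshold(img) == pytest.approx(15.0, abs=0.5)

    def test_matches_exhaustive_oracle_on_random_8bit(self, rng):
        for _ in range(10):
            img = np.concatenate(
                [
                    rng.normal(60, 15, size=300),
                    rng.normal(180, 20, size=120),
                ]
            ).clip(0, 255).astype(np.uint8)
            t = iterative_threshold(img.reshape(20, 21))
            oracle = exhaustive_isodata(img)
            assert oracle is not None
            assert t == pytest.approx(oracle, abs=1.0)

    def test_threshold_restricted_to_roi(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0
        roi = np.zeros((10, 10), bool)
        roi[:, 4:7] = True  # ROI holds values 0 and 100 only
        assert iterative_threshold(img, roi) == pytest.approx(50.0)

    def test_constant_roi_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            iterative_threshold(np.full((5, 5), 3.0))


class TestSizeFilter:
    def _three_components(self):
        mask = np.zeros((30, 200), bool)
        mask[2:7, 0:10] = True  # 50 px
        mask[10:13, 20:37] = True  # 51 px
        mask[20:26, 50:60] = True  # 60 px
        return mask

    def test_strictly_smaller_than_threshold_removed(self):
        out = size_filter(self._three_components(), pixel_area_um2=1.0, min_area_um2=51.0)
        assert not out[2:7, 0:10].any()  # 50 px dropped
        assert out[10:13, 20:37].all()  # exactly 51 px kept
        assert out[20:26, 50:60].all()

    def test_empty_mask_passes_through(self):
        out = size_filter(np.zeros((5, 5), bool), 1.0)
        assert not out.any()

    def test_idempotent_and_subset(self, rng):
        mask = rng.random((60, 60)) > 0.6
        out = size_filter(mask, 1.0, 20.0)
        assert np.all(out <= mask)
        np.testing.assert_array_equal(size_filter(out, 1.0, 20.0), out)

    def test_physical_area_scaling(self):
        mask = np.zeros((10, 10), bool)
        mask[2:7, 2:7] = True  # 25 px
        assert size_filter(mask, pixel_area_um2=4.0, min_area_um2=51.0).any()  # 100 um^2
        assert not size_filter(mask, pixel_area_um2=1.0, min_area_um2=51.0).any()


class TestSkeleton:
    def test_bar_reduces_to_centerline(self):
        mask = np.zeros((20, 120), bool)
        mask[8:13, 10:110] = True
        skel = skeletonize_mask(mask)
        assert np.all(skel <= mask)
        assert abs(int(skel.sum()) - 100) <= 5

    def test_single_pixel_and_empty(self):
        one = np.zeros((5, 5), bool)
        one[2, 2] = True
        assert skeletonize_mask(one)[2, 2]
        assert not skeletonize_mask(np.zeros((5, 5), bool)).any()

    def test_straight_path_is_one_segment_of_length_nine(self):
        skel = np.zeros((5, 12), bool)
        skel[2, 1:11] = True
        segs = segment_skeleton(skel)
        assert len(segs) == 1
        assert segs[0]["length_px"] == pytest.approx(9.0)

    def test_diagonal_path_weighs_sqrt2_per_step(self):
        skel = np.zeros((12, 12), bool)
        for i in range(10):
            skel[i, i] = True
        segs = segment_skeleton(skel)
        assert len(segs) == 1
        assert segs[0]["length_px"] == pytest.approx(9.0 * np.sqrt(2.0))

    def test_t_junction_splits_into_three_arms(self):
        skel = np.zeros((11, 11), bool)
        skel[5, 0:11] = True  # horizontal bar
        skel[0:5, 5] = True  # vertical arm onto its middle
        # brute-force oracle: the centre pixel has >= 3 eight-neighbours
        nbrs = sum(
            skel[5 + dy, 5 + dx]
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dy, dx) != (0, 0)
        )
        assert nbrs >= 3
        segs = segment_skeleton(skel)
        assert len(segs) == 3

    def test_closed_loop_traced_once(self):
        # diamond loop: every pixel has exactly two (diagonal) neighbours
        skel = np.zeros((11, 11), bool)
        r = 3
        for dy in range(-r, r + 1):
            dx = r - abs(dy)
            skel[5 + dy, 5 + dx] = True
            skel[5 + dy, 5 - dx] = True
        segs = segment_skeleton(skel)
        assert len(segs) == 1
        assert segs[0]["length_px"] == pytest.approx(4 * r * np.sqrt(2.0))


class TestDiameters:
    def test_bar_diameter_within_one_pixel(self):
        mask = np.zeros((20, 120), bool)
        mask[8:13, :] = True  # width 5, full span
        skel = skeletonize_mask(mask)
        table = vessel_diameters(mask, segment_skeleton(skel), pixel_size_um=1.0)
        assert len(table) == 1
        assert table.diameter_um.iloc[0] == pytest.approx(5.0, abs=1.0)

    def test_two_widths_give_two_segment_values(self):
        mask = np.zeros((40, 120), bool)
        mask[5:8, :] = True  # width 3
        mask[20:29, :] = True  # width 9
        skel = skeletonize_mask(mask)
        table = vessel_diameters(mask, segment_skeleton(skel), 1.0)
        diams = np.sort(table.diameter_um.to_numpy())
        assert len(diams) == 2
        assert diams[0] == pytest.approx(3.0, abs=1.0)
        assert diams[1] == pytest.approx(9.0, abs=1.0)

    def test_disk_maximum_local_diameter_is_its_width(self):
        yy, xx = np.mgrid[0:41, 0:41]
        r = 12
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= r * r
        edt = distance_transform_edt(mask)
        assert 2.0 * edt.max() == pytest.approx(2 * r, abs=2.0)

    def test_centerline_on_background_is_an_error(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.raises(ValueError):
            vessel_diameters(mask, [{"points": [(0, 0)], "length_px": 0.0}], 1.0)


class TestVesselDensity:
    def _table(self, lengths):
        return pd.DataFrame(
            {
                "segment_id": range(len(lengths)),
                "mip_index": 0,
                "length_um": lengths,
                "diameter_um": 5.0,
                "component_area_um2": 100.0,
            }
        )

    def test_single_mip_ratio(self):
        assert vessel_density([self._table([100.0])], [10_000.0], n_select=1) == pytest.approx(0.01)

    def test_two_mips_pool_lengths_and_areas(self):
        t1, t2 = self._table([120.0]), self._table([80.0, 40.0])
        out = vessel_density([t1, t2], [5000.0, 5000.0], n_select=2)
        assert out == pytest.approx((120.0 + 120.0) / 10_000.0)

    def test_selects_five_longest_mips_like_brute_force(self, rng):
        lengths = rng.uniform(50, 500, size=7)
        tables = [self._table([L]) for L in lengths]
        areas = rng.uniform(1000, 2000, size=7)
        out = vessel_density(tables, list(areas), n_select=5)
        top = np.argsort(-lengths)[:5]
        assert out == pytest.approx(lengths[top].sum() / areas[top].sum())

    def test_zero_area_is_an_error(self):
        with pytest.raises(DegenerateInputError):
            vessel_density([self._table([10.0])], [0.0], n_select=1)


class TestDiameterHistogram:
    def _table(self, diams):
        return pd.DataFrame(
            {
                "segment_id": range(len(diams)),
                "mip_index": 0,
                "length_um": 10.0,
                "diameter_um": diams,
                "component_area_um2": 100.0,
            }
        )

    def test_mode_normalization(self):
        hist = diameter_histogram([self._table([4.0, 4.0, 6.0])], bin_width_um=1.0)
        assert hist.normalized_counts.max() == 1.0
        by_center = dict(zip(hist.bin_centers_um, hist.normalized_counts))
        assert by_center[3.5] == 1.0  # the 4-um pair is the mode
        assert by_center[5.5] == 0.5

    def test_single_segment_is_its_own_mode(self):
        hist = diameter_histogram([self._table([7.2])])
        assert hist.normalized_counts.max() == 1.0
        assert hist.raw_counts.sum() == 1

    @settings(max_examples=30, deadline=None)
    @given(
        diams=st.lists(st.floats(min_value=0.1, max_value=11.9), min_size=1, max_size=40)
    )
    def test_max_is_exactly_one_on_any_nonempty_input(self, diams):
        hist = diameter_histogram([self._table(diams)])
        assert hist.normalized_counts.max() == 1.0

    def test_all_out_of_range_is_an_error(self):
        with pytest.raises(DegenerateInputError):
            diameter_histogram([self._table([25.0, 30.0])], d_max_um=12.0)


class TestGeometryRecovery:
    def test_noiseless_phantom_density_and_diameters(self, bar_phantom):
        spec, img, truth, widths = bar_phantom
        table, area, mask, skel = analyze_mip(img, np.ones(img.shape, bool), 1.0)
        true_length = sum(
            min(r["length_um"], spec.canvas[1]) for r in truth.parameters["segments"]
        )
        density = vessel_density([table], [area], n_select=1)
        assert density == pytest.approx(true_length / area, rel=0.05)
        diams = np.sort(table.diameter_um.to_numpy())
        assert len(diams) == len(widths)
        for d, w in zip(diams, sorted(widths)):
            assert abs(d - w) <= 1.0

    def test_blurred_noisy_phantom_stays_close(self, noisy_bar_phantom):
        spec, img, truth, widths = noisy_bar_phantom
        table, area, mask, skel = analyze_mip(img, np.ones(img.shape, bool), 1.0)
        true_length = sum(
            min(r["length_um"], spec.canvas[1]) for r in truth.parameters["segments"]
        )
        density = vessel_density([table], [area], n_select=1)
        assert density == pytest.approx(true_length / area, rel=0.15)
        diams = np.sort(table.diameter_um.to_numpy())[-len(widths):]
        for d, w in zip(diams, sorted(widths)):
            assert abs(d - w) <= 1.5

    def test_equal_width_mix_gives_flat_normalized_histogram(self):
        from speckleflow.synthetic import VesselPhantomSpec, generate_vessel_phantom

        h, w = 240, 300
        segments = []
        for i, wd in enumerate([3.0, 5.0, 7.0] * 2):
            y = 20.0 + 36.0 * i
            segments.append(([(y, -5.0), (y, w + 5.0)], wd, 200.0))
        img, _ = generate_vessel_phantom(
            VesselPhantomSpec(canvas=(h, w), segments=segments, background=10.0)
        )
        table, area, mask, skel = analyze_mip(img, np.ones(img.shape, bool), 1.0)
        hist = diameter_histogram([table], bin_width_um=2.0, d_max_um=12.0)
        occupied = hist.normalized_counts[hist.raw_counts > 0]
        assert occupied.min() >= 0.99  # 2 segments per width class
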