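"""SURS designs, Cavalieri estimation, disector counting, shrinkage."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acinostereo import stereo
from acinostereo.stereo import (
    PointGrid,
    SliceSample,
    cavalieri_volume,
    count_points,
    detect_interruptions,
    disector_count,
    shrinkage_factor,
    subsample_acini,
    surs_slices,
)

VOX = 1.48


class TestSliceSampling:
    def test_forced_offset_zero(self):
        s = surs_slices(100, 10, offset=0)
        assert s.indices.tolist() == list(range(0, 100, 10))

    def test_half_open_arithmetic(self):
        s = surs_slices(95, 10, offset=7)
        assert s.indices.tolist() == [7, 17, 27, 37, 47, 57, 67, 77, 87]
        assert len(s) == 9

    def test_exhaustive_offsets_cover_depth(self):
        """Mean slice count times interval equals depth to within one interval."""
        depth, interval = 95, 10
        counts = [len(surs_slices(depth, interval, offset=o)) for o in range(interval)]
        assert abs(np.mean(counts) * interval - depth) <= interval
        # and the offset sets partition [0, depth)
        union = sorted(
            set().union(*(surs_slices(depth, interval, offset=o).indices.tolist()
                          for o in range(interval)))
        )
        assert union == list(range(depth))

    def test_interval_exceeding_depth_is_design_error(self):
        with pytest.raises(ValueError):
            surs_slices(5, 10)

    def test_random_offset_in_range(self):
        offsets = {surs_slices(100, 10, seed=s).offset for s in range(50)}
        assert offsets <= set(range(10)) and len(offsets) > 3


class TestSubsampling:
    def test_every_third_starting_first(self):
        ids = [f"a{i}" for i in range(1, 10)]
        assert subsample_acini(ids, 3, start=0) == ["a1", "a4", "a7"]

    def test_denominator_one_returns_all(self):
        assert subsample_acini([1, 2, 3], 1, start=0) == [1, 2, 3]

    def test_starts_partition_the_list(self):
        ids = list(range(11))
        picks = [subsample_acini(ids, 3, start=s) for s in range(3)]
        assert sorted(itertools.chain(*picks)) == ids
        for a, b in itertools.combinations(picks, 2):
            assert not set(a) & set(b)

    def test_empty_list_is_empty_not_error(self):
        assert subsample_acini([], 3, seed=0) == []


class TestPointCounting:
    def test_full_slice_regular_grid(self):
        grid = PointGrid(spacing_um=10 * VOX)
        assert count_points(np.ones((100, 100), bool), grid, VOX) == 100

    def test_empty_slice(self):
        grid = PointGrid(spacing_um=10 * VOX)
        assert count_points(np.zeros((100, 100), bool), grid, VOX) == 0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        spacing=st.integers(2, 9),
        oy=st.floats(0, 0.99),
        ox=st.floats(0, 0.99),
    )
    def test_matches_bruteforce_membership_oracle(self, seed, spacing, oy, ox):
        """Grid counting equals node-by-node nearest-voxel membership."""
        rng = np.random.default_rng(seed)
        mask = rng.random((40, 40)) > 0.6
        grid = PointGrid(spacing * VOX, (oy * spacing * VOX, ox * spacing * VOX))
        expected = 0
        y = grid.origin_offset_um[0] / VOX
        while y < 40:
            x = grid.origin_offset_um[1] / VOX
            while x < 40:
                yi, xi = int(round(y)), int(round(x))
                if yi < 40 and xi < 40 and mask[yi, xi]:
                    expected += 1
                x += spacing
            y += spacing
        assert count_points(mask, grid, VOX) == expected


class TestCavalieri:
    def test_aligned_cuboid_is_exact(self):
        mask = np.zeros((128, 128, 128), bool)
        mask[:120, :120, :120] = True
        sample = surs_slices(120, 12, offset=0)
        grid = PointGrid(12 * VOX)
        est = cavalieri_volume(mask[:120], sample, grid, VOX)
        assert est.volume_mm3 == pytest.approx((120 * VOX) ** 3 * 1e-9, rel=1e-12)

    def test_exhaustive_design_average_is_unbiased(self, sphere_mask):
        """Average over all offsets and integer grid origins equals truth <0.5%."""
        true = sphere_mask.sum() * VOX**3 * 1e-9
        interval, spacing = 6, 6
        estimates = []
        for off in range(interval):
            sample = surs_slices(64, interval, offset=off)
            for oy in range(spacing):
                for ox in range(spacing):
                    grid = PointGrid(spacing * VOX, (oy * VOX, ox * VOX))
                    estimates.append(
                        cavalieri_volume(sphere_mask, sample, grid, VOX).volume_mm3
                    )
        assert abs(np.mean(estimates) - true) / true < 0.005

    def test_zero_points_zero_volume(self):
        est = cavalieri_volume(
            np.zeros((20, 20, 20), bool), surs_slices(20, 5, offset=0), PointGrid(5 * VOX), VOX
        )
        assert est.sum_points == 0 and est.volume_mm3 == 0.0

    def test_precomputed_counts_path(self):
        sample = surs_slices(30, 10, offset=0)
        est = cavalieri_volume([4, 5, 6], sample, PointGrid(2.0), 1.0)
        assert est.volume_mm3 == pytest.approx(10 * 4.0 * 15 * 1e-9)

    def test_ce_reported_with_three_sections(self, sphere_mask):
        est = cavalieri_volume(sphere_mask, surs_slices(64, 8, offset=1), PointGrid(4 * VOX), VOX)
        assert est.ce is not None and 0 <= est.ce < 0.2

    def test_ce_not_larger_at_finer_sampling(self, sphere_mask):
        """Halving the slice interval does not increase the mean CE."""
        def mean_ce(interval):
            ces = []
            for off in range(interval):
                est = cavalieri_volume(
                    sphere_mask, surs_slices(64, interval, offset=off), PointGrid(4 * VOX), VOX
                )
                ces.append(est.ce)
            return np.mean(ces)

        assert mean_ce(4) <= mean_ce(8) + 1e-12

    def test_empty_sample_is_design_error(self):
        with pytest.raises(ValueError):
            cavalieri_volume([], surs_slices(10, 5, offset=0), PointGrid(2.0), 1.0)


class TestDisector:
    def test_phantom_exhaustive_pairs_exact(self, small_tree):
        from acinostereo.phantom import synthesize_acinus

        ph = synthesize_acinus(small_tree, 12, 9.0, 1.48, seed=42)
        res = disector_count(ph.labels)
        assert res.pairs_examined == res.pairs_total
        assert res.n_estimate == 12

    def test_empty_label_volume_counts_zero(self):
        res = disector_count(np.zeros((10, 5, 5), np.uint16))
        assert res.n_estimate == 0

    def test_reversed_order_swaps_events(self, small_phantom):
        fwd = disector_count(small_phantom.labels)
        rev = disector_count(small_phantom.labels[::-1])
        assert (fwd.q_appear, fwd.q_disappear) == (rev.q_disappear, rev.q_appear)
        assert fwd.n_estimate == rev.n_estimate

    def test_fractional_pair_sampling_unbiased(self, small_phantom):
        """Every-2nd-pair designs scale back to the truth within 5% on average."""
        truth = small_phantom.truth["n_alveoli"]
        pairs_total = small_phantom.labels.shape[0] - 1
        estimates = [
            disector_count(
                small_phantom.labels,
                sample=SliceSample(depth=pairs_total, interval=2, offset=o),
            ).n_estimate
            for o in range(2)
        ]
        assert abs(np.mean(estimates) - truth) / truth < 0.05

    def test_fewer_than_two_sections_is_design_error(self):
        with pytest.raises(ValueError):
            disector_count(np.zeros((1, 4, 4), np.uint16))

    def test_event_list_input_path(self):
        presence = [set(), {2}, {2, 3}, {3}, set()]
        res = disector_count(presence)
        assert res.q_appear == 2 and res.q_disappear == 2
        assert res.n_estimate == 2


class TestInterruptionHeuristic:
    def test_two_open_mouths_give_two_events(self):
        """Two free-ended septa inside the air space -> two wall gaps."""
        air = np.zeros((64, 64), bool)
        yy, xx = np.mgrid[0:64, 0:64]
        air[(yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2] = True
        air[31:34, 14:27] = False  # partial septum, free tips at both ends
        air[31:34, 38:51] = False
        events = detect_interruptions(air)
        assert len(events) == 2

    def test_closed_profile_has_no_events(self):
        air = np.zeros((40, 40), bool)
        yy, xx = np.mgrid[0:40, 0:40]
        air[(yy - 20) ** 2 + (xx - 20) ** 2 <= 12**2] = True
        assert detect_interruptions(air) == []

    def test_all_air_has_no_wall(self):
        assert detect_interruptions(np.ones((20, 20), bool)) == []


class TestShrinkage:
    def test_equal_volumes_identity(self):
        f = shrinkage_factor(2.0, 2.0)
        assert f.factor == 1.0
        assert stereo.apply_correction(0.7, f) == 0.7

    def test_ratio_and_application(self):
        f = shrinkage_factor(1.2, 1.0)
        assert f.factor == pytest.approx(1.2)
        assert stereo.apply_correction(0.5, f) == pytest.approx(0.6)

    def test_round_trip_inversion(self):
        f = shrinkage_factor(1.37, 1.0)
        v = stereo.apply_correction(0.25, f)
        assert stereo.apply_correction(v, 1.0 / f.factor) == pytest.approx(0.25)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            shrinkage_factor(0.0, 1.0)
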