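import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbetrans import (
    DVH,
    DoseGrid,
    StructureMask,
    VolumeSpec,
    average_dvh,
    compute_dvh,
    dose_at_volume,
    dvh_from_dose_points,
    expand_mask,
    geud,
    uniform_dvh,
    volume_at_dose,
)


def two_bin_dvh(d_low, d_high, volume_cc=80.0):
    """Equal-volume differential bins centered exactly at d_low and d_high."""
    half = (d_high - d_low) / 2.0
    edges = np.array([d_low - half, d_low + half, d_high + half])
    return DVH(
        dose_edges=edges,
        cum_volume_fraction=np.array([1.0, 0.5, 0.0]),
        total_volume_cc=volume_cc,
        rbe_model="MKM",
    )


class TestComputeDvh:
    def test_uniform_dose_curve(self, uniform_grid):
        grid, mask = uniform_grid
        dvh = compute_dvh(grid, mask, bin_width=0.1)
        assert volume_at_dose(dvh, 49.0) == 1.0
        assert volume_at_dose(dvh, 50.0) == 1.0
        assert volume_at_dose(dvh, 51.0) == 0.0

    def test_volume_cc_arithmetic(self):
        grid = DoseGrid(values=np.ones((2, 2, 2)), voxel_size=(1.0, 1.0, 1.0))
        mask = StructureMask(mask=np.ones((2, 2, 2), dtype=bool))
        dvh = compute_dvh(grid, mask)
        assert dvh.total_volume_cc == pytest.approx(0.008)

    def test_linear_span_matches_sort_oracle(self, rng):
        # equal-volume voxels spanning 0..100 -> survival ~ (100 - d)/100
        doses = np.linspace(0.0, 100.0, 10 * 10 * 10)
        values = rng.permutation(doses).reshape(10, 10, 10)
        grid = DoseGrid(values=values, voxel_size=(1, 1, 1))
        mask = StructureMask(mask=np.ones((10, 10, 10), dtype=bool))
        dvh = compute_dvh(grid, mask, bin_width=0.1)
        for d in [10.0, 37.0, 50.0, 90.0]:
            assert volume_at_dose(dvh, d) == pytest.approx((100 - d) / 100, abs=2e-3)

    def test_empty_mask_raises(self, uniform_grid):
        grid, _ = uniform_grid
        empty = StructureMask(mask=np.zeros((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError, match="empty structure"):
            compute_dvh(grid, empty)

    def test_shape_mismatch_raises(self, uniform_grid):
        grid, _ = uniform_grid
        bad = StructureMask(mask=np.ones((3, 3, 3), dtype=bool))
        with pytest.raises(ValueError, match="shape"):
            compute_dvh(grid, bad)

    def test_survival_exact_at_edges(self, rng):
        values = rng.uniform(0, 70, size=(12, 12, 12))
        mask_arr = rng.random((12, 12, 12)) < 0.5
        mask_arr[0, 0, 0] = True
        grid = DoseGrid(values=values, voxel_size=(1.5, 1.5, 3.0))
        dvh = compute_dvh(grid, StructureMask(mask=mask_arr), bin_width=0.1)
        doses = values[mask_arr]
        for edge, frac in zip(dvh.dose_edges[::37], dvh.cum_volume_fraction[::37]):
            assert frac == pytest.approx(np.mean(doses >= edge), abs=1e-12)


class TestDoseAtVolume:
    def test_uniform_dose(self):
        dvh = uniform_dvh(50.0, 80.0)
        assert dose_at_volume(dvh, VolumeSpec("percent", 5)) == pytest.approx(50.0, abs=1e-6)

    def test_cc_percent_equivalence(self, linear_dvh):
        # 4 cc of an 80 cc structure is 5%
        d_4cc = dose_at_volume(linear_dvh, VolumeSpec("cc", 4))
        d_5pct = dose_at_volume(linear_dvh, VolumeSpec("percent", 5))
        assert d_4cc == pytest.approx(d_5pct, abs=1e-12)

    def test_linear_dvh_d20(self, linear_dvh):
        assert dose_at_volume(linear_dvh, VolumeSpec("percent", 20)) == pytest.approx(80.0)

    def test_out_of_range_spec_raises(self, linear_dvh):
        with pytest.raises(ValueError):
            VolumeSpec("percent", 0)
        with pytest.raises(ValueError):
            VolumeSpec("percent", 101)
        with pytest.raises(ValueError):
            dose_at_volume(linear_dvh, VolumeSpec("cc", 81))

    def test_monotone_in_v(self, default_cohort):
        for patient in default_cohort.patients[::7]:
            doses = [
                dose_at_volume(patient.dvh_lem, VolumeSpec("percent", v))
                for v in (1, 5, 10, 20)
            ]
            assert doses == sorted(doses, reverse=True)


class TestVolumeAtDose:
    def test_uniform_bounds(self):
        dvh = uniform_dvh(50.0, 60.0)
        assert volume_at_dose(dvh, 49.0) == 1.0
        assert volume_at_dose(dvh, 51.0) == 0.0

    def test_linear_interior(self, linear_dvh):
        assert volume_at_dose(linear_dvh, 30.0) == pytest.approx(0.70)

    def test_round_trip_with_dose_at_volume(self, linear_dvh):
        for v in [1, 5, 10, 20, 50, 80]:
            d = dose_at_volume(linear_dvh, VolumeSpec("percent", v))
            assert volume_at_dose(linear_dvh, d) == pytest.approx(v / 100, abs=1e-9)


class TestGeud:
    @pytest.mark.parametrize("n", [0.035, 0.5, 1.0, 2.0])
    def test_uniform_identity(self, n):
        dvh = uniform_dvh(60.0, 80.0)
        assert geud(dvh, n) == pytest.approx(60.0, rel=1e-6)

    def test_mean_at_n_one(self):
        assert geud(two_bin_dvh(40.0, 60.0), 1.0) == pytest.approx(50.0)

    def test_serial_power_sum_oracle(self):
        # direct oracle: (0.5 * 30^(1/0.035) + 0.5 * 60^(1/0.035))^0.035
        expected = (0.5 * 30.0 ** (1 / 0.035) + 0.5 * 60.0 ** (1 / 0.035)) ** 0.035
        assert geud(two_bin_dvh(30.0, 60.0), 0.035) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(58.5619, abs=1e-3)

    def test_small_n_approaches_max(self, default_cohort):
        dvh = default_cohort.patients[0].dvh_mkm
        top = geud(dvh, 1e-4)
        assert top <= dvh.max_dose + 1e-9
        assert top >= 0.995 * dvh.max_dose - 0.06  # within 0.5% of max (one bin slack)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            geud(uniform_dvh(50, 80), 0.0)

    def test_bounded_by_min_max(self, default_cohort):
        dvh = default_cohort.patients[3].dvh_lem
        for n in [0.01, 0.1, 1.0, 5.0]:
            assert 0.0 <= geud(dvh, n) <= dvh.max_dose + 1e-9


class TestAverageDvh:
    def test_identical_inputs(self, linear_dvh):
        edges, mean, sd = average_dvh([linear_dvh, linear_dvh], edges=linear_dvh.dose_edges)
        np.testing.assert_allclose(mean, linear_dvh.cum_volume_fraction, atol=1e-12)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_two_point_statistics(self):
        d1 = DVH(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.0, 0.0]), 10.0)
        d2 = DVH(np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0, 0.0]), 10.0)
        _, mean, sd = average_dvh([d1, d2], edges=np.array([0.0, 1.0, 2.0]))
        assert mean[1] == pytest.approx(0.5)
        assert sd[1] == pytest.approx(0.5)  # population SD of {0, 1}

    def test_matches_brute_force(self, default_cohort):
        dvhs = [p.dvh_lem for p in default_cohort.patients[:10]]
        edges = np.arange(0.0, 70.0, 0.5)
        _, mean, sd = average_dvh(dvhs, edges=edges)
        stack = np.vstack([[volume_at_dose(d, e) for e in edges] for d in dvhs])
        np.testing.assert_allclose(mean, stack.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(sd, stack.std(axis=0), atol=1e-12)

    def test_mean_monotone(self, default_cohort):
        dvhs = [p.dvh_mkm for p in default_cohort.patients[:10]]
        _, mean, _ = average_dvh(dvhs, edges=np.arange(0.0, 70.0, 0.1))
        assert np.all(np.diff(mean) <= 1e-12)

    def test_requires_two(self, linear_dvh):
        with pytest.raises(ValueError):
            average_dvh([linear_dvh])


class TestDvhFromDosePoints:
    def test_reproduces_points_exactly(self):
        points = {
            VolumeSpec("percent", 20): 14.0,
            VolumeSpec("percent", 10): 38.1,
            VolumeSpec("percent", 5): 50.7,
            VolumeSpec("percent", 1): 63.3,
        }
        dvh = dvh_from_dose_points(points, total_volume_cc=68.6)
        for spec, dose in points.items():
            assert dose_at_volume(dvh, spec) == pytest.approx(dose, abs=1e-9)

    def test_rejects_non_monotone(self):
        points = {VolumeSpec("percent", 20): 40.0, VolumeSpec("percent", 10): 30.0}
        with pytest.raises(ValueError):
            dvh_from_dose_points(points, total_volume_cc=60.0)


class TestExpandMask:
    def test_single_voxel_cross(self):
        arr = np.zeros((5, 5, 5), dtype=bool)
        arr[2, 2, 2] = True
        out = expand_mask(StructureMask(mask=arr), (1.0, 1.0, 1.0), 1.0)
        assert out.mask.sum() == 7  # center + 6 face neighbors within 1 mm
        assert out.mask[2, 2, 2] and out.mask[1, 2, 2] and not out.mask[1, 1, 2]

    def test_zero_margin_is_identity(self):
        arr = np.zeros((3, 3, 3), dtype=bool)
        arr[1, 1, 1] = True
        out = expand_mask(StructureMask(mask=arr), (1.0, 1.0, 1.0), 0.0)
        assert out.mask.sum() == 1


class TestInvariants:
    def test_dvh_validation(self):
        with pytest.raises(ValueError):
            DVH(np.array([0.0, 1.0]), np.array([0.5, 0.0]), 10.0)  # first != 1
        with pytest.raises(ValueError):
            DVH(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.2, 0.5]), 10.0)  # not monotone
        with pytest.raises(ValueError):
            DVH(np.array([0.0, 0.0, 2.0]), np.array([1.0, 0.5, 0.0]), 10.0)  # edges tie

    def test_dose_grid_validation(self):
        with pytest.raises(ValueError):
            DoseGrid(values=-np.ones((2, 2, 2)), voxel_size=(1, 1, 1))
        with pytest.raises(ValueError):
            DoseGrid(values=np.ones((2, 2)), voxel_size=(1, 1, 1))
        with pytest.raises(ValueError):
            DoseGrid(values=np.ones((2, 2, 2)), voxel_size=(0, 1, 1))

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), bins=st.integers(5, 60))
    def test_metric_round_trip_random_curves(self, seed, bins):
        # strictly decreasing random DVH: dose_at_volume and volume_at_dose invert
        r = np.random.default_rng(seed)
        edges = np.concatenate([[0.0], np.cumsum(r.uniform(0.1, 3.0, size=bins))])
        drops = r.uniform(0.01, 1.0, size=bins)
        frac = np.concatenate([[1.0], 1.0 - np.cumsum(drops) / drops.sum()])
        frac[-1] = 0.0
        dvh = DVH(edges, frac, 50.0)
        for f in r.uniform(0.01, 0.99, size=5):
            d = dose_at_volume(dvh, VolumeSpec("percent", 100 * f))
            assert volume_at_dose(dvh, d) == pytest.approx(f, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_binned_dvh_within_one_bin_of_oracle(self, seed):
        r = np.random.default_rng(seed)
        shape = (8, 8, 8)
        values = r.uniform(0, 80, size=shape)
        grid = DoseGrid(values=values, voxel_size=(2, 2, 2))
        mask = StructureMask(mask=np.ones(shape, dtype=bool))
        bw = 0.1
        dvh = compute_dvh(grid, mask, bin_width=bw)
        doses = np.sort(values.ravel())[::-1]
        n = doses.size
        for v in (1, 5, 10, 20, 50):
            # smallest dose with empirical survival <= v/100 (infimum is the
            # voxel dose at 0-based descending index floor(f n))
            m = min(int(np.floor(v / 100 * n + 1e-9)), n - 1)
            oracle = doses[m]
            assert abs(dose_at_volume(dvh, VolumeSpec("percent", v)) - oracle) <= bw
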