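import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nethomog.homogeneity import (compute_nh_map, fisher_z, region_mean_nh,
                                  smooth_nh_map)
from nethomog.io import NetworkMask, Volume4D


def brute_force_nh(series):
    """O(N^2) double-loop oracle: mean correlation with every other voxel."""
    n = series.shape[0]
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i != j:
                acc += np.corrcoef(series[i], series[j])[0, 1]
        out[i] = acc / (n - 1)
    return out


def _vol_mask(series, shape):
    vol = Volume4D(series.reshape(*shape, -1))
    mask = NetworkMask(np.ones(shape, dtype=bool))
    return vol, mask


class TestComputeNH:
    def test_exact_cancellation_three_voxels(self):
        """Series a, a, -a: the first voxel's mean r is (1 + (-1))/2 = 0."""
        a = np.sin(np.linspace(0, 7, 40))
        vol, mask = _vol_mask(np.stack([a, a, -a]), (3, 1, 1))
        nh = compute_nh_map(vol, mask)
        assert nh.mean_r[0] == pytest.approx(0.0, abs=1e-12)
        assert nh.z[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_pair_is_clamped_finite(self):
        a = np.cos(np.linspace(0, 5, 30))
        vol, mask = _vol_mask(np.stack([a, a]), (2, 1, 1))
        nh = compute_nh_map(vol, mask)
        assert nh.mean_r == pytest.approx([1.0, 1.0])
        expected = np.arctanh(1 - 1e-7)
        np.testing.assert_allclose(nh.z, expected)
        assert np.all(np.isfinite(nh.z))

    def test_matches_brute_force_oracle(self, rng):
        series = rng.standard_normal((6, 30))
        vol, mask = _vol_mask(series, (6, 1, 1))
        nh = compute_nh_map(vol, mask)
        np.testing.assert_allclose(nh.mean_r, brute_force_nh(series), atol=1e-10)

    def test_constant_series_reported_with_voxel(self):
        series = np.random.default_rng(1).standard_normal((4, 20))
        series[2] = 5.0
        vol, mask = _vol_mask(series, (4, 1, 1))
        with pytest.raises(ValueError, match="constant"):
            compute_nh_map(vol, mask)

    def test_affine_rescaling_invariance(self, rng):
        series = rng.standard_normal((8, 25))
        vol, mask = _vol_mask(series, (8, 1, 1))
        base = compute_nh_map(vol, mask)
        scaled = compute_nh_map(Volume4D((3.7 * series + 11.0).reshape(8, 1, 1, -1)), mask)
        np.testing.assert_allclose(base.mean_r, scaled.mean_r, atol=1e-10)


class TestFisherZ:
    def test_reference_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.2)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)


class TestSmoothing:
    def test_constant_map_is_preserved(self, rng):
        from nethomog.homogeneity import NHMap

        grid = np.zeros((8, 8, 8), dtype=bool)
        grid[2:6, 2:6, 2:6] = True
        mask = NetworkMask(grid)
        z = np.full(mask.n_voxels, 0.37)
        nh = NHMap(mean_r=np.tanh(z), z=z, mask=mask)
        sm = smooth_nh_map(nh, fwhm_mm=8.0, voxel_size_mm=3.0)
        np.testing.assert_allclose(sm.z, 0.37, atol=1e-10)

    def test_impulse_mass_conserved_inside_mask(self):
        from nethomog.homogeneity import NHMap

        grid = np.ones((11, 11, 11), dtype=bool)
        mask = NetworkMask(grid)
        z = np.zeros(mask.n_voxels)
        center = np.ravel_multi_index((5, 5, 5), (11, 11, 11))
        z[center] = 1.0
        nh = NHMap(mean_r=np.tanh(z), z=z, mask=mask)
        sm = smooth_nh_map(nh, fwhm_mm=6.0, voxel_size_mm=3.0)
        # renormalized smoothing preserves total mass up to edge truncation
        assert sm.z.sum() == pytest.approx(1.0, abs=1e-3)

    def test_output_autocorrelation_width_matches_kernel(self, rng):
        """Smoothing white noise with an 8-mm kernel yields ~8-mm smoothness."""
        from nethomog.group_stats import estimate_smoothness
        from nethomog.homogeneity import NHMap

        grid = np.ones((16, 16, 16), dtype=bool)
        mask = NetworkMask(grid)
        maps = []
        for _ in range(8):
            z = rng.standard_normal(mask.n_voxels)
            nh = NHMap(mean_r=np.tanh(z), z=z, mask=mask)
            maps.append(smooth_nh_map(nh, fwhm_mm=8.0, voxel_size_mm=3.0).z)
        sm = estimate_smoothness(np.asarray(maps), mask, voxel_size_mm=3.0)
        np.testing.assert_allclose(sm.fwhm_mm, 8.0, rtol=0.2)

    def test_subvoxel_fwhm_warns(self):
        from nethomog.homogeneity import NHMap

        mask = NetworkMask(np.ones((4, 4, 4), dtype=bool))
        nh = NHMap(mean_r=np.zeros(64), z=np.zeros(64), mask=mask)
        with pytest.warns(UserWarning, match="below one voxel"):
            smooth_nh_map(nh, fwhm_mm=1.0, voxel_size_mm=3.0)


class TestRegionMean:
    def _nh(self, rng, shape=(6, 6, 6)):
        from nethomog.homogeneity import NHMap

        mask = NetworkMask(np.ones(shape, dtype=bool))
        z = rng.standard_normal(mask.n_voxels)
        return NHMap(mean_r=np.tanh(z), z=z, mask=mask), mask

    def test_single_voxel_region(self, rng):
        nh, mask = self._nh(rng)
        region = np.zeros(mask.shape, dtype=bool)
        region[2, 3, 4] = True
        grid = nh.to_grid("z")
        assert region_mean_nh(nh, region) == pytest.approx(grid[2, 3, 4])

    def test_uniform_map_returns_constant(self):
        from nethomog.homogeneity import NHMap

        mask = NetworkMask(np.ones((4, 4, 4), dtype=bool))
        nh = NHMap(mean_r=np.tanh(np.full(64, 1.5)), z=np.full(64, 1.5), mask=mask)
        region = np.zeros((4, 4, 4), dtype=bool)
        region[:2] = True
        assert region_mean_nh(nh, region) == pytest.approx(1.5)

    def test_matches_explicit_mean_over_listed_voxels(self, rng):
        nh, mask = self._nh(rng)
        voxels = [(0, 0, 0), (1, 2, 3), (5, 5, 5), (2, 2, 2)]
        region = np.zeros(mask.shape, dtype=bool)
        for v in voxels:
            region[v] = True
        grid = nh.to_grid("z")
        expected = np.mean([grid[v] for v in voxels])
        assert region_mean_nh(nh, region) == pytest.approx(expected, abs=1e-12)

    def test_region_outside_mask_rejected(self, rng):
        from nethomog.homogeneity import NHMap

        grid = np.zeros((6, 6, 6), dtype=bool)
        grid[:3] = True
        mask = NetworkMask(grid)
        nh = NHMap(mean_r=np.zeros(mask.n_voxels), z=np.zeros(mask.n_voxels), mask=mask)
        region = np.zeros((6, 6, 6), dtype=bool)
        region[4, 4, 4] = True
        with pytest.raises(ValueError, match="outside"):
            region_mean_nh(nh, region)


def test_transform_then_average_variant(rng):
    """The optional variant averages Fisher z of each pairwise r instead of
    transforming the average; it must match its own double-loop oracle and
    differ from the default on heterogeneous data."""
    series = rng.standard_normal((7, 25))
    vol, mask = _vol_mask(series, (7, 1, 1))
    nh = compute_nh_map(vol, mask, average_first=False)
    n = series.shape[0]
    oracle = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i != j:
                acc += np.arctanh(np.corrcoef(series[i], series[j])[0, 1])
        oracle[i] = acc / (n - 1)
    np.testing.assert_allclose(nh.z, oracle, atol=1e-10)
    default = compute_nh_map(vol, mask)
    assert not np.allclose(nh.z, default.z)


def test_efficient_equals_oracle_up_to_fifty_voxels(rng):
    """Inner-product accumulation equals the O(N^2) double loop at N=50."""
    series = rng.standard_normal((50, 40))
    vol, mask = _vol_mask(series, (50, 1, 1))
    nh = compute_nh_map(vol, mask)
    np.testing.assert_allclose(nh.mean_r, brute_force_nh(series), atol=1e-10)
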