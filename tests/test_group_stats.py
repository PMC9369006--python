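import numpy as np
import pytest
from scipy import ndimage, stats

from nethomog.group_stats import (GLMResult, SmoothnessEstimate,
                                  estimate_smoothness, fit_voxelwise_glm,
                                  grf_cluster_inference, t_to_z)
from nethomog.io import NetworkMask


def flood_fill_label(binary, connectivity=26):
    """Brute-force 26/6-neighbour connected-component oracle."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(di) + abs(dj) + abs(dk) != 1:
                    continue
                offsets.append((di, dj, dk))
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    for start in np.argwhere(binary):
        start = tuple(start)
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            p = stack.pop()
            for off in offsets:
                q = tuple(np.add(p, off))
                if any(c < 0 or c >= s for c, s in zip(q, binary.shape)):
                    continue
                if binary[q] and not labels[q]:
                    labels[q] = current
                    stack.append(q)
    return labels, current


class TestVoxelwiseGLM:
    def test_reduces_to_pooled_two_sample_t(self, rng):
        y = rng.standard_normal((20, 15))
        g = np.array([1] * 10 + [0] * 10)
        glm = fit_voxelwise_glm(y, g)
        for v in range(15):
            t_ref, _ = stats.ttest_ind(y[g == 1, v], y[g == 0, v])
            assert glm.t[v] == pytest.approx(t_ref, abs=1e-10)
        assert glm.df == 18

    def test_planted_difference_yields_expected_t(self):
        """Mean difference d with noise sd s at n=20+20 gives t ~ d/(s sqrt(2/20))."""
        d, s = 0.5, 1.0
        ts = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            y = r.normal(0, s, size=(40, 10))
            y[:20] += d
            g = np.array([1] * 20 + [0] * 20)
            ts.append(fit_voxelwise_glm(y, g).t.mean())
        expected = d / (s * np.sqrt(2 / 20))
        assert np.mean(ts) == pytest.approx(expected, rel=0.15)

    def test_collinear_covariate_named(self, rng):
        y = rng.standard_normal((12, 5))
        g = np.array([1] * 6 + [0] * 6)
        with pytest.raises(ValueError, match="group_copy"):
            fit_voxelwise_glm(y, g, covariates=g[:, None].astype(float),
                              covariate_names=["group_copy"])

    def test_null_covariates_leave_t_centered(self, rng):
        y = rng.standard_normal((30, 200))
        g = np.array([1] * 15 + [0] * 15)
        covs = rng.standard_normal((30, 3))
        plain = fit_voxelwise_glm(y, g)
        with_covs = fit_voxelwise_glm(y, g, covariates=covs)
        assert with_covs.df == plain.df - 3
        assert abs(with_covs.t.mean()) < 0.15

    def test_minimum_group_size_enforced(self, rng):
        y = rng.standard_normal((4, 5))
        with pytest.raises(ValueError, match="2 subjects per group"):
            fit_voxelwise_glm(y, np.array([1, 0, 0, 0]))


class TestSmoothness:
    def _smoothed_noise(self, rng, fwhm_vox, shape=(16, 16, 16), n=10):
        from scipy.ndimage import gaussian_filter

        sigma = fwhm_vox / (2 * np.sqrt(2 * np.log(2)))
        return np.stack([gaussian_filter(rng.standard_normal(shape), sigma).ravel()
                         for _ in range(n)])

    def test_known_kernel_recovered(self, rng):
        mask = NetworkMask(np.ones((16, 16, 16), dtype=bool))
        resid = self._smoothed_noise(rng, fwhm_vox=2.0)  # 6 mm at 3 mm voxels
        sm = estimate_smoothness(resid, mask, voxel_size_mm=3.0)
        np.testing.assert_allclose(sm.fwhm_mm, 6.0, rtol=0.2)

    def test_unsmoothed_noise_has_subvoxel_fwhm(self, rng):
        mask = NetworkMask(np.ones((16, 16, 16), dtype=bool))
        resid = np.stack([rng.standard_normal(16**3) for _ in range(10)])
        sm = estimate_smoothness(resid, mask, voxel_size_mm=3.0)
        # white noise: roughness of one voxel width, within 30%
        np.testing.assert_allclose(sm.fwhm_mm, 3.0, rtol=0.3)

    def test_fwhm_scales_with_voxel_size(self, rng):
        mask = NetworkMask(np.ones((16, 16, 16), dtype=bool))
        resid = self._smoothed_noise(rng, fwhm_vox=2.0)
        a = estimate_smoothness(resid, mask, voxel_size_mm=3.0)
        b = estimate_smoothness(resid, mask, voxel_size_mm=6.0)
        np.testing.assert_allclose(b.fwhm_mm, 2 * a.fwhm_mm, rtol=1e-10)
        assert b.resels == pytest.approx(a.resels, rel=1e-10)

    def test_needs_three_subjects(self, rng):
        mask = NetworkMask(np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError, match="3 subjects"):
            estimate_smoothness(rng.standard_normal((2, 64)), mask)


class TestClusterLabelling:
    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        shape = (12, 13, 11)
        binary = rng.random(shape) < 0.25
        structure = (np.ones((3, 3, 3)) if connectivity == 26
                     else ndimage.generate_binary_structure(3, 1))
        labels, n = ndimage.label(binary, structure=structure)
        _, n_oracle = flood_fill_label(binary, connectivity)
        assert n == n_oracle


def _make_glm(t_values, df=18, n_vox=None):
    n_vox = n_vox or len(t_values)
    return GLMResult(t=np.asarray(t_values, dtype=float), df=df,
                     residuals=np.zeros((df + 2, n_vox)), design_columns=["intercept", "group"])


class TestGRFInference:
    def test_all_zero_t_map_yields_empty_table(self):
        mask = NetworkMask(np.ones((8, 8, 8), dtype=bool))
        glm = _make_glm(np.zeros(512))
        sm = SmoothnessEstimate(fwhm_mm=[8, 8, 8], resels=20.0)
        table = grf_cluster_inference(glm, sm, mask)
        assert len(table) == 0

    def test_planted_blob_survives_and_overlaps(self):
        """A 60-voxel blob of |t|=8 on a null background survives with high
        overlap and the correct direction."""
        rng = np.random.default_rng(0)
        shape = (15, 15, 15)
        mask = NetworkMask(np.ones(shape, dtype=bool))
        t = 0.3 * rng.standard_normal(mask.n_voxels)
        grid = np.zeros(shape)
        grid[mask.grid] = t
        blob = np.zeros(shape, dtype=bool)
        blob[5:10, 5:9, 5:8] = True  # 60 voxels
        grid[blob] = -8.0
        glm = _make_glm(grid[mask.grid])
        sm = SmoothnessEstimate(fwhm_mm=[8, 8, 8], resels=mask.n_voxels * 27 / 512)
        table = grf_cluster_inference(glm, sm, mask)
        assert len(table) == 1
        c = table.clusters[0]
        assert c.direction == "patients<controls"
        found = np.zeros(shape, dtype=bool)
        found[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]] = True
        dice = 2 * (found & blob).sum() / (found.sum() + blob.sum())
        assert dice > 0.5
        assert c.peak_t == pytest.approx(-8.0)

    def test_stricter_voxel_threshold_never_grows_clusters(self):
        rng = np.random.default_rng(3)
        shape = (12, 12, 12)
        mask = NetworkMask(np.ones(shape, dtype=bool))
        t = rng.standard_normal(mask.n_voxels) * 2.5
        glm = _make_glm(t)
        sm = SmoothnessEstimate(fwhm_mm=[6, 6, 6], resels=50.0)
        loose = grf_cluster_inference(glm, sm, mask, voxel_p=0.01, cluster_p=1.0 - 1e-9)
        strict = grf_cluster_inference(glm, sm, mask, voxel_p=0.001, cluster_p=1.0 - 1e-9)
        assert sum(c.size for c in strict.clusters) <= sum(c.size for c in loose.clusters)

    def test_voxel_p_range_validated(self):
        mask = NetworkMask(np.ones((4, 4, 4), dtype=bool))
        glm = _make_glm(np.zeros(64))
        sm = SmoothnessEstimate(fwhm_mm=[8, 8, 8], resels=5.0)
        with pytest.raises(ValueError, match="voxel_p"):
            grf_cluster_inference(glm, sm, mask, voxel_p=0.7)

    def test_cluster_table_reports_world_coordinates(self):
        shape = (10, 10, 10)
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = [-12.0, -12.0, -12.0]
        mask = NetworkMask(np.ones(shape, dtype=bool), affine=affine)
        grid = np.zeros(shape)
        grid[4:7, 4:7, 4:7] = 9.0
        glm = _make_glm(grid[mask.grid])
        sm = SmoothnessEstimate(fwhm_mm=[8, 8, 8], resels=20.0)
        table = grf_cluster_inference(glm, sm, mask)
        assert len(table) == 1
        df = table.to_dataframe()
        i, j, k = df.loc[0, ["peak_i", "peak_j", "peak_k"]]
        np.testing.assert_allclose(
            df.loc[0, ["peak_x", "peak_y", "peak_z"]].to_numpy(dtype=float),
            np.array([i, j, k], dtype=float) * 3.0 - 12.0)


def test_t_to_z_preserves_tail_probability():
    t = np.array([-4.0, -1.0, 0.0, 2.0, 5.0])
    df = 18
    z = t_to_z(t, df)
    np.testing.assert_allclose(stats.norm.sf(np.abs(z)), stats.t.sf(np.abs(t), df), rtol=1e-8)
    assert np.all(np.sign(z) == np.sign(t))
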