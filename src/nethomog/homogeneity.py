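"""Network homogeneity (NH): per-voxel mean correlation within a network mask.

For a mask of N voxels, the NH of voxel i is the mean Pearson correlation of
its time series with the N-1 other masked series (self-correlation
excluded), Fisher r-to-z transformed. The efficient path standardizes every
series once and accumulates the correlation sums by inner products; a
brute-force double loop over voxel pairs gives the same numbers and serves
as the test oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import NetworkMask, Volume4D

__all__ = ["NHMap", "compute_nh_map", "fisher_z", "smooth_nh_map", "region_mean_nh", "FWHM_TO_SIGMA"]

#: sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_CLAMP = 1.0 - 1e-7


@dataclass
class NHMap:
    """Per-voxel homogeneity over a mask: raw mean r and its Fisher z."""

    mean_r: np.ndarray  # (n_mask_voxels,)
    z: np.ndarray  # (n_mask_voxels,)
    mask: NetworkMask
    subject_id: str = ""

    def to_grid(self, which: str = "z") -> np.ndarray:
        """Scatter values into a full 3D grid, zero outside the mask."""
        out = np.zeros(self.mask.shape)
        vals = self.z if which == "z" else self.mean_r
        out[self.mask.grid] = vals
        return out


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z: atanh(r) with |r| clamped to 1 - 1e-7 so z stays finite."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(r, -_CLAMP, _CLAMP))
    return float(out) if out.ndim == 0 else out


def _masked_series(vol: Volume4D, mask: NetworkMask) -> np.ndarray:
    mask.check_compatible(vol)
    return vol.data[mask.grid].astype(np.float64)  # (N, T), C-order of mask voxels


def compute_nh_map(vol: Volume4D, mask: NetworkMask, subject_id: str = "",
                   average_first: bool = True) -> NHMap:
    """NH of every mask voxel: mean correlation with all other mask voxels.

    By default the correlations are averaged first and the mean Fisher
    transformed (``z = atanh(mean r)``). With ``average_first=False`` each
    pairwise r is transformed and the z values averaged instead — a variant
    some pipelines use; it materializes the full N x N correlation matrix.

    Raises on constant series inside the mask (correlation undefined) and on
    mask/volume dimension mismatch.
    """
    series = _masked_series(vol, mask)
    n = series.shape[0]
    if n < 2:
        raise ValueError("mask must contain at least 2 voxels")
    centered = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        coords = mask.indices()[dead[:5]]
        raise ValueError(f"constant time series inside mask at voxels {coords.tolist()}")
    std = centered / norms[:, None]
    if average_first:
        # sum_j r_ij = x_i . sum_j x_j ; subtract the self term r_ii = 1
        total = std.sum(axis=0)
        mean_r = (std @ total - 1.0) / (n - 1)
        mean_r = np.clip(mean_r, -1.0, 1.0)  # guard float drift past +-1
        return NHMap(mean_r=mean_r, z=fisher_z(mean_r), mask=mask, subject_id=subject_id)
    R = np.clip(std @ std.T, -1.0, 1.0)
    Z = np.arctanh(np.clip(R, -_CLAMP, _CLAMP))
    np.fill_diagonal(Z, 0.0)
    z = Z.sum(axis=1) / (n - 1)
    return NHMap(mean_r=np.tanh(z), z=z, mask=mask, subject_id=subject_id)


def smooth_nh_map(nh: NHMap, fwhm_mm: float = 8.0, voxel_size_mm: float | np.ndarray | None = None) -> NHMap:
    """Gaussian smoothing of the z map, renormalized within the mask.

    The kernel uses sigma = FWHM / (2 sqrt(2 ln 2)) per axis in mm. Both the
    value map and the mask indicator are smoothed and their ratio taken, so
    out-of-mask voxels neither leak signal in nor dilute mask-edge voxels;
    a constant map is exactly preserved.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if voxel_size_mm is None:
        voxel_size_mm = np.sqrt((nh.mask.affine[:3, :3] ** 2).sum(axis=0))
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    if fwhm_mm < float(np.min(voxel_size_mm)):
        warnings.warn("smoothing FWHM is below one voxel; effect will be negligible", stacklevel=2)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    grid = nh.to_grid("z")
    ind = nh.mask.grid.astype(np.float64)
    num = gaussian_filter(grid, sigma=sigma_vox)
    den = gaussian_filter(ind, sigma=sigma_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / den, 0.0)
    z = sm[nh.mask.grid]
    return NHMap(mean_r=np.tanh(z), z=z, mask=nh.mask, subject_id=nh.subject_id)


def region_mean_nh(nh: NHMap, region: NetworkMask | np.ndarray) -> float:
    """Mean Fisher-z NH over a region; the scalar feature for regression and
    classification. The region (a mask or boolean grid, possibly a single
    voxel) must be a nonempty subset of the NH mask."""
    grid = region.grid if isinstance(region, NetworkMask) else np.asarray(region, dtype=bool)
    if grid.shape != nh.mask.shape:
        raise ValueError("region and NH mask have different grid shapes")
    if np.any(grid & ~nh.mask.grid):
        raise ValueError("region extends outside the NH mask")
    sel = grid[nh.mask.grid]
    if not sel.any():
        raise ValueError("region selects no mask voxels")
    return float(nh.z[sel].mean())
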