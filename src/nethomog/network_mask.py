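"""Network-mask derivation by temporal-concatenation group ICA.

The classic three-stage recipe: (1) per-subject PCA reduction of each
time-by-voxel matrix, (2) concatenation across subjects and a second PCA,
(3) fixed-point (FastICA) unmixing of the reduced data into independent
spatial maps, which are z-scored. The component best matching a network
template (by absolute spatial correlation) is binarized into the analysis
mask. Back-reconstruction projects the group maps onto each subject's data
to give subject-specific time courses.

The component count is fixed (default 20) rather than estimated from the
data; a user-supplied mask can bypass this stage entirely since the
downstream homogeneity analysis is mask-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA

from .io import NetworkMask, Volume4D

__all__ = [
    "ICADecomposition",
    "GroupICA",
    "group_ica",
    "select_network_component",
    "component_to_mask",
    "extract_network_mask",
]


@dataclass
class ICADecomposition:
    """Group ICA output: z-scored spatial maps plus subject time courses."""

    n_components: int
    spatial_maps: np.ndarray  # (k, n_voxels), z-scored per component
    mixing: list[np.ndarray]  # per subject (T_i, k) back-reconstructed time courses
    mask: NetworkMask | None = None

    def map_grid(self, index: int) -> np.ndarray:
        if self.mask is None:
            raise ValueError("decomposition has no mask geometry attached")
        out = np.zeros(self.mask.shape)
        out[self.mask.grid] = self.spatial_maps[index]
        return out


class GroupICA(BaseEstimator):
    """Temporal-concatenation group spatial ICA.

    Parameters
    ----------
    n_components : int
        Number of independent components (fixed, not estimated).
    random_state : int or None
        Seed for the FastICA fixed-point iteration; a fixed seed makes the
        decomposition fully deterministic.

    Attributes
    ----------
    components_ : ndarray of shape (n_components, n_voxels)
        z-scored independent spatial maps.
    mixing_ : list of ndarray
        Per-subject (T_i, n_components) time courses from back-reconstruction.
    mean_ : ndarray
        Per-voxel mean of the concatenated reduced data.
    """

    def __init__(self, n_components: int = 20, random_state: int | None = None,
                 max_iter: int = 1000, tol: float = 1e-6):
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: list[np.ndarray], y=None) -> "GroupICA":
        """Fit on a list of per-subject (T_i, n_voxels) matrices."""
        if len(X) < 2:
            raise ValueError("group ICA needs at least 2 subjects")
        n_vox = X[0].shape[1]
        total_t = sum(x.shape[0] for x in X)
        k = self.n_components
        if k >= total_t:
            raise ValueError(f"n_components={k} must be below total timepoints {total_t}")
        centered = []
        reduced = []
        for x in X:
            x = np.asarray(x, dtype=np.float64)
            if x.shape[1] != n_vox:
                raise ValueError("all subjects must have the same voxel count")
            x = x - x.mean(axis=0, keepdims=True)
            if np.any(np.all(x == 0.0, axis=0)):
                raise ValueError("degenerate constant voxel series in input")
            centered.append(x)
            k_sub = min(k, *x.shape)
            u, s, vt = np.linalg.svd(x, full_matrices=False)
            reduced.append(s[:k_sub, None] * vt[:k_sub])  # (k_sub, n_vox)
        concat = np.vstack(reduced)
        if np.linalg.matrix_rank(concat) < k:
            raise ValueError(f"data rank is below n_components={k}")
        u, s, vt = np.linalg.svd(concat, full_matrices=False)
        group_reduced = s[:k, None] * vt[:k]  # (k, n_vox)

        self.mean_ = group_reduced.mean(axis=1)
        ica = FastICA(
            n_components=k,
            random_state=self.random_state,
            max_iter=self.max_iter,
            tol=self.tol,
            whiten="unit-variance",
        )
        sources = ica.fit_transform(group_reduced.T)  # (n_vox, k): spatial maps
        maps = sources.T
        mu = maps.mean(axis=1, keepdims=True)
        sd = maps.std(axis=1, keepdims=True)
        self.components_ = (maps - mu) / sd
        # back-reconstruction: project each subject's data on the group maps
        pinv_maps = np.linalg.pinv(self.components_)  # (n_vox, k)
        self.mixing_ = [x @ pinv_maps for x in centered]
        return self

    def to_decomposition(self, mask: NetworkMask | None = None) -> ICADecomposition:
        return ICADecomposition(
            n_components=self.n_components,
            spatial_maps=self.components_,
            mixing=self.mixing_,
            mask=mask,
        )


def group_ica(volumes: list[Volume4D], mask: NetworkMask, n_components: int = 20,
              seed: int | None = None) -> ICADecomposition:
    """Run group ICA on the masked voxel series of a cohort."""
    X = [vol.data[mask.grid].T.astype(np.float64) for vol in volumes]  # (T, n_vox) each
    est = GroupICA(n_components=n_components, random_state=seed).fit(X)
    return est.to_decomposition(mask=mask)


def select_network_component(dec: ICADecomposition, template: NetworkMask | np.ndarray) -> tuple[int, float]:
    """Pick the component whose map best matches the template.

    Returns ``(index, score)`` where score is the maximal absolute Pearson
    correlation between a component map and the template indicator over the
    analyzable voxels; ties resolve to the lowest index. An all-true
    template degenerates to matching the map mean.
    """
    grid = template.grid if isinstance(template, NetworkMask) else np.asarray(template, dtype=bool)
    if dec.mask is not None:
        if grid.shape != dec.mask.shape:
            raise ValueError("template grid does not match decomposition geometry")
        ind = grid[dec.mask.grid].astype(np.float64)
    else:
        ind = grid.ravel().astype(np.float64)
    if ind.sum() == 0:
        raise ValueError("empty template")
    maps = dec.spatial_maps
    ind_c = ind - ind.mean()
    denom_t = np.linalg.norm(ind_c)
    scores = np.empty(maps.shape[0])
    for i, m in enumerate(maps):
        m_c = m - m.mean()
        if denom_t == 0 or np.linalg.norm(m_c) == 0:
            # degenerate: constant template (all-true) -> rank by map mean
            scores[i] = maps[i].mean()
        else:
            scores[i] = abs(float(m_c @ ind_c) / (np.linalg.norm(m_c) * denom_t))
    best = int(np.argmax(scores))  # argmax returns the first (lowest) index on ties
    return best, float(scores[best])


def component_to_mask(map_values: np.ndarray, z_threshold: float = 1.0,
                      geometry: NetworkMask | None = None) -> NetworkMask | np.ndarray:
    """Binarize a z-scored component map at ``z > z_threshold``.

    ``map_values`` may be a 3D grid or a flat per-voxel vector with
    ``geometry`` giving the analyzable-voxel mask. Raises when fewer than 2
    voxels survive.
    """
    map_values = np.asarray(map_values, dtype=float)
    if map_values.ndim == 1:
        if geometry is None:
            raise ValueError("flat map needs a geometry mask")
        above = map_values > z_threshold
        if above.sum() < 2:
            raise ValueError(f"threshold z > {z_threshold} leaves {int(above.sum())} voxels (need >= 2)")
        grid = np.zeros(geometry.shape, dtype=bool)
        grid[geometry.grid] = above
        return NetworkMask(grid=grid, affine=geometry.affine)
    grid = map_values > z_threshold
    if grid.sum() < 2:
        raise ValueError(f"threshold z > {z_threshold} leaves {int(grid.sum())} voxels (need >= 2)")
    return NetworkMask(grid=grid)


def extract_network_mask(dec: ICADecomposition, template: NetworkMask | np.ndarray,
                         z_threshold: float = 1.0) -> tuple[NetworkMask, int, float]:
    """Select the template-matched component, orient its sign toward the
    template, and binarize it. Returns (mask, component index, match score)."""
    idx, score = select_network_component(dec, template)
    grid = template.grid if isinstance(template, NetworkMask) else np.asarray(template, dtype=bool)
    m = dec.spatial_maps[idx]
    ind = grid[dec.mask.grid].astype(float) if dec.mask is not None else grid.ravel().astype(float)
    signed = float((m - m.mean()) @ (ind - ind.mean()))
    if signed < 0:
        m = -m
    mask = component_to_mask(m, z_threshold=z_threshold, geometry=dec.mask)
    return mask, idx, score
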