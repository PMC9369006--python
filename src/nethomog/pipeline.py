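"""End-to-end study runners chaining the analysis stages.

These are the functions the command-line interface and the reproduction
script call: simulate a cohort, compute smoothed NH maps, run the
voxelwise group comparison with GRF correction, regional brain-behavior
regressions, and ROC/SVM classification. They also host the two
simulation-based validation routines — family-wise-error calibration on
null cohorts and planted-effect recovery — that back the statistical
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .clinical_assoc import association_table, group_comparison_table
from .classify import roc_with_youden, subset_search
from .group_stats import (ClusterTable, GLMResult, SmoothnessEstimate,
                          estimate_smoothness, fit_voxelwise_glm,
                          grf_cluster_inference)
from .homogeneity import compute_nh_map, region_mean_nh, smooth_nh_map
from .io import COGNITION_COLUMNS, NetworkMask, Volume4D
from .simulate import (RegionSpec, SimulationConfig, SyntheticCohort,
                       default_config, generate_cohort, generate_null_cohort,
                       sphere_voxels)

__all__ = [
    "nh_matrix",
    "regional_features",
    "group_nh_analysis",
    "StudyResult",
    "run_study",
    "fwe_calibration",
    "planted_effect_dice",
    "nearest_voxel_ball",
]


def nh_matrix(volumes: list[Volume4D], mask: NetworkMask,
              smooth_fwhm_mm: float | None = 8.0) -> np.ndarray:
    """Per-subject smoothed NH z values: (n_subjects, n_mask_voxels)."""
    rows = []
    for vol in volumes:
        nh = compute_nh_map(vol, mask)
        if smooth_fwhm_mm:
            nh = smooth_nh_map(nh, fwhm_mm=smooth_fwhm_mm)
        rows.append(nh.z)
    return np.asarray(rows)


def regional_features(nh: np.ndarray, mask: NetworkMask,
                      regions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Region-mean NH per subject for each named region (voxel-coordinate sets)."""
    key = {tuple(v): i for i, v in enumerate(map(tuple, mask.indices()))}
    out = {}
    for name, voxels in regions.items():
        rows = [key[tuple(v)] for v in np.atleast_2d(voxels) if tuple(v) in key]
        if not rows:
            raise ValueError(f"region {name!r} has no voxels inside the mask")
        out[name] = nh[:, rows].mean(axis=1)
    return pd.DataFrame(out)


def group_nh_analysis(nh: np.ndarray, group_labels: np.ndarray, mask: NetworkMask,
                      covariates: pd.DataFrame | None = None,
                      voxel_p: float = 0.001, cluster_p: float = 0.05,
                      connectivity: int = 26) -> tuple[GLMResult, SmoothnessEstimate, ClusterTable]:
    """Voxelwise group GLM + smoothness estimation + GRF cluster inference."""
    glm = fit_voxelwise_glm(nh, group_labels, covariates)
    sm = estimate_smoothness(glm.residuals, mask)
    clusters = grf_cluster_inference(glm, sm, mask, voxel_p=voxel_p,
                                     cluster_p=cluster_p, connectivity=connectivity)
    return glm, sm, clusters


@dataclass
class StudyResult:
    cohort: SyntheticCohort
    nh: np.ndarray
    glm: GLMResult
    smoothness: SmoothnessEstimate
    clusters: ClusterTable
    demographics: pd.DataFrame
    associations: pd.DataFrame
    roc: pd.DataFrame
    svm_subsets: pd.DataFrame
    features: pd.DataFrame


def run_study(config: SimulationConfig | None = None, seed: int = 0,
              smooth_fwhm_mm: float = 8.0, voxel_p: float = 0.001,
              cluster_p: float = 0.05, svm_C_grid=None, svm_gamma_grid=None) -> StudyResult:
    """Simulate a cohort and run every analysis stage on it.

    The network mask is the generator's truth mask (a user-supplied mask
    plays the same role on real data); regional features for regression and
    classification come from the planted regions.
    """
    from .classify import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID

    config = config or default_config(seed=seed)
    cohort = generate_cohort(config)
    mask = cohort.truth_mask
    labels = cohort.table["group_code"].to_numpy()
    nh = nh_matrix(cohort.volumes, mask, smooth_fwhm_mm=smooth_fwhm_mm)
    covs = cohort.table[["age", "sex", "education"]]
    glm, sm, clusters = group_nh_analysis(nh, labels, mask, covariates=covs,
                                          voxel_p=voxel_p, cluster_p=cluster_p)
    demo = group_comparison_table(cohort.table, ["age", "education"] + COGNITION_COLUMNS)
    feats = regional_features(nh, mask, {r.name: r.voxel_set for r in cohort.regions})
    feats.index = cohort.table["subject_id"].tolist()
    assoc = association_table(
        cohort.table, feats,
        outcomes=["panss_positive", "panss_negative", "panss_general"] + COGNITION_COLUMNS,
    )
    roc_rows = []
    for name in feats.columns:
        r = roc_with_youden(feats[name].to_numpy(), labels)
        roc_rows.append(dict(region=name, auc=r.auc, cutoff=r.cutoff,
                             sensitivity_pct=100 * r.sensitivity,
                             specificity_pct=100 * r.specificity,
                             accuracy_pct=100 * r.accuracy, flipped=r.flipped))
    svm = subset_search(feats.to_numpy(), labels,
                        C_grid=svm_C_grid or DEFAULT_C_GRID,
                        gamma_grid=svm_gamma_grid or DEFAULT_GAMMA_GRID)
    return StudyResult(cohort=cohort, nh=nh, glm=glm, smoothness=sm, clusters=clusters,
                       demographics=demo, associations=assoc, roc=pd.DataFrame(roc_rows),
                       svm_subsets=svm, features=feats)


def _calibration_config(seed: int) -> SimulationConfig:
    """Null-calibration conditions: 15^3 grid, 10+10 subjects, three ~90-voxel
    regions with moderate within-network coupling (lambda = 0.5)."""
    grid = (15, 15, 15)
    centers = [(4, 4, 4), (10, 10, 4), (7, 5, 11)]
    regions = tuple(
        RegionSpec(name=f"region_{i}", voxel_set=sphere_voxels(c, 2.5, grid),
                   loading_patients=0.5, loading_controls=0.5)
        for i, c in enumerate(centers)
    )
    return SimulationConfig(grid_dims=grid, n_patients=10, n_controls=10,
                            regions=regions, covariate_model={}, seed=seed)


def fwe_calibration(n_replicates: int = 500, seed: int = 0,
                    voxel_p: float = 0.001, cluster_p: float = 0.05,
                    smooth_fwhm_mm: float = 8.0) -> float:
    """Family-wise false-positive rate of GRF cluster inference under the null.

    Each replicate draws a null cohort (identical group distributions) and
    runs the NH -> smoothing -> GLM -> GRF chain over an analysis mask
    spanning the whole grid — a search volume of network scale (hundreds of
    resels at 8-mm smoothness), where cluster-level random-field theory is
    actually exercised. Returns the fraction of replicates with any
    surviving cluster, which should sit near the nominal ``cluster_p``.
    """
    hits = 0
    for rep in range(n_replicates):
        cfg = _calibration_config(seed=seed + rep)
        cohort = generate_null_cohort(cfg)
        mask = NetworkMask(grid=np.ones(cfg.grid_dims, dtype=bool), affine=cfg.affine)
        nh = nh_matrix(cohort.volumes, mask, smooth_fwhm_mm=smooth_fwhm_mm)
        labels = cohort.table["group_code"].to_numpy()
        _, _, clusters = group_nh_analysis(nh, labels, mask, covariates=None,
                                           voxel_p=voxel_p, cluster_p=cluster_p)
        if len(clusters):
            hits += 1
    return hits / n_replicates


def nearest_voxel_ball(center: tuple[int, int, int], k: int,
                       shape: tuple[int, int, int]) -> np.ndarray:
    """The k voxels nearest to ``center`` (a quasi-spherical region of exact size)."""
    vox = sphere_voxels(center, max(2.0, k ** (1 / 3) * 1.5), shape)
    d = np.linalg.norm(vox - np.asarray(center), axis=1)
    order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0], d))
    return vox[order[:k]]


def _effect_config(seed: int, lam_patients: float, lam_controls: float,
                   region_size: int) -> tuple[SimulationConfig, np.ndarray]:
    """20^3 study grid with one affected region and three null regions."""
    grid = (20, 20, 20)
    target = nearest_voxel_ball((5, 5, 5), region_size, grid)
    others = [
        RegionSpec("null_a", sphere_voxels((14, 5, 14), 2.5, grid), 0.5, 0.5),
        RegionSpec("null_b", sphere_voxels((5, 14, 14), 2.5, grid), 0.5, 0.5),
        RegionSpec("null_c", sphere_voxels((14, 14, 5), 2.5, grid), 0.5, 0.5),
    ]
    regions = (RegionSpec("target", target, lam_patients, lam_controls), *others)
    cfg = SimulationConfig(grid_dims=grid, n_patients=20, n_controls=20,
                           regions=regions, covariate_model={}, seed=seed)
    return cfg, target


def planted_effect_dice(seed: int = 0, lam_patients: float = 0.7,
                        lam_controls: float = 0.4, region_size: int = 30,
                        voxel_p: float = 0.001, cluster_p: float = 0.05) -> float:
    """Recovery of a planted regional coupling difference.

    Plants a region whose shared-factor loading differs between groups,
    runs the full NH group comparison, and returns the best Dice overlap
    between a surviving cluster and the affected region (0.0 when nothing
    survives).
    """
    cfg, target = _effect_config(seed, lam_patients, lam_controls, region_size)
    cohort = generate_cohort(cfg)
    mask = cohort.truth_mask
    nh = nh_matrix(cohort.volumes, mask, smooth_fwhm_mm=8.0)
    labels = cohort.table["group_code"].to_numpy()
    _, _, clusters = group_nh_analysis(nh, labels, mask, covariates=None,
                                       voxel_p=voxel_p, cluster_p=cluster_p)
    truth = {tuple(v) for v in target}
    best = 0.0
    for c in clusters.clusters:
        found = {tuple(v) for v in c.voxels}
        dice = 2 * len(truth & found) / (len(truth) + len(found))
        best = max(best, dice)
    return best
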