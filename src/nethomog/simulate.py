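"""Synthetic resting-state cohorts with known network-homogeneity ground truth.

The generator plants a shared-factor signal model: every voxel of a network
region carries

    y_i(t) = lam * s(t) + sqrt(1 - lam^2) * e_i(t)

with a unit-variance latent region series ``s`` and independent unit-variance
Gaussian noise ``e_i``, so the population pairwise correlation between two
voxels of the same region is exactly ``lam**2``. That closed form is what the
recovery and calibration tests key on. Group differences are planted by
giving patients and controls different loadings ``lam`` per region.
Out-of-network voxels are independent noise.

Latent series and noise are white; the band-limited temporal structure of
real BOLD data is imposed later by the preprocessing stage, which keeps the
correlation analytics exact on raw generator output.

Clinical covariates (age, sex, education, PANSS) are drawn from
distributions matching a first-episode schizophrenia cohort, and cognition
scores are linear functions of per-subject regional NH plus demographics
with known coefficients, so stepwise-regression recovery has a stored truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import COGNITION_COLUMNS, NetworkMask, Volume4D

__all__ = [
    "RegionSpec",
    "ScoreModel",
    "SimulationConfig",
    "SyntheticCohort",
    "default_config",
    "default_regions",
    "generate_cohort",
    "generate_clinical_scores",
    "generate_null_cohort",
    "sphere_voxels",
]

# Group-level demographic / clinical distributions (mean, sd) emulating a
# drug-naive first-episode cohort versus matched controls.
_DEMOGRAPHICS = {
    "patient": {
        "age": (31.63, 11.43),
        "education": (12.86, 3.42),
        "duration": (2.41, 2.70),
        "male_fraction": 20 / 57,
        "panss_positive": (26.39, 4.85),
        "panss_negative": (20.68, 6.89),
        "panss_general": (44.79, 7.41),
    },
    "control": {
        "age": (28.38, 6.87),
        "education": (15.64, 2.26),
        "male_fraction": 23 / 50,
    },
}

# Cognition battery: (patient mean, control mean, within-group sd).
_COGNITION = {
    "speed_of_processing": (34.70, 44.28, 10.8),
    "attention_vigilance": (38.19, 45.56, 11.9),
    "verbal_learning": (37.67, 44.52, 11.2),
    "visual_learning": (42.05, 47.16, 10.7),
    "reasoning_problem_solving": (38.84, 45.44, 10.4),
    "working_memory": (32.51, 34.28, 11.8),
    "social_cognition": (33.14, 35.32, 7.4),
    "overall_composite": (28.47, 37.60, 11.7),
}


def sphere_voxels(center: tuple[int, int, int], radius: float, shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel coordinates within ``radius`` (in voxels) of ``center``, clipped to the grid."""
    c = np.asarray(center, dtype=float)
    lo = np.maximum(np.floor(c - radius).astype(int), 0)
    hi = np.minimum(np.ceil(c + radius).astype(int) + 1, np.asarray(shape))
    grids = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].reshape(3, -1).T
    keep = np.linalg.norm(grids - c, axis=1) <= radius
    return grids[keep]


@dataclass(frozen=True)
class RegionSpec:
    """A network region: its voxels and its per-group shared-factor loading."""

    name: str
    voxel_set: np.ndarray  # (k, 3) int voxel coordinates
    loading_patients: float
    loading_controls: float

    def __post_init__(self) -> None:
        vs = np.atleast_2d(np.asarray(self.voxel_set, dtype=int))
        object.__setattr__(self, "voxel_set", vs)
        if vs.shape[0] == 0:
            raise ValueError(f"region {self.name!r}: empty voxel set")
        for lam, grp in ((self.loading_patients, "patients"), (self.loading_controls, "controls")):
            if not (0.0 <= lam < 1.0):
                raise ValueError(f"region {self.name!r}: loading for {grp} must lie in [0, 1), got {lam}")

    def loading(self, group: str) -> float:
        return self.loading_patients if group == "patient" else self.loading_controls


@dataclass(frozen=True)
class ScoreModel:
    """Linear generative model for one clinical/cognition score.

    score = intercept + sum_k beta_k * x_k + N(0, residual_sd)

    Regressor names may be region names (resolved to that subject's
    region-mean NH z value), ``age``, ``education``, ``duration`` or
    ``group`` (patient=1/control=0). With ``standardize_regressors`` the
    regressors are z-scored across the cohort first, so each beta is in
    score units per regressor SD.
    """

    intercept: float
    coefs: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 1.0
    standardize_regressors: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    grid_dims: tuple[int, int, int] = (20, 20, 20)
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    n_patients: int = 20
    n_controls: int = 20
    regions: tuple[RegionSpec, ...] = ()
    network_coherence: float = 0.9
    noise_sd: float = 1.0
    covariate_model: dict[str, ScoreModel] = field(default_factory=dict)
    voxel_size_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if min(self.n_patients, self.n_controls) < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.network_coherence < 1.0):
            raise ValueError("network_coherence must lie in [0, 1)")
        if any(d < 1 for d in self.grid_dims):
            raise ValueError("grid_dims must be positive")
        seen: set[tuple[int, int, int]] = set()
        for reg in self.regions:
            vox = {tuple(v) for v in reg.voxel_set}
            if vox & seen:
                raise ValueError(f"region {reg.name!r} overlaps another region")
            seen |= vox
            if np.any(reg.voxel_set < 0) or np.any(reg.voxel_set >= np.asarray(self.grid_dims)):
                raise ValueError(f"region {reg.name!r} extends outside the grid")

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])


@dataclass
class SyntheticCohort:
    """Generated volumes plus the ground truth behind them."""

    volumes: list[Volume4D]
    table: pd.DataFrame
    truth_mask: NetworkMask
    regions: tuple[RegionSpec, ...]
    region_nh: pd.DataFrame  # per-subject realized region-mean NH (z), one column per region
    config: SimulationConfig
    motion: list[np.ndarray] = field(default_factory=list)  # per subject (T, 6): mm, deg


def default_regions(
    grid_dims: tuple[int, int, int] = (20, 20, 20),
    loadings: dict[str, tuple[float, float]] | None = None,
    radius: float = 2.5,
) -> tuple[RegionSpec, ...]:
    """Four well-separated spherical regions named after DMN nodes.

    Defaults plant the mixed-direction pattern of the motivating study:
    patients couple more strongly in the medial-frontal and cerebellar
    regions and more weakly in the posterior-cingulate and
    inferior-temporal regions.
    """
    if loadings is None:
        loadings = {
            "smfg": (0.65, 0.50),
            "cerebellum_crus": (0.65, 0.50),
            "pcc": (0.50, 0.65),
            "itg": (0.50, 0.65),
        }
    dims = np.asarray(grid_dims)
    lo = np.maximum((0.25 * dims).astype(int), int(np.ceil(radius)))
    hi = np.minimum((0.75 * dims).astype(int), dims - 1 - int(np.ceil(radius)))
    centers = [
        (lo[0], lo[1], lo[2]),
        (hi[0], lo[1], hi[2]),
        (lo[0], hi[1], hi[2]),
        (hi[0], hi[1], lo[2]),
    ]
    out = []
    for (name, (lp, lc)), center in zip(loadings.items(), centers):
        out.append(
            RegionSpec(
                name=name,
                voxel_set=sphere_voxels(center, radius, grid_dims),
                loading_patients=lp,
                loading_controls=lc,
            )
        )
    return tuple(out)


def _default_covariate_model() -> dict[str, ScoreModel]:
    """Cognition scores with group offsets matching the cohort table plus
    moderate NH/demographic couplings (in score units per regressor SD)."""
    model: dict[str, ScoreModel] = {}
    extra = {
        "speed_of_processing": {"itg": -3.0},
        "social_cognition": {"age": 2.5, "cerebellum_crus": -2.0, "itg": -2.0},
        "attention_vigilance": {"age": 3.0},
        "reasoning_problem_solving": {"education": -3.0},
    }
    for name, (pm, cm, sd) in _COGNITION.items():
        coefs = {"group": pm - cm}
        coefs.update(extra.get(name, {}))
        model[name] = ScoreModel(
            intercept=cm, coefs=coefs, residual_sd=sd, standardize_regressors=True
        )
    return model


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale study defaults: 20^3 grid, 4 regions of ~80 voxels, 20+20 subjects."""
    grid = overrides.pop("grid_dims", (20, 20, 20))
    regions = overrides.pop("regions", default_regions(grid))
    cov = overrides.pop("covariate_model", _default_covariate_model())
    return SimulationConfig(
        grid_dims=grid, regions=tuple(regions), covariate_model=cov, seed=seed, **overrides
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def _draw_demographics(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    rows = []
    idx = 0
    for group, n in (("patient", config.n_patients), ("control", config.n_controls)):
        d = _DEMOGRAPHICS[group]
        age = _truncated_normal(rng, *d["age"], 16, 60, n)
        edu = _truncated_normal(rng, *d["education"], 6, 22, n)
        sex = (rng.random(n) < d["male_fraction"]).astype(int)
        if group == "patient":
            dur = _truncated_normal(rng, *d["duration"], 0.1, 20, n)
            panss = {
                k: np.round(_truncated_normal(rng, *d[k], 7, 80, n), 0)
                for k in ("panss_positive", "panss_negative", "panss_general")
            }
        else:
            dur = np.zeros(n)
            panss = {k: np.full(n, np.nan) for k in ("panss_positive", "panss_negative", "panss_general")}
        for i in range(n):
            rows.append(
                dict(
                    subject_id=f"sub-{idx:03d}",
                    group=group,
                    age=round(float(age[i]), 1),
                    sex=int(sex[i]),
                    education=round(float(edu[i]), 1),
                    duration=round(float(dur[i]), 2),
                    panss_positive=panss["panss_positive"][i],
                    panss_negative=panss["panss_negative"][i],
                    panss_general=panss["panss_general"][i],
                )
            )
            idx += 1
    df = pd.DataFrame(rows)
    df["panss_total"] = df[["panss_positive", "panss_negative", "panss_general"]].sum(axis=1, min_count=3)
    df["group_code"] = (df["group"] == "patient").astype(int)
    return df


def _subject_volume(rng: np.random.Generator, config: SimulationConfig, group: str) -> np.ndarray:
    """One subject's X*Y*Z*T grid under the shared-factor model (float32).

    Region latents share a subject-level network factor with weight
    ``network_coherence`` (rho), so the regions cohere as one network:
    s_region = rho * s_net + sqrt(1 - rho^2) * u_region, still unit
    variance, leaving the within-region pairwise correlation exactly
    lambda^2 while making between-region correlations lambda_a lambda_b
    rho^2.
    """
    dims = config.grid_dims
    T = config.n_timepoints
    rho = config.network_coherence
    data = rng.standard_normal(size=(*dims, T)).astype(np.float32)
    s_net = rng.standard_normal(T).astype(np.float32)
    for reg in config.regions:
        lam = reg.loading(group)
        u = rng.standard_normal(T).astype(np.float32)
        s = rho * s_net + np.float32(np.sqrt(1.0 - rho**2)) * u
        ii, jj, kk = reg.voxel_set.T
        data[ii, jj, kk, :] = lam * s + np.sqrt(1.0 - lam**2) * data[ii, jj, kk, :]
    if config.noise_sd != 1.0:
        data *= np.float32(config.noise_sd)
    return data


def _region_mean_nh(data: np.ndarray, regions, mask_idx: np.ndarray) -> dict[str, float]:
    """Region-mean NH (Fisher z) of one subject, computed over the full mask."""
    from .homogeneity import fisher_z  # local import to avoid a cycle

    series = data[mask_idx[:, 0], mask_idx[:, 1], mask_idx[:, 2], :].astype(np.float64)
    n = series.shape[0]
    z = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    z /= norms
    total = z.sum(axis=0)
    mean_r = (z @ total - 1.0) / (n - 1)
    nh = fisher_z(mean_r)
    key = {tuple(v): i for i, v in enumerate(map(tuple, mask_idx))}
    out = {}
    for reg in regions:
        rows = [key[tuple(v)] for v in map(tuple, reg.voxel_set)]
        out[reg.name] = float(nh[rows].mean())
    return out


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort: volumes, clinical table and truth.

    Deterministic under ``config.seed``: the same config reproduces the
    cohort bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    table = _draw_demographics(rng, config)

    mask_grid = np.zeros(config.grid_dims, dtype=bool)
    for reg in config.regions:
        mask_grid[reg.voxel_set[:, 0], reg.voxel_set[:, 1], reg.voxel_set[:, 2]] = True
    truth_mask = NetworkMask(grid=mask_grid, affine=config.affine)
    mask_idx = truth_mask.indices()

    volumes = []
    nh_rows = []
    motion = []
    for _, row in table.iterrows():
        data = _subject_volume(rng, config, row["group"])
        volumes.append(Volume4D(data=data, affine=config.affine))
        nh_rows.append(_region_mean_nh(data, config.regions, mask_idx))
        # slow small-amplitude drift: a random walk well inside the 3 mm / 3 deg gate
        steps = rng.normal(0.0, 0.02, size=(config.n_timepoints, 6))
        steps[0] = 0.0
        motion.append(np.cumsum(steps, axis=0))
    region_nh = pd.DataFrame(nh_rows, index=table["subject_id"].tolist())

    table = generate_clinical_scores(table, region_nh, config.covariate_model, rng)
    return SyntheticCohort(
        volumes=volumes,
        table=table,
        truth_mask=truth_mask,
        regions=config.regions,
        region_nh=region_nh,
        config=config,
        motion=motion,
    )


def generate_clinical_scores(
    table: pd.DataFrame,
    region_nh: pd.DataFrame,
    covariate_model: dict[str, ScoreModel],
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Append score columns generated from per-subject regional NH + demographics.

    Each score is ``intercept + sum_k beta_k * x_k + N(0, residual_sd)``;
    the coefficients are the stored ground truth for recovery tests.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    table = table.copy()
    n = len(table)
    known = set(region_nh.columns) | {"age", "education", "duration", "group"}
    for score, model in covariate_model.items():
        y = np.full(n, float(model.intercept))
        for name, beta in model.coefs.items():
            if name not in known:
                raise ValueError(f"score {score!r}: unknown regressor {name!r} (regions: {list(region_nh.columns)})")
            if name == "group":
                x = table["group_code"].to_numpy(float)
            elif name in ("age", "education", "duration"):
                x = table[name].to_numpy(float)
            else:
                x = region_nh[name].to_numpy(float)
            if model.standardize_regressors:
                sd = x.std(ddof=1)
                x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
            y = y + beta * x
        if model.residual_sd > 0:
            y = y + rng.normal(0.0, model.residual_sd, size=n)
        table[score] = np.round(y, 2)
    return table


def generate_null_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Cohort with identical signal distributions in both groups.

    Loadings are equalized to the control value per region, so group labels
    are exchangeable — the input for family-wise error calibration.
    """
    null_regions = tuple(
        replace(reg, loading_patients=reg.loading_controls) for reg in config.regions
    )
    return generate_cohort(replace(config, regions=null_regions))
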