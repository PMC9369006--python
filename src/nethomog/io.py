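"""Volume and cohort-table I/O.

Volumes are NIfTI-1 on disk (float32) and float64 ``numpy`` arrays in
memory, carried together with their affine so that cluster peaks can be
reported in both voxel indices (0-based) and world (scanner/MNI-style)
millimetre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume4D",
    "NetworkMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_cohort_table",
    "write_cohort_table",
    "REQUIRED_COHORT_COLUMNS",
    "COGNITION_COLUMNS",
    "PANSS_COLUMNS",
]

#: MCCB-style cognition domain columns (seven domains plus the composite).
COGNITION_COLUMNS = [
    "speed_of_processing",
    "attention_vigilance",
    "verbal_learning",
    "visual_learning",
    "reasoning_problem_solving",
    "working_memory",
    "social_cognition",
    "overall_composite",
]

PANSS_COLUMNS = ["panss_positive", "panss_negative", "panss_general", "panss_total"]

REQUIRED_COHORT_COLUMNS = ["subject_id", "group", "age", "sex", "education", "duration"]


@dataclass
class Volume4D:
    """One subject's X*Y*Z*T time-series grid plus voxel geometry."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.diag([3.0, 3.0, 3.0, 1.0]))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4D array, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz.squeeze()


@dataclass
class NetworkMask:
    """Boolean 3D grid marking in-network voxels."""

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.diag([3.0, 3.0, 3.0, 1.0]))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.grid.ndim}D")
        if self.grid.sum() < 2:
            raise ValueError("mask must contain at least 2 voxels")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def indices(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel coordinates, C-order."""
        return np.argwhere(self.grid)

    def check_compatible(self, vol: Volume4D) -> None:
        if vol.data.shape[:3] != self.grid.shape:
            raise ValueError(
                f"mask shape {self.grid.shape} does not match volume "
                f"spatial shape {vol.data.shape[:3]}"
            )


def read_volume(path: str | Path) -> Volume4D:
    """Read a 4D NIfTI-1 volume.

    Raises ``ValueError`` when the payload is not 4D.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D data, found {data.ndim}D")
    return Volume4D(data=np.asarray(data, dtype=np.float64), affine=img.affine)


def write_volume(vol: Volume4D, path: str | Path) -> Path:
    """Write a volume as float32 NIfTI-1; returns the path written."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> NetworkMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D mask, found {data.ndim}D")
    return NetworkMask(grid=data > 0, affine=img.affine)


def write_mask(mask: NetworkMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    return path


def _normalize_sex(series: pd.Series) -> pd.Series:
    mapping = {"male": 1, "female": 0, "m": 1, "f": 0, "1": 1, "0": 0, 1: 1, 0: 0}
    out = series.map(lambda v: mapping.get(str(v).strip().lower() if isinstance(v, str) else v))
    if out.isna().any():
        bad = series[out.isna()].unique()
        raise ValueError(f"unrecognized sex labels: {list(bad)}")
    return out.astype(int)


def read_cohort_table(path: str | Path, require: list[str] | None = None) -> pd.DataFrame:
    """Read a cohort CSV into a typed table.

    Group is recoded patient=1 / control=0 into ``group_code``; sex is
    normalized to 1=male / 0=female. ``require`` lists columns that the
    requesting stage needs; a missing one raises naming the column.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    if require:
        absent = [c for c in require if c not in df.columns]
        if absent:
            raise ValueError(f"cohort table missing columns needed by this stage: {absent}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    bad_groups = set(df["group"].unique()) - {"patient", "control"}
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    df = df.copy()
    df["group_code"] = (df["group"] == "patient").astype(int)
    df["sex"] = _normalize_sex(df["sex"])
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
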