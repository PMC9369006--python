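"""Temporal preprocessing: motion screening, detrend + band-pass, nuisance regression.

Order is fixed to detrend -> band-pass -> nuisance regression. The band-pass
is an ideal frequency-domain filter (hard cut of FFT bins outside the band),
the convention of the DPARSF/REST lineage, so there are no filter-order or
ripple parameters. The whole-brain global mean is deliberately NOT a
nuisance regressor: global signal is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Volume4D

__all__ = [
    "MotionParams",
    "ScreenResult",
    "read_motion_params",
    "screen_motion",
    "friston24",
    "detrend_and_filter",
    "regress_nuisance",
]


@dataclass
class MotionParams:
    """Per-timepoint rigid-body parameters: 3 translations (mm), 3 rotations (deg)."""

    translations_mm: np.ndarray  # (T, 3)
    rotations_deg: np.ndarray  # (T, 3)

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, dtype=float))
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, dtype=float))
        if self.translations_mm.shape != self.rotations_deg.shape or self.translations_mm.shape[1] != 3:
            raise ValueError("motion parameters must be (T, 3) translations and (T, 3) rotations")

    @property
    def n_timepoints(self) -> int:
        return self.translations_mm.shape[0]

    def as_matrix(self) -> np.ndarray:
        return np.hstack([self.translations_mm, self.rotations_deg])


@dataclass(frozen=True)
class ScreenResult:
    keep: bool
    reason: str = ""
    axis: str | None = None
    timepoint: int | None = None


def read_motion_params(path: str | Path) -> MotionParams:
    """Read a 6-column whitespace-delimited rigid-body parameter file."""
    arr = np.loadtxt(str(path), ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, found {arr.shape[1]}")
    return MotionParams(translations_mm=arr[:, :3], rotations_deg=arr[:, 3:])


def screen_motion(mp: MotionParams, max_trans_mm: float = 3.0, max_rot_deg: float = 3.0,
                  n_timepoints: int | None = None) -> ScreenResult:
    """Exclude a subject whose motion exceeds the screening gate.

    Exclusion is strict: |translation| must exceed ``max_trans_mm`` mm or
    |rotation| exceed ``max_rot_deg`` degrees on some axis at some
    timepoint; values exactly at the threshold are kept.
    """
    if n_timepoints is not None and mp.n_timepoints != n_timepoints:
        raise ValueError(
            f"motion parameters have {mp.n_timepoints} rows but the volume has {n_timepoints} timepoints"
        )
    axes = ["x", "y", "z"]
    for kind, values, limit in (
        ("translation", mp.translations_mm, max_trans_mm),
        ("rotation", mp.rotations_deg, max_rot_deg),
    ):
        over = np.abs(values) > limit
        if over.any():
            t, a = np.argwhere(over)[0]
            unit = "mm" if kind == "translation" else "deg"
            return ScreenResult(
                keep=False,
                reason=f"{kind} {values[t, a]:+.3f} {unit} on axis {axes[a]} at timepoint {t}",
                axis=axes[a],
                timepoint=int(t),
            )
    return ScreenResult(keep=True)


def friston24(mp: MotionParams) -> np.ndarray:
    """Friston 24-parameter expansion: [p, p^2, p(t-1), p(t-1)^2].

    The lagged terms are zero-padded at the first timepoint.
    """
    p = mp.as_matrix()
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, p**2, lag, lag**2])


def detrend_and_filter(vol: Volume4D, tr_seconds: float, low_hz: float = 0.01,
                       high_hz: float = 0.08) -> Volume4D:
    """Linear detrend then ideal band-pass of every voxel series.

    The band must satisfy 0 < low < high < Nyquist = 1/(2 TR). FFT bins with
    frequency inside [low, high] (inclusive) are kept; all others, including
    DC, are zeroed.
    """
    T = vol.n_timepoints
    if T < 8:
        raise ValueError("need at least 8 timepoints to filter")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy 0 < low < high < Nyquist ({nyquist:.4g} Hz)"
        )
    data = vol.data.reshape(-1, T).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite input")
    # linear detrend: project out [1, t]
    t = np.arange(T, dtype=np.float64)
    t = (t - t.mean()) / np.linalg.norm(t - t.mean())
    data = data - data.mean(axis=1, keepdims=True)
    data -= np.outer(data @ t, t)
    # ideal band-pass
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(data, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=1)
    return Volume4D(data=out.reshape(vol.shape), affine=vol.affine)


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Columns whose removal restores full rank (greedy QR-based scan)."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [int(i) for i in np.flatnonzero(diag < tol)]


def regress_nuisance(vol: Volume4D, confounds: np.ndarray,
                     column_names: list[str] | None = None) -> Volume4D:
    """Residualize every voxel series on [intercept | confounds].

    All-zero confound columns are ignored (they contribute nothing); a
    rank-deficient confound matrix raises, naming the collinear columns.
    Residuals are orthogonal to every confound column.
    """
    T = vol.n_timepoints
    C = np.atleast_2d(np.asarray(confounds, dtype=np.float64))
    if C.shape[0] != T:
        raise ValueError(f"confounds have {C.shape[0]} rows, volume has {T} timepoints")
    names = column_names or [f"confound_{i}" for i in range(C.shape[1])]
    nonzero = ~np.all(C == 0.0, axis=0)
    C = C[:, nonzero]
    kept_names = [n for n, keep in zip(names, nonzero) if keep]
    X = np.column_stack([np.ones(T), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [kept_names[i - 1] for i in _collinear_columns(X) if i > 0]
        raise ValueError(f"confound matrix is rank-deficient; collinear columns: {bad}")
    Q, _ = np.linalg.qr(X)
    data = vol.data.reshape(-1, T).astype(np.float64)
    resid = data - (data @ Q) @ Q.T
    return Volume4D(data=resid.reshape(vol.shape), affine=vol.affine)
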