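"""Confound regression: remove systemic and indirect-movement components
from long channels by OLS on short-channel principal components and head
kinematics.

This is the pipeline's central denoising step.  Both signal families are
first low-pass filtered at 0.5 Hz (third-order Butterworth, zero-phase)
to strip heartbeats and footfalls; the regressors are the first k
principal components of the pooled z-transformed short-channel HbO/HbR
rows (default k = 8) plus nine z-transformed head-kinematic series
(acceleration, angular acceleration, head-relative-to-neck orientation).
Regression is fitted per run; the residuals carry on through the
pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import PCA

from .core import Kinematics, Recording


@dataclass
class RegressorSet:
    """Design matrix (samples x p) with labelled, z-transformed columns."""

    matrix: np.ndarray
    labels: list
    k_components: int = 0
    variance_explained: float = float("nan")

    def __post_init__(self) -> None:
        if self.matrix.size and np.isnan(self.matrix).any():
            raise ValueError("regressor matrix contains NaN")

    @staticmethod
    def concat(parts: list) -> "RegressorSet":
        parts = [p for p in parts if p.matrix.size]
        if not parts:
            return RegressorSet(np.empty((0, 0)), [])
        mat = np.hstack([p.matrix for p in parts])
        labels = sum((p.labels for p in parts), [])
        k = max(p.k_components for p in parts)
        ve = max((p.variance_explained for p in parts
                  if np.isfinite(p.variance_explained)), default=float("nan"))
        return RegressorSet(mat, labels, k, ve)


@dataclass
class RegressionReport:
    """Per-channel fit diagnostics."""

    table: pd.DataFrame  # row, channel, chromophore, r2, residual_variance
    coefficients: dict   # row index -> coefficient vector (incl. intercept)


def _butter_lowpass_sos(fc: float, fs: float, order: int):
    return sps.butter(order, fc, btype="low", fs=fs, output="sos")


def lowpass_pre(x, fc: float = 0.5, order: int = 3):
    """0.5 Hz third-order Butterworth, applied zero-phase (forward-backward),
    to a Recording or Kinematics stream."""
    if isinstance(x, Recording):
        sos = _butter_lowpass_sos(fc, x.fs_hz, order)
        return x.copy(data=sps.sosfiltfilt(sos, x.data, axis=1))
    if isinstance(x, Kinematics):
        sos = _butter_lowpass_sos(fc, x.fs_hz, order)
        series = {k: sps.sosfiltfilt(sos, v, axis=1) for k, v in x.series.items()}
        return x.copy(series=series)
    raise TypeError("lowpass_pre expects a Recording or Kinematics")


def _zscore_cols(mat: np.ndarray, labels: list) -> tuple[np.ndarray, list]:
    keep_cols, keep_labels = [], []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        sd = col.std()
        if sd <= 1e-12:
            warnings.warn(f"dropping zero-variance regressor {labels[j]!r}")
            continue
        keep_cols.append((col - col.mean()) / sd)
        keep_labels.append(labels[j])
    if not keep_cols:
        return np.empty((mat.shape[0], 0)), []
    return np.column_stack(keep_cols), keep_labels


def pca_short_channels(short: Recording, k: int = 8) -> RegressorSet:
    """Top-k principal component scores of the pooled z-transformed
    short-channel HbO and HbR rows.

    Returns scores ordered by explained variance, with the total fraction
    of short-channel variance they capture.
    """
    if k == 0:
        return RegressorSet(np.empty((short.n_samples, 0)), [], 0, float("nan"))
    keep = short.unmasked_row_indices()
    data = short.data[keep]
    if data.shape[0] == 0:
        raise ValueError("no unpruned short-channel rows available")
    sds = data.std(axis=1, keepdims=True)
    sds[sds == 0] = 1.0
    z = (data - data.mean(axis=1, keepdims=True)) / sds
    k_eff = min(k, z.shape[0], z.shape[1])
    if k_eff < k:
        warnings.warn(f"only {k_eff} short-channel rows available; using k={k_eff}")
    pca = PCA(n_components=k_eff, svd_solver="full")
    scores = pca.fit_transform(z.T)  # samples x k
    ve = float(pca.explained_variance_ratio_.sum())
    mat, labels = _zscore_cols(scores, [f"sc_pc_{i + 1}" for i in range(k_eff)])
    return RegressorSet(mat, labels, k_components=k_eff, variance_explained=ve)


_MOTION_LABELS = [
    "head_accel_x", "head_accel_y", "head_accel_z",
    "head_angaccel_x", "head_angaccel_y", "head_angaccel_z",
    "head_neck_yaw", "head_neck_pitch", "head_neck_roll",
]


def build_motion_regressors(kin: Kinematics, target_fs: float | None = None,
                            n_samples: int | None = None) -> RegressorSet:
    """Nine z-transformed head-movement columns, optionally interpolated
    onto the fNIRS clock."""
    stack = np.vstack([
        kin.series["head_acceleration"],
        kin.series["head_angular_acceleration"],
        kin.series["head_neck_orientation"],
    ])
    if target_fs is not None and n_samples is not None and not np.isclose(
            target_fs, kin.fs_hz):
        t_out = np.arange(n_samples) / target_fs
        stack = np.vstack([np.interp(t_out, kin.times() - kin.time0_s, row)
                           for row in stack])
    elif n_samples is not None and stack.shape[1] != n_samples:
        m = min(stack.shape[1], n_samples)
        stack = stack[:, :m]
    mat, labels = _zscore_cols(stack.T, list(_MOTION_LABELS))
    return RegressorSet(mat, labels)


def regress_confounds(long: Recording, regs: RegressorSet) -> tuple[Recording, RegressionReport]:
    """OLS per long channel: residuals = y - X (X'X)^-1 X'y, intercept
    included.  Residuals are orthogonal to every regressor column."""
    n = long.n_samples
    if regs.matrix.size and regs.matrix.shape[0] != n:
        raise ValueError("regressor sample count does not match recording")
    X = np.column_stack([np.ones(n)] + ([regs.matrix] if regs.matrix.size else []))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify (approximately) collinear columns for the error message
        _, r = np.linalg.qr(X)
        bad = [regs.labels[j - 1] for j in range(1, X.shape[1])
               if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Y = long.data.T  # samples x channels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    yvar = long.data.var(axis=1)
    rvar = resid.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(yvar > 0, 1.0 - rvar / yvar, 0.0)
    report = RegressionReport(
        table=pd.DataFrame({
            "channel": long.rows["channel"],
            "chromophore": long.rows["chromophore"],
            "r2": np.clip(r2, 0.0, 1.0),
            "residual_variance": rvar,
        }),
        coefficients={i: beta[:, i].copy() for i in range(beta.shape[1])},
    )
    return long.copy(data=resid), report


def denoise_run(hb_long: Recording, hb_short: Recording, kin: Kinematics,
                k: int = 8, use_short_channels: bool = True,
                use_motion: bool = True, fc: float = 0.5,
                order: int = 3) -> tuple[Recording, RegressionReport, RegressorSet]:
    """Full denoising of one run: 0.5 Hz low-pass on fNIRS and movement
    data, then OLS on short-channel PCs and/or head-motion regressors.

    Either regressor family can be ablated (the Box-1-style comparison);
    with both off, the low-passed long channels pass through unchanged.
    """
    long_lp = lowpass_pre(hb_long, fc=fc, order=order)
    parts = []
    if use_short_channels and k > 0:
        short_lp = lowpass_pre(hb_short, fc=fc, order=order)
        parts.append(pca_short_channels(short_lp, k=k))
    if use_motion:
        kin_lp = lowpass_pre(kin, fc=fc, order=order)
        parts.append(build_motion_regressors(kin_lp, target_fs=hb_long.fs_hz,
                                             n_samples=hb_long.n_samples))
    regs = RegressorSet.concat(parts)
    if regs.matrix.size == 0:
        empty = RegressionReport(table=pd.DataFrame(
            {"channel": long_lp.rows["channel"],
             "chromophore": long_lp.rows["chromophore"],
             "r2": 0.0, "residual_variance": long_lp.data.var(axis=1)}), coefficients={})
        return long_lp, empty, regs
    resid, report = regress_confounds(long_lp, regs)
    return resid, report, regs
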