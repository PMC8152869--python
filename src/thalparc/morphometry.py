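"""Nucleus shape statistics from deformation fields.

The voxelwise log-Jacobian determinant of the subject-template warp measures
local volume change (> 0 expansion, < 0 shrinkage).  Per-nucleus means feed a
covariate-adjusted one-sample t-test (intercept test of a linear model on
mean-centered covariates), and volumetric-ratio changes summarize each
nucleus's size relative to a reference.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm

from .parcellation import Parcellation


def jacobian_field(displacement: np.ndarray, voxel_size=(1.25, 1.25, 1.25)) -> np.ndarray:
    """Per-voxel Jacobian J = I + d(displacement)/dx, shape (x, y, z, 3, 3).

    Finite differences: central in the interior, one-sided at the borders
    (numpy.gradient), with spacing equal to the voxel size in mm.
    """
    u = np.asarray(displacement, dtype=float)
    if u.ndim != 4 or u.shape[-1] != 3:
        raise ValueError("displacement must be a (x, y, z, 3) field")
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite displacement values")
    J = np.empty(u.shape[:3] + (3, 3))
    for comp in range(3):
        grads = np.gradient(u[..., comp], *voxel_size, axis=(0, 1, 2))
        for ax in range(3):
            J[..., comp, ax] = grads[ax]
    J += np.eye(3)
    return J


def log_jacobian(
    displacement: np.ndarray,
    voxel_size=(1.25, 1.25, 1.25),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxelwise log det(I + grad u); raises if the warp folds inside the mask."""
    J = jacobian_field(displacement, voxel_size)
    det = np.linalg.det(J)
    check = det if mask is None else det[np.asarray(mask, bool)]
    if np.any(check <= 0):
        bad = np.argwhere((det <= 0) if mask is None else (np.asarray(mask, bool) & (det <= 0)))
        raise ValueError(f"folding warp: non-positive Jacobian determinant at voxels {bad[:5].tolist()}...")
    with np.errstate(invalid="ignore"):
        out = np.where(det > 0, np.log(np.where(det > 0, det, 1.0)), np.nan)
    return out


def nucleus_shape_stats(logj: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Mean log-Jacobian over each nucleus; NaN (with warning) if a nucleus is empty."""
    if logj.shape != parcellation.labels.shape:
        raise ValueError("log-Jacobian and parcellation grids differ")
    out = np.full(parcellation.k, np.nan)
    for nuc in range(1, parcellation.k + 1):
        sel = parcellation.labels == nuc
        if not sel.any():
            warnings.warn(f"nucleus {nuc} is empty; shape statistic missing")
            continue
        out[nuc - 1] = float(logj[sel].mean())
    return out


def volume_ratio_change(
    subject_parc: Parcellation,
    reference_parc: Parcellation,
    subject_voxel_volume: float = 1.0,
    reference_voxel_volume: float = 1.0,
) -> np.ndarray:
    """Per-nucleus volume ratio subject/reference (labels must be matched)."""
    k = reference_parc.k
    out = np.empty(k)
    for nuc in range(1, k + 1):
        ref = np.sum(reference_parc.labels == nuc) * reference_voxel_volume
        if ref == 0:
            raise ValueError(f"empty reference nucleus {nuc}: volume ratio undefined")
        out[nuc - 1] = np.sum(subject_parc.labels == nuc) * subject_voxel_volume / ref
    return out


def volume_ratio_from_logj(logj: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Per-nucleus volume ratio implied by the warp: mean of exp(logJ).

    Appropriate when subject and reference parcellations share one grid and
    the size difference is encoded in the deformation field.
    """
    out = np.full(parcellation.k, np.nan)
    for nuc in range(1, parcellation.k + 1):
        sel = parcellation.labels == nuc
        if sel.any():
            out[nuc - 1] = float(np.exp(logj[sel]).mean())
    return out


def covariate_adjusted_one_sample_test(
    values: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """One-sample t-test of mean(values) = 0, adjusted for covariates.

    Fits value ~ intercept + mean-centered covariates and tests the intercept
    with a two-sided t; with no covariates this is exactly the classical
    one-sample t-test.
    """
    y = np.asarray(values, dtype=float)
    if covariates is None or np.size(covariates) == 0:
        X = np.ones((y.size, 1))
        n_cov = 0
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.size:
            C = C.T
        C = C - C.mean(axis=0)
        X = np.column_stack([np.ones(y.size), C])
        n_cov = C.shape[1]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear covariate matrix")
    if y.size < n_cov + 2:
        raise ValueError(f"n={y.size} too small for {n_cov} covariates")
    if np.allclose(y, 0.0):
        return 0.0, 1.0
    fit = sm.OLS(y, X).fit()
    return float(fit.tvalues[0]), float(fit.pvalues[0])
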