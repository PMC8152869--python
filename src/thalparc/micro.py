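"""Microstructural metrics and their group statistics.

Voxel metrics come from the diffusion-tensor eigenvalues (FA, MD, AD, RD);
fixel metrics (FD, FC, FDC) come from the FOD lobes and the warp Jacobian.
All metrics are averaged within each thalamic nucleus or along each
thalamo-cortical pathway, tested between groups with a covariate-adjusted
permutation test (residualize on age / intracranial volume / DOC duration,
then permute group labels; statistic = difference of residual group means),
corrected by Benjamini-Hochberg FDR at q = 0.05 within each metric family,
and related to CRS-R by partial correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

VOXEL_METRICS = ("FA", "MD", "AD", "RD")
FIXEL_METRICS = ("FD", "FC", "FDC")
ALL_METRICS = FIXEL_METRICS + VOXEL_METRICS


def tensor_metrics(eigs: np.ndarray) -> dict[str, np.ndarray]:
    """FA, MD, AD, RD from eigenvalue arrays (..., 3) sorted descending.

    FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||, defined as 0 where all
    eigenvalues vanish.
    """
    lam = np.asarray(eigs, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("eigenvalue array must have a trailing axis of length 3")
    if np.any(lam < 0):
        raise ValueError("negative diffusion-tensor eigenvalue")
    if np.any(np.diff(lam, axis=-1) > 1e-18):
        raise ValueError("eigenvalues must be sorted descending")
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = (lam[..., 1] + lam[..., 2]) / 2.0
    norm2 = np.sum(lam**2, axis=-1)
    dev2 = np.sum((lam - md[..., None]) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(norm2 > 0, dev2 / np.where(norm2 > 0, norm2, 1.0), 0.0))
    return {"FA": fa, "MD": md, "AD": ad, "RD": rd}


def aggregate_metric(values: np.ndarray, region: np.ndarray) -> float:
    """Arithmetic mean of a voxel map over a region selection."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        warnings.warn("empty region: aggregate metric missing")
        return float("nan")
    return float(np.asarray(values)[region].mean())


def aggregate_fixel_metric(
    fixel_lists: list,
    attr: str = "fd",
) -> float:
    """Equal-weight mean of a fixel attribute over all fixels of a region.

    ``fixel_lists`` holds per-voxel (possibly matched/filtered) fixel lists;
    None entries (unmatched template fixels) contribute nothing.
    """
    vals = [getattr(f, attr) for fx in fixel_lists for f in (fx or []) if f is not None
            and getattr(f, attr) is not None]
    if not vals:
        warnings.warn("no fixels in region: aggregate metric missing")
        return float("nan")
    return float(np.mean(vals))


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if covariates is None or np.size(covariates) == 0:
        return y - y.mean()
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != y.size:
        C = C.T
    X = np.column_stack([np.ones(y.size), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariate matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class StatResult:
    table: pd.DataFrame  # columns: region, metric, observed, p, q, significant

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def group_permutation_test(
    table: pd.DataFrame,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 2000,
    q: float = 0.05,
    seed: int = 0,
    family: str | None = "metric",
) -> StatResult:
    """Covariate-adjusted two-group permutation test per metric column.

    ``table`` is subjects x columns with a two-level MultiIndex or
    'region|metric' column names; ``groups`` a two-level label vector.
    Residuals (after regressing out covariates on the pooled sample) are
    permuted; the statistic is the difference of group means (group A - B in
    sorted label order).  BH-FDR is applied within each metric family.
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"need exactly two groups, got {levels.tolist()}")
    ga = groups == levels[0]
    if ga.sum() < 3 or (~ga).sum() < 3:
        raise ValueError("both groups need at least 3 subjects")
    rng = np.random.default_rng(seed)
    n = len(groups)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])

    rows = []
    for col in table.columns:
        y = table[col].to_numpy(dtype=float)
        region, metric = _split_column(col)
        if np.allclose(y, y[0]):
            rows.append((region, metric, 0.0, 1.0, True))
            continue
        r = _residualize(y, covariates)
        obs = r[ga].mean() - r[~ga].mean()
        perm_r = r[perm_idx]  # (n_perm, n)
        null = perm_r[:, ga].mean(axis=1) - perm_r[:, ~ga].mean(axis=1)
        p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1.0)
        rows.append((region, metric, float(obs), float(p), False))

    df = pd.DataFrame(rows, columns=["region", "metric", "observed", "p", "constant"])
    df["q"] = np.nan
    if family == "metric":
        for m, sub in df.groupby("metric"):
            df.loc[sub.index, "q"] = fdr_bh(sub["p"].to_numpy(), q=q)[0]
    else:
        df["q"] = fdr_bh(df["p"].to_numpy(), q=q)[0]
    df["significant"] = (df["q"] <= q) & ~df["constant"]
    return StatResult(table=df.drop(columns="constant"))


def _split_column(col) -> tuple[str, str]:
    if isinstance(col, tuple):
        return str(col[0]), str(col[1])
    if "|" in str(col):
        region, metric = str(col).split("|", 1)
        return region, metric
    return str(col), str(col)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted q-values, significance flags)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out, out <= q


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    p-value from the t distribution with n - n_cov - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    n_cov = 0 if covariates is None or np.size(covariates) == 0 else np.atleast_2d(np.asarray(covariates)).reshape(n, -1).shape[1]
    if n < n_cov + 3:
        raise ValueError(f"n={n} too small for {n_cov} covariates")
    rx = _residualize(x, covariates)
    ry = _residualize(y, covariates)
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx == 0 or sy == 0:
        raise ValueError("zero residual variance: correlation undefined")
    r = float(np.dot(rx, ry) / (sx * sy))
    df = n - n_cov - 2
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)
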