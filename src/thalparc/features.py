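"""Feature assembly and sparse-logistic classification of subject groups.

Features are the seven microstructural metrics (FD, FC, FDC, FA, MD, AD, RD)
per region of the chosen parcellation (individual, consensus, external atlas,
or whole-thalamus means); nucleus volume is deliberately excluded because
population-level parcellations give every subject the same volumes.  The
classifier is an L1-regularized logistic regression evaluated by stratified
3-fold cross-validation repeated 20 times, standardizing and selecting the
penalty on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

C_GRID = (0.1, 1.0, 10.0)


def build_features(metric_table: pd.DataFrame, mode: str = "individual") -> pd.DataFrame:
    """Subjects x (region, metric) feature matrix; volume excluded.

    ``metric_table`` columns are (region, metric) tuples or 'region|metric'
    strings.  ``mode='whole'`` collapses regions to the whole-thalamus mean
    per metric (7 columns); other modes keep one column per region x metric.
    """
    cols = []
    for col in metric_table.columns:
        region, metric = (col if isinstance(col, tuple) else str(col).split("|", 1))
        if metric.lower() == "volume":
            continue
        cols.append((str(region), str(metric), col))
    if not cols:
        raise ValueError("no usable metric columns")
    df = pd.DataFrame(
        {f"{r}|{m}": metric_table[c].to_numpy(dtype=float) for r, m, c in cols},
        index=metric_table.index,
    )
    missing = df.columns[df.isna().any()].tolist()
    if missing:
        bad = {c: df.index[df[c].isna()].tolist() for c in missing}
        raise ValueError(f"missing region metrics: {bad}")
    if mode == "whole":
        metrics = sorted({m for _, m, _ in cols})
        out = pd.DataFrame(index=df.index)
        for m in metrics:
            sel = [f"{r}|{mm}" for r, mm, _ in cols if mm == m]
            out[f"whole|{m}"] = df[sel].mean(axis=1)
        return out
    return df


@dataclass
class CVResult:
    accuracies: np.ndarray  # per repeat x fold
    mean: float
    std: float
    oof_predictions: pd.DataFrame
    chosen_c: list = field(default_factory=list)


def _fit_fold(X_train, y_train, seed: int, c_grid=C_GRID):
    """Standardize on the training rows and fit L1 logistic with inner C selection."""
    mu, sd = X_train.mean(axis=0), X_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X_train - mu) / sd

    best_c, best_score = c_grid[len(c_grid) // 2], -np.inf
    counts = np.bincount(y_train)
    if counts.min() >= 2 and len(y_train) >= 6:
        inner = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
        for c in c_grid:
            score = 0
            for tr, te in inner.split(Xs, y_train):
                clf = LogisticRegression(
                    l1_ratio=1.0, C=c, solver="liblinear", random_state=0, max_iter=1000
                ).fit(Xs[tr], y_train[tr])
                score += np.mean(clf.predict(Xs[te]) == y_train[te])
            if score > best_score:
                best_score, best_c = score, c
    model = LogisticRegression(
        l1_ratio=1.0, C=best_c, solver="liblinear", random_state=0, max_iter=1000
    ).fit(Xs, y_train)
    return model, mu, sd, best_c


def crossval_classify(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    n_folds: int = 3,
    n_repeats: int = 20,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold accuracy of the sparse logistic classifier."""
    X = np.asarray(features, dtype=float)
    ids = features.index if isinstance(features, pd.DataFrame) else pd.RangeIndex(len(X))
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size != 2:
        raise ValueError("labels must have exactly two levels")
    if np.bincount(y).min() < n_folds:
        raise ValueError("smallest class has fewer members than n_folds")

    accs = np.empty((n_repeats, n_folds))
    chosen = []
    oof = np.full((n_repeats, len(y)), -1, dtype=int)
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            model, mu, sd, c = _fit_fold(X[tr], y[tr], seed=seed + 1000 * rep + f)
            pred = model.predict((X[te] - mu) / sd)
            accs[rep, f] = np.mean(pred == y[te])
            oof[rep, te] = pred
            chosen.append(c)
    oof_df = pd.DataFrame(
        classes[oof], index=[f"rep{r}" for r in range(n_repeats)], columns=ids
    )
    return CVResult(
        accuracies=accs,
        mean=float(accs.mean()),
        std=float(accs.mean(axis=1).std()),
        oof_predictions=oof_df,
        chosen_c=chosen,
    )


def pca_embed(features: pd.DataFrame | np.ndarray, n_components: int = 3):
    """Top principal-component coordinates of the standardized feature matrix.

    Columns are z-scored (metrics live on incommensurate scales), components
    come from the SVD of the centered matrix, and each component's sign is
    canonicalized so its largest-magnitude loading is positive.  Returns
    (coordinates, explained_variance_ratio).
    """
    X = np.asarray(features, dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    var = S**2
    total = var.sum()
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    n_out = min(n_components, rank)
    if n_out < n_components:
        import warnings

        warnings.warn(f"feature rank {rank} < {n_components}; returning {n_out} components")
    coords = U[:, :n_out] * S[:n_out]
    loadings = Vt[:n_out]
    signs = np.sign(loadings[np.arange(n_out), np.argmax(np.abs(loadings), axis=1)])
    signs = np.where(signs == 0, 1.0, signs)
    return coords * signs, (var / total if total > 0 else var)[:n_out]
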