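"""Individualized thalamus segmentation by combined FOD/spatial k-means.

The clustering metric between two voxels is

    D = alpha * X + (1 - alpha) * beta * Y

where X is the Euclidean distance between their SH coefficient vectors, Y the
Euclidean distance between their voxel coordinates, alpha (default 0.5)
balances the two feature families and beta (default 85) puts them on a common
scale.  k-means (default k = 7 per hemisphere) is initialized from the
centroids of a spatial-only hierarchical clustering, which makes the whole
segmentation deterministic.

Because the metric uses unsquared norms while centroids are updated by the
arithmetic mean (the standard k-means heuristic, not the exact minimizer of
summed unsquared distances), an explicit guard keeps the objective monotone:
if an update would increase the summed assigned distance, the previous state
is kept and iteration stops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, squareform

from .shmath import FODImage


@dataclass(frozen=True)
class ClusteringConfig:
    k: int = 7
    alpha: float = 0.5
    beta: float = 85.0
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0
    linkage_method: str = "ward"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class Parcellation:
    """3D integer label volume: 0 outside the mask, 1..k inside."""

    labels: np.ndarray
    mask: np.ndarray
    hemisphere: str = "left"
    provenance: str = "individual"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels.shape != self.mask.shape:
            raise ValueError("labels and mask shapes differ")
        if np.any(self.labels[~self.mask] != 0):
            raise ValueError("nonzero labels outside the mask")
        if np.any(self.labels[self.mask] < 1):
            raise ValueError("masked voxels must carry labels >= 1")

    @property
    def k(self) -> int:
        return int(self.labels.max())

    def masked_labels(self) -> np.ndarray:
        return self.labels[self.mask]

    def relabeled(self, perm: np.ndarray) -> "Parcellation":
        """Apply a permutation: new label of old label l is perm[l - 1]."""
        new = np.zeros_like(self.labels)
        new[self.mask] = np.asarray(perm)[self.labels[self.mask] - 1]
        return Parcellation(new, self.mask, self.hemisphere, self.provenance, dict(self.meta))


def combined_distance(
    fod_i: np.ndarray,
    fod_j: np.ndarray,
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    config: ClusteringConfig,
) -> float:
    """The segmentation metric D = alpha*X + (1 - alpha)*beta*Y for one pair."""
    fod_i, fod_j = np.asarray(fod_i, float), np.asarray(fod_j, float)
    if fod_i.shape != fod_j.shape:
        raise ValueError(f"coefficient shapes differ: {fod_i.shape} vs {fod_j.shape}")
    x = np.linalg.norm(fod_i - fod_j)
    y = np.linalg.norm(np.asarray(pos_i, float) - np.asarray(pos_j, float))
    return float(config.alpha * x + (1.0 - config.alpha) * config.beta * y)


def _pair_distances(C, P, Cc, Pc, config):
    """(n_voxels, k) combined distances to centroid features."""
    return config.alpha * cdist(C, Cc) + (1.0 - config.alpha) * config.beta * cdist(P, Pc)


def init_centroids(
    positions: np.ndarray,
    k: int,
    coeffs: np.ndarray | None = None,
    method: str = "ward",
) -> tuple[np.ndarray, np.ndarray]:
    """Initial centroids from spatial-only hierarchical clustering.

    Agglomerates the voxel coordinates, cuts at k clusters and returns the
    per-cluster means of (coefficients, positions); deterministic.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < k:
        raise ValueError(f"{n} voxels < k = {k}")
    if k == n:
        assign = np.arange(1, n + 1)
    else:
        Z = linkage(positions, method=method)
        assign = fcluster(Z, t=k, criterion="maxclust")
    if coeffs is None:
        coeffs = np.zeros((n, 0))
    Cc = np.vstack([coeffs[assign == c].mean(axis=0) for c in range(1, assign.max() + 1)])
    Pc = np.vstack([positions[assign == c].mean(axis=0) for c in range(1, assign.max() + 1)])
    return Cc, Pc


def kmeans_segment(
    fod: FODImage,
    mask: np.ndarray | None = None,
    config: ClusteringConfig | None = None,
    hemisphere: str = "left",
) -> Parcellation:
    """Segment the masked voxels into k nuclei with the combined metric."""
    config = config or ClusteringConfig()
    mask = np.asarray(fod.mask if mask is None else mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    C = fod.coeffs[mask]
    P = np.argwhere(mask).astype(float)
    n = C.shape[0]
    if config.k == 1:
        labels = np.zeros(mask.shape, dtype=int)
        labels[mask] = 1
        return Parcellation(labels, mask, hemisphere, "individual", {"objective": [0.0]})

    Cc, Pc = init_centroids(P, config.k, coeffs=C, method=config.linkage_method)
    objective_trace: list[float] = []
    prev_obj = np.inf
    assign = None
    converged = False
    for _ in range(config.max_iter):
        D = _pair_distances(C, P, Cc, Pc, config)
        new_assign = np.argmin(D, axis=1)  # argmin breaks ties at lowest index
        # re-seed empty clusters with the voxel farthest from its centroid
        for c in range(config.k):
            if not np.any(new_assign == c):
                d_own = D[np.arange(n), new_assign]
                far = int(np.argmax(d_own))
                new_assign[far] = c
                Cc[c], Pc[c] = C[far], P[far]
                D = _pair_distances(C, P, Cc, Pc, config)
        obj = float(D[np.arange(n), new_assign].sum())
        if obj > prev_obj + 1e-12:
            converged = True  # mean update overshot; keep the previous state
            break
        objective_trace.append(obj)
        assign = new_assign
        shift = 0.0
        newCc, newPc = Cc.copy(), Pc.copy()
        for c in range(config.k):
            members = assign == c
            newCc[c] = C[members].mean(axis=0)
            newPc[c] = P[members].mean(axis=0)
        shift = max(
            np.linalg.norm(config.alpha * (newCc - Cc), axis=1).max(),
            np.linalg.norm((1 - config.alpha) * config.beta * (newPc - Pc), axis=1).max(),
        )
        Cc, Pc = newCc, newPc
        if obj <= prev_obj - 1e-12 and shift < config.tol:
            converged = True
            break
        if abs(prev_obj - obj) < 1e-12 and shift < config.tol:
            converged = True
            break
        prev_obj = obj
    if not converged:
        warnings.warn("k-means did not converge within max_iter; best partition returned")

    labels = np.zeros(mask.shape, dtype=int)
    labels[mask] = assign + 1
    return Parcellation(
        labels,
        mask,
        hemisphere,
        "individual",
        {"objective": objective_trace, "converged": converged},
    )


def contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shared-voxel counts between two label vectors (labels 1..k)."""
    ka, kb = int(a.max()), int(b.max())
    idx = (a - 1) * kb + (b - 1)
    return np.bincount(idx, minlength=ka * kb).reshape(ka, kb)


def match_labels(parcellation: Parcellation, reference: Parcellation) -> Parcellation:
    """Relabel by Hungarian assignment maximizing voxel overlap with reference."""
    if not np.array_equal(parcellation.mask, reference.mask):
        raise ValueError("parcellations live on different masks")
    if parcellation.k != reference.k:
        raise ValueError(f"differing k: {parcellation.k} vs {reference.k}")
    overlap = contingency(parcellation.masked_labels(), reference.masked_labels())
    rows, cols = linear_sum_assignment(-overlap)
    perm = np.empty(parcellation.k, dtype=int)
    perm[rows] = cols + 1
    return parcellation.relabeled(perm)


def consensus_partition(
    parcellations: list[Parcellation],
    k: int | None = None,
    method: str = "vote",
) -> Parcellation:
    """Group-level consensus partition, invariant to per-subject label permutations.

    ``method='vote'`` (default): every input is label-aligned to the first by
    Hungarian overlap matching, then each voxel takes the majority label (ties
    to the smallest label).  The consensus responds gradually to the group's
    composition, which the group-reallocation NMI test relies on.

    ``method='coassoc'``: builds the co-association matrix (fraction of
    subjects putting each voxel pair in the same nucleus) and cuts an
    average-linkage agglomeration of 1 - co-association at k clusters.
    """
    if len(parcellations) < 2:
        raise ValueError("consensus needs at least 2 parcellations")
    mask = parcellations[0].mask
    for p in parcellations[1:]:
        if not np.array_equal(p.mask, mask):
            raise ValueError("parcellations live on different masks")
    k = k or max(p.k for p in parcellations)

    if method == "vote":
        ref = parcellations[0]
        aligned = [ref.masked_labels()]
        for p in parcellations[1:]:
            aligned.append(match_labels(p, ref).masked_labels())
        L = np.stack(aligned)  # (subjects, voxels)
        counts = np.zeros((k, L.shape[1]), dtype=int)
        for lab in range(1, k + 1):
            counts[lab - 1] = (L == lab).sum(axis=0)
        assign = counts.argmax(axis=0) + 1  # argmax ties -> smallest label
    elif method == "coassoc":
        L = np.stack([p.masked_labels() for p in parcellations])
        n = L.shape[1]
        co = np.zeros((n, n))
        for row in L:
            co += row[:, None] == row[None, :]
        co /= L.shape[0]
        dist = 1.0 - co
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        assign = fcluster(Z, t=k, criterion="maxclust")
    else:
        raise ValueError(f"unknown consensus method {method!r}")
    labels = np.zeros(mask.shape, dtype=int)
    labels[mask] = assign
    return Parcellation(labels, mask, parcellations[0].hemisphere, "consensus")


def dice_per_nucleus(parcellation: Parcellation, reference: Parcellation) -> np.ndarray:
    """Per-nucleus Dice after labels have been matched."""
    a, b = parcellation.masked_labels(), reference.masked_labels()
    k = max(int(a.max()), int(b.max()))
    out = np.zeros(k)
    for lab in range(1, k + 1):
        ai, bi = a == lab, b == lab
        denom = ai.sum() + bi.sum()
        out[lab - 1] = 2.0 * np.sum(ai & bi) / denom if denom else np.nan
    return out
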