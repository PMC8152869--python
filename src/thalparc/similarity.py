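"""Normalized mutual information between parcellations and its group-permutation test.

NMI of partitions A, B on the same voxel set, in the over-entropies form

    NMI(A, B) = -2 * sum_ij N_ij log(N_ij N / (N_i N_j))
                / ( sum_i N_i log(N_i / N) + sum_j N_j log(N_j / N) )

with 0 log 0 = 0; it is symmetric, invariant to label permutation, and 1 iff
the partitions are identical up to relabeling.  Group dissimilarity is tested
by randomly reallocating subjects to two groups of the original sizes and
recomputing the NMI between the groups' consensus partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .parcellation import Parcellation, consensus_partition, contingency


def nmi(a: Parcellation | np.ndarray, b: Parcellation | np.ndarray) -> float:
    """NMI between two partitions on an identical voxel set."""
    va = a.masked_labels() if isinstance(a, Parcellation) else np.asarray(a)
    vb = b.masked_labels() if isinstance(b, Parcellation) else np.asarray(b)
    if va.shape != vb.shape:
        raise ValueError("partitions cover different voxel sets")
    nij = contingency(va, vb).astype(float)
    n = nij.sum()
    ni = nij.sum(axis=1)
    nj = nij.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.where(nij > 0, nij * np.log(nij * n / np.outer(ni, nj)), 0.0)
    num = -2.0 * log_term.sum()
    den = np.sum(ni[ni > 0] * np.log(ni[ni > 0] / n)) + np.sum(nj[nj > 0] * np.log(nj[nj > 0] / n))
    if den == 0.0:
        # both partitions are single-cluster: identical trivial partitions
        warnings.warn("degenerate NMI: both partitions have a single cluster; defined as 1")
        return 1.0
    return float(num / den)


@dataclass
class PermutationNull:
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    lower: float  # empirical 2.5th percentile of the null
    upper: float  # empirical 97.5th percentile

    @property
    def significant(self) -> bool:
        """Two-tailed decision: observed outside the null's central 95% interval."""
        return bool(self.observed < self.lower or self.observed > self.upper)


def nmi_permutation_test(
    group1: list[Parcellation],
    group2: list[Parcellation],
    n_perm: int = 1000,
    seed: int = 0,
    k: int | None = None,
) -> PermutationNull:
    """Group-reallocation permutation test for consensus-partition dissimilarity.

    Observed statistic: NMI between the consensus partitions of the two
    groups.  Each permutation reassigns subjects to two groups of the
    original sizes without replacement; p is the add-one two-tailed
    probability of a null value at least as far from the null median.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("both groups need at least 2 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: unstable null percentiles")
    rng = np.random.default_rng(seed)
    everyone = list(group1) + list(group2)
    n1 = len(group1)
    k = k or max(p.k for p in everyone)

    observed = nmi(consensus_partition(group1, k=k), consensus_partition(group2, k=k))
    null = np.empty(n_perm)
    idx = np.arange(len(everyone))
    for b in range(n_perm):
        perm = rng.permutation(idx)
        g1 = [everyone[i] for i in perm[:n1]]
        g2 = [everyone[i] for i in perm[n1:]]
        null[b] = nmi(consensus_partition(g1, k=k), consensus_partition(g2, k=k))
    center = float(np.median(null))
    p = (1.0 + np.sum(np.abs(null - center) >= abs(observed - center))) / (n_perm + 1.0)
    return PermutationNull(
        observed=float(observed),
        null_values=null,
        p_value=float(p),
        n_perm=n_perm,
        lower=float(np.percentile(null, 2.5)),
        upper=float(np.percentile(null, 97.5)),
    )
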