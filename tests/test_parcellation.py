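"""Combined-metric k-means segmentation, label matching, consensus clustering."""

import itertools

import numpy as np
import pytest

from thalparc.parcellation import (
    ClusteringConfig,
    Parcellation,
    combined_distance,
    consensus_partition,
    contingency,
    dice_per_nucleus,
    init_centroids,
    kmeans_segment,
    match_labels,
)
from thalparc.phantom import PhantomConfig, config_with_ratio, make_phantom
from thalparc.shmath import FODImage
from thalparc.similarity import nmi


def small_fod(labels_1d, means, grid, mask, noise=0.0, seed=0):
    """Assemble a FODImage whose masked voxels carry the given class means."""
    rng = np.random.default_rng(seed)
    coeffs = np.zeros(grid + (means.shape[1],))
    coeffs[mask] = means[labels_1d - 1] + noise * rng.normal(size=(mask.sum(), means.shape[1]))
    return FODImage(coeffs, mask=mask)


# ------------------------------------------------------------- the metric


def test_combined_distance_formula():
    cfg = ClusteringConfig(alpha=0.5, beta=85.0)
    d = combined_distance(np.array([1.0, 0.0]), np.array([1.0, 2.0]),
                          np.array([0, 0, 0]), np.array([0.5, 0, 0]), cfg)
    assert d == pytest.approx(0.5 * 2.0 + 0.5 * 85.0 * 0.5)  # = 22.25


def test_combined_distance_limits():
    f1, f2 = np.array([1.0, 1.0]), np.array([4.0, 5.0])
    p1, p2 = np.array([0.0, 0, 0]), np.array([1.0, 0, 0])
    only_fod = combined_distance(f1, f2, p1, p2, ClusteringConfig(alpha=1.0))
    assert only_fod == pytest.approx(5.0)
    only_spatial = combined_distance(f1, f2, p1, p2, ClusteringConfig(alpha=0.0, beta=85.0))
    assert only_spatial == pytest.approx(85.0)
    assert combined_distance(f1, f1, p1, p1, ClusteringConfig()) == 0.0
    with pytest.raises(ValueError):
        combined_distance(f1, np.array([1.0]), p1, p2, ClusteringConfig())


def test_combined_distance_symmetry(rng):
    cfg = ClusteringConfig(alpha=0.3, beta=10.0)
    for _ in range(5):
        f1, f2 = rng.normal(size=(2, 28))
        p1, p2 = rng.normal(size=(2, 3))
        assert combined_distance(f1, f2, p1, p2, cfg) == pytest.approx(
            combined_distance(f2, f1, p2, p1, cfg)
        )


# ------------------------------------------------------- initialization


def test_init_each_voxel_own_centroid():
    P = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
    Cc, Pc = init_centroids(P, k=3)
    assert sorted(Pc[:, 0].tolist()) == [0.0, 1.0, 2.0]


def test_init_two_separated_blobs():
    P = np.vstack([np.random.default_rng(0).normal(0, 0.1, (10, 3)),
                   np.random.default_rng(1).normal(10, 0.1, (10, 3))])
    _, Pc = init_centroids(P, k=2)
    assert sorted(np.round(Pc.mean(axis=1)).tolist()) == [0.0, 10.0]


def test_init_three_collinear_blobs():
    blobs = [np.array([[i * 10.0 + dx, 0.0, 0.0] for dx in (-0.5, 0.0, 0.5)]) for i in range(3)]
    P = np.vstack(blobs)
    _, Pc = init_centroids(P, k=3)
    assert sorted(np.round(Pc[:, 0]).tolist()) == [0.0, 10.0, 20.0]


def test_init_rejects_too_few_voxels():
    with pytest.raises(ValueError):
        init_centroids(np.zeros((2, 3)), k=3)


# ------------------------------------------------------------- k-means


def test_kmeans_k1_labels_everything_one():
    ph = make_phantom(PhantomConfig(grid_shape=(10, 10, 8), seed=0))
    parc = kmeans_segment(ph.fod, config=ClusteringConfig(k=1))
    assert set(np.unique(parc.labels[ph.mask])) == {1}


def test_kmeans_zero_noise_exact_recovery():
    ph = make_phantom(PhantomConfig(snr=0.0, seed=0))
    truth = Parcellation(ph.labels, ph.mask)
    parc = match_labels(kmeans_segment(ph.fod), truth)
    np.testing.assert_allclose(dice_per_nucleus(parc, truth), 1.0)


def test_kmeans_objective_monotone_and_recovery_under_noise():
    for seed in range(3):
        cfg = config_with_ratio(PhantomConfig(seed=seed), 1 / 3)
        ph = make_phantom(cfg)
        truth = Parcellation(ph.labels, ph.mask)
        parc = kmeans_segment(ph.fod)
        obj = parc.meta["objective"]
        assert all(b <= a + 1e-9 for a, b in zip(obj, obj[1:]))
        assert dice_per_nucleus(match_labels(parc, truth), truth).mean() >= 0.9


def test_kmeans_scale_coupling():
    """Multiplying coefficients by c and beta by c preserves the partition."""
    cfg = config_with_ratio(PhantomConfig(grid_shape=(12, 12, 10), seed=5), 1 / 3)
    ph = make_phantom(cfg)
    base = kmeans_segment(ph.fod, config=ClusteringConfig(beta=85.0))
    scaled_fod = FODImage(ph.fod.coeffs * 3.0, mask=ph.mask)
    scaled = kmeans_segment(scaled_fod, config=ClusteringConfig(beta=85.0 * 3.0))
    assert nmi(base, scaled) == pytest.approx(1.0)


def test_kmeans_small_instance_matches_multirestart_search(rng):
    """Converged objective is not worse than a 50-restart randomized search."""
    grid = (6, 5, 1)
    mask = np.ones(grid, bool)
    means = rng.normal(size=(2, 28)) * 5
    lab1d = (np.argwhere(mask)[:, 0] < 3).astype(int) + 1
    fod = small_fod(lab1d, means, grid, mask, noise=0.3, seed=0)
    cfg = ClusteringConfig(k=2, alpha=0.5, beta=1.0)
    parc = kmeans_segment(fod, config=cfg)
    ours = parc.meta["objective"][-1]

    C = fod.coeffs[mask]
    P = np.argwhere(mask).astype(float)

    def objective(assign):
        tot = 0.0
        for c in range(2):
            m = assign == c
            if not m.any():
                return np.inf
            fc, pc = C[m].mean(0), P[m].mean(0)
            tot += sum(
                cfg.alpha * np.linalg.norm(C[i] - fc)
                + (1 - cfg.alpha) * cfg.beta * np.linalg.norm(P[i] - pc)
                for i in np.flatnonzero(m)
            )
        return tot

    best = np.inf
    for r in range(50):
        assign = np.random.default_rng(r).integers(0, 2, C.shape[0])
        for _ in range(30):
            fc = np.stack([C[assign == c].mean(0) if (assign == c).any() else C[r % len(C)] for c in range(2)])
            pc = np.stack([P[assign == c].mean(0) if (assign == c).any() else P[r % len(P)] for c in range(2)])
            d = (cfg.alpha * np.linalg.norm(C[:, None] - fc[None], axis=2)
                 + (1 - cfg.alpha) * cfg.beta * np.linalg.norm(P[:, None] - pc[None], axis=2))
            new = d.argmin(1)
            if np.array_equal(new, assign):
                break
            assign = new
        best = min(best, objective(assign))
    assert ours <= best + 1e-6


def test_kmeans_empty_mask_raises():
    ph = make_phantom(PhantomConfig(grid_shape=(10, 10, 8), seed=0))
    with pytest.raises(ValueError):
        kmeans_segment(ph.fod, mask=np.zeros_like(ph.mask))


# -------------------------------------------------------- label matching


def test_match_labels_identity_and_cyclic_shift():
    ph = make_phantom(PhantomConfig(grid_shape=(12, 12, 10), seed=0))
    truth = Parcellation(ph.labels, ph.mask)
    assert np.array_equal(match_labels(truth, truth).labels, truth.labels)
    k = truth.k
    shift = np.roll(np.arange(1, k + 1), 1)
    shifted = truth.relabeled(shift)
    recovered = match_labels(shifted, truth)
    assert np.array_equal(recovered.labels, truth.labels)


def test_match_labels_equals_exhaustive_search(rng):
    mask = np.ones((4, 4, 3), bool)
    for trial in range(5):
        a = Parcellation(rng.integers(1, 4, mask.shape), mask)
        b = Parcellation(rng.integers(1, 4, mask.shape), mask)
        got = match_labels(a, b)
        overlap = contingency(got.masked_labels(), b.masked_labels())
        best = max(
            sum(contingency(a.masked_labels(), b.masked_labels())[i, p[i]] for i in range(3))
            for p in itertools.permutations(range(3))
        )
        assert np.trace(overlap) == best


def test_match_labels_rejects_mismatched_k():
    mask = np.ones((4, 4, 3), bool)
    a = Parcellation(np.ones(mask.shape, int), mask)
    b = Parcellation(np.random.default_rng(0).integers(1, 3, mask.shape), mask)
    with pytest.raises(ValueError):
        match_labels(a, b)


# ------------------------------------------------------------ consensus


def _noisy_variant(parc, frac, seed):
    rng = np.random.default_rng(seed)
    lab = parc.labels.copy()
    vox = np.argwhere(parc.mask)
    flip = vox[rng.random(len(vox)) < frac]
    for x, y, z in flip:
        lab[x, y, z] = rng.integers(1, parc.k + 1)
    return Parcellation(lab, parc.mask)


@pytest.mark.parametrize("method", ["vote", "coassoc"])
def test_consensus_of_identical_inputs_is_input(method):
    ph = make_phantom(PhantomConfig(grid_shape=(12, 12, 10), seed=0))
    truth = Parcellation(ph.labels, ph.mask)
    cons = consensus_partition([truth, truth, truth], method=method)
    assert nmi(cons, truth) == pytest.approx(1.0)


@pytest.mark.parametrize("method", ["vote", "coassoc"])
def test_consensus_invariant_to_label_permutation(rng, method):
    ph = make_phantom(PhantomConfig(grid_shape=(12, 12, 10), seed=0))
    truth = Parcellation(ph.labels, ph.mask)
    inputs = [_noisy_variant(truth, 0.05, s) for s in range(4)]
    permuted = [p.relabeled(rng.permutation(np.arange(1, p.k + 1))) for p in inputs]
    a = consensus_partition(inputs, k=truth.k, method=method)
    b = consensus_partition(permuted, k=truth.k, method=method)
    assert nmi(a, b) == pytest.approx(1.0)


def test_consensus_denoises_beyond_single_inputs():
    """Consensus of noisy perturbations is closer to the clean partition than
    typical single inputs are (checked across seeds)."""
    ph = make_phantom(PhantomConfig(grid_shape=(12, 12, 10), seed=0))
    truth = Parcellation(ph.labels, ph.mask)
    wins = 0
    for seed in range(5):
        inputs = [_noisy_variant(truth, 0.05, 100 * seed + s) for s in range(10)]
        cons = consensus_partition(inputs, k=truth.k)
        if nmi(cons, truth) > max(nmi(p, truth) for p in inputs):
            wins += 1
    assert wins >= 4


def test_consensus_rejects_bad_inputs():
    ph = make_phantom(PhantomConfig(grid_shape=(12, 12, 10), seed=0))
    truth = Parcellation(ph.labels, ph.mask)
    with pytest.raises(ValueError):
        consensus_partition([truth])
    other = Parcellation(np.ones((12, 12, 10), int), np.ones((12, 12, 10), bool))
    with pytest.raises(ValueError):
        consensus_partition([truth, other])
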