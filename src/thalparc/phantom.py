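"""Seeded synthetic cohorts for the thalamic-parcellation pipeline.

The generator emulates the study design the analysis assumes: per-hemisphere
thalamus phantoms of k nuclei with distinct dominant fiber orientations
(Watson-like SH lobes), a cohort of healthy controls (HC) and patients in
minimally conscious (MCS) or vegetative state (VS), analytic deformation
fields planting expansion/shrinkage of designated nuclei, apparent-fiber-
density (FD) reduction in designated nuclei and their thalamo-cortical
pathways, diffusivity increases along those pathways, and CRS-R scores tied
to the planted per-subject effect magnitudes (lower CRS-R with larger volume
change, higher CRS-R with higher FD).

Every output is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .shmath import FODImage, SHBasis, sh_basis_size


# --------------------------------------------------------------------------
# configuration


def default_orientations(k: int) -> np.ndarray:
    """k unit vectors, pairwise separated by >= 20 deg under antipodal metric.

    One polar direction plus a ring at 45 deg polar angle (adjacent ring
    members ~41 deg apart for k = 7).
    """
    dirs = [np.array([0.0, 0.0, 1.0])]
    for i in range(k - 1):
        th, ph = np.deg2rad(45.0), 2.0 * np.pi * i / max(k - 1, 1)
        dirs.append(np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]))
    return np.array(dirs[:k])


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and signal model of a single-hemisphere thalamus phantom."""

    grid_shape: tuple[int, int, int] = (20, 24, 16)
    k_nuclei: int = 7
    lmax: int = 6
    kappa: float = 20.0  # Watson concentration of each nucleus lobe
    amplitude: float = 250.0  # FOD spherical integral per voxel (a.u.); chosen
    # so between-nucleus coefficient distances are commensurate with
    # beta * voxel distances in the combined clustering metric (beta = 85)
    snr: float = 0.22  # coefficient noise std relative to c00; at the default
    # amplitude the between-nucleus class-mean distance exceeds the mean
    # within-nucleus voxel distance by a factor > 3
    voxel_size: tuple[float, float, float] = (1.25, 1.25, 1.25)
    mask_margin: tuple[int, int, int] = (3, 3, 3)
    seed: int = 0
    orientations: np.ndarray | None = None

    def resolved_orientations(self) -> np.ndarray:
        dirs = (
            default_orientations(self.k_nuclei)
            if self.orientations is None
            else np.asarray(self.orientations, dtype=float)
        )
        if dirs.shape != (self.k_nuclei, 3):
            raise ValueError("orientations must be (k_nuclei, 3)")
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        if self.k_nuclei > 1:
            cos = np.abs(dirs @ dirs.T)
            np.fill_diagonal(cos, 0.0)
            if np.rad2deg(np.arccos(np.clip(cos.max(), -1, 1))) < 20.0:
                raise ValueError("nucleus orientations closer than 20 degrees")
        return dirs

    @property
    def noise_sigma(self) -> float:
        c00 = self.amplitude / (2.0 * np.sqrt(np.pi))
        return self.snr * c00


@dataclass(frozen=True)
class EffectConfig:
    """Planted group effects.

    ``volume_effect`` is the full-severity volume ratio of the expanded
    nucleus (the shrunk nucleus gets its reciprocal); ``fd_reduction`` the
    full-severity fractional FD decrease; ``crs_r_link`` the slope of CRS-R
    on planted severity (negative: more severe -> lower CRS-R, which yields
    the study's effect directions corr(CRS-R, volume change) < 0 and
    corr(CRS-R, FD) > 0).
    """

    expand_nucleus: int = 6
    shrink_nucleus: int = 1
    volume_effect: float = 1.2
    fd_reduction: float = 0.3
    md_increase: float = 0.15
    crs_r_link: float = -12.0
    crs_r_base: float = 16.0
    crs_r_noise: float = 1.0
    fd_nuclei: tuple[int, ...] | None = None  # default: (expand_nucleus,)

    def __post_init__(self):
        if not 0.0 <= self.fd_reduction < 1.0:
            raise ValueError("fd_reduction must be in [0, 1)")
        if self.volume_effect <= 0:
            raise ValueError("volume_effect must be positive")

    def resolved_fd_nuclei(self) -> tuple[int, ...]:
        return self.fd_nuclei if self.fd_nuclei is not None else (self.expand_nucleus,)


NULL_EFFECTS = EffectConfig(volume_effect=1.0, fd_reduction=0.0, md_increase=0.0)


# --------------------------------------------------------------------------
# geometry


@lru_cache(maxsize=16)
def _cached_geometry(grid_shape, mask_margin, k):
    nx, ny, nz = grid_shape
    mx, my, mz = mask_margin
    if nx - 2 * mx < 2 or ny - 2 * my < 2 or nz - 2 * mz < 2:
        raise ValueError(f"grid {grid_shape} too small for margins {mask_margin}")
    mask = np.zeros(grid_shape, dtype=bool)
    mask[mx : nx - mx, my : ny - my, mz : nz - mz] = True
    pos = np.argwhere(mask).astype(float)
    if pos.shape[0] < k:
        raise ValueError(f"mask has fewer voxels than k = {k}")
    labels = np.zeros(grid_shape, dtype=int)
    if k == 1:
        labels[mask] = 1
    else:
        from scipy.cluster.hierarchy import fcluster, linkage

        assign = fcluster(linkage(pos, method="ward"), t=k, criterion="maxclust")
        labels[mask] = assign
    labels.setflags(write=False)
    mask.setflags(write=False)
    return mask, labels


def nucleus_labels(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth parcellation: mask plus k compact, contiguous nuclei.

    The mask is an interior box of the grid; nuclei are the spatially compact
    territories produced by deterministic minimum-variance (Ward) spatial
    agglomeration of the masked voxels, mirroring the spatial coherence of
    real thalamic nuclei.
    """
    mask, labels = _cached_geometry(
        tuple(config.grid_shape), tuple(config.mask_margin), config.k_nuclei
    )
    return mask.copy(), labels.copy()


def make_pathways(
    labels: np.ndarray,
    mask: np.ndarray,
    n_targets: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Pathway label volume linking each nucleus to ``n_targets`` cortical targets.

    Each (nucleus, target) pathway is a straight voxel tube that starts at a
    voxel of the nucleus and runs along +z out of the mask toward the grid
    top (a stand-in for a thalamo-cortical tract).  Tubes use globally
    distinct (x, y) columns, so pathways are pairwise disjoint.  Label values
    are (nucleus - 1) * n_targets + target + 1.
    """
    rng = np.random.default_rng(seed)
    nz = labels.shape[2]
    k = int(labels.max())
    z_mask_top = int(np.max(np.nonzero(mask.any(axis=(0, 1)))[0]))
    if nz - 1 - z_mask_top < 2:
        raise ValueError("grid too small above the mask to route pathway tubes")
    pathways = np.zeros(labels.shape, dtype=int)
    used: set[tuple[int, int]] = set()
    for nuc in range(1, k + 1):
        occupied = labels == nuc
        cols = sorted({(int(x), int(y)) for x, y, _ in np.argwhere(occupied)})
        avail = [c for c in cols if c not in used]
        if len(avail) < n_targets:
            raise ValueError(f"nucleus {nuc} has {len(avail)} free columns < n_targets={n_targets}")
        idx = np.linspace(0, len(avail) - 1, n_targets).round().astype(int)
        idx = (idx + rng.integers(0, 2)) % len(avail)
        idx = np.unique(idx)
        while idx.size < n_targets:
            extra = int(rng.integers(0, len(avail)))
            if extra not in idx:
                idx = np.sort(np.append(idx, extra))
        for t, i in enumerate(idx[:n_targets]):
            x, y = avail[i]
            z0 = int(np.max(np.nonzero(occupied[x, y])[0]))  # topmost in-nucleus voxel
            value = (nuc - 1) * n_targets + t + 1
            pathways[x, y, z0:nz] = value
            used.add((x, y))
    return pathways


# --------------------------------------------------------------------------
# analytic deformation fields


@dataclass(frozen=True)
class RadialWarp:
    """Radial scaling centered at ``center`` (mm), smoothly blended to identity.

    The local linear scale is s inside radius r0, 1 outside r1, with a
    smoothstep blend between; the map is x -> c + lam(r) * (x - c) and its
    Jacobian determinant has the closed form (lam'(r) r + lam) * lam^2.
    """

    center: np.ndarray
    scale: float
    r0: float
    r1: float

    def _lam(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.clip((r - self.r0) / (self.r1 - self.r0), 0.0, 1.0)
        smooth = t**3 * (6 * t**2 - 15 * t + 10)  # C2 quintic smoothstep
        lam = self.scale + (1.0 - self.scale) * smooth
        dlam = (1.0 - self.scale) * 30 * t**2 * (t - 1) ** 2 / (self.r1 - self.r0)
        dlam = np.where((r <= self.r0) | (r >= self.r1), 0.0, dlam)
        return lam, dlam

    def map(self, x: np.ndarray) -> np.ndarray:
        d = x - self.center
        r = np.linalg.norm(d, axis=-1)
        lam, _ = self._lam(r)
        return self.center + lam[..., None] * d

    def log_jacobian(self, x: np.ndarray) -> np.ndarray:
        d = x - self.center
        r = np.linalg.norm(d, axis=-1)
        lam, dlam = self._lam(r)
        det = (dlam * r + lam) * lam**2
        if np.any(det <= 0):
            raise ValueError("radial warp folds (non-positive Jacobian determinant)")
        return np.log(det)


class ComposedWarp:
    """Composition w1 after w2; log-Jacobian by the chain rule (exact)."""

    def __init__(self, *warps: RadialWarp):
        self.warps = warps

    def map(self, x: np.ndarray) -> np.ndarray:
        for w in reversed(self.warps):
            x = w.map(x)
        return x

    def log_jacobian(self, x: np.ndarray) -> np.ndarray:
        total = np.zeros(x.shape[:-1])
        for w in reversed(self.warps):
            total = total + w.log_jacobian(x)
            x = w.map(x)
        return total


def world_grid(grid_shape, voxel_size) -> np.ndarray:
    """(x, y, z, 3) array of voxel-center world coordinates in mm."""
    axes = [np.arange(n) * s for n, s in zip(grid_shape, voxel_size)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def displacement_from_warp(warp, grid_shape, voxel_size) -> np.ndarray:
    x = world_grid(grid_shape, voxel_size)
    return warp.map(x) - x


# --------------------------------------------------------------------------
# single-subject phantom


@dataclass
class Phantom:
    fod: FODImage
    mask: np.ndarray
    labels: np.ndarray  # ground-truth parcellation (0 outside mask)
    tensor_eigs: np.ndarray  # (x, y, z, 3), sorted descending, mm^2/s


def watson_coefficients(basis: SHBasis, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Unit-integral Watson-like lobe exp(kappa (mu.u)^2) projected on the basis."""
    f = np.exp(kappa * (basis.mesh.vertices @ np.asarray(mu, dtype=float)) ** 2)
    c = basis.project(f)
    return c / (c[0] * 2.0 * np.sqrt(np.pi))


def nucleus_mean_coefficients(config: PhantomConfig, basis: SHBasis | None = None) -> np.ndarray:
    """(k, n_coeff) noiseless class-mean coefficient vectors."""
    basis = basis or SHBasis(config.lmax)
    dirs = config.resolved_orientations()
    return np.array(
        [config.amplitude * watson_coefficients(basis, mu, config.kappa) for mu in dirs]
    )


BASE_EIGS = np.array([1.7e-3, 0.45e-3, 0.35e-3])  # prolate, mm^2/s


def make_phantom(
    config: PhantomConfig,
    basis: SHBasis | None = None,
    rng: np.random.Generator | None = None,
) -> Phantom:
    """Generate one seeded single-hemisphere phantom."""
    basis = basis or SHBasis(config.lmax)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mask, labels = nucleus_labels(config)
    means = nucleus_mean_coefficients(config, basis)
    n_coeff = sh_basis_size(config.lmax)

    coeffs = np.zeros(config.grid_shape + (n_coeff,))
    for nuc in range(1, config.k_nuclei + 1):
        coeffs[labels == nuc] = means[nuc - 1]
    coeffs[mask] += rng.normal(0.0, config.noise_sigma, size=(mask.sum(), n_coeff))

    eigs = np.broadcast_to(BASE_EIGS, config.grid_shape + (3,)).copy()
    jitter = 1.0 + 0.02 * rng.standard_normal(config.grid_shape)[..., None]
    eigs = np.sort(eigs * np.abs(jitter), axis=-1)[..., ::-1]

    fod = FODImage(coeffs, voxel_size=config.voxel_size, mask=mask)
    return Phantom(fod=fod, mask=mask, labels=labels, tensor_eigs=eigs)


def noise_sigma_for_ratio(config: PhantomConfig, ratio: float = 1.0 / 3.0) -> float:
    """Coefficient-noise std giving a target within/between feature-distance ratio.

    Between-nucleus distance is measured on the noiseless class means; the
    expected within-nucleus distance of two voxels with iid N(0, sigma^2 I_n)
    noise is sigma * sqrt(2) * E||N(0, I_n)||.
    """
    means = nucleus_mean_coefficients(config)
    if means.shape[0] < 2:
        raise ValueError("need at least two nuclei to define a between-class distance")
    from scipy.spatial.distance import pdist
    from scipy.special import gamma

    between = pdist(means).mean()
    n = means.shape[1]
    e_norm = np.sqrt(2.0) * gamma((n + 1) / 2) / gamma(n / 2)
    return ratio * between / (np.sqrt(2.0) * e_norm)


def config_with_ratio(config: PhantomConfig, ratio: float = 1.0 / 3.0) -> PhantomConfig:
    """Copy of ``config`` with snr set to achieve the given distance ratio."""
    sigma = noise_sigma_for_ratio(config, ratio)
    c00 = config.amplitude / (2.0 * np.sqrt(np.pi))
    return replace(config, snr=sigma / c00)


# --------------------------------------------------------------------------
# cohort


@dataclass
class Subject:
    record: dict
    fod: FODImage
    warp_field: np.ndarray  # (x, y, z, 3) displacement, mm
    tensor_eigs: np.ndarray
    severity: float
    analytic_logj: np.ndarray | None = None


@dataclass
class Cohort:
    subjects: list[Subject]
    mask: np.ndarray
    labels: np.ndarray  # shared ground-truth parcellation
    pathways: np.ndarray  # pathway label volume
    metadata: pd.DataFrame
    manifest: dict
    config: PhantomConfig
    effects: EffectConfig

    @property
    def groups(self) -> np.ndarray:
        return self.metadata["group"].to_numpy()


def _severity(group: str, rng: np.random.Generator) -> float:
    if group == "HC":
        return 0.0
    lo, hi = (0.3, 0.6) if group == "MCS" else (0.7, 1.0)
    return float(rng.uniform(lo, hi))


def _jitter_warp(grid_shape, voxel_size, rng, amplitude=0.02):
    """Small smooth random displacement so controls have non-trivial fields."""
    x = world_grid(grid_shape, voxel_size)
    extent = np.array(grid_shape) * np.array(voxel_size)
    u = np.zeros_like(x)
    for axis in range(3):
        phase = rng.uniform(0, 2 * np.pi, size=3)
        freq = 2 * np.pi / extent
        u[..., axis] = amplitude * (
            np.sin(freq[0] * x[..., 0] + phase[0])
            * np.sin(freq[1] * x[..., 1] + phase[1])
            * np.sin(freq[2] * x[..., 2] + phase[2])
        )
    return u


def make_cohort(
    n_hc: int = 10,
    n_mcs: int = 5,
    n_vs: int = 5,
    phantom: PhantomConfig | None = None,
    effects: EffectConfig | None = None,
    seed: int = 0,
    n_targets: int = 5,
) -> Cohort:
    """Generate a full seeded cohort with planted group effects."""
    config = phantom or PhantomConfig()
    effects = effects if effects is not None else EffectConfig()
    basis = SHBasis(config.lmax)
    root = np.random.SeedSequence(seed)
    n_total = n_hc + n_mcs + n_vs
    child_seqs = root.spawn(n_total + 2)  # child 0 reserved for cohort-level draws

    mask, labels = nucleus_labels(config)
    pathways = make_pathways(labels, mask, n_targets=n_targets, seed=int(child_seqs[1].generate_state(1)[0] % (2**31)))
    means = nucleus_mean_coefficients(config, basis)
    path_lobe = config.amplitude * watson_coefficients(basis, np.array([0.0, 0.0, 1.0]), config.kappa)

    vs = np.array(config.voxel_size)
    centers_vox = {
        nuc: np.argwhere(labels == nuc).mean(axis=0) for nuc in range(1, config.k_nuclei + 1)
    }
    def _covering_radius(nuc: int) -> float:
        vox = np.argwhere(labels == nuc) * vs
        return float(np.linalg.norm(vox - vox.mean(axis=0), axis=1).max()) if vox.size else 5.0

    # full-scale core just covers the nucleus; blend to identity over ~2 voxels
    r0 = {
        n: _covering_radius(n) * 1.02 + 0.5 * float(vs.mean())
        for n in (effects.expand_nucleus, effects.shrink_nucleus)
    }
    r1 = {n: r for n, r in ((n, r0[n] + 2.0 * float(vs.mean())) for n in r0)}

    fd_nuclei = effects.resolved_fd_nuclei()
    fd_region = np.isin(labels, fd_nuclei)
    path_of = (pathways - 1) // n_targets + 1  # nucleus owning each pathway label
    fd_pathway = (pathways > 0) & ~mask & np.isin(path_of, fd_nuclei)
    fd_region_full = fd_region | fd_pathway

    groups = ["HC"] * n_hc + ["MCS"] * n_mcs + ["VS"] * n_vs
    subjects: list[Subject] = []
    grid = world_grid(config.grid_shape, config.voxel_size)
    for i, group in enumerate(groups):
        rng = np.random.default_rng(child_seqs[i + 2])
        sev = _severity(group, rng)

        # FOD: nucleus lobes + pathway lobes + noise, with planted FD scaling
        coeffs = np.zeros(config.grid_shape + (basis.n_coeff,))
        for nuc in range(1, config.k_nuclei + 1):
            coeffs[labels == nuc] = means[nuc - 1]
        coeffs[(pathways > 0) & ~mask] = path_lobe
        fd_factor = 1.0 - effects.fd_reduction * sev
        coeffs[fd_region_full] *= fd_factor
        full_mask = mask | (pathways > 0)
        coeffs[full_mask] += rng.normal(0.0, config.noise_sigma, size=(int(full_mask.sum()), basis.n_coeff))

        # deformation: radial expansion/shrinkage composed with smooth jitter
        vol_expand = effects.volume_effect ** sev
        vol_shrink = effects.volume_effect ** (-sev)
        warps = []
        analytic_logj = np.zeros(config.grid_shape)
        if sev > 0 and effects.volume_effect != 1.0:
            ne, ns = effects.expand_nucleus, effects.shrink_nucleus
            w_e = RadialWarp(centers_vox[ne] * vs, vol_expand ** (1 / 3), r0[ne], r1[ne])
            w_s = RadialWarp(centers_vox[ns] * vs, vol_shrink ** (1 / 3), r0[ns], r1[ns])
            composed = ComposedWarp(w_e, w_s)
            field = displacement_from_warp(composed, config.grid_shape, config.voxel_size)
            analytic_logj = composed.log_jacobian(grid)
            warps.append(composed)
        else:
            field = np.zeros(config.grid_shape + (3,))
        field = field + _jitter_warp(config.grid_shape, config.voxel_size, rng)

        # tensors: prolate base, diffusivity raised along affected pathways
        eigs = np.broadcast_to(BASE_EIGS, config.grid_shape + (3,)).copy()
        eigs = eigs * (1.0 + effects.md_increase * sev * fd_pathway[..., None])
        jitter = 1.0 + 0.02 * rng.standard_normal(config.grid_shape)[..., None]
        eigs = np.sort(eigs * np.abs(jitter), axis=-1)[..., ::-1]

        if group == "HC":
            crs = 23
            age = float(np.clip(rng.normal(43.1, 16.4), 18, 90))
            duration = 0.0
        else:
            crs = int(np.clip(round(effects.crs_r_base + effects.crs_r_link * sev
                                    + rng.normal(0, effects.crs_r_noise)), 0, 23))
            age = float(np.clip(rng.normal(54.5, 11.7), 18, 90))
            duration = float(rng.uniform(1.5, 8.0))
        record = {
            "id": f"{group.lower()}{i:02d}",
            "group": group,
            "crs_r_total": crs,
            "age": round(age, 1),
            "icv": round(float(rng.normal(1.45e6, 1.2e5)), 1),
            "doc_duration": round(duration, 2),
        }
        subjects.append(
            Subject(
                record=record,
                fod=FODImage(coeffs, voxel_size=config.voxel_size, mask=mask),
                warp_field=field,
                tensor_eigs=eigs,
                severity=sev,
                analytic_logj=analytic_logj,
            )
        )

    metadata = pd.DataFrame([s.record for s in subjects])
    manifest = {
        "expand_nucleus": effects.expand_nucleus,
        "shrink_nucleus": effects.shrink_nucleus,
        "fd_nuclei": list(fd_nuclei),
        "volume_effect": effects.volume_effect,
        "fd_reduction": effects.fd_reduction,
        "severity": {s.record["id"]: s.severity for s in subjects},
        "seed": seed,
    }
    return Cohort(
        subjects=subjects,
        mask=mask,
        labels=labels,
        pathways=pathways,
        metadata=metadata,
        manifest=manifest,
        config=config,
        effects=effects,
    )
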