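"""Fixel (fiber-population) extraction from FODs and the fixel metrics FD, FC, FDC.

A fixel is a distinct fiber population within a voxel: a direction plus its
apparent fiber density (FD), the integral of the FOD over that population's
lobe.  Fiber-bundle cross-section (FC) measures the area change of the plane
perpendicular to the fixel direction under the subject-to-template warp, and
FDC = FD * FC combines the two.

Lobe segmentation: the FOD is sampled on the sphere mesh, negative amplitudes
(CSD ringing) are clipped to zero, mesh-local maxima above a fraction of the
per-voxel maximum become peaks, and every positive sample is assigned to the
nearest peak under antipodal angular distance.  Each fixel's FD therefore
integrates both antipodal lobes, so an isotropic FOD yields a single fixel
carrying the full spherical integral c00 * 2*sqrt(pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shmath import SHBasis


@dataclass(frozen=True)
class Fixel:
    """One fiber population: canonical unit direction, FD, optional FC/FDC."""

    direction: np.ndarray
    fd: float
    fc: float | None = None
    fdc: float | None = None
    peakless: bool = False

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("fixel direction must be a unit vector")
        object.__setattr__(self, "direction", canonical_direction(d))
        if self.fd < 0:
            raise ValueError("fd must be non-negative")
        if self.fc is not None and self.fc <= 0:
            raise ValueError("fc must be positive")

    def with_warp(self, jacobian: np.ndarray) -> "Fixel":
        fc = fixel_fc(self.direction, jacobian)
        return Fixel(self.direction, self.fd, fc=fc, fdc=fdc(self.fd, fc), peakless=self.peakless)


def canonical_direction(d: np.ndarray) -> np.ndarray:
    """Resolve the antipodal ambiguity: non-negative z, ties by y then x."""
    d = np.asarray(d, dtype=float)
    key = d[2] if abs(d[2]) > 1e-12 else (d[1] if abs(d[1]) > 1e-12 else d[0])
    return -d if key < 0 else d.copy()


@dataclass
class FixelSet:
    """Per-masked-voxel fixel lists, each sorted by descending FD.

    ``fixels[i]`` belongs to the i-th masked voxel (C-order of the mask).
    """

    fixels: list[list[Fixel]]
    max_fixels: int = 3
    voxel_index: np.ndarray | None = field(default=None)

    def __len__(self) -> int:
        return len(self.fixels)

    def total_fd(self) -> np.ndarray:
        return np.array([sum(f.fd for f in fx) for fx in self.fixels])


def extract_fixels(
    coeffs: np.ndarray,
    basis: SHBasis,
    peak_threshold: float = 0.1,
    max_fixels: int = 3,
) -> list[Fixel]:
    """Extract the fixels of a single voxel's FOD coefficient vector."""
    amp = basis.sample(np.asarray(coeffs, dtype=float))
    return _fixels_from_amplitudes(amp[None], basis, peak_threshold, max_fixels)[0]


def extract_fixels_volume(
    coeffs: np.ndarray,
    basis: SHBasis,
    peak_threshold: float = 0.1,
    max_fixels: int = 3,
) -> list[list[Fixel]]:
    """Vectorised fixel extraction for a (n_voxels, n_coeff) coefficient array."""
    amps = basis.sample(np.asarray(coeffs, dtype=float))
    return _fixels_from_amplitudes(amps, basis, peak_threshold, max_fixels)


def _fixels_from_amplitudes(amps, basis, peak_threshold, max_fixels):
    mesh = basis.mesh
    amps = np.clip(amps, 0.0, None)  # negative ringing carries no density
    n_vox = amps.shape[0]
    neigh_max = amps[:, mesh.neighbors].max(axis=2)
    global_max = amps.max(axis=1)
    is_peak = (amps >= neigh_max) & (amps >= peak_threshold * global_max[:, None]) & (amps > 0)
    # keep one representative of each antipodal peak pair
    canon = mesh.vertices[:, 2] > 1e-12
    canon |= (np.abs(mesh.vertices[:, 2]) <= 1e-12) & (mesh.vertices[:, 1] > 1e-12)
    canon |= (
        (np.abs(mesh.vertices[:, 2]) <= 1e-12)
        & (np.abs(mesh.vertices[:, 1]) <= 1e-12)
        & (mesh.vertices[:, 0] > 0)
    )
    is_peak &= canon[None, :]

    verts = mesh.vertices
    weights = mesh.weights
    out: list[list[Fixel]] = []
    for v in range(n_vox):
        a = amps[v]
        if global_max[v] <= 0:
            out.append([])
            continue
        pk = np.flatnonzero(is_peak[v])
        if a.max() - a.min() <= 1e-9 * a.max():
            pk = np.empty(0, dtype=int)  # numerically flat: no distinct peak
        if pk.size == 0:
            # peakless (numerically flat) FOD: one +z fixel with the full integral
            out.append([Fixel(np.array([0.0, 0.0, 1.0]), float(a @ weights), peakless=True)])
            continue
        # order candidate peaks by amplitude; nearest-peak lobe assignment
        pk = pk[np.argsort(a[pk])[::-1]]
        cos = np.abs(verts @ verts[pk].T)  # antipodal angular proximity
        assign = np.argmax(cos, axis=1)
        fd = np.zeros(pk.size)
        np.add.at(fd, assign, a * weights)
        order = np.argsort(fd)[::-1][:max_fixels]
        out.append(
            [Fixel(verts[pk[i]].copy(), float(fd[i])) for i in order if fd[i] > 0]
        )
    return out


def fixel_fc(direction: np.ndarray, jacobian: np.ndarray) -> float:
    """Fiber-bundle cross-section: area change perpendicular to the fixel.

    FC = |det J| / ||J d||; identity gives 1, uniform scaling s*I gives s^2.
    """
    J = np.asarray(jacobian, dtype=float)
    det = np.linalg.det(J)
    if det <= 0:
        raise ValueError(f"degenerate warp: Jacobian determinant {det} <= 0")
    d = np.asarray(direction, dtype=float)
    return float(abs(det) / np.linalg.norm(J @ d))


def fdc(fd: float, fc: float) -> float:
    """Fiber density and cross-section: the product FD * FC."""
    if fd < 0:
        raise ValueError("fd must be non-negative")
    if fc <= 0:
        raise ValueError("fc must be positive")
    return fd * fc


def match_fixels(
    subject_fixels: list[Fixel],
    template_fixels: list[Fixel],
    max_angle_deg: float = 45.0,
) -> list[Fixel | None]:
    """Greedy angular matching of subject fixels to template fixels.

    For each template fixel (descending FD) the closest unmatched subject
    fixel within ``max_angle_deg`` (antipodal metric) is taken; templates with
    no match get ``None`` and contribute nothing to aggregation.
    """
    cos_thr = np.cos(np.deg2rad(max_angle_deg))
    taken = [False] * len(subject_fixels)
    out: list[Fixel | None] = []
    for tf in template_fixels:
        best, best_cos = None, cos_thr
        for i, sf in enumerate(subject_fixels):
            if taken[i]:
                continue
            c = abs(float(np.dot(tf.direction, sf.direction)))
            if c >= best_cos:
                best, best_cos = i, c
        if best is None:
            out.append(None)
        else:
            taken[best] = True
            out.append(subject_fixels[best])
    return out
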