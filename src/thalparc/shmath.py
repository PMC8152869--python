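"""Real even-order spherical-harmonic (SH) representation of FODs.

A fiber orientation distribution is an antipodally symmetric spherical
function, so only even harmonic orders contribute.  Coefficients are stored
in the MRtrix-style ordering — l ascending over even orders, m from -l to +l
within each l — with the real orthonormal basis

    Y_{l,m} = sqrt(2) * (-1)^m * Im(Y_l^{|m|})   m < 0
    Y_{l,0} = Y_l^0                              m = 0
    Y_{l,m} = sqrt(2) * (-1)^m * Re(Y_l^m)       m > 0

so that for lmax = 6 a voxel carries 28 coefficients and the spherical
integral of the FOD is c00 * 2*sqrt(pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from .sphere import SphereMesh, icosphere


def sh_basis_size(lmax: int) -> int:
    """Number of even-order real SH basis functions up to order ``lmax``.

    (lmax + 1)(lmax + 2) / 2; lmax = 6 gives 28.
    """
    if not isinstance(lmax, (int, np.integer)):
        raise ValueError(f"lmax must be an integer, got {lmax!r}")
    if lmax < 0 or lmax % 2 != 0:
        raise ValueError(f"lmax must be an even non-negative integer, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def sh_degrees_orders(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """(l, m) index pair per coefficient, in storage order."""
    sh_basis_size(lmax)
    ls, ms = [], []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


def real_sh_matrix(lmax: int, directions: np.ndarray) -> np.ndarray:
    """Design matrix B with B[i, j] = Y_j(direction_i), shape (n_dirs, n_coeff)."""
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(directions, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("directions must be unit vectors")
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])

    ls, ms = sh_degrees_orders(lmax)
    cols = np.empty((directions.shape[0], ls.size))
    for j, (l, m) in enumerate(zip(ls, ms)):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.imag
        elif m == 0:
            cols[:, j] = y.real
        else:
            cols[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.real
    return cols


@dataclass(frozen=True)
class SHBasis:
    """Even-order real SH basis bound to a sphere tessellation.

    ``design`` caches the evaluation matrix on the mesh vertices so that
    amplitude sampling is a single matrix product.
    """

    lmax: int
    mesh: SphereMesh = field(default_factory=icosphere)

    def __post_init__(self):
        object.__setattr__(self, "_design", real_sh_matrix(self.lmax, self.mesh.vertices))

    @property
    def n_coeff(self) -> int:
        return sh_basis_size(self.lmax)

    @property
    def sample_directions(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def design(self) -> np.ndarray:
        return self._design

    def sample(self, coeffs: np.ndarray) -> np.ndarray:
        """Amplitudes on the mesh vertices; coeffs may be (..., n_coeff)."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape[-1] != self.n_coeff:
            raise ValueError(
                f"coefficient vector length {coeffs.shape[-1]} != basis size {self.n_coeff}"
            )
        return coeffs @ self._design.T

    def project(self, samples: np.ndarray) -> np.ndarray:
        """Weighted least-squares projection of mesh samples onto the basis.

        For band-limited functions this inverts :meth:`sample` to quadrature
        accuracy (the tessellation-adequacy round trip).
        """
        samples = np.asarray(samples, dtype=float)
        w = self.mesh.weights
        bw = self._design * w[:, None]
        gram = self._design.T @ bw
        rhs = samples @ bw
        return np.linalg.solve(gram, rhs.T).T


@dataclass
class FODImage:
    """4D grid of per-voxel SH coefficient vectors on a 3D voxel lattice.

    ``coeffs`` has shape (x, y, z, n_coeff); ``mask`` marks the voxels whose
    coefficients are meaningful; ``voxel_size`` is mm per axis.
    """

    coeffs: np.ndarray
    voxel_size: tuple[float, float, float] = (1.25, 1.25, 1.25)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 4:
            raise ValueError("FODImage coefficients must be a 4D (x, y, z, n_coeff) array")
        n = self.coeffs.shape[-1]
        lmax = int(round((np.sqrt(8 * n + 1) - 3) / 2))
        if sh_basis_size(lmax) != n:
            raise ValueError(f"coefficient axis length {n} is not an even-order basis size")
        self.lmax = lmax
        if self.mask is None:
            self.mask = np.ones(self.coeffs.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.coeffs.shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} != grid shape {self.coeffs.shape[:3]}"
                )
        if not np.all(np.isfinite(self.coeffs[self.mask])):
            raise ValueError("non-finite FOD coefficients inside the mask")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coeffs.shape[:3]

    def masked_coeffs(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_masked, n_coeff) coefficient matrix in C-order of the mask."""
        m = self.mask if mask is None else np.asarray(mask, dtype=bool)
        return self.coeffs[m]


def evaluate_amplitude(coeffs: np.ndarray, directions: np.ndarray, lmax: int | None = None) -> np.ndarray:
    """Evaluate an SH coefficient vector at arbitrary unit directions.

    Linear in ``coeffs`` and antipodally symmetric (even orders only).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if lmax is None:
        n = coeffs.shape[-1]
        lmax = int(round((np.sqrt(8 * n + 1) - 3) / 2))
        if sh_basis_size(lmax) != n:
            raise ValueError(f"coefficient length {n} is not a valid even-order basis size")
    elif sh_basis_size(lmax) != coeffs.shape[-1]:
        raise ValueError(
            f"coefficient length {coeffs.shape[-1]} != basis size {sh_basis_size(lmax)}"
        )
    B = real_sh_matrix(lmax, directions)
    return coeffs @ B.T
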