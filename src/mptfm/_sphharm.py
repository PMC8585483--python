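"""Real spherical-harmonic machinery on the sphere.

Fields on the particle surface are expanded in the orthonormal *real*
spherical harmonics ``S_lm`` (colatitude ``theta`` from +z, azimuth ``phi``
from +x).  A surface vector field is written in the standard
radial / spheroidal / toroidal split::

    u(theta, phi) = sum_lm [ U_lm S_lm r^
                           + V_lm grad_s S_lm
                           + W_lm (r^ x grad_s S_lm) ]

where ``grad_s`` is the dimensionless angular gradient
``(d/dtheta, (1/sin theta) d/dphi)``.  With this normalization
``integral |grad_s S_lm|^2 dOmega = l(l+1)``.

Analysis (grid -> coefficients) is exact for band-limited fields when done
on a Gauss-Legendre colatitude grid with a uniform azimuth grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y


def mode_list(lmax: int) -> list[tuple[int, int]]:
    """Modes ordered by degree, then order ``m = -l..l``."""
    return [(l, m) for l in range(lmax + 1) for m in range(-l, l + 1)]


def n_modes(lmax: int) -> int:
    return (lmax + 1) ** 2


def gauss_legendre_grid(n_theta: int, n_phi: int):
    """Colatitude Gauss-Legendre nodes + uniform azimuths.

    Returns ``(theta, phi, w_theta)`` where the surface quadrature is
    ``sum_ij w_theta[i] * (2 pi / n_phi) * f[i, j]`` (exact for polynomials
    in cos(theta) up to degree ``2 n_theta - 1``).
    """
    x, w = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x[::-1])  # increasing colatitude
    w_theta = w[::-1].copy()
    phi = np.arange(n_phi) * 2.0 * np.pi / n_phi
    return theta, phi, w_theta


def _theta_amplitudes(lmax: int, theta: np.ndarray):
    """Per-(l, m>=0) colatitude amplitudes A_lm and their theta-derivatives.

    ``A_lm(theta) = Y_lm(theta, 0)`` (real for the scipy convention at
    ``phi = 0``).  The derivative uses the ladder recurrence
    ``dA_lm/dtheta = m cot(theta) A_lm + sqrt((l-m)(l+m+1)) A_{l,m+1}``.
    """
    theta = np.asarray(theta, dtype=float)
    amp = {}
    for l in range(lmax + 1):
        for m in range(l + 1):
            amp[(l, m)] = np.real(sph_harm_y(l, m, theta, 0.0))
    cot = np.cos(theta) / np.sin(theta)
    damp = {}
    for l in range(lmax + 1):
        for m in range(l + 1):
            d = m * cot * amp[(l, m)]
            if m < l:
                d = d + np.sqrt((l - m) * (l + m + 1)) * amp[(l, m + 1)]
            damp[(l, m)] = d
    return amp, damp


def _assemble(lmax, theta, phi, paired: bool, scalar_only: bool = False):
    """Build (Y, dY/dtheta, (1/sin)dY/dphi) for the real basis.

    ``paired=False``: tensor grid, output shape (nmodes, ntheta, nphi).
    ``paired=True``: scattered points, theta/phi same length, output
    (nmodes, npts).  ``scalar_only`` skips the derivative arrays (returned
    as None) -- a threefold memory saving for purely radial fields.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    amp, damp = _theta_amplitudes(lmax, theta)
    inv_sin = 1.0 / np.sin(theta)
    nm = n_modes(lmax)
    if paired:
        shape = (nm, theta.size)
    else:
        shape = (nm, theta.size, phi.size)
    Y = np.zeros(shape)
    dYdt = None if scalar_only else np.zeros(shape)
    dYdp_sin = None if scalar_only else np.zeros(shape)

    def put(idx, a, da, cosf, sinf_deriv_factor):
        # cosf: azimuthal factor; sinf_deriv_factor: its phi-derivative
        if paired:
            Y[idx] = a * cosf
            if not scalar_only:
                dYdt[idx] = da * cosf
                dYdp_sin[idx] = a * inv_sin * sinf_deriv_factor
        else:
            Y[idx] = np.outer(a, cosf)
            if not scalar_only:
                dYdt[idx] = np.outer(da, cosf)
                dYdp_sin[idx] = np.outer(a * inv_sin, sinf_deriv_factor)

    idx = 0
    for l in range(lmax + 1):
        for m in range(-l, l + 1):
            ma = abs(m)
            a, da = amp[(l, ma)], damp[(l, ma)]
            if m == 0:
                put(idx, a, da, np.ones_like(phi), np.zeros_like(phi))
            else:
                scale = np.sqrt(2.0) * (-1.0) ** ma
                if m > 0:
                    f = scale * np.cos(ma * phi)
                    df = -scale * ma * np.sin(ma * phi)
                else:
                    f = scale * np.sin(ma * phi)
                    df = scale * ma * np.cos(ma * phi)
                put(idx, a, da, f, df)
            idx += 1
    return Y, dYdt, dYdp_sin


@dataclass
class RealSHBasis:
    """Real spherical-harmonic basis evaluated on a tensor grid."""

    lmax: int
    theta: np.ndarray
    phi: np.ndarray
    Y: np.ndarray
    dYdt: np.ndarray | None  # None for scalar-only bases
    dYdp_sin: np.ndarray | None
    w_theta: np.ndarray | None = None  # colatitude quadrature weights

    @classmethod
    def gauss_legendre(
        cls, lmax: int, n_theta: int, n_phi: int, scalar_only: bool = False
    ) -> "RealSHBasis":
        theta, phi, w = gauss_legendre_grid(n_theta, n_phi)
        Y, dYdt, dYdp = _assemble(lmax, theta, phi, paired=False, scalar_only=scalar_only)
        return cls(lmax, theta, phi, Y, dYdt, dYdp, w)

    @classmethod
    def on_grid(cls, lmax: int, theta, phi) -> "RealSHBasis":
        """Arbitrary tensor grid (no quadrature weights; synthesis only).

        Colatitudes at the exact poles are nudged inward so tangential basis
        functions stay finite.
        """
        theta = np.clip(np.asarray(theta, dtype=float), 1e-6, np.pi - 1e-6)
        Y, dYdt, dYdp = _assemble(lmax, theta, phi, paired=False)
        return cls(lmax, theta, np.asarray(phi, float), Y, dYdt, dYdp, None)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([l for l, _ in mode_list(self.lmax)])

    @property
    def area_weights(self) -> np.ndarray:
        """Per-node surface quadrature weights (ntheta, nphi), summing to 4 pi."""
        if self.w_theta is None:
            raise ValueError("basis has no quadrature rule")
        return np.outer(self.w_theta, np.full(self.phi.size, 2.0 * np.pi / self.phi.size))

    # -- scalar fields ------------------------------------------------------
    def synth(self, coeffs: np.ndarray) -> np.ndarray:
        return np.tensordot(coeffs, self.Y, axes=(0, 0))

    def analyze(self, field: np.ndarray) -> np.ndarray:
        return np.tensordot(self.Y, field * self.area_weights, axes=([1, 2], [0, 1]))

    # -- vector fields (spherical components) -------------------------------
    def synth_vector(self, U, V, W):
        """Return ``(u_r, u_theta, u_phi)`` grids from mode coefficients."""
        u_r = np.tensordot(U, self.Y, axes=(0, 0))
        u_t = np.tensordot(V, self.dYdt, axes=(0, 0)) - np.tensordot(
            W, self.dYdp_sin, axes=(0, 0)
        )
        u_p = np.tensordot(V, self.dYdp_sin, axes=(0, 0)) + np.tensordot(
            W, self.dYdt, axes=(0, 0)
        )
        return u_r, u_t, u_p

    def analyze_vector(self, u_r, u_t, u_p):
        """Project spherical-component grids onto (U, V, W) coefficients."""
        wa = self.area_weights
        L = self.degrees * (self.degrees + 1.0)
        U = np.tensordot(self.Y, u_r * wa, axes=([1, 2], [0, 1]))
        V = np.tensordot(self.dYdt, u_t * wa, axes=([1, 2], [0, 1])) + np.tensordot(
            self.dYdp_sin, u_p * wa, axes=([1, 2], [0, 1])
        )
        W = -np.tensordot(self.dYdp_sin, u_t * wa, axes=([1, 2], [0, 1])) + np.tensordot(
            self.dYdt, u_p * wa, axes=([1, 2], [0, 1])
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            V = np.where(L > 0, V / np.where(L > 0, L, 1.0), 0.0)
            W = np.where(L > 0, W / np.where(L > 0, L, 1.0), 0.0)
        return U, V, W


def point_eval_scalar(coeffs: np.ndarray, lmax: int, theta, phi) -> np.ndarray:
    """Evaluate a scalar SH expansion at scattered points, mode by mode.

    Memory-light alternative to building the full point basis (used when
    evaluating perturbation fields over entire voxel grids).
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.zeros_like(theta)
    idx = 0
    for l in range(lmax + 1):
        for m in range(-l, l + 1):
            c = coeffs[idx]
            idx += 1
            if c == 0.0:
                continue
            ma = abs(m)
            a = np.real(sph_harm_y(l, ma, theta, 0.0))
            if m == 0:
                out += c * a
            elif m > 0:
                out += c * np.sqrt(2.0) * (-1.0) ** ma * a * np.cos(ma * phi)
            else:
                out += c * np.sqrt(2.0) * (-1.0) ** ma * a * np.sin(ma * phi)
    return out


def point_basis(lmax: int, theta, phi):
    """Basis arrays at scattered (theta, phi) pairs, shape (nmodes, npts)."""
    theta = np.clip(np.asarray(theta, dtype=float), 1e-6, np.pi - 1e-6)
    return _assemble(lmax, theta, np.asarray(phi, dtype=float), paired=True)
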