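"""Solid-sphere linear elastostatics in a spherical-harmonics basis.

The particle is a homogeneous, isotropic, linearly elastic solid sphere
(radius ``R0``, Young's modulus ``E``, Poisson ratio ``nu``).  For boundary
fields expanded in real spherical harmonics the displacement -> traction map
is block-diagonal in degree ``l``: the toroidal channel maps through a
scalar, the coupled radial/spheroidal channel through a 2x2 matrix per
degree.  The blocks follow from the two interior Navier solutions that are
regular at the origin,

* harmonic-gradient family  ``u = grad(r^l Y_lm)``,
* graded family             ``u = r^2 grad(r^l Y_lm) + gamma_l x r^l Y_lm``,

with ``gamma_l = -[(4l+2)(1-2 nu) + 2l] / (l + 5 - 4 nu)``, plus the toroidal
family ``u = r^l (r^ x grad_s Y_lm)``.  Rigid translations (degree-1
harmonic-gradient family) and rigid rotations (degree-1 toroidal) carry zero
traction.

The inverse problem ("traction inference") fixes the *radial* boundary
displacement to the observed shape deviation and chooses the unobservable
tangential displacement by minimizing

    f(u) = E_el + alpha * R^2(T; outside contact) + beta * E_pen(T)

where ``E_el`` is the stored elastic energy, ``R^2`` integrates squared
traction outside the cell-target contact mask, and ``E_pen`` is a steep
high-degree penalty on traction power (anti-aliasing).  All three terms are
quadratic in the free coefficients, so the minimizer is an exact linear
solve.  Terms are nondimensionalized (lengths by ``R0``, stresses by ``E``)
before summing with ``alpha = beta = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from mptfm._sphharm import RealSHBasis, mode_list, n_modes, point_basis


@dataclass(frozen=True)
class ElasticBody:
    """Reference sphere: radius in um, Young's modulus in Pa, Poisson ratio."""

    radius: float
    youngs_modulus: float
    poisson: float = 0.49

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.poisson < 0.5:
            raise ValueError(
                "Poisson ratio must be in [0, 0.5); for a nearly incompressible "
                "gel use nu = 0.499"
            )

    @property
    def mu(self) -> float:
        """Shear modulus, Pa."""
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson))

    @property
    def lam(self) -> float:
        """First Lame parameter, Pa."""
        e, nu = self.youngs_modulus, self.poisson
        return e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))

    def check_strain(self, max_displacement: float, tol: float = 0.1) -> bool:
        """Small-strain validity check (strain scale u/R below ``tol``)."""
        return abs(max_displacement) / self.radius <= tol


@dataclass
class VectorFieldSH:
    """Surface vector field as radial/spheroidal/toroidal SH coefficients.

    Coefficients are with respect to the orthonormal real harmonics on the
    unit sphere; physical surface integrals carry an extra ``R0^2``.
    """

    lmax: int
    radial: np.ndarray
    spheroidal: np.ndarray
    toroidal: np.ndarray

    @classmethod
    def zeros(cls, lmax: int) -> "VectorFieldSH":
        nm = n_modes(lmax)
        return cls(lmax, np.zeros(nm), np.zeros(nm), np.zeros(nm))

    @property
    def degrees(self) -> np.ndarray:
        return np.array([l for l, _ in mode_list(self.lmax)])

    def copy(self) -> "VectorFieldSH":
        return VectorFieldSH(
            self.lmax, self.radial.copy(), self.spheroidal.copy(), self.toroidal.copy()
        )

    def __add__(self, other: "VectorFieldSH") -> "VectorFieldSH":
        if other.lmax != self.lmax:
            raise ValueError("truncation degrees differ")
        return VectorFieldSH(
            self.lmax,
            self.radial + other.radial,
            self.spheroidal + other.spheroidal,
            self.toroidal + other.toroidal,
        )

    def __mul__(self, s: float) -> "VectorFieldSH":
        return VectorFieldSH(
            self.lmax, self.radial * s, self.spheroidal * s, self.toroidal * s
        )

    __rmul__ = __mul__

    def mode_power(self) -> np.ndarray:
        """Per-mode contribution to the unit-sphere integral of |field|^2."""
        L = self.degrees * (self.degrees + 1.0)
        return self.radial**2 + L * (self.spheroidal**2 + self.toroidal**2)

    def dot(self, other: "VectorFieldSH") -> float:
        """Unit-sphere integral of the pointwise dot product."""
        if other.lmax != self.lmax:
            raise ValueError("truncation degrees differ")
        L = self.degrees * (self.degrees + 1.0)
        return float(
            np.sum(
                self.radial * other.radial
                + L * (self.spheroidal * other.spheroidal + self.toroidal * other.toroidal)
            )
        )

    def l2_norm(self) -> float:
        return float(np.sqrt(np.sum(self.mode_power())))

    def synth(self, basis: RealSHBasis):
        """Spherical-component grids ``(f_r, f_theta, f_phi)`` on a basis grid."""
        if basis.lmax < self.lmax:
            raise ValueError("basis truncation too low")
        if basis.lmax == self.lmax:
            return basis.synth_vector(self.radial, self.spheroidal, self.toroidal)
        return basis.synth_vector(
            _pad(self.radial, basis.lmax),
            _pad(self.spheroidal, basis.lmax),
            _pad(self.toroidal, basis.lmax),
        )


def _pad(c: np.ndarray, lmax: int) -> np.ndarray:
    out = np.zeros(n_modes(lmax))
    out[: c.size] = c
    return out


# ---------------------------------------------------------------------------
# Per-degree displacement <-> traction blocks
# ---------------------------------------------------------------------------


def _gamma(l: np.ndarray, nu: float) -> np.ndarray:
    return -(((4.0 * l + 2.0) * (1.0 - 2.0 * nu) + 2.0 * l) / (l + 5.0 - 4.0 * nu))


def mode_matrices(lmax: int, body: ElasticBody):
    """Boundary displacement -> traction blocks for each degree.

    Returns ``(M_sph, M_tor)`` where ``M_sph[l]`` is the 2x2 map
    ``(U, V) -> (T_r, T_psi)`` and ``M_tor[l]`` the scalar ``W -> T_w`` map,
    in Pa per um.  Degree 0 uses only the (0, 0) entry.
    """
    mu, lam, R = body.mu, body.lam, body.radius
    M_sph = np.zeros((lmax + 1, 2, 2))
    M_tor = np.zeros(lmax + 1)
    M_sph[0, 0, 0] = (3.0 * lam + 2.0 * mu) / R
    for l in range(1, lmax + 1):
        g = float(_gamma(np.array(l, float), body.poisson))
        # columns: harmonic-gradient family, graded family (radius scaled out)
        S = np.array([[l, l + g], [1.0, 1.0]])
        T = np.array(
            [
                [
                    2.0 * mu * l * (l - 1.0),
                    lam * (2.0 * l + g * (l + 3.0)) + 2.0 * mu * (l + g) * (l + 1.0),
                ],
                [2.0 * mu * (l - 1.0), mu * (2.0 * l + g)],
            ]
        )
        M_sph[l] = T @ np.linalg.inv(S) / R
        M_tor[l] = mu * (l - 1.0) / R
    return M_sph, M_tor


def forward_solve(u: VectorFieldSH, body: ElasticBody) -> VectorFieldSH:
    """Boundary displacement (um) -> boundary traction (Pa) on the sphere.

    Linear and block-diagonal in degree; rigid-body modes map to zero.
    """
    M_sph, M_tor = mode_matrices(u.lmax, body)
    degs = u.degrees
    t = VectorFieldSH.zeros(u.lmax)
    t.radial = M_sph[degs, 0, 0] * u.radial + M_sph[degs, 0, 1] * u.spheroidal
    t.spheroidal = M_sph[degs, 1, 0] * u.radial + M_sph[degs, 1, 1] * u.spheroidal
    t.toroidal = M_tor[degs] * u.toroidal
    return t


def traction_to_displacement(t: VectorFieldSH, body: ElasticBody) -> VectorFieldSH:
    """Boundary traction (Pa) -> boundary displacement (um); inverse of
    :func:`forward_solve` on the equilibrium subspace.

    Degree-1 spheroidal tractions are resolved by least squares (the rigid
    component is unobservable and the net-force-carrying part has no static
    solution); degree-1 toroidal (net torque) maps to zero displacement.
    """
    mu, lam, R = body.mu, body.lam, body.radius
    u = VectorFieldSH.zeros(t.lmax)
    modes = mode_list(t.lmax)
    for i, (l, _m) in enumerate(modes):
        if l == 0:
            u.radial[i] = t.radial[i] * R / (3.0 * lam + 2.0 * mu)
            continue
        g = float(_gamma(np.array(l, float), body.poisson))
        S = np.array([[l, l + g], [1.0, 1.0]])
        T = np.array(
            [
                [
                    2.0 * mu * l * (l - 1.0),
                    lam * (2.0 * l + g * (l + 3.0)) + 2.0 * mu * (l + g) * (l + 1.0),
                ],
                [2.0 * mu * (l - 1.0), mu * (2.0 * l + g)],
            ]
        )
        rhs = np.array([t.radial[i], t.spheroidal[i]]) * R
        if l == 1:
            ab = np.linalg.lstsq(T, rhs, rcond=None)[0]
        else:
            ab = np.linalg.solve(T, rhs)
        uv = S @ ab
        u.radial[i], u.spheroidal[i] = uv
        mt = mu * (l - 1.0) / R
        u.toroidal[i] = t.toroidal[i] / mt if mt > 0 else 0.0
    return u


def min_energy_tangential(radial_coeffs: np.ndarray, lmax: int, body: ElasticBody):
    """Spheroidal coefficients minimizing stored energy at fixed radial shape.

    Per degree the elastic energy is ``(1/2) [U V] K [U V]^T`` with
    ``K = sym(diag(1, l(l+1)) M_l)``; the minimizer is
    ``V = -K_12 / K_22 * U``.  Toroidal components at fixed shape cost pure
    energy, so their minimum-energy value is zero.
    """
    M_sph, _ = mode_matrices(lmax, body)
    degs = np.array([l for l, _ in mode_list(lmax)])
    L = degs * (degs + 1.0)
    K12 = 0.5 * (M_sph[degs, 0, 1] + L * M_sph[degs, 1, 0])
    K22 = L * M_sph[degs, 1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        V = np.where(K22 > 0, -K12 / np.where(K22 > 0, K22, 1.0), 0.0) * radial_coeffs
    return V


# ---------------------------------------------------------------------------
# Traction maps on grids
# ---------------------------------------------------------------------------


@dataclass
class TractionMap:
    """Traction vectors on a (theta, phi) grid with normal/shear split.

    ``normal`` is the signed component along the outward surface normal
    (negative = pushing inward); ``shear`` is the tangential magnitude.
    """

    theta: np.ndarray
    phi: np.ndarray
    t_r: np.ndarray
    t_theta: np.ndarray
    t_phi: np.ndarray
    normal: np.ndarray
    shear: np.ndarray
    body: ElasticBody | None = None
    w_theta: np.ndarray | None = None  # colatitude quadrature weights, if any

    @property
    def area_weights(self) -> np.ndarray:
        """Unit-sphere area weights per node (requires a quadrature grid)."""
        if self.w_theta is None:
            raise ValueError("traction map was built on a display grid; "
                             "use a Gauss-Legendre map for integration")
        return np.outer(self.w_theta, np.full(self.phi.size, 2.0 * np.pi / self.phi.size))


def decompose_stress(t_r, t_theta, t_phi, normals=None):
    """Split traction into signed normal and shear magnitude.

    ``normals`` is an optional ``(n_r, n_theta, n_phi)`` triple of unit
    surface-normal components per node; default is the radial direction.
    Satisfies ``|T|^2 = normal^2 + shear^2`` pointwise.
    """
    if normals is None:
        normal = np.asarray(t_r, float)
        shear = np.hypot(t_theta, t_phi)
        return normal, shear
    n_r, n_t, n_p = normals
    normal = t_r * n_r + t_theta * n_t + t_phi * n_p
    sq = t_r**2 + t_theta**2 + t_phi**2 - normal**2
    shear = np.sqrt(np.maximum(sq, 0.0))
    return normal, shear


def traction_map_from_field(
    t: VectorFieldSH,
    body: ElasticBody,
    grid: str = "gl",
    n_theta: int = 21,
    n_phi: int = 41,
    normals=None,
) -> TractionMap:
    """Evaluate a traction coefficient field on a grid.

    ``grid='gl'`` gives a Gauss-Legendre quadrature grid (for integration);
    ``grid='equiangular'`` an inclusive equiangular display grid (the
    conventional 21 x 41 output).
    """
    if grid == "gl":
        basis = RealSHBasis.gauss_legendre(t.lmax, n_theta, n_phi)
        w = basis.w_theta
    elif grid == "equiangular":
        theta = np.linspace(0.0, np.pi, n_theta)
        phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
        basis = RealSHBasis.on_grid(t.lmax, theta, phi)
        w = None
    else:
        raise ValueError("grid must be 'gl' or 'equiangular'")
    t_r, t_t, t_p = t.synth(basis)
    normal, shear = decompose_stress(t_r, t_t, t_p, normals)
    return TractionMap(basis.theta, basis.phi, t_r, t_t, t_p, normal, shear, body, w)


@dataclass
class RegionForce:
    """Force integrals over a surface region; Pa x um^2 = pN."""

    net_pN: np.ndarray
    net_magnitude_pN: float
    total_unsigned_pN: float
    mean_stress_Pa: float
    area_um2: float

    @property
    def net_nN(self) -> np.ndarray:
        return self.net_pN / 1000.0

    @property
    def total_unsigned_nN(self) -> float:
        return self.total_unsigned_pN / 1000.0


def integrate_region_force(tmap: TractionMap, region=None) -> RegionForce:
    """Area-weighted force integrals of a traction map over a region.

    ``region`` is a boolean grid (same shape as the map), a callable
    ``f(theta_grid, phi_grid) -> bool grid``, or ``None`` for the whole
    sphere.  Requires a quadrature (Gauss-Legendre) map.
    """
    wa = tmap.area_weights
    th = tmap.theta[:, None] * np.ones_like(tmap.phi)[None, :]
    ph = np.ones_like(tmap.theta)[:, None] * tmap.phi[None, :]
    if region is None:
        sel = np.ones_like(th, dtype=bool)
    elif callable(region):
        sel = np.asarray(region(th, ph), dtype=bool)
    else:
        sel = np.asarray(region, dtype=bool)
    if not sel.any():
        raise ValueError("empty integration region")
    if tmap.body is None:
        raise ValueError("traction map has no body reference")
    R2 = tmap.body.radius**2
    w = wa * sel * R2  # um^2 per node
    st, ct = np.sin(th), np.cos(th)
    sp, cp = np.sin(ph), np.cos(ph)
    fx = tmap.t_r * st * cp + tmap.t_theta * ct * cp - tmap.t_phi * sp
    fy = tmap.t_r * st * sp + tmap.t_theta * ct * sp + tmap.t_phi * cp
    fz = tmap.t_r * ct - tmap.t_theta * st
    net = np.array([np.sum(fx * w), np.sum(fy * w), np.sum(fz * w)])
    mag = np.sqrt(tmap.t_r**2 + tmap.t_theta**2 + tmap.t_phi**2)
    total = float(np.sum(mag * w))
    area = float(np.sum(w))
    return RegionForce(net, float(np.linalg.norm(net)), total, total / area, area)


# ---------------------------------------------------------------------------
# Inverse problem
# ---------------------------------------------------------------------------


@dataclass
class CostBreakdown:
    """Terms of the inference cost (nondimensional: lengths/R0, stresses/E)."""

    E_el: float
    R2: float
    E_pen: float
    alpha: float = 1.0
    beta: float = 1.0

    @property
    def total(self) -> float:
        return self.E_el + self.alpha * self.R2 + self.beta * self.E_pen


def cost_terms(
    u: VectorFieldSH,
    t: VectorFieldSH,
    body: ElasticBody,
    mask=None,
    alpha: float = 1.0,
    beta: float = 1.0,
    pen_exponent: int = 8,
    n_theta: int = 48,
    n_phi: int = 96,
) -> CostBreakdown:
    """Evaluate the inference cost for given displacement/traction fields.

    ``u`` in um, ``t`` in Pa; both nondimensionalized internally.  ``mask``
    is the contact region (True = covered) as a boolean grid on the
    Gauss-Legendre evaluation grid or a callable of ``(theta, phi)`` grids;
    ``None`` means full contact (no residual term).
    """
    if u.lmax != t.lmax:
        raise ValueError("truncation degrees differ")
    R0, E = body.radius, body.youngs_modulus
    un = u * (1.0 / R0)
    tn = t * (1.0 / E)
    e_el = 0.5 * tn.dot(un)
    degs = un.degrees
    w_l = (degs / max(u.lmax, 1)) ** pen_exponent
    e_pen = float(np.sum(w_l * tn.mode_power()))
    if mask is None:
        r2 = 0.0
    else:
        basis = RealSHBasis.gauss_legendre(u.lmax, n_theta, n_phi)
        th = basis.theta[:, None] * np.ones_like(basis.phi)[None, :]
        ph = np.ones_like(basis.theta)[:, None] * basis.phi[None, :]
        sel = np.asarray(mask(th, ph) if callable(mask) else mask, dtype=bool)
        t_r, t_t, t_p = tn.synth(basis)
        wa = basis.area_weights
        outside = ~sel
        r2 = float(np.sum(wa[outside] * (t_r**2 + t_t**2 + t_p**2)[outside]))
    return CostBreakdown(max(e_el, 0.0), r2, e_pen, alpha, beta)


def fit_radial_coeffs(theta, phi, radii, lmax: int) -> np.ndarray:
    """Least-squares SH fit of scattered radii (quasi-uniform directions).

    Fitting (rather than interpolating onto a quadrature grid) keeps
    mesh-resolution noise out of the high degrees, where the elastic
    stiffness would amplify it.
    """
    Y, _, _ = point_basis(lmax, theta, phi)
    A = Y.T
    coeffs, *_ = np.linalg.lstsq(A, np.asarray(radii, float), rcond=None)
    return coeffs


@dataclass
class InferenceResult:
    traction: VectorFieldSH  # Pa
    displacement: VectorFieldSH  # um
    tmap: TractionMap  # 21 x 41 display grid
    cost: CostBreakdown
    body: ElasticBody


def infer_tractions(
    observed,
    body: ElasticBody,
    mask=None,
    lmax: int = 20,
    alpha: float = 1.0,
    beta: float = 1.0,
    pen_exponent: int = 8,
    n_theta: int = 48,
    n_phi: int = 96,
    out_shape: tuple[int, int] = (21, 41),
) -> InferenceResult:
    """Infer surface tractions from an observed particle shape.

    The radial displacement on the evaluation grid is fixed to
    ``r_obs(theta, phi) - R0`` (shape matched exactly); tangential
    displacement coefficients are free and found as the exact minimizer of
    the convex quadratic cost.  ``observed`` is a
    :class:`mptfm.mesh.SurfaceMesh` (or any object with a
    ``radial_on_grid(theta, phi)`` method returning radii in um about its
    center).  ``mask``: per-vertex boolean (contact=True) aligned with the
    mesh, a callable of grid angles, or None for full contact.
    """
    R0, E = body.radius, body.youngs_modulus
    basis = RealSHBasis.gauss_legendre(lmax, n_theta, n_phi)
    th = basis.theta[:, None] * np.ones_like(basis.phi)[None, :]
    ph = np.ones_like(basis.theta)[:, None] * basis.phi[None, :]

    if hasattr(observed, "angles") and hasattr(observed, "radii"):
        th_v, ph_v = observed.angles
        r_v = observed.radii
        if not body.check_strain(float(np.max(np.abs(r_v - R0)))):
            raise ValueError("observed deformation outside the small-strain regime")
        coeffs = fit_radial_coeffs(th_v, ph_v, r_v, lmax)
        coeffs[0] -= R0 * np.sqrt(4.0 * np.pi)  # subtract the reference sphere
        U = coeffs / R0
    else:
        r_obs = observed.radial_on_grid(basis.theta, basis.phi)
        if not body.check_strain(float(np.max(np.abs(r_obs - R0)))):
            raise ValueError("observed deformation outside the small-strain regime")
        U = basis.analyze((r_obs - R0) / R0)
    # The mean (degree-0) radial component is excluded from the shape
    # constraint: for a nearly incompressible gel the uniform-compression
    # channel is unidentifiable from shape (its compliance vanishes as
    # nu -> 1/2, so tiny shape errors map to huge isotropic pressure).
    U[0] = 0.0

    # contact mask on the evaluation grid
    if mask is None:
        sel = np.ones_like(th, dtype=bool)
    elif callable(mask):
        sel = np.asarray(mask(th, ph), dtype=bool)
    else:
        sel = observed.mask_on_grid(np.asarray(mask, bool), basis.theta, basis.phi)

    M_sph, M_tor = mode_matrices(lmax, body)
    scale = R0 / E  # nondimensional displacement -> nondimensional traction
    Ms = M_sph * scale
    Mt = M_tor * scale
    degs = basis.degrees
    L = degs * (degs + 1.0)
    w_l = (degs / lmax) ** pen_exponent

    modes_V = np.where(degs >= 1)[0]
    modes_W = np.where(degs >= 2)[0]
    nV, nW = modes_V.size, modes_W.size
    nfree = nV + nW

    a = Ms[degs, 0, 0] * U  # fixed part of T_r coefficients
    c = Ms[degs, 1, 0] * U  # fixed part of T_psi coefficients
    b = Ms[degs, 0, 1]  # dT_r/dV
    d = Ms[degs, 1, 1]  # dT_psi/dV
    e = Mt[degs]  # dT_w/dW

    H = np.zeros((nfree, nfree))
    g = np.zeros(nfree)

    # elastic energy: (1/2) sum [T_r U + L T_psi V] with T affine in V
    iV = np.arange(nV)
    iW = nV + np.arange(nW)
    H[iV, iV] += (L * d)[modes_V]
    g[iV] += 0.5 * ((b + L * Ms[degs, 1, 0]) * U)[modes_V]
    H[iW, iW] += (L * e)[modes_W]

    # anti-aliasing penalty on traction power
    H[iV, iV] += 2.0 * (w_l * (b**2 + L * d**2))[modes_V]
    g[iV] += 2.0 * (w_l * (a * b + L * c * d))[modes_V]
    H[iW, iW] += 2.0 * (w_l * L * e**2)[modes_W]

    # residual traction outside the contact area
    outside = ~sel
    if outside.any():
        N = th.size
        idx = np.where(outside.ravel())[0]
        wa = basis.area_weights.ravel()[idx]
        Yf = basis.Y.reshape(-1, N)[:, idx]
        Dtf = basis.dYdt.reshape(-1, N)[:, idx]
        Dpf = basis.dYdp_sin.reshape(-1, N)[:, idx]
        no = idx.size
        G = np.zeros((3 * no, nfree))
        G[:no, iV] = (b[modes_V, None] * Yf[modes_V]).T
        G[no : 2 * no, iV] = (d[modes_V, None] * Dtf[modes_V]).T
        G[2 * no :, iV] = (d[modes_V, None] * Dpf[modes_V]).T
        G[no : 2 * no, iW] = (-e[modes_W, None] * Dpf[modes_W]).T
        G[2 * no :, iW] = (e[modes_W, None] * Dtf[modes_W]).T
        t0 = np.concatenate([a @ Yf, c @ Dtf, c @ Dpf])
        wrep = np.tile(wa, 3)
        Gw = G * wrep[:, None]
        H += 2.0 * alpha * (G.T @ Gw)
        g += 2.0 * alpha * (Gw.T @ t0)

    # tiny ridge keeps the degree-1 rigid directions harmless
    H[np.diag_indices_from(H)] += 1e-12 * max(float(np.max(np.abs(H))), 1.0)
    x = scipy.linalg.solve(H, -g, assume_a="pos")

    u = VectorFieldSH.zeros(lmax)
    u.radial = U * R0
    V = np.zeros_like(U)
    W = np.zeros_like(U)
    V[modes_V] = x[:nV]
    W[modes_W] = x[nV:]
    u.spheroidal = V * R0
    u.toroidal = W * R0

    t = forward_solve(u, body)
    cost = cost_terms(
        u, t, body, mask=sel, alpha=alpha, beta=beta,
        pen_exponent=pen_exponent, n_theta=n_theta, n_phi=n_phi,
    )

    # display map with normals from the deformed surface
    out_basis_theta = np.linspace(0.0, np.pi, out_shape[0])
    out_basis_phi = np.linspace(0.0, 2.0 * np.pi, out_shape[1], endpoint=False)
    out_basis = RealSHBasis.on_grid(lmax, out_basis_theta, out_basis_phi)
    t_r, t_t, t_p = t.synth(out_basis)
    r_coeff = U * R0  # radial deviation coefficients (um)
    r_grid = R0 + out_basis.synth(r_coeff)
    drdt = np.tensordot(r_coeff, out_basis.dYdt, axes=(0, 0))
    drdp = np.tensordot(r_coeff, out_basis.dYdp_sin, axes=(0, 0))
    n_r = np.ones_like(r_grid)
    n_t = -drdt / r_grid
    n_p = -drdp / r_grid
    norm = np.sqrt(n_r**2 + n_t**2 + n_p**2)
    normal, shear = decompose_stress(t_r, t_t, t_p, (n_r / norm, n_t / norm, n_p / norm))
    tmap = TractionMap(
        out_basis_theta, out_basis_phi, t_r, t_t, t_p, normal, shear, body, None
    )
    return InferenceResult(t, u, tmap, cost, body)


def evaluate_field_at_points(t: VectorFieldSH, theta, phi):
    """Spherical components of a coefficient field at scattered points."""
    Y, Dt, Dp = point_basis(t.lmax, theta, phi)
    f_r = t.radial @ Y
    f_t = t.spheroidal @ Dt - t.toroidal @ Dp
    f_p = t.spheroidal @ Dp + t.toroidal @ Dt
    return f_r, f_t, f_p
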