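"""Multi-tooth Hertz indentation of a soft spherical target.

Actin teeth are modeled as rigid spherical indenters (radius ``R_teeth``)
pressed to absolute depth ``d`` into a nearly incompressible elastic sphere
(radius ``R_target``, Young's modulus ``E_target``, ``nu = 0.5`` handled as
the 0.499 limit).  Per tooth the Hertz contact solution gives

    F  = (4/3) E* sqrt(R_eff) d^(3/2)
    a  = sqrt(R_eff d),        p(r) = p0 sqrt(1 - (r/a)^2),  p0 = 3F / (2 pi a^2)

with ``1/E* = 3/(4 E_target)`` for a rigid tooth on an incompressible
target and ``1/R_eff = 1/R_teeth + 1/R_target``.  The teeth (default 10)
are spaced equally around the equator; the resulting purely normal traction
map is the boundary condition of the solid-sphere elasticity problem, whose
displacement map yields the effective tooth depth and the average
equatorial constriction.  Units: Pa and um, so Pa x um^2 = pN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mptfm._sphharm import RealSHBasis
from mptfm.elasticity import (
    ElasticBody,
    VectorFieldSH,
    evaluate_field_at_points,
    traction_to_displacement,
)
from mptfm.geometry import great_circle_distance


@dataclass(frozen=True)
class IndenterConfig:
    """Geometry and elasticity of the multi-tooth indentation scene."""

    depth_um: float
    r_target_um: float = 3.7
    r_teeth_um: float = 0.5
    n_teeth: int = 10
    e_target_pa: float = 1400.0
    nu_target: float = 0.5  # incompressible; solved at the 0.499 limit

    def __post_init__(self):
        if self.depth_um < 0:
            raise ValueError("indentation depth must be >= 0")
        if self.r_teeth_um <= 0 or self.r_target_um <= 0:
            raise ValueError("radii must be positive")


@dataclass(frozen=True)
class HertzContact:
    """Single-indenter Hertz solution."""

    e_star_pa: float
    r_eff_um: float
    force_pn: float
    contact_radius_um: float
    peak_pressure_pa: float


def hertz_contact(config: IndenterConfig) -> HertzContact:
    """Evaluate the Hertz formulas; identities hold to machine precision."""
    e_star = 4.0 * config.e_target_pa / 3.0  # rigid tooth, nu_target = 1/2
    r_eff = 1.0 / (1.0 / config.r_teeth_um + 1.0 / config.r_target_um)
    d = config.depth_um
    force = (4.0 / 3.0) * e_star * np.sqrt(r_eff) * d**1.5
    a = np.sqrt(r_eff * d)
    p0 = 3.0 * force / (2.0 * np.pi * a**2) if a > 0 else 0.0
    contact = HertzContact(e_star, r_eff, float(force), float(a), float(p0))
    _check_overlap(config, contact)
    return contact


def _check_overlap(config: IndenterConfig, contact: HertzContact) -> None:
    if config.n_teeth < 1:
        return
    ring = 2.0 * np.pi * config.r_target_um
    if config.n_teeth * 2.0 * contact.contact_radius_um >= ring:
        raise ValueError("contact zones overlap on the equator")


def tooth_centers(config: IndenterConfig):
    """Equatorial tooth centers ``(theta, phi)``."""
    phis = 2.0 * np.pi * np.arange(config.n_teeth) / max(config.n_teeth, 1)
    return np.full(config.n_teeth, np.pi / 2.0), phis[: config.n_teeth]


def pressure_field(config: IndenterConfig, contact: HertzContact):
    """Inward normal pressure (Pa) as a function of ``(theta, phi)``.

    ``r`` is the great-circle distance on the target sphere from the nearest
    tooth's initial contact point.
    """
    th_c, ph_c = tooth_centers(config)
    a = contact.contact_radius_um
    p0 = contact.peak_pressure_pa

    def p(theta, phi):
        theta = np.asarray(theta, float)
        phi = np.asarray(phi, float)
        out = np.zeros(np.broadcast(theta, phi).shape)
        if a <= 0:
            return out
        for tc, pc in zip(th_c, ph_c):
            r = great_circle_distance((theta, phi), (tc, pc), config.r_target_um)
            inside = r < a
            out = out + np.where(
                inside, p0 * np.sqrt(np.maximum(1.0 - (r / a) ** 2, 0.0)), 0.0
            )
        return out

    return p


def zone_force_pn(config: IndenterConfig, contact: HertzContact, n_quad: int = 400) -> float:
    """Quadrature of one contact zone's pressure over the sphere surface.

    1-D Gauss-Legendre in the arc coordinate; equals the Hertz force up to
    the (tiny) sphere-curvature correction.
    """
    a = contact.contact_radius_um
    if a <= 0:
        return 0.0
    x, w = np.polynomial.legendre.leggauss(n_quad)
    r = 0.5 * a * (x + 1.0)
    wr = 0.5 * a * w
    R = config.r_target_um
    p = contact.peak_pressure_pa * np.sqrt(np.maximum(1.0 - (r / a) ** 2, 0.0))
    return float(np.sum(p * 2.0 * np.pi * R * np.sin(r / R) * wr))


def indenter_traction_map(
    config: IndenterConfig,
    contact: HertzContact | None = None,
    n_theta: int = 61,
    n_phi: int = 121,
):
    """Evaluate the multi-tooth pressure map on the Gauss-Legendre grid.

    Returns ``(theta, phi, T_r)`` with ``T_r`` the signed radial traction
    (negative: pushing inward).  The default 61 x 121 grid is the map size
    used for reporting; the elastic solve analyzes the pressure on a finer
    internal grid (see :func:`simulate_constriction`).
    """
    contact = contact or hertz_contact(config)
    basis = RealSHBasis.gauss_legendre(0, n_theta, n_phi)
    p = pressure_field(config, contact)
    th = basis.theta[:, None] * np.ones_like(basis.phi)[None, :]
    ph = np.ones_like(basis.theta)[:, None] * basis.phi[None, :]
    return basis.theta, basis.phi, -p(th, ph)


@dataclass
class ConstrictionSim:
    """Whole-sphere elastic response to the multi-tooth pressure map."""

    config: IndenterConfig
    contact: HertzContact
    theta: np.ndarray
    phi: np.ndarray
    traction_r: np.ndarray  # 61 x 121 report grid, Pa
    displacement_r: np.ndarray  # um, same grid
    effective_depth_um: float  # inward displacement at a tooth center
    constriction_um: float  # mean inward radial displacement on the equator
    constriction_outside_contact_um: float  # equator average excluding contacts


def _simulation_bases(lmax: int, n_theta: int, n_phi: int, analysis_factor: int):
    """Scalar analysis/reporting bases, reusable across sweep points."""
    fine = RealSHBasis.gauss_legendre(
        lmax, analysis_factor * (lmax + 1), 2 * analysis_factor * lmax + 1,
        scalar_only=True,
    )
    report = RealSHBasis.gauss_legendre(lmax, n_theta, n_phi, scalar_only=True)
    return fine, report


def simulate_constriction(
    config: IndenterConfig,
    lmax: int = 40,
    n_theta: int = 61,
    n_phi: int = 121,
    analysis_factor: int = 3,
    bases=None,
) -> ConstrictionSim:
    """Solve the solid-sphere elasticity problem for the tooth pressure map.

    The pressure field is expanded in spherical harmonics (analysis on a
    finer internal Gauss-Legendre grid so truncation, not aliasing, limits
    accuracy), converted per degree to boundary displacement, and evaluated
    on the reporting grid.  ``nu = 0.5`` is handled as 0.499.  The pressure
    is purely radial, so all syntheses are scalar.
    """
    contact = hertz_contact(config)
    nu = min(config.nu_target, 0.499)
    body = ElasticBody(config.r_target_um, config.e_target_pa, nu)

    fine, report = bases or _simulation_bases(lmax, n_theta, n_phi, analysis_factor)
    p = pressure_field(config, contact)
    th = fine.theta[:, None] * np.ones_like(fine.phi)[None, :]
    ph = np.ones_like(fine.theta)[:, None] * fine.phi[None, :]
    t = VectorFieldSH.zeros(lmax)
    t.radial = fine.analyze(-p(th, ph))
    u = traction_to_displacement(t, body)

    t_r = report.synth(t.radial)
    u_r = report.synth(u.radial)

    th_c, ph_c = tooth_centers(config)
    if config.n_teeth > 0:
        u_tooth, _, _ = evaluate_field_at_points(u, th_c[:1], ph_c[:1])
        eff_depth = float(-u_tooth[0])
    else:
        eff_depth = 0.0

    phi_eq = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    th_eq = np.full_like(phi_eq, np.pi / 2.0)
    u_eq, _, _ = evaluate_field_at_points(u, th_eq, phi_eq)
    constriction = float(np.mean(-u_eq))
    a = contact.contact_radius_um
    in_contact = np.zeros_like(phi_eq, dtype=bool)
    for tc, pc in zip(th_c, ph_c):
        r = great_circle_distance((th_eq, phi_eq), (tc, pc), config.r_target_um)
        in_contact |= r < a
    if (~in_contact).any():
        constriction_out = float(np.mean(-u_eq[~in_contact]))
    else:
        constriction_out = np.nan

    return ConstrictionSim(
        config, contact, report.theta, report.phi, t_r, u_r,
        eff_depth, constriction, constriction_out,
    )


def sweep(
    depths_um,
    teeth_radii_um,
    base: IndenterConfig | None = None,
    lmax: int = 40,
) -> pd.DataFrame:
    """Parameter sweep over tooth depth and radius; tidy one-row-per-point."""
    base = base or IndenterConfig(depth_um=0.2)
    bases = _simulation_bases(lmax, 61, 121, 3)
    rows = []
    for rt in teeth_radii_um:
        for d in depths_um:
            cfg = IndenterConfig(
                depth_um=float(d),
                r_target_um=base.r_target_um,
                r_teeth_um=float(rt),
                n_teeth=base.n_teeth,
                e_target_pa=base.e_target_pa,
                nu_target=base.nu_target,
            )
            sim = simulate_constriction(cfg, lmax=lmax, bases=bases)
            rows.append(
                {
                    "r_teeth_um": float(rt),
                    "depth_um": float(d),
                    "force_pn": sim.contact.force_pn,
                    "contact_radius_um": sim.contact.contact_radius_um,
                    "peak_pressure_pa": sim.contact.peak_pressure_pa,
                    "effective_depth_um": sim.effective_depth_um,
                    "constriction_um": sim.constriction_um,
                    "constriction_outside_contact_um": sim.constriction_outside_contact_um,
                }
            )
    return pd.DataFrame(rows)
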