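"""Synthetic phagocytic-target scenes with known ground truth.

Generates deformed-sphere meshes, surface signal layouts (equatorial/rim
actin band, tooth spots, exposed-surface stain), band-limited equilibrium
traction fields, and rendered confocal-like image stacks, so every analysis
stage can be tested against planted truth without raw microscopy data.

Scene scales follow the study system: spheres of radius ~3.7-5.5 um and
Young's modulus 1.4-6.5 kPa, surface deformations of 50-400 nm, a ~2 um
wide actin band at the cup rim, and ~10 teeth of ~1 um diameter indenting
~200 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from mptfm import elasticity
from mptfm._sphharm import n_modes, point_eval_scalar
from mptfm.elasticity import ElasticBody, VectorFieldSH, evaluate_field_at_points
from mptfm.geometry import (
    cap_colatitude,
    fibonacci_directions,
    great_circle_distance,
)
from mptfm.mesh import SurfaceMesh
from mptfm.stack import ImageStack


@dataclass(frozen=True)
class Dimple:
    """Compact inward bump: cosine taper, depth attained exactly at center."""

    theta: float  # colatitude of center, rad
    phi: float  # azimuth of center, rad
    footprint_um: float  # geodesic footprint radius, um
    depth_um: float

    def profile(self, theta, phi, radius_um):
        s = great_circle_distance((theta, phi), (self.theta, self.phi), radius_um)
        inside = s < self.footprint_um
        return np.where(
            inside,
            self.depth_um * np.cos(0.5 * np.pi * s / self.footprint_um),
            0.0,
        )


@dataclass(frozen=True)
class RingGroove:
    """Axisymmetric inward groove around a colatitude circle."""

    theta: float  # colatitude of groove center, rad
    half_width_um: float  # arc half-width, um
    depth_um: float

    def profile(self, theta, radius_um):
        s = np.abs(theta - self.theta) * radius_um
        inside = s < self.half_width_um
        return np.where(
            inside,
            self.depth_um * np.cos(0.5 * np.pi * s / self.half_width_um),
            0.0,
        )


@dataclass(frozen=True)
class ShPerturbation:
    """Band-limited random radial perturbation, seeded."""

    lmax: int = 6
    amplitude_um: float = 0.05  # RMS over the sphere
    seed: int = 0


@dataclass(frozen=True)
class Imaging:
    """Confocal-like acquisition parameters.

    Defaults emulate spinning-disk anisotropy: voxel 0.2 x 0.2 x 0.4 um
    (x, y, z), PSF sigma 0.15 / 0.15 / 0.4 um.  ``photon_scale`` converts
    intensity to expected photon counts for Poisson noise; 0 disables noise.
    """

    voxel_um: tuple[float, float, float] = (0.2, 0.2, 0.4)  # (x, y, z)
    psf_sigma_um: tuple[float, float, float] = (0.15, 0.15, 0.4)  # (x, y, z)
    background: float = 0.0
    background_sigma: float = 0.0
    photon_scale: float = 0.0
    noise_seed: int = 0


@dataclass(frozen=True)
class SurfaceSignal:
    """Actin-like surface pattern: rim band plus tooth spots."""

    band_center_x: float = 1.0  # normalized axial position (0 base, 1 rim)
    band_width_um: float = 2.0
    band_amplitude: float = 100.0
    spot_amplitude: float = 200.0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic target scene."""

    radius_um: float = 3.7
    dimples: tuple[Dimple, ...] = ()
    rings: tuple[RingGroove, ...] = ()
    sh_perturbation: ShPerturbation | None = None
    surface_signal: SurfaceSignal = field(default_factory=SurfaceSignal)
    imaging: Imaging = field(default_factory=Imaging)
    n_directions: int = 3000
    tooth_footprint_um: float = 0.5
    tooth_depth_um: float = 0.2
    exposed_amplitude: float = 100.0

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        for d in self.dimples:
            if d.depth_um < 0:
                raise ValueError("dimple depths must be >= 0")
            if d.depth_um > self.radius_um:
                raise ValueError("dimple depth exceeds the sphere radius")
        for r in self.rings:
            if r.depth_um < 0 or r.depth_um > self.radius_um:
                raise ValueError("ring depth out of range")


def _perturbation_coeffs(p: ShPerturbation) -> np.ndarray:
    rng = np.random.default_rng(p.seed)
    c = rng.standard_normal(n_modes(p.lmax))
    degs = np.array([l for l in range(p.lmax + 1) for _ in range(2 * l + 1)])
    c[degs < 2] = 0.0
    rms = math.sqrt(float(np.sum(c**2)) / (4.0 * math.pi))
    if rms > 0:
        c *= p.amplitude_um / rms
    return c


def radial_field(spec: SceneSpec):
    """The scene's analytic radius function ``r(theta, phi)`` in um."""
    coeffs = (
        _perturbation_coeffs(spec.sh_perturbation)
        if spec.sh_perturbation is not None
        else None
    )

    def r(theta, phi):
        theta = np.asarray(theta, float)
        phi = np.asarray(phi, float)
        out = np.full(np.broadcast(theta, phi).shape, spec.radius_um, dtype=float)
        for d in spec.dimples:
            out = out - d.profile(theta, phi, spec.radius_um)
        for g in spec.rings:
            out = out - g.profile(theta, spec.radius_um)
        if coeffs is not None:
            out = out + point_eval_scalar(
                coeffs, spec.sh_perturbation.lmax, theta, phi
            )
        return out

    return r


def make_deformed_sphere(spec: SceneSpec) -> SurfaceMesh:
    """Closed outward-oriented mesh with radii from the scene radial field."""
    dirs = fibonacci_directions(spec.n_directions)
    z = np.clip(dirs[:, 2], -1.0, 1.0)
    theta = np.arccos(z)
    phi = np.mod(np.arctan2(dirs[:, 1], dirs[:, 0]), 2.0 * np.pi)
    fn = radial_field(spec)
    radii = fn(theta, phi)
    if np.any(radii <= 0):
        raise ValueError("deformations exceed the sphere radius")
    return SurfaceMesh.from_directions(dirs, radii, radial_function=fn)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_stack(
    mesh: SurfaceMesh,
    spec: SceneSpec,
    mode: str = "volume",
    surface_amplitude=None,
    channel: str = "",
) -> ImageStack:
    """Render a mesh into a confocal-like image stack.

    ``mode='volume'``: uniform interior intensity 1 (volumetric label).
    ``mode='surface'``: a thin Gaussian shell (sigma 0.1 um, i.e. ~0.2 um
    thickness) weighted by ``surface_amplitude`` -- a callable of
    ``(theta, phi)`` or a per-vertex array (nearest-direction transfer).
    Both are blurred with the anisotropic Gaussian PSF; Poisson noise at
    ``photon_scale`` plus Gaussian background is applied when configured.
    The particle center sits at the exact stack center.
    """
    if mode not in ("volume", "surface"):
        raise ValueError("mode must be 'volume' or 'surface'")
    im = spec.imaging
    if any(v <= 0 for v in im.voxel_um):
        raise ValueError("voxel spacing must be positive")
    vx, vy, vz = im.voxel_um
    px, py, pz = im.psf_sigma_um
    rmax = float(np.max(mesh.radii - 0.0))
    pad = 3.0 * max(px, py, pz) + 0.8
    half = rmax + pad

    # supersample each axis to ~0.1 um so that block-averaging back to the
    # acquisition grid gives true partial-volume voxel values (point-sampling
    # a sharp edge would quantize it to half-voxel positions)
    fz, fy, fx = (max(1, int(round(v / 0.1))) for v in (vz, vy, vx))

    def axis(spacing, factor):
        n = 2 * int(np.ceil(half / spacing)) + 1
        coarse = (np.arange(n) - (n - 1) / 2.0) * spacing
        sub = (np.arange(factor) - (factor - 1) / 2.0) * (spacing / factor)
        return coarse, (coarse[:, None] + sub[None, :]).ravel()

    zs, zf = axis(vz, fz)
    ys, yf = axis(vy, fy)
    xs, xf = axis(vx, fx)
    Z, Y, X = np.meshgrid(zf, yf, xf, indexing="ij")
    dx, dy, dz = X, Y, Z  # particle frame centered at stack center
    r_vox = np.sqrt(dx**2 + dy**2 + dz**2)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.divide(dz, np.where(r_vox > 0, r_vox, 1.0)), -1, 1))
    phi = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)

    if mesh.radial_function is not None:
        r_surf = mesh.radial_function(theta, phi)
    else:
        pts = np.stack([dx, dy, dz], axis=-1).reshape(-1, 3)
        nrm = np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), 1e-9)
        r_surf = mesh._interp_radii(pts / nrm).reshape(r_vox.shape)

    if mode == "volume":
        # slight analytic softening below the supersampling scale
        sigma_e = 0.25 * min(vx / fx, vy / fy, vz / fz)
        from scipy.special import erfc

        img = 0.5 * erfc((r_vox - r_surf) / (np.sqrt(2.0) * sigma_e))
    else:
        if surface_amplitude is None:
            amp = np.ones_like(r_vox)
        elif callable(surface_amplitude):
            amp = np.asarray(surface_amplitude(theta, phi), dtype=float)
        else:
            vals = np.asarray(surface_amplitude, dtype=float)
            pts = np.stack([dx, dy, dz], axis=-1).reshape(-1, 3)
            nrm = np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), 1e-9)
            from scipy.spatial import cKDTree

            tree = cKDTree(mesh.directions)
            _, idx = tree.query(pts / nrm)
            amp = vals[idx].reshape(r_vox.shape)
        sigma_shell = 0.1  # um; 0.2 um shell thickness, sub-PSF
        img = amp * np.exp(-0.5 * ((r_vox - r_surf) / sigma_shell) ** 2)

    img = gaussian_filter(img, sigma=(pz / (vz / fz), py / (vy / fy), px / (vx / fx)))
    # block-average the supersampled grid down to acquisition voxels
    img = img.reshape(len(zs), fz, len(ys), fy, len(xs), fx).mean(axis=(1, 3, 5))

    if im.photon_scale > 0 or im.background_sigma > 0 or im.background != 0:
        rng = np.random.default_rng(im.noise_seed)
        if im.photon_scale > 0:
            img = rng.poisson(np.maximum(img, 0.0) * im.photon_scale) / im.photon_scale
        img = img + im.background
        if im.background_sigma > 0:
            img = img + rng.normal(0.0, im.background_sigma, size=img.shape)

    origin = np.array(
        [
            mesh.center[2] - (len(zs) - 1) / 2.0 * vz,
            mesh.center[1] - (len(ys) - 1) / 2.0 * vy,
            mesh.center[0] - (len(xs) - 1) / 2.0 * vx,
        ]
    )
    return ImageStack(img, (vz, vy, vx), channel=channel, origin=origin)


# ---------------------------------------------------------------------------
# Traction fixtures
# ---------------------------------------------------------------------------


def make_synthetic_traction(
    l_max_gen: int,
    amplitude: float,
    seed: int,
    body: ElasticBody | None = None,
) -> VectorFieldSH:
    """Random band-limited equilibrium traction field (Pa).

    Degrees 0 and 1 are excluded, so the field carries no net force and no
    net torque.  The field is built from a random radial boundary
    displacement with its minimum-energy tangential completion, which places
    it in the class identifiable from shape alone; ``amplitude`` sets the
    peak traction magnitude.
    """
    if l_max_gen < 2:
        raise ValueError("l_max_gen must be >= 2")
    body = body or ElasticBody(3.7, 1400.0, 0.49)
    rng = np.random.default_rng(seed)
    u = VectorFieldSH.zeros(l_max_gen)
    degs = u.degrees
    U = rng.standard_normal(n_modes(l_max_gen))
    U[degs < 2] = 0.0
    # whiten across degrees so each degree carries comparable power
    for l in range(2, l_max_gen + 1):
        m = degs == l
        U[m] /= np.sqrt(2 * l + 1.0)
    u.radial = U
    u.spheroidal = elasticity.min_energy_tangential(U, l_max_gen, body)
    t = elasticity.forward_solve(u, body)
    if amplitude == 0:
        return VectorFieldSH.zeros(l_max_gen)
    from mptfm._sphharm import RealSHBasis

    basis = RealSHBasis.gauss_legendre(l_max_gen, 2 * l_max_gen + 8, 4 * l_max_gen + 9)
    t_r, t_t, t_p = t.synth(basis)
    peak = float(np.max(np.sqrt(t_r**2 + t_t**2 + t_p**2)))
    return t * (amplitude / peak)


def forward_displace_mesh(
    traction: VectorFieldSH,
    body: ElasticBody,
    n_directions: int = 3000,
    noise_rms_um: float = 0.0,
    seed: int = 0,
) -> SurfaceMesh:
    """Reference sphere displaced by the elastic response to a traction.

    Optional radial measurement noise (white, ``noise_rms_um`` RMS) emulates
    reconstruction error.
    """
    u = elasticity.traction_to_displacement(traction, body)
    dirs = fibonacci_directions(n_directions)
    z = np.clip(dirs[:, 2], -1.0, 1.0)
    theta = np.arccos(z)
    phi = np.mod(np.arctan2(dirs[:, 1], dirs[:, 0]), 2.0 * np.pi)
    u_r, u_t, u_p = evaluate_field_at_points(u, theta, phi)
    # spherical unit vectors at each direction
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    e_r = dirs
    e_t = np.stack([ct * cp, ct * sp, -st], axis=1)
    e_p = np.stack([-sp, cp, np.zeros_like(sp)], axis=1)
    pos = body.radius * e_r + u_r[:, None] * e_r + u_t[:, None] * e_t + u_p[:, None] * e_p
    if noise_rms_um > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.normal(0.0, noise_rms_um, size=len(pos))[:, None] * e_r
    radii = np.linalg.norm(pos, axis=1)
    ndirs = pos / radii[:, None]
    return SurfaceMesh.from_directions(ndirs, radii)


# ---------------------------------------------------------------------------
# Cup fixtures
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    """Ground truth plus (optionally) rendered channels, one shared frame."""

    mesh: SurfaceMesh
    truth_mask: np.ndarray  # per-vertex, True = covered by the cell
    vertex_actin: np.ndarray
    vertex_exposed: np.ndarray
    truth_teeth: pd.DataFrame
    axis: np.ndarray  # phagocytic axis (base -> centroid), unit
    theta_rim: float  # colatitude of the mask boundary
    fraction: float
    stacks: dict = field(default_factory=dict)
    traction: VectorFieldSH | None = None
    actin_signal: object = None  # callable (theta, phi) -> a.u.
    exposed_signal: object = None


def cup_signals(spec: SceneSpec, fraction: float, teeth: pd.DataFrame):
    """Analytic actin / exposed-surface signal functions for a cup scene."""
    R = spec.radius_um
    alpha_rim = cap_colatitude(fraction)  # angle from the base pole (-z)
    theta_rim = np.pi - alpha_rim
    sig = spec.surface_signal
    theta_band = np.pi - sig.band_center_x * alpha_rim
    sigma_band = sig.band_width_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def actin(theta, phi):
        theta = np.asarray(theta, float)
        phi = np.asarray(phi, float)
        out = sig.band_amplitude * np.exp(
            -0.5 * ((theta - theta_band) * R / sigma_band) ** 2
        )
        for _, row in teeth.iterrows():
            s = great_circle_distance((theta, phi), (row.theta, row.phi), R)
            inside = s < row.footprint_um
            out = out + np.where(
                inside,
                sig.spot_amplitude * np.cos(0.5 * np.pi * s / row.footprint_um),
                0.0,
            )
        return out

    def exposed(theta, phi):
        theta = np.asarray(theta, float)
        return np.where(theta < theta_rim, spec.exposed_amplitude, 0.0) * np.ones_like(
            np.asarray(phi, float)
        )

    return actin, exposed, theta_rim


def make_cup_fixture(
    fraction: float,
    n_teeth: int,
    spec: SceneSpec | None = None,
    render: bool = False,
) -> FixtureBundle:
    """Phagocytic-cup scene: polar-cap contact mask (base at -z), actin band
    on the mask boundary, tooth dimples on the boundary circle, exposed
    stain outside the mask.  Truth tables are recorded.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    spec = spec or SceneSpec()
    R = spec.radius_um
    alpha_rim = cap_colatitude(fraction)
    theta_rim = np.pi - alpha_rim
    ring_circumference = 2.0 * np.pi * R * np.sin(theta_rim)
    if n_teeth > 0 and n_teeth * 2.0 * spec.tooth_footprint_um >= ring_circumference:
        raise ValueError("teeth do not fit on the rim circle at this footprint")

    phis = 2.0 * np.pi * np.arange(n_teeth) / max(n_teeth, 1)
    teeth = pd.DataFrame(
        {
            "id": np.arange(n_teeth),
            "theta": np.full(n_teeth, theta_rim),
            "phi": phis[:n_teeth],
            "depth_um": np.full(n_teeth, spec.tooth_depth_um),
            "footprint_um": np.full(n_teeth, spec.tooth_footprint_um),
            "diameter_um": np.full(n_teeth, 2.0 * spec.tooth_footprint_um),
        }
    )
    dimples = tuple(
        Dimple(row.theta, row.phi, row.footprint_um, row.depth_um)
        for _, row in teeth.iterrows()
    )
    scene = replace(spec, dimples=spec.dimples + dimples)
    mesh = make_deformed_sphere(scene)

    actin_fn, exposed_fn, _ = cup_signals(spec, fraction, teeth)
    th, ph = mesh.angles
    vertex_actin = actin_fn(th, ph)
    vertex_exposed = exposed_fn(th, ph)
    truth_mask = th >= theta_rim

    stacks = {}
    if render:
        stacks["particle"] = render_stack(mesh, scene, "volume", channel="particle")
        stacks["actin"] = render_stack(
            mesh, scene, "surface", surface_amplitude=actin_fn, channel="actin"
        )
        stacks["exposed"] = render_stack(
            mesh, scene, "surface", surface_amplitude=exposed_fn, channel="exposed"
        )

    bundle = FixtureBundle(
        mesh=mesh,
        truth_mask=truth_mask,
        vertex_actin=vertex_actin,
        vertex_exposed=vertex_exposed,
        truth_teeth=teeth,
        axis=np.array([0.0, 0.0, 1.0]),
        theta_rim=float(theta_rim),
        fraction=float(fraction),
        stacks=stacks,
    )
    bundle.actin_signal = actin_fn
    bundle.exposed_signal = exposed_fn
    return bundle
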