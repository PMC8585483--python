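"""Surface fluorescence mapping and phagocytic-cup quantification.

Maps stain channels onto the reconstructed particle surface, determines the
cell-target contact mask (engulfment state), aligns each cup to the
phagocytic axis -- the line from the contact-area centroid through the
particle centroid -- and computes progression metrics: fraction engulfed,
30-bin axial profiles, constriction, elongation, and F-actin band
descriptors.

Alignment convention: after :func:`align_to_axis` the phagocytic axis is
+z, the cup base sits at colatitude ``theta = pi`` and the normalized axial
coordinate ``x = (pi - theta) / alpha_rim`` runs from 0 at the base to 1 at
the mask boundary (values up to 1.05 ahead of the rim are retained, then
clipped for binning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import connected_components
from skimage.filters import threshold_otsu

from mptfm.geometry import (
    mollweide_inverse,
    rotation_to_z,
    spherical_to_cartesian,
)
from mptfm.mesh import SurfaceMesh
from mptfm.stack import ImageStack

X_MAX = 1.05  # slight overshoot ahead of the rim is kept, then clipped


def project_surface_intensity(
    stack: ImageStack, mesh: SurfaceMesh, window_um: float = 1.0
) -> np.ndarray:
    """Maximum intensity within ``+- window_um`` of each vertex radius.

    Intensities are linearly interpolated along the radial line through each
    vertex; the maximum over the radial window is projected onto the vertex.
    Windows partially outside the stack are clamped.
    """
    step = 0.5 * min(stack.spacing)
    offsets = np.arange(-window_um, window_um + step / 2, step)
    dirs = mesh.directions
    radii = mesh.radii[:, None] + offsets[None, :]
    radii = np.maximum(radii, 0.0)
    pts = mesh.center[None, None, :] + radii[:, :, None] * dirs[:, None, :]
    idx = (pts[..., ::-1] - stack.origin) / np.asarray(stack.spacing)
    flat = idx.reshape(-1, 3).T
    vals = ndimage.map_coordinates(stack.data, flat, order=1, mode="nearest")
    return vals.reshape(len(dirs), len(offsets)).max(axis=1)


def _otsu_or_uniform(values: np.ndarray):
    """Otsu threshold, or ``None`` for an effectively uniform channel."""
    spread = np.ptp(values)
    if spread <= 1e-6 * max(1.0, abs(float(np.mean(values)))):
        return None
    return float(threshold_otsu(values))


def compute_contact_mask(
    mesh: SurfaceMesh,
    exposed: np.ndarray,
    actin: np.ndarray,
    exposed_threshold: float | None = None,
    actin_threshold: float | None = None,
    closing_steps: int = 1,
) -> np.ndarray:
    """Per-vertex contact mask from exposed-surface and actin stains.

    Both channels are thresholded (per-channel Otsu by default).  The
    exposed-surface stain is the primary engulfment indicator: where it is
    bimodal, covered means below its threshold.  The actin criterion
    (above threshold) takes over only when the exposed channel is
    uninformative -- uniform, as in live imaging without a surface stain, or
    fully internalized targets; a uniform exposed channel is interpreted
    directly (all-zero: fully internalized; uniformly bright: fully
    exposed).  The mask is then morphologically closed on the mesh graph
    and the largest covered component kept.
    """
    exposed = np.asarray(exposed, float)
    actin = np.asarray(actin, float)
    thr_e = exposed_threshold if exposed_threshold is not None else _otsu_or_uniform(exposed)
    thr_a = actin_threshold if actin_threshold is not None else _otsu_or_uniform(actin)
    covered_a = np.zeros(len(actin), bool) if thr_a is None else actin > thr_a
    if thr_e is None:
        if float(np.mean(exposed)) <= 1e-9:
            mask = np.ones(len(exposed), bool)  # fully internalized
        elif covered_a.any():
            mask = covered_a
        else:
            mask = np.zeros(len(exposed), bool)
    else:
        mask = exposed < thr_e

    adj = mesh.vertex_adjacency
    for _ in range(closing_steps):  # dilate
        mask = mask | (adj.dot(mask.astype(np.int64)) > 0)
    for _ in range(closing_steps):  # erode
        mask = mask & ~(adj.dot((~mask).astype(np.int64)) > 0)

    if mask.any() and not mask.all():
        sub = adj[mask][:, mask]
        n, labels = connected_components(sub, directed=False)
        if n > 1:
            counts = np.bincount(labels)
            keep = labels == np.argmax(counts)
            idx = np.where(mask)[0]
            mask = np.zeros_like(mask)
            mask[idx[keep]] = True
    return mask


@dataclass
class CupFrame:
    """An aligned phagocytic cup: mesh + contact mask + axial coordinates."""

    mesh: SurfaceMesh  # aligned: axis = +z, base at theta = pi
    contact_mask: np.ndarray  # per-vertex bool
    axis: np.ndarray  # phagocytic axis in the ORIGINAL frame, unit
    fraction_engulfed: float
    x: np.ndarray  # per-vertex normalized axial coordinate
    alpha_rim: float  # rim angle from the base pole, rad
    signals: dict = field(default_factory=dict)  # per-vertex intensities

    @property
    def r_eq(self) -> float:
        return self.mesh.r_equivalent

    @property
    def boundary_vertices(self) -> np.ndarray:
        return _mask_boundary(self.mesh, self.contact_mask)


def _mask_boundary(mesh: SurfaceMesh, mask: np.ndarray) -> np.ndarray:
    """Indices of covered vertices adjacent to uncovered ones."""
    adj = mesh.vertex_adjacency
    touches_out = adj.dot((~mask).astype(np.int64)) > 0
    return np.where(mask & touches_out)[0]


def fraction_engulfed(mesh: SurfaceMesh, mask: np.ndarray) -> float:
    """Covered area fraction: triangle areas weighted by covered-vertex count."""
    w = np.asarray(mask, float)[mesh.faces].mean(axis=1)
    fa = mesh.trimesh.area_faces
    return float(np.sum(fa * w) / np.sum(fa))


def align_to_axis(
    mesh: SurfaceMesh,
    mask: np.ndarray,
    signals: dict | None = None,
    axis_override=None,
) -> CupFrame:
    """Rotate a cup so the phagocytic axis is +z with the base at theta=pi.

    The axis runs from the area-weighted centroid of the contact region
    through the particle centroid.  An empty or full mask requires
    ``axis_override`` (live-imaging convention: axis supplied manually).
    """
    mask = np.asarray(mask, bool)
    if axis_override is not None:
        axis = np.asarray(axis_override, float)
        axis = axis / np.linalg.norm(axis)
    else:
        if not mask.any() or mask.all():
            raise ValueError("empty or full mask: supply axis_override")
        va = mesh.vertex_areas
        w = va[mask]
        contact_centroid = np.sum(mesh.vertices[mask] * w[:, None], axis=0) / np.sum(w)
        axis = mesh.center - contact_centroid
        axis = axis / np.linalg.norm(axis)

    rot = rotation_to_z(axis)
    verts = (mesh.vertices - mesh.center) @ rot.T
    aligned = SurfaceMesh(verts, mesh.faces.copy(), np.zeros(3),
                          vertex_data=dict(mesh.vertex_data))
    frac = fraction_engulfed(mesh, mask)

    th, _ = aligned.angles
    s = np.pi - th  # angle from the base pole
    bidx = _mask_boundary(aligned, mask)
    if bidx.size:
        alpha_rim = float(np.mean(s[bidx]))
    else:
        alpha_rim = np.pi
    x = np.clip(s / alpha_rim, 0.0, X_MAX)
    return CupFrame(
        aligned, mask, axis, frac, x, alpha_rim, signals=dict(signals or {})
    )


@dataclass
class AxialProfile:
    """Surface-averaged profiles along the phagocytic axis (30 bins)."""

    x_centers: np.ndarray
    deviation_um: np.ndarray  # per-bin mean radial deviation
    radius_um: np.ndarray  # per-bin azimuthal-mean radius
    intensity: dict  # signal name -> per-bin mean
    counts: np.ndarray
    empty: np.ndarray
    alpha_rim: float
    r_eq: float

    def arc_um(self) -> np.ndarray:
        """Bin centers as arc length from the base pole, um."""
        return self.x_centers * self.alpha_rim * self.r_eq


def axial_profiles(cup: CupFrame, n_bins: int = 30) -> AxialProfile:
    """Area-weighted binned means of deviation, radius and signals vs x."""
    mesh = cup.mesh
    if "radial_deviation" not in mesh.vertex_data:
        mesh.compute_vertex_fields()
    dev = mesh.vertex_data["radial_deviation"]
    va = mesh.vertex_areas
    edges = np.linspace(0.0, X_MAX, n_bins + 1)
    which = np.clip(np.digitize(cup.x, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)

    def binned(vals):
        s = np.bincount(which, weights=va * vals, minlength=n_bins)
        w = np.bincount(which, weights=va, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            return np.where(w > 0, s / np.where(w > 0, w, 1.0), np.nan)

    prof_dev = binned(dev)
    prof_rad = binned(mesh.radii)
    intensity = {name: binned(v) for name, v in cup.signals.items()}
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AxialProfile(
        centers, prof_dev, prof_rad, intensity, counts, counts == 0,
        cup.alpha_rim, cup.r_eq,
    )


@dataclass
class ConstrictionResult:
    constriction_um: float
    location_x: float
    elongation: float
    actin_peak: float
    actin_band_width_um: float
    actin_behind_peak: float
    width_one_sided: bool = False


def constriction_metrics(
    profile: AxialProfile,
    actin_key: str = "actin",
    behind_um: float = 3.0,
) -> ConstrictionResult:
    """Constriction and F-actin band descriptors from an axial profile.

    Constriction is the largest azimuthal-mean *inward* radial deviation
    over the bins (the radially symmetric deformation component); the band
    width is the FWHM of the actin profile in arc length; the behind-peak
    intensity is read a fixed arc distance toward the cup base from the
    peak.
    """
    dev = np.where(profile.empty, np.nan, profile.deviation_um)
    inward = -dev
    k = int(np.nanargmax(inward))
    constriction = float(max(np.nanmax(inward), 0.0))
    location = float(profile.x_centers[k])

    actin = profile.intensity.get(actin_key)
    if actin is None:
        return ConstrictionResult(constriction, location, np.nan, np.nan, np.nan, np.nan)
    arc = profile.arc_um()
    a = np.where(profile.empty, np.nan, actin)
    pk = int(np.nanargmax(a))
    peak_val = float(a[pk])
    base = float(np.nanmin(a))
    half = 0.5 * (peak_val + base)
    one_sided = False

    def cross(side):
        idxs = range(pk - 1, -1, -1) if side < 0 else range(pk + 1, len(a))
        prev = pk
        for i in idxs:
            if np.isnan(a[i]):
                break
            if a[i] <= half:
                f = (a[prev] - half) / (a[prev] - a[i])
                return arc[prev] + f * (arc[i] - arc[prev])
            prev = i
        return None

    lo, hi = cross(-1), cross(+1)
    if lo is None and hi is None:
        width = np.nan
        one_sided = True
    elif lo is None:
        width = 2.0 * abs(hi - arc[pk])
        one_sided = True
    elif hi is None:
        width = 2.0 * abs(arc[pk] - lo)
        one_sided = True
    else:
        width = float(hi - lo)

    s_behind = arc[pk] - behind_um
    valid = ~np.isnan(a)
    behind = float(np.interp(s_behind, arc[valid], a[valid]))
    return ConstrictionResult(
        constriction, location, np.nan, peak_val, width, behind, one_sided
    )


def elongation(cup: CupFrame) -> float:
    """Relative elongation: axial extent over the equivalent diameter, minus 1."""
    z = cup.mesh.vertices[:, 2]
    return float((z.max() - z.min()) / (2.0 * cup.r_eq) - 1.0)


def mollweide_map(
    cup: CupFrame, signal: np.ndarray, shape: tuple[int, int] = (180, 360)
):
    """Equal-area Mollweide raster of a per-vertex signal.

    Returns ``(raster, inside)``: pixels outside the projection ellipse are
    NaN.  Latitude is ``pi/2 - theta`` of the aligned cup; the base pole
    maps to the bottom of the map.  Pixels sample the nearest vertex, so the
    raster mean over inside pixels approximates the surface mean (equal-area
    property).
    """
    from scipy.spatial import cKDTree

    ny, nx = shape
    ys = (np.arange(ny) + 0.5) / ny * 2.0 * np.sqrt(2.0) - np.sqrt(2.0)
    xs = (np.arange(nx) + 0.5) / nx * 4.0 * np.sqrt(2.0) - 2.0 * np.sqrt(2.0)
    X, Y = np.meshgrid(xs, ys)
    lat, lon, inside = mollweide_inverse(X, Y)
    theta = np.pi / 2.0 - lat
    phi = np.mod(lon, 2.0 * np.pi)
    pts = spherical_to_cartesian(theta, phi)
    tree = cKDTree(cup.mesh.directions)
    _, idx = tree.query(pts[inside])
    raster = np.full(shape, np.nan)
    raster[inside] = np.asarray(signal, float)[idx]
    return raster, inside
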