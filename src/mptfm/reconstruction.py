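"""Particle surface recovery from a volumetric particle channel.

The pipeline follows the classic super-resolution edge localization scheme:
threshold for a seed centroid/volume, cast radial intensity profiles from
the centroid (cubic interpolation), fit a Gaussian to the discrete
derivative of each profile to localize the edge with sub-voxel accuracy,
smooth the radial coordinates over a fixed geodesic window (1 um^2), and
triangulate the edge cloud into a closed mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from mptfm.geometry import fibonacci_directions
from mptfm.mesh import SurfaceMesh
from mptfm.stack import ImageStack


def estimate_seed(stack: ImageStack, smooth_sigma_um: float = 0.3):
    """Threshold-based centroid (um, xyz) and volume (um^3) estimate.

    Otsu threshold on a lightly Gaussian-smoothed copy; the largest
    above-threshold connected component wins.  Raises if nothing is found.
    """
    sig = [smooth_sigma_um / s for s in stack.spacing]
    sm = ndimage.gaussian_filter(stack.data, sigma=sig)
    if np.ptp(sm) <= 0:
        raise ValueError("no particle found: stack is constant")
    thr = threshold_otsu(sm)
    bw = sm > thr
    labels, n = ndimage.label(bw)
    if n == 0:
        raise ValueError("no particle found above threshold")
    counts = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(counts)) + 1
    comp = labels == biggest
    volume = float(counts[biggest - 1]) * stack.voxel_volume
    w = np.where(comp, stack.data, 0.0)
    idx = np.array(ndimage.center_of_mass(w))
    centroid_zyx = stack.point_of(idx)
    return centroid_zyx[::-1].copy(), volume  # (x, y, z) um


@dataclass
class RadialProfiles:
    """Intensity samples along rays from the centroid; one row per direction."""

    centroid: np.ndarray  # (3,) um, xyz
    directions: np.ndarray  # (N, 3) unit
    radii: np.ndarray  # (n_samples,) um, uniform from 0
    values: np.ndarray  # (N, n_samples)
    valid: np.ndarray  # (N, n_samples) sample inside the stack


def cast_radial_profiles(
    stack: ImageStack,
    centroid_xyz,
    directions: np.ndarray,
    r_max_um: float,
    step_um: float | None = None,
) -> RadialProfiles:
    """Cubic-interpolated intensities along rays from the centroid.

    ``step_um`` defaults to half the smallest voxel spacing (Nyquist-safe).
    """
    centroid = np.asarray(centroid_xyz, dtype=float)
    c_idx = stack.index_of(centroid[::-1])
    if np.any(c_idx < 0) or np.any(c_idx > np.array(stack.data.shape) - 1):
        raise ValueError("centroid outside the stack")
    if step_um is None:
        step_um = 0.5 * min(stack.spacing)
    n_samples = int(np.floor(r_max_um / step_um)) + 1
    radii = np.arange(n_samples) * step_um
    dirs = np.asarray(directions, dtype=float)
    # sample coordinates in fractional voxel units, (z, y, x)
    pts = centroid[None, None, ::-1] + radii[None, :, None] * dirs[:, None, ::-1]
    idx = (pts - stack.origin) / np.asarray(stack.spacing)
    flat = idx.reshape(-1, 3).T
    vals = ndimage.map_coordinates(stack.data, flat, order=3, mode="constant", cval=0.0)
    shape_max = np.array(stack.data.shape) - 1
    ok = np.all((flat.T >= 0) & (flat.T <= shape_max), axis=1)
    return RadialProfiles(
        centroid,
        dirs,
        radii,
        vals.reshape(len(dirs), n_samples),
        ok.reshape(len(dirs), n_samples),
    )


def _gauss(r, amp, center, sigma):
    return amp * np.exp(-0.5 * ((r - center) / sigma) ** 2)


def localize_edge(
    radii: np.ndarray,
    values: np.ndarray,
    window: int = 4,
    sigma_init_um: float = 0.3,
    search_range_um: tuple[float, float] | None = None,
):
    """Sub-voxel edge radius from one descending radial profile.

    Fits a Gaussian to the discrete (central-difference) derivative around
    its most negative sample.  With noisy data the most negative *smoothed*
    derivative selects the fit window (the fit itself uses the raw
    derivative), optionally restricted to a radial search range around the
    expected edge.  Returns ``(r_edge, residual, sigma)`` or ``None`` when
    the profile has no negative-going edge or the fit fails.
    """
    dv = np.gradient(values, radii)
    dv_sel = ndimage.gaussian_filter1d(dv, 1.0)
    if search_range_um is not None:
        lo_r, hi_r = search_range_um
        sel = (radii >= lo_r) & (radii <= hi_r)
        if not sel.any():
            return None
        cand = np.where(sel)[0]
        k = int(cand[np.argmin(dv_sel[cand])])
    else:
        k = int(np.argmin(dv_sel))
    if dv_sel[k] >= 0 or k == 0 or k == len(radii) - 1:
        return None
    lo, hi = max(k - window, 0), min(k + window + 1, len(radii))
    r_w, d_w = radii[lo:hi], dv[lo:hi]
    if len(r_w) < 4:
        return None
    p0 = (dv_sel[k], radii[k], sigma_init_um)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_gauss, r_w, d_w, p0=p0, maxfev=400)
    except RuntimeError:
        return None
    amp, center, sigma = popt
    sigma = abs(sigma)
    if amp >= 0 or not (radii[lo] - sigma <= center <= radii[hi - 1] + sigma):
        return None
    resid = float(np.sqrt(np.mean((_gauss(r_w, *popt) - d_w) ** 2)))
    return float(center), resid, float(sigma)


@dataclass
class EdgeCloud:
    """Per-direction edge radii about a common centroid."""

    centroid: np.ndarray  # (3,) um, xyz
    directions: np.ndarray  # (N, 3) unit
    radii: np.ndarray  # (N,) um
    valid: np.ndarray  # (N,) bool
    residual: np.ndarray  # (N,) fit RMS residual
    sigma: np.ndarray  # (N,) fitted edge width, um

    @property
    def angles(self):
        z = np.clip(self.directions[:, 2], -1.0, 1.0)
        theta = np.arccos(z)
        phi = np.mod(np.arctan2(self.directions[:, 1], self.directions[:, 0]), 2 * np.pi)
        return theta, phi

    @property
    def r_median(self) -> float:
        return float(np.median(self.radii[self.valid]))


def localize_edges(
    profiles: RadialProfiles,
    sigma_init_um: float = 0.3,
    nominal_radius_um: float | None = None,
    outlier_mads: float = 5.0,
) -> EdgeCloud:
    """Run :func:`localize_edge` over all directions of a profile set.

    When a nominal radius is given the edge search is restricted to
    0.6-1.4x that radius.  Directions whose radius deviates from the median
    of their 1 um^2 geodesic neighborhood by more than ``outlier_mads``
    robust deviations are flagged invalid (and later filled by surface
    smoothing); the criterion is local so that genuine deformations --
    which are spatially coherent -- survive it.
    """
    n = len(profiles.directions)
    radii = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    residual = np.full(n, np.nan)
    sigma = np.full(n, np.nan)
    rng = (
        (0.6 * nominal_radius_um, 1.4 * nominal_radius_um)
        if nominal_radius_um is not None
        else None
    )
    for i in range(n):
        res = localize_edge(
            profiles.radii, profiles.values[i],
            sigma_init_um=sigma_init_um, search_range_um=rng,
        )
        if res is None:
            continue
        radii[i], residual[i], sigma[i] = res
        valid[i] = True
    if not valid.any():
        raise ValueError("no edges localized in any direction")
    if outlier_mads > 0 and valid.sum() > 10:
        r_med = float(np.median(radii[valid]))
        ang = np.sqrt(1.0 / np.pi) / r_med  # 1 um^2 window on the median sphere
        chord = 2.0 * np.sin(ang / 2.0)
        tree = cKDTree(profiles.directions[valid])
        vr = radii[valid]
        local_med = np.empty(n)
        nb_lists = tree.query_ball_point(profiles.directions, chord)
        for i, nb in enumerate(nb_lists):
            local_med[i] = np.median(vr[nb]) if nb else r_med
        resid = radii - local_med
        mad = float(np.median(np.abs(resid[valid])))
        # floor of 0.2 um (half the largest physiological deformation) so
        # that steep genuine indentations are never discarded; only gross
        # localization failures exceed it
        tol = max(outlier_mads * mad, 0.2)
        valid &= np.abs(resid) <= tol
    return EdgeCloud(profiles.centroid, profiles.directions, radii, valid, residual, sigma)


def smooth_surface(cloud: EdgeCloud, window_area_um2: float = 1.0) -> EdgeCloud:
    """Moving-average smoothing of the radial coordinate on the sphere.

    Each radius is replaced by the mean of valid edge radii within geodesic
    radius ``sqrt(window_area / pi)`` on the median-radius sphere; angles
    are unchanged, invalid directions are filled from their neighbors.
    """
    r_med = cloud.r_median
    r_w = np.sqrt(window_area_um2 / np.pi)
    ang = r_w / r_med
    chord = 2.0 * np.sin(min(ang, np.pi) / 2.0)
    tree = cKDTree(cloud.directions[cloud.valid])
    valid_radii = cloud.radii[cloud.valid]
    out = np.empty_like(cloud.radii)
    neighbor_lists = tree.query_ball_point(cloud.directions, max(chord, 1e-9))
    for i, nb in enumerate(neighbor_lists):
        if len(nb) == 0:
            if not cloud.valid[i]:
                raise ValueError(f"direction {i} has no valid neighbors to fill from")
            out[i] = cloud.radii[i]
        else:
            out[i] = float(np.mean(valid_radii[nb]))
    return EdgeCloud(
        cloud.centroid,
        cloud.directions,
        out,
        np.ones_like(cloud.valid),
        cloud.residual,
        cloud.sigma,
    )


def build_mesh(cloud: EdgeCloud) -> SurfaceMesh:
    """Triangulate an edge cloud (hull topology of the unit directions)."""
    if not cloud.valid.all():
        raise ValueError("smooth or fill the cloud before meshing")
    mesh = SurfaceMesh.from_directions(cloud.directions, cloud.radii, center=cloud.centroid)
    return mesh


def reconstruct_particle(
    stack: ImageStack,
    n_directions: int = 3000,
    nominal_radius_um: float | None = None,
    window_area_um2: float = 1.0,
    reference: str = "median",
) -> SurfaceMesh:
    """Full reconstruction: seed, profiles, edges, smoothing, mesh, fields."""
    centroid, volume = estimate_seed(stack)
    if nominal_radius_um is None:
        nominal_radius_um = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    dirs = fibonacci_directions(n_directions)
    profiles = cast_radial_profiles(stack, centroid, dirs, 1.6 * nominal_radius_um)
    cloud = localize_edges(profiles, nominal_radius_um=nominal_radius_um)
    cloud = smooth_surface(cloud, window_area_um2)
    mesh = build_mesh(cloud)
    mesh.compute_vertex_fields(reference=reference)
    return mesh
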