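"""Spherical geometry helpers shared across the package.

Conventions (used everywhere):

* colatitude ``theta`` in ``[0, pi]`` measured from +z,
* azimuth ``phi`` in ``[0, 2*pi)`` measured CCW from +x,
* latitude ``lam = pi/2 - theta``.
"""

from __future__ import annotations

import numpy as np


def spherical_to_cartesian(theta, phi, r=1.0):
    """Unit-sphere (or radius ``r``) points from colatitude/azimuth."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    return np.stack(
        [r * st * np.cos(phi), r * st * np.sin(phi), r * np.cos(theta)], axis=-1
    )


def cartesian_to_spherical(xyz):
    """Return ``(r, theta, phi)`` with ``phi`` wrapped to ``[0, 2*pi)``."""
    xyz = np.asarray(xyz, dtype=float)
    r = np.linalg.norm(xyz, axis=-1)
    safe = np.where(r > 0, r, 1.0)
    theta = np.arccos(np.clip(xyz[..., 2] / safe, -1.0, 1.0))
    phi = np.mod(np.arctan2(xyz[..., 1], xyz[..., 0]), 2.0 * np.pi)
    return r, theta, phi


def great_circle_distance(p_i, p_j, radius=1.0):
    """Great-circle distance between ``(theta, phi)`` points on a sphere.

    Computed from latitudes ``lam = pi/2 - theta``::

        d = arccos(sin lam_i sin lam_j + cos lam_i cos lam_j cos(phi_i - phi_j)) * R

    The arccos argument is clamped to ``[-1, 1]``; the result is symmetric and
    lies in ``[0, pi * R]``. Inputs broadcast.
    """
    ti, pi_ = np.asarray(p_i[0], float), np.asarray(p_i[1], float)
    tj, pj = np.asarray(p_j[0], float), np.asarray(p_j[1], float)
    li = np.pi / 2.0 - ti
    lj = np.pi / 2.0 - tj
    c = np.sin(li) * np.sin(lj) + np.cos(li) * np.cos(lj) * np.cos(pi_ - pj)
    return np.arccos(np.clip(c, -1.0, 1.0)) * radius


def fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere (spherical Fibonacci lattice)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.mod(2.0 * np.pi * i / golden, 2.0 * np.pi)
    return spherical_to_cartesian(theta, phi)


def cap_colatitude(area_fraction: float) -> float:
    """Half-angle of a polar cap covering the given fraction of sphere area.

    Inverts ``fraction = (1 - cos(alpha)) / 2``.
    """
    if not 0.0 <= area_fraction <= 1.0:
        raise ValueError("area fraction must be in [0, 1]")
    return float(np.arccos(1.0 - 2.0 * area_fraction))


# ---------------------------------------------------------------------------
# Mollweide equal-area projection (unit sphere).  Map coordinates:
#   X in [-2*sqrt(2), 2*sqrt(2)], Y in [-sqrt(2), sqrt(2)]
# with longitude lon in [-pi, pi] and latitude lam in [-pi/2, pi/2].
# ---------------------------------------------------------------------------

_SQRT2 = np.sqrt(2.0)


def mollweide_forward(lat, lon, n_iter: int = 25):
    """Forward Mollweide projection; returns map coordinates ``(X, Y)``."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    t = np.arcsin(np.clip(2.0 * lat / np.pi, -1.0, 1.0))  # starting guess
    target = np.pi * np.sin(lat)
    for _ in range(n_iter):
        f = 2.0 * t + np.sin(2.0 * t) - target
        df = 2.0 + 2.0 * np.cos(2.0 * t)
        t = t - f / np.maximum(df, 1e-12)
    x = 2.0 * _SQRT2 / np.pi * lon * np.cos(t)
    y = _SQRT2 * np.sin(t)
    return x, y


def mollweide_inverse(x, y):
    """Inverse Mollweide projection; returns ``(lat, lon, inside)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.arcsin(np.clip(y / _SQRT2, -1.0, 1.0))
    lat = np.arcsin(np.clip((2.0 * t + np.sin(2.0 * t)) / np.pi, -1.0, 1.0))
    cos_t = np.cos(t)
    lon = np.where(cos_t > 1e-12, np.pi * x / (2.0 * _SQRT2 * np.maximum(cos_t, 1e-12)), 0.0)
    inside = (np.abs(lon) <= np.pi) & (np.abs(y) <= _SQRT2)
    return lat, lon, inside


def rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking the unit vector ``axis`` onto +z (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(np.dot(a, z))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antipodal: rotate pi about x
        return np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1.0 - c) / s**2)
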