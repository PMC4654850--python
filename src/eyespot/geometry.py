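"""Coordinate mathematics for the curtailed-sphere model of the eye.

The retinal cup is modelled as the part of an ellipsoid lying below a
circular rim.  All angular bookkeeping happens on the *normalized* unit
sphere obtained by dividing eye-frame coordinates componentwise by the
ellipsoid semi-axes.

Conventions
-----------
* Eye frame: the deepest point of the retinal cup sits at ``(0, 0, -1)``
  on the normalized sphere and the opening faces ``+z``.
* ``rim_opening_deg`` is the angle between the optical (``+z``) axis and
  the rim, seen from the eye centre.  The rim *colatitude* measured from
  the deepest point is ``phi0 = 180 - rim_opening_deg``; with the default
  opening of 53 degrees the rim lies at a colatitude of 127 degrees.
* The nasal pole of the nasotemporal (NT) axis sits at ``+x`` on the rim;
  which world direction is nasal is carried entirely by the view
  transforms, so this is a pure internal convention.
* Angles are degrees at API boundaries and radians internally.

Wedge coordinates
-----------------
A point below the rim is addressed by ``(psi, f)``: the plane through the
two poles of an axis (NT or DV), tilted ``psi`` from vertical, cuts the
unit sphere in a circle; ``f`` is the fractional arc distance from the
first pole to the second, walked through the deep side of the eye.  The
arc has radius ``rho``, centre ``(0, y0, z0)``, angular parameter
``alpha`` starting at ``alpha0 = arcsin(sin(phi0)/rho)`` on the rim and
spanning ``2*pi - 2*alpha0``.  Every arc passes through the two fixed
poles ``(+-sin(phi0), 0, -cos(phi0))``; ``f = 0.5`` on the vertical plane
is the deepest point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np

__all__ = [
    "EyeModel",
    "ViewTransform",
    "WedgeCoordinate",
    "WedgeArc",
    "rotation_matrix",
    "euler_xyz_from_matrix",
    "apply_view",
    "invert_view",
    "wedge_arc",
    "wedge_forward",
    "wedge_inverse",
    "wedge_coordinates_both_axes",
    "wedge_fractions_both_axes",
    "normalize_to_sphere",
    "spherical_polar",
    "line_ellipsoid_nearest",
]

Handedness = Literal["left", "right"]
Axis = Literal["NT", "DV"]


@dataclass(frozen=True)
class EyeModel:
    """Ellipsoidal eye with a circular rim opening.

    Parameters
    ----------
    semi_axes
        Semi-axis lengths ``(r_x, r_y, r_z)`` in consistent units
        (pixels of the images being analysed, or micrometres).
    rim_opening_deg
        Angle between the optical axis and the rim, in ``(0, 90)``.
        Default 53, typical of the early-postnatal mouse eye.
    handedness
        ``"left"`` or ``"right"``; flips the dorsoventral axis.
    """

    semi_axes: Tuple[float, float, float]
    rim_opening_deg: float = 53.0
    handedness: str = "left"

    def __post_init__(self) -> None:
        axes = tuple(float(a) for a in np.asarray(self.semi_axes, dtype=float).ravel())
        if len(axes) != 3:
            raise ValueError("semi_axes must contain exactly three lengths")
        if not all(np.isfinite(a) and a > 0 for a in axes):
            raise ValueError(f"semi_axes must be positive and finite, got {axes}")
        object.__setattr__(self, "semi_axes", axes)
        rim = float(self.rim_opening_deg)
        if not 0.0 < rim < 90.0:
            raise ValueError(f"rim_opening_deg must lie in (0, 90), got {rim}")
        object.__setattr__(self, "rim_opening_deg", rim)
        if self.handedness not in ("left", "right"):
            raise ValueError(f"handedness must be 'left' or 'right', got {self.handedness!r}")

    @property
    def r_max(self) -> float:
        """Largest semi-axis."""
        return max(self.semi_axes)

    @property
    def phi0_deg(self) -> float:
        """Rim colatitude measured from the deepest point, in (90, 180)."""
        return 180.0 - self.rim_opening_deg

    @property
    def rim_z(self) -> float:
        """z of the rim circle on the normalized unit sphere (= cos(rim_opening))."""
        return float(np.cos(np.deg2rad(self.rim_opening_deg)))

    def scaled(self, factor: float) -> "EyeModel":
        """Same eye with all semi-axes multiplied by ``factor`` (unit change)."""
        return EyeModel(tuple(a * factor for a in self.semi_axes),
                        self.rim_opening_deg, self.handedness)

    def with_handedness(self, handedness: str) -> "EyeModel":
        return EyeModel(self.semi_axes, self.rim_opening_deg, handedness)


def rotation_matrix(angles_deg) -> np.ndarray:
    """Rotation matrix ``Rx(ax) @ Ry(ay) @ Rz(az)`` for angles in degrees.

    The product order matches the view-transform convention used
    throughout: the z-rotation is applied first.
    """
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float).ravel())
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cx, -sx], [0.0, sx, cx]])
    ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    return rx @ ry @ rz


def euler_xyz_from_matrix(matrix: np.ndarray) -> Tuple[float, float, float]:
    """Recover ``(ax, ay, az)`` in degrees with ``R = Rx(ax) @ Ry(ay) @ Rz(az)``.

    Inverse of :func:`rotation_matrix`; at gimbal lock (``|R[0,2]| = 1``)
    the z angle is fixed to 0 and the x angle absorbs the remaining spin.
    """
    r = np.asarray(matrix, dtype=float)
    ay = np.arcsin(np.clip(r[0, 2], -1.0, 1.0))
    if abs(np.cos(ay)) > 1e-9:
        az = np.arctan2(-r[0, 1], r[0, 0])
        ax = np.arctan2(-r[1, 2], r[2, 2])
    else:  # gimbal lock: only ax +- az is determined
        az = 0.0
        ax = np.sign(r[0, 2]) * np.arctan2(r[1, 0], r[1, 1])
    return tuple(np.rad2deg([ax, ay, az]))


@dataclass(frozen=True)
class ViewTransform:
    """Rigid map from the eye frame to a camera/image frame.

    ``b = R @ a + t`` with ``R`` built by :func:`rotation_matrix` from
    ``rotation_deg``.  Camera convention: ``x``/``y`` are the image axes
    (y up), the viewing direction is ``-z``, so the viewer sits at large
    positive camera ``z``.
    """

    rotation_deg: Tuple[float, float, float]
    translation: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        rot = tuple(float(a) for a in np.asarray(self.rotation_deg, dtype=float).ravel())
        tra = tuple(float(a) for a in np.asarray(self.translation, dtype=float).ravel())
        if len(rot) != 3 or len(tra) != 3:
            raise ValueError("rotation_deg and translation must each have three components")
        if not all(np.isfinite(v) for v in rot + tra):
            raise ValueError("view transform parameters must be finite")
        object.__setattr__(self, "rotation_deg", rot)
        object.__setattr__(self, "translation", tra)

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix(self.rotation_deg)

    @property
    def translation_vec(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)


def apply_view(points, view: ViewTransform) -> np.ndarray:
    """Map eye-frame points (..., 3) to the camera frame."""
    p = np.asarray(points, dtype=float)
    return p @ view.matrix.T + view.translation_vec


def invert_view(points, view: ViewTransform) -> np.ndarray:
    """Map camera-frame points (..., 3) back to the eye frame."""
    p = np.asarray(points, dtype=float)
    return (p - view.translation_vec) @ view.matrix


# ---------------------------------------------------------------------------
# wedge coordinate system
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WedgeCoordinate:
    """A ``(psi, f)`` pair on a named retinal axis.

    ``psi_deg`` is the tilt of the arc plane from vertical in
    ``[-90, 90]``; ``f`` is the fractional arc distance in ``[0, 1]``
    from the first pole (nasal or dorsal) to the second.  ``degenerate``
    marks points at a pole, where ``psi`` is undefined and reported as 0.
    """

    psi_deg: float
    f: float
    axis: str = "NT"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not -90.0 - 1e-9 <= self.psi_deg <= 90.0 + 1e-9:
            raise ValueError(f"psi_deg must lie in [-90, 90], got {self.psi_deg}")
        if not -1e-9 <= self.f <= 1.0 + 1e-9:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if self.axis not in ("NT", "DV"):
            raise ValueError(f"axis must be 'NT' or 'DV', got {self.axis!r}")


@dataclass(frozen=True)
class WedgeArc:
    """Circular arc cut on the unit sphere by a tilted pole plane.

    ``rho`` is the arc radius, ``(0, y0, z0)`` its centre, ``alpha0`` the
    angular parameter at the rim (radians) and ``span`` the total angular
    extent ``2*pi - 2*alpha0`` (strictly less than a full turn).
    """

    rho: float
    y0: float
    z0: float
    alpha0: float
    span: float


def _check_phi0(phi0_deg: float) -> float:
    phi0 = float(phi0_deg)
    if not 90.0 < phi0 < 180.0:
        raise ValueError(f"rim colatitude phi0 must lie in (90, 180) degrees, got {phi0}")
    return np.deg2rad(phi0)


def _arc_params(psi_rad, phi0_rad: float):
    """Vectorized arc parameters (rho, y0, z0, alpha0, span) for tilt psi."""
    cphi = np.cos(phi0_rad)
    sphi = np.sin(phi0_rad)
    cpsi = np.cos(psi_rad)
    spsi = np.sin(psi_rad)
    rho = np.sqrt(sphi ** 2 + cphi ** 2 * cpsi ** 2)
    y0 = -spsi * cpsi * cphi
    z0 = -spsi ** 2 * cphi
    alpha0 = np.arcsin(np.clip(sphi / rho, -1.0, 1.0))
    span = 2.0 * np.pi - 2.0 * alpha0
    return rho, y0, z0, alpha0, span


def wedge_arc(psi_deg: float, phi0_deg: float) -> WedgeArc:
    """Arc geometry for the plane tilted ``psi_deg`` from vertical."""
    phi0 = _check_phi0(phi0_deg)
    if not -90.0 - 1e-9 <= float(psi_deg) <= 90.0 + 1e-9:
        raise ValueError(f"psi_deg must lie in [-90, 90], got {psi_deg}")
    rho, y0, z0, alpha0, span = _arc_params(np.deg2rad(float(psi_deg)), phi0)
    return WedgeArc(float(rho), float(y0), float(z0), float(alpha0), float(span))


def wedge_forward(psi_deg, f, phi0_deg: float) -> np.ndarray:
    """Map wedge coordinates ``(psi, f)`` to a unit-sphere point.

    Vectorized: ``psi_deg`` and ``f`` broadcast; the result has shape
    ``broadcast(psi, f).shape + (3,)``.  ``f = 0`` maps to the first pole
    ``(sin(phi0), 0, -cos(phi0))`` for every ``psi``; ``f = 1`` to the
    opposite pole; ``(psi=0, f=0.5)`` to the deepest point ``(0, 0, -1)``.
    """
    phi0 = _check_phi0(phi0_deg)
    psi_deg = np.asarray(psi_deg, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(np.abs(psi_deg) > 90.0 + 1e-9):
        raise ValueError("psi_deg must lie in [-90, 90]")
    if np.any((f < -1e-9) | (f > 1.0 + 1e-9)):
        raise ValueError("f must lie in [0, 1]")
    psi = np.deg2rad(psi_deg)
    rho, y0, z0, alpha0, span = _arc_params(psi, phi0)
    alpha = alpha0 + f * span
    x = rho * np.sin(alpha)
    y = y0 - rho * np.sin(psi) * np.cos(alpha)
    z = z0 + rho * np.cos(psi) * np.cos(alpha)
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


def wedge_inverse(point, phi0_deg: float, *, pole_atol: float = 1e-9):
    """Invert unit-sphere points to wedge coordinates.

    Returns ``(psi_deg, f, degenerate)`` with the shapes of the input
    minus the last axis.  Points above the rim (``z > -cos(phi0)``) are
    outside the coordinate system's domain and raise ``ValueError``.  At
    the two poles ``psi`` is undefined; there ``psi = 0`` is reported,
    ``f`` is 0 or 1 by the sign of ``x``, and ``degenerate`` is set.
    """
    phi0 = _check_phi0(phi0_deg)
    p = np.asarray(point, dtype=float)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    rim_z = -np.cos(phi0)
    if np.any(z > rim_z + 1e-9):
        raise ValueError("point above the rim: wedge coordinates are undefined there")
    denom = rim_z - z  # distance below the pole-axis line, >= 0 below the rim
    degenerate = (np.abs(y) < pole_atol) & (np.abs(denom) < pole_atol)
    psi = np.where(degenerate, 0.0, np.arctan2(y, denom))
    rho, y0, z0, alpha0, span = _arc_params(psi, phi0)
    v = -(y - y0) * np.sin(psi) + (z - z0) * np.cos(psi)
    alpha = np.arctan2(x, v)
    alpha = np.where(alpha < 0.0, alpha + 2.0 * np.pi, alpha)
    f = (alpha - alpha0) / span
    f = np.where(degenerate, np.where(x > 0.0, 0.0, 1.0), f)
    f = np.clip(f, 0.0, 1.0)
    psi_deg = np.rad2deg(psi)
    if p.ndim == 1:
        return float(psi_deg), float(f), bool(degenerate)
    return psi_deg, f, degenerate


def wedge_fractions_both_axes(points, phi0_deg: float, handedness: str = "left"):
    """Vectorized NT and DV fractions for points at/below the rim.

    The DV fraction is the NT computation applied after rotating the
    point by -90 degrees about the optical axis; for a right eye the DV
    axis is mirrored (``f_DV -> 1 - f_DV``).
    """
    p = np.asarray(points, dtype=float)
    _, f_nt, _ = _as_arrays(wedge_inverse(p, phi0_deg))
    p_dv = np.stack([p[..., 1], -p[..., 0], p[..., 2]], axis=-1)
    _, f_dv, _ = _as_arrays(wedge_inverse(p_dv, phi0_deg))
    if handedness == "right":
        f_dv = 1.0 - f_dv
    elif handedness != "left":
        raise ValueError(f"handedness must be 'left' or 'right', got {handedness!r}")
    return f_nt, f_dv


def _as_arrays(res):
    return tuple(np.asarray(r) for r in res)


def wedge_coordinates_both_axes(point, phi0_deg: float,
                                handedness: str = "left") -> Tuple[WedgeCoordinate, WedgeCoordinate]:
    """NT and DV :class:`WedgeCoordinate` pair for a single point."""
    p = np.asarray(point, dtype=float)
    if p.shape != (3,):
        raise ValueError("wedge_coordinates_both_axes expects a single 3-vector")
    psi_nt, f_nt, deg_nt = wedge_inverse(p, phi0_deg)
    p_dv = np.array([p[1], -p[0], p[2]])
    psi_dv, f_dv, deg_dv = wedge_inverse(p_dv, phi0_deg)
    if handedness == "right":
        f_dv = 1.0 - f_dv
    elif handedness != "left":
        raise ValueError(f"handedness must be 'left' or 'right', got {handedness!r}")
    return (WedgeCoordinate(psi_nt, f_nt, "NT", deg_nt),
            WedgeCoordinate(psi_dv, f_dv, "DV", deg_dv))


# ---------------------------------------------------------------------------
# ellipsoid <-> sphere plumbing
# ---------------------------------------------------------------------------


def normalize_to_sphere(points, eye: EyeModel) -> np.ndarray:
    """Divide componentwise by the semi-axes, then renormalize to unit length.

    Radial directions on the normalized sphere index points on the
    ellipsoid surface; the wedge machinery operates on this sphere.
    """
    p = np.asarray(points, dtype=float)
    scaled = p / np.asarray(eye.semi_axes)
    norm = np.linalg.norm(scaled, axis=-1)
    if np.any(norm < 1e-12):
        raise ValueError("cannot normalize the origin onto the sphere")
    return scaled / norm[..., None]


def spherical_polar(points):
    """Polar-export coordinates of unit-sphere points.

    Returns ``(colatitude_deg, azimuth_deg)``: colatitude is measured
    from the deepest point ``(0, 0, -1)`` (so the rim of a 53-degree
    opening sits at 127), azimuth is ``atan2(y, x)`` in ``(-180, 180]``.
    """
    p = np.asarray(points, dtype=float)
    colat = np.rad2deg(np.arccos(np.clip(-p[..., 2], -1.0, 1.0)))
    azim = np.rad2deg(np.arctan2(p[..., 1], p[..., 0]))
    if p.ndim == 1:
        return float(colat), float(azim)
    return colat, azim


def _ellipsoid_v(points, eye: EyeModel) -> np.ndarray:
    """|x^2/rx^2 + y^2/ry^2 + z^2/rz^2 - 1| — zero on the surface."""
    s = np.asarray(points, dtype=float) / np.asarray(eye.semi_axes)
    return np.abs(np.sum(s * s, axis=-1) - 1.0)


def _lines_ellipsoid_nearest(q1, q2, eye: EyeModel, n_samples: int = 2000,
                             mode: str = "sampled"):
    """Batch nearest-surface points for segments ``q1 -> q2`` (viewer first).

    Returns ``(points, v)`` with the leading shape of ``q1``.  In
    ``"sampled"`` mode ``n_samples`` evenly spaced points on each segment
    are scored by the surface residual ``v`` and the *first local
    minimum* of the sampled sequence wins: a segment crossing the
    ellipsoid has near-zero ``v`` at both crossings, and the earlier one
    (smaller parameter) is the viewer-side surface — a plain global
    argmin would let floating-point noise pick either crossing.  In
    ``"exact"`` mode the quadratic is solved and the root nearest the
    viewer (smallest segment parameter) is taken, falling back to the
    continuous minimum-``v`` point when the ray misses.
    """
    q1 = np.atleast_2d(np.asarray(q1, dtype=float))
    q2 = np.atleast_2d(np.asarray(q2, dtype=float))
    if mode == "sampled":
        t = np.linspace(0.0, 1.0, n_samples)
        d = q2 - q1
        # chunk to bound memory at ~n_samples * chunk * 3 floats
        out_pts = np.empty_like(q1)
        out_v = np.empty(q1.shape[0])
        chunk = max(1, 4_000_000 // (3 * n_samples))
        for lo in range(0, q1.shape[0], chunk):
            hi = min(lo + chunk, q1.shape[0])
            pts = q1[lo:hi, None, :] + t[None, :, None] * d[lo:hi, None, :]
            v = _ellipsoid_v(pts, eye)
            is_min = np.zeros(v.shape, dtype=bool)
            is_min[:, 1:-1] = (v[:, 1:-1] <= v[:, :-2]) & (v[:, 1:-1] <= v[:, 2:])
            is_min[:, 0] = v[:, 0] <= v[:, 1]
            is_min[:, -1] = v[:, -1] <= v[:, -2]
            idx = np.argmax(is_min, axis=1)  # first local minimum
            rows = np.arange(hi - lo)
            out_pts[lo:hi] = pts[rows, idx]
            out_v[lo:hi] = v[rows, idx]
        return out_pts, out_v
    if mode != "exact":
        raise ValueError(f"mode must be 'sampled' or 'exact', got {mode!r}")
    inv2 = 1.0 / np.asarray(eye.semi_axes) ** 2
    d = q2 - q1
    a = np.sum(d * d * inv2, axis=-1)
    b = 2.0 * np.sum(q1 * d * inv2, axis=-1)
    c = np.sum(q1 * q1 * inv2, axis=-1) - 1.0
    disc = b * b - 4.0 * a * c
    hit = disc >= 0.0
    sq = np.sqrt(np.maximum(disc, 0.0))
    t_front = (-b - sq) / (2.0 * a)      # smaller parameter = nearer the viewer
    t_vertex = np.clip(-b / (2.0 * a), 0.0, 1.0)
    t = np.where(hit, t_front, t_vertex)
    pts = q1 + t[..., None] * d
    return pts, _ellipsoid_v(pts, eye)


def line_ellipsoid_nearest(line_start, line_end, eye: EyeModel,
                           n_samples: int = 2000, mode: str = "sampled") -> np.ndarray:
    """Point of the segment nearest the ellipsoid surface (viewer side first).

    ``line_start`` is the viewer-side endpoint.  See
    :func:`_lines_ellipsoid_nearest` for the two modes.
    """
    p1 = np.asarray(line_start, dtype=float)
    p2 = np.asarray(line_end, dtype=float)
    if np.allclose(p1, p2):
        raise ValueError("degenerate line: endpoints coincide")
    pts, _ = _lines_ellipsoid_nearest(p1[None, :], p2[None, :], eye,
                                      n_samples=n_samples, mode=mode)
    return pts[0]
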