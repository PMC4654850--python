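"""Two-view localization of a retinal mark.

Under orthographic projection a pixel mark in one view constrains the
injection to a line segment perpendicular to that image plane.  Marks in
two views give two such segments in the eye frame; the injection is the
midpoint of their mutual perpendicular, snapped to the ellipsoid surface
and expressed as NT/DV wedge fractions.

Pixel convention: marks are stored in image coordinates (origin top-left,
y down).  The camera frame has y up, so the y coordinate is negated at
the single conversion point inside :func:`back_project`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Tuple

import numpy as np

from .geometry import (
    EyeModel,
    ViewTransform,
    invert_view,
    normalize_to_sphere,
    spherical_polar,
    wedge_fractions_both_axes,
)

__all__ = [
    "ViewMark",
    "BackProjectionLine",
    "LocalizationResult",
    "FlatRetinaAnnotation",
    "ProjectionResult",
    "NearParallelError",
    "back_project",
    "triangulate",
    "localize",
    "projection_method",
]


class NearParallelError(ValueError):
    """The two viewing rays are too close to parallel to triangulate."""


@dataclass(frozen=True)
class ViewMark:
    """A pixel mark in one view: ``pixel = (x, y)``, origin top-left, y down."""

    view_label: str
    pixel: Tuple[float, float]

    def __post_init__(self) -> None:
        px = tuple(float(v) for v in np.asarray(self.pixel, dtype=float).ravel())
        if len(px) != 2 or not all(np.isfinite(v) for v in px):
            raise ValueError(f"pixel must be a finite 2-vector, got {self.pixel!r}")
        object.__setattr__(self, "pixel", px)


@dataclass(frozen=True)
class BackProjectionLine:
    """Eye-frame segment of candidate injection locations.

    ``q1`` is the viewer-side endpoint (camera z = +r_max), ``q2`` the far
    endpoint; the segment is perpendicular to the image plane.
    """

    q1: np.ndarray
    q2: np.ndarray

    def __post_init__(self) -> None:
        q1 = np.asarray(self.q1, dtype=float)
        q2 = np.asarray(self.q2, dtype=float)
        if q1.shape != (3,) or q2.shape != (3,):
            raise ValueError("endpoints must be 3-vectors")
        if np.allclose(q1, q2):
            raise ValueError("degenerate back-projection line")
        object.__setattr__(self, "q1", q1)
        object.__setattr__(self, "q2", q2)

    @property
    def direction(self) -> np.ndarray:
        d = self.q2 - self.q1
        return d / np.linalg.norm(d)


def back_project(mark: ViewMark, view: ViewTransform, eye: EyeModel) -> BackProjectionLine:
    """Back-project a pixel mark to its eye-frame line segment.

    The candidate segment runs from camera depth ``+r_max`` to ``-r_max``
    about the eye centre's depth, guaranteeing it spans the whole
    ellipsoid.
    """
    x, y_img = mark.pixel
    tz = view.translation[2]
    p1 = np.array([x, -y_img, tz + eye.r_max])
    p2 = np.array([x, -y_img, tz - eye.r_max])
    return BackProjectionLine(invert_view(p1, view), invert_view(p2, view))


def triangulate(line_a: BackProjectionLine, line_b: BackProjectionLine,
                min_angle_deg: float = 5.0) -> Tuple[np.ndarray, float]:
    """Midpoint of the mutual perpendicular between two infinite lines.

    Returns ``(point, gap)`` where ``gap`` is the closest-approach
    distance (zero for exactly intersecting lines).  Raises
    :class:`NearParallelError` when the lines subtend less than
    ``min_angle_deg``, below which the second view adds no depth
    information.
    """
    p1, d1 = line_a.q1, line_a.q2 - line_a.q1
    p2, d2 = line_b.q1, line_b.q2 - line_b.q1
    n1 = d1 / np.linalg.norm(d1)
    n2 = d2 / np.linalg.norm(d2)
    angle = np.rad2deg(np.arccos(np.clip(abs(float(n1 @ n2)), 0.0, 1.0)))
    if angle < min_angle_deg:
        raise NearParallelError(
            f"viewing rays subtend {angle:.2f} deg < {min_angle_deg} deg")
    w0 = p1 - p2
    a = d1 @ d1
    b = d1 @ d2
    c = d2 @ d2
    d = d1 @ w0
    e = d2 @ w0
    denom = a * c - b * b
    s = (b * e - c * d) / denom
    t = (a * e - b * d) / denom
    c1 = p1 + s * d1
    c2 = p2 + t * d2
    return (c1 + c2) / 2.0, float(np.linalg.norm(c1 - c2))


@dataclass(frozen=True)
class LocalizationResult:
    """Recovered injection location.

    ``point_eye_frame`` is on the ellipsoid surface (eye units);
    ``point_unit`` the matching normalized-sphere direction;
    ``polar = (colatitude_deg, azimuth_deg)`` measured from the deepest
    point; ``ray_gap`` the triangulation residual; ``above_rim`` flags a
    snapped point outside the retina (fractions then refer to the nearest
    rim point at the same azimuth).
    """

    point_eye_frame: Tuple[float, float, float]
    point_unit: Tuple[float, float, float]
    nt_fraction: float
    dv_fraction: float
    polar: Tuple[float, float]
    ray_gap: float
    above_rim: bool = False
    area_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("nt_fraction", "dv_fraction"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.ray_gap < 0:
            raise ValueError("ray_gap must be non-negative")

    def with_area(self, area_fraction: float) -> "LocalizationResult":
        return LocalizationResult(self.point_eye_frame, self.point_unit,
                                  self.nt_fraction, self.dv_fraction, self.polar,
                                  self.ray_gap, self.above_rim, area_fraction)

    def to_dict(self) -> dict:
        return {
            "point_eye_frame": list(self.point_eye_frame),
            "point_unit": list(self.point_unit),
            "nt_fraction": self.nt_fraction,
            "dv_fraction": self.dv_fraction,
            "colatitude_deg": self.polar[0],
            "azimuth_deg": self.polar[1],
            "ray_gap": self.ray_gap,
            "above_rim": self.above_rim,
            "area_fraction": self.area_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LocalizationResult":
        return cls(tuple(d["point_eye_frame"]), tuple(d["point_unit"]),
                   d["nt_fraction"], d["dv_fraction"],
                   (d["colatitude_deg"], d["azimuth_deg"]),
                   d["ray_gap"], d.get("above_rim", False), d.get("area_fraction"))


def _rim_point_same_azimuth(unit: np.ndarray, eye: EyeModel) -> np.ndarray:
    """Nearest rim point sharing the point's azimuth (for above-rim snaps)."""
    az = np.arctan2(unit[1], unit[0]) if np.hypot(unit[0], unit[1]) > 1e-12 else 0.0
    s = np.sin(np.deg2rad(eye.rim_opening_deg))
    return np.array([s * np.cos(az), s * np.sin(az), eye.rim_z])


def localize(mark_top: ViewMark, mark_side: ViewMark,
             view_top: ViewTransform, view_side: ViewTransform,
             eye: EyeModel, min_angle_deg: float = 5.0) -> LocalizationResult:
    """Full two-view localization of a marked injection.

    Back-projects both marks, triangulates, snaps the point to the
    ellipsoid surface by radial rescaling on the normalized sphere, and
    reports NT/DV wedge fractions (handedness taken from ``eye``) plus
    polar-export coordinates.
    """
    line_top = back_project(mark_top, view_top, eye)
    line_side = back_project(mark_side, view_side, eye)
    point, gap = triangulate(line_top, line_side, min_angle_deg)
    unit = normalize_to_sphere(point, eye)
    above_rim = bool(unit[2] > eye.rim_z + 1e-9)
    unit_for_fractions = _rim_point_same_azimuth(unit, eye) if above_rim else unit
    f_nt, f_dv = wedge_fractions_both_axes(unit_for_fractions, eye.phi0_deg,
                                           eye.handedness)
    surface = unit * np.asarray(eye.semi_axes)
    colat, azim = spherical_polar(unit)
    return LocalizationResult(tuple(surface), tuple(unit),
                              float(f_nt), float(f_dv), (colat, azim),
                              gap, above_rim)


# ---------------------------------------------------------------------------
# legacy flat-retina projection method (baseline)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlatRetinaAnnotation:
    """Landmarks on a flattened-retina image, in pixels.

    ``n1``/``n2`` are the two ends of the nasal cut, ``t1``/``t2`` of the
    temporal cut; their midpoints define the NT axis.  ``injection`` is
    the marked injection centre.
    """

    n1: Tuple[float, float]
    n2: Tuple[float, float]
    t1: Tuple[float, float]
    t2: Tuple[float, float]
    injection: Tuple[float, float]


class ProjectionResult(NamedTuple):
    fraction: float
    out_of_range: bool


def projection_method(annotation: FlatRetinaAnnotation) -> ProjectionResult:
    """|NA|/|NT| fraction of the legacy flat-retina projection method.

    N and T are the midpoints of the nasal and temporal cut endpoints;
    the injection A is orthogonally projected onto the NT line and its
    signed fraction reported.  Projections outside [0, 1] (injections
    beyond the poles) are clamped with ``out_of_range`` set.
    """
    n = (np.asarray(annotation.n1, float) + np.asarray(annotation.n2, float)) / 2.0
    t = (np.asarray(annotation.t1, float) + np.asarray(annotation.t2, float)) / 2.0
    a = np.asarray(annotation.injection, float)
    nt = t - n
    nt_len2 = float(nt @ nt)
    if nt_len2 < 1e-18:
        raise ValueError("nasal and temporal poles coincide")
    raw = float((a - n) @ nt) / nt_len2
    out = not 0.0 <= raw <= 1.0
    return ProjectionResult(min(max(raw, 0.0), 1.0), out)
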