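"""Synthetic eyes with known injection ground truth.

Emulates the validation protocol for the two-view localization method:
ellipsoid semi-axes drawn from Normal(1400, 70) um (a P12 mouse eye), rim
opening from Normal(53, 3) degrees, top/side camera tilts from
Normal(0, 9) degrees truncated at +-20 with a free spin about the optical
axis, an injection centre randomized on the sub-rim sphere surface, and
100 injection points scattered with a 6-degree angular SD (points landing
above the rim are discarded).  Scenes can be rendered to a pair of
orthographic RGB rasters with the nasal cut marked by an "M" glyph.

Visibility model: the eye is an opaque cup (there is no surface above the
rim).  A surface point shows in a view if it is the viewer-side
intersection of its own pixel ray (front face), or if that ray enters
through the rim opening (front intersection above the rim) so the
interior back wall is seen -- this is how the optic disc at the bottom of
the cup appears in a top view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .geometry import (
    EyeModel,
    ViewTransform,
    _lines_ellipsoid_nearest,
    apply_view,
    euler_xyz_from_matrix,
    invert_view,
    normalize_to_sphere,
    rotation_matrix,
    wedge_fractions_both_axes,
)
from .localization import ViewMark, localize

__all__ = [
    "GroundTruth",
    "SyntheticScene",
    "VisibilityError",
    "sample_eye",
    "sample_views",
    "sample_injection",
    "make_scene",
    "render_views",
    "points_visible",
    "auto_mark",
    "validate_scenes",
]

# study conditions
SEMI_AXIS_MEAN_UM = 1400.0
SEMI_AXIS_SD_UM = 70.0
RIM_MEAN_DEG = 53.0
RIM_SD_DEG = 3.0
RIM_CLAMP = (10.0, 85.0)
TILT_SD_DEG = 9.0
TILT_MAX_DEG = 20.0
N_INJECTION_POINTS = 100
SCATTER_SD_DEG = 6.0

DEFAULT_PIXEL_SIZE_UM = 10.0
DEFAULT_IMAGE_SHAPE = (360, 360)
TRANSLATION_JITTER_PX = 8.0

# rendering palette (geometry is contractual, colours are config)
COLOR_BACKGROUND = (240, 240, 240)
COLOR_RETINA_OUTSIDE = (246, 205, 195)
COLOR_RETINA_INSIDE = (234, 188, 178)
COLOR_RIM = (214, 181, 60)
COLOR_WIREFRAME = (170, 170, 170)
COLOR_INJECTION = (150, 25, 60)  # claret, distinct chroma from the retina
COLOR_GLYPH = (20, 20, 20)
INJECTION_DOT_RADIUS_PX = 2.5


class VisibilityError(ValueError):
    """The injection is not visible in a required view."""


@dataclass
class GroundTruth:
    """Everything the generator knows about one synthetic scene.

    ``center_unit`` and ``injection_points`` live on the normalized unit
    sphere; ``eye`` is in image (pixel) units so the views map directly
    to raster coordinates.  ``nt_true``/``dv_true`` are the wedge
    fractions of the injection centre.
    """

    center_unit: np.ndarray
    theta_inj_deg: float
    phi_inj_deg: float
    injection_points: np.ndarray
    n_discarded: int
    nt_true: float
    dv_true: float
    eye: EyeModel
    views: Optional[Tuple[ViewTransform, ViewTransform]] = None
    pixel_size_um: Optional[float] = None
    semi_axes_um: Optional[Tuple[float, float, float]] = None


@dataclass
class SyntheticScene:
    truth: GroundTruth
    image_top: Optional[np.ndarray]
    image_side: Optional[np.ndarray]
    seed: Optional[int] = None


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = -np.inf, high: float = np.inf,
                      size: int = 1) -> np.ndarray:
    """Normal draws redrawn until inside (low, high)."""
    out = np.empty(size)
    for i in range(size):
        while True:
            x = rng.normal(mean, sd)
            if low < x < high:
                out[i] = x
                break
    return out


def sample_eye(rng: np.random.Generator) -> EyeModel:
    """Random eye in micrometres: semi-axes N(1400, 70), rim N(53, 3).

    The rim draw is clamped to (10, 85) degrees to keep the model valid;
    a clamp is triggered about once in 10^43 draws.
    """
    axes = _truncated_normal(rng, SEMI_AXIS_MEAN_UM, SEMI_AXIS_SD_UM, low=0.0, size=3)
    rim = float(np.clip(rng.normal(RIM_MEAN_DEG, RIM_SD_DEG), *RIM_CLAMP))
    return EyeModel(tuple(axes), rim)


def _sample_tilted_view(rng: np.random.Generator):
    tx, ty = _truncated_normal(rng, 0.0, TILT_SD_DEG,
                               -TILT_MAX_DEG, TILT_MAX_DEG, size=2)
    tz = rng.uniform(0.0, 360.0)
    return tx, ty, tz


def sample_views(rng: np.random.Generator,
                 image_shape: Tuple[int, int] = DEFAULT_IMAGE_SHAPE
                 ) -> Tuple[ViewTransform, ViewTransform]:
    """Random top and side camera poses.

    Top: x/y tilts N(0, 9) truncated at +-20 degrees, free z-spin.  Side:
    an independent draw from the same law composed with a 90-degree
    rotation about the eye-frame x axis, so the two optical axes are
    roughly orthogonal.  Translations centre the eye in the raster with a
    small Gaussian jitter.
    """
    h, w = image_shape
    top_angles = _sample_tilted_view(rng)
    r_top = rotation_matrix(top_angles)
    side_tilt = _sample_tilted_view(rng)
    r_side = rotation_matrix(side_tilt) @ rotation_matrix((90.0, 0.0, 0.0)) @ r_top
    side_angles = euler_xyz_from_matrix(r_side)
    views = []
    for label, angles in (("top", top_angles), ("side", side_angles)):
        jx, jy = rng.normal(0.0, TRANSLATION_JITTER_PX, size=2)
        views.append(ViewTransform(tuple(angles),
                                   (w / 2.0 + jx, -h / 2.0 + jy, 0.0), label))
    return tuple(views)


def _tangent_basis(center: np.ndarray):
    helper = np.array([0.0, 0.0, 1.0]) if abs(center[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(center, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(center, e1)
    return e1, e2


def sample_injection(rng: np.random.Generator, eye: EyeModel,
                     n_points: int = N_INJECTION_POINTS,
                     scatter_deg: float = SCATTER_SD_DEG,
                     legacy_angles: bool = False) -> GroundTruth:
    """Random injection centre plus scattered points, above-rim points discarded.

    By default the centre is area-uniform over the sub-rim cap (uniform z
    below the rim).  ``legacy_angles=True`` instead draws the spherical
    angles theta in [0, 360) and phi in [0, 180] uniformly -- pole-heavy
    and not area-uniform -- redrawing until the centre lands at or below
    the rim so the ground-truth fractions stay defined.

    The 6-degree scatter is an isotropic normal in the tangent plane at
    the centre mapped through the exponential map (the spherical-angle
    formulation is ill-defined near the poles).
    """
    rim_z = eye.rim_z
    if legacy_angles:
        while True:
            theta = rng.uniform(0.0, 360.0)
            phi = rng.uniform(0.0, 180.0)
            tr, pr = np.deg2rad(theta), np.deg2rad(phi)
            center = np.array([np.sin(pr) * np.cos(tr), np.sin(pr) * np.sin(tr), np.cos(pr)])
            if center[2] <= rim_z:
                break
    else:
        z = rng.uniform(-1.0, rim_z)
        theta = rng.uniform(0.0, 360.0)
        tr = np.deg2rad(theta)
        s = np.sqrt(max(0.0, 1.0 - z * z))
        center = np.array([s * np.cos(tr), s * np.sin(tr), z])
        phi = float(np.rad2deg(np.arccos(np.clip(center[2], -1.0, 1.0))))
    e1, e2 = _tangent_basis(center)
    offsets = rng.normal(0.0, np.deg2rad(scatter_deg), size=(n_points, 2))
    ang = np.linalg.norm(offsets, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(ang[:, None] > 0, offsets / ang[:, None], 0.0)
    points = (np.cos(ang)[:, None] * center
              + np.sin(ang)[:, None] * (direction[:, 0:1] * e1 + direction[:, 1:2] * e2))
    keep = points[:, 2] <= rim_z + 1e-12
    n_discarded = int(np.count_nonzero(~keep))
    f_nt, f_dv = wedge_fractions_both_axes(center, eye.phi0_deg, eye.handedness)
    return GroundTruth(center_unit=center, theta_inj_deg=float(theta),
                       phi_inj_deg=float(phi), injection_points=points[keep],
                       n_discarded=n_discarded,
                       nt_true=float(f_nt), dv_true=float(f_dv), eye=eye)


def make_scene(seed: Optional[int] = None, rng: Optional[np.random.Generator] = None,
               render: bool = True,
               image_shape: Tuple[int, int] = DEFAULT_IMAGE_SHAPE,
               pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
               legacy_angles: bool = False) -> SyntheticScene:
    """Generate one seeded scene (eye, two views, injection, optional rasters)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    eye_um = sample_eye(rng)
    eye_px = eye_um.scaled(1.0 / pixel_size_um)
    views = sample_views(rng, image_shape)
    truth = sample_injection(rng, eye_px, legacy_angles=legacy_angles)
    truth.eye = eye_px
    truth.views = views
    truth.pixel_size_um = pixel_size_um
    truth.semi_axes_um = eye_um.semi_axes
    image_top = image_side = None
    if render:
        image_top, image_side = render_views(truth, image_shape)
    return SyntheticScene(truth, image_top, image_side, seed)


# ---------------------------------------------------------------------------
# visibility and rendering
# ---------------------------------------------------------------------------


def _pixel_rays(b: np.ndarray, view: ViewTransform, eye: EyeModel):
    """Eye-frame ray endpoints for camera-frame positions ``b`` (..., 3)."""
    tz = view.translation[2]
    p1 = np.stack([b[..., 0], b[..., 1], np.full(b.shape[:-1], tz + eye.r_max)], axis=-1)
    p2 = np.stack([b[..., 0], b[..., 1], np.full(b.shape[:-1], tz - eye.r_max)], axis=-1)
    return invert_view(p1, view), invert_view(p2, view)


def points_visible(points_eye, view: ViewTransform, eye: EyeModel,
                   tol: float = 1e-6) -> np.ndarray:
    """Boolean visibility of eye-frame surface points in one view.

    A point is visible when it is the viewer-side (front) intersection of
    its own pixel ray, or when that front intersection lies above the rim
    -- i.e. the ray enters through the opening and the point is the
    interior back wall of the cup.
    """
    p = np.atleast_2d(np.asarray(points_eye, dtype=float))
    b = apply_view(p, view)
    q1, q2 = _pixel_rays(b, view, eye)
    front, _ = _lines_ellipsoid_nearest(q1, q2, eye, mode="exact")
    front_cam_z = apply_view(front, view)[..., 2]
    is_front = b[..., 2] >= front_cam_z - tol * eye.r_max
    front_unit = normalize_to_sphere(front, eye)
    through_aperture = front_unit[..., 2] > eye.rim_z + 1e-9
    vis = is_front | through_aperture
    if np.asarray(points_eye).ndim == 1:
        return bool(vis[0])
    return vis


def _project_to_pixels(points_eye, view: ViewTransform):
    """Eye-frame points -> float (col, row) image coordinates."""
    b = apply_view(np.atleast_2d(np.asarray(points_eye, dtype=float)), view)
    return np.stack([b[..., 0], -b[..., 1]], axis=-1)


def _draw_discs(img: np.ndarray, centers: np.ndarray, radius: float, color) -> None:
    h, w = img.shape[:2]
    r = int(np.ceil(radius))
    for cx, cy in np.atleast_2d(centers):
        x0, x1 = int(np.floor(cx)) - r, int(np.ceil(cx)) + r + 1
        y0, y1 = int(np.floor(cy)) - r, int(np.ceil(cy)) + r + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        hit = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
        img[y0:y1, x0:x1][hit] = color


def _draw_polyline(img: np.ndarray, pts: np.ndarray, color, step: float = 0.5) -> None:
    pts = np.asarray(pts, dtype=float)
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.linalg.norm(b - a) / step) + 1)
        seg = a + np.linspace(0.0, 1.0, n)[:, None] * (b - a)
        cols = np.round(seg[:, 0]).astype(int)
        rows = np.round(seg[:, 1]).astype(int)
        ok = (cols >= 0) & (cols < img.shape[1]) & (rows >= 0) & (rows < img.shape[0])
        img[rows[ok], cols[ok]] = color


def _render_one_view(truth: GroundTruth, view: ViewTransform,
                     image_shape: Tuple[int, int]) -> np.ndarray:
    eye = truth.eye
    h, w = image_shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = COLOR_BACKGROUND

    # per-pixel ray casting of the curtailed ellipsoid (orthographic)
    rows, cols = np.mgrid[0:h, 0:w]
    b0 = np.stack([cols.astype(float), -rows.astype(float),
                   np.zeros((h, w))], axis=-1)
    r = view.matrix
    t = view.translation_vec
    u = (b0 - t) @ r  # eye-frame position at camera z = 0
    wvec = r[2, :]    # eye-frame direction of camera +z
    inv2 = 1.0 / np.asarray(eye.semi_axes) ** 2
    qa = float(np.sum(wvec * wvec * inv2))
    qb = 2.0 * np.sum(u * wvec * inv2, axis=-1)
    qc = np.sum(u * u * inv2, axis=-1) - 1.0
    disc = qb * qb - 4.0 * qa * qc
    hit = disc >= 0.0
    sq = np.sqrt(np.maximum(disc, 0.0))
    z_front = (-qb + sq) / (2.0 * qa)
    z_back = (-qb - sq) / (2.0 * qa)
    front_unit_z = normalize_to_sphere(u + z_front[..., None] * wvec, eye)[..., 2]
    back_unit_z = normalize_to_sphere(u + z_back[..., None] * wvec, eye)[..., 2]
    front_below = front_unit_z <= eye.rim_z
    back_below = back_unit_z <= eye.rim_z
    img[hit & front_below] = COLOR_RETINA_OUTSIDE
    img[hit & ~front_below & back_below] = COLOR_RETINA_INSIDE

    semi = np.asarray(eye.semi_axes)
    phi0 = np.deg2rad(eye.phi0_deg)

    def draw_curve(unit_pts, color):
        surf = unit_pts * semi
        vis = points_visible(surf, view, eye)
        if vis.any():
            pix = _project_to_pixels(surf[vis], view)
            cols_i = np.round(pix[:, 0]).astype(int)
            rows_i = np.round(pix[:, 1]).astype(int)
            ok = (cols_i >= 0) & (cols_i < w) & (rows_i >= 0) & (rows_i < h)
            img[rows_i[ok], cols_i[ok]] = color

    # wire-frame meridians (the two cardinal pole planes)
    alpha = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    ntm = np.stack([np.sin(alpha), np.zeros_like(alpha), np.cos(alpha)], axis=-1)
    keep = ntm[:, 2] <= eye.rim_z
    draw_curve(ntm[keep], COLOR_WIREFRAME)
    dvm = np.stack([np.zeros_like(alpha), np.sin(alpha), np.cos(alpha)], axis=-1)
    draw_curve(dvm[keep], COLOR_WIREFRAME)

    # rim circle
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    rim = np.stack([np.sin(phi0) * np.cos(theta), np.sin(phi0) * np.sin(theta),
                    np.full_like(theta, eye.rim_z)], axis=-1)
    draw_curve(rim, COLOR_RIM)

    # nasal "M" glyph just outside the nasal rim point, when visible
    nasal_unit = np.array([np.sin(phi0), 0.0, eye.rim_z])
    nasal_surf = nasal_unit * semi
    if points_visible(nasal_surf, view, eye):
        pix = _project_to_pixels(nasal_surf, view)[0]
        centre_pix = _project_to_pixels(np.zeros(3), view)[0]
        out = pix - centre_pix
        nrm = np.linalg.norm(out)
        out = out / nrm if nrm > 1e-9 else np.array([1.0, 0.0])
        anchor = pix + 12.0 * out
        m = np.array([[-4.0, 4.0], [-4.0, -4.0], [0.0, 1.0], [4.0, -4.0], [4.0, 4.0]])
        _draw_polyline(img, anchor + m, COLOR_GLYPH)

    # injection points
    surf = truth.injection_points * semi
    vis = points_visible(surf, view, eye)
    if vis.any():
        pix = _project_to_pixels(surf[vis], view)
        _draw_discs(img, pix, INJECTION_DOT_RADIUS_PX, COLOR_INJECTION)
    return img


def render_views(truth: GroundTruth,
                 image_shape: Tuple[int, int] = DEFAULT_IMAGE_SHAPE
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Render the two orthographic RGB rasters for a scene."""
    if truth.views is None:
        raise ValueError("ground truth carries no views")
    return (_render_one_view(truth, truth.views[0], image_shape),
            _render_one_view(truth, truth.views[1], image_shape))


def auto_mark(scene) -> Tuple[ViewMark, ViewMark]:
    """Marks at the projected centroid of visible injection points.

    Stands in for a human observer clicking the injection in each view.
    Raises :class:`VisibilityError` naming the view when no injection
    point is visible there.
    """
    truth = scene.truth if isinstance(scene, SyntheticScene) else scene
    if truth.views is None:
        raise ValueError("ground truth carries no views")
    surf = truth.injection_points * np.asarray(truth.eye.semi_axes)
    marks = []
    for view in truth.views:
        vis = points_visible(surf, view, truth.eye)
        if not np.any(vis):
            raise VisibilityError(f"injection not visible in view {view.label!r}")
        pix = _project_to_pixels(surf[vis], view).mean(axis=0)
        marks.append(ViewMark(view.label, tuple(pix)))
    return tuple(marks)


# ---------------------------------------------------------------------------
# end-to-end validation
# ---------------------------------------------------------------------------


def validate_scenes(n_scenes: int = 150, seed: int = 0,
                    legacy_angles: bool = False) -> dict:
    """Recover injections over many seeded scenes and correlate with truth.

    Scenes where the injection is invisible in one of the two views are
    skipped (and counted) until ``n_scenes`` usable scenes accumulate.
    Rendering is bypassed: marks come from the geometric point
    projections, which is what the rasteriser draws.

    Returns a report dict with Pearson r and RMSE for the NT and DV
    fractions; with fewer than two usable scenes the correlations are
    ``None`` and ``degenerate`` is set.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    nt_true, nt_est, dv_true, dv_est, gaps = [], [], [], [], []
    n_skipped = 0
    attempts = 0
    max_attempts = max(8 * n_scenes, n_scenes + 20)
    while len(nt_true) < n_scenes and attempts < max_attempts:
        attempts += 1
        scene = make_scene(rng=rng, render=False, legacy_angles=legacy_angles)
        truth = scene.truth
        try:
            mark_top, mark_side = auto_mark(truth)
        except VisibilityError:
            n_skipped += 1
            continue
        res = localize(mark_top, mark_side, truth.views[0], truth.views[1], truth.eye)
        nt_true.append(truth.nt_true)
        nt_est.append(res.nt_fraction)
        dv_true.append(truth.dv_true)
        dv_est.append(res.dv_fraction)
        gaps.append(res.ray_gap)
    nt_true = np.asarray(nt_true)
    nt_est = np.asarray(nt_est)
    dv_true = np.asarray(dv_true)
    dv_est = np.asarray(dv_est)
    report = {
        "n_scenes": int(len(nt_true)),
        "n_skipped": int(n_skipped),
        "seed": int(seed),
        "degenerate": bool(len(nt_true) < 2),
    }
    if len(nt_true) >= 2:
        from scipy.stats import pearsonr
        report["r_nt"] = float(pearsonr(nt_true, nt_est).statistic)
        report["r_dv"] = float(pearsonr(dv_true, dv_est).statistic)
    else:
        report["r_nt"] = None
        report["r_dv"] = None
    if len(nt_true) >= 1:
        report["rmse_nt"] = float(np.sqrt(np.mean((nt_true - nt_est) ** 2)))
        report["rmse_dv"] = float(np.sqrt(np.mean((dv_true - dv_est) ** 2)))
        report["mean_ray_gap"] = float(np.mean(gaps))
    return report
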