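"""Independent oracles and controlled fixtures shared by the test modules.

Everything here is deliberately written from first principles (plane/sphere
intersections, brute-force grid searches, analytic cap areas) so that it
cannot share a bug with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np

from eyespot.geometry import EyeModel, ViewTransform, apply_view, wedge_fractions_both_axes
from eyespot.localization import ViewMark
from eyespot.synthetic import GroundTruth


def arc_point_oracle(psi_deg: float, f: float, phi0_deg: float) -> np.ndarray:
    """Wedge-coordinate point by direct circle geometry.

    Construct the plane through both poles tilted ``psi`` from vertical,
    intersect it with the unit sphere, and walk a fraction ``f`` of the
    long arc (through the deep side) from the first pole.
    """
    phi0 = np.deg2rad(phi0_deg)
    psi = np.deg2rad(psi_deg)
    pole_n = np.array([np.sin(phi0), 0.0, -np.cos(phi0)])
    pole_t = np.array([-np.sin(phi0), 0.0, -np.cos(phi0)])
    # plane normal: the vertical plane (psi=0) is y=0; tilting about the
    # pole axis rotates the normal in the y-z plane
    n = np.array([0.0, np.cos(psi), np.sin(psi)])
    d = float(n @ pole_n)
    centre = d * n                      # foot of the sphere centre on the plane
    rho = np.sqrt(max(0.0, 1.0 - d * d))
    u1 = (pole_n - centre) / rho
    u2 = np.cross(n, u1)                # heads below the rim at the first pole
    short = np.arccos(np.clip(u1 @ ((pole_t - centre) / rho), -1.0, 1.0))
    span = 2.0 * np.pi - short          # the long way, through the deep side
    ang = f * span
    return centre + rho * (np.cos(ang) * u1 + np.sin(ang) * u2)


def closest_pair_construction(rng: np.random.Generator, min_angle_deg: float = 30.0):
    """Random skew-line pair with a known closest-approach answer.

    Returns ``(p1, d1, p2, d2, midpoint, gap)``: the mutual perpendicular
    of the two lines has its feet at ``midpoint -+ gap/2`` along the
    common normal by construction.
    """
    while True:
        d1 = rng.normal(size=3)
        d1 /= np.linalg.norm(d1)
        d2 = rng.normal(size=3)
        d2 /= np.linalg.norm(d2)
        cosang = abs(float(d1 @ d2))
        if cosang < np.cos(np.deg2rad(min_angle_deg)):
            break
    normal = np.cross(d1, d2)
    normal /= np.linalg.norm(normal)
    mid = rng.uniform(-0.5, 0.5, size=3)
    gap = float(rng.uniform(0.0, 0.8))
    c1 = mid - 0.5 * gap * normal
    c2 = mid + 0.5 * gap * normal
    return c1, d1, c2, d2, mid, gap


def grid_search_closest(p1, d1, p2, d2, half_range: float = 1.0, n: int = 801):
    """Brute-force closest pair over a two-parameter grid."""
    s = np.linspace(-half_range, half_range, n)
    a = p1 + s[:, None] * d1
    b = p2 + s[:, None] * d2
    d2_mat = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmin(d2_mat), d2_mat.shape)
    return (a[i] + b[j]) / 2.0, float(np.sqrt(d2_mat[i, j])), (s[1] - s[0])


def exact_mark(point_eye, view: ViewTransform) -> ViewMark:
    """Image-pixel mark of an eye-frame point under a view (y flipped down)."""
    b = apply_view(np.asarray(point_eye, dtype=float), view)
    return ViewMark(view.label, (float(b[0]), float(-b[1])))


def controlled_truth(seed: int = 0, r_px: float = 140.0,
                     center_unit=(0.0, 0.6, -0.8), n_points: int = 100,
                     scatter_deg: float = 6.0,
                     image_shape=(360, 360)) -> GroundTruth:
    """Hand-built scene with the injection fully visible in both views.

    Top camera is the identity, side camera a pure 90-degree rotation
    about x; the default centre ``(0, 0.6, -0.8)`` is seen through the
    opening from the top and front-face from the side.
    """
    eye = EyeModel((r_px, r_px, r_px), 53.0)
    h, w = image_shape
    top = ViewTransform((0.0, 0.0, 0.0), (w / 2.0, -h / 2.0, 0.0), "top")
    side = ViewTransform((90.0, 0.0, 0.0), (w / 2.0, -h / 2.0, 0.0), "side")
    c = np.asarray(center_unit, dtype=float)
    c = c / np.linalg.norm(c)
    rng = np.random.default_rng(seed)
    helper = np.array([0.0, 0.0, 1.0]) if abs(c[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(c, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(c, e1)
    off = rng.normal(0.0, np.deg2rad(scatter_deg), size=(n_points, 2))
    ang = np.linalg.norm(off, axis=1)
    direction = np.where(ang[:, None] > 0, off / np.maximum(ang[:, None], 1e-300), 0.0)
    pts = (np.cos(ang)[:, None] * c
           + np.sin(ang)[:, None] * (direction[:, 0:1] * e1 + direction[:, 1:2] * e2))
    pts = pts[pts[:, 2] <= eye.rim_z]
    f_nt, f_dv = wedge_fractions_both_axes(c, eye.phi0_deg, eye.handedness)
    return GroundTruth(center_unit=c,
                       theta_inj_deg=float(np.rad2deg(np.arctan2(c[1], c[0])) % 360.0),
                       phi_inj_deg=float(np.rad2deg(np.arccos(np.clip(c[2], -1, 1)))),
                       injection_points=pts, n_discarded=0,
                       nt_true=float(f_nt), dv_true=float(f_dv),
                       eye=eye, views=(top, side), pixel_size_um=10.0,
                       semi_axes_um=tuple(a * 10.0 for a in eye.semi_axes))


def render_cap_image(eye: EyeModel, view: ViewTransform, cap_center_unit,
                     cap_half_angle_deg: float, image_shape=(360, 360),
                     background=(240, 240, 240), sclera=(246, 205, 195),
                     dye=(150, 25, 60)) -> np.ndarray:
    """Raster with a dye-coloured geodesic cap painted on the front surface.

    Pixels are classified by the analytic viewer-side ray/ellipsoid
    intersection: dye where the front surface lies within the cap,
    sclera elsewhere on the eye, background off the eye.
    """
    h, w = image_shape
    rows, cols = np.mgrid[0:h, 0:w]
    b0 = np.stack([cols.astype(float), -rows.astype(float), np.zeros((h, w))], axis=-1)
    r = view.matrix
    t = view.translation_vec
    u = (b0 - t) @ r
    wvec = r[2, :]
    inv2 = 1.0 / np.asarray(eye.semi_axes) ** 2
    qa = float(np.sum(wvec * wvec * inv2))
    qb = 2.0 * np.sum(u * wvec * inv2, axis=-1)
    qc = np.sum(u * u * inv2, axis=-1) - 1.0
    disc = qb * qb - 4.0 * qa * qc
    hit = disc >= 0.0
    z_front = (-qb + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * qa)
    front = u + z_front[..., None] * wvec
    unit = front / np.asarray(eye.semi_axes)
    unit = unit / np.maximum(np.linalg.norm(unit, axis=-1), 1e-300)[..., None]
    c = np.asarray(cap_center_unit, dtype=float)
    c = c / np.linalg.norm(c)
    in_cap = hit & (unit @ c >= np.cos(np.deg2rad(cap_half_angle_deg)))
    img = np.full((h, w, 3), background, dtype=np.uint8)
    img[hit] = sclera
    img[in_cap] = dye
    return img


def cap_points(n: int, half_angle_deg: float, center_unit=(0.0, 0.0, -1.0)) -> np.ndarray:
    """Area-uniform quasi-random points filling a geodesic cap."""
    c = np.asarray(center_unit, dtype=float)
    c = c / np.linalg.norm(c)
    i = np.arange(n) + 0.5
    cz = np.cos(np.deg2rad(half_angle_deg))
    z = 1.0 - (1.0 - cz) * i / n          # uniform in cap height
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    local = np.stack([s * np.cos(theta), s * np.sin(theta), z], axis=-1)
    helper = np.array([0.0, 0.0, 1.0]) if abs(c[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(c, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(c, e1)
    basis = np.stack([e1, e2, c], axis=0)
    return local @ basis


def spherical_polygon_area(vertices: np.ndarray) -> float:
    """Area of a spherical polygon on the unit sphere by Girard's excess."""
    v = np.asarray(vertices, dtype=float)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    n = len(v)
    angles = []
    for i in range(n):
        prev_v, cur, next_v = v[i - 1], v[i], v[(i + 1) % n]
        t_prev = prev_v - (prev_v @ cur) * cur
        t_next = next_v - (next_v @ cur) * cur
        t_prev /= np.linalg.norm(t_prev)
        t_next /= np.linalg.norm(t_next)
        angles.append(np.arccos(np.clip(t_prev @ t_next, -1.0, 1.0)))
    return float(sum(angles) - (n - 2) * np.pi)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([s * np.cos(theta), s * np.sin(theta), z], axis=-1)
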