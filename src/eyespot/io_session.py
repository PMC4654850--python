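"""Image loading, session persistence and polar export.

A session is a versioned JSON document: the eye model, the two view
transforms, optional pixel marks and results, and references to the two
images by path plus SHA-256 checksum (images are never embedded).  All
geometry in a session is expressed in image pixel units; an optional
``pixel_scale_um`` records micrometres per pixel, but every reported
fraction is scale-free so legacy images without a scale still work.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image

from .geometry import EyeModel, ViewTransform, wedge_forward
from .localization import LocalizationResult, ViewMark

__all__ = [
    "Session",
    "SessionError",
    "SCHEMA_VERSION",
    "load_images",
    "split_composite",
    "save_session",
    "load_session",
    "export_flat",
    "load_flat_csv",
]

SCHEMA_VERSION = 1
SUPPORTED_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}


class SessionError(ValueError):
    """Schema or validation failure while reading a session file."""


@dataclass
class Session:
    eye: EyeModel
    views: Tuple[ViewTransform, ViewTransform]
    image_paths: Tuple[Optional[str], Optional[str]] = (None, None)
    image_checksums: Tuple[Optional[str], Optional[str]] = (None, None)
    pixel_scale_um: Optional[float] = None
    marks: Optional[Tuple[ViewMark, ViewMark]] = None
    result: Optional[LocalizationResult] = None
    provenance: dict = field(default_factory=dict)


def _read_image(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise SessionError(f"unsupported image format {path.suffix!r} "
                           f"(expected tiff, png or jpeg)")
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def split_composite(image: np.ndarray, axis: Optional[str] = None,
                    top_pane: str = "first") -> Tuple[np.ndarray, np.ndarray]:
    """Split a composite raster into its two view panes.

    The two views were merged side by side (equal heights) or stacked
    (equal widths); the split halves the longer dimension, which must be
    even.  A square composite is ambiguous and needs an explicit
    ``axis`` (``"horizontal"`` for left/right panes, ``"vertical"`` for
    top/bottom).  The top view is the first (left or upper) pane unless
    ``top_pane="second"``.
    """
    h, w = image.shape[:2]
    if axis is None:
        if w > h:
            axis = "horizontal"
        elif h > w:
            axis = "vertical"
        else:
            raise SessionError("square composite is ambiguous: pass an explicit "
                               "split axis")
    if axis == "horizontal":
        if w % 2:
            raise SessionError(f"cannot merge-split composite of width {w}: the two "
                               "views must have equal size")
        panes = image[:, : w // 2], image[:, w // 2:]
    elif axis == "vertical":
        if h % 2:
            raise SessionError(f"cannot merge-split composite of height {h}: the two "
                               "views must have equal size")
        panes = image[: h // 2], image[h // 2:]
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    if top_pane == "second":
        panes = panes[::-1]
    elif top_pane != "first":
        raise ValueError(f"top_pane must be 'first' or 'second', got {top_pane!r}")
    return panes


def load_images(path_a, path_b=None, *, axis: Optional[str] = None,
                top_pane: str = "first") -> Tuple[np.ndarray, np.ndarray]:
    """Load the two views from two files, or split one composite file."""
    img_a = _read_image(path_a)
    if path_b is not None:
        return img_a, _read_image(path_b)
    return split_composite(img_a, axis=axis, top_pane=top_pane)


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def save_session(session: Session, path) -> None:
    checksums = list(session.image_checksums)
    for i, img_path in enumerate(session.image_paths):
        if img_path is not None and Path(img_path).exists():
            checksums[i] = _sha256(img_path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "eye": {"semi_axes": list(session.eye.semi_axes),
                "rim_opening_deg": session.eye.rim_opening_deg,
                "handedness": session.eye.handedness},
        "views": [{"label": v.label,
                   "rotation_deg": list(v.rotation_deg),
                   "translation": list(v.translation)}
                  for v in session.views],
        "images": [{"path": p, "sha256": c}
                   for p, c in zip(session.image_paths, checksums)],
        "pixel_scale_um": session.pixel_scale_um,
        "marks": None if session.marks is None else [
            {"view_label": m.view_label, "pixel": list(m.pixel)}
            for m in session.marks],
        "result": None if session.result is None else session.result.to_dict(),
        "provenance": session.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _build(field_name: str, ctor, *args, **kwargs):
    try:
        return ctor(*args, **kwargs)
    except (ValueError, TypeError, KeyError) as exc:
        raise SessionError(f"invalid session field {field_name!r}: {exc}") from exc


def load_session(path) -> Session:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"session not found: {path}")
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SessionError(f"not a valid session JSON: {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SessionError(f"unsupported schema_version {version!r} "
                           f"(this build reads version {SCHEMA_VERSION})")
    eye_doc = doc.get("eye", {})
    eye = _build("eye", EyeModel, tuple(eye_doc.get("semi_axes", ())),
                 eye_doc.get("rim_opening_deg", 53.0),
                 eye_doc.get("handedness", "left"))
    views_doc = doc.get("views", [])
    if len(views_doc) != 2:
        raise SessionError(f"invalid session field 'views': expected 2, "
                           f"got {len(views_doc)}")
    views = tuple(_build(f"views[{i}]", ViewTransform,
                         tuple(v.get("rotation_deg", ())),
                         tuple(v.get("translation", (0, 0, 0))),
                         v.get("label", ""))
                  for i, v in enumerate(views_doc))
    images = doc.get("images", [{}, {}])
    paths = tuple(img.get("path") for img in images)
    sums = tuple(img.get("sha256") for img in images)
    for p, s in zip(paths, sums):
        if p is not None and s is not None and Path(p).exists():
            actual = _sha256(p)
            if actual != s:
                warnings.warn(f"checksum mismatch for image {p}: session has {s[:12]}..., "
                              f"file has {actual[:12]}...", stacklevel=2)
    marks_doc = doc.get("marks")
    marks = None
    if marks_doc is not None:
        marks = tuple(_build(f"marks[{i}]", ViewMark, m.get("view_label", ""),
                             tuple(m.get("pixel", ())))
                      for i, m in enumerate(marks_doc))
    result_doc = doc.get("result")
    result = None
    if result_doc is not None:
        result = _build("result", LocalizationResult.from_dict, result_doc)
    return Session(eye=eye, views=views, image_paths=paths, image_checksums=sums,
                   pixel_scale_um=doc.get("pixel_scale_um"), marks=marks,
                   result=result, provenance=doc.get("provenance", {}))


# ---------------------------------------------------------------------------
# polar export
# ---------------------------------------------------------------------------

_CSV_FIELDS = ("colatitude_deg", "azimuth_deg", "nt_fraction", "dv_fraction",
               "area_fraction")


def export_flat(result: LocalizationResult, eye: EyeModel, csv_path,
                figure_path=None) -> None:
    """Write the flat polar export: a CSV row and, optionally, a figure.

    The figure is a polar plot with colatitude (from the deepest point)
    as radius: the rim circle sits at ``phi0`` (127 degrees for a
    53-degree opening) and the injection dot is drawn to scale when an
    area fraction is present.
    """
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        writer.writerow({
            "colatitude_deg": repr(result.polar[0]),
            "azimuth_deg": repr(result.polar[1]),
            "nt_fraction": repr(result.nt_fraction),
            "dv_fraction": repr(result.dv_fraction),
            "area_fraction": "" if result.area_fraction is None
                             else repr(result.area_fraction),
        })
    if figure_path is None:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phi0 = eye.phi0_deg
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    theta_grid = np.linspace(0.0, 2.0 * np.pi, 361)
    ax.plot(theta_grid, np.full_like(theta_grid, phi0), color="goldenrod",
            lw=2, label=f"rim ({phi0:.0f}\N{DEGREE SIGN})")
    colat, azim = result.polar
    az_rad = np.deg2rad(azim)
    if result.area_fraction is not None and result.area_fraction > 0:
        # angular radius of the equal-area spherical cap with that fraction
        cos_cap = 1.0 - result.area_fraction * (1.0 - np.cos(np.deg2rad(phi0)))
        cap_deg = np.rad2deg(np.arccos(np.clip(cos_cap, -1.0, 1.0)))
        ring = _geodesic_circle(colat, azim, cap_deg)
        ax.plot(np.deg2rad(ring[:, 1]), ring[:, 0], color="firebrick", lw=1)
    ax.plot([az_rad], [colat], "o", color="firebrick", label="injection")
    ax.set_rmax(min(phi0 + 15.0, 180.0))
    ax.set_title("injection location (polar export)")
    ax.legend(loc="lower left", bbox_to_anchor=(0.85, 0.9), fontsize=8)
    fig.savefig(figure_path, dpi=120)
    plt.close(fig)


def _geodesic_circle(colat_deg: float, azim_deg: float, radius_deg: float,
                     n: int = 181) -> np.ndarray:
    """(colatitude, azimuth) samples of a small circle around a point."""
    c = np.deg2rad(colat_deg)
    a = np.deg2rad(azim_deg)
    centre = np.array([np.sin(c) * np.cos(a), np.sin(c) * np.sin(a), -np.cos(c)])
    helper = np.array([0.0, 0.0, 1.0]) if abs(centre[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(centre, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(centre, e1)
    r = np.deg2rad(radius_deg)
    t = np.linspace(0.0, 2.0 * np.pi, n)
    pts = (np.cos(r) * centre[None, :]
           + np.sin(r) * (np.cos(t)[:, None] * e1 + np.sin(t)[:, None] * e2))
    colat = np.rad2deg(np.arccos(np.clip(-pts[:, 2], -1.0, 1.0)))
    azim = np.rad2deg(np.arctan2(pts[:, 1], pts[:, 0]))
    return np.stack([colat, azim], axis=-1)


def load_flat_csv(path) -> dict:
    """Read back a polar-export CSV row as a dict of floats (None if empty)."""
    with open(path, newline="") as fh:
        row = next(csv.DictReader(fh))
    return {k: (float(v) if v not in ("", None) else None) for k, v in row.items()}
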