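"""Planar optic-nerve-head geometry around the Bruch's membrane opening (BMO).

All angular measurements follow the right-eye convention used in fundus
reading: left-eye records are mirrored about the vertical axis through the BMO
centroid first, so "nasal" and "temporal" mean the same thing for every eye.
The fovea-BMO axis is the reference line; angles are signed with positive =
superior. Two trunk-position metrics are derived:

* angular deviation (alpha): signed angle of the BMO-centre -> vascular-trunk
  ray from the nasal horizontal midline (the negated fovea direction);
* shift index: a/b, where a is the centre-to-trunk distance and b the
  centre-to-margin distance along the same ray; defined as exactly 1.0 when
  the trunk lies outside the BMO.

The BMO margin is treated as the piecewise-linear closed polygon through the
delineated margin points; b comes from exact ray/segment intersection, taking
the first crossing outward from the centre.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from shapely.geometry import LinearRing, LineString, Point as ShPoint, Polygon

from .types import GeometrySummary, LandmarkRecord, Point

__all__ = [
    "to_right_eye_orientation",
    "bmo_centroid",
    "bmo_area",
    "fobmo_axis",
    "angular_deviation",
    "shift_index",
    "ppa_angular_location",
    "obliqueness",
    "classify_shift_group",
    "lcd",
    "summarize_geometry",
]

#: shift indices at or above this are treated as exactly 1 (severe shift).
SEVERE_SHIFT_TOL = 1e-9


def _polygon(margin: np.ndarray) -> Polygon:
    ring = LinearRing(margin)
    if not ring.is_simple:
        raise ValueError("BMO margin polygon is self-intersecting")
    return Polygon(ring)


def to_right_eye_orientation(rec: LandmarkRecord) -> LandmarkRecord:
    """Return ``rec`` expressed in right-eye orientation.

    Right eyes pass through unchanged. Left eyes are mirrored about the
    vertical axis through the BMO centroid (x -> 2*cx - x), which flips the
    nasal/temporal axis while preserving superior/inferior offsets. The result
    is flagged as ``laterality='right'`` so the operation is idempotent.
    """
    if rec.laterality == "right":
        return rec
    cx, _ = bmo_centroid(rec.bmo_margin)

    def mirror(p: Point | None) -> Point | None:
        if p is None:
            return None
        return (2.0 * cx - p[0], p[1])

    # reversed() keeps the ring orientation (mirroring alone reverses winding)
    margin = tuple(mirror(p) for p in reversed(rec.bmo_margin))
    return LandmarkRecord(
        eye_id=rec.eye_id,
        laterality="right",
        bmo_margin=margin,  # type: ignore[arg-type]
        fovea=mirror(rec.fovea),  # type: ignore[arg-type]
        trunk=mirror(rec.trunk),
        trunk_depth_um=rec.trunk_depth_um,
        bmo_plane_depth_um=rec.bmo_plane_depth_um,
        ppa_max_point=mirror(rec.ppa_max_point),
        scale_um_per_unit=rec.scale_um_per_unit,
    )


def bmo_centroid(margin) -> Point:
    """Area centroid of the closed BMO margin polygon.

    Uses the polygon (shoelace) centroid rather than the vertex mean, so the
    result is robust to uneven spacing of the delineated points.
    """
    arr = np.asarray(margin, dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 margin points")
    c = _polygon(arr).centroid
    return (c.x, c.y)


def bmo_area(margin) -> float:
    """Polygon area of the BMO margin (input units squared)."""
    return float(_polygon(np.asarray(margin, dtype=float)).area)


def fobmo_axis(center: Point, fovea: Point) -> np.ndarray:
    """Unit vector from the BMO centre toward the fovea (the temporal direction).

    The nasal reference ray for angular deviation is the negation of this
    vector; the temporal reference ray for the parapapillary-atrophy angle is
    the vector itself.
    """
    d = np.asarray(fovea, dtype=float) - np.asarray(center, dtype=float)
    n = np.hypot(*d)
    if n == 0.0:
        raise ValueError("fovea coincides with BMO centre; axis undefined")
    return d / n


def _signed_angle_deg(reference: np.ndarray, vec: np.ndarray) -> float:
    """Signed angle from ``reference`` to ``vec`` in (-180, 180].

    Positive when ``vec`` lies counter-clockwise of the reference in a frame
    with y up; with y = superior and the nasal ray as reference this realizes
    "positive = superior" on either side of a tilted fovea-BMO axis.
    """
    cross = reference[0] * vec[1] - reference[1] * vec[0]
    dot = reference[0] * vec[0] + reference[1] * vec[1]
    ang = math.degrees(math.atan2(cross, dot))
    if ang <= -180.0:
        ang += 360.0
    return ang


def angular_deviation(center: Point, trunk: Point | None, nasal_ray: np.ndarray) -> float | None:
    """Signed trunk angle (degrees) from the nasal horizontal midline.

    Returns None for an absent trunk (outside-BMO convention). A trunk
    coincident with the centre yields 0 with a degenerate-input warning.
    """
    if trunk is None:
        return None
    v = np.asarray(trunk, dtype=float) - np.asarray(center, dtype=float)
    if np.hypot(*v) == 0.0:
        warnings.warn("trunk coincides with BMO centre; angular deviation set to 0", stacklevel=2)
        return 0.0
    return _signed_angle_deg(np.asarray(nasal_ray, dtype=float), v)


def shift_index(center: Point, trunk: Point | None, margin) -> float:
    """Ratio a/b of trunk displacement to margin distance along the trunk ray.

    a = ||trunk - centre||; b = distance from the centre to the first crossing
    of the margin polygon along the centre -> trunk ray. Clipped to [0, 1].
    Returns exactly 1.0 when the trunk is absent (outside the BMO).
    """
    if trunk is None:
        return 1.0
    arr = np.asarray(margin, dtype=float)
    poly = _polygon(arr)
    c = np.asarray(center, dtype=float)
    t = np.asarray(trunk, dtype=float)
    a = float(np.hypot(*(t - c)))
    if a == 0.0:
        return 0.0
    direction = (t - c) / a
    # a ray long enough to leave any clinically plausible BMO
    reach = 4.0 * max(arr.max(0).max() - arr.min(0).min(), a) + 1.0
    ray = LineString([tuple(c), tuple(c + direction * reach)])
    hit = ray.intersection(poly.exterior)
    if hit.is_empty:
        raise ValueError(
            f"centre->trunk ray missed the margin polygon (centre {tuple(c)}, trunk {tuple(t)})"
        )
    pts = [hit] if isinstance(hit, ShPoint) else [g for g in getattr(hit, "geoms", []) ]
    dists = []
    for g in pts:
        for x, y in getattr(g, "coords", []):
            d = float(np.hypot(x - c[0], y - c[1]))
            if d > 1e-12:
                dists.append(d)
    if not dists:
        raise ValueError("ray/margin intersection degenerate at the centre")
    b = min(dists)
    return min(max(a / b, 0.0), 1.0)


def ppa_angular_location(center: Point, ppa_point: Point | None, temporal_ray: np.ndarray) -> float | None:
    """Signed angle (degrees) of maximal beta-zone PPA width from the temporal midline.

    Positive = superior; None when the eye has no beta-zone parapapillary atrophy.
    """
    if ppa_point is None:
        return None
    v = np.asarray(ppa_point, dtype=float) - np.asarray(center, dtype=float)
    if np.hypot(*v) == 0.0:
        raise ValueError("PPA point coincides with BMO centre")
    t = np.asarray(temporal_ray, dtype=float)
    # superior side of the fovea-BMO line: cross sign taken against the nasal
    # ray (-t), magnitude against the temporal ray, so positive = superior
    cross = -(t[0] * v[1] - t[1] * v[0])
    dot = t[0] * v[0] + t[1] * v[1]
    ang = math.degrees(math.atan2(cross, dot))
    if ang <= -180.0:
        ang += 360.0
    return ang


def obliqueness(alpha_deg: float | None) -> float | None:
    """In-quadrant angle of the trunk from the horizontal, in [0, 90].

    90 = trunk on the vertical axis, 0 = on the horizontal; symmetric in all
    four quadrants: obliqueness(a) = obliqueness(-a) = obliqueness(180 - a).
    """
    if alpha_deg is None:
        return None
    if not -180.0 < alpha_deg <= 180.0:
        raise ValueError(f"alpha must lie in (-180, 180], got {alpha_deg}")
    return 90.0 - abs(abs(alpha_deg) - 90.0)


def classify_shift_group(si: float) -> str:
    """Shift-severity group: A (<0.5, mild), B ([0.5, 1), moderate), C (=1, severe)."""
    if not 0.0 <= si <= 1.0:
        raise ValueError(f"shift index must lie in [0, 1], got {si}")
    if si >= 1.0 - SEVERE_SHIFT_TOL:
        return "C"
    return "B" if si >= 0.5 else "A"


def lcd(bmo_plane_depth_um: float | None, trunk_depth_um: float | None) -> float | None:
    """Lamina cribrosa depth at the trunk: axial trunk depth minus BMO-plane depth (um).

    Floored at 0 (a trunk anterior to the BMO plane is a measurement artefact)
    with a warning; None if either depth is missing.
    """
    if bmo_plane_depth_um is None or trunk_depth_um is None:
        return None
    d = float(trunk_depth_um) - float(bmo_plane_depth_um)
    if d < 0:
        warnings.warn(f"negative lamina cribrosa depth {d:.1f} um floored at 0", stacklevel=2)
        return 0.0
    return d


def summarize_geometry(rec: LandmarkRecord) -> GeometrySummary:
    """Full per-eye geometry summary in right-eye orientation."""
    r = to_right_eye_orientation(rec)
    center = bmo_centroid(r.bmo_margin)
    temporal = fobmo_axis(center, r.fovea)
    nasal = -temporal
    alpha = angular_deviation(center, r.trunk, nasal)
    si = shift_index(center, r.trunk, r.bmo_margin)
    group = classify_shift_group(si)
    area_mm2 = bmo_area(r.bmo_margin) * (r.scale_um_per_unit**2) / 1e6
    return GeometrySummary(
        eye_id=r.eye_id,
        alpha_deg=alpha,
        shift_index=si,
        shift_group=group,
        beta_deg=ppa_angular_location(center, r.ppa_max_point, temporal),
        obliqueness_deg=obliqueness(alpha),
        lcd_um=lcd(r.bmo_plane_depth_um, r.trunk_depth_um),
        bmo_area_mm2=area_mm2,
    )
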