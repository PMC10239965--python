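"""Exact planar geometry for hollow (cortical-ring) cross-sections.

A rib cross-section is modelled as the region between two simple closed
polygons: an outer periosteal border and an inner endosteal border, both in
section-plane coordinates (mm).  From this pair the module computes the
standard cortical bone morphometry quantities:

``Tt.Ar``
    total sub-periosteal area (area inside the periosteal border), mm^2
``Es.Ar``
    endosteal area (area inside the endosteal border), mm^2
``Ct.Ar``
    cortical bone area, ``Tt.Ar - Es.Ar``, mm^2
``Imax, Imin``
    principal / secondary second moments of area of the cortical ring about
    axes through the ring's own (composite) centroid, mm^4
``Irat``
    natural-log aspect measure ``ln(Imax / Imin)``; 0 for round sections.

All polygon integrals use Green's-theorem (shoelace) vertex summations and
are exact for the polygon; curved shapes are handled by polygonization.
A brute-force rasterization oracle is provided for testing only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import shapely

__all__ = [
    "Contour",
    "SectionProperties",
    "ContourError",
    "InvalidContourError",
    "DegenerateContourError",
    "validate_contour",
    "polygon_area_centroid",
    "polygon_second_moments",
    "principal_moments",
    "composite_section_properties",
    "offset_contour",
    "vertex_normals",
    "rasterize_section",
]


class ContourError(ValueError):
    """Base class for contour validation failures."""


class InvalidContourError(ContourError):
    """Self-intersecting (non-simple) contour."""


class DegenerateContourError(ContourError):
    """Fewer than 3 distinct vertices, or zero enclosed area."""


@dataclass(frozen=True)
class Contour:
    """A simple closed planar polygon, counter-clockwise, in mm.

    ``points`` has shape (n, 2); the polygon is closed by convention (the
    last vertex connects back to the first; no repeated closing vertex is
    stored).  Construct through :func:`validate_contour` for arbitrary
    input.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))

    @property
    def n_vertices(self) -> int:
        return self.points.shape[0]

    @property
    def area(self) -> float:
        return float(_batch_area(self.points[None])[0])

    @property
    def centroid(self) -> Tuple[float, float]:
        c = _batch_area_centroid(self.points[None])[1][0]
        return (float(c[0]), float(c[1]))

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def transformed(self, *, rotation: float = 0.0,
                    translation: Tuple[float, float] = (0.0, 0.0),
                    scale: float = 1.0) -> "Contour":
        """Similarity transform (rotate, then scale, then translate)."""
        c, s = math.cos(rotation), math.sin(rotation)
        rot = np.array([[c, -s], [s, c]])
        pts = scale * (self.points @ rot.T) + np.asarray(translation, float)
        return Contour(pts)

    def to_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.points)


@dataclass(frozen=True, slots=True)
class SectionProperties:
    """Area and inertial-moment properties of one cortical cross-section.

    Areas in mm^2, moments in mm^4, ``theta_max`` in radians in
    (-pi/2, pi/2] giving the in-plane direction of the axis about which the
    second moment equals ``i_max`` (0 when the section is isotropic).
    """

    tt_ar: float
    ct_ar: float
    es_ar: float
    i_max: float
    i_min: float
    i_rat: float
    theta_max: float
    centroid: Tuple[float, float]


# ---------------------------------------------------------------------------
# Vectorized Green's-theorem kernels.  pts has shape (..., n, 2); signed
# conventions assume CCW orientation gives positive area.

def _rolled(pts: np.ndarray) -> np.ndarray:
    return np.roll(pts, -1, axis=-2)


def _cross_terms(pts: np.ndarray) -> np.ndarray:
    nxt = _rolled(pts)
    return pts[..., 0] * nxt[..., 1] - nxt[..., 0] * pts[..., 1]


def _batch_area(pts: np.ndarray) -> np.ndarray:
    return 0.5 * _cross_terms(pts).sum(axis=-1)


def _batch_area_centroid(pts: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    nxt = _rolled(pts)
    cr = pts[..., 0] * nxt[..., 1] - nxt[..., 0] * pts[..., 1]
    area = 0.5 * cr.sum(axis=-1)
    cx = ((pts[..., 0] + nxt[..., 0]) * cr).sum(axis=-1) / (6.0 * area)
    cy = ((pts[..., 1] + nxt[..., 1]) * cr).sum(axis=-1) / (6.0 * area)
    return area, np.stack([cx, cy], axis=-1)


def _batch_moments(pts: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Second moments (ixx, iyy, ixy) of the solid lamina about ``origin``.

    Points are shifted before summation so the result is numerically stable
    regardless of where the polygon sits in the plane.
    """
    p = pts - np.asarray(origin, float)[..., None, :]
    nxt = _rolled(p)
    x0, y0 = p[..., 0], p[..., 1]
    x1, y1 = nxt[..., 0], nxt[..., 1]
    cr = x0 * y1 - x1 * y0
    ixx = ((y0 * y0 + y0 * y1 + y1 * y1) * cr).sum(axis=-1) / 12.0
    iyy = ((x0 * x0 + x0 * x1 + x1 * x1) * cr).sum(axis=-1) / 12.0
    ixy = ((x0 * y1 + 2.0 * x0 * y0 + 2.0 * x1 * y1 + x1 * y0) * cr).sum(axis=-1) / 24.0
    return np.stack([ixx, iyy, ixy], axis=-1)


def _principal(ixx, iyy, ixy):
    """Principal decomposition of the 2x2 second-moment tensor.

    Returns (i_max, i_min, theta_max); theta_max is the direction of the
    axis of maximal moment, ties resolved to 0.
    """
    avg = 0.5 * (ixx + iyy)
    diff = 0.5 * (ixx - iyy)
    r = np.hypot(diff, ixy)
    i_max = avg + r
    i_min = avg - r
    theta = 0.5 * np.arctan2(-ixy, diff)
    tie = r <= 1e-12 * np.abs(avg)
    theta = np.where(tie, 0.0, theta)
    i_max = np.where(tie, avg, i_max)
    i_min = np.where(tie, avg, i_min)
    return i_max, i_min, theta


def batch_composite_properties(outer: np.ndarray, inner: np.ndarray) -> dict:
    """Composite (hollow) section properties for stacks of contour pairs.

    ``outer`` and ``inner`` have shape (..., n, 2) in CCW orientation and
    are assumed valid (nested, simple).  Returns a dict of arrays keyed
    tt_ar, ct_ar, es_ar, i_max, i_min, i_rat, theta_max, centroid.  This is
    the fast path used by the population generator and mesh extraction;
    the scalar :func:`composite_section_properties` adds full validation.
    """
    a_out, c_out = _batch_area_centroid(outer)
    a_in, c_in = _batch_area_centroid(inner)
    ct = a_out - a_in
    cen = (a_out[..., None] * c_out - a_in[..., None] * c_in) / ct[..., None]
    m = _batch_moments(outer, cen) - _batch_moments(inner, cen)
    i_max, i_min, theta = _principal(m[..., 0], m[..., 1], m[..., 2])
    return {
        "tt_ar": a_out,
        "ct_ar": ct,
        "es_ar": a_in,
        "i_max": i_max,
        "i_min": i_min,
        "i_rat": np.log(i_max / i_min),
        "theta_max": theta,
        "centroid": cen,
    }


# ---------------------------------------------------------------------------
# Public scalar operations.

def validate_contour(points) -> Contour:
    """Validate and normalize a raw point sequence into a :class:`Contour`.

    Consecutive duplicate vertices (and a repeated closing vertex) are
    dropped; orientation is normalized to counter-clockwise.

    Raises
    ------
    DegenerateContourError
        fewer than 3 distinct vertices or zero enclosed area.
    InvalidContourError
        self-intersecting boundary.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateContourError("degenerate contour: need an (n, 2) point sequence")
    if pts.shape[0] >= 2 and np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] >= 2:
        keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
        pts = pts[keep]
    if pts.shape[0] < 3:
        raise DegenerateContourError("degenerate contour: fewer than 3 distinct vertices")
    # collinear point sets are degenerate, not self-intersecting
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-12) < 2:
        raise DegenerateContourError("degenerate contour: collinear points")
    ring = shapely.LinearRing(pts)
    if not ring.is_simple:
        raise InvalidContourError("invalid contour: self-intersecting boundary")
    area = float(_batch_area(pts[None])[0])
    if area == 0.0:
        raise DegenerateContourError("degenerate contour: zero area")
    if area < 0.0:
        pts = pts[::-1].copy()
    return Contour(pts)


def polygon_area_centroid(c: Contour) -> Tuple[float, Tuple[float, float]]:
    """Area (mm^2) and centroid (mm) of the solid lamina bounded by ``c``."""
    area, cen = _batch_area_centroid(c.points[None])
    return float(area[0]), (float(cen[0, 0]), float(cen[0, 1]))


def polygon_second_moments(c: Contour, origin: Tuple[float, float] = (0.0, 0.0)):
    """Second moments (ixx, iyy, ixy) in mm^4 of the solid lamina about
    axes through ``origin``."""
    m = _batch_moments(c.points[None], np.asarray(origin, float))[0]
    return float(m[0]), float(m[1]), float(m[2])


def principal_moments(ixx: float, iyy: float, ixy: float):
    """(i_max, i_min, theta_max) of a second-moment tensor."""
    i_max, i_min, theta = _principal(np.float64(ixx), np.float64(iyy), np.float64(ixy))
    return float(i_max), float(i_min), float(theta)


def composite_section_properties(periosteal: Contour,
                                 endosteal: Contour) -> SectionProperties:
    """Properties of the cortical ring between two nested contours.

    The endosteal contour must lie strictly inside the periosteal one.
    Moments are reported about the composite centroid of the ring itself
    (the mechanics convention for section stiffness).
    """
    p_poly = periosteal.to_shapely()
    e_poly = endosteal.to_shapely()
    if p_poly.boundary.intersects(e_poly.boundary):
        raise ContourError("contours intersect")
    if not p_poly.contains_properly(e_poly):
        raise ContourError("endosteal outside periosteal")
    out = batch_composite_properties(periosteal.points[None], endosteal.points[None])
    return SectionProperties(
        tt_ar=float(out["tt_ar"][0]),
        ct_ar=float(out["ct_ar"][0]),
        es_ar=float(out["es_ar"][0]),
        i_max=float(out["i_max"][0]),
        i_min=float(out["i_min"][0]),
        i_rat=float(out["i_rat"][0]),
        theta_max=float(out["theta_max"][0]),
        centroid=(float(out["centroid"][0, 0]), float(out["centroid"][0, 1])),
    )


def vertex_normals(points: np.ndarray) -> np.ndarray:
    """Unit outward vertex normals (bisectors of adjacent edge normals).

    ``points`` must be CCW.  The normal at each vertex is the normalized
    sum of the outward unit normals of its two adjacent edges; a vertex is
    displaced *by* the offset distance along this direction (no miter-length
    scaling), so a regular n-gon of vertex radius R offsets to vertex
    radius R + delta exactly.
    """
    pts = np.asarray(points, float)
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    if np.any(lengths == 0.0):
        raise DegenerateContourError("degenerate contour: repeated vertices")
    # outward normal of a CCW edge (dx, dy) is (dy, -dx)
    en = np.stack([edges[:, 1], -edges[:, 0]], axis=1) / lengths[:, None]
    vsum = en + np.roll(en, 1, axis=0)
    norm = np.hypot(vsum[:, 0], vsum[:, 1])
    if np.any(norm < 1e-12):
        raise InvalidContourError("invalid contour: reflex spike prevents vertex normal")
    return vsum / norm[:, None]


def offset_contour(c: Contour, delta: float) -> Contour:
    """Offset every vertex by ``delta`` mm along its outward vertex normal.

    Positive delta dilates, negative erodes.  The result is re-validated;
    an erosion that self-intersects or loses all area raises
    ``ContourError("offset collapses contour")``.
    """
    if delta == 0.0:
        return Contour(c.points.copy())
    new_pts = c.points + delta * vertex_normals(c.points)
    # a collapse (erosion past the medial axis) reverses edge directions
    # or the winding; both can survive validate_contour's orientation
    # normalization, so reject them explicitly
    old_edges = np.roll(c.points, -1, axis=0) - c.points
    new_edges = np.roll(new_pts, -1, axis=0) - new_pts
    if np.any(np.sum(old_edges * new_edges, axis=1) <= 0.0) \
            or float(_batch_area(new_pts[None])[0]) <= 0.0:
        raise ContourError("offset collapses contour")
    try:
        out = validate_contour(new_pts)
    except ContourError as exc:
        raise ContourError("offset collapses contour") from exc
    return out


def rasterize_section(periosteal: Contour, endosteal: Contour,
                      pixel: float) -> SectionProperties:
    """Brute-force pixel-sum oracle for composite section properties.

    Samples pixel centres on a regular grid of spacing ``pixel`` mm over
    the periosteal bounding box and classifies each against both polygons.
    Per-pixel self-moments (pixel^4/12) are included.  Test oracle only --
    O(bbox area / pixel^2).
    """
    if pixel <= 0:
        raise ValueError("pixel size must be positive")
    pts = periosteal.points
    x0, y0 = pts.min(axis=0) - pixel
    x1, y1 = pts.max(axis=0) + pixel
    xs = np.arange(x0 + pixel / 2, x1, pixel)
    ys = np.arange(y0 + pixel / 2, y1, pixel)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    p_poly = periosteal.to_shapely()
    e_poly = endosteal.to_shapely()
    shapely.prepare(p_poly)
    shapely.prepare(e_poly)
    in_p = shapely.contains_xy(p_poly, gx, gy)
    in_e = shapely.contains_xy(e_poly, gx, gy)
    px2 = pixel * pixel
    ring = in_p & ~in_e
    n_ring = int(ring.sum())
    if n_ring == 0:
        return SectionProperties(float(in_p.sum()) * px2, 0.0,
                                 float(in_e.sum()) * px2, 0.0, 0.0, 0.0, 0.0,
                                 (float("nan"), float("nan")))
    rx, ry = gx[ring], gy[ring]
    cx, cy = rx.mean(), ry.mean()
    self_moment = n_ring * px2 * px2 / 12.0
    ixx = float(((ry - cy) ** 2).sum()) * px2 + self_moment
    iyy = float(((rx - cx) ** 2).sum()) * px2 + self_moment
    ixy = float(((rx - cx) * (ry - cy)).sum()) * px2
    i_max, i_min, theta = principal_moments(ixx, iyy, ixy)
    i_rat = math.log(i_max / i_min) if i_min > 0 else float("inf")
    return SectionProperties(
        tt_ar=float(in_p.sum()) * px2,
        ct_ar=n_ring * px2,
        es_ar=float(in_e.sum()) * px2,
        i_max=i_max, i_min=i_min, i_rat=i_rat, theta_max=theta,
        centroid=(float(cx), float(cy)),
    )
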