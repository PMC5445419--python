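"""Cell geometry: polarity axes, eccentricity, and anterior/posterior ROIs.

Conventions
-----------
Coordinates are 0-based (row, col) in the continuous pixel-centre
frame; shapely geometries store (x, y) = (col, row).  Pixel membership
uses pixel centres, and a pixel whose centre lies exactly on the
bisecting line belongs to the anterior half.

The cell is bisected by the line through the nucleus centroid
perpendicular to the nucleus-to-aggregation-centre direction; the half
on the aggregation side is the anterior, the opposite half the
posterior.  Cell elongation is summarised by the eccentricity
``eps = sqrt(1 - b^2/a^2)`` of the equivalent-inertia ellipse: 0 for a
round (unpolarized) cell, approaching 1 for an elongated (polarized)
one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon
from shapely.ops import split as shapely_split

__all__ = [
    "CellGeometry",
    "RoiPair",
    "fit_cell_axes",
    "eccentricity",
    "bisect_cell",
    "roi_pair_masks",
    "polygon_mask",
    "posterior_intensity_fraction",
]


@dataclass
class RoiPair:
    """Anterior/posterior halves of a cell with the cut that made them.

    ``bisect_point`` and ``anterior_direction`` are (row, col); the
    bisecting line passes through ``bisect_point`` perpendicular to
    ``anterior_direction``, and pixels with
    ``dot(p - bisect_point, anterior_direction) >= 0`` are anterior.
    """

    anterior: Polygon
    posterior: Polygon
    bisect_point: tuple[float, float]
    anterior_direction: tuple[float, float]

    def swapped(self) -> "RoiPair":
        d = self.anterior_direction
        return RoiPair(self.posterior, self.anterior, self.bisect_point, (-d[0], -d[1]))


@dataclass
class CellGeometry:
    """Full per-cell geometry record."""

    cell_polygon: Polygon
    nucleus_centroid: tuple[float, float]
    aggregation_point: tuple[float, float]
    semi_major: float = float("nan")
    semi_minor: float = float("nan")
    orientation: float = float("nan")
    cell_id: str = ""
    stream_position: str = "single"
    qc_pass: bool = True

    @property
    def eccentricity(self) -> float:
        return eccentricity(self.semi_major, self.semi_minor)


def _polygon_moments(poly: Polygon) -> tuple[float, tuple[float, float], np.ndarray]:
    """Area, centroid and central second-moment (covariance) matrix.

    Shoelace-based closed forms; covariance is of the uniform measure
    over the polygon interior, in (x, y) coordinates.
    """
    x, y = np.asarray(poly.exterior.coords).T
    x0, x1 = x[:-1], x[1:]
    y0, y1 = y[:-1], y[1:]
    cross = x0 * y1 - x1 * y0
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        raise ValueError("degenerate polygon: zero area")
    cx = ((x0 + x1) * cross).sum() / (6.0 * area)
    cy = ((y0 + y1) * cross).sum() / (6.0 * area)
    sxx = ((x0**2 + x0 * x1 + x1**2) * cross).sum() / (12.0 * area) - cx**2
    syy = ((y0**2 + y0 * y1 + y1**2) * cross).sum() / (12.0 * area) - cy**2
    sxy = ((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross).sum() / (
        24.0 * area
    ) - cx * cy
    return abs(area), (cx, cy), np.array([[sxx, sxy], [sxy, syy]])


def fit_cell_axes(cell_polygon: Polygon) -> tuple[float, float, float]:
    """Semi-axes (a, b) and orientation of the equivalent-inertia ellipse.

    For a uniform ellipse the coordinate covariance eigenvalues are
    (a^2/4, b^2/4), so the semi-axes are twice the square roots of the
    polygon's covariance eigenvalues.  Orientation is the major-axis
    angle in radians in the (col, row) plane.
    """
    if not cell_polygon.is_valid or cell_polygon.is_empty:
        raise ValueError("cell polygon must be a valid, non-empty simple polygon")
    _, _, cov = _polygon_moments(cell_polygon)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    a = 2.0 * math.sqrt(float(evals[1]))
    b = 2.0 * math.sqrt(float(evals[0]))
    vx, vy = evecs[:, 1]
    return a, b, math.atan2(vy, vx)


def eccentricity(a: float, b: float) -> float:
    """Polarization eccentricity ``sqrt(1 - b^2/a^2)``.

    0 for a circle (a = b, non-polarized); 1 in the fully elongated
    limit (b = 0, polarized).
    """
    if a <= 0:
        raise ValueError("semi-major axis a must be > 0")
    if b < 0 or b > a:
        raise ValueError(f"axes must satisfy a >= b >= 0, got a={a}, b={b}")
    return math.sqrt(1.0 - (b * b) / (a * a))


def bisect_cell(
    cell_polygon: Polygon,
    nucleus_centroid: tuple[float, float],
    aggregation_point: tuple[float, float],
) -> RoiPair:
    """Cut the cell into anterior/posterior halves about the nucleus.

    The cut line passes through the nucleus centroid perpendicular to
    the nucleus-to-aggregation direction; the piece(s) on the
    aggregation side form the anterior.  If the cut produces more than
    two pieces (non-convex outline), pieces are assigned to halves by
    the side of their centroid, with a warning.
    """
    nr, nc = nucleus_centroid
    ar, ac = aggregation_point
    d = np.array([ar - nr, ac - nc], dtype=float)
    norm = float(np.linalg.norm(d))
    if norm == 0:
        raise ValueError("aggregation point coincides with nucleus centroid")
    d /= norm
    nuc_pt = shapely.points(nc, nr)
    if not cell_polygon.contains(nuc_pt):
        raise ValueError("nucleus centroid must lie strictly inside the cell polygon")

    # cut direction perpendicular to d, in (x=col, y=row) coordinates
    tx, ty = -d[0], d[1]
    span = 4.0 * max(
        cell_polygon.bounds[2] - cell_polygon.bounds[0],
        cell_polygon.bounds[3] - cell_polygon.bounds[1],
    )
    line = LineString(
        [(nc - span * tx, nr - span * ty), (nc + span * tx, nr + span * ty)]
    )
    pieces = list(shapely_split(cell_polygon, line).geoms)
    if len(pieces) > 2:
        warnings.warn(
            f"bisection produced {len(pieces)} pieces; assigning each to a half "
            "by centroid side",
            stacklevel=2,
        )
    ant_parts, post_parts = [], []
    for piece in pieces:
        c = piece.centroid
        side = (c.y - nr) * d[0] + (c.x - nc) * d[1]
        (ant_parts if side >= 0 else post_parts).append(piece)
    if not ant_parts or not post_parts:
        raise ValueError("bisection failed to produce pieces on both sides")
    anterior = shapely.union_all(ant_parts)
    posterior = shapely.union_all(post_parts)
    return RoiPair(
        anterior=anterior,
        posterior=posterior,
        bisect_point=(float(nr), float(nc)),
        anterior_direction=(float(d[0]), float(d[1])),
    )


def polygon_mask(shape: tuple[int, int], polygon: Polygon) -> np.ndarray:
    """Boolean pixel mask of centres inside (or on) the polygon."""
    rr, cc = np.indices(shape)
    inside = shapely.intersects_xy(polygon, cc.ravel(), rr.ravel())
    return inside.reshape(shape)


def roi_pair_masks(
    shape: tuple[int, int], rois: RoiPair
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint anterior/posterior pixel masks that exactly cover the cell.

    Cell membership is tested on the union of the two halves; the
    halves are then separated by the signed side of the bisecting
    line, so every cell pixel lands in exactly one half (ties to the
    anterior).  This makes anterior + posterior sums add up to the
    whole-cell sum identically.
    """
    cell = shapely.union_all([rois.anterior, rois.posterior])
    in_cell = polygon_mask(shape, cell)
    rr, cc = np.indices(shape)
    pr, pc = rois.bisect_point
    dr, dc = rois.anterior_direction
    side = (rr - pr) * dr + (cc - pc) * dc
    return in_cell & (side >= 0), in_cell & (side < 0)


def posterior_intensity_fraction(
    image, rois: RoiPair
) -> float:
    """Fraction of total within-cell pixel intensity in the posterior half.

    Operates on a background-subtracted image.  Returns the convention
    value 0.5 (with a warning) when the total cell intensity is zero.
    """
    ant_mask, post_mask = roi_pair_masks(image.shape, rois)
    ant = float(image.pixels[ant_mask].sum())
    post = float(image.pixels[post_mask].sum())
    total = ant + post
    if total == 0:
        warnings.warn(
            "total cell intensity is zero; returning posterior fraction 0.5",
            stacklevel=2,
        )
        return 0.5
    return post / total
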