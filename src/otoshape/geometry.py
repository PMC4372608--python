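"""Outline geometry: smoothing, normalization, radial sampling, size descriptors.

Coordinate conventions
----------------------
Traced outlines arrive in raster coordinates (origin top-left, x right,
y down).  :func:`normalize_outline` converts to mathematical orientation
(y up) before any angle is measured, so 0 deg points right and angles
increase counter-clockwise, matching the polar-coordinate convention used
for the radial profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull


class DegenerateOutlineError(ValueError):
    """Raised when an outline has no usable area or too few points."""


def polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (last vertex not repeated)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(points: np.ndarray) -> float:
    p = np.asarray(points, dtype=float)
    d = np.roll(p, -1, axis=0) - p
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def feret_diameter(points: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Maximum caliper (pairwise point) distance of a polygon.

    Returns ``(length, p_a, p_b)`` where the two points realise the maximum.
    Uses the convex hull first (the diameter is attained on the hull), then
    an exact pairwise scan over hull vertices.
    """
    p = np.asarray(points, dtype=float)
    if len(p) < 2:
        raise DegenerateOutlineError("need at least 2 points for a Feret diameter")
    try:
        hull = ConvexHull(p)
        h = p[hull.vertices]
    except Exception:  # collinear input: fall back to the raw points
        h = p
    d2 = np.sum((h[:, None, :] - h[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return float(np.sqrt(d2[i, j])), h[i], h[j]


def feret_dimensions(points: np.ndarray) -> tuple[float, float]:
    """(Feret length, width) of a polygon.

    Width is the maximal extent along the direction perpendicular to the
    Feret-length axis; length >= width always holds.
    """
    length, pa, pb = feret_diameter(points)
    if length == 0:
        raise DegenerateOutlineError("all points coincide")
    axis = (pb - pa) / length
    perp = np.array([-axis[1], axis[0]])
    proj = np.asarray(points, dtype=float) @ perp
    return length, float(proj.max() - proj.min())


def smooth_polygon(points: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Weighted moving average over three successive coordinate points.

    Each iteration replaces vertex ``p_i`` by ``(p_{i-1} + 2 p_i + p_{i+1})/4``
    with cyclic indexing, damping pixel-scale noise while leaving straight
    segments fixed.  ``iterations`` is the number of passes applied.
    """
    p = np.asarray(points, dtype=float)
    if len(p) < 3:
        raise DegenerateOutlineError("smoothing needs at least 3 points")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    for _ in range(iterations):
        p = (np.roll(p, 1, axis=0) + 2.0 * p + np.roll(p, -1, axis=0)) / 4.0
    return p


@dataclass
class NormalizedOutline:
    """Outline centered on its coordinate centroid, longest axis horizontal,
    polygon area scaled to 1, in math orientation (y up)."""

    points: np.ndarray
    source: tuple[str, str] | None = None
    smoothing_iterations: int = 0

    @property
    def area(self) -> float:
        return abs(polygon_area(self.points))

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def normalize_outline(
    points: np.ndarray,
    *,
    flip_y: bool = True,
    source: tuple[str, str] | None = None,
    smoothing_iterations: int = 0,
) -> NormalizedOutline:
    """Center, rotate and rescale an outline for shape analysis.

    Steps: optional raster-to-math flip of the y axis; translate the
    coordinate centroid (mean of the outline x and y coordinates) to the
    origin; rotate so the longest axis (maximum Feret diameter direction)
    is horizontal; scale uniformly so the shoelace area equals 1.  The
    180-degree ambiguity after horizontal alignment is resolved by putting
    the longer extent from the centroid on the positive-x side.
    """
    p = np.asarray(points, dtype=float).copy()
    if len(p) < 3:
        raise DegenerateOutlineError("outline needs at least 3 points")
    if flip_y:
        p[:, 1] = -p[:, 1]
    p -= p.mean(axis=0)
    area = abs(polygon_area(p))
    if area <= 0:
        raise DegenerateOutlineError("outline encloses zero area")
    _, pa, pb = feret_diameter(p)
    axis = pb - pa
    ang = np.arctan2(axis[1], axis[0]) % np.pi  # direction in [0, pi)
    c, s = np.cos(-ang), np.sin(-ang)
    rot = np.array([[c, -s], [s, c]])
    p = p @ rot.T
    if p[:, 0].max() < -p[:, 0].min():
        p = -p  # rotate by 180 deg
    p /= np.sqrt(area)
    p -= p.mean(axis=0)  # exact re-centering against round-off
    return NormalizedOutline(points=p, source=source, smoothing_iterations=smoothing_iterations)


@dataclass
class RadialProfile:
    """Centroid-to-outline distances at equidistant angles.

    ``radii[k]`` is the distance along the ray at angle ``360*k/n`` degrees,
    k = 0 on the positive-x radial, proceeding counter-clockwise.
    """

    radii: np.ndarray
    source: tuple[str, str] | None = None

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def angles_deg(self) -> np.ndarray:
        n = len(self.radii)
        return 360.0 * np.arange(n) / n


def radial_profile(
    outline: NormalizedOutline | np.ndarray,
    n_angles: int = 1024,
    *,
    warn_multi: bool = True,
) -> RadialProfile:
    """Sample the outline as radii at ``n_angles`` equidistant angles.

    The outline must contain its centroid (otoliths are near star-shaped
    about it).  Each radius is the ray-polygon intersection interpolated
    along the crossing segment; if a ray crosses several segments the
    crossing farthest from the centroid is taken (preserving the outer
    silhouette) and a warning is issued once.
    """
    if n_angles < 4 or (n_angles & (n_angles - 1)) != 0:
        raise ValueError("n_angles must be a power of two >= 4")
    src = None
    if isinstance(outline, NormalizedOutline):
        src = outline.source
        pts = outline.points - outline.points.mean(axis=0)
    else:
        pts = np.asarray(outline, dtype=float)
        pts = pts - pts.mean(axis=0)

    theta = 2.0 * np.pi * np.arange(n_angles) / n_angles
    d = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (N, 2)
    p = pts
    q = np.roll(pts, -1, axis=0)
    seg = q - p  # (M, 2)

    # cross(d, v) = d_x v_y - d_y v_x, broadcast to (N, M)
    denom = d[:, 0:1] * seg[None, :, 1] - d[:, 1:2] * seg[None, :, 0]
    num = d[:, 0:1] * p[None, :, 1] - d[:, 1:2] * p[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -num / denom
    # closed interval with epsilon so rays passing exactly through a vertex
    # are caught on at least one adjacent segment (max-of-crossings makes
    # double counting harmless)
    valid = np.isfinite(t) & (t >= -1e-9) & (t <= 1.0 + 1e-9)
    # distance along the ray at the crossing
    cross_x = p[None, :, 0] + t * seg[None, :, 0]
    cross_y = p[None, :, 1] + t * seg[None, :, 1]
    s = cross_x * d[:, 0:1] + cross_y * d[:, 1:2]
    valid &= s > 0.0
    if not valid.any(axis=1).all():
        missing = int(np.argmin(valid.any(axis=1)))
        name = f" for {src[0]}/{src[1]}" if src else ""
        raise DegenerateOutlineError(
            f"no outline crossing on the ray at {360.0 * missing / n_angles:.1f} deg"
            f"{name}; the centroid may lie outside the outline"
        )
    s_masked = np.where(valid, s, -np.inf)
    radii = s_masked.max(axis=1)
    if warn_multi:
        # a ray through a shared vertex yields two coincident crossings;
        # only genuinely distinct crossing distances indicate a
        # non-star-shaped outline
        s_min = np.where(valid, s, np.inf).min(axis=1)
        if np.any(valid.any(axis=1) & (radii - s_min > 1e-6 * np.abs(radii))):
            warnings.warn(
                "outline is not star-shaped about its centroid; "
                "taking the farthest crossing on multi-crossing rays",
                stacklevel=2,
            )
    return RadialProfile(radii=radii, source=src)


def profile_to_polygon(profile: RadialProfile | np.ndarray) -> np.ndarray:
    """Closed polygon (about the origin) from a radial profile."""
    r = profile.radii if isinstance(profile, RadialProfile) else np.asarray(profile, float)
    n = len(r)
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
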