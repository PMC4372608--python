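"""Binarization and closed-contour tracing of otolith images.

The otolith is a bright object on a dark background, so a single global
intensity threshold separates it from the background; the boundary of the
selected connected component is then traced as an ordered, closed,
8-connected pixel chain (Moore-neighbor tracing with Jacob's stopping
criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class EmptyForegroundError(ValueError):
    """Binarization produced no foreground pixels."""


class ContourError(ValueError):
    """No traceable component was found at/near the seed."""


# Rec.709 luminance weights; otolith/background contrast is high so the
# exact weights are non-critical.
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def to_gray(image: np.ndarray) -> np.ndarray:
    """Convert an image array to grayscale floats in [0, 1]."""
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    else:
        img = img.astype(float)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    return img


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold a grayscale (or color) image: foreground iff intensity > threshold.

    Raises :class:`EmptyForegroundError` when nothing exceeds the threshold
    (advising a lower threshold); warns when foreground touches the image
    border, since the traced contour may then be clipped.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    gray = to_gray(image)
    fg = gray > threshold
    if not fg.any():
        raise EmptyForegroundError(
            f"no pixel exceeds threshold {threshold}; try a lower threshold"
        )
    if fg[0, :].any() or fg[-1, :].any() or fg[:, 0].any() or fg[:, -1].any():
        warnings.warn(
            "foreground touches the image border; the contour may be clipped",
            stacklevel=2,
        )
    return fg


@dataclass
class Outline:
    """Ordered closed boundary contour in pixel coordinates.

    ``points[:, 0]`` is x (column), ``points[:, 1]`` is y (row); consecutive
    points are 8-neighbors, the first point is not repeated at the end, and
    the last point is an 8-neighbor of the first.
    """

    points: np.ndarray
    source: tuple[str, str] | None = None
    threshold_used: float | None = None

    def __len__(self) -> int:
        return len(self.points)


# Clockwise Moore neighborhood in raster coordinates (y down), as
# (dy, dx) starting from north.
_NEIGHBORS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)
_NEIGHBOR_INDEX = {tuple(v): i for i, v in enumerate(_NEIGHBORS)}


def _select_component(
    binary: np.ndarray, seed: tuple[int, int] | None, *, strict_seed: bool
) -> tuple[np.ndarray, tuple[int, int]]:
    """Pick the target connected component (8-connectivity).

    With a seed: the component containing it, else the nearest foreground
    within a search radius (error beyond it when ``strict_seed``).  Without
    a seed hit at the default image-center seed, the largest component.
    Returns the component mask and an interior pixel (y, x) of it.
    """
    lab, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise EmptyForegroundError("binary image has no foreground component")
    h, w = binary.shape
    if seed is None:
        sy, sx = h // 2, w // 2
    else:
        sx, sy = seed  # seeds are given as (x, y)
        sy, sx = int(round(sy)), int(round(sx))
        if not (0 <= sy < h and 0 <= sx < w):
            raise ContourError(f"seed {seed} lies outside the image")
    if lab[sy, sx] > 0:
        comp = lab[sy, sx]
    else:
        fg_y, fg_x = np.nonzero(lab)
        d2 = (fg_y - sy) ** 2 + (fg_x - sx) ** 2
        k = int(np.argmin(d2))
        radius = 0.25 * min(h, w)
        if strict_seed and d2[k] > radius**2:
            raise ContourError(
                f"no foreground within {radius:.0f} px of seed ({sx}, {sy})"
            )
        if strict_seed:
            comp = lab[fg_y[k], fg_x[k]]
        else:
            sizes = ndimage.sum_labels(binary, lab, index=np.arange(1, n + 1))
            comp = int(np.argmax(sizes)) + 1
            k = int(np.argmin(np.where(lab[fg_y, fg_x] == comp, d2, np.inf)))
        sy, sx = int(fg_y[k]), int(fg_x[k])
    # fill interior holes so the boundary scan cannot stop at a pinhole
    mask = ndimage.binary_fill_holes(lab == comp)
    return mask, (sy, sx)


def trace_contour(
    binary: np.ndarray,
    seed: tuple[int, int] | None = None,
    *,
    min_boundary: int = 10,
) -> Outline:
    """Trace the closed 8-connected boundary of one foreground component.

    The component is chosen by ``seed`` (x, y); without a seed the image
    center is tried and the largest component is used as fallback.  From an
    interior pixel the scan proceeds along +x to the last foreground pixel,
    which starts a clockwise Moore-neighbor trace terminated by Jacob's
    criterion (re-entering the start pixel from the initial direction).
    """
    mask, (sy, sx) = _select_component(binary, seed, strict_seed=seed is not None)
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    y, x = sy + 1, sx + 1
    while padded[y, x + 1]:
        x += 1
    start = (y, x)
    # backtrack = background pixel just right of the start
    back = (y, x + 1)

    # Moore-neighbor tracing; termination generalizes Jacob's criterion by
    # stopping as soon as the (pixel, backtrack) state repeats, which is the
    # first re-entry of a boundary pixel from the same direction.
    points = [start]
    seen = {(start, back): 0}
    cur = start
    limit = 8 * padded.size
    for _ in range(limit):
        idx = _NEIGHBOR_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        for step in range(1, 9):
            dy, dx = _NEIGHBORS[(idx + step) % 8]
            cand = (cur[0] + dy, cur[1] + dx)
            if padded[cand]:
                nxt = cand
                break
            back = cand
        if nxt is None:  # isolated pixel
            break
        state = (nxt, back)
        if state in seen:
            points = points[seen[state] :]
            break
        seen[state] = len(points)
        points.append(nxt)
        cur = nxt
    else:
        raise ContourError("contour tracing failed to terminate")

    if len(points) < min_boundary:
        raise ContourError(
            f"component boundary has only {len(points)} pixels (< {min_boundary}); "
            "likely a noise speck"
        )
    pts = np.array(points, dtype=float)[:, ::-1]  # (y, x) -> (x, y)
    pts -= 1.0  # undo padding offset
    return Outline(points=pts)
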