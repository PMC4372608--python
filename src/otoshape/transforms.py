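"""Shape descriptors: dyadic wavelet coefficients of the radial profile and
normalized elliptic Fourier descriptors (EFD) of the outline.

Wavelet pathway
---------------
The radius-vs-angle signal (1024 = 2**10 equidistant samples) is decomposed
with a full dyadic discrete wavelet transform using the Daubechies
least-asymmetric wavelet with 8 vanishing moments (``sym8``) and periodic
boundary handling, which suits a signal that is periodic in the angle by
construction.  Detail levels are numbered coarse-to-fine: level L holds
2**L coefficients, each localizing an angular window of 360/2**L degrees.
The retained descriptor is the scaling coefficient plus detail levels 0-5,
64 values in total; finer levels carry pixel-scale noise and are dropped.

Fourier pathway
---------------
The closed outline, parameterized by cumulative chord length, is expanded
in harmonic ellipses (Kuhl-Giardina).  Normalization removes size,
rotation, traversal direction and starting point, fixing a1 = 1, b1 = 0,
c1 = 0; with 12 harmonics the descriptor is the remaining 4*12 - 3 = 45
numbers, ordered (d1, a2, b2, c2, d2, ..., a12, ..., d12).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .geometry import NormalizedOutline, RadialProfile

WAVELET = "sym8"
_MODE = "periodization"
N_PROFILE = 1024
N_LEVELS = 10  # full dyadic depth for a 2**10-sample profile
RETAIN_LEVELS = 6  # detail levels 0..5 kept -> 1 + (1+2+4+8+16+32) = 64
N_WAVELET = 64
N_HARMONICS = 12
N_FOURIER = 4 * N_HARMONICS - 3  # 45


def wavelet_column_names() -> list[str]:
    return [f"W{i + 1}" for i in range(N_WAVELET)]


def fourier_column_names() -> list[str]:
    return [f"F{i + 1}" for i in range(N_FOURIER)]


def _check_profile(radii: np.ndarray) -> np.ndarray:
    r = np.asarray(radii, dtype=float)
    n = len(r)
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"profile length {n} is not a power of two")
    return r


def dwt_full(profile: RadialProfile | np.ndarray) -> list[np.ndarray]:
    """Full dyadic DWT of a radial profile, pywt coefficient layout
    ``[cA, cD_level0, cD_level1, ...]`` with level 0 the coarsest detail."""
    r = _check_profile(profile.radii if isinstance(profile, RadialProfile) else profile)
    depth = int(np.log2(len(r)))
    with warnings.catch_warnings():
        # pywt flags full-depth decompositions; with periodization the
        # transform stays orthogonal and perfectly invertible.
        warnings.simplefilter("ignore", UserWarning)
        return pywt.wavedec(r, WAVELET, mode=_MODE, level=depth)


def idwt_full(coeffs: list[np.ndarray]) -> np.ndarray:
    return pywt.waverec(coeffs, WAVELET, mode=_MODE)


@dataclass
class WaveletCoefficients:
    """64 retained wavelet descriptors of one radial profile.

    ``values[0]`` is the scaling coefficient; then detail levels 0..5 in
    coarse-to-fine order.  ``angle_map[i]`` is the nominal center angle (deg)
    the i-th coefficient localizes (NaN for the scaling coefficient).
    """

    values: np.ndarray
    source: tuple[str, str] | None = None

    @property
    def angle_map(self) -> np.ndarray:
        return wavelet_angle_map()

    def level_slice(self, level: int) -> slice:
        """Index slice of detail level ``level`` (0..5) within ``values``."""
        if not 0 <= level < RETAIN_LEVELS:
            raise ValueError(f"level must be in 0..{RETAIN_LEVELS - 1}")
        start = 1 + (2**level - 1)
        return slice(start, start + 2**level)


def wavelet_angle_map() -> np.ndarray:
    """Nominal center angle (degrees) localized by each retained coefficient."""
    angles = [np.nan]
    for level in range(RETAIN_LEVELS):
        k = np.arange(2**level)
        angles.extend(360.0 * (k + 0.5) / 2**level)
    return np.asarray(angles)


def wavelet_coefficients(
    profile: RadialProfile | np.ndarray,
    source: tuple[str, str] | None = None,
) -> WaveletCoefficients:
    """Retained 64-number wavelet descriptor of a 1024-sample radial profile."""
    coeffs = dwt_full(profile)
    if len(coeffs[0]) != 1:
        raise ValueError("full dyadic transform expected a length-1 scaling band")
    values = np.concatenate(coeffs[: RETAIN_LEVELS + 1])
    if len(values) != N_WAVELET:
        raise ValueError(
            f"profile of length {2 ** (len(coeffs) - 1)} does not yield "
            f"{N_WAVELET} retained coefficients; use a {N_PROFILE}-sample profile"
        )
    return WaveletCoefficients(values=values, source=source)


def wavelet_reconstruct(
    coeffs: WaveletCoefficients | np.ndarray | list[np.ndarray],
    level: int | None = None,
    n_out: int = N_PROFILE,
) -> np.ndarray:
    """Inverse transform keeping detail levels below ``level``.

    ``level`` counts included detail levels: 0 reconstructs from the scaling
    coefficient alone, 6 uses all levels stored in a 64-vector, 10 (with a
    full transform) reproduces the input exactly.  ``None`` keeps everything
    available.
    """
    depth = int(np.log2(n_out))
    if isinstance(coeffs, WaveletCoefficients):
        vec = coeffs.values
    elif isinstance(coeffs, np.ndarray):
        vec = np.asarray(coeffs, dtype=float)
    else:
        vec = None

    if vec is not None:
        if len(vec) != N_WAVELET:
            raise ValueError(f"expected a {N_WAVELET}-vector")
        if level is None:
            level = RETAIN_LEVELS
        if not 0 <= level <= RETAIN_LEVELS:
            raise ValueError(
                f"level must be in 0..{RETAIN_LEVELS} when reconstructing "
                "from the retained coefficients"
            )
        full = [np.array([vec[0]])]
        pos = 1
        for lv in range(depth):
            n = 2**lv
            if lv < level:
                full.append(vec[pos : pos + n].astype(float))
                pos += n
            else:
                full.append(np.zeros(n))
        return idwt_full(full)

    full_in = coeffs
    depth = len(full_in) - 1
    if level is None:
        level = depth
    if not 0 <= level <= depth:
        raise ValueError(f"level must be in 0..{depth}")
    full = [np.asarray(full_in[0], dtype=float)]
    for lv in range(depth):
        band = np.asarray(full_in[lv + 1], dtype=float)
        full.append(band if lv < level else np.zeros_like(band))
    return idwt_full(full)


# ---------------------------------------------------------------------------
# Elliptic Fourier descriptors


@dataclass
class EFD:
    """Raw elliptic Fourier decomposition of a closed outline.

    ``coeffs[h - 1] = (a_h, b_h, c_h, d_h)``;  ``a0, c0`` locate the centroid
    of the parameterized curve.
    """

    coeffs: np.ndarray  # (H, 4)
    a0: float
    c0: float

    @property
    def harmonics(self) -> int:
        return len(self.coeffs)


def efourier(outline: np.ndarray | NormalizedOutline, harmonics: int = N_HARMONICS) -> EFD:
    """Elliptic Fourier decomposition of a closed polygon.

    The curve is parameterized by cumulative chord length, making the
    coefficients robust to uneven vertex spacing from contour tracing.
    """
    pts = outline.points if isinstance(outline, NormalizedOutline) else np.asarray(outline, float)
    n = len(pts)
    if harmonics < 1:
        raise ValueError("harmonics must be >= 1")
    if n < 2 * harmonics + 1:
        raise ValueError(
            f"{n} outline points cannot support {harmonics} harmonics "
            f"(need >= {2 * harmonics + 1})"
        )
    d = np.roll(pts, -1, axis=0) - pts  # (n, 2) edge vectors, closed
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt == 0):
        keep = dt > 0
        pts = pts[keep]
        d = np.roll(pts, -1, axis=0) - pts
        dt = np.hypot(d[:, 0], d[:, 1])
    t = np.concatenate([[0.0], np.cumsum(dt)])
    big_t = t[-1]
    phi = 2.0 * np.pi * t / big_t  # (n+1,)
    h = np.arange(1, harmonics + 1)[:, None]  # (H, 1)
    dcos = np.cos(h * phi[1:]) - np.cos(h * phi[:-1])  # (H, n)
    dsin = np.sin(h * phi[1:]) - np.sin(h * phi[:-1])
    const = big_t / (2.0 * np.pi**2 * h[:, 0] ** 2)  # (H,)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    dd = const * (dsin @ vy)
    # DC terms: exact average of the piecewise-linear curve over chord length
    mid = (pts + np.roll(pts, -1, axis=0)) / 2.0
    a0 = float(np.sum(mid[:, 0] * dt) / big_t)
    c0 = float(np.sum(mid[:, 1] * dt) / big_t)
    return EFD(coeffs=np.stack([a, b, c, dd], axis=1), a0=a0, c0=c0)


def iefourier(
    efd: "EFD | FourierCoefficients | np.ndarray",
    n_points: int = 256,
    t: np.ndarray | None = None,
    harmonics: int | None = None,
) -> np.ndarray:
    """Inverse elliptic Fourier synthesis.

    ``t`` (values in [0, 1)) overrides the default uniform sampling; pass
    the original normalized chord-length parameters to compare a
    reconstruction point-to-point with its source polygon.
    """
    if isinstance(efd, FourierCoefficients):
        efd = efd.to_efd()
    if isinstance(efd, np.ndarray):
        efd = EFD(coeffs=np.asarray(efd, float), a0=0.0, c0=0.0)
    coeffs = efd.coeffs
    if harmonics is not None:
        coeffs = coeffs[:harmonics]
    if t is None:
        t = np.arange(n_points) / n_points
    phi = 2.0 * np.pi * np.asarray(t, float)[None, :]  # (1, N)
    h = np.arange(1, len(coeffs) + 1)[:, None]  # (H, 1)
    cos_t = np.cos(h * phi)
    sin_t = np.sin(h * phi)
    x = efd.a0 + coeffs[:, 0] @ cos_t + coeffs[:, 1] @ sin_t
    y = efd.c0 + coeffs[:, 2] @ cos_t + coeffs[:, 3] @ sin_t
    return np.stack([x, y], axis=1)


class DegenerateHarmonicError(ValueError):
    """First-harmonic ellipse is degenerate; normalization impossible."""


@dataclass
class FourierCoefficients:
    """Normalized elliptic Fourier descriptor (45 numbers for 12 harmonics).

    Invariant to the outline's position, size, rotation, traversal
    direction and starting point; ordered (d1, a2, b2, c2, d2, ...).
    """

    values: np.ndarray
    source: tuple[str, str] | None = None

    @property
    def harmonics(self) -> int:
        return (len(self.values) + 3) // 4

    def to_efd(self) -> EFD:
        """Re-insert the normalization-fixed a1=1, b1=0, c1=0 entries."""
        first = np.array([[1.0, 0.0, 0.0, self.values[0]]])
        rest = self.values[1:].reshape(-1, 4)
        return EFD(coeffs=np.vstack([first, rest]), a0=0.0, c0=0.0)


def _shift_start(coeffs: np.ndarray, delta: float) -> np.ndarray:
    """Coefficients after shifting the curve's starting point by phase
    ``delta`` of the first harmonic (harmonic h rotates by h*delta)."""
    h = np.arange(1, len(coeffs) + 1)
    ch, sh = np.cos(h * delta), np.sin(h * delta)
    a, b, c, d = coeffs.T
    return np.stack(
        [a * ch + b * sh, -a * sh + b * ch, c * ch + d * sh, -c * sh + d * ch], axis=1
    )


def _rotate(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Coefficients of the curve rotated by ``-psi`` (undoing orientation)."""
    cp, sp = np.cos(psi), np.sin(psi)
    a, b, c, d = coeffs.T
    return np.stack([cp * a + sp * c, cp * b + sp * d, -sp * a + cp * c, -sp * b + cp * d], axis=1)


def normalize_efd(efd: EFD, source: tuple[str, str] | None = None) -> FourierCoefficients:
    """Normalize raw EFD for size, rotation, direction and starting point.

    The starting point is moved to the first-harmonic ellipse's major axis,
    the shape rotated so that axis lies on positive x, traversal made
    counter-clockwise (d1 > 0), and all coefficients divided by the
    semi-major axis length, fixing a1 = 1 and b1 = c1 = 0 (dropped).  The
    residual 180-degree symmetry (which flips the sign of every even
    harmonic) is resolved by a deterministic lexicographic rule.
    """
    coeffs = np.asarray(efd.coeffs, dtype=float)
    a1, b1, c1, d1 = coeffs[0]
    denom = a1**2 + c1**2 - b1**2 - d1**2
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), denom)

    def candidate(delta: float) -> np.ndarray | None:
        cc = _shift_start(coeffs, delta)
        e = np.hypot(cc[0, 0], cc[0, 2])  # semi-axis length at t=0
        if e <= 0:
            return None
        psi = np.arctan2(cc[0, 2], cc[0, 0])
        cc = _rotate(cc, psi)
        if cc[0, 3] < 0:  # enforce counter-clockwise traversal
            cc[:, 1] *= -1.0
            cc[:, 3] *= -1.0
        return cc / cc[0, 0]

    # theta locates one semi-axis of the first-harmonic ellipse; pick the
    # major one, then resolve the remaining theta vs theta+pi ambiguity.
    e_theta = np.hypot(*_shift_start(coeffs[:1], theta)[0, [0, 2]])
    e_perp = np.hypot(*_shift_start(coeffs[:1], theta + np.pi / 2)[0, [0, 2]])
    if max(e_theta, e_perp) <= 1e-12 * max(1.0, np.abs(coeffs).max()):
        raise DegenerateHarmonicError("first-harmonic ellipse is degenerate")
    if e_perp > e_theta:
        theta += np.pi / 2
    v1 = candidate(theta)
    v2 = candidate(theta + np.pi)
    if v1 is None or v2 is None:
        raise DegenerateHarmonicError("first-harmonic ellipse is degenerate")
    f1, f2 = v1.ravel(), v2.ravel()
    diff = np.nonzero(np.abs(f1 - f2) > 1e-8)[0]
    chosen = v1 if len(diff) == 0 or f1[diff[0]] >= f2[diff[0]] else v2
    values = np.concatenate([[chosen[0, 3]], chosen[1:].ravel()])
    return FourierCoefficients(values=values, source=source)


def fourier_coefficients(
    outline: np.ndarray | NormalizedOutline,
    harmonics: int = N_HARMONICS,
    source: tuple[str, str] | None = None,
) -> FourierCoefficients:
    """Normalized EFD of an outline (45 values for the default 12 harmonics)."""
    return normalize_efd(efourier(outline, harmonics), source=source)
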