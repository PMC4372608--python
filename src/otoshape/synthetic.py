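"""Synthetic otolith-like projects and coefficient datasets.

Blobs are star-shaped by construction, ``r(theta) = R (1 + sum_k eps_k
cos(k theta + phi_k))``, which guarantees the radial-profile preconditions
while low-order harmonics mimic the gross otolith features (elongation,
rostrum lobe pointing left at 180 degrees).  Group structure, individual
variation and length-shape allometry are planted through the harmonic
amplitudes, so every downstream module can be exercised end-to-end with
known ground truth and no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

# Baseline otolith-like harmonic content: elongation (k=2), a left-pointing
# rostrum lobe (k=1 at 180 deg) and mild higher-order texture.
DEFAULT_HARMONICS: dict[int, tuple[float, float]] = {
    1: (0.08, np.pi),
    2: (0.15, 0.0),
    3: (0.04, 0.6),
    4: (0.03, 1.9),
}
JPEG_QUALITY = 95  # keeps compression artifacts below the binarization contrast


@dataclass
class BlobSpec:
    """Parameters of one rendered otolith-like blob.

    ``bumps`` are localized angular lobes (amplitude, center deg,
    width deg), each a Gaussian perturbation of the radial function —
    useful for planting group differences at a specific outline angle the
    way real populations differ near the postrostrum or excisura.
    """

    base_radius: float = 180.0  # px
    harmonics: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HARMONICS)
    )
    bumps: tuple[tuple[float, float, float], ...] = ()
    foreground: float = 0.8
    background: float = 0.05
    noise_sd: float = 0.02
    size: tuple[int, int] = (800, 600)  # (width, height)

    def radius(self, theta: np.ndarray) -> np.ndarray:
        r = np.ones_like(theta)
        for k, (amp, phase) in self.harmonics.items():
            r = r + amp * np.cos(k * theta + phase)
        for amp, center_deg, width_deg in self.bumps:
            delta = np.angle(np.exp(1j * (theta - np.radians(center_deg))))
            r = r + amp * np.exp(-0.5 * (np.degrees(delta) / width_deg) ** 2)
        return self.base_radius * r

    def validate(self) -> None:
        amp_sum = sum(abs(a) for a, _ in self.harmonics.values())
        amp_sum += sum(abs(b[0]) for b in self.bumps)
        if amp_sum >= 1.0:
            raise ValueError("harmonic amplitudes sum >= 1: radius would vanish")
        if self.foreground - self.background <= 3.0 * self.noise_sd:
            raise ValueError("foreground/background gap must exceed 3x noise sd")
        w, h = self.size
        margin = 3.0
        if self.base_radius * (1.0 + amp_sum) >= min(w, h) / 2.0 - margin:
            raise ValueError("blob exceeds the image frame")


def render_blob(spec: BlobSpec, seed: int, path: str | Path | None = None) -> np.ndarray:
    """Render a blob as an 8-bit image (optionally written as JPEG).

    Deterministic for a given spec and seed; the same call twice produces
    identical bytes.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    w, h = spec.size
    cx, cy = w / 2.0, h / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.arctan2(cy - yy, xx - cx)  # math orientation, y up
    rad = np.hypot(xx - cx, yy - cy)
    mask = rad <= spec.radius(theta)
    img = np.where(mask, spec.foreground, spec.background)
    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    if path is not None:
        Image.fromarray(np.repeat(img8[..., None], 3, axis=2)).save(
            path, quality=JPEG_QUALITY
        )
    return img8


@dataclass
class LengthModel:
    """Fish-length distribution and length-shape allometry."""

    mean: float = 27.5  # cm
    sd: float = 2.5
    radius_intercept_mm: float = 0.9  # otolith radius at length 0
    radius_slope_mm_per_cm: float = 0.04
    harmonic_slopes: dict[int, float] = field(default_factory=dict)  # d eps_k / d cm


def make_project(
    out_dir: str | Path,
    n_per_group: tuple[int, ...] = (65, 65, 30),
    groups: tuple[str, ...] = ("IC", "NO", "SC"),
    stations: tuple[str, ...] | None = None,
    group_effects: dict[str, dict[int, float]] | None = None,
    group_bumps: dict[str, tuple[tuple[float, float, float], ...]] | None = None,
    length_model: LengthModel | None = None,
    individual_sd: float = 0.01,
    cal: float | None = None,
    image_size: tuple[int, int] = (800, 600),
    seed: int = 0,
) -> tuple[Path, pd.DataFrame]:
    """Write a complete synthetic project: image trees plus ``FISH.csv``.

    ``group_effects`` maps group code to per-harmonic amplitude offsets
    (planted shape differences); ``length_model.harmonic_slopes`` plants
    allometric shape-length coupling; ``individual_sd`` is the per-fish
    amplitude noise.  Returns the project path and the ground-truth table
    (one row per fish with its planted parameters).
    """
    if len(n_per_group) != len(groups):
        raise ValueError("n_per_group and groups must have equal length")
    group_effects = group_effects or {}
    group_bumps = group_bumps or {}
    lm = length_model or LengthModel()
    if cal is None:
        # 90 px/mm at the reference 800x600 frame, scaled so blobs fit
        cal = round(90.0 * min(image_size[0] / 800.0, image_size[1] / 600.0), 2)
    stations = stations or tuple(str(403 + i) for i in range(len(groups)))
    out_dir = Path(out_dir)
    for sub in ("Original", "Fixed"):
        for g in groups:
            (out_dir / sub / g).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for g, station, n in zip(groups, stations, n_per_group):
        deltas = group_effects.get(g, {})
        for i in range(1, n + 1):
            picname = f"{station}_{i}"
            length = float(np.clip(rng.normal(lm.mean, lm.sd), 15.0, 45.0))
            radius_mm = lm.radius_intercept_mm + lm.radius_slope_mm_per_cm * length
            harmonics = {}
            for k, (amp, phase) in DEFAULT_HARMONICS.items():
                amp_i = (
                    amp
                    + deltas.get(k, 0.0)
                    + lm.harmonic_slopes.get(k, 0.0) * (length - lm.mean)
                    + rng.normal(0.0, individual_sd)
                )
                harmonics[k] = (amp_i, phase)
            for k, delta in deltas.items():
                if k not in harmonics:
                    harmonics[k] = (delta + rng.normal(0.0, individual_sd), 0.0)
            spec = BlobSpec(
                base_radius=radius_mm * cal,
                harmonics=harmonics,
                bumps=group_bumps.get(g, ()),
                size=image_size,
            )
            img_seed = int(rng.integers(2**31))
            img = render_blob(spec, img_seed)
            for sub in ("Original", "Fixed"):
                Image.fromarray(np.repeat(img[..., None], 3, axis=2)).save(
                    out_dir / sub / g / f"{picname}.jpg", quality=JPEG_QUALITY
                )
            rows.append(
                {"folder": g, "picname": picname, "pop": g,
                 "length_cm": round(length, 2), "cal": cal}
            )
            truth_rows.append(
                {"folder": g, "picname": picname, "pop": g, "length_cm": length,
                 "radius_mm": radius_mm, "seed": img_seed}
                | {f"eps{k}": harmonics[k][0] for k in sorted(harmonics)}
            )
    pd.DataFrame(rows).to_csv(out_dir / "FISH.csv", index=False)
    return out_dir, pd.DataFrame(truth_rows)


def make_coefficient_dataset(
    n_per_group: tuple[int, ...],
    n_coef: int = 10,
    effect_matrix: np.ndarray | None = None,
    length_slopes: np.ndarray | None = None,
    interaction_slopes: np.ndarray | None = None,
    noise_sd: float = 1.0,
    length_mean: float = 27.5,
    length_sd: float = 2.5,
    groups: tuple[str, ...] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Gaussian coefficient matrix with planted group/length structure.

    ``c_ij = effect[g, j] + (length_slopes[j] + interaction_slopes[g, j])
    * (L_i - length_mean) + N(0, noise_sd)``.  Returns (coefficients,
    group labels, lengths), deterministic per seed.
    """
    k = len(n_per_group)
    groups = groups or tuple(f"G{i + 1}" for i in range(k))
    effect = np.zeros((k, n_coef)) if effect_matrix is None else np.asarray(effect_matrix, float)
    slopes = np.zeros(n_coef) if length_slopes is None else np.asarray(length_slopes, float)
    inter = (
        np.zeros((k, n_coef))
        if interaction_slopes is None
        else np.asarray(interaction_slopes, float)
    )
    if effect.shape != (k, n_coef) or inter.shape != (k, n_coef) or len(slopes) != n_coef:
        raise ValueError("effect/interaction/slope dimensions do not match")
    rng = np.random.default_rng(seed)
    labels, lengths, blocks = [], [], []
    for g in range(k):
        n = n_per_group[g]
        ln = rng.normal(length_mean, length_sd, size=n)
        centered = (ln - length_mean)[:, None]
        block = (
            effect[g][None, :]
            + (slopes[None, :] + inter[g][None, :]) * centered
            + rng.normal(0.0, noise_sd, size=(n, n_coef))
        )
        blocks.append(block)
        labels.extend([groups[g]] * n)
        lengths.extend(ln)
    coefs = pd.DataFrame(
        np.vstack(blocks), columns=[f"C{j + 1}" for j in range(n_coef)]
    )
    return coefs, pd.Series(labels, name="pop"), pd.Series(lengths, name="length_cm")


def slope_se(n: int, noise_sd: float, length_sd: float) -> float:
    """Approximate sampling sd of a per-group length slope estimate."""
    return noise_sd / (length_sd * np.sqrt(n))
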