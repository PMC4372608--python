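"""Shared fixtures: analytic shapes and a small rendered synthetic project."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import otoshape as ot


def ellipse(a: float, b: float, n: int = 2048, phase: float = 0.0) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(n) / n + phase
    return np.stack([a * np.cos(t), b * np.sin(t)], axis=1)


def star(seed: int, n: int = 2048, base: float = 1.0) -> np.ndarray:
    """Random smooth star-shaped outline (low-order cosine perturbations)."""
    rng = np.random.default_rng(seed)
    t = 2.0 * np.pi * np.arange(n) / n
    r = np.full(n, base)
    for k in range(1, 7):
        amp = rng.uniform(0.0, 0.25 / k)
        r += base * amp * np.cos(k * t + rng.uniform(0, 2 * np.pi))
    return np.stack([r * np.cos(t), r * np.sin(t)], axis=1)


def rotate(points: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return points @ np.array([[c, s], [-s, c]])


@pytest.fixture(scope="session")
def small_project(tmp_path_factory) -> ot.ProjectStore:
    """Rendered 3-group project (22 fish) carried through the full pipeline.

    Group SC has a planted lobe at 220 deg; a mild length-shape allometry is
    planted on the elongation harmonic.
    """
    root = tmp_path_factory.mktemp("proj")
    path, _ = ot.make_project(
        root / "ShapeAnalysis",
        n_per_group=(8, 8, 6),
        groups=("IC", "NO", "SC"),
        image_size=(360, 280),
        group_bumps={"SC": ((0.06, 220.0, 6.0),)},
        length_model=ot.LengthModel(harmonic_slopes={2: 0.003}),
        seed=101,
    )
    store = ot.load_project(path, "FISH.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ot.detect_outline(store, threshold=0.2, write_overlay=True)
        ot.smooth_outlines(store, 100)
        ot.generate_shape_coefficients(store)
        ot.enrich_master_list(store)
    return store
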