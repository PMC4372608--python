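"""Calibrated size descriptors, group mean shapes and per-angle variance.

Size descriptors are computed on the raw (unnormalized) analyzed outline —
smoothed when smoothing was applied — and converted from pixels to
millimetres with the per-fish calibration ``cal`` (pixels per mm), so
lengths scale as 1/cal and areas as 1/cal^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    feret_dimensions,
    polygon_area,
    polygon_perimeter,
    profile_to_polygon,
)
from .store import ProjectStore
from .transforms import RETAIN_LEVELS, WaveletCoefficients, wavelet_reconstruct

MEASUREMENT_COLUMNS = [
    "otolith_length",
    "otolith_width",
    "otolith_perimeter",
    "otolith_area",
]


def measure_polygon(points: np.ndarray, cal: float = 1.0) -> dict[str, float]:
    """Feret length/width, perimeter and area of one outline, scaled by cal."""
    if cal <= 0:
        raise ValueError("cal must be positive")
    length, width = feret_dimensions(points)
    return {
        "otolith_length": length / cal,
        "otolith_width": width / cal,
        "otolith_perimeter": polygon_perimeter(points) / cal,
        "otolith_area": abs(polygon_area(points)) / cal**2,
    }


def get_measurements(store: ProjectStore, use_filter: bool = True) -> pd.DataFrame:
    """Per-fish otolith length, width, perimeter (mm) and area (mm^2).

    Without a ``cal`` column the measurements are returned in pixel units
    with a warning.
    """
    ml = store.master_list(use_filter)
    if ml.empty:
        raise ValueError("no active outlined records to measure")
    calibrated = store.has_cal
    if not calibrated:
        warnings.warn("no 'cal' column: measurements are in pixel units")
    rows = []
    for _, rec in ml.iterrows():
        key = (rec["folder"], rec["picname"])
        cal = float(rec["cal"]) if calibrated else 1.0
        if calibrated and (np.isnan(cal) or cal <= 0):
            raise ValueError(
                f"non-positive or missing cal for {rec['folder']}/{rec['picname']}"
            )
        rows.append(
            {"folder": rec["folder"], "picname": rec["picname"]}
            | measure_polygon(store.analysis_outline(key), cal)
        )
    return pd.DataFrame(rows)


def group_means(table: pd.DataFrame, classes) -> pd.DataFrame:
    """Arithmetic per-group means of the numeric measurement columns."""
    classes = pd.Series(np.asarray(classes), index=table.index, name="group")
    numeric = table.select_dtypes("number")
    counts = classes.value_counts()
    empty = [g for g in counts.index if counts[g] == 0]
    if empty:
        warnings.warn(f"empty group(s) omitted: {empty}")
    return numeric.groupby(classes).mean()


def mean_wavelet_shape(
    store: ProjectStore, class_column: str = "pop", use_filter: bool = True
) -> dict[str, np.ndarray]:
    """Per-group mean otolith outline from wavelet reconstruction.

    The 64-coefficient vectors are averaged within each group and inverted
    to a radial profile about the centroid; by linearity of the transform
    this equals the reconstruction of the group's mean profile.
    """
    mat, ml = store.aligned("wavelet", use_filter)
    if class_column not in ml.columns:
        raise ValueError(f"class column {class_column!r} missing")
    shapes: dict[str, np.ndarray] = {}
    for group, idx in ml.groupby(class_column).groups.items():
        vec = mat.iloc[np.asarray(idx)].to_numpy().mean(axis=0)
        radii = wavelet_reconstruct(vec, level=RETAIN_LEVELS)
        shapes[str(group)] = profile_to_polygon(radii)
    return shapes


def one_way_icc(values: np.ndarray, classes: np.ndarray) -> float:
    """Intraclass correlation from one-way random-effects variance components.

    Unequal group sizes use the n0 correction; a negative among-group
    variance estimate is truncated at 0, so 0 <= ICC <= 1.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    groups, codes = np.unique(classes, return_inverse=True)
    k = len(groups)
    if k < 2:
        raise ValueError("ICC needs at least 2 groups")
    n = len(values)
    counts = np.bincount(codes).astype(float)
    means = np.bincount(codes, weights=values) / counts
    grand = values.mean()
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[codes]) ** 2))
    msb = ss_between / (k - 1)
    msw = ss_within / (n - k)
    n0 = (n - np.sum(counts**2) / n) / (k - 1)
    sigma_a = max(0.0, (msb - msw) / n0)
    total = sigma_a + msw
    return sigma_a / total if total > 0 else 0.0


def angle_variance_icc(
    store: ProjectStore,
    level: int = 5,
    class_column: str = "pop",
    use_std: bool = True,
    use_filter: bool = True,
) -> pd.DataFrame:
    """Mean, sd, se and ICC of each wavelet detail coefficient at one level.

    Rows are ordered by the coefficient's center angle; coefficients the
    standardization screen omitted are absent when ``use_std``.
    """
    if not 0 <= level < RETAIN_LEVELS:
        raise ValueError(f"level must be in 0..{RETAIN_LEVELS - 1}")
    which = "stdwavelet" if use_std else "wavelet"
    mat, ml = store.aligned(which, use_filter)
    if class_column not in ml.columns:
        raise ValueError(f"class column {class_column!r} missing")
    classes = ml[class_column].to_numpy()
    if len(np.unique(classes)) < 2:
        raise ValueError("ICC needs at least 2 groups")
    sl = WaveletCoefficients(values=np.zeros(64)).level_slice(level)
    names = [f"W{i + 1}" for i in range(sl.start, sl.stop)]
    rows = []
    for pos, name in enumerate(names):
        if name not in mat.columns:
            continue
        vals = mat[name].to_numpy(dtype=float)
        rows.append(
            {
                "coefficient": name,
                "angle": 360.0 * (pos + 0.5) / 2**level,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "se": vals.std(ddof=1) / np.sqrt(len(vals)),
                "icc": one_way_icc(vals, classes),
            }
        )
    return pd.DataFrame(rows)
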