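"""Store-level outline detection, removal and QC overlays."""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from PIL import Image

from .contours import Outline, binarize, trace_contour
from .store import Key, ProjectStore, discover_images

logger = logging.getLogger(__name__)

OVERLAY_DIR = "Original_with_outline"
OVERLAY_COLOR = (255, 0, 0)  # pure red 1-px outline


def read_image(path: str | Path) -> np.ndarray:
    """Read a JPEG as an RGB uint8 array (H, W, 3)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def detect_outline(
    store: ProjectStore,
    threshold: float = 0.2,
    write_overlay: bool = False,
    seed_points: dict[Key, tuple[int, int]] | None = None,
) -> ProjectStore:
    """Trace outlines for every linked image that does not have one yet.

    Images are binarized at ``threshold`` (foreground = otolith brighter
    than the dark background) and the boundary of the component at the
    image center (or at the explicit per-fish seed point) is traced.
    Re-runs only process fish whose outlines were removed.  Unreadable or
    untraceable images are logged, skipped and summarized at the end.
    When ``write_overlay`` the traced outline is drawn in red on the
    ``Original/`` image and written under ``Original_with_outline/``.
    """
    seed_points = seed_points or {}
    fixed = discover_images(store, "Fixed")
    keys = [k for k in store.record_keys() if k in fixed]
    todo = [k for k in keys if k not in store.outlines]
    failures: list[tuple[Key, str]] = []
    for key in todo:
        try:
            img = read_image(fixed[key])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # border warnings summarized per run
                binary = binarize(img, threshold)
            outline = trace_contour(binary, seed=seed_points.get(key))
            outline.source = key
            outline.threshold_used = threshold
            store.outlines[key] = outline
            if write_overlay:
                write_outline_overlay(store, key)
        except Exception as exc:  # per-image fault isolation
            failures.append((key, str(exc)))
            logger.warning("outline detection failed for %s: %s", ProjectStore.key_str(key), exc)
    if failures:
        warnings.warn(
            f"outline detection failed for {len(failures)} image(s): "
            + ", ".join(ProjectStore.key_str(k) for k, _ in failures[:10])
        )
    logger.info(
        "detect_outline: %d processed, %d failed, %d total outlines",
        len(todo) - len(failures), len(failures), len(store.outlines),
    )
    store.reset_filter_if_stale()
    return store


def remove_outline(store: ProjectStore, folder: str, picname: str) -> ProjectStore:
    """Delete one fish's outline (and its derived coefficients)."""
    key = (folder, picname)
    if key not in store.outlines:
        raise KeyError(f"no outline stored for {folder}/{picname}")
    del store.outlines[key]
    store.invalidate_fish(key)
    store.reset_filter_if_stale()
    return store


def _overlay_array(store: ProjectStore, key: Key) -> np.ndarray:
    original = discover_images(store, "Original")
    if key not in original:
        raise FileNotFoundError(
            f"no Original/ image for {ProjectStore.key_str(key)}"
        )
    if key not in store.outlines:
        raise KeyError(f"no outline stored for {ProjectStore.key_str(key)}")
    img = read_image(original[key]).copy()
    pts = np.round(store.outlines[key].points).astype(int)
    x = np.clip(pts[:, 0], 0, img.shape[1] - 1)
    y = np.clip(pts[:, 1], 0, img.shape[0] - 1)
    img[y, x] = OVERLAY_COLOR
    return img


def show_original_with_outline(store: ProjectStore, folder: str, picname: str) -> np.ndarray:
    """Original image with the traced outline recolored red."""
    return _overlay_array(store, (folder, picname))


def write_outline_overlay(store: ProjectStore, key: Key) -> Path:
    """Write the QC overlay JPEG under ``Original_with_outline/<AREA>/``."""
    img = _overlay_array(store, key)
    out_dir = store.project_path / OVERLAY_DIR / key[0]
    out_dir.mkdir(parents=True, exist_ok=True)
    out_path = out_dir / f"{key[1]}.jpg"
    Image.fromarray(img).save(out_path, quality=95)
    return out_path
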