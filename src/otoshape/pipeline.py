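"""Store-level smoothing and shape-coefficient generation."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .geometry import normalize_outline, radial_profile, smooth_polygon
from .store import ProjectStore
from .transforms import (
    N_PROFILE,
    fourier_column_names,
    fourier_coefficients,
    wavelet_coefficients,
    wavelet_column_names,
)

logger = logging.getLogger(__name__)


def smooth_outlines(store: ProjectStore, iterations: int = 100) -> ProjectStore:
    """Smooth every traced outline with the 3-point weighted moving average.

    ``iterations`` is the number of smoothing passes applied to each
    outline.  Smoothed outlines are stored alongside the as-traced ones;
    all downstream analysis (coefficients, measurements) uses the smoothed
    version when present.  Already-computed coefficients are discarded so
    they get regenerated from the smoothed outlines.
    """
    if not store.outlines:
        raise ValueError("no outlines to smooth; run detect_outline first")
    for key, outline in store.outlines.items():
        store.smoothed[key] = smooth_polygon(outline.points, iterations)
    store.smoothing_iterations = iterations
    if store.coefficients:
        store.coefficients.clear()
        warnings.warn("existing coefficients discarded after smoothing; regenerate them")
    return store


def generate_shape_coefficients(
    store: ProjectStore, n_angles: int = N_PROFILE
) -> ProjectStore:
    """Compute wavelet (64) and normalized Fourier (45) descriptors per fish.

    Each outlined fish is normalized (centered, longest axis horizontal,
    area 1), sampled as a ``n_angles``-point radial profile for the wavelet
    pathway, and expanded in 12 normalized elliptic Fourier harmonics.
    Only fish missing from the matrices are processed, so re-runs after
    adding an outline are incremental; failures are logged and skipped.
    """
    if not store.outlines:
        raise ValueError("no outlines present; run detect_outline first")
    wnames, fnames = wavelet_column_names(), fourier_column_names()
    wav = store.coefficients.get("wavelet", pd.DataFrame(columns=wnames))
    fou = store.coefficients.get("fourier", pd.DataFrame(columns=fnames))
    new_w, new_f, failed = {}, {}, []
    for key in store.outlined_keys():
        ks = ProjectStore.key_str(key)
        if ks in wav.index and ks in fou.index:
            continue
        try:
            norm = normalize_outline(store.analysis_outline(key), source=key)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                profile = radial_profile(norm, n_angles)
            new_w[ks] = wavelet_coefficients(profile, source=key).values
            new_f[ks] = fourier_coefficients(norm, source=key).values
        except Exception as exc:
            failed.append(ks)
            logger.warning("coefficients failed for %s: %s", ks, exc)
    if failed:
        warnings.warn(
            f"shape coefficients failed for {len(failed)} fish: " + ", ".join(failed[:10])
        )
    if new_w:
        add = pd.DataFrame.from_dict(new_w, orient="index", columns=wnames)
        wav = add if wav.empty else pd.concat([wav, add])
    if new_f:
        add = pd.DataFrame.from_dict(new_f, orient="index", columns=fnames)
        fou = add if fou.empty else pd.concat([fou, add])
    store.coefficients["wavelet"] = wav
    store.coefficients["fourier"] = fou
    logger.info("coefficients: %d wavelet rows, %d fourier rows", len(wav), len(fou))
    return store
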