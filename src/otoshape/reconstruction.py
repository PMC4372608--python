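"""Reconstruction-quality curves: accuracy vs wavelet level / harmonic count.

Accuracy is L1-relative agreement, a bounded and interpretable metric:

* wavelet (radial domain): ``100 * (1 - sum|r_hat - r| / sum r)`` between
  the reconstructed and the original radial profile;
* Fourier (planar domain): ``100 * (1 - mean|p_hat - p| / mean radius)``
  between reconstructed and original outline points at the same
  chord-length parameters.

Both metrics are invariant to uniform rescaling of the otoliths.  The
accuracy definition is pluggable (pass another ``metric``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import normalize_outline, radial_profile
from .store import ProjectStore
from .transforms import N_PROFILE, dwt_full, efourier, iefourier, wavelet_reconstruct


@dataclass
class ReconstructionCurve:
    """Mean reconstruction accuracy across fish at each resolution step."""

    method: str  # "wavelet" | "fourier"
    x: np.ndarray  # wavelet level (0..10) or harmonic count (1..H)
    accuracy: np.ndarray  # mean percent agreement, <= 100
    per_fish: np.ndarray  # fish x len(x)


def wavelet_accuracy(radii: np.ndarray, rec: np.ndarray) -> float:
    """L1-relative agreement between profiles (percent)."""
    return 100.0 * (1.0 - np.sum(np.abs(rec - radii)) / np.sum(radii))


def wavelet_accuracy_l2(radii: np.ndarray, rec: np.ndarray) -> float:
    """L2 variant; provably monotone per fish for the orthogonal transform."""
    return 100.0 * (1.0 - np.linalg.norm(rec - radii) / np.linalg.norm(radii))


def fourier_accuracy(points: np.ndarray, rec: np.ndarray) -> float:
    """Mean point-to-point deviation relative to the mean radius (percent)."""
    mean_radius = np.mean(np.hypot(points[:, 0], points[:, 1]))
    dev = np.mean(np.hypot(*(rec - points).T))
    return 100.0 * (1.0 - dev / mean_radius)


def fourier_accuracy_l2(points: np.ndarray, rec: np.ndarray) -> float:
    rms_radius = np.sqrt(np.mean(np.sum(points**2, axis=1)))
    dev = np.sqrt(np.mean(np.sum((rec - points) ** 2, axis=1)))
    return 100.0 * (1.0 - dev / rms_radius)


_METRICS = {
    "l1": (wavelet_accuracy, fourier_accuracy),
    "l2": (wavelet_accuracy_l2, fourier_accuracy_l2),
}


def estimate_outline_reconstruction(
    store: ProjectStore,
    max_harmonics: int = 15,
    n_angles: int = N_PROFILE,
    use_filter: bool = True,
    metric: str | tuple = "l1",
) -> tuple[ReconstructionCurve, ReconstructionCurve]:
    """Accuracy curves over wavelet levels 0..10 and harmonics 1..max.

    Per fish the outline is normalized once; the wavelet curve compares
    truncated inverse transforms of the radial profile, the Fourier curve
    compares partial elliptic-Fourier syntheses with the outline itself.
    ``metric`` selects the accuracy definition: ``"l1"`` (default),
    ``"l2"`` (monotone per fish by construction), or a custom pair of
    callables ``(profile_metric, outline_metric)``.
    """
    if isinstance(metric, str):
        wav_metric, fou_metric = _METRICS[metric]
    else:
        wav_metric, fou_metric = metric
    ml = store.master_list(use_filter)
    if ml.empty:
        raise ValueError("no active outlined records")
    depth = int(np.log2(n_angles))
    wav_rows, fou_rows = [], []
    for _, rec in ml.iterrows():
        key = (rec["folder"], rec["picname"])
        norm = normalize_outline(store.analysis_outline(key), source=key)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile = radial_profile(norm, n_angles)
        full = dwt_full(profile)
        wav_rows.append(
            [
                wav_metric(profile.radii, wavelet_reconstruct(full, level))
                for level in range(depth + 1)
            ]
        )
        pts = norm.points
        efd = efourier(pts, max_harmonics)
        d = np.roll(pts, -1, axis=0) - pts
        t = np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])
        t = t[:-1] / t[-1]
        centered = pts - [efd.a0, efd.c0]
        fou_rows.append(
            [
                fou_metric(centered, iefourier(efd, t=t, harmonics=h) - [efd.a0, efd.c0])
                for h in range(1, max_harmonics + 1)
            ]
        )
    wav = np.asarray(wav_rows)
    fou = np.asarray(fou_rows)
    return (
        ReconstructionCurve("wavelet", np.arange(depth + 1), wav.mean(axis=0), wav),
        ReconstructionCurve("fourier", np.arange(1, max_harmonics + 1), fou.mean(axis=0), fou),
    )


def find_threshold_level(curve: ReconstructionCurve, target_pct: float) -> int | None:
    """Smallest x whose mean accuracy reaches the target, else None."""
    hit = np.nonzero(curve.accuracy >= target_pct)[0]
    return int(curve.x[hit[0]]) if len(hit) else None
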