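"""Project layout, metadata table and per-fish state.

A shape-analysis project is a directory holding ``Original/<AREA>/`` and
``Fixed/<AREA>/`` JPEG trees plus one CSV metadata file.  The CSV has one
row per fish; columns ``folder`` (area code, e.g. ``IC``) and ``picname``
(image stem, e.g. ``403_1``) are mandatory and link each row to its image.
``length_cm`` enables allometric standardization and ``cal`` (pixels per
mm) enables calibrated size measurements; grouping columns such as ``pop``
pass through verbatim.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import Outline

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("folder", "picname")
_STATE_VERSION = 1

Key = tuple[str, str]


class ProjectValidationError(ValueError):
    """Project layout or metadata violates the loading contract."""


@dataclass
class ProjectStore:
    """All state of one shape-analysis project.

    ``records`` is the parsed CSV (one row per fish).  ``outlines`` maps
    ``(folder, picname)`` to the traced :class:`~otoshape.contours.Outline`;
    ``smoothed`` holds smoothed point arrays for the same keys.  Coefficient
    matrices (``wavelet``, ``fourier``, ``stdwavelet``, ``stdfourier``) are
    DataFrames whose index is the ``folder/picname`` key string, one row per
    outlined-and-linked fish.  ``filter_mask`` restricts the active records.
    """

    project_path: Path
    csv_name: str
    records: pd.DataFrame
    outlines: dict[Key, Outline] = field(default_factory=dict)
    smoothed: dict[Key, np.ndarray] = field(default_factory=dict)
    smoothing_iterations: int = 0
    coefficients: dict[str, pd.DataFrame] = field(default_factory=dict)
    std_reports: dict[str, pd.DataFrame] = field(default_factory=dict)
    filter_mask: np.ndarray | None = None

    # -- capabilities -----------------------------------------------------
    @property
    def has_length(self) -> bool:
        return "length_cm" in self.records.columns

    @property
    def has_cal(self) -> bool:
        return "cal" in self.records.columns

    # -- keys and views ---------------------------------------------------
    @staticmethod
    def key_str(key: Key) -> str:
        return f"{key[0]}/{key[1]}"

    def record_keys(self) -> list[Key]:
        return list(zip(self.records["folder"], self.records["picname"]))

    def outlined_keys(self) -> list[Key]:
        """Keys of records that have an outline, in CSV record order."""
        return [k for k in self.record_keys() if k in self.outlines]

    def analysis_outline(self, key: Key) -> np.ndarray:
        """Outline points used for analysis: smoothed when available."""
        if key in self.smoothed:
            return self.smoothed[key]
        return self.outlines[key].points

    def master_list(self, use_filter: bool = True) -> pd.DataFrame:
        """Records with outlines, in record order, optionally filtered."""
        keys = self.outlined_keys()
        idx = [self.key_str(k) for k in keys]
        mask = self.records.set_index(
            self.records["folder"] + "/" + self.records["picname"]
        )
        out = mask.loc[idx].reset_index(drop=True)
        if use_filter and self.filter_mask is not None:
            out = out.loc[np.asarray(self.filter_mask, bool)].reset_index(drop=True)
        return out

    def get_coefficients(self, which: str, use_filter: bool = True) -> pd.DataFrame:
        """Coefficient matrix aligned with :meth:`master_list` rows.

        ``which`` is one of ``wavelet``, ``fourier``, ``stdwavelet``,
        ``stdfourier``.
        """
        if which not in self.coefficients:
            raise KeyError(
                f"coefficients {which!r} not available; run "
                "generate_shape_coefficients (and std_coefs for std matrices)"
            )
        mat = self.coefficients[which]
        idx = [self.key_str(k) for k in self.outlined_keys() if self.key_str(k) in mat.index]
        mat = mat.loc[idx]
        if use_filter and self.filter_mask is not None:
            mat = mat.loc[np.asarray(self.filter_mask, bool)]
        return mat

    def aligned(self, which: str, use_filter: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Coefficient matrix and master-list rows aligned on fish keys.

        Records lacking a coefficient row (failed fish) are dropped from
        both sides so rows correspond one-to-one.
        """
        if which not in self.coefficients:
            raise KeyError(
                f"coefficients {which!r} not available; run "
                "generate_shape_coefficients (and std_coefs for std matrices)"
            )
        ml = self.master_list(use_filter)
        keys = ml["folder"] + "/" + ml["picname"]
        mat = self.coefficients[which]
        present = keys.isin(mat.index).to_numpy()
        return mat.loc[keys[present]], ml.loc[present].reset_index(drop=True)

    # -- invalidation -----------------------------------------------------
    def invalidate_fish(self, key: Key) -> None:
        """Drop derived per-fish state after its outline changed."""
        self.smoothed.pop(key, None)
        ks = self.key_str(key)
        for name in list(self.coefficients):
            self.coefficients[name] = self.coefficients[name].drop(index=ks, errors="ignore")

    def reset_filter_if_stale(self) -> None:
        n = len(self.outlined_keys())
        if self.filter_mask is not None and len(self.filter_mask) != n:
            warnings.warn("active filter no longer matches the outlined records; resetting")
            self.filter_mask = None


def load_project(project_path: str | Path, csv_name: str) -> ProjectStore:
    """Load and validate a project directory and its CSV metadata.

    Requires ``Original/`` and ``Fixed/`` subfolders and the CSV (comma
    separator, semicolon auto-detected).  Missing optional columns disable
    the corresponding capabilities with a warning rather than failing.
    """
    project_path = Path(project_path)
    if not project_path.is_dir():
        raise ProjectValidationError(f"project path {project_path} does not exist")
    for sub in ("Original", "Fixed"):
        if not (project_path / sub).is_dir():
            raise ProjectValidationError(
                f"required subfolder {sub!r} is missing under {project_path}"
            )
    csv_path = project_path / csv_name
    if not csv_path.is_file():
        raise ProjectValidationError(f"metadata file {csv_path} not found")

    records = pd.read_csv(csv_path, sep=None, engine="python")
    records.columns = [str(c).strip() for c in records.columns]
    for col in MANDATORY_COLUMNS:
        if col not in records.columns:
            raise ProjectValidationError(f"mandatory column {col!r} missing from {csv_name}")
    records["folder"] = records["folder"].astype(str).str.strip()
    records["picname"] = records["picname"].astype(str).str.strip()
    dup = records.duplicated(subset=["folder", "picname"], keep=False)
    if dup.any():
        pairs = records.loc[dup, ["folder", "picname"]].drop_duplicates()
        listing = ", ".join(f"{f}/{p}" for f, p in pairs.itertuples(index=False))
        raise ProjectValidationError(f"duplicate (folder, picname) pairs: {listing}")

    for col, what in (("cal", "calibration"), ("length_cm", "fish length")):
        if col in records.columns:
            vals = pd.to_numeric(records[col], errors="coerce")
            bad = vals.notna() & (vals <= 0)
            if bad.any():
                raise ProjectValidationError(
                    f"non-positive {col} for "
                    + ", ".join(
                        f"{f}/{p}"
                        for f, p in records.loc[bad, ["folder", "picname"]].itertuples(index=False)
                    )
                )
            records[col] = vals
        else:
            warnings.warn(
                f"column {col!r} absent: {what}-dependent operations are disabled"
            )

    store = ProjectStore(project_path=project_path, csv_name=csv_name, records=records)
    _report_image_links(store)
    return store


def discover_images(store: ProjectStore, tree: str = "Fixed") -> dict[Key, Path]:
    """Eligible images (``*.jpg``/``*.jpeg``, case-insensitive) under the tree."""
    root = store.project_path / tree
    found: dict[Key, Path] = {}
    for area_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for img in sorted(area_dir.iterdir()):
            if img.suffix.lower() in (".jpg", ".jpeg"):
                found[(area_dir.name, img.stem)] = img
    return found


def _report_image_links(store: ProjectStore) -> None:
    fixed = discover_images(store, "Fixed")
    original = discover_images(store, "Original")
    keys = set(store.record_keys())
    unlisted = sorted(set(fixed) - keys)
    if unlisted:
        warnings.warn(
            f"{len(unlisted)} image(s) in Fixed/ without CSV rows (ignored): "
            + ", ".join(ProjectStore.key_str(k) for k in unlisted[:10])
        )
    missing_fixed = sorted((set(original) & keys) - set(fixed))
    if missing_fixed:
        warnings.warn(
            f"{len(missing_fixed)} image(s) present in Original/ but missing from Fixed/: "
            + ", ".join(ProjectStore.key_str(k) for k in missing_fixed[:10])
        )


def enrich_master_list(store: ProjectStore) -> ProjectStore:
    """Join records to coefficient rows on (folder, picname) and report it.

    Records lacking outlines are excluded from the joined view; orphan
    outline keys (no CSV row) are warned about.  The join itself is
    maintained lazily by :meth:`ProjectStore.master_list`; this operation
    validates and reports it, mirroring the enrich step of the original
    workflow.
    """
    if not store.outlines:
        raise ProjectValidationError("no outlines present; run detect_outline first")
    keys = set(store.record_keys())
    orphans = sorted(set(store.outlines) - keys)
    if orphans:
        warnings.warn(
            "outline keys without CSV rows: "
            + ", ".join(ProjectStore.key_str(k) for k in orphans)
        )
    matched = [k for k in store.record_keys() if k in store.outlines]
    if not matched:
        raise ProjectValidationError(
            "no outline matches any CSV row; check the folder/picname columns"
        )
    unmatched = len(store.records) - len(matched)
    logger.info("enrich: %d records matched to outlines, %d unmatched", len(matched), unmatched)
    store.reset_filter_if_stale()
    return store


def set_filter(store: ProjectStore, mask) -> ProjectStore:
    """Restrict downstream getters to the selected joined rows.

    ``mask`` is boolean with one entry per outlined record (the unfiltered
    master-list rows); pass ``None`` to clear.
    """
    if mask is None:
        store.filter_mask = None
        return store
    mask = np.asarray(mask, dtype=bool)
    n = len(store.outlined_keys())
    if len(mask) != n:
        raise ProjectValidationError(
            f"filter length {len(mask)} does not match the {n} outlined records"
        )
    store.filter_mask = mask
    return store


# ---------------------------------------------------------------------------
# Persistence: one .npz archive (outlines + coefficient matrices + metadata)


def save_project(store: ProjectStore, path: str | Path) -> None:
    """Serialize the store to a single versioned ``.npz`` archive."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "version": _STATE_VERSION,
        "project_path": str(store.project_path),
        "csv_name": store.csv_name,
        "smoothing_iterations": store.smoothing_iterations,
        "outline_keys": [list(k) for k in store.outlines],
        "outline_thresholds": [store.outlines[k].threshold_used for k in store.outlines],
        "smoothed_keys": [list(k) for k in store.smoothed],
        "coefficient_names": list(store.coefficients),
        "std_report_names": list(store.std_reports),
    }
    buf = io.StringIO()
    store.records.to_csv(buf, index=False)
    arrays["records_csv"] = np.frombuffer(buf.getvalue().encode(), dtype=np.uint8)
    for i, key in enumerate(store.outlines):
        arrays[f"outline_{i}"] = store.outlines[key].points
    for i, key in enumerate(store.smoothed):
        arrays[f"smoothed_{i}"] = store.smoothed[key]
    for name, mat in store.coefficients.items():
        arrays[f"coef_{name}"] = mat.to_numpy()
        meta[f"coef_{name}_index"] = list(mat.index)
        meta[f"coef_{name}_columns"] = list(mat.columns)
    for name, rep in store.std_reports.items():
        buf = io.StringIO()
        rep.to_csv(buf, index=False)
        arrays[f"stdrep_{name}"] = np.frombuffer(buf.getvalue().encode(), dtype=np.uint8)
    if store.filter_mask is not None:
        arrays["filter_mask"] = store.filter_mask
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez_compressed(fh, **arrays)


def load_saved_project(path: str | Path) -> ProjectStore:
    """Reload a store written by :func:`save_project` (bit-exact matrices)."""
    with np.load(Path(path)) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        if meta["version"] != _STATE_VERSION:
            raise ProjectValidationError(
                f"unsupported state version {meta['version']}"
            )
        records = pd.read_csv(io.StringIO(bytes(npz["records_csv"]).decode()))
        records["folder"] = records["folder"].astype(str)
        records["picname"] = records["picname"].astype(str)
        store = ProjectStore(
            project_path=Path(meta["project_path"]),
            csv_name=meta["csv_name"],
            records=records,
            smoothing_iterations=meta["smoothing_iterations"],
        )
        for i, (key, thr) in enumerate(
            zip(meta["outline_keys"], meta["outline_thresholds"])
        ):
            k = (key[0], key[1])
            store.outlines[k] = Outline(
                points=npz[f"outline_{i}"], source=k, threshold_used=thr
            )
        for i, key in enumerate(meta["smoothed_keys"]):
            store.smoothed[(key[0], key[1])] = npz[f"smoothed_{i}"]
        for name in meta["coefficient_names"]:
            store.coefficients[name] = pd.DataFrame(
                npz[f"coef_{name}"],
                index=meta[f"coef_{name}_index"],
                columns=meta[f"coef_{name}_columns"],
            )
        for name in meta["std_report_names"]:
            store.std_reports[name] = pd.read_csv(
                io.StringIO(bytes(npz[f"stdrep_{name}"]).decode())
            )
        if "filter_mask" in npz:
            store.filter_mask = npz["filter_mask"].astype(bool)
    return store
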