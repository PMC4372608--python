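"""Allometric length-standardization of shape coefficients.

Otolith shape covaries with fish length, so raw coefficients mix shape and
size-at-capture.  For each coefficient a linear model
``coefficient ~ length x group`` is screened: a significant
length-by-group interaction means the allometric slope differs among
groups and no single correction applies, so that coefficient is omitted.
The remaining coefficients are adjusted with the pooled common slope
``b_j`` from the additive model: ``std_ij = c_ij - b_j (L_i - Lbar)`` with
``Lbar`` the grand mean length, which removes the shared length trend while
preserving group mean differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .store import ProjectStore


@dataclass
class StandardizationResult:
    """Outcome of the interaction screen and length adjustment."""

    std_matrix: pd.DataFrame  # fish x kept coefficients
    kept: list[str]
    omitted: pd.DataFrame  # columns: coefficient, p_interaction
    p_interaction: pd.Series  # per coefficient (all, kept and omitted)
    slopes: pd.Series  # pooled length slope per kept coefficient
    alpha: float
    bonferroni: bool

    @property
    def report(self) -> pd.DataFrame:
        rep = pd.DataFrame(
            {
                "coefficient": self.p_interaction.index,
                "p_interaction": self.p_interaction.to_numpy(),
            }
        )
        rep["omitted"] = rep["coefficient"].isin(self.omitted["coefficient"]).to_numpy()
        return rep


def _designs(classes: np.ndarray, lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    groups, codes = np.unique(classes, return_inverse=True)
    counts = np.bincount(codes)
    if len(groups) < 2:
        raise ValueError("standardization needs at least 2 groups")
    if counts.min() < 3:
        small = groups[counts < 3]
        raise ValueError(
            f"group(s) {list(small)} have fewer than 3 fish; slopes are not estimable"
        )
    dummies = (codes[:, None] == np.arange(1, len(groups))[None, :]).astype(float)
    n = len(classes)
    additive = np.column_stack([np.ones(n), dummies, lengths])
    full = np.column_stack([additive, dummies * lengths[:, None]])
    return additive, full


def standardize_matrix(
    coefs: pd.DataFrame,
    classes,
    lengths,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> StandardizationResult:
    """Screen and length-adjust a fish-by-coefficient matrix.

    The interaction screen is a partial F-test of the length-by-group term
    against the additive model at level ``alpha`` (divided by the number of
    coefficients tested when ``bonferroni``).
    """
    classes = np.asarray(classes)
    lengths = np.asarray(lengths, dtype=float)
    if len(coefs) != len(classes) or len(coefs) != len(lengths):
        raise ValueError("coefficients, classes and lengths must have equal length")
    if np.isnan(lengths).any() or (lengths <= 0).any():
        raise ValueError("lengths must be present and positive for every fish")
    additive, full = _designs(classes, lengths)
    alpha_eff = alpha / coefs.shape[1] if bonferroni else alpha
    centered_l = lengths - lengths.mean()
    length_col = additive.shape[1] - 1

    kept, omitted_rows, pvals, slopes, std_cols = [], [], {}, {}, {}
    for name in coefs.columns:
        y = coefs[name].to_numpy(dtype=float)
        fit_add = sm.OLS(y, additive).fit()
        fit_full = sm.OLS(y, full).fit()
        _, p_int, _ = fit_full.compare_f_test(fit_add)
        pvals[name] = float(p_int)
        if p_int < alpha_eff:
            omitted_rows.append((name, float(p_int)))
            continue
        b = float(fit_add.params[length_col])
        kept.append(name)
        slopes[name] = b
        std_cols[name] = y - b * centered_l
    std = pd.DataFrame(std_cols, index=coefs.index)
    return StandardizationResult(
        std_matrix=std,
        kept=kept,
        omitted=pd.DataFrame(omitted_rows, columns=["coefficient", "p_interaction"]),
        p_interaction=pd.Series(pvals),
        slopes=pd.Series(slopes, dtype=float),
        alpha=alpha,
        bonferroni=bonferroni,
    )


def std_coefs(
    store: ProjectStore,
    class_column: str = "pop",
    length_column: str = "length_cm",
    bonferroni: bool = False,
    alpha: float = 0.05,
) -> ProjectStore:
    """Length-standardize both coefficient matrices of a project.

    Stores ``stdwavelet`` and ``stdfourier`` matrices (active fish only,
    honoring the filter) plus per-coefficient screening reports.
    """
    if length_column not in store.records.columns:
        raise ValueError(f"length column {length_column!r} missing from the metadata")
    if class_column not in store.records.columns:
        raise ValueError(f"class column {class_column!r} missing from the metadata")
    done = False
    for which in ("wavelet", "fourier"):
        if which not in store.coefficients:
            continue
        mat, ml = store.aligned(which)
        res = standardize_matrix(
            mat, ml[class_column], ml[length_column], alpha=alpha, bonferroni=bonferroni
        )
        store.coefficients[f"std{which}"] = res.std_matrix
        store.std_reports[which] = res.report
        done = True
    if not done:
        raise ValueError("no coefficient matrices present; run generate_shape_coefficients")
    return store
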