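"""Population statistics on coefficient matrices.

Canonical analysis of principal coordinates (CAP) on Euclidean distances
reduces to redundancy analysis: the centered coefficient matrix is
projected onto the group-indicator space and the fitted part
eigen-decomposed, giving at most (groups - 1) constrained axes.  Group
separation is tested with a distance-based permutation (pseudo-F) ANOVA,
and classification success is estimated with linear discriminant analysis
under cross-validation or bootstrap resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold

_EIG_TOL = 1e-9


def _as_matrix(coefs) -> np.ndarray:
    x = coefs.to_numpy(dtype=float) if isinstance(coefs, pd.DataFrame) else np.asarray(coefs, float)
    if x.ndim != 2:
        raise ValueError("coefficient matrix must be 2-D (fish x coefficients)")
    return x


def _group_codes(classes) -> tuple[np.ndarray, np.ndarray]:
    groups, codes = np.unique(np.asarray(classes), return_inverse=True)
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    return groups, codes


@dataclass
class CapResult:
    """Constrained ordination of fish shape coefficients by group."""

    site_scores: np.ndarray  # fish x axes, projections of the (centered) data
    lc_scores: np.ndarray  # fish x axes, projections of the fitted values
    eigenvalues: np.ndarray
    eig_ratio: np.ndarray
    groups: np.ndarray
    axis_labels: list[str]


def cap(coefs, classes) -> CapResult:
    """Canonical analysis of principal coordinates (Euclidean distances).

    Requires more specimens than coefficients, since otherwise the
    within-group structure is rank-deficient and the ordination overfits.
    """
    y = _as_matrix(coefs)
    n, p = y.shape
    if n <= p:
        raise ValueError(
            f"the number of specimens ({n}) needs to be larger than the "
            f"number of coefficients ({p})"
        )
    groups, codes = _group_codes(classes)
    k = len(groups)
    yc = y - y.mean(axis=0)
    counts = np.bincount(codes).astype(float)
    means = np.zeros((k, p))
    for g in range(k):
        means[g] = yc[codes == g].mean(axis=0)
    yfit = means[codes]
    u, s, vt = np.linalg.svd(yfit, full_matrices=False)
    rank = min(k - 1, p, int(np.sum(s > _EIG_TOL * max(1.0, s[0]))))
    eig = s[:rank] ** 2 / (n - 1)
    v = vt[:rank].T
    ratio = eig / eig.sum()
    labels = [f"CAP{i + 1} ({100 * r:.1f}%)" for i, r in enumerate(ratio)]
    return CapResult(
        site_scores=yc @ v,
        lc_scores=yfit @ v,
        eigenvalues=eig,
        eig_ratio=ratio,
        groups=groups,
        axis_labels=labels,
    )


@dataclass
class PermanovaTable:
    """Distance-based permutation ANOVA of group differences."""

    model_df: int
    residual_df: int
    model_var: float
    residual_var: float
    pseudo_f: float
    p: float
    permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.model_df, self.residual_df],
                "Var": [self.model_var, self.residual_var],
                "F": [self.pseudo_f, np.nan],
                "P": [self.p, np.nan],
            },
            index=["Model", "Residual"],
        )


def permutation_anova(
    coefs, classes, permutations: int = 1000, seed: int | None = None
) -> PermanovaTable:
    """Pseudo-F test of group separation on Euclidean distances.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + permutations)``, so the smallest
    attainable p with 1000 permutations is 1/1001 (reported as 0.001).
    Variances are sums of squares divided by n - 1.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    y = _as_matrix(coefs)
    n = len(y)
    groups, codes = _group_codes(classes)
    k = len(groups)
    yc = y - y.mean(axis=0)
    ss_total = float(np.sum(yc**2))

    def model_ss(codes_: np.ndarray) -> float:
        ss = 0.0
        for g in range(k):
            sel = yc[codes_ == g]
            ss += np.sum(sel.sum(axis=0) ** 2) / len(sel)
        return float(ss)

    df_model, df_res = k - 1, n - k
    ss_model = model_ss(codes)
    ss_res = ss_total - ss_model
    f_obs = (ss_model / df_model) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(codes)
        ss_m = model_ss(perm)
        f_perm = (ss_m / df_model) / ((ss_total - ss_m) / df_res)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + permutations)
    return PermanovaTable(
        model_df=df_model,
        residual_df=df_res,
        model_var=ss_model / (n - 1),
        residual_var=ss_res / (n - 1),
        pseudo_f=f_obs,
        p=p,
        permutations=permutations,
    )


def cluster_plot_data(
    cap_result: CapResult, classes, conf_level: float = 0.95
) -> pd.DataFrame:
    """Group means and standard errors of the first two CAP axes.

    Feeds the cluster plot: one row per group with mean +/- 1 SE intervals;
    axis labels carry the constrained-eigenvalue percentages.
    """
    scores = cap_result.site_scores
    n_axes = min(2, scores.shape[1])
    classes = np.asarray(classes)
    rows = []
    for group in cap_result.groups:
        sel = scores[classes == group][:, :n_axes]
        m = sel.mean(axis=0)
        # population sd: SE halves exactly by sqrt(2) on duplicated samples
        # and is 0 for single-fish groups
        se = sel.std(axis=0, ddof=0) / np.sqrt(len(sel))
        row = {"group": group, "n": len(sel)}
        for a in range(n_axes):
            row[f"mean{a + 1}"] = m[a]
            row[f"se{a + 1}"] = se[a]
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["axis_labels"] = cap_result.axis_labels[:n_axes]
    out.attrs["conf_level"] = conf_level
    return out


@dataclass
class ClassificationError:
    """Misclassification-rate estimate of the LDA classifier."""

    estimator: str
    error_rate: float
    replicates: int

    @property
    def accuracy(self) -> float:
        return 1.0 - self.error_rate


def lda_error(
    coefs,
    classes,
    estimator: str = "cv",
    folds_or_reps: int | None = None,
    seed: int | None = None,
) -> ClassificationError:
    """LDA misclassification rate by cross-validation or bootstrap.

    ``cv``: k-fold (default 10; ``folds_or_reps = n`` gives leave-one-out).
    ``boot``: out-of-bag error over the replicates (default 1000).
    ``boot632``: 0.368 * apparent + 0.632 * out-of-bag.
    """
    y = _as_matrix(coefs)
    n = len(y)
    groups, codes = _group_codes(classes)
    if n - len(groups) < y.shape[1]:
        raise ValueError(
            "too few fish for a stable within-group covariance; use fewer "
            "coefficients or more fish"
        )
    rng = np.random.default_rng(seed)

    def fit_predict(train, test) -> np.ndarray:
        model = LinearDiscriminantAnalysis()
        model.fit(y[train], codes[train])
        return model.predict(y[test])

    if estimator == "cv":
        folds = folds_or_reps or 10
        if folds < 2 or folds > n:
            raise ValueError("folds must be between 2 and n")
        counts = np.bincount(codes)
        if counts.min() < 2:
            raise ValueError("each group needs at least 2 members for cv")
        kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
        wrong = 0
        for train, test in kf.split(y):
            wrong += int(np.sum(fit_predict(train, test) != codes[test]))
        return ClassificationError("cv", wrong / n, folds)

    if estimator in ("boot", "boot632"):
        reps = folds_or_reps or 1000
        wrong = total = 0
        for _ in range(reps):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            if len(oob) == 0 or len(np.unique(codes[boot])) < 2:
                continue
            wrong += int(np.sum(fit_predict(boot, oob) != codes[oob]))
            total += len(oob)
        oob_err = wrong / total if total else np.nan
        if estimator == "boot":
            return ClassificationError("boot", oob_err, reps)
        model = LinearDiscriminantAnalysis().fit(y, codes)
        apparent = float(np.mean(model.predict(y) != codes))
        return ClassificationError("boot632", 0.368 * apparent + 0.632 * oob_err, reps)

    raise ValueError(f"unknown estimator {estimator!r}")
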