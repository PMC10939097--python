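"""Per-feature univariate screens and multivariate models for biomarker discovery.

Implements the statistical toolbox applied to region x feature intensity
matrices: Student's t test with fold changes and BH correction, ROC/AUC
discrimination screening, ICC reproducibility across replicate acquisitions
(two-way mixed model, consistency, average measures — ICC(C,k)), PCA, and
PLS-DA with VIP scores plus the VIP/loading biomarker gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

#: ICC reproducibility bands: >=0.75 excellent, 0.60-0.75 good,
#: 0.40-0.60 fair, <0.40 poor.
ICC_BANDS = ((0.75, "excellent"), (0.60, "good"), (0.40, "fair"))

#: AUC window considered discriminative (two-sided reading of the
#: one-directional 0.7 threshold).
AUC_DISCRIMINATIVE = 0.7


def _split_groups(M: np.ndarray, groups, group_a=None, group_b=None):
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValidationError(f"need exactly two groups, got {list(uniq)}")
    if group_a is None or group_b is None:
        group_a, group_b = uniq
    A = M[groups == group_a]
    B = M[groups == group_b]
    if len(A) < 1 or len(B) < 1:
        raise ValidationError("both groups must be nonempty")
    return A, B, group_a, group_b


# ---------------------------------------------------------------------------
# Univariate screens
# ---------------------------------------------------------------------------

def ttest_features(M, groups, feature_names=None, group_a=None, group_b=None,
                   welch: bool = False) -> pd.DataFrame:
    """Two-sample t test per feature on a sample x feature matrix.

    Student's pooled-variance t by default (``welch=True`` switches to the
    unequal-variance form). Returns a DataFrame with group means, log2 fold
    change (NaN when a mean is non-positive), t, two-sided p, and
    Benjamini-Hochberg adjusted p across features. Features that are
    constant and equal in both groups get t = 0, p = 1.
    """
    M = np.asarray(M, dtype=float)
    A, B, ga, gb = _split_groups(M, groups, group_a, group_b)
    if len(A) < 2 or len(B) < 2:
        raise ValidationError("need >= 2 samples per group for a t test")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sstats.ttest_ind(A, B, axis=0, equal_var=not welch)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate & np.isclose(mean_a, mean_b), 0.0, t)
    p = np.where(degenerate & np.isclose(mean_a, mean_b), 1.0, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.where((mean_a > 0) & (mean_b > 0),
                          np.log2(np.maximum(mean_a, 1e-300) /
                                  np.maximum(mean_b, 1e-300)), np.nan)
    finite = np.isfinite(p)
    p_adj = np.full_like(p, np.nan, dtype=float)
    if finite.any():
        p_adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
    if feature_names is None:
        feature_names = np.arange(M.shape[1])
    return pd.DataFrame({
        "feature": np.asarray(feature_names),
        "mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc,
        "t": t, "p": p, "p_adj": p_adj,
    }).assign(group_a=ga, group_b=gb)


def auc_features(M, groups, positive_group=None, feature_names=None,
                 threshold: float = AUC_DISCRIMINATIVE) -> pd.DataFrame:
    """Per-feature ROC AUC for discriminating the positive group.

    AUC is the Mann-Whitney U statistic normalized by n1*n2, computed with
    midranks so ties contribute 1/2. A feature is flagged ``discriminative``
    when AUC >= ``threshold`` or AUC <= 1 - ``threshold`` (direction depends
    only on which group is called positive).
    """
    M = np.asarray(M, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValidationError(f"need exactly two groups, got {list(uniq)}")
    if positive_group is None:
        positive_group = uniq[0]
    pos = groups == positive_group
    n1, n2 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be nonempty")
    ranks = sstats.rankdata(M, axis=0)  # midranks along samples
    r1 = ranks[pos].sum(axis=0)
    auc = (r1 - n1 * (n1 + 1) / 2) / (n1 * n2)
    if feature_names is None:
        feature_names = np.arange(M.shape[1])
    return pd.DataFrame({
        "feature": np.asarray(feature_names),
        "auc": auc,
        "discriminative": (auc >= threshold) | (auc <= 1 - threshold),
    })


def icc_band(icc: float) -> str:
    if not np.isfinite(icc):
        return "undefined"
    for lo, name in ICC_BANDS:
        if icc >= lo:
            return name
    return "poor"


def icc_ck(matrix) -> float:
    """ICC(C,k): two-way mixed model, consistency, average measures.

    ``matrix`` is targets x raters (e.g. tissue regions x replicate
    acquisitions), complete. From the two-way ANOVA decomposition without
    interaction, ICC(C,k) = (MS_T - MS_E) / MS_T where MS_T is the
    between-target and MS_E the residual mean square. Returns NaN (with a
    warning) when MS_T is zero.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("need a targets x raters matrix, >= 2 each")
    if not np.all(np.isfinite(X)):
        raise ValidationError("ICC requires a complete matrix")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_t = k * np.sum((row_means - grand) ** 2)
    resid = X - row_means[:, None] - col_means[None, :] + grand
    ss_e = np.sum(resid ** 2)
    ms_t = ss_t / (n - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    if ms_t == 0:
        warnings.warn("no between-target variance: ICC undefined", stacklevel=2)
        return float("nan")
    return float((ms_t - ms_e) / ms_t)


def icc_features(matrices, feature_names=None) -> pd.DataFrame:
    """ICC(C,k) and reproducibility band per feature.

    ``matrices`` is a (n_features, n_targets, k_raters) array or a sequence
    of targets x raters matrices, one per feature.
    """
    matrices = [np.asarray(m, dtype=float) for m in matrices]
    iccs = np.array([icc_ck(m) for m in matrices])
    if feature_names is None:
        feature_names = np.arange(len(matrices))
    return pd.DataFrame({
        "feature": np.asarray(feature_names),
        "icc": iccs,
        "icc_band": [icc_band(v) for v in iccs],
    })


# ---------------------------------------------------------------------------
# Multivariate models
# ---------------------------------------------------------------------------

def pca(M, n_components: int = 2):
    """Column-centered SVD principal components.

    Returns (scores, loadings, explained_variance_ratio). The sign of each
    component is fixed so its largest-magnitude loading entry is positive,
    making the output independent of SVD implementation details.
    """
    from sklearn.decomposition import PCA

    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise ValidationError("PCA needs >= 2 samples")
    max_comp = min(M.shape[0] - 1, M.shape[1])
    if n_components > max_comp:
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)"
            f"={max_comp}")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(M)
    loadings = model.components_.T  # feature x comp
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(n_components)])
    flip[flip == 0] = 1.0
    return scores * flip, loadings * flip, model.explained_variance_ratio_


@dataclass
class PLSDAModel:
    """Fitted two-class PLS-DA with per-feature VIP scores.

    ``vip`` satisfies sum(vip^2) = number of modeled features; ``x_loadings``
    and ``weights`` are feature x component matrices over the modeled
    (non-constant) features, indexed by ``feature_names``.
    """

    n_components: int
    scores: np.ndarray
    x_loadings: np.ndarray
    weights: np.ndarray
    y_variance_per_comp: np.ndarray
    vip: np.ndarray
    feature_names: np.ndarray
    dropped_features: np.ndarray = field(default_factory=lambda: np.empty(0))


def plsda(M, groups, n_components: int = 2, feature_names=None) -> PLSDAModel:
    """PLS-DA on autoscaled X against a dummy-coded two-class response.

    Fits PLS2 (NIPALS) regression of the centered/unit-variance feature
    matrix on a 0/1 group indicator and derives VIP scores

        VIP_j = sqrt( p * sum_a w_ja^2 SSY_a / sum_a SSY_a ),

    where w_a are the unit-norm X weights and SSY_a the response variance
    captured by component a. Constant feature columns carry no direction and
    are dropped with a warning before fitting.
    """
    from sklearn.cross_decomposition import PLSRegression

    M = np.asarray(M, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValidationError("PLS-DA here supports exactly two classes")
    y = (groups == uniq[1]).astype(float)
    if feature_names is None:
        feature_names = np.arange(M.shape[1])
    feature_names = np.asarray(feature_names)

    keep = M.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} constant feature column(s)",
                      stacklevel=2)
    X = M[:, keep]
    if X.shape[1] == 0:
        raise ValidationError("no non-constant features to fit")
    n_components = min(n_components, X.shape[1], X.shape[0] - 1)

    model = PLSRegression(n_components=n_components, scale=True)
    model.fit(X, y)
    W = model.x_weights_            # p x A, unit-norm columns
    T = model.x_scores_             # n x A
    Q = model.y_loadings_.ravel()   # A
    ssy = (Q ** 2) * np.sum(T ** 2, axis=0)
    if ssy.sum() == 0:
        raise ValidationError("response carries no variance along components")
    p = X.shape[1]
    vip = np.sqrt(p * (W ** 2 @ ssy) / ssy.sum())
    return PLSDAModel(
        n_components=n_components,
        scores=T,
        x_loadings=model.x_loadings_,
        weights=W,
        y_variance_per_comp=ssy / ssy.sum(),
        vip=vip,
        feature_names=feature_names[keep],
        dropped_features=feature_names[~keep],
    )


def select_biomarkers(model: PLSDAModel, vip_min: float = 1.0,
                      loading_min: float = 0.05) -> np.ndarray:
    """Biomarker gate: VIP >= ``vip_min`` and |component-1 loading| >= ``loading_min``.

    Both thresholds are inclusive, matching the conventional "VIP >= 1 and
    loading >= 0.05" filter for PLS-DA biomarker shortlists. Returns the
    names of the retained features.
    """
    keep = (model.vip >= vip_min) & (np.abs(model.x_loadings[:, 0]) >= loading_min)
    return model.feature_names[keep]
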