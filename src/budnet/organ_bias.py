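"""Organ-bias classification and projection PCA.

Each gene's log2 expression is fitted with a linear model

    expression ~ intercept + Condition + Timepoint(categorical)

where Condition distinguishes flower from vegetative buds (coded so the
coefficient is flower minus vegetative) and the categorical Timepoint
absorbs temporal variation. Genes are classified flower-biased /
vegetative-biased / balanced from the Condition coefficient and its
BH-adjusted p-value. A PCA is then computed over the genes expressed in
both organs ("shared" genes, one observation per gene, features = organ x
timepoint mean expression by default); organ-specific genes are projected
into the same space, and PC1 scores are correlated with the Condition
coefficient.

Sign convention: coef_condition > 0 means higher expression in flower
buds. Flipping the organ encoding flips both coef_condition and the
PC1-coefficient correlation; |r| is invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix
from .expression_prep import bh_adjust

DEFAULT_COEF_MIN = math.log2(1.5)


def fit_condition_model(
    expr: pd.DataFrame,
    condition: pd.Series | np.ndarray,
    timepoint: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Per-gene least-squares fit of expression on Condition + Timepoint.

    ``expr`` is genes x samples (log2 scale); ``condition`` holds
    "flower"/"vegetative" labels and ``timepoint`` the categorical
    timepoint per sample. Returns a DataFrame indexed by gene with
    ``coef_condition`` (flower minus vegetative, log2 units) and
    ``p_condition`` (two-sided t-test on that coefficient).
    """
    cond = np.asarray(condition).astype(str)
    tp = np.asarray(timepoint)
    organs = set(cond)
    if not {"flower", "vegetative"} <= organs:
        raise ValueError("both 'flower' and 'vegetative' samples are required")
    levels = list(pd.unique(tp))
    if len(levels) < 2:
        raise ValueError("at least two timepoints are required")

    flower = (cond == "flower").astype(float)
    dummies = [(tp == t).astype(float) for t in levels[1:]]
    X = np.column_stack([np.ones_like(flower), flower] + dummies)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design: organ is confounded with timepoint")

    Y = expr.to_numpy(dtype=float).T  # samples x genes
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # params x genes
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough samples for the design")
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    coef = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return pd.DataFrame(
        {"coef_condition": coef, "p_condition": p}, index=expr.index
    )


def classify_bias(
    coef,
    p,
    coef_min: float = DEFAULT_COEF_MIN,
    alpha: float = 0.05,
):
    """Map (coefficient, adjusted p) to flower / vegetative / balanced.

    Flower-biased if coef >= +coef_min with p < alpha; vegetative-biased if
    coef <= -coef_min with p < alpha; balanced otherwise. The coefficient
    boundary is inclusive. Accepts scalars or aligned arrays.
    """
    coef_arr = np.atleast_1d(np.asarray(coef, dtype=float))
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    cat = np.full(coef_arr.shape, "balanced", dtype=object)
    sig = p_arr < alpha
    cat[(coef_arr >= coef_min - 1e-12) & sig] = "flower"
    cat[(coef_arr <= -coef_min + 1e-12) & sig] = "vegetative"
    if np.isscalar(coef) or np.asarray(coef).ndim == 0:
        return str(cat[0])
    return cat


def organ_specificity(
    expr: pd.DataFrame,
    condition: pd.Series | np.ndarray,
    min_expr: float = 1.0,
    min_samples: int = 2,
) -> pd.Series:
    """Shared / flower_specific / vegetative_specific per gene.

    A gene is present in an organ if its expression is >= ``min_expr``
    (CPM-scale by convention) in at least ``min_samples`` samples of that
    organ; specific means present in exactly one organ. Presence is
    independent of the bias category.
    """
    cond = np.asarray(condition).astype(str)
    x = expr.to_numpy(dtype=float)
    present = {}
    for organ in ("flower", "vegetative"):
        cols = cond == organ
        present[organ] = (x[:, cols] >= min_expr).sum(axis=1) >= min_samples
    out = np.full(x.shape[0], "shared", dtype=object)
    out[present["flower"] & ~present["vegetative"]] = "flower_specific"
    out[~present["flower"] & present["vegetative"]] = "vegetative_specific"
    out[~present["flower"] & ~present["vegetative"]] = "absent"
    return pd.Series(out, index=expr.index, name="specificity")


def bias_table(
    matrix: ExpressionMatrix,
    coef_min: float = DEFAULT_COEF_MIN,
    alpha: float = 0.05,
    presence_expr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit, BH-adjust and classify every gene of a log2 matrix.

    ``presence_expr`` optionally supplies a CPM-scale matrix for the
    specificity call (defaults to 2**log2-values of the input).
    """
    meta = matrix.sample_meta
    if meta is None:
        raise ValueError("sample metadata with organ and timepoint is required")
    fit = fit_condition_model(matrix.values, meta["organ"], meta["timepoint"])
    fit["p_adj"] = bh_adjust(fit["p_condition"])
    fit["category"] = classify_bias(fit["coef_condition"], fit["p_adj"], coef_min, alpha)
    pres = presence_expr if presence_expr is not None else 2.0 ** matrix.values - 1.0
    fit["specificity"] = organ_specificity(pres, meta["organ"])
    return fit


# ----------------------------------------------------------------- PCA part
def _row_zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


@dataclass
class PCAModel:
    """Centered PCA over genes-as-observations with projection support.

    When ``scale_genes_`` is set, each gene's feature vector is z-scored
    across features before centering — removing the overall-abundance
    component so the leading PCs describe profile shape (the organ and
    time structure), not expression level. Projection applies the same
    per-gene scaling, which depends only on the projected gene itself, so
    training genes projected through :meth:`project` reproduce their
    stored scores exactly.
    """

    mean_: np.ndarray
    components_: np.ndarray  # n_components x n_features, orthonormal rows
    scores_: pd.DataFrame  # training genes x PCs
    variance_explained_: np.ndarray  # percent per component
    feature_names_: list[str]
    scale_genes_: bool = False

    def project(self, x: pd.DataFrame) -> pd.DataFrame:
        """Project new gene profiles into the trained space."""
        if x.shape[1] != self.mean_.size:
            raise ValueError(
                f"feature dimension {x.shape[1]} != training dimension {self.mean_.size}"
            )
        arr = x.to_numpy(dtype=float)
        if self.scale_genes_:
            arr = _row_zscore(arr)
        scores = (arr - self.mean_) @ self.components_.T
        cols = [f"PC{i + 1}" for i in range(self.components_.shape[0])]
        return pd.DataFrame(scores, index=x.index, columns=cols)


def group_mean_features(
    matrix: ExpressionMatrix, by: tuple[str, ...] = ("organ", "timepoint")
) -> pd.DataFrame:
    """Genes x (organ x timepoint group mean) feature matrix for PCA."""
    meta = matrix.sample_meta
    if meta is None:
        raise ValueError("sample metadata is required")
    key = meta[list(by)].astype(str).agg(":".join, axis=1)
    return matrix.values.T.groupby(key.to_numpy()).mean().T


def pca_shared(
    features: pd.DataFrame,
    n_components: int | None = None,
    scale_genes: bool = True,
) -> PCAModel:
    """PCA with genes as observations (rows) and group means as features.

    ``scale_genes`` (default) z-scores each gene's profile across features
    first, so PC1 reflects profile shape rather than overall abundance.
    """
    if features.shape[0] < 3 or features.shape[1] < 3:
        raise ValueError("need at least 3 genes and 3 feature dimensions")
    x = features.to_numpy(dtype=float)
    if scale_genes:
        x = _row_zscore(x)
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("constant feature matrix has no principal components")
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAModel(
        mean_=pca.mean_,
        components_=pca.components_,
        scores_=pd.DataFrame(scores, index=features.index, columns=cols),
        variance_explained_=pca.explained_variance_ratio_ * 100.0,
        feature_names_=list(features.columns),
        scale_genes_=scale_genes,
    )


def project_specific(model: PCAModel, features: pd.DataFrame) -> pd.DataFrame:
    """Project organ-specific genes into the shared-gene PCA space."""
    return model.project(features)


def pc_bias_correlation(pc1_scores, coef_conditions) -> tuple[float, float]:
    """Pearson correlation between PC1 scores and coef_condition.

    The sign is meaningful (it reports whether PC1 runs along the
    vegetative-to-flower axis or its mirror) and is returned as computed.
    """
    x = np.asarray(pc1_scores, dtype=float)
    y = np.asarray(coef_conditions, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in scores or coefficients")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
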