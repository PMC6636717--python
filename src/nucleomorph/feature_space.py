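"""Standardized-PCA feature space and group-separation reporting.

Pools per-nucleus feature vectors, standardizes each parameter to zero mean
and unit SD (sample, n-1 convention), computes principal components by
eigendecomposition of the sample covariance, and quantifies how well labeled
groups segregate in the low-dimensional score space (silhouette coefficient
plus leave-one-out nearest-centroid accuracy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = [
    "StandardizationParams",
    "FeatureSpaceModel",
    "SeparationReport",
    "build_feature_matrix",
    "standardize",
    "fit_pca",
    "variance_explained",
    "group_separation",
    "MORPHOMETRIC_FEATURES",
    "TEXTURAL_FEATURES",
]

#: Parameter classes for loading reports (the centre-centroid mismatch is both).
MORPHOMETRIC_FEATURES = (
    "projected_area_um2",
    "aspect_ratio",
    "perimeter_um",
    "shape_factor",
    "relative_concavity",
    "centre_centroid_mismatch_um",
)
TEXTURAL_FEATURES = (
    "centre_centroid_mismatch_um",
    "entropy_bits",
    "sd_normalized_intensities",
    "autocorrelation_length_scale_um",
)


@dataclass
class StandardizationParams:
    means: pd.Series
    sds: pd.Series
    dropped_columns: list = field(default_factory=list)


@dataclass
class FeatureSpaceModel:
    """Standardization parameters, PCA loadings, scores and variances."""

    standardization: StandardizationParams
    loadings: pd.DataFrame  # parameters x components, unit-norm columns
    scores: pd.DataFrame  # nuclei x components
    component_variances: np.ndarray  # eigenvalues, non-increasing
    variance_explained_pct: np.ndarray  # per component, sums to 100


@dataclass
class SeparationReport:
    centroids: pd.DataFrame  # group x component
    silhouette: float
    nearest_centroid_accuracy: float  # leave-one-out, in [0, 1]
    top_loadings: list  # per component: {morphometric, textural}
    n_components: int
    excluded_groups: list = field(default_factory=list)


def build_feature_matrix(
    feature_vectors: list,
    labels: list,
    impute: str = "drop",
) -> tuple:
    """Assemble a (nuclei x 9) DataFrame from FeatureVectors and apply the
    missing-length-scale policy ('drop' rows, or 'median' imputation within
    the pooled data).  Returns ``(matrix, labels_series, n_dropped)``.
    """
    rows = [fv.to_dict() for fv in feature_vectors]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES)).astype(float)
    lab = pd.Series(list(labels), name="group")
    missing = df.isna().any(axis=1)
    n_missing = int(missing.sum())
    if impute == "drop":
        df = df.loc[~missing].reset_index(drop=True)
        lab = lab.loc[~missing].reset_index(drop=True)
    elif impute == "median":
        df = df.fillna(df.median())
    else:
        raise ValueError("impute must be 'drop' or 'median'")
    return df, lab, n_missing


def standardize(matrix: pd.DataFrame) -> tuple:
    """Center each column and divide by its sample SD (n-1).

    Constant columns cannot be standardized; they are dropped with a warning.
    """
    if len(matrix) < 2:
        raise ValueError("standardization needs >= 2 rows")
    means = matrix.mean()
    sds = matrix.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}", stacklevel=2)
    kept = [c for c in matrix.columns if c not in constant]
    z = (matrix[kept] - means[kept]) / sds[kept]
    return z, StandardizationParams(means[kept], sds[kept], constant)


def fit_pca(standardized: pd.DataFrame) -> FeatureSpaceModel:
    """Principal components of the standardized matrix.

    Loadings are eigenvectors of the sample covariance ordered by descending
    eigenvalue; scores are the centered data projected on them.  Sign
    convention: each loading column is flipped so its largest-magnitude
    entry is positive, making the decomposition deterministic across runs.
    """
    n, p = standardized.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 rows")
    # contiguous copy: eigendecomposition must be bit-stable regardless of
    # the memory layout pandas hands back
    X = np.ascontiguousarray(standardized.to_numpy(dtype=float))
    X = X - X.mean(axis=0)
    cov = X.T @ X / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = X @ eigvecs
    comp_names = [f"PC{i + 1}" for i in range(p)]
    total = eigvals.sum()
    pct = 100 * eigvals / total if total > 0 else np.zeros_like(eigvals)
    return FeatureSpaceModel(
        standardization=StandardizationParams(standardized.mean(), standardized.std(ddof=1)),
        loadings=pd.DataFrame(eigvecs, index=standardized.columns, columns=comp_names),
        scores=pd.DataFrame(scores, columns=comp_names),
        component_variances=eigvals,
        variance_explained_pct=pct,
    )


def variance_explained(model: FeatureSpaceModel, k: int) -> float:
    """Cumulative percent of total variance carried by the first k components."""
    n = len(model.component_variances)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    return float(model.variance_explained_pct[:k].sum())


def _loo_nearest_centroid_accuracy(scores: np.ndarray, labels: np.ndarray) -> float:
    """Leave-one-out accuracy of nearest-centroid assignment."""
    groups = np.unique(labels)
    sums = {g: scores[labels == g].sum(axis=0) for g in groups}
    counts = {g: int((labels == g).sum()) for g in groups}
    correct = 0
    for i in range(len(labels)):
        best, best_d = None, np.inf
        for g in groups:
            if g == labels[i]:
                if counts[g] < 2:
                    continue
                centroid = (sums[g] - scores[i]) / (counts[g] - 1)
            else:
                centroid = sums[g] / counts[g]
            d = np.linalg.norm(scores[i] - centroid)
            if d < best_d:
                best, best_d = g, d
        correct += best == labels[i]
    return correct / len(labels)


def group_separation(
    model: FeatureSpaceModel, labels, n_components: int = 3
) -> SeparationReport:
    """Quantify how distinctly labeled groups occupy the score space.

    Uses the first ``n_components`` scores: per-group centroids, the
    silhouette coefficient, leave-one-out nearest-centroid accuracy, and the
    top-loading morphometric and textural parameter per component.  Groups
    with fewer than 5 nuclei are excluded with a warning.
    """
    from sklearn.metrics import silhouette_score

    labels = np.asarray(labels)
    k = min(n_components, model.scores.shape[1])
    scores = model.scores.to_numpy()[:, :k]
    groups, counts = np.unique(labels, return_counts=True)
    excluded = [g for g, c in zip(groups, counts) if c < 5]
    if excluded:
        warnings.warn(f"excluding groups below 5 nuclei: {excluded}", stacklevel=2)
    keep = ~np.isin(labels, excluded)
    scores, labels = scores[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        raise ValueError("group separation needs >= 2 groups of >= 5 nuclei")

    centroids = pd.DataFrame(
        {g: scores[labels == g].mean(axis=0) for g in np.unique(labels)},
        index=model.scores.columns[:k],
    ).T
    sil = float(silhouette_score(scores, labels))
    acc = _loo_nearest_centroid_accuracy(scores, labels)

    top = []
    for comp in model.loadings.columns[:k]:
        col = model.loadings[comp].abs()
        morpho = [f for f in MORPHOMETRIC_FEATURES if f in col.index]
        textur = [f for f in TEXTURAL_FEATURES if f in col.index]
        top.append(
            {
                "component": comp,
                "morphometric": col[morpho].idxmax() if morpho else None,
                "textural": col[textur].idxmax() if textur else None,
            }
        )
    return SeparationReport(
        centroids=centroids,
        silhouette=sil,
        nearest_centroid_accuracy=acc,
        top_loadings=top,
        n_components=k,
        excluded_groups=excluded,
    )
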