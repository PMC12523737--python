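"""Exploratory statistics on concentration profiles.

Three views of a samples × compounds concentration matrix:

* a Welch two-sample t-test (unequal variances) on per-sample total HAA,
  commercial vs homemade, with the 95% confidence interval of the mean
  difference — chosen over the pooled-variance test because the two groups
  differ in size and spread;
* principal component analysis of the (centered or autoscaled) matrix,
  with explained-variance percentages from the squared singular values;
* agglomerative hierarchical clustering (Ward or average linkage) on
  Euclidean distances of the scaled matrix, labels assigned deterministically
  in first-occurrence order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .data import CensoringPolicy, ConcentrationSet, Source, iter_profiles, totals_by_sample
from .errors import ComputationError, DegenerateFitError

__all__ = [
    "GroupComparison",
    "PCAResult",
    "ClusterResult",
    "compare_groups",
    "compare_commercial_homemade",
    "pca",
    "hcluster",
    "scale_matrix",
]


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    mean_difference: float  # mean(a) − mean(b), µg L⁻¹ when applied to totals
    ci95: tuple[float, float]
    t_stat: float
    p_value: float
    df: float


def compare_groups(
    values_a, values_b, label_a: str = "a", label_b: str = "b"
) -> GroupComparison:
    """Welch t-test on two samples with a 95% CI for the mean difference."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ComputationError(
            f"each group needs >= 2 samples, got {a.size} and {b.size}"
        )
    res = sps.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        mean_difference=float(a.mean() - b.mean()),
        ci95=(float(ci.low), float(ci.high)),
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
    )


def compare_commercial_homemade(
    cset: ConcentrationSet, policy: CensoringPolicy = CensoringPolicy.ZERO
) -> GroupComparison:
    """Commercial vs homemade Welch comparison on per-sample total HAA."""
    totals = totals_by_sample(cset, policy)
    sources = {sid: cset.sample_meta(sid).source for sid in totals.index}
    commercial = [totals[s] for s in totals.index if sources[s] is Source.COMMERCIAL]
    homemade = [totals[s] for s in totals.index if sources[s] is Source.HOMEMADE]
    return compare_groups(commercial, homemade, "commercial", "homemade")


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # variables × components
    explained_variance_pct: np.ndarray


def scale_matrix(matrix: pd.DataFrame, scaling: str = "autoscale") -> pd.DataFrame:
    """Column-wise center or autoscale (unit variance) a numeric matrix."""
    if scaling not in ("center", "autoscale"):
        raise ComputationError(f"unknown scaling {scaling!r}")
    centered = matrix - matrix.mean(axis=0)
    if scaling == "center":
        return centered
    sd = matrix.std(axis=0, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise DegenerateFitError(
            f"constant column(s) under autoscale: {', '.join(map(str, flat))}"
        )
    return centered / sd


def pca(
    matrix: pd.DataFrame,
    scaling: str = "autoscale",
    n_components: int | None = None,
) -> PCAResult:
    """PCA by singular-value decomposition of the scaled matrix."""
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ComputationError(
            f"PCA needs >= 3 samples and >= 2 variables, got {matrix.shape}"
        )
    if matrix.isna().any().any():
        raise ComputationError("PCA input contains missing cells")
    scaled = scale_matrix(matrix, scaling)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(scaled.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(model.n_components_)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(
            model.components_.T, index=matrix.columns, columns=comp_names
        ),
        explained_variance_pct=model.explained_variance_ratio_ * 100.0,
    )


def profile_pca(
    cset: ConcentrationSet,
    scaling: str = "autoscale",
    policy: CensoringPolicy = CensoringPolicy.ZERO,
) -> PCAResult:
    """PCA of the per-sample compound profiles of a concentration set."""
    return pca(iter_profiles(cset, policy), scaling=scaling)


@dataclass(frozen=True)
class ClusterResult:
    labels: pd.Series  # sample → cluster id, 0-based, first-occurrence order
    linkage_matrix: np.ndarray

    def to_tree_dict(self) -> dict:
        """Merge tree as nested dicts (leaves carry sample ids)."""
        root = hierarchy.to_tree(self.linkage_matrix)
        names = list(self.labels.index)

        def walk(node):
            if node.is_leaf():
                return {"leaf": names[node.id]}
            return {
                "height": float(node.dist),
                "left": walk(node.get_left()),
                "right": walk(node.get_right()),
            }

        return walk(root)


def hcluster(
    matrix: pd.DataFrame, linkage: str = "ward", k: int = 2
) -> ClusterResult:
    """Agglomerative clustering on Euclidean distances of the given matrix.

    Cluster ids are relabeled so the first sample (row order) gets 0, the
    next previously unseen cluster 1, and so on.
    """
    if linkage not in ("ward", "average"):
        raise ComputationError(f"unknown linkage {linkage!r}")
    n = matrix.shape[0]
    if not 1 <= k <= n:
        raise ComputationError(f"k must be in [1, {n}], got {k}")
    Z = hierarchy.linkage(matrix.to_numpy(), method=linkage, metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = []
    for value in raw:
        if value not in remap:
            remap[value] = len(remap)
        labels.append(remap[value])
    return ClusterResult(
        labels=pd.Series(labels, index=matrix.index, name="cluster"),
        linkage_matrix=Z,
    )
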