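"""Temporal pattern clustering, sample trees, and PCA.

DE genes are clustered on their per-stage profiles with agglomerative
hierarchical clustering (average linkage by default) under a
1 − Pearson-correlation distance; cutting the dendrogram at k = 6 yields the
six canonical temporal patterns (up at 30 DAT, up at 60 DAT, up between
15–90 DAT, down at 20 DAT, monotone increasing, monotone decreasing).
Cluster centroids are matched greedily one-to-one to the canonical template
shapes by Pearson correlation; a centroid correlating below 0.5 with every
remaining template stays unmatched.

Samples can be clustered the same way (columns instead of rows), and PCA
reduces the samples to a few components with a fixed sign convention (the
largest-magnitude loading of each component is positive) so scores are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA

from .io import ExpressionMatrix
from .simulate import canonical_templates

__all__ = [
    "ClusterResult",
    "hcluster",
    "cut_clusters",
    "label_templates",
    "to_newick",
    "pca_samples",
    "TemporalClusterer",
    "SamplePCA",
]

_METRICS = {"correlation", "euclidean", "precomputed"}
_LINKAGES = {"average", "complete", "single"}


def hcluster(profiles, linkage="average", metric="correlation"):
    """Agglomerative dendrogram over profile rows.

    ``profiles`` is a DataFrame (rows clustered) or, with
    ``metric="precomputed"``, a condensed distance vector.  Returns a scipy
    linkage matrix; merge order on exact distance ties follows scipy's
    deterministic lowest-index convention.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unsupported linkage {linkage!r}")
    if metric not in _METRICS:
        raise ValueError(f"unsupported metric {metric!r}")
    if metric == "precomputed":
        dists = np.asarray(profiles, dtype=float)
    else:
        arr = pd.DataFrame(profiles).to_numpy(dtype=float)
        if arr.shape[0] < 2:
            raise ValueError("need at least two profiles")
        if metric == "correlation" and (arr.std(axis=1) == 0).any():
            raise ValueError(
                "zero-variance profile under correlation metric; "
                "remove flat profiles first"
            )
        dists = pdist(arr, metric=metric)
    return hierarchy.linkage(dists, method=linkage)


@dataclass
class ClusterResult:
    """A flat cut of a dendrogram over gene expression profiles.

    ``labels`` maps each gene to a cluster id in 1..k (ids ordered by first
    appearance in the input); ``centroids`` holds the mean member profile
    per cluster; ``template_labels`` (after :func:`label_templates`) maps
    cluster id to a canonical template name or ``"unmatched"``.
    """

    labels: pd.Series
    centroids: pd.DataFrame
    linkage: np.ndarray
    leaves: pd.Index
    template_labels: dict = field(default_factory=dict)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def cut_clusters(linkage_matrix, profiles: pd.DataFrame, k=6) -> ClusterResult:
    """Cut the dendrogram into k flat clusters (the k−1 highest merges).

    Cluster ids are relabelled 1..k in order of first appearance so the
    numbering is deterministic for a fixed input order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    profiles = pd.DataFrame(profiles)
    n = profiles.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles ({n})")
    raw = hierarchy.fcluster(linkage_matrix, t=k, criterion="maxclust")
    remap, labels = {}, np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = remap.setdefault(r, len(remap) + 1)
    labels = pd.Series(labels, index=profiles.index, name="cluster")
    centroids = profiles.groupby(labels).mean()
    centroids.index.name = "cluster"
    return ClusterResult(labels=labels, centroids=centroids,
                         linkage=linkage_matrix, leaves=profiles.index)


def label_templates(result: ClusterResult, templates=None,
                    min_correlation=0.5) -> ClusterResult:
    """Greedy one-to-one assignment of cluster centroids to template shapes.

    Repeatedly takes the highest remaining centroid-template Pearson
    correlation; clusters whose best remaining correlation is below
    ``min_correlation`` are labelled ``"unmatched"``.
    """
    if templates is None:
        templates = canonical_templates(result.centroids.columns)
    templates = pd.DataFrame(templates)[result.centroids.columns]
    corr = np.full((len(result.centroids), len(templates)), -np.inf)
    for i, (_, c) in enumerate(result.centroids.iterrows()):
        for j, (_, t) in enumerate(templates.iterrows()):
            if c.std() == 0 or t.std() == 0:
                continue
            corr[i, j] = np.corrcoef(c, t)[0, 1]
    assignment = {cid: "unmatched" for cid in result.centroids.index}
    corr = corr.copy()
    while np.isfinite(corr).any() and corr.max() >= min_correlation:
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        assignment[result.centroids.index[i]] = str(templates.index[j])
        corr[i, :] = -np.inf
        corr[:, j] = -np.inf
    result.template_labels = assignment
    return result


def to_newick(linkage_matrix, leaf_names) -> str:
    """Export a dendrogram as a Newick string with merge heights as
    branch lengths."""
    tree = TreeNode.from_linkage_matrix(linkage_matrix,
                                        [str(n) for n in leaf_names])
    return str(tree)


def pca_samples(values, n_components=3):
    """PCA of samples (columns as observations over all genes).

    Components are mean-centered, ordered by explained variance, and
    sign-fixed so the largest-magnitude loading of each component is
    positive.  Returns ``(scores, explained_variance_ratio)`` with scores
    indexed by sample id.
    """
    values = values.values if isinstance(values, ExpressionMatrix) else pd.DataFrame(values)
    X = values.to_numpy(dtype=float).T           # samples x genes
    n_components = min(n_components, *X.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for i in range(n_components):
        j = np.argmax(np.abs(pca.components_[i]))
        if pca.components_[i, j] < 0:
            pca.components_[i] *= -1
            scores[:, i] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=values.columns, columns=cols),
            pca.explained_variance_ratio_.copy())


class TemporalClusterer(ClusterMixin, BaseEstimator):
    """Hierarchical clustering of temporal expression profiles.

    Parameters
    ----------
    n_clusters : int
        Number of flat clusters to cut (default 6).
    linkage : {"average", "complete", "single"}
    metric : {"correlation", "euclidean"}
        ``correlation`` is 1 − Pearson; profiles flat under this metric are
        held out of the dendrogram and assigned post hoc to the cluster
        with the nearest (Euclidean) centroid.
    templates : DataFrame, optional
        Template shapes for labelling; defaults to the six canonical ones.

    Attributes after ``fit``: ``labels_``, ``result_`` (ClusterResult),
    ``linkage_``, ``template_labels_``.
    """

    def __init__(self, n_clusters=6, linkage="average", metric="correlation",
                 templates=None, min_correlation=0.5):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.metric = metric
        self.templates = templates
        self.min_correlation = min_correlation

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        flat = X.index[X.std(axis=1, ddof=0) == 0] if self.metric == "correlation" \
            else X.index[:0]
        core = X.drop(index=flat)
        Z = hcluster(core, linkage=self.linkage, metric=self.metric)
        result = cut_clusters(Z, core, k=self.n_clusters)
        if len(flat):
            cent = result.centroids.to_numpy()
            extra = {}
            for probe in flat:
                d = ((cent - X.loc[probe].to_numpy()[None, :]) ** 2).sum(axis=1)
                extra[probe] = int(result.centroids.index[np.argmin(d)])
            result.labels = pd.concat(
                [result.labels, pd.Series(extra, name="cluster")]
            ).loc[X.index]
            result.centroids = X.groupby(result.labels).mean()
        result = label_templates(result, templates=self.templates,
                                 min_correlation=self.min_correlation)
        self.result_ = result
        self.labels_ = result.labels
        self.linkage_ = result.linkage
        self.template_labels_ = result.template_labels
        return self

    def to_newick(self) -> str:
        return to_newick(self.result_.linkage, self.result_.leaves)


class SamplePCA(BaseEstimator):
    """PCA of the sample columns with a deterministic sign convention."""

    def __init__(self, n_components=3):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.scores_, self.explained_variance_ratio_ = pca_samples(
            X, n_components=self.n_components
        )
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_
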