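"""Weighted co-expression network construction and module detection.

The construction follows the standard weighted co-expression recipe:
Pearson correlation across samples, soft-thresholding to a weighted
adjacency (unsigned ``|r|**beta`` or signed ``((1+r)/2)**beta``),
topological overlap to blend direct adjacency with shared-neighbour
structure, and average-linkage hierarchical clustering of ``1 - TOM``
with a static cut.  Clusters smaller than ``min_size`` are relabelled
gray; surviving modules are named by colour in order of decreasing size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .partition import GRAY_LABEL, ModulePartition, color_name

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "correlation_matrix",
    "soft_threshold_adjacency",
    "topological_overlap",
    "detect_modules",
    "TOMModuleDetector",
]


@dataclass
class WeightedNetwork:
    """Symmetric weighted adjacency with entries in [0, 1] and zero diagonal."""

    adjacency: np.ndarray
    gene_ids: list

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if len(self.gene_ids) != a.shape[0]:
            raise ValueError("gene_ids length must match adjacency size")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be exactly 0")
        if a.size and (a.min() < -1e-12 or a.max() > 1 + 1e-12):
            raise ValueError("adjacency entries must lie in [0, 1]")
        self.adjacency = a

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        """Weighted degree (connectivity) k_i = sum_j a_ij."""
        return self.adjacency.sum(axis=0)

    def subnetwork(self, genes) -> "WeightedNetwork":
        idx = [self.gene_ids.index(g) for g in genes]
        return WeightedNetwork(self.adjacency[np.ix_(idx, idx)], [self.gene_ids[i] for i in idx])


def correlation_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlation across samples.

    Rows with zero variance get correlation 0 to every other gene (their
    diagonal stays 1) and are reported in a warning, so a constant probe
    cannot silently contaminate the network.
    """
    values = np.asarray(data, dtype=float)
    if values.shape[1] < 3:
        raise ValueError(f"need at least 3 samples, got {values.shape[1]}")
    sd = values.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(values)
    if constant.size:
        names = [str(data.index[i]) for i in constant[:10]]
        logger.warning("zero-variance gene(s) set to correlation 0: %s", ", ".join(names))
        cor[constant, :] = 0.0
        cor[:, constant] = 0.0
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    cor = (cor + cor.T) / 2.0
    return pd.DataFrame(cor, index=data.index, columns=data.index)


def soft_threshold_adjacency(
    cor: pd.DataFrame | np.ndarray, beta: int = 6, signed: bool = False
) -> WeightedNetwork:
    """Raise correlations to a soft-thresholding power.

    unsigned: ``a_ij = |r_ij|**beta``;  signed: ``a_ij = ((1+r_ij)/2)**beta``.
    The diagonal is forced to zero.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    gene_ids = list(cor.index) if isinstance(cor, pd.DataFrame) else list(range(np.asarray(cor).shape[0]))
    c = np.asarray(cor, dtype=float)
    if signed:
        adj = ((1.0 + c) / 2.0) ** beta
    else:
        adj = np.abs(c) ** beta
    np.fill_diagonal(adj, 0.0)
    return WeightedNetwork(adjacency=adj, gene_ids=gene_ids)


def topological_overlap(network: WeightedNetwork) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), i != j,
    TOM_ii = 1.  Entries lie in [0, 1] for adjacency entries in [0, 1].
    """
    a = network.adjacency
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    dissimilarity: np.ndarray,
    gene_ids,
    min_size: int = 3,
    cut_height: float | None = None,
) -> ModulePartition:
    """Cut an average-linkage tree of a dissimilarity matrix into modules.

    ``cut_height`` is an absolute merge-height threshold in (0, 1]; when
    None it defaults to 0.99 of the maximum merge height (static cut).
    Clusters smaller than ``min_size`` are relabelled gray; the rest get
    colour names by descending size (ties broken by first gene index for
    determinism).
    """
    d = np.asarray(dissimilarity, dtype=float)
    if min_size < 2:
        raise ValueError(f"min_size must be >= 2, got {min_size}")
    if cut_height is not None and not (0.0 < cut_height <= 1.0):
        raise ValueError(f"cut_height must lie in (0, 1], got {cut_height}")
    n = d.shape[0]
    gene_ids = list(gene_ids)
    if len(gene_ids) != n:
        raise ValueError("gene_ids length must match dissimilarity size")
    dsym = (d + d.T) / 2.0
    np.fill_diagonal(dsym, 0.0)
    link = linkage(squareform(dsym, checks=False), method="average")
    height = cut_height if cut_height is not None else 0.99 * link[:, 2].max()
    raw = fcluster(link, t=height, criterion="distance")
    labels = np.full(n, GRAY_LABEL, dtype=object)
    clusters = []
    for c in np.unique(raw):
        members = np.flatnonzero(raw == c)
        if members.size >= min_size:
            clusters.append(members)
    clusters.sort(key=lambda m: (-m.size, m.min()))
    for rank, members in enumerate(clusters):
        labels[members] = color_name(rank)
    return ModulePartition(
        labels=pd.Series(labels, index=gene_ids, name="module"), min_size=min_size
    )


class TOMModuleDetector(ClusterMixin, BaseEstimator):
    """Detect co-expression modules from an expression matrix.

    Pipeline: Pearson correlation -> soft-threshold adjacency ->
    topological overlap -> average-linkage clustering of 1 - TOM ->
    static cut -> size filter with gray relabelling.

    Parameters
    ----------
    beta : int, default=6
        Soft-thresholding power (the conventional unsigned default).
    signed : bool, default=False
        Use the signed adjacency map instead of ``|r|**beta``.
    cut_height : float or None, default=None
        Static cut height on the dendrogram; None means 0.99 of the
        maximum merge height.
    min_size : int, default=3
        Minimum module size; smaller clusters become gray.

    Attributes
    ----------
    correlation_ : DataFrame of gene-gene Pearson correlations.
    network_ : WeightedNetwork (soft-thresholded adjacency).
    tom_ : ndarray, topological overlap matrix.
    partition_ : ModulePartition with colour labels.
    labels_ : ndarray of str, module label per gene (fit order).
    """

    def __init__(self, beta: int = 6, signed: bool = False,
                 cut_height: float | None = None, min_size: int = 3):
        self.beta = beta
        self.signed = signed
        self.cut_height = cut_height
        self.min_size = min_size

    def fit(self, X: pd.DataFrame, y=None):
        """Fit on a genes x samples expression DataFrame (or array)."""
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if X.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.correlation_ = correlation_matrix(X)
        self.network_ = soft_threshold_adjacency(self.correlation_, self.beta, self.signed)
        self.tom_ = topological_overlap(self.network_)
        self.partition_ = detect_modules(
            1.0 - self.tom_, list(X.index), min_size=self.min_size, cut_height=self.cut_height
        )
        self.labels_ = self.partition_.labels.values.copy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
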