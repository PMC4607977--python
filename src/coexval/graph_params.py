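"""Global topological parameters of the binarized co-expression graph.

Six parameters commonly reported for biological networks: modularity Q,
density, mean local clustering coefficient, characteristic path length,
network heterogeneity, and degree centralization.  The weighted network
is binarized at ``edge_threshold`` first; parameters that are undefined
on the resulting graph (e.g. an empty one) are reported as NaN markers,
never as zeros.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .indices import modularity_q
from .network import WeightedNetwork
from .partition import ModulePartition

logger = logging.getLogger(__name__)

__all__ = ["NetworkParameters", "binarize", "compute_network_parameters"]

PARAMETER_NAMES = (
    "modularity", "density", "clustering_coefficient",
    "characteristic_path_length", "heterogeneity", "centralization",
)


@dataclass
class NetworkParameters:
    modularity: float
    density: float
    clustering_coefficient: float
    characteristic_path_length: float
    heterogeneity: float
    centralization: float

    def as_dict(self) -> dict:
        return asdict(self)


def binarize(network: WeightedNetwork, edge_threshold: float | None = None) -> nx.Graph:
    """Simple graph with an edge wherever adjacency >= edge_threshold.

    A None threshold defaults to the median off-diagonal adjacency.
    """
    a = network.adjacency
    if edge_threshold is None:
        off = a[np.triu_indices_from(a, k=1)]
        edge_threshold = float(np.median(off)) if off.size else 0.5
    if not (0.0 < edge_threshold < 1.0):
        raise ValueError(f"edge_threshold must lie in (0, 1), got {edge_threshold}")
    g = nx.Graph()
    g.add_nodes_from(network.gene_ids)
    ii, jj = np.nonzero(np.triu(a >= edge_threshold, k=1))
    g.add_edges_from((network.gene_ids[i], network.gene_ids[j]) for i, j in zip(ii, jj))
    return g


def characteristic_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over connected ordered pairs.

    Pairs in different components are excluded rather than counted as
    infinite; NaN if no connected pair exists.
    """
    total = 0
    pairs = 0
    for node, lengths in nx.all_pairs_shortest_path_length(g):
        for other, dist in lengths.items():
            if other != node:
                total += dist
                pairs += 1
    return total / pairs if pairs else math.nan


def compute_network_parameters(
    network: WeightedNetwork,
    partition: ModulePartition,
    edge_threshold: float | None = None,
) -> NetworkParameters:
    """Compute the six global parameters on the binarized graph.

    density = 2E / (n(n-1)); clustering coefficient = mean local
    clustering over nodes of degree >= 2 (degree-<2 nodes excluded);
    heterogeneity = sd(degree)/mean(degree); centralization =
    n/(n-2) * (max(degree)/(n-1) - density); modularity = Newman-Girvan
    Q of the partition with gray genes as singleton communities.
    """
    g = binarize(network, edge_threshold)
    n = g.number_of_nodes()
    if g.number_of_edges() == 0:
        logger.warning("binarized graph has no edges; parameters undefined")
        return NetworkParameters(*([math.nan] * 6))
    density = nx.density(g)
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    local_cc = nx.clustering(g)
    eligible = [v for v, d in g.degree() if d >= 2]
    if len(eligible) < n:
        logger.info("%d node(s) of degree < 2 excluded from clustering coefficient", n - len(eligible))
    cc = float(np.mean([local_cc[v] for v in eligible])) if eligible else math.nan
    cpl = characteristic_path_length(g)
    mean_deg = degrees.mean()
    heterogeneity = float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else math.nan
    if n > 2:
        centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density)
    else:
        centralization = math.nan
    q = modularity_q(g, partition, gray_policy="singletons")
    return NetworkParameters(
        modularity=q,
        density=density,
        clustering_coefficient=cc,
        characteristic_path_length=cpl,
        heterogeneity=heterogeneity,
        centralization=float(centralization),
    )
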