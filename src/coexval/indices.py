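"""Single topological indexes for module quality.

Four stand-alone indexes: degree-distribution entropy (lower = a more
hub-dominated, better-organised module), Mpres (cross-network
preservation of intramodular connectivity), the NB value (within- vs
boundary-edge ratio; NB >= 0.5 is the conventional quality bar), and
Newman-Girvan modularity Q of a whole partition (0.3 <= Q <= 0.7 is the
conventional band for meaningful modular structure).
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
from scipy import stats

from .network import WeightedNetwork
from .partition import ModulePartition

logger = logging.getLogger(__name__)

__all__ = ["entropy_index", "mpres", "nb_value", "modularity_q", "intramodular_connectivity"]


def intramodular_connectivity(network: WeightedNetwork, module) -> np.ndarray:
    """Per-gene sum of adjacency to the other members of the module (kIM)."""
    idx = [network.gene_ids.index(g) for g in module]
    sub = network.adjacency[np.ix_(idx, idx)]
    return sub.sum(axis=0)


def entropy_index(network: WeightedNetwork, module) -> float:
    """Shannon entropy (bits) of the normalized within-module degree distribution.

    p_i = k_i / sum(k) over module members, with k_i the weighted degree
    restricted to the module; H = -sum p_i log2 p_i.  A single-member
    module or one with zero internal weight has H = 0 (warned).  Uniform
    internal degrees maximise H at log2(module size).
    """
    module = list(module)
    if not module:
        raise ValueError("module must be non-empty")
    k = intramodular_connectivity(network, module)
    total = k.sum()
    if len(module) == 1 or total == 0:
        logger.warning("module has no internal weight; entropy set to 0")
        return 0.0
    p = k / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mpres(reference_network: WeightedNetwork, test_network: WeightedNetwork, module) -> float:
    """Correlation of intramodular connectivity between two networks.

    Mpres = cor(k_ref, k_test) over the module's genes; 1 means the
    module's internal hub structure is perfectly preserved.  Returns NaN
    (an undefined marker, not 0) when either connectivity vector is
    constant.
    """
    module = list(module)
    k_ref = intramodular_connectivity(reference_network, module)
    k_test = intramodular_connectivity(test_network, module)
    if np.ptp(k_ref) == 0 or np.ptp(k_test) == 0:
        return math.nan
    return float(stats.pearsonr(k_ref, k_test)[0])


def nb_value(graph: nx.Graph, module) -> float:
    """Within-edge fraction of a module's incident edges.

    NB = E_within / (E_within + E_boundary) on a binarized graph, where a
    boundary edge has exactly one endpoint in the module.  NaN when the
    module has no incident edges at all.
    """
    members = set(module)
    if not members:
        raise ValueError("module must be non-empty")
    within = 0
    boundary = 0
    for u, v in graph.edges():
        inside = (u in members) + (v in members)
        if inside == 2:
            within += 1
        elif inside == 1:
            boundary += 1
    if within + boundary == 0:
        return math.nan
    return within / (within + boundary)


def modularity_q(
    graph: nx.Graph, partition: ModulePartition, gray_policy: str = "singletons"
) -> float:
    """Newman-Girvan modularity Q of a partition on a binarized graph.

    Q = sum_c (e_cc - a_c^2), with e_cc the fraction of edges inside
    community c and a_c the fraction of edge endpoints in c.  Gray genes
    are treated as singleton communities (``gray_policy="singletons"``)
    or dropped from the graph (``"exclude"``).
    """
    if graph.number_of_edges() == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    labels = partition.labels
    if gray_policy == "exclude":
        keep = [v for v in graph.nodes if labels.get(v, partition.gray_label) != partition.gray_label]
        graph = graph.subgraph(keep)
        if graph.number_of_edges() == 0:
            raise ValueError("no edges remain after excluding gray genes")
    elif gray_policy != "singletons":
        raise ValueError(f"gray_policy must be 'singletons' or 'exclude', got {gray_policy!r}")
    communities: dict[str, set] = {}
    for v in graph.nodes:
        lab = labels.get(v, partition.gray_label)
        if lab == partition.gray_label and gray_policy == "singletons":
            communities[f"__gray__{v}"] = {v}
        else:
            communities.setdefault(lab, set()).add(v)
    return float(nx.community.modularity(graph, communities.values()))
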