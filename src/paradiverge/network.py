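"""Thresholded weighted co-expression network of DE paralogs and TFs.

Edge weights are the soft-thresholded adjacency |r|^power (power 10 by
default) of the pairwise Pearson correlations of log expression. The display
network keeps edges with weight >= 0.3 and then nodes whose strongest
remaining correlation is >= 0.5; the full module-detection machinery of
WGCNA (minModuleSize, mergeCutHeight, dynamic tree cut) is intentionally not
reproduced — only the published network-display computation is.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, TFList

__all__ = ["build_adjacency", "threshold_network", "annotate_and_count"]

logger = logging.getLogger(__name__)


def build_adjacency(
    expression: ExpressionMatrix,
    genes: Sequence[str],
    power: int = 10,
    samples: Optional[Sequence[str]] = None,
) -> nx.Graph:
    """Weighted co-expression graph: edge weight = |pearson r|^power.

    Correlations are computed on log expression across treated samples (or an
    explicit sample list). Gene pairs with undefined correlation (zero
    variance) get no edge. Each edge stores both ``weight`` and the raw ``r``.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    if samples is None:
        samples = expression.treated_samples()
    if len(samples) < 3:
        raise ValueError("need >= 3 samples to correlate")
    genes = list(dict.fromkeys(genes))
    mat = expression.log_values(samples).loc[genes].to_numpy()
    sd = mat.std(axis=1)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    n_undefined = 0
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if sd[i] == 0.0 or sd[j] == 0.0:
                n_undefined += 1
                continue
            r = float(corr[i, j])
            graph.add_edge(genes[i], genes[j], r=r, weight=abs(r) ** power)
    if n_undefined:
        logger.info("build_adjacency: %d pair(s) with undefined correlation skipped", n_undefined)
    return graph


def threshold_network(
    adjacency: nx.Graph,
    node_r_min: float = 0.5,
    edge_w_min: float = 0.3,
) -> tuple[nx.Graph, dict]:
    """Apply the display thresholds: edges below ``edge_w_min`` first, then
    nodes whose max |r| to any retained neighbour is below ``node_r_min``.

    Returns the pruned graph and a dict of node/edge counts before and after.
    Idempotent: thresholding a thresholded network changes nothing.
    """
    graph = adjacency.copy()
    before = {"nodes": graph.number_of_nodes(), "edges": graph.number_of_edges()}
    weak_edges = [(u, v) for u, v, w in graph.edges(data="weight") if w < edge_w_min]
    graph.remove_edges_from(weak_edges)
    weak_nodes = [
        n
        for n in graph.nodes
        if not any(abs(d["r"]) >= node_r_min for _, _, d in graph.edges(n, data=True))
    ]
    graph.remove_nodes_from(weak_nodes)
    counts = {
        "nodes_before": before["nodes"],
        "edges_before": before["edges"],
        "nodes_after": graph.number_of_nodes(),
        "edges_after": graph.number_of_edges(),
    }
    if graph.number_of_nodes() == 0:
        logger.info("threshold_network: empty network after thresholding")
    return graph, counts


def annotate_and_count(
    network: nx.Graph,
    tf_list: TFList,
    dep_genes: Iterable[str],
    tf_families: Optional[Mapping[str, str]] = None,
    gene_trajectory: Optional[Mapping[str, str]] = None,
    gene_direction: Optional[Mapping[str, str]] = None,
) -> dict:
    """Annotate nodes (TF flag, trajectory, direction) and rank TF families by
    the number of DE-paralog neighbours.

    Returns a dict with ``ranking`` (DataFrame: family, tf_gene, dep_neighbors,
    sorted descending) and ``dep_tf_edges`` (DEP–TF edge counts split by the
    DEP gene's enhancing/decreasing trajectory).
    """
    dep_genes = set(dep_genes)
    tf_families = dict(tf_families or {})
    gene_trajectory = dict(gene_trajectory or {})
    gene_direction = dict(gene_direction or {})
    for node in network.nodes:
        network.nodes[node]["is_tf"] = node in tf_list
        network.nodes[node]["pattern_label"] = gene_trajectory.get(node, "none")
        network.nodes[node]["direction"] = gene_direction.get(node, "none")

    rows = []
    edge_counts = {"enhancing": 0, "decreasing": 0, "other": 0}
    for node in network.nodes:
        if node not in tf_list:
            continue
        dep_neighbors = [nb for nb in network.neighbors(node) if nb in dep_genes]
        rows.append(
            {
                "tf_gene": node,
                "family": tf_families.get(node, "unknown"),
                "dep_neighbors": len(dep_neighbors),
            }
        )
        for nb in dep_neighbors:
            label = gene_trajectory.get(nb, "other")
            edge_counts[label if label in edge_counts else "other"] += 1
    ranking = (
        pd.DataFrame(rows, columns=["tf_gene", "family", "dep_neighbors"])
        .sort_values(["dep_neighbors", "tf_gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return {"ranking": ranking, "dep_tf_edges": edge_counts}
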