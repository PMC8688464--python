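"""Protein-protein interaction thresholding and degree-hub ranking.

Scored edge tables come in two dialects: combined scores already on [0, 1],
or STRING-style integers on 0-999. Integer-style tables (any score above 1)
are normalized by dividing by 1000 before thresholding; anything outside
[0, 1] after normalization is an error.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .cerna import rank_hubs

__all__ = ["threshold_edges", "degree_hubs", "network_summary"]


def threshold_edges(
    edges: pd.DataFrame, min_score: float = 0.7
) -> nx.Graph:
    """Keep edges with combined score >= ``min_score`` (inclusive).

    ``edges`` needs columns ``protein1, protein2, combined_score``.
    Self-edges are dropped; a pair listed more than once (in either order)
    keeps its maximum score. Isolated nodes are not part of the result.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    scores = edges["combined_score"].to_numpy(float)
    if scores.size and not np.isfinite(scores).all():
        raise ValueError("non-finite combined scores")
    if scores.size and scores.max() > 1.0:
        scores = scores / 1000.0  # STRING 0-999 integer dialect
    if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
        raise ValueError("combined scores outside [0, 1] after normalization")

    best: dict[tuple[str, str], float] = {}
    for a, b, s in zip(edges["protein1"], edges["protein2"], scores):
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if s > best.get(key, -1.0):
            best[key] = s
    g = nx.Graph()
    for (a, b), s in best.items():
        if s >= min_score:
            g.add_edge(a, b, combined_score=float(s))
    return g


#: hub ranking is the same degree statistic used on the ceRNA network
degree_hubs = rank_hubs


def network_summary(network: nx.Graph) -> tuple[int, int]:
    """(node count, edge count) of the thresholded network."""
    return network.number_of_nodes(), network.number_of_edges()
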