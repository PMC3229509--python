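"""The 22 per-subgraph features: 10 graph metrics + 12 averaged node features.

Topological metrics (category T) describe the subgraph itself — node/edge
counts, eccentricity-derived diameter/radius/central points, clustering
coefficient, end-node statistics and the hop-plot exponent.  Morphological
(M) and intensity (I) features are computed per nucleus and averaged
(unweighted arithmetic mean) over the subgraph's member nuclei.

Conventions (the published description leaves them open):

* hop-plot pairs are unordered with self-pairs excluded, and the exponent is
  the least-squares slope of ``log P(h)`` against ``log h`` for
  ``h = 1..diameter``; graphs of diameter < 2 get exponent 0 with a warning
  (the regression is degenerate).
* nodes of degree < 2 contribute clustering coefficient 0.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .segment import NucleusRecord

__all__ = [
    "GRAPH_FEATURES",
    "NODE_FEATURES",
    "FEATURE_NAMES",
    "FEATURE_CATEGORIES",
    "eccentricities",
    "diameter_radius_central",
    "avg_clustering_coefficient",
    "end_node_stats",
    "hop_plot_values",
    "hop_plot_exponent",
    "node_shape_intensity",
    "graph_feature_vector",
    "feature_matrix",
    "node_feature_matrix",
]

GRAPH_FEATURES: List[str] = [
    "n_nodes",
    "n_edges",
    "avg_degree",
    "diameter",
    "radius",
    "n_central_points",
    "avg_clustering_coeff",
    "n_end_nodes",
    "pct_end_nodes",
    "hop_plot_exponent",
]

NODE_FEATURES: List[str] = [
    "area",
    "eccentricity",
    "equivalent_diameter",
    "extent",
    "major_axis",
    "minor_axis",
    "max_intensity",
    "min_intensity",
    "mean_intensity",
    "perimeter",
    "std_intensity",
    "median_intensity",
]

FEATURE_NAMES: List[str] = GRAPH_FEATURES + [f"avg_{n}" for n in NODE_FEATURES]

_INTENSITY = {"max_intensity", "min_intensity", "mean_intensity",
              "std_intensity", "median_intensity"}

#: feature name -> category: T (topological), M (morphological), I (intensity)
FEATURE_CATEGORIES: Dict[str, str] = {
    **{n: "T" for n in GRAPH_FEATURES},
    **{f"avg_{n}": ("I" if n in _INTENSITY else "M") for n in NODE_FEATURES},
}


def _require_connected(graph: nx.Graph) -> None:
    if graph.number_of_nodes() == 0 or not nx.is_connected(graph):
        raise ValueError("metric requires a non-empty connected graph")


def eccentricities(graph: nx.Graph) -> Dict:
    """Eccentricity per node: the maximum shortest-path distance to any
    other node.  Raises on disconnected input."""
    _require_connected(graph)
    return dict(nx.eccentricity(graph))


def diameter_radius_central(graph: nx.Graph) -> Tuple[int, int, int]:
    """(diameter, radius, number of central points) of a connected graph.

    The diameter is the maximum node eccentricity, the radius the minimum,
    and the central points are the nodes whose eccentricity equals the
    radius.
    """
    ecc = eccentricities(graph)
    vals = list(ecc.values())
    diameter, radius = max(vals), min(vals)
    n_central = sum(1 for v in vals if v == radius)
    return diameter, radius, n_central


def avg_clustering_coefficient(graph: nx.Graph) -> float:
    """Mean over nodes of C_i = 2 E_i / (k_i (k_i - 1)), where k_i is the
    degree and E_i the edge count among the node's neighbours; nodes with
    k_i < 2 contribute 0."""
    if graph.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(graph))


def end_node_stats(graph: nx.Graph) -> Tuple[int, float]:
    """Count and percentage of end nodes (degree exactly 1)."""
    n = graph.number_of_nodes()
    n_end = sum(1 for _, d in graph.degree() if d == 1)
    return n_end, (100.0 * n_end / n if n else 0.0)


def hop_plot_values(graph: nx.Graph) -> np.ndarray:
    """P(h) for h = 1..diameter: number of unordered node pairs whose
    shortest-path distance is <= h."""
    _require_connected(graph)
    diam = max(nx.eccentricity(graph).values())
    if diam < 1:
        return np.array([], dtype=np.int64)
    counts = np.zeros(diam, dtype=np.int64)
    for _, dists in nx.all_pairs_shortest_path_length(graph):
        for d in dists.values():
            if 1 <= d <= diam:
                counts[d - 1] += 1
    return np.cumsum(counts) // 2  # each unordered pair was seen twice


def hop_plot_exponent(graph: nx.Graph) -> float:
    """Least-squares slope of log P(h) versus log h over h = 1..diameter.

    Degenerate graphs (diameter < 2, a single regression point) return 0
    with a warning.
    """
    p = hop_plot_values(graph)
    if len(p) < 2:
        warnings.warn("hop-plot exponent undefined for diameter < 2; returning 0")
        return 0.0
    h = np.arange(1, len(p) + 1)
    slope, _ = np.polyfit(np.log(h), np.log(p.astype(float)), 1)
    return float(slope)


def node_shape_intensity(nucleus: NucleusRecord) -> Dict[str, float]:
    """The 12 morphological/intensity features of one nucleus."""
    return {
        "area": float(nucleus.area_px),
        "eccentricity": nucleus.eccentricity,
        "equivalent_diameter": nucleus.equivalent_diameter_px,
        "extent": nucleus.extent,
        "major_axis": nucleus.major_axis_px,
        "minor_axis": nucleus.minor_axis_px,
        "max_intensity": nucleus.max_intensity,
        "min_intensity": nucleus.min_intensity,
        "mean_intensity": nucleus.mean_intensity,
        "perimeter": nucleus.perimeter_px,
        "std_intensity": nucleus.std_intensity,
        "median_intensity": nucleus.median_intensity,
    }


def graph_feature_vector(graph: nx.Graph) -> Dict[str, float]:
    """All 22 features of one connected subgraph (>= 2 nodes).

    Node features are read from each node's ``record`` attribute and
    averaged with an unweighted arithmetic mean.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("a cell subgraph must contain at least 2 nodes")
    diameter, radius, n_central = diameter_radius_central(graph)
    n_end, pct_end = end_node_stats(graph)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hop = hop_plot_exponent(graph)
    vec: Dict[str, float] = {
        "n_nodes": float(n),
        "n_edges": float(graph.number_of_edges()),
        "avg_degree": 2.0 * graph.number_of_edges() / n,
        "diameter": float(diameter),
        "radius": float(radius),
        "n_central_points": float(n_central),
        "avg_clustering_coeff": avg_clustering_coefficient(graph),
        "n_end_nodes": float(n_end),
        "pct_end_nodes": pct_end,
        "hop_plot_exponent": hop,
    }
    records = [graph.nodes[u]["record"] for u in graph.nodes]
    per_node = [node_shape_intensity(r) for r in records]
    for name in NODE_FEATURES:
        vec[f"avg_{name}"] = float(np.mean([p[name] for p in per_node]))
    return vec


def feature_matrix(subgraphs: Sequence[nx.Graph]) -> pd.DataFrame:
    """One row of the 22 named features per subgraph; index = subgraph id."""
    rows = [graph_feature_vector(g) for g in subgraphs]
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    df.index.name = "subgraph_id"
    return df


def node_feature_matrix(nuclei: Iterable[NucleusRecord]) -> pd.DataFrame:
    """The 12 per-nucleus features; index = nucleus label."""
    nuclei = list(nuclei)
    df = pd.DataFrame([node_shape_intensity(r) for r in nuclei],
                      columns=NODE_FEATURES,
                      index=[r.label for r in nuclei])
    df.index.name = "label"
    return df
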