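"""Brute-force reference implementations shared by the test modules.

Everything here is deliberately naive (BFS, exhaustive enumeration) and
independent of the package's code paths.
"""

import networkx as nx
import numpy as np


def bfs_distances(graph, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def oracle_metrics(graph):
    """(ecc map, diameter, radius, n_central, avg clustering, n_end, hop list)."""
    nodes = list(graph.nodes)
    dists = {u: bfs_distances(graph, u) for u in nodes}
    ecc = {u: max(dists[u].values()) for u in nodes}
    diam, rad = max(ecc.values()), min(ecc.values())
    central = sum(1 for v in ecc.values() if v == rad)
    cs = []
    for u in nodes:
        nb = list(graph.neighbors(u))
        k = len(nb)
        if k < 2:
            cs.append(0.0)
            continue
        e = sum(1 for i in range(k) for j in range(i + 1, k)
                if graph.has_edge(nb[i], nb[j]))
        cs.append(2.0 * e / (k * (k - 1)))
    hop = [sum(1 for u in nodes for v in nodes
               if u < v and dists[u][v] <= h) for h in range(1, diam + 1)]
    n_end = sum(1 for u in nodes if graph.degree(u) == 1)
    return ecc, diam, rad, central, float(np.mean(cs)), n_end, hop


def random_connected_graph(rng, n_max=30):
    n = int(rng.integers(2, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = list(rng.permutation(n))
    for i in range(1, n):  # random spanning tree keeps it connected
        g.add_edge(order[i], order[int(rng.integers(0, i))])
    for _ in range(int(rng.integers(0, 2 * n))):
        a, b = rng.integers(0, n, 2)
        if a != b:
            g.add_edge(int(a), int(b))
    return g


def min_l1(coords_a, coords_b):
    """Exhaustive pixel-pair city-block distance."""
    d = np.abs(np.asarray(coords_a)[:, None, :]
               - np.asarray(coords_b)[None, :, :]).sum(axis=2)
    return int(d.min())
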