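"""Brute-force tree oracle: enumerate unrooted topologies, least-squares branch fit.

Independent of the package's NJ/UPGMA code; used to certify exact recovery on
additive and ultrametric matrices for small taxon counts.
"""

from itertools import combinations

import numpy as np


def enumerate_topologies(labels):
    """All unrooted binary topologies over labels (n >= 3), as edge lists.

    A topology is (edges, leaf_of): edges are (node_a, node_b) pairs over
    integer node ids; leaves are ids 0..n-1 in label order.
    """
    n = len(labels)
    base_edges = [(0, n), (1, n), (2, n)]  # star over first three leaves
    topologies = [(base_edges, n + 1)]
    for leaf in range(3, n):
        grown = []
        for edges, next_id in topologies:
            for k, (a, b) in enumerate(edges):
                new_internal = next_id
                new_edges = edges[:k] + edges[k + 1:]
                new_edges += [(a, new_internal), (b, new_internal), (leaf, new_internal)]
                grown.append((new_edges, next_id + 1))
        topologies = grown
    return topologies


def _paths(edges, n_leaves):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    paths = {}
    for leaf in range(n_leaves):
        stack = [(leaf, None, [])]
        while stack:
            node, prev, used = stack.pop()
            if node < n_leaves and node != leaf:
                paths[(leaf, node)] = used
            for nxt in adj[node]:
                if nxt != prev:
                    edge = frozenset((node, nxt))
                    stack.append((nxt, node, used + [edge]))
    return paths


def ls_fit(edges, n_leaves, d):
    """Least-squares branch lengths for one topology; returns (residual, lengths)."""
    edge_ids = [frozenset(e) for e in edges]
    index = {e: i for i, e in enumerate(edge_ids)}
    paths = _paths(edges, n_leaves)
    pairs = list(combinations(range(n_leaves), 2))
    A = np.zeros((len(pairs), len(edge_ids)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for e in paths[(i, j)]:
            A[row, index[e]] = 1.0
        y[row] = d[i, j]
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    residual = float(np.sum((A @ lengths - y) ** 2))
    return residual, dict(zip(edge_ids, lengths))


def bipartitions_of(edges, n_leaves, labels):
    """Non-trivial splits of a topology, canonicalized as in the package."""
    all_set = frozenset(labels)
    anchor = min(all_set)
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    out = set()
    for a, b in edges:
        # leaves reachable from b without crossing (a, b)
        stack, seen = [b], {a, b}
        side = set()
        while stack:
            node = stack.pop()
            if node < n_leaves:
                side.add(labels[node])
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        split = frozenset(side)
        if anchor in split:
            split = all_set - split
        if 1 < len(split) < n_leaves - 1:
            out.add(split)
    return out


def best_topology(labels, d):
    """The topology with the smallest least-squares residual."""
    n = len(labels)
    best = None
    for edges, _ in enumerate_topologies(labels):
        residual, lengths = ls_fit(edges, n, d)
        if best is None or residual < best[0] - 1e-12:
            best = (residual, edges, lengths)
    residual, edges, lengths = best
    return {"residual": residual,
            "bipartitions": bipartitions_of(edges, n, labels),
            "lengths": lengths}
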