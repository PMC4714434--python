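"""Independent brute-force oracles used by the test suite.

Each oracle deliberately re-derives a quantity from first principles
(explicit allele multisets, pair enumeration, exhaustive topology search)
and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def cssc_multiset_oracle(g_a, g_b):
    """Allele-sharing coefficient via explicit allele multiset intersection.

    Dosage 0 -> {A, A}, 1 -> {A, B}, 2 -> {B, B}; shared alleles at a marker
    is the multiset-intersection size. Returns (cssc, n_informative) or None
    if no marker is informative.
    """
    alleles = {0.0: ("A", "A"), 1.0: ("A", "B"), 2.0: ("B", "B")}
    total, n = 0.0, 0
    for da, db in zip(g_a, g_b):
        if da is None or db is None or (isinstance(da, float) and math.isnan(da)) or (
            isinstance(db, float) and math.isnan(db)
        ):
            continue
        a = list(alleles[float(da)])
        b = list(alleles[float(db)])
        shared = 0
        for al in a:
            if al in b:
                b.remove(al)
                shared += 1
        total += shared / 2.0
        n += 1
    if n == 0:
        return None
    return total / n, n


def di_pair_enumeration_oracle(small_dosages, large_dosages):
    """DI at one marker by enumerating every small x large pair."""
    diff = same = 0
    for ds in small_dosages:
        for dl in large_dosages:
            if ds is None or dl is None or (isinstance(ds, float) and math.isnan(ds)) or (
                isinstance(dl, float) and math.isnan(dl)
            ):
                continue
            if ds == dl:
                same += 1
            else:
                diff += 1
    n = same + diff
    return (diff / n if n else float("nan")), n


def mendelian_consistent(offspring, dam, sire) -> bool:
    """Is an offspring dosage reachable from (dam, sire) dosages by any of
    the <= 4 transmitted-allele pairs?"""
    if math.isnan(offspring):
        return True
    transmit = {0.0: (0,), 1.0: (0, 1), 2.0: (1,)}
    return any(
        a + b == offspring for a in transmit[float(dam)] for b in transmit[float(sire)]
    )


def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies on the labels, as edge lists.

    Nodes are label strings (leaves) or integers (internal). Built by
    attaching each successive leaf to every edge of every partial topology:
    yields (2n-5)!! topologies for n leaves.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    base_internal = 0
    trees = [([(labels[0], base_internal), (labels[1], base_internal), (labels[2], base_internal)], 1)]
    for leaf in labels[3:]:
        nxt = []
        for edges, n_internal in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                new_node = n_internal
                new_edges = edges[:k] + edges[k + 1:] + [
                    (u, new_node),
                    (v, new_node),
                    (leaf, new_node),
                ]
                nxt.append((new_edges, n_internal + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def _edge_paths(edges, leaves):
    """For each leaf pair, the set of edge indices on the connecting path."""
    adj = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))
    paths = {}
    for src in leaves:
        stack = [(src, [])]
        seen = {src}
        while stack:
            node, path = stack.pop()
            if isinstance(node, str) and node != src:
                paths[(src, node)] = path
                continue
            for nb, k in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, path + [k]))
    return paths


def least_squares_fit(edges, labels, dist):
    """Least-squares branch lengths (non-negativity enforced) for a topology
    against a distance matrix; returns (sum of squared residuals, lengths)."""
    from scipy.optimize import nnls

    pairs = list(itertools.combinations(labels, 2))
    paths = _edge_paths(edges, labels)
    design = np.zeros((len(pairs), len(edges)))
    target = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        for k in paths[(a, b)]:
            design[r, k] = 1.0
        target[r] = dist.loc[a, b]
    lengths, _ = nnls(design, target)
    resid = design @ lengths - target
    return float(resid @ resid), lengths


def best_topology_by_least_squares(labels, dist):
    """Exhaustive all-topology search: the topology (edge list) minimising the
    least-squares fit to the matrix, with its residual."""
    best = None
    for edges in enumerate_unrooted_topologies(labels):
        ssq, lengths = least_squares_fit(edges, labels, dist)
        if best is None or ssq < best[0]:
            best = (ssq, edges, lengths)
    return best


def topology_splits(edges, labels):
    """Non-trivial bipartitions of an edge-list topology (canonical sides)."""
    all_leaves = frozenset(labels)
    adj = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))
    splits = set()
    for k, (u, v) in enumerate(edges):
        # leaves reachable from v without crossing edge k
        stack, seen = [v], {v}
        side = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                side.add(node)
            for nb, ek in adj[node]:
                if ek != k and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(side)
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(min(side, all_leaves - side, key=sorted))
    return splits


def g_statistic_oracle(table):
    """G = 2 sum o ln(o/e) computed cell by cell with plain floats."""
    table = [[float(c) for c in row] for row in table]
    n = sum(sum(r) for r in table)
    rows = [sum(r) for r in table]
    cols = [sum(table[i][j] for i in range(len(table))) for j in range(len(table[0]))]
    g = 0.0
    for i, row in enumerate(table):
        for j, o in enumerate(row):
            if o > 0:
                g += 2.0 * o * math.log(o / (rows[i] * cols[j] / n))
    return g


def pearson_2x2_closed_form(a, b, c, d):
    """N(ad - bc)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
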