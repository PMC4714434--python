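"""Neighbour-joining tree construction and Newick output.

Implements the standard Saitou-Nei agglomerative procedure on a symmetric
distance matrix: at each step the pair minimising the Q-criterion is joined,
limb lengths are computed from the net divergences, and the matrix is
reduced; the procedure is exact for additive (tree) metrics.  Ties in Q are
broken deterministically by the lowest (row, column) index pair, negative
limb lengths are clamped to zero (the deficit is logged), and trees are
left unrooted, written with a trifurcating base node.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import PairwiseMatrix

log = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "Tree",
    "neighbor_joining",
    "write_newick",
    "random_additive_tree",
]


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree held as a rooted structure with a trifurcating base."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        names: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                names.append(node.name or "")
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return names

    def _edges(self) -> list[tuple[TreeNode, TreeNode, float]]:
        edges = []

        def walk(node: TreeNode) -> None:
            for child, length in node.children:
                edges.append((node, child, length))
                walk(child)

        walk(self.root)
        return edges

    def patristic_distances(self) -> pd.DataFrame:
        """Leaf-to-leaf path-length matrix on the tree."""
        adj: dict[int, list[tuple[int, float]]] = {}
        leaves: dict[int, str] = {}
        nodes: dict[int, TreeNode] = {id(self.root): self.root}
        for a, b, w in self._edges():
            nodes[id(a)] = a
            nodes[id(b)] = b
            adj.setdefault(id(a), []).append((id(b), w))
            adj.setdefault(id(b), []).append((id(a), w))
        for nid, node in nodes.items():
            if node.is_leaf:
                leaves[nid] = node.name or ""
        names = sorted(leaves.values())
        dist = pd.DataFrame(0.0, index=names, columns=names)
        for src, src_name in leaves.items():
            seen = {src: 0.0}
            stack = [src]
            while stack:
                cur = stack.pop()
                for nb, w in adj.get(cur, []):
                    if nb not in seen:
                        seen[nb] = seen[cur] + w
                        stack.append(nb)
            for nid, name in leaves.items():
                dist.loc[src_name, name] = seen[nid]
        # path sums accumulate in traversal order; average the two
        # directions so the matrix is exactly symmetric
        v = dist.to_numpy()
        dist.iloc[:, :] = (v + v.T) / 2.0
        np.fill_diagonal(dist.values, 0.0)
        return dist

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (as the child-side leaf set) induced by
        internal edges; two trees share topology iff their split sets match."""
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset[str]] = set()

        def leafset(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name or ""])
            s: frozenset[str] = frozenset()
            for child, _ in node.children:
                s |= leafset(child)
            return s

        for _, child, _ in self._edges():
            side = leafset(child)
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(min(side, all_leaves - side, key=sorted))
        return out


def _as_matrix(matrix: PairwiseMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(matrix, PairwiseMatrix):
        return matrix.values
    return matrix


def neighbor_joining(matrix: PairwiseMatrix | pd.DataFrame) -> Tree:
    """Build the neighbour-joining tree for a distance matrix.

    Requires at least 3 labels and an exactly symmetric, finite,
    zero-diagonal matrix.  For additive inputs the generating topology and
    branch lengths are recovered exactly.
    """
    df = _as_matrix(matrix)
    d = df.to_numpy(dtype=float)
    labels = list(df.index)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix must be finite")
    if not np.array_equal(d, d.T) or not np.allclose(np.diag(d), 0.0, atol=0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    def clamp(x: float, where: str) -> float:
        if x < 0:
            log.debug("clamping negative branch length %.3g at %s", x, where)
            return 0.0
        return x

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    d = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin scans row-major, so ties resolve to the lowest (i, j)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        new = TreeNode(
            children=[
                (nodes[i], clamp(li, f"join({nodes[i].name or 'internal'})")),
                (nodes[j], clamp(lj, f"join({nodes[j].name or 'internal'})")),
            ]
        )
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]

    (a, b, c), dd = nodes, d
    la = clamp(0.5 * (dd[0, 1] + dd[0, 2] - dd[1, 2]), "base")
    lb = clamp(0.5 * (dd[0, 1] + dd[1, 2] - dd[0, 2]), "base")
    lc = clamp(0.5 * (dd[0, 2] + dd[1, 2] - dd[0, 1]), "base")
    return Tree(TreeNode(children=[(a, la), (b, lb), (c, lc)]))


_NEEDS_QUOTING = re.compile(r"[\s()\[\]{}:;,']")


def _format_label(label: str) -> str:
    if _NEEDS_QUOTING.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, decimals: int = 6) -> str:
    """Serialise a tree to Newick text (semicolon-terminated).

    Labels containing whitespace or Newick metacharacters are single-quoted
    (embedded quotes doubled); branch lengths are fixed-point with
    ``decimals`` digits.
    """
    names = [n for n in tree.leaf_names()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels")

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _format_label(node.name or "")
        inner = ",".join(
            f"{render(child)}:{length:.{decimals}f}" for child, length in node.children
        )
        return f"({inner})"

    return render(tree.root) + ";"


def random_additive_tree(
    n_leaves: int,
    rng: np.random.Generator,
    length_low: float = 0.1,
    length_high: float = 2.0,
) -> tuple[Tree, pd.DataFrame]:
    """A random unrooted binary tree and its (additive) patristic matrix.

    Leaves are labelled T1..Tn; branch lengths are uniform on
    [length_low, length_high].  Used to exercise NJ recovery: running
    neighbour joining on the returned matrix must reproduce the returned
    tree's topology and branch lengths.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    subtrees = [TreeNode(name=f"T{i + 1}") for i in range(n_leaves)]
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        li, lj = rng.uniform(length_low, length_high, size=2)
        merged = TreeNode(children=[(subtrees[i], float(li)), (subtrees[j], float(lj))])
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [merged]
    lengths = rng.uniform(length_low, length_high, size=3)
    tree = Tree(TreeNode(children=[(s, float(l)) for s, l in zip(subtrees, lengths)]))
    return tree, tree.patristic_distances()
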