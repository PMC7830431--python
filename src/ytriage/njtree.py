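"""p-distances and neighbor-joining trees with outgroup/midpoint rooting.

The agglomeration is the classic Saitou-Nei algorithm: minimize the
Q-criterion, join, compute branch lengths from the row sums, reduce the
matrix.  On an additive matrix the output tree's path-length matrix
reproduces the input exactly.  Negative branch lengths (possible on
non-additive input) are clamped to zero with the deficit moved to the
sibling branch, preserving the joined pair's path length.  Ties in Q are
broken toward the lowest (row, column) pair, making the output
deterministic.

The default distance is the uncorrected p-distance; a Jukes-Cantor
correction is available behind a flag.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

GAP_CHARS = frozenset("-N")


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = self.d
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("diagonal must be zero")


def _as_pairs(aligned) -> list[tuple[str, str]]:
    if hasattr(aligned, "items"):
        return list(aligned.items())
    out = []
    for item in aligned:
        if isinstance(item, tuple):
            out.append(item)
        else:
            out.append((item.id, item.sequence))
    return out


def p_distance(aligned_sequences) -> DistanceMatrix:
    """Pairwise p-distance over an alignment.

    Columns with a gap or N in either sequence of a pair are excluded; a
    pair with zero comparable columns is an error.
    """
    pairs = _as_pairs(aligned_sequences)
    if len(pairs) < 2:
        raise ValueError("need at least two aligned sequences")
    lengths = {len(seq) for _, seq in pairs}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    names = tuple(name for name, _ in pairs)
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon names")
    arrays = [np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8) for _, seq in pairs]
    bad = np.array([ord(c) for c in GAP_CHARS], dtype=np.uint8)
    comparable = [~np.isin(a, bad) for a in arrays]
    n = len(pairs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = comparable[i] & comparable[j]
            total = int(ok.sum())
            if total == 0:
                raise ValueError(f"no comparable columns between {names[i]} and {names[j]}")
            mismatches = int((arrays[i][ok] != arrays[j][ok]).sum())
            d[i, j] = d[j, i] = mismatches / total
    return DistanceMatrix(names, d)


def jukes_cantor(dm: DistanceMatrix) -> DistanceMatrix:
    """Jukes-Cantor corrected distances: d = -3/4 ln(1 - 4p/3)."""
    p = dm.d
    if (p >= 0.75).any():
        raise ValueError("p-distance >= 0.75: Jukes-Cantor correction undefined")
    with np.errstate(divide="ignore"):
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(dm.taxa, d)


class TreeNode:
    """A rooted-view tree node; ``length`` is the branch to the parent."""

    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None = None, length: float = 0.0, children=None):
        self.name = name
        self.length = length
        self.children: list[TreeNode] = list(children or [])

    def leaves(self) -> list["TreeNode"]:
        # named nodes are taxa; in degenerate hand-built trees a taxon can
        # carry children (e.g. the two-leaf unrooted tree a--b)
        out = []
        if self.name is not None or not self.children:
            out.append(self)
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_node() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"

    def __repr__(self):  # pragma: no cover
        return f"TreeNode({self.newick()})"


def leaf_distance_matrix(tree: TreeNode, taxa: Sequence[str] | None = None) -> DistanceMatrix:
    """Path-length matrix between leaves (rooting-invariant)."""
    adj = _adjacency(tree)
    leaves = {node.name: node for node in tree.leaves()}
    taxa = tuple(taxa or sorted(leaves))
    n = len(taxa)
    d = np.zeros((n, n))
    for i, name in enumerate(taxa):
        dist = _distances_from(adj, leaves[name])
        for j, other in enumerate(taxa):
            d[i, j] = dist[id(leaves[other])]
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(taxa, d)


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating root)."""
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = matrix.d.astype(float).copy()
    nodes = [TreeNode(name=t) for t in matrix.taxa]
    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)  # row-major => lowest (i, j)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j])
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        Dn = np.empty((len(keep) + 1, len(keep) + 1))
        Dn[:-1, :-1] = D[np.ix_(keep, keep)]
        Dn[-1, :-1] = Dn[:-1, -1] = du[keep]
        Dn[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        D = Dn
    a, b = nodes
    # hang the remaining edge off the internal node
    root, other = (a, b) if a.children else (b, a)
    other.length = max(D[0, 1], 0.0)
    root.children.append(other)
    root.length = 0.0
    return root


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _adjacency(tree: TreeNode) -> dict[int, list[tuple[TreeNode, float]]]:
    adj: dict[int, list[tuple[TreeNode, float]]] = {}

    def visit(node: TreeNode):
        adj.setdefault(id(node), [])
        for child in node.children:
            adj.setdefault(id(child), [])
            adj[id(node)].append((child, child.length))
            adj[id(child)].append((node, child.length))
            visit(child)

    visit(tree)
    return adj


def _distances_from(adj, start: TreeNode) -> dict[int, float]:
    dist = {id(start): 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, w in adj[id(node)]:
            if id(nbr) not in dist:
                dist[id(nbr)] = dist[id(node)] + w
                stack.append(nbr)
    return dist


def _rebuild(node: TreeNode, parent: TreeNode | None, adj, length: float) -> TreeNode:
    new = TreeNode(name=node.name, length=length)
    for nbr, w in adj[id(node)]:
        if parent is not None and nbr is parent:
            continue
        new.children.append(_rebuild(nbr, node, adj, w))
    return new


def _edges(tree: TreeNode):
    # enumerate parent->child edges from the rooted view
    out = []

    def visit(node: TreeNode):
        for child in node.children:
            out.append((node, child, child.length))
            visit(child)

    visit(tree)
    return out


def _leafset_below(node: TreeNode) -> frozenset[str]:
    return frozenset(node.leaf_names())


def root_tree(tree: TreeNode, outgroup: Iterable[str] | None = None, midpoint: bool = False) -> TreeNode:
    """Root an unrooted tree on an outgroup branch or at the midpoint.

    Outgroup mode places the root on the branch separating the (monophyletic)
    outgroup from the ingroup; a non-monophyletic outgroup raises an error
    naming the smallest split containing it.  Midpoint mode roots at the
    middle of the longest leaf-to-leaf path.
    """
    if (outgroup is None) == (not midpoint):
        raise ValueError("choose exactly one of outgroup or midpoint rooting")
    adj = _adjacency(tree)
    all_leaves = set(tree.leaf_names())
    if midpoint:
        return _root_midpoint(tree, adj, all_leaves)
    out = set(outgroup)
    if not out or out - all_leaves:
        raise ValueError(f"outgroup taxa not in tree: {sorted(out - all_leaves)}")
    if out == all_leaves:
        raise ValueError("outgroup cannot contain every taxon")
    for parent, child, length in _edges(tree):
        below = _leafset_below(child)
        if below == out or (all_leaves - below) == out:
            return _split_edge(parent, child, length, length / 2, adj, all_leaves, out)
    smallest = min(
        (s for _, c, _ in _edges(tree) if out <= (s := _leafset_below(c))),
        key=len,
        default=frozenset(all_leaves),
    )
    raise ValueError(
        f"outgroup {sorted(out)} is not monophyletic; smallest containing split is {sorted(smallest)}"
    )


def _split_edge(u: TreeNode, v: TreeNode, length: float, dist_from_u: float, adj, all_leaves, outgroup=None) -> TreeNode:
    root = TreeNode()
    side_u = _rebuild(u, v, adj, max(dist_from_u, 0.0))
    side_v = _rebuild(v, u, adj, max(length - dist_from_u, 0.0))
    # put the outgroup side last for a stable, readable orientation
    if outgroup is not None and set(side_u.leaf_names()) == set(outgroup):
        side_u, side_v = side_v, side_u
    root.children = [side_u, side_v]
    return root


def _root_midpoint(tree: TreeNode, adj, all_leaves) -> TreeNode:
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least two leaves")
    # two-sweep farthest-leaf search
    d0 = _distances_from(adj, leaves[0])
    a = max(leaves, key=lambda l: d0[id(l)])
    da = _distances_from(adj, a)
    b = max(leaves, key=lambda l: da[id(l)])
    target = da[id(b)] / 2
    # walk the a->b path accumulating distance
    path = _path(adj, a, b)
    acc = 0.0
    for u, v, w in path:
        if acc + w >= target - 1e-12:
            return _split_edge_any(u, v, w, target - acc, adj)
        acc += w
    return _split_edge_any(path[-1][0], path[-1][1], path[-1][2], path[-1][2], adj)


def _split_edge_any(u: TreeNode, v: TreeNode, length: float, dist_from_u: float, adj) -> TreeNode:
    root = TreeNode()
    root.children = [
        _rebuild(u, v, adj, max(dist_from_u, 0.0)),
        _rebuild(v, u, adj, max(length - dist_from_u, 0.0)),
    ]
    return root


def _path(adj, a: TreeNode, b: TreeNode):
    parent: dict[int, tuple[TreeNode, TreeNode, float]] = {}
    stack = [a]
    seen = {id(a)}
    while stack:
        node = stack.pop()
        if node is b:
            break
        for nbr, w in adj[id(node)]:
            if id(nbr) not in seen:
                seen.add(id(nbr))
                parent[id(nbr)] = (node, nbr, w)
                stack.append(nbr)
    edges = []
    node = b
    while node is not a:
        u, v, w = parent[id(node)]
        edges.append((u, v, w))
        node = u
    edges.reverse()
    return edges


def write_newick(tree: TreeNode, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")
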