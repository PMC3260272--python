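"""Guide tree construction and tree-derived pair weights.

A plain sum-of-pairs column score over-counts clusters of closely related
sequences.  The weighting scheme here distributes each branch length of a
neighbor-joining guide tree among the sequence pairs whose path crosses
that branch, using per-side "correlation weights" (an equal-split
Felsenstein-style scheme) so that redundant pairs share, rather than
duplicate, the evidence carried by a branch.  The weight of a pair is the
square root of its summed branch shares.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .msa_io import GAP, Alignment

#: Mismatch fraction at which the distance correction saturates.
MAX_MISMATCH = 0.85
#: Distance assigned to saturated pairs: the corrected distance at p = 0.85.
MAX_DISTANCE = float(-np.log(1.0 - MAX_MISMATCH - 0.2 * MAX_MISMATCH**2))


@dataclass(frozen=True)
class BranchPartition:
    """The bipartition induced by one branch, with correlation weights.

    ``left``/``right`` are leaf-id tuples; ``lw``/``rw`` map leaf id to its
    correlation weight, each side summing to 1.  The left side is the one
    containing the lexicographically smallest leaf id, which makes every
    downstream quantity deterministic on unrooted trees.
    """

    left: tuple[str, ...]
    right: tuple[str, ...]
    lw: dict[str, float]
    rw: dict[str, float]
    length: float


class GuideTree:
    """Unrooted tree with branch lengths over the alignment's sequence ids.

    Thin adjacency-list representation; construction goes through newick
    (user-supplied or emitted by neighbor joining).
    """

    def __init__(
        self,
        n_nodes: int,
        edges: list[tuple[int, int, float]],
        leaf_labels: dict[int, str],
    ):
        self.n_nodes = n_nodes
        self.edges = edges
        self.leaf_labels = dict(leaf_labels)
        self.adj: list[list[tuple[int, int]]] = [[] for _ in range(n_nodes)]
        for eid, (u, v, _w) in enumerate(edges):
            self.adj[u].append((v, eid))
            self.adj[v].append((u, eid))
        labels = list(self.leaf_labels.values())
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in guide tree")
        if any(w < 0 for _u, _v, w in edges):
            raise ValueError("negative branch length in guide tree")
        if len(edges) != n_nodes - 1:
            raise ValueError("guide tree must be connected and acyclic")

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.leaf_labels.values()))

    # -- newick conversion ------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "GuideTree":
        if isinstance(source, Path) or (
            isinstance(source, str) and "(" not in source
        ):
            text = Path(source).read_text()
        else:
            text = source
        dt = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        dt.suppress_unifurcations()
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "GuideTree":
        nodes = list(dt.preorder_node_iter())
        index = {id(n): k for k, n in enumerate(nodes)}
        edges: list[tuple[int, int, float]] = []
        leaf_labels: dict[int, str] = {}
        for n in nodes:
            k = index[id(n)]
            if n.is_leaf():
                if n.taxon is None or n.taxon.label is None:
                    raise ValueError("guide tree has an unlabelled leaf")
                leaf_labels[k] = n.taxon.label
            if n.parent_node is not None:
                w = n.edge.length if n.edge.length is not None else 0.0
                edges.append((index[id(n.parent_node)], k, max(0.0, float(w))))
        return cls(len(nodes), edges, leaf_labels)

    def to_newick(self) -> str:
        # root at an arbitrary internal node; a two-leaf tree has none
        root = None
        for k in range(self.n_nodes):
            if k not in self.leaf_labels:
                root = k
                break
        if root is None:
            (u, v, w) = self.edges[0]
            return f"({self.leaf_labels[u]}:0,{self.leaf_labels[v]}:{w:.10g});"

        def build(node: int, parent: int) -> str:
            children = [
                (nb, self.edges[eid][2])
                for nb, eid in self.adj[node]
                if nb != parent
            ]
            if not children:
                return f"{self.leaf_labels[node]}"
            inner = ",".join(
                f"{build(nb, node)}:{w:.10g}" for nb, w in children
            )
            return f"({inner})"

        return build(root, -1) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- traversal helpers ------------------------------------------------

    def side_leaves(self, edge_id: int, endpoint: int) -> list[int]:
        """Leaf node indices on the ``endpoint`` side of ``edge_id``."""
        u, v, _w = self.edges[edge_id]
        other = v if endpoint == u else u
        out: list[int] = []
        stack = [(endpoint, other)]
        while stack:
            node, parent = stack.pop()
            if node in self.leaf_labels:
                out.append(node)
            for nb, _eid in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        return out

    def path_edges(self, leaf_u: int, leaf_v: int) -> list[int]:
        parent = {leaf_u: (-1, -1)}
        stack = [leaf_u]
        while stack:
            node = stack.pop()
            if node == leaf_v:
                break
            for nb, eid in self.adj[node]:
                if nb not in parent:
                    parent[nb] = (node, eid)
                    stack.append(nb)
        path = []
        node = leaf_v
        while parent[node][0] != -1:
            node, eid = parent[node]
            path.append(eid)
        return path


# -- distances -----------------------------------------------------------


def pairwise_distances(aln: Alignment) -> np.ndarray:
    """Corrected pairwise protein distances.

    Uses Kimura's correction of the mismatch fraction p over columns where
    neither sequence is gapped: ``d = -ln(1 - p - 0.2 p^2)``, clamped to
    :data:`MAX_DISTANCE` for saturated pairs (p >= 0.85).  A pair with no
    comparable column is an error.
    """
    n = aln.N
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in aln.rows]
    gaps = [r == GAP.encode() for r in rows]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(gaps[i] | gaps[j])
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"sequences {aln.ids[i]!r} and {aln.ids[j]!r} share no "
                    "gap-free column; cannot compute a distance"
                )
            p = float((rows[i][both] != rows[j][both]).sum()) / m
            if p >= MAX_MISMATCH:
                dist = MAX_DISTANCE
            else:
                dist = float(-np.log(1.0 - p - 0.2 * p * p))
            d[i, j] = d[j, i] = dist
    return d


def build_nj_tree(distances: np.ndarray, ids: tuple[str, ...]) -> GuideTree:
    """Saitou–Nei neighbor joining; negative branch estimates clamped to 0.

    For N = 2 the tree is a single branch of length ``d_12``.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape != (len(ids), len(ids)):
        raise ValueError("distance matrix shape does not match ids")
    if np.any(d < 0) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric and non-negative")
    if len(ids) < 2:
        raise ValueError("need at least two sequences to build a guide tree")
    if len(ids) == 2:
        return GuideTree(
            2, [(0, 1, float(d[0, 1]))], {0: ids[0], 1: ids[1]}
        )
    safe = [f"t{k}" for k in range(len(ids))]
    tree = _skbio_nj(DistanceMatrix(d, safe))
    newick = io.StringIO()
    tree.write(newick, format="newick")
    gt = GuideTree.from_newick(newick.getvalue())
    back = {s: real for s, real in zip(safe, ids)}
    gt.leaf_labels = {k: back[lbl] for k, lbl in gt.leaf_labels.items()}
    return gt


def tree_from_alignment(aln: Alignment) -> GuideTree:
    return build_nj_tree(pairwise_distances(aln), aln.ids)


# -- correlation weights and pair weights --------------------------------


def _equal_split(tree: GuideTree, start: int, avoid: int) -> dict[int, float]:
    """Equal-split leaf weights of the subtree at ``start``, not crossing
    the edge towards ``avoid``.

    Each node divides its incoming share equally among its child subtrees;
    the resulting leaf weights sum to 1 by construction.
    """
    out: dict[int, float] = {}
    stack = [(start, avoid, 1.0)]
    while stack:
        node, parent, share = stack.pop()
        children = [nb for nb, _eid in tree.adj[node] if nb != parent]
        if node in tree.leaf_labels and (node != start or not children):
            out[node] = share
            continue
        if not children:  # unlabelled degree-1 node; should not happen
            continue
        for nb in children:
            stack.append((nb, node, share / len(children)))
    return out


def correlation_weights(tree: GuideTree, edge_id: int) -> BranchPartition:
    """Per-leaf correlation weights on the two sides of one branch."""
    u, v, w = tree.edges[edge_id]
    wu = _equal_split(tree, u, v)
    wv = _equal_split(tree, v, u)

    def normalise(d: dict[int, float]) -> dict[str, float]:
        total = sum(d.values())
        return {tree.leaf_labels[k]: val / total for k, val in d.items()}

    side_u, side_v = normalise(wu), normalise(wv)
    if min(side_u) <= min(side_v):
        lw, rw = side_u, side_v
    else:
        lw, rw = side_v, side_u
    return BranchPartition(
        left=tuple(sorted(lw)),
        right=tuple(sorted(rw)),
        lw=lw,
        rw=rw,
        length=w,
    )


def pair_weights(tree: GuideTree, ids: tuple[str, ...] | None = None) -> np.ndarray:
    """Pair weight matrix ``w_ij``.

    Every branch e distributes its length among the pairs crossing it:
    the pair (i, j) receives the share ``w_e * lw_i(e) * rw_j(e)``, and

        w_ij = sqrt(sum over branches on path(i, j) of that share).

    Identical sequences (zero-length path) get weight 0.
    """
    if ids is None:
        ids = tree.leaf_ids
    index = {sid: k for k, sid in enumerate(ids)}
    if set(index) != set(tree.leaf_labels.values()):
        missing = sorted(set(index) ^ set(tree.leaf_labels.values()))
        raise ValueError(f"tree leaves do not match sequence ids: {missing}")
    n = len(ids)
    acc = np.zeros((n, n))
    for eid in range(len(tree.edges)):
        part = correlation_weights(tree, eid)
        if part.length == 0.0:
            continue
        for li in part.left:
            a = index[li]
            s = part.length * part.lw[li]
            for rj in part.right:
                b = index[rj]
                acc[a, b] += s * part.rw[rj]
    acc = acc + acc.T
    return np.sqrt(acc)
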