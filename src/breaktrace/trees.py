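"""Unrooted phylogenies: construction, random generation, exhaustive
enumeration of leaf-labeled binary topologies, and Newick I/O.

Trees are stored as plain adjacency maps over integer vertex ids with a
``leaf_names`` map from degree-1 vertices to genome labels.  A binary
unrooted tree on ``N`` leaves has ``N - 2`` internal vertices of degree 3
and ``2N - 3`` edges; multifurcating trees (internal degree > 3) are also
valid.  Topologies are compared through their edge-induced leaf
bipartitions (splits), the standard order-independent encoding.
"""

from __future__ import annotations

from typing import Dict, Hashable, Iterable, Iterator, List, Sequence, Tuple

import dendropy
import numpy as np

Edge = Tuple[int, int]
LeafName = Hashable


class TreeError(ValueError):
    """Invalid tree structure, size or Newick text."""


def _canon_edge(u: int, v: int) -> Edge:
    return (u, v) if u < v else (v, u)


def _name_key(name: LeafName) -> str:
    # Deterministic ordering across int and str labels.
    return f"{len(str(name)):08d}{name}" if isinstance(name, int) else f"s{name}"


class PhyloTree:
    """An unrooted tree with named leaves.

    Parameters
    ----------
    edges:
        Iterable of vertex pairs (any hashable ints).
    leaf_names:
        Map from every degree-1 vertex to its label (genome index or name).
    """

    __slots__ = ("_adj", "leaf_names", "_split_cache")

    def __init__(self, edges: Iterable[Edge], leaf_names: Dict[int, LeafName]):
        adj: Dict[int, List[int]] = {}
        nedges = 0
        for u, v in edges:
            if u == v:
                raise TreeError(f"self-loop at vertex {u}")
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
            nedges += 1
        if not adj:
            raise TreeError("tree has no edges")
        if nedges != len(adj) - 1:
            raise TreeError("edge count != vertex count - 1: not a tree")
        # connectivity
        seen = {next(iter(adj))}
        stack = list(seen)
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) != len(adj):
            raise TreeError("tree is not connected")
        leaves = {v for v, nb in adj.items() if len(nb) == 1}
        if leaves != set(leaf_names):
            raise TreeError("leaf_names must name exactly the degree-1 vertices")
        if len(leaves) < 3:
            raise TreeError(f"tree must have at least 3 leaves, got {len(leaves)}")
        if len(set(leaf_names.values())) != len(leaf_names):
            raise TreeError("duplicate leaf names")
        for v, nb in adj.items():
            if v not in leaves and len(nb) < 3:
                raise TreeError(f"internal vertex {v} has degree {len(nb)} < 3")
        for v in adj:
            adj[v] = sorted(adj[v])
        self._adj = adj
        self.leaf_names = dict(leaf_names)
        self._split_cache: Dict[Edge, frozenset] | None = None

    # -- basic structure ---------------------------------------------------
    @property
    def vertices(self) -> List[int]:
        return sorted(self._adj)

    @property
    def edges(self) -> List[Edge]:
        return sorted(
            _canon_edge(u, v) for u, nb in self._adj.items() for v in nb if u < v
        )

    @property
    def leaves(self) -> List[int]:
        return sorted(self.leaf_names)

    @property
    def internal_vertices(self) -> List[int]:
        return sorted(v for v in self._adj if v not in self.leaf_names)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def neighbors(self, v: int) -> List[int]:
        return self._adj[v]

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def is_binary(self) -> bool:
        return all(len(self._adj[v]) == 3 for v in self.internal_vertices)

    def leaf_vertex(self, name: LeafName) -> int:
        for v, nm in self.leaf_names.items():
            if nm == name:
                return v
        raise TreeError(f"no leaf named {name!r}")

    def postorder(self, root: int | None = None) -> Tuple[List[int], Dict[int, int | None]]:
        """Vertices in postorder from ``root`` plus the parent map.

        Defaults to rooting at the smallest internal vertex; the DP optimum
        on an unrooted tree does not depend on this choice.
        """
        if root is None:
            root = self.internal_vertices[0]
        parent: Dict[int, int | None] = {root: None}
        order: List[int] = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            for w in self._adj[v]:
                if w != parent[v]:
                    parent[w] = v
                    stack.append(w)
        order.reverse()
        return order, parent

    def path(self, u: int, v: int) -> List[int]:
        """Vertices on the unique path from ``u`` to ``v`` inclusive."""
        if u not in self._adj or v not in self._adj:
            raise TreeError("path endpoints must be tree vertices")
        _, parent = self._rooted_at(u)
        chain = [v]
        while chain[-1] != u:
            chain.append(parent[chain[-1]])  # type: ignore[arg-type]
        chain.reverse()
        return chain

    def _rooted_at(self, root: int):
        parent: Dict[int, int | None] = {root: None}
        order = [root]
        stack = [root]
        while stack:
            x = stack.pop()
            for w in self._adj[x]:
                if w != parent[x]:
                    parent[w] = x
                    order.append(w)
                    stack.append(w)
        return order, parent

    # -- splits and topology identity --------------------------------------
    def split(self, edge: Edge) -> frozenset:
        """Leaf-name bipartition induced by ``edge``, canonical side.

        The returned side is the one *not* containing the smallest leaf
        name, so equal splits compare equal across trees on the same leaves.
        """
        if self._split_cache is None:
            self._split_cache = {}
        edge = _canon_edge(*edge)
        cached = self._split_cache.get(edge)
        if cached is not None:
            return cached
        u, v = edge
        if v not in self._adj.get(u, ()):
            raise TreeError(f"{edge} is not an edge of this tree")
        side = set()
        stack = [u]
        seen = {u, v}
        while stack:
            x = stack.pop()
            if x in self.leaf_names:
                side.add(self.leaf_names[x])
            for w in self._adj[x]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        all_names = set(self.leaf_names.values())
        min_name = min(all_names, key=_name_key)
        result = frozenset(side if min_name not in side else all_names - side)
        self._split_cache[edge] = result
        return result

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_leaves={self.n_leaves}, edges={len(self.edges)})"


class TopologyKey(str):
    """Canonical text encoding of an unrooted leaf-labeled topology."""


def topology_key(t: PhyloTree) -> TopologyKey:
    """Canonical key: equal iff two trees are the same leaf-labeled topology.

    Encodes the sorted set of non-trivial splits plus the leaf set, so it is
    invariant under internal-vertex relabeling and edge ordering.
    """
    names = sorted(t.leaf_names.values(), key=_name_key)
    splits = []
    for u, v in t.edges:
        if u in t.leaf_names or v in t.leaf_names:
            continue
        side = sorted(t.split((u, v)), key=_name_key)
        splits.append(",".join(str(x) for x in side))
    body = "|".join(sorted(splits))
    return TopologyKey(f"L[{','.join(str(x) for x in names)}];S[{body}]")


# -- generation and enumeration --------------------------------------------

def _star(leaf_labels: Sequence[LeafName]) -> tuple[list[Edge], Dict[int, LeafName], int]:
    n = len(leaf_labels)
    center = n + 1
    edges = [(1, center), (2, center), (3, center)]
    names = {i + 1: leaf_labels[i] for i in range(3)}
    return edges, names, center + 1


def random_binary_unrooted_tree(
    N: int, rng: np.random.Generator, leaf_labels: Sequence[LeafName] | None = None
) -> PhyloTree:
    """Uniform random leaf-labeled unrooted binary topology on ``N`` leaves.

    Sequential leaf addition: start from the 3-leaf star and attach each
    next leaf to a uniformly chosen existing edge.  Every topology arises
    via exactly one attachment history, so the distribution is uniform over
    the ``(2N-5)!!`` topologies.
    """
    if N < 3:
        raise TreeError(f"need at least 3 leaves, got {N}")
    labels = list(leaf_labels) if leaf_labels is not None else list(range(1, N + 1))
    if len(labels) != N:
        raise TreeError("leaf_labels length must equal N")
    edges, names, next_internal = _star(labels)
    for i in range(4, N + 1):
        j = int(rng.integers(len(edges)))
        u, v = edges.pop(j)
        w = next_internal
        next_internal += 1
        edges.extend([(u, w), (v, w), (i, w)])
        names[i] = labels[i - 1]
    return PhyloTree(edges, names)


def enumerate_binary_unrooted_topologies(
    N: int, leaf_labels: Sequence[LeafName] | None = None
) -> Iterator[PhyloTree]:
    """Yield every leaf-labeled unrooted binary topology on ``N`` leaves once.

    Same edge-insertion recursion as random generation, exploring every
    edge; emits exactly ``(2N-5)!!`` trees (3, 15, 105, 945 for N=4..7).
    """
    if not (3 <= N <= 9):
        raise TreeError(f"enumeration supported for 3 <= N <= 9, got {N}")
    labels = list(leaf_labels) if leaf_labels is not None else list(range(1, N + 1))
    if len(labels) != N:
        raise TreeError("leaf_labels length must equal N")

    def rec(edges: list[Edge], names: Dict[int, LeafName], leaf: int, nxt: int):
        if leaf > N:
            yield PhyloTree(edges, names)
            return
        for j in range(len(edges)):
            u, v = edges[j]
            w = nxt
            new_edges = edges[:j] + edges[j + 1 :] + [(u, w), (v, w), (leaf, w)]
            new_names = dict(names)
            new_names[leaf] = labels[leaf - 1]
            yield from rec(new_edges, new_names, leaf + 1, nxt + 1)

    edges, names, nxt = _star(labels)
    yield from rec(edges, names, 4, nxt)


def n_unrooted_binary_topologies(N: int) -> int:
    """(2N-5)!! — the count of leaf-labeled unrooted binary topologies."""
    out = 1
    for k in range(3, 2 * N - 4, 2):
        out *= k
    return out


# -- Newick I/O -------------------------------------------------------------

def write_newick(t: PhyloTree) -> str:
    """Deterministic Newick text with a trifurcating (unrooted) base vertex."""
    base = t.neighbors(t.leaf_vertex(min(t.leaf_names.values(), key=_name_key)))[0]

    def rec(v: int, parent: int | None) -> tuple[str, str]:
        if v in t.leaf_names:
            name = t.leaf_names[v]
            return _name_key(name), str(name)
        kids = sorted(
            (rec(w, v) for w in t.neighbors(v) if w != parent), key=lambda p: p[0]
        )
        return kids[0][0], "(" + ",".join(txt for _, txt in kids) + ")"

    return rec(base, None)[1] + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse Newick into a :class:`PhyloTree` (unrooted semantics).

    A bifurcating root is suppressed; all-digit leaf labels become ints so
    simulated trees round-trip.  ``read ∘ write`` preserves the topology key.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"newick parse error: {exc}") from exc

    ids: Dict[int, int] = {}
    edges: list[Edge] = []
    names: Dict[int, LeafName] = {}
    for i, nd in enumerate(dt.preorder_node_iter(), start=1):
        ids[id(nd)] = i
        if nd.parent_node is not None:
            edges.append((ids[id(nd.parent_node)], i))
        if nd.is_leaf():
            label = None
            if nd.taxon is not None and nd.taxon.label is not None:
                label = str(nd.taxon.label)
            elif getattr(nd, "label", None):
                label = str(nd.label)
            if not label:
                raise TreeError("newick leaf without a name")
            names[i] = int(label) if label.lstrip("-").isdigit() else label

    # contract unnamed degree-1/2 vertices (rooted representations)
    adj: Dict[int, set] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    changed = True
    while changed:
        changed = False
        for v in list(adj):
            if v in names:
                continue
            nb = adj[v]
            if len(nb) == 2:
                a, b = sorted(nb)
                adj[a].discard(v)
                adj[b].discard(v)
                adj[a].add(b)
                adj[b].add(a)
                del adj[v]
                changed = True
            elif len(nb) <= 1:
                for w in nb:
                    adj[w].discard(v)
                del adj[v]
                changed = True
    final_edges = sorted(
        _canon_edge(u, v) for u, nb in adj.items() for v in nb if u < v
    )
    return PhyloTree(final_edges, names)


def read_newick_file(path) -> PhyloTree:
    from pathlib import Path

    return read_newick(Path(path).read_text())
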