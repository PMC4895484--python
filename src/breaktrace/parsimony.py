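"""Minimal event assignment on a tree by two-state small parsimony.

Leaves carry labels 1 (split), 2 (not split) or 3 (can't tell).  Internal
vertices take 1 or 2; an *event* is an edge whose endpoints differ — the
branch on which a rearrangement disrupting the scaffold must have occurred.
The minimum number of events over all completions (label-3 leaves are free
states) is computed by unit-cost Sankoff dynamic programming; the set of
alternative optimal labelings is enumerated exhaustively to identify every
branch that is an event in at least one optimum and to split each
scaffold's score fractionally across those branches.

Trees here are small (a handful of genomes), so exhaustive enumeration over
the free vertices is exact and doubles as an independent route against the
DP optimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Sequence, Tuple

import numpy as np

from .labeling import LabelMatrix
from .trees import Edge, PhyloTree, topology_key

_INF = np.int32(10**6)


class LabelingError(ValueError):
    """Missing or invalid leaf labels."""


def _leaf_label_array(
    tree: PhyloTree, leaf_labels: Mapping[Hashable, int]
) -> Dict[int, int]:
    out = {}
    for v in tree.leaves:
        name = tree.leaf_names[v]
        if name not in leaf_labels:
            raise LabelingError(f"leaf {name!r} has no label")
        lab = int(leaf_labels[name])
        if lab not in (1, 2, 3):
            raise LabelingError(f"leaf {name!r} label {lab} not in {{1,2,3}}")
        out[v] = lab
    return out


def min_events_batch(
    tree: PhyloTree, label_matrix: np.ndarray, leaf_order: Sequence[Hashable]
) -> np.ndarray:
    """Minimum event counts for many scaffolds at once.

    ``label_matrix`` is (m, N) with columns ordered as ``leaf_order``
    (leaf names).  Sankoff over states {1, 2} with unit change cost;
    label 3 contributes zero cost in either state.
    """
    m = label_matrix.shape[0]
    col = {name: j for j, name in enumerate(leaf_order)}
    order, parent = tree.postorder()
    cost: Dict[int, np.ndarray] = {}
    for v in order:
        if v in tree.leaf_names:
            labs = label_matrix[:, col[tree.leaf_names[v]]]
            c = np.zeros((m, 2), dtype=np.int32)
            c[labs == 1, 1] = _INF
            c[labs == 2, 0] = _INF
            cost[v] = c
        else:
            c = np.zeros((m, 2), dtype=np.int32)
            for w in tree.neighbors(v):
                if w != parent[v]:
                    cw = cost.pop(w)
                    c += np.minimum(cw, cw[:, ::-1] + 1)
            cost[v] = c
    root = order[-1]
    return cost[root].min(axis=1)


def min_events(tree: PhyloTree, leaf_labels: Mapping[Hashable, int]) -> int:
    """Minimum number of event edges for one scaffold's leaf labels."""
    labs = _leaf_label_array(tree, leaf_labels)
    names = [tree.leaf_names[v] for v in tree.leaves]
    mat = np.array([[labs[tree.leaf_vertex(n)] for n in names]], dtype=np.int8)
    return int(min_events_batch(tree, mat, names)[0])


# -- exhaustive enumeration of optimal labelings ----------------------------

def _enumerate_labelings(tree: PhyloTree, leaf_labels: Mapping[Hashable, int]):
    """All {1,2} completions with their event counts.

    Returns ``(vertex order, index map, assignments (A, V) int8,
    event counts (A,), edges, per-edge event flags (A, E) bool)``.
    Free vertices are the internal vertices plus the label-3 leaves.
    """
    labs = _leaf_label_array(tree, leaf_labels)
    verts = tree.vertices
    idx = {v: i for i, v in enumerate(verts)}
    free = [v for v in verts if v not in tree.leaf_names or labs[v] == 3]
    if len(free) > 22:
        raise LabelingError(
            f"{len(free)} free vertices: exhaustive enumeration not practical"
        )
    A = 1 << len(free)
    asg = np.ones((A, len(verts)), dtype=np.int8)
    for v, lab in labs.items():
        if lab != 3:
            asg[:, idx[v]] = lab
    codes = np.arange(A)
    for j, v in enumerate(free):
        asg[:, idx[v]] = 1 + ((codes >> j) & 1)
    edges = tree.edges
    ui = np.array([idx[u] for u, _ in edges])
    vi = np.array([idx[v] for _, v in edges])
    is_event = asg[:, ui] != asg[:, vi]
    events = is_event.sum(axis=1)
    return verts, idx, asg, events, edges, is_event


@dataclass(frozen=True)
class EventAssignment:
    """Result of event localization for one scaffold.

    ``candidate_edges`` are the branches that carry the event in at least
    one optimal labeling; ``edge_fractions`` splits each unit of score
    across the alternatives (fraction of optima in which the edge is an
    event), so fractions sum to ``event_number``.
    """

    scaffold_id: int | None
    event_number: int
    candidate_edges: Tuple[Edge, ...]
    optimal_labeling_count: int
    edge_fractions: Mapping[Edge, float]
    candidate_splits: Tuple[frozenset, ...] = ()


def optimal_assignments(
    tree: PhyloTree,
    leaf_labels: Mapping[Hashable, int],
    scaffold_id: int | None = None,
) -> EventAssignment:
    """Enumerate every optimal labeling and collect candidate event branches."""
    _, _, _, events, edges, is_event = _enumerate_labelings(tree, leaf_labels)
    best = int(events.min())
    opt = events == best
    count = int(opt.sum())
    frac = is_event[opt].mean(axis=0)
    candidate = tuple(e for e, f in zip(edges, frac) if f > 0)
    fractions = {e: float(f) for e, f in zip(edges, frac) if f > 0}
    splits = tuple(tree.split(e) for e in candidate)
    return EventAssignment(
        scaffold_id=scaffold_id,
        event_number=best,
        candidate_edges=candidate,
        optimal_labeling_count=count,
        edge_fractions=fractions,
        candidate_splits=splits,
    )


def fractional_edge_weights(a: EventAssignment) -> Dict[Edge, float]:
    """Per-branch fractional scores; sums to ``event_number``."""
    return dict(a.edge_fractions)


@dataclass(frozen=True)
class ConflictReport:
    """Conflicts: a 1-labeled vertex on a path between breakpoint-free leaves.

    A pair of leaves both labeled 2 shares the scaffold's adjacencies, so no
    rearrangement affecting the scaffold can lie on the path between them.
    ``has_conflict`` is True when *every* optimal labeling places a
    1-labeled vertex on some such path; ``offending_pairs`` is the union of
    witnessing leaf-name pairs across optimal labelings.
    """

    has_conflict: bool
    offending_pairs: Tuple[Tuple[Hashable, Hashable], ...]


def detect_conflict(
    tree: PhyloTree, leaf_labels: Mapping[Hashable, int]
) -> ConflictReport:
    verts, idx, asg, events, _, _ = _enumerate_labelings(tree, leaf_labels)
    labs = _leaf_label_array(tree, leaf_labels)
    twos = [v for v, lab in labs.items() if lab == 2]
    pairs = []
    for a, b in itertools.combinations(sorted(twos), 2):
        inner = [idx[w] for w in tree.path(a, b)[1:-1]]
        pairs.append(((tree.leaf_names[a], tree.leaf_names[b]), np.array(inner)))
    opt_rows = np.flatnonzero(events == events.min())
    all_offend = len(opt_rows) > 0
    witnesses: set = set()
    for r in opt_rows:
        row = asg[r]
        row_pairs = [
            names for names, inner in pairs if inner.size and (row[inner] == 1).any()
        ]
        if row_pairs:
            witnesses.update(row_pairs)
        else:
            all_offend = False
    return ConflictReport(
        has_conflict=all_offend and len(opt_rows) > 0,
        offending_pairs=tuple(sorted(witnesses, key=str)),
    )


# -- whole-matrix scoring and tree ranking ----------------------------------

@dataclass(frozen=True)
class TreeScore:
    """Total inferred events for one candidate topology.

    ``scaffold_class_counts`` tallies scaffolds by their minimal event
    number (key 3 collects 3 or more); the total equals
    ``1*count[1] + 2*count[2] + 3*count[3+]`` when no scaffold exceeds
    three events.
    """

    tree: PhyloTree
    total_events: int
    scaffold_class_counts: Dict[int, int]
    per_scaffold: Tuple[int, ...] = ()


def score_tree(tree: PhyloTree, M: LabelMatrix) -> TreeScore:
    """Sum per-scaffold minimal event counts over the whole label matrix."""
    tree_names = set(tree.leaf_names.values())
    if tree_names != set(M.genomes):
        raise LabelingError(
            f"tree leaves {sorted(tree_names, key=str)} != matrix genomes "
            f"{sorted(M.genomes, key=str)}"
        )
    mat = M.as_array()
    ev = min_events_batch(tree, mat, M.genomes)
    counts = {0: 0, 1: 0, 2: 0, 3: 0}
    for e in ev:
        counts[min(int(e), 3)] += 1
    return TreeScore(
        tree=tree,
        total_events=int(ev.sum()),
        scaffold_class_counts=counts,
        per_scaffold=tuple(int(x) for x in ev),
    )


@dataclass(frozen=True)
class TreeRanking:
    """Scores for every candidate topology plus the reference's rank.

    Competition ranking: rank = 1 + number of strictly better (lower
    total) trees; ties share the best rank.
    """

    entries: Tuple[Tuple[str, int], ...]  # (topology key, total events)
    reference_key: str
    reference_total: int
    reference_rank: int


def rank_trees(
    M: LabelMatrix, trees: Sequence[PhyloTree], reference: PhyloTree
) -> TreeRanking:
    """Score every tree and rank the reference topology among them."""
    ref_key = topology_key(reference)
    entries = []
    ref_total = None
    for t in trees:
        key = topology_key(t)
        total = score_tree(t, M).total_events
        entries.append((str(key), total))
        if key == ref_key:
            ref_total = total
    if ref_total is None:
        raise LabelingError("reference tree is not among the candidate trees")
    rank = 1 + sum(1 for _, tot in entries if tot < ref_total)
    return TreeRanking(
        entries=tuple(entries),
        reference_key=str(ref_key),
        reference_total=ref_total,
        reference_rank=rank,
    )
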