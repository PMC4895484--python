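"""Simulation of inversion evolution along a tree plus scaffold fragmentation.

A root genome (the identity signed permutation of ``1..n``) sits on a
randomly chosen internal vertex; along every branch, ``k`` inversions with
independently uniform boundary pairs are applied, walking outward from the
root.  One designated leaf genome is then cut into ``m`` scaffolds at
``m - 1`` distinct uniformly chosen internal boundaries, which for m << n
yields approximately geometric scaffold sizes.  Every inversion is logged
with its branch and the adjacencies it destroyed, so ground truth is
available for every downstream experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Hashable, List, Tuple

import numpy as np

from .genomes import (
    Adjacency,
    FragmentedGenome,
    Genome,
    GenomeError,
    Scaffold,
    canonical_adjacency,
    identity_genome,
)
from .trees import Edge, PhyloTree, random_binary_unrooted_tree, write_newick
from . import grimm


@dataclass(frozen=True)
class TrueEvent:
    """One simulated inversion: where it happened and what it broke.

    ``cut_left``/``cut_right`` are boundary indices in the genome state at
    the moment of application.  ``broken_adjacencies`` holds the 2 canonical
    adjacencies destroyed by an interior inversion, 1 when a cut sits on a
    chromosome end (0 only in the degenerate full-chromosome reversal).
    """

    branch: Edge
    cut_left: int
    cut_right: int
    broken_adjacencies: Tuple[Adjacency, ...]


@dataclass(frozen=True)
class SimulationResult:
    tree: PhyloTree
    root_vertex: int
    leaf_genomes: Dict[Hashable, Genome]
    designated: Hashable
    fragmented: FragmentedGenome
    events: Tuple[TrueEvent, ...]
    seed: int | None


def _sample_inversion(n: int, rng: np.random.Generator) -> Tuple[int, int]:
    """Two distinct boundaries uniform over the (n+1 choose 2) pairs."""
    a, b = rng.choice(n + 1, size=2, replace=False)
    return (int(a), int(b)) if a < b else (int(b), int(a))


def _broken(genes: Tuple[int, ...], cut: int) -> Adjacency | None:
    n = len(genes)
    if 0 < cut < n:
        return canonical_adjacency(genes[cut - 1], genes[cut])
    return None


def evolve_genomes(
    tree: PhyloTree,
    n_genes: int,
    k_per_branch: int,
    rng: np.random.Generator,
    root_vertex: int | None = None,
) -> Tuple[Dict[Hashable, Genome], List[TrueEvent], int]:
    """Evolve an identity root genome outward along every branch.

    Each edge receives exactly ``k_per_branch`` inversions, sampled
    independently.  Branches are visited in a deterministic (sorted
    depth-first) order so the whole run is reproducible from the generator
    state.  Returns ``(leaf genomes keyed by leaf name, event log, root)``.
    """
    if n_genes < 2:
        raise GenomeError("need at least 2 genes")
    if k_per_branch < 0:
        raise GenomeError("k_per_branch must be >= 0")
    internal = tree.internal_vertices
    if root_vertex is None:
        root_vertex = int(internal[int(rng.integers(len(internal)))])
    elif root_vertex not in internal:
        raise ValueError(f"root vertex {root_vertex} is not internal")

    from .genomes import apply_inversion

    states: Dict[int, Genome] = {root_vertex: identity_genome(n_genes)}
    events: List[TrueEvent] = []
    order, parent = tree.postorder(root=root_vertex)
    # walk root->leaves (reverse postorder), children already sorted
    for v in reversed(order):
        if v == root_vertex:
            continue
        g = states[parent[v]]  # type: ignore[index]
        branch = (min(v, parent[v]), max(v, parent[v]))  # type: ignore[type-var]
        for _ in range(k_per_branch):
            l, r = _sample_inversion(n_genes, rng)
            broken = tuple(
                adj for adj in (_broken(g.genes, l), _broken(g.genes, r)) if adj
            )
            events.append(TrueEvent(branch, l, r, broken))
            g = apply_inversion(g, l, r)
        states[v] = g
    leaf_genomes = {
        tree.leaf_names[v]: Genome(states[v].genes, name=str(tree.leaf_names[v]))
        for v in tree.leaves
    }
    return leaf_genomes, events, root_vertex


def replay_events(
    tree: PhyloTree, root_vertex: int, events: List[TrueEvent] | Tuple[TrueEvent, ...], n_genes: int
) -> Dict[Hashable, Genome]:
    """Reconstruct leaf genomes from the event log alone.

    Applies the logged cut pairs grouped by branch, walking outward from
    the root in the same deterministic order as :func:`evolve_genomes`;
    exact agreement with the simulated leaves is a correctness check on
    the log.
    """
    from .genomes import apply_inversion

    by_branch: Dict[Edge, List[TrueEvent]] = {}
    for ev in events:
        by_branch.setdefault(ev.branch, []).append(ev)
    states: Dict[int, Genome] = {root_vertex: identity_genome(n_genes)}
    order, parent = tree.postorder(root=root_vertex)
    for v in reversed(order):
        if v == root_vertex:
            continue
        g = states[parent[v]]  # type: ignore[index]
        branch = (min(v, parent[v]), max(v, parent[v]))  # type: ignore[type-var]
        for ev in by_branch.get(branch, []):
            g = apply_inversion(g, ev.cut_left, ev.cut_right)
        states[v] = g
    return {
        tree.leaf_names[v]: Genome(states[v].genes, name=str(tree.leaf_names[v]))
        for v in tree.leaves
    }


def fragment_genome(g: Genome, m: int, rng: np.random.Generator) -> FragmentedGenome:
    """Cut ``g`` into exactly ``m`` scaffolds at uniform distinct boundaries.

    The ``m - 1`` cut positions are drawn without replacement from the
    ``n - 1`` internal boundaries; for m << n the resulting sizes are
    approximately geometric with mean ``n / m``.
    """
    n = len(g)
    if not (1 <= m <= n):
        raise GenomeError(f"scaffold count m={m} must be in [1, {n}]")
    cuts = np.sort(rng.choice(n - 1, size=m - 1, replace=False)) + 1 if m > 1 else []
    bounds = [0, *map(int, cuts), n]
    scaffolds = tuple(
        Scaffold(i, g.genes[bounds[i] : bounds[i + 1]]) for i in range(m)
    )
    return FragmentedGenome(scaffolds, source_name=g.name)


def simulate_dataset(
    N: int = 7,
    n_genes: int = 1000,
    k_per_branch: int = 1,
    m_scaffolds: int = 100,
    rng: np.random.Generator | int | None = None,
    designated: Hashable = 1,
) -> SimulationResult:
    """One full synthetic dataset: tree, genomes, fragmentation, event log.

    Defaults mirror the study conditions: 7 genomes, a 1000-gene
    unichromosomal root, uniform random binary unrooted topology, the
    designated genome (leaf 1) fragmented into ``m_scaffolds`` scaffolds.
    Fully reproducible from the generator / integer seed.
    """
    if N < 4:
        raise ValueError("need at least 4 genomes")
    seed = rng if isinstance(rng, int) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tree = random_binary_unrooted_tree(N, gen)
    leaf_genomes, events, root_vertex = evolve_genomes(tree, n_genes, k_per_branch, gen)
    if designated not in leaf_genomes:
        raise ValueError(f"designated genome {designated!r} is not a leaf")
    fragmented = fragment_genome(leaf_genomes[designated], m_scaffolds, gen)
    return SimulationResult(
        tree=tree,
        root_vertex=root_vertex,
        leaf_genomes=leaf_genomes,
        designated=designated,
        fragmented=fragmented,
        events=tuple(events),
        seed=seed,
    )


def write_dataset(sim: SimulationResult, outdir: str | Path) -> None:
    """Write genomes (GRIMM), fragmented genome (GRIMM), tree (Newick) and
    the event log (TSV) into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    order = sorted(sim.leaf_genomes, key=str)
    grimm.write_grimm(out / "genomes.txt", [sim.leaf_genomes[k] for k in order])
    grimm.write_fragmented(out / "fragmented.txt", sim.fragmented)
    (out / "tree.nwk").write_text(write_newick(sim.tree) + "\n")
    lines = ["branch_u\tbranch_v\tcut_left\tcut_right\tbroken_adjacencies"]
    for ev in sim.events:
        adjs = ";".join(f"{a.left},{a.right}" for a in ev.broken_adjacencies)
        lines.append(
            f"{ev.branch[0]}\t{ev.branch[1]}\t{ev.cut_left}\t{ev.cut_right}\t{adjs}"
        )
    (out / "events.tsv").write_text("\n".join(lines) + "\n")
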