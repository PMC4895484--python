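# Methods

## Model and representations

**Genomes.** A genome is one linear chromosome written as a signed
permutation of `1..n` (sign = reading orientation). The model assumes
equal, single-copy gene content: no duplication, loss, fractionation or
multichromosomal events. An *adjacency* is an ordered, orientation-aware
pair of neighbouring genes, stored canonically so that `(a, b)` and
`(−b, −a)` — the same junction read from the opposite strand — compare
equal. Telomeres carry no adjacency, so an `n`-gene genome has exactly
`n − 1` adjacencies. A *breakpoint* between two genomes is an adjacency of
one absent from the other; the two directions always have equal
cardinality.

**Inversions.** An inversion is specified by two inter-gene boundaries
`0 ≤ l < r ≤ n` (0 = before the first gene); the genes strictly between
the boundaries are reversed with signs flipped. The operation is an
involution. With both cuts interior it disrupts exactly two adjacencies;
with a cut on a chromosome end, one; the degenerate whole-chromosome
reversal (both cuts at the ends, probability `2/(n+1 choose 2)` under the
sampler below) disrupts none. This is why, at low rates, `k` inversions
yield slightly fewer than `2k` observable breakpoints even before
fragmentation losses.

**Scaffolds.** A fragmented genome is an ordered partition of its source
into contiguous signed runs. Only adjacencies *internal* to a scaffold are
testable; breakpoints coinciding with scaffold ends are invisible, which
is the central observational limitation being studied.

## Scaffold labeling

Against each complete genome a scaffold is labeled **1** (split: at least
one internal adjacency missing), **2** (not split: all conserved) or **3**
(can't tell). Because the other genomes are complete single chromosomes,
"split" cannot be observed as content spread over their scaffolds; the
observable signal is a disrupted adjacency, so the breakpoint criterion is
the operational definition. Single-gene scaffolds have nothing to test and
are labeled 3. The designated genome's own column is identically 2.
Label degradation (`inject_cant_tell`) replaces, per scaffold
independently, the labels of exactly `c` uniformly chosen non-designated
genomes by 3, modelling unidentifiable breakpoints in real data.

## Event parsimony

Given a candidate unrooted tree with the scaffold's leaf labels, internal
vertices are assigned 1 or 2 to minimize the number of *event edges*
(endpoints labeled 1 and 2). This is two-state unit-cost small parsimony:
a Sankoff up-pass with state costs `[0, ∞]` / `[∞, 0]` / `[0, 0]` for leaf
labels 1 / 2 / 3, rooted arbitrarily at an internal vertex (the optimum of
an unrooted tree is root-independent). The batch implementation evaluates
all scaffolds of a label matrix simultaneously as vectorized `(m, 2)` cost
arrays, which is what makes exhaustive 945-topology ranking cheap.

**Enumeration of optima.** Alternative optimal labelings are enumerated
exhaustively over the free vertices (internal vertices plus can't-tell
leaves): with at most a dozen vertices for the tree sizes this package
targets (N ≤ 9), all `2^F` completions fit comfortably in one vectorized
pass. This route is deliberately independent of the DP — the two are
cross-checked against each other and against a pure-Python oracle in the
tests. From the enumeration we report: the candidate edge set (branches
that are an event in ≥ 1 optimum), the count of optimal labelings, and
fractional branch weights — the fraction of optima in which each branch is
an event — which split each scaffold's unit scores across alternative
branches and always sum to the event number.

**Conflicts.** A pair of genomes labeled 2 shares the scaffold's
adjacencies, so no event affecting the scaffold can lie on the path
between them. A conflict is reported when *every* optimal labeling places
a 1-vertex on some 2–2 path; the report lists the witnessing leaf pairs.
Note that isolated split genomes never force a conflict (their events
resolve onto pendant edges); a forced conflict needs unsplit genomes
flanking a connected block of split ones.

**Tree scoring and ranking.** A topology's score is the sum over scaffolds
of minimal event numbers — equivalently `1·(#1-event scaffolds) +
2·(#2-event) + 3·(#3-event)` when no scaffold exceeds three. Candidate
trees are ranked by competition rank (1 + number of strictly better
trees; ties share the best rank). Competition rank is optimistic under
ties: a completely uninformative matrix ties every tree at rank 1, so the
experiments also record the number of topologies the true tree strictly
beats, which degrades monotonically as information is removed.

## Synthetic data generator

The generator reproduces the validation conditions: `N = 7` genomes,
`n = 1000` genes, a uniform random leaf-labeled unrooted binary topology
(sequential leaf addition onto a uniformly chosen edge), the identity
genome on a uniformly chosen internal root vertex (root choice is
immaterial by symmetry of inversion), exactly `k` inversions per branch
with independently uniform distinct boundary pairs, and fragmentation of
the designated leaf (leaf 1; symmetric under random topologies) into `m`
scaffolds by `m − 1` distinct uniform cuts. Uniform cuts guarantee exactly
`m` scaffolds while giving approximately geometric sizes for `m ≪ n`
(measured total-variation distance to Geometric(m/n) ≈ 0.06 at
`n = 1000, m = 100`; the size-distribution test documents a 0.1
tolerance). Every inversion is logged with its branch, cuts and destroyed
adjacencies; replaying the log reconstructs all leaf genomes exactly, and
that replay is a standing test.

What the generator does *not* emulate: gene loss/duplication and
fractionation, translocations and transpositions, rate heterogeneity
across branches, multiple fragmented genomes, and real annotation noise in
breakpoint identification. Passing simulations therefore demonstrate the
combinatorial recoverability of inversion events from single-genome
breakpoint data — not robustness to those real-data complications.

## Experiments and defaults

All experiments average 100 replicates by default, with replicate RNG
streams spawned deterministically from the master seed
(`SeedSequence(seed, spawn_key=(stage, replicate[, level]))`). Simulation
seeds depend only on the replicate index, so sweeps (scaffold count,
degradation level) re-analyse matched histories — this makes the
directional comparisons paired rather than independent.

* **Rate experiment** — `m = 100` fixed, sweep `k`; reports detected
  totals, scaffold event-class counts, breakpoint tallies and the number
  of true events whose branch appears in some scaffold's candidate set.
* **Fragmentation experiment** — `k = 5` fixed, sweep `m`; reports
  breakpoint-free scaffolds (increasing in `m`) and multi-breakpoint
  scaffolds (collisions, decreasing in `m`).
* **Ranking experiment** — `m = 60`, `k = 3` headline (the per-branch rate
  for this experiment is not pinned by the validation setup; `k = 3` is a
  small rate at which a 1000-gene genome is far from breakpoint
  saturation, and the CLI exposes the sweep); scores all 945 topologies
  per replicate and records the generating tree's rank.
* **Can't-tell experiment** — ranking repeated after label degradation at
  each level `c`, matched seeds across levels.

The acceptance script runs the first experiment at `k = 1` over 100
replicates and the ranking experiment over 30 replicates (a sample size at
which the median rank is stable while keeping the 945-topology scoring,
the dominant cost, to ~30 s on one core).

## Numerical and degenerate-input notes

* DP costs use a large-integer infinity; all arithmetic is exact integer.
* `m = 1` (no fragmentation) and `m = n` (single-gene scaffolds, all
  labels 3) are both valid; the latter is completely uninformative and
  scores 0 on every tree.
* `k = 0` produces no events: all multi-gene scaffolds label 2 everywhere,
  every topology ties at 0, rank 1 by the tie rule.
* Enumeration refuses more than 22 free vertices (beyond the supported
  tree sizes) rather than silently thrashing.
* Newick reading accepts rooted (bifurcating-base) representations and
  collapses them to unrooted form; all-digit leaf labels are read as
  integer genome indices.

## Known limitations

Exhaustive topology ranking is limited to N ≤ 9 by `(2N−5)!!` growth; the
method itself (labeling + DP) extends to larger multifurcating trees, but
no heuristic tree search is provided. Real-data labeling from syntenic
blocks, and the case where several or all genomes are fragmented, are out
of scope.
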