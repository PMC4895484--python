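"""Signed gene orders: adjacencies, breakpoints and the inversion operation.

A genome is a single linear chromosome written as a signed permutation of
``1..n``; the sign records reading orientation.  The unit of comparison
between genomes is the *adjacency* — an orientation-aware pair of immediate
neighbours — and a *breakpoint* is an adjacency present in one genome but
absent from another.  An inversion excises a segment, reverses its gene
order and flips every sign; one inversion with interior endpoints disrupts
exactly two adjacencies, one endpoint on a chromosome end disrupts one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Tuple


class GenomeError(ValueError):
    """Invalid genome, adjacency or inversion parameters."""


class ContentMismatchError(GenomeError):
    """Two genomes (or a scaffold and a genome) do not share gene content."""


@dataclass(frozen=True, order=True)
class Adjacency:
    """Canonical orientation-aware neighbour pair.

    Construct through :func:`canonical_adjacency`; ``(a, b)`` and
    ``(-b, -a)`` — the same junction read from the other strand — map to
    the identical stored value.
    """

    left: int
    right: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Adj({self.left:+d},{self.right:+d})"


def canonical_adjacency(a: int, b: int) -> Adjacency:
    """Return the canonical :class:`Adjacency` for neighbouring genes ``a, b``.

    Raises
    ------
    GenomeError
        If either gene is zero or both refer to the same gene.
    """
    if a == 0 or b == 0:
        raise GenomeError("adjacency genes must be nonzero signed integers")
    if abs(a) == abs(b):
        raise GenomeError(f"adjacency cannot join a gene to itself: {a}, {b}")
    fwd = (a, b)
    rev = (-b, -a)
    return Adjacency(*min(fwd, rev))


@dataclass(frozen=True)
class Genome:
    """A single linear chromosome as a signed permutation of ``1..n``."""

    genes: Tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        genes = tuple(int(g) for g in self.genes)
        object.__setattr__(self, "genes", genes)
        n = len(genes)
        if n == 0:
            raise GenomeError("genome must contain at least one gene")
        content = set(abs(g) for g in genes)
        if 0 in content or len(content) != n or content != set(range(1, n + 1)):
            raise GenomeError(
                "genes must be a signed permutation of 1..n (single copy, "
                f"equal content); got {genes[:10]}..."
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[int]:
        return iter(self.genes)


def identity_genome(n: int, name: str = "") -> Genome:
    """The unrearranged reference order ``(1, 2, ..., n)``."""
    return Genome(tuple(range(1, n + 1)), name=name)


def adjacency_set(g: Genome | Sequence[int]) -> frozenset[Adjacency]:
    """All ``n - 1`` canonical adjacencies of a linear genome.

    Telomeres (chromosome ends) carry no adjacency.
    """
    genes = g.genes if isinstance(g, Genome) else tuple(g)
    return frozenset(
        canonical_adjacency(genes[i], genes[i + 1]) for i in range(len(genes) - 1)
    )


def breakpoint_set(a: Genome, b: Genome) -> frozenset[Adjacency]:
    """Adjacencies of ``a`` that are disrupted in ``b``.

    ``|breakpoint_set(a, b)| == |breakpoint_set(b, a)|`` always, since both
    genomes have ``n - 1`` adjacencies and shared ones cancel symmetrically.
    """
    if set(abs(g) for g in a.genes) != set(abs(g) for g in b.genes):
        raise ContentMismatchError(
            f"genomes {a.name!r} and {b.name!r} differ in gene content"
        )
    return adjacency_set(a) - adjacency_set(b)


def apply_inversion(g: Genome, cut_left: int, cut_right: int) -> Genome:
    """Invert the segment between two inter-gene boundaries.

    Boundaries are 0-based positions in ``[0, n]``: boundary ``i`` lies
    before the gene at index ``i`` (boundary 0 precedes the first gene,
    boundary ``n`` follows the last).  The genes strictly between the two
    boundaries are reversed in order with all signs flipped.  Applying the
    same inversion twice restores the original genome.
    """
    n = len(g)
    if not (0 <= cut_left < cut_right <= n):
        raise GenomeError(
            f"invalid inversion segment: cuts ({cut_left}, {cut_right}) "
            f"must satisfy 0 <= left < right <= {n}"
        )
    genes = g.genes
    segment = tuple(-x for x in reversed(genes[cut_left:cut_right]))
    return Genome(genes[:cut_left] + segment + genes[cut_right:], name=g.name)


@dataclass(frozen=True)
class Scaffold:
    """A contiguous ordered run of genes from a fragmented assembly."""

    id: int
    genes: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(int(g) for g in self.genes))
        if len(self.genes) == 0:
            raise GenomeError("scaffold must contain at least one gene")

    def __len__(self) -> int:
        return len(self.genes)

    def internal_adjacencies(self) -> frozenset[Adjacency]:
        """Adjacencies between consecutive genes inside this scaffold."""
        return frozenset(
            canonical_adjacency(self.genes[i], self.genes[i + 1])
            for i in range(len(self.genes) - 1)
        )


@dataclass(frozen=True)
class FragmentedGenome:
    """An ordered partition of a source genome into scaffolds.

    Concatenating the scaffolds in order reconstructs the source genome
    exactly; scaffold order/orientation is what a fragmented assembly does
    *not* know, but the simulator retains it so ground truth stays checkable.
    """

    scaffolds: Tuple[Scaffold, ...]
    source_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "scaffolds", tuple(self.scaffolds))
        if not self.scaffolds:
            raise GenomeError("fragmented genome must have at least one scaffold")

    @property
    def m(self) -> int:
        return len(self.scaffolds)

    def reassemble(self) -> Genome:
        """Concatenate scaffolds back into the source genome."""
        genes: list[int] = []
        for s in self.scaffolds:
            genes.extend(s.genes)
        return Genome(tuple(genes), name=self.source_name)
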