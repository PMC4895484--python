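"""Scaffold labels against complete genomes: split / not split / can't tell.

For each scaffold of the designated (fragmented) genome and each complete
genome we record one of three labels:

* ``1`` (split) — at least one internal adjacency of the scaffold is absent
  from the other genome, i.e. a breakpoint falls inside the scaffold;
* ``2`` (not split) — every internal adjacency is conserved;
* ``3`` (can't tell) — no testable adjacency (single-gene scaffold) or the
  label was deliberately degraded to model unidentifiable breakpoints.

The designated genome's own column is fixed at 2: a scaffold is trivially
unsplit in the genome it came from.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Hashable, Mapping, Tuple

import numpy as np

from .genomes import (
    ContentMismatchError,
    FragmentedGenome,
    Genome,
    Scaffold,
    adjacency_set,
)

SPLIT, NOT_SPLIT, CANT_TELL = 1, 2, 3


def label_scaffold(s: Scaffold, g: Genome) -> int:
    """Label one scaffold against one complete genome.

    Single-gene scaffolds have no internal adjacency to test and get 3.
    """
    content = {abs(x) for x in g.genes}
    if not {abs(x) for x in s.genes} <= content:
        raise ContentMismatchError(
            f"scaffold {s.id} has genes absent from genome {g.name!r}"
        )
    if len(s) < 2:
        return CANT_TELL
    adj = adjacency_set(g)
    return NOT_SPLIT if s.internal_adjacencies() <= adj else SPLIT


@dataclass(frozen=True)
class LabelMatrix:
    """Per (scaffold, genome) labels in {1, 2, 3}."""

    labels: Mapping[Tuple[int, Hashable], int]
    scaffold_ids: Tuple[int, ...]
    genomes: Tuple[Hashable, ...]
    designated: Hashable

    def __post_init__(self) -> None:
        for sid in self.scaffold_ids:
            for g in self.genomes:
                v = self.labels[(sid, g)]
                if v not in (1, 2, 3):
                    raise ValueError(f"label {v} at ({sid}, {g}) not in {{1,2,3}}")
            if self.labels[(sid, self.designated)] != NOT_SPLIT:
                raise ValueError("designated genome column must be all 2")

    def row(self, sid: int) -> Dict[Hashable, int]:
        return {g: self.labels[(sid, g)] for g in self.genomes}

    def as_array(self, genome_order: Tuple[Hashable, ...] | None = None) -> np.ndarray:
        """(m, N) int8 array of labels, rows in scaffold-id order."""
        order = genome_order if genome_order is not None else self.genomes
        return np.array(
            [[self.labels[(sid, g)] for g in order] for sid in self.scaffold_ids],
            dtype=np.int8,
        )

    # -- serialization -----------------------------------------------------
    def to_tsv(self) -> str:
        lines = [f"# designated: {self.designated}"]
        lines.append("scaffold\t" + "\t".join(str(g) for g in self.genomes))
        for sid in self.scaffold_ids:
            lines.append(
                f"{sid}\t" + "\t".join(str(self.labels[(sid, g)]) for g in self.genomes)
            )
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())

    @classmethod
    def from_tsv(cls, text: str) -> "LabelMatrix":
        lines = [l for l in text.splitlines() if l.strip()]
        designated: Hashable | None = None
        if lines and lines[0].startswith("#"):
            _, _, val = lines.pop(0).partition(":")
            val = val.strip()
            designated = int(val) if val.lstrip("-").isdigit() else val
        header = lines.pop(0).split("\t")
        if header[0] != "scaffold":
            raise ValueError("label TSV must start with a 'scaffold' header column")
        genomes = tuple(int(h) if h.lstrip("-").isdigit() else h for h in header[1:])
        if designated is None:
            raise ValueError("label TSV missing '# designated:' line")
        labels: Dict[Tuple[int, Hashable], int] = {}
        sids = []
        for line in lines:
            parts = line.split("\t")
            sid = int(parts[0])
            sids.append(sid)
            for g, v in zip(genomes, parts[1:]):
                labels[(sid, g)] = int(v)
        return cls(labels, tuple(sids), genomes, designated)

    @classmethod
    def read(cls, path: str | Path) -> "LabelMatrix":
        return cls.from_tsv(Path(path).read_text())


def build_label_matrix(
    f: FragmentedGenome,
    genomes: Mapping[Hashable, Genome],
    designated: Hashable,
) -> LabelMatrix:
    """Label every scaffold of ``f`` against every complete genome.

    ``genomes`` maps leaf name -> complete genome and must include the
    designated genome (whose column is fixed at 2).
    """
    if designated not in genomes:
        raise ValueError(f"designated genome {designated!r} missing from genomes")
    order = tuple(sorted(genomes, key=str))
    adj_cache = {k: adjacency_set(g) for k, g in genomes.items()}
    content = {k: {abs(x) for x in g.genes} for k, g in genomes.items()}
    labels: Dict[Tuple[int, Hashable], int] = {}
    sids = tuple(s.id for s in f.scaffolds)
    for s in f.scaffolds:
        s_content = {abs(x) for x in s.genes}
        s_adj = s.internal_adjacencies() if len(s) > 1 else None
        for k in order:
            if k == designated:
                labels[(s.id, k)] = NOT_SPLIT
                continue
            if not s_content <= content[k]:
                raise ContentMismatchError(
                    f"scaffold {s.id} has genes absent from genome {k!r}"
                )
            if s_adj is None:
                labels[(s.id, k)] = CANT_TELL
            else:
                labels[(s.id, k)] = NOT_SPLIT if s_adj <= adj_cache[k] else SPLIT
    return LabelMatrix(labels, sids, order, designated)


def inject_cant_tell(
    M: LabelMatrix, c: int, rng: np.random.Generator
) -> LabelMatrix:
    """Degrade labels: per scaffold, ``c`` random non-designated genomes -> 3.

    Models unidentifiable breakpoints in real data.  For each scaffold
    independently, exactly ``c`` distinct non-designated genomes (uniform
    without replacement) have their label replaced by "can't tell"; the
    designated column is untouched.
    """
    others = [g for g in M.genomes if g != M.designated]
    if not (0 <= c <= len(others)):
        raise ValueError(f"c={c} out of range [0, {len(others)}]")
    labels = dict(M.labels)
    if c > 0:
        for sid in M.scaffold_ids:
            picks = rng.choice(len(others), size=c, replace=False)
            for j in picks:
                labels[(sid, others[int(j)])] = CANT_TELL
    return LabelMatrix(labels, M.scaffold_ids, M.genomes, M.designated)
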