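"""GRIMM-style signed gene-order text I/O.

Format: a record per genome — a header line ``>name`` followed by
whitespace-separated signed integers terminated by ``$`` (linear
chromosome).  One chromosome per genome; circular chromosomes (``@``) are
not part of the model.  Reading then writing a canonical file is bit-exact.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from .genomes import FragmentedGenome, Genome, GenomeError, Scaffold


class GrimmFormatError(GenomeError):
    """Malformed GRIMM text."""


def _parse_records(text: str) -> list[tuple[str, tuple[int, ...]]]:
    records: list[tuple[str, tuple[int, ...]]] = []
    name: str | None = None
    genes: list[int] = []
    closed = True

    def flush() -> None:
        nonlocal name, genes, closed
        if name is None:
            return
        if not closed:
            raise GrimmFormatError(f"record {name!r} not terminated by '$'")
        records.append((name, tuple(genes)))
        name, genes, closed = None, [], True

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            if not name:
                raise GrimmFormatError(f"line {lineno}: empty genome name")
            closed = False
            continue
        if name is None:
            raise GrimmFormatError(f"line {lineno}: gene data before any '>' header")
        for tok in line.split():
            if tok == "$":
                if closed:
                    raise GrimmFormatError(
                        f"line {lineno}: second chromosome in record {name!r}; "
                        "only unichromosomal genomes are supported"
                    )
                closed = True
            elif tok == "@":
                raise GrimmFormatError(
                    f"line {lineno}: circular chromosomes ('@') are not supported"
                )
            else:
                if closed:
                    raise GrimmFormatError(
                        f"line {lineno}: gene {tok!r} after '$' in record {name!r}"
                    )
                try:
                    genes.append(int(tok))
                except ValueError:
                    raise GrimmFormatError(
                        f"line {lineno}: {tok!r} is not a signed integer"
                    ) from None
    flush()
    if not records:
        raise GrimmFormatError("no genome records found")
    return records


def parse_genomes(text: str) -> list[Genome]:
    """Parse GRIMM text into a list of :class:`Genome`."""
    return [Genome(genes, name=name) for name, genes in _parse_records(text)]


def format_genomes(genomes: Iterable[Genome]) -> str:
    """Serialize genomes to canonical GRIMM text."""
    parts = []
    for g in genomes:
        body = " ".join(str(x) for x in g.genes)
        parts.append(f">{g.name}\n{body} $\n")
    return "".join(parts)


def read_grimm(path: str | Path) -> list[Genome]:
    return parse_genomes(Path(path).read_text())


def write_grimm(path: str | Path, genomes: Iterable[Genome]) -> None:
    Path(path).write_text(format_genomes(genomes))


def parse_fragmented(text: str, source_name: str = "") -> FragmentedGenome:
    """Parse a GRIMM file with one ``>scaffold_i`` record per scaffold.

    Scaffold ids are taken from a trailing integer in the record name when
    present, else assigned 0..m-1 in file order.
    """
    records = _parse_records(text)
    scaffolds = []
    for i, (name, genes) in enumerate(records):
        sid = i
        tail = name.rsplit("_", 1)[-1]
        if tail.isdigit():
            sid = int(tail)
        scaffolds.append(Scaffold(sid, genes))
    return FragmentedGenome(tuple(scaffolds), source_name=source_name)


def format_fragmented(f: FragmentedGenome) -> str:
    parts = []
    for s in f.scaffolds:
        body = " ".join(str(x) for x in s.genes)
        parts.append(f">scaffold_{s.id}\n{body} $\n")
    return "".join(parts)


def read_fragmented(path: str | Path, source_name: str = "") -> FragmentedGenome:
    return parse_fragmented(Path(path).read_text(), source_name=source_name)


def write_fragmented(path: str | Path, f: FragmentedGenome) -> None:
    Path(path).write_text(format_fragmented(f))
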