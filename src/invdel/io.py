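"""Gene-order file format for circular genomes.

The dialect is GRIMM-style: a record is a header line ``>NAME`` followed
by whitespace-separated region tokens terminated by ``@`` (the circular
terminator; tokens may continue over several lines).  Blank lines and
``#`` comments are ignored.  The linear terminator ``$`` is rejected —
this model is defined for single circular chromosomes only.
"""

from __future__ import annotations

from typing import Iterable, TextIO

from .genomes import ReferenceFrame

__all__ = ["parse_genomes", "format_genomes", "read_genome_file",
           "write_genome_file"]


class GenomeFormatError(ValueError):
    """Malformed gene-order input."""


def parse_genomes(text: str) -> list[tuple[str, ReferenceFrame]]:
    """Parse gene-order records into (name, reference frame) pairs.

    The token order is the reference frame exactly as written, position
    1 first.  Duplicate labels, missing ``@`` terminators, empty records
    and linear ``$`` terminators are all rejected with the offending
    name and token.
    """
    records: list[tuple[str, ReferenceFrame]] = []
    name: str | None = None
    tokens: list[str] = []
    closed = False

    def flush():
        nonlocal name, tokens, closed
        if name is None:
            return
        if not closed:
            raise GenomeFormatError(
                f"record {name!r} is missing the circular terminator '@'")
        if not tokens:
            raise GenomeFormatError(f"record {name!r} has no regions")
        seen = set()
        for tok in tokens:
            if tok in seen:
                raise GenomeFormatError(
                    f"duplicate region label {tok!r} in record {name!r}")
            seen.add(tok)
        records.append((name, ReferenceFrame(tokens)))
        name, tokens, closed = None, [], False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            if not name:
                raise GenomeFormatError(
                    f"line {lineno}: header without a name")
            continue
        if name is None:
            raise GenomeFormatError(
                f"line {lineno}: region tokens before any '>' header")
        if closed:
            raise GenomeFormatError(
                f"line {lineno}: tokens after the '@' terminator of "
                f"record {name!r}")
        for tok in line.split():
            if tok == "$":
                raise GenomeFormatError(
                    f"record {name!r}: linear terminator '$' is not "
                    "supported; this model is for circular chromosomes "
                    "(use '@')")
            if tok == "@":
                closed = True
            elif closed:
                raise GenomeFormatError(
                    f"record {name!r}: token {tok!r} after '@'")
            else:
                tokens.append(tok)
    flush()
    return records


def format_genomes(records: Iterable[tuple[str, ReferenceFrame]]) -> str:
    """Render (name, frame) pairs in the gene-order dialect."""
    chunks = []
    for name, frame in records:
        chunks.append(f">{name}\n{' '.join(frame.word)} @\n")
    return "".join(chunks)


def read_genome_file(handle: TextIO) -> list[tuple[str, ReferenceFrame]]:
    return parse_genomes(handle.read())


def write_genome_file(handle: TextIO,
                      records: Iterable[tuple[str, ReferenceFrame]]) -> None:
    handle.write(format_genomes(records))
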