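"""Circular genomes as dihedral equivalence classes of region words.

A circular bacterial chromosome with ``n`` distinct conserved regions is
read clockwise from a distinguished point, giving a word of region
labels.  Rotating or reflecting the chromosome in space changes the word
but not the genome, so a *genome* is the equivalence class of a word
under the dihedral group ``D_n`` and a *reference frame* is one concrete
reading — equivalently a bijection from regions to positions ``1..n``.

The module also builds the alignment partial permutation ``sigma``
between two frames (position ``i`` of the first frame maps to position
``j`` of the second iff both hold the same region label) and applies
words of elementary operations to frames.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .algebra import ElementaryOp, PartialPerm

__all__ = [
    "ReferenceFrame",
    "Genome",
    "OpWord",
    "genome_from_word",
    "reference_frames",
    "sigma",
    "apply_word",
]


class ReferenceFrame:
    """One clockwise reading of a circular genome.

    ``word[0]`` is the region at position 1.  Labels are opaque tokens
    and must be pairwise distinct.
    """

    __slots__ = ("word",)

    def __init__(self, labels: Iterable[str]):
        word = tuple(labels)
        if not word:
            raise ValueError("a reference frame needs at least one region")
        seen = set()
        for tok in word:
            if tok in seen:
                raise ValueError(f"duplicate region label {tok!r}")
            seen.add(tok)
        object.__setattr__(self, "word", word)

    def __setattr__(self, name, value):  # pragma: no cover
        raise AttributeError("ReferenceFrame is immutable")

    def __len__(self) -> int:
        return len(self.word)

    def __iter__(self):
        return iter(self.word)

    def __eq__(self, other):
        if not isinstance(other, ReferenceFrame):
            return NotImplemented
        return self.word == other.word

    def __hash__(self):
        return hash(self.word)

    def __repr__(self):
        return f"ReferenceFrame({' '.join(self.word)})"

    @property
    def regions(self) -> frozenset:
        return frozenset(self.word)

    def position_of(self, label: str) -> int:
        """1-based position of ``label`` in this frame."""
        return self.word.index(label) + 1

    def rotate(self, steps: int = 1) -> "ReferenceFrame":
        """Reading of the same circle started ``steps`` positions later.

        The region at old position ``p`` appears at new position
        ``p - steps`` (mod n); equivalently the frame composed on the
        right with ``c_n^{-steps}``.
        """
        n = len(self.word)
        k = steps % n
        return ReferenceFrame(self.word[k:] + self.word[:k])

    def reflect(self) -> "ReferenceFrame":
        """Frame after the reflection (reads the circle the other way)."""
        return ReferenceFrame(self.word[::-1])

    def genome(self) -> "Genome":
        return Genome(self.word)


class Genome:
    """A circular genome: the dihedral orbit of a region word.

    Two genomes are equal iff their canonical words are equal; the
    canonical word is the lexicographically least member of the orbit
    (plain string ordering of tokens).
    """

    __slots__ = ("canonical",)

    def __init__(self, labels: Iterable[str]):
        frame = ReferenceFrame(labels)
        orbit = _dihedral_orbit(frame.word)
        object.__setattr__(self, "canonical", min(orbit))

    def __setattr__(self, name, value):  # pragma: no cover
        raise AttributeError("Genome is immutable")

    def __eq__(self, other):
        if not isinstance(other, Genome):
            return NotImplemented
        return self.canonical == other.canonical

    def __hash__(self):
        return hash(self.canonical)

    def __len__(self):
        return len(self.canonical)

    def __repr__(self):
        return f"Genome[{' '.join(self.canonical)}]"

    @property
    def regions(self) -> frozenset:
        return frozenset(self.canonical)

    def canonical_frame(self) -> ReferenceFrame:
        return ReferenceFrame(self.canonical)

    def frames(self) -> list[ReferenceFrame]:
        """All distinct reference frames, in sorted order (2n for n >= 3)."""
        return [ReferenceFrame(w)
                for w in sorted(_dihedral_orbit(self.canonical))]

    def __contains__(self, frame: ReferenceFrame) -> bool:
        return (isinstance(frame, ReferenceFrame)
                and Genome(frame.word) == self)


def _dihedral_orbit(word: tuple) -> set:
    """All distinct rotations and reflected rotations of ``word``.

    Degenerate small orbits (n = 1, 2) fall out of the set construction
    without special casing.
    """
    n = len(word)
    orbit = set()
    rev = word[::-1]
    for k in range(n):
        orbit.add(word[k:] + word[:k])
        orbit.add(rev[k:] + rev[:k])
    return orbit


def genome_from_word(labels: Iterable[str]) -> Genome:
    """Genome (dihedral class) of a region word; duplicates are rejected."""
    return Genome(labels)


def reference_frames(genome: Genome) -> list[ReferenceFrame]:
    """All reference frames of ``genome`` in deterministic sorted order."""
    return genome.frames()


def sigma(g1: ReferenceFrame, g2: ReferenceFrame) -> PartialPerm:
    """Alignment partial permutation between two frames.

    ``(i)sigma = j`` iff the region at position ``i`` of ``g1`` equals
    the region at position ``j`` of ``g2``; its rank is the number of
    shared regions, its crossings measure their disorder.
    """
    pos2 = {tok: j for j, tok in enumerate(g2.word, start=1)}
    pairs = tuple((i, pos2[tok])
                  for i, tok in enumerate(g1.word, start=1)
                  if tok in pos2)
    return PartialPerm(len(g1), len(g2), pairs)


class OpWord:
    """A composable word of elementary operations (a path in the free
    category over inversions, deletions, rotations and reflections).

    Consecutive letters must chain: a letter with target size ``n`` may
    only be followed by a letter with source size ``n``.  ``length``
    counts inversion and deletion letters only — rotations and
    reflections change the viewpoint, not the genome, and are free.
    """

    __slots__ = ("ops",)

    def __init__(self, ops: Sequence[ElementaryOp] = ()):
        ops = tuple(ops)
        for prev, nxt in zip(ops, ops[1:]):
            if prev.target_size != nxt.source_size:
                raise ValueError(
                    f"size chain break: {prev} yields {prev.target_size} "
                    f"positions but {nxt} expects {nxt.source_size}")
        object.__setattr__(self, "ops", ops)

    def __setattr__(self, name, value):  # pragma: no cover
        raise AttributeError("OpWord is immutable")

    def __len__(self):
        return len(self.ops)

    def __iter__(self):
        return iter(self.ops)

    def __eq__(self, other):
        if not isinstance(other, OpWord):
            return NotImplemented
        return self.ops == other.ops

    def __hash__(self):
        return hash(self.ops)

    def __repr__(self):
        return f"OpWord({self})"

    def __str__(self):
        return " ".join(str(op) for op in self.ops) or "(empty)"

    @property
    def length(self) -> int:
        """Evolutionary cost: number of inversion/deletion letters."""
        return sum(1 for op in self.ops if op.counts_toward_length)

    @property
    def source_size(self) -> int:
        return self.ops[0].source_size if self.ops else 0

    @property
    def target_size(self) -> int:
        return self.ops[-1].target_size if self.ops else 0

    def realize(self, size: int | None = None) -> PartialPerm:
        """The partial permutation the word evaluates to.

        For the empty word ``size`` must be given (identity at that
        object of the category).
        """
        if not self.ops:
            if size is None:
                raise ValueError("empty word needs an explicit size")
            from .algebra import identity
            return identity(size)
        result = self.ops[0].realize()
        for op in self.ops[1:]:
            result = result * op.realize()
        return result


def apply_word(frame: ReferenceFrame, word: OpWord
               ) -> tuple[ReferenceFrame, list[str]]:
    """Apply an operation word to a frame, tracking deleted regions.

    Returns the frame of surviving regions in their new positions (the
    restriction of the composed map to its domain) together with the
    deleted labels in deletion order.  A word that would empty the
    genome is rejected.
    """
    labels = list(frame.word)
    deleted: list[str] = []
    for op in word:
        n = len(labels)
        if op.source_size != n:
            raise ValueError(
                f"operation {op} expects {op.source_size} positions "
                f"but the frame has {n}")
        if op.tag == "inversion":
            a, b = (0, n - 1) if op.index == n else (op.index - 1, op.index)
            labels[a], labels[b] = labels[b], labels[a]
        elif op.tag == "deletion":
            if n == 1:
                raise ValueError("cannot delete the last remaining region")
            deleted.append(labels.pop(op.index - 1))
        elif op.tag == "rotation":
            # right-composition with c_n sends position p to p + 1 (mod n)
            labels = labels[-1:] + labels[:-1]
        else:  # reflection
            labels.reverse()
    return ReferenceFrame(labels), deleted
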