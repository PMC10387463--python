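"""Partial permutations between finite position sets.

A partial permutation is an injective map defined on a subset of the
positions ``{1..m}``, taking values in ``{1..n}``.  The collection of all
such maps for fixed ``m = n`` is the symmetric inverse monoid ``I_n``;
letting the two sizes differ gives the arrows of the symmetric inverse
category.  Partial permutations are the universal currency of this
package: they encode the relative order of regions shared by two circular
genomes, and they realise the elementary rearrangement operations
(adjacent inversions, single-region deletions, rotations, reflections).

Two conventions are fixed globally and never deviated from:

* positions are 1-based;
* maps are written on the right, so ``compose(f, g)`` applies ``f``
  first: ``(i)fg = ((i)f)g``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional


__all__ = [
    "PartialPerm",
    "ElementaryOp",
    "compose",
    "invert",
    "identity",
    "inversion",
    "deletion",
    "rotation",
    "reflection",
    "transpositions",
    "deletions",
    "crossings",
    "is_order_preserving",
    "is_orientation_preserving",
]


class PartialPerm:
    """An injective partial map from ``{1..source_size}`` to ``{1..target_size}``.

    Equality and hashing are structural: two partial permutations are
    equal iff their sizes and pair sets coincide.  Instances are
    immutable and safe to use as search-state keys.

    Parameters
    ----------
    source_size:
        Number of source positions ``m`` (>= 0).
    target_size:
        Number of target positions ``n`` (>= 0).
    pairs:
        Iterable of ``(i, j)`` pairs with ``1 <= i <= m``, ``1 <= j <= n``.
        No first coordinate and no second coordinate may repeat.
    """

    __slots__ = ("source_size", "target_size", "pairs", "_map", "_hash")

    source_size: int
    target_size: int
    pairs: tuple

    def __init__(self, source_size: int, target_size: int,
                 pairs: Iterable[tuple[int, int]] = ()):
        if source_size < 0 or target_size < 0:
            raise ValueError("sizes must be nonnegative")
        pairs = tuple(sorted(pairs))
        seen_i, seen_j = set(), set()
        for i, j in pairs:
            if not (1 <= i <= source_size):
                raise ValueError(
                    f"domain position {i} outside 1..{source_size}")
            if not (1 <= j <= target_size):
                raise ValueError(
                    f"image position {j} outside 1..{target_size}")
            if i in seen_i:
                raise ValueError(f"domain position {i} mapped twice")
            if j in seen_j:
                raise ValueError(f"image position {j} hit twice")
            seen_i.add(i)
            seen_j.add(j)
        object.__setattr__(self, "source_size", source_size)
        object.__setattr__(self, "target_size", target_size)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "_map", None)
        object.__setattr__(self, "_hash", None)

    @classmethod
    def _unchecked(cls, source_size: int, target_size: int,
                   sorted_pairs: tuple) -> "PartialPerm":
        # fast path for enumeration; caller guarantees the invariants
        self = object.__new__(cls)
        object.__setattr__(self, "source_size", source_size)
        object.__setattr__(self, "target_size", target_size)
        object.__setattr__(self, "pairs", sorted_pairs)
        object.__setattr__(self, "_map", None)
        object.__setattr__(self, "_hash", None)
        return self

    def __setattr__(self, name, value):  # pragma: no cover - immutability
        raise AttributeError("PartialPerm is immutable")

    # -- basic queries -------------------------------------------------

    @property
    def mapping(self) -> dict:
        m = self._map
        if m is None:
            m = dict(self.pairs)
            object.__setattr__(self, "_map", m)
        return m

    @property
    def rank(self) -> int:
        """Size of the domain (Green's D-relation groups equal ranks)."""
        return len(self.pairs)

    def domain(self) -> tuple:
        return tuple(i for i, _ in self.pairs)

    def image(self) -> tuple:
        return tuple(sorted(j for _, j in self.pairs))

    def __call__(self, i: int) -> Optional[int]:
        """Image of position ``i``, or None when undefined."""
        return self.mapping.get(i)

    def is_total(self) -> bool:
        return self.rank == self.source_size

    # -- structural equality ------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, PartialPerm):
            return NotImplemented
        return (self.source_size == other.source_size
                and self.target_size == other.target_size
                and self.pairs == other.pairs)

    def __hash__(self) -> int:
        h = self._hash
        if h is None:
            h = hash((self.source_size, self.target_size, self.pairs))
            object.__setattr__(self, "_hash", h)
        return h

    def __repr__(self) -> str:
        body = ", ".join(f"{i}->{j}" for i, j in self.pairs)
        return (f"PartialPerm({self.source_size}->{self.target_size}: "
                f"{{{body}}})")

    def __mul__(self, other: "PartialPerm") -> "PartialPerm":
        return compose(self, other)

    def inverse(self) -> "PartialPerm":
        return invert(self)

    def diagram(self) -> str:
        """Two-row debug rendering of the map (upper row = source)."""
        top = " ".join(f"{i:>2}" for i in range(1, self.source_size + 1))
        bot = " ".join(f"{j:>2}" for j in range(1, self.target_size + 1))
        edges = " ".join(f"{i}-{j}" for i, j in self.pairs)
        return f"[{top}]\n[{bot}]\n{edges or '(empty)'}"


def compose(f: PartialPerm, g: PartialPerm) -> PartialPerm:
    """Composite ``fg`` applying ``f`` first (maps written on the right).

    ``i`` lies in the domain of the result iff ``(i)f`` is defined and
    itself lies in the domain of ``g``.
    """
    if f.target_size != g.source_size:
        raise ValueError(
            f"cannot compose: left factor targets {f.target_size} positions "
            f"but right factor starts from {g.source_size}")
    gm = g.mapping
    pairs = tuple(sorted(
        (i, gm[j]) for i, j in f.pairs if j in gm))
    return PartialPerm._unchecked(f.source_size, g.target_size, pairs)


def invert(f: PartialPerm) -> PartialPerm:
    """Semigroup inverse: transpose the pair set and swap the sizes."""
    pairs = tuple(sorted((j, i) for i, j in f.pairs))
    return PartialPerm._unchecked(f.target_size, f.source_size, pairs)


def identity(n: int) -> PartialPerm:
    """The identity map on ``{1..n}``."""
    return PartialPerm._unchecked(n, n, tuple((i, i) for i in range(1, n + 1)))


def inversion(i: int, n: int) -> PartialPerm:
    """Adjacent transposition ``s_{i;n}`` modelling a two-region inversion.

    Swaps positions ``i`` and ``i+1``; ``i = n`` denotes the wrap-around
    2-cycle ``(1, n)`` joining the last and first positions of a circular
    genome.  For ``n = 1`` this degenerates to the identity.
    """
    if not (1 <= i <= n):
        raise ValueError(f"inversion index {i} outside 1..{n}")
    a, b = (1, n) if i == n else (i, i + 1)
    pairs = []
    for p in range(1, n + 1):
        if p == a:
            pairs.append((p, b))
        elif p == b:
            pairs.append((p, a))
        else:
            pairs.append((p, p))
    return PartialPerm._unchecked(n, n, tuple(pairs))


def deletion(i: int, n: int) -> PartialPerm:
    """Single-region deletion ``d_{i;n}``: the unique order-preserving
    partial permutation from ``n`` to ``n-1`` positions omitting ``i``.

    Positions below ``i`` are fixed, positions above shift down by one.
    """
    if n < 2:
        raise ValueError("deletion requires at least 2 positions")
    if not (1 <= i <= n):
        raise ValueError(f"deletion index {i} outside 1..{n}")
    pairs = tuple((p, p if p < i else p - 1)
                  for p in range(1, n + 1) if p != i)
    return PartialPerm._unchecked(n, n - 1, pairs)


def rotation(n: int) -> PartialPerm:
    """The n-cycle ``c_n = (1, 2, ..., n)`` (one clockwise step)."""
    if n < 1:
        raise ValueError("rotation requires a positive size")
    pairs = tuple(sorted((p, p % n + 1) for p in range(1, n + 1)))
    return PartialPerm._unchecked(n, n, pairs)


def reflection(n: int) -> PartialPerm:
    """The reflection ``(1,n)(2,n-1)...`` reversing the position order."""
    if n < 1:
        raise ValueError("reflection requires a positive size")
    pairs = tuple((p, n + 1 - p) for p in range(1, n + 1))
    return PartialPerm._unchecked(n, n, pairs)


def transpositions(n: int) -> list[PartialPerm]:
    """The inversion generating set ``T_n``, deduplicated for small n.

    ``T_1`` is empty (the only candidate is the identity, a zero-cost
    move) and ``T_2`` has one element (the wrap move coincides with the
    single adjacent swap).
    """
    if n <= 1:
        return []
    if n == 2:
        return [inversion(1, 2)]
    return [inversion(i, n) for i in range(1, n + 1)]


def transposition_indices(n: int) -> list[int]:
    """Indices ``i`` of the deduplicated generating set ``T_n``."""
    if n <= 1:
        return []
    if n == 2:
        return [1]
    return list(range(1, n + 1))


def deletions(n: int) -> list[PartialPerm]:
    """The deletion generating set ``D_n`` (empty for n < 2)."""
    if n < 2:
        return []
    return [deletion(i, n) for i in range(1, n + 1)]


def crossings(f: PartialPerm) -> set[tuple[int, int]]:
    """All domain pairs ``(i, j)`` with ``i < j`` but ``(i)f > (j)f``.

    A crossing witnesses two shared regions appearing in opposite
    relative order in the two genomes.
    """
    out = set()
    pairs = f.pairs  # sorted by domain position
    for a in range(len(pairs)):
        ia, ja = pairs[a]
        for b in range(a + 1, len(pairs)):
            ib, jb = pairs[b]
            if ja > jb:
                out.add((ia, ib))
    return out


def is_order_preserving(f: PartialPerm) -> bool:
    """True iff ``f`` has no crossings (class POI)."""
    prev = 0
    for _, j in f.pairs:
        if j < prev:
            return False
        prev = j
    return True


def is_orientation_preserving(f: PartialPerm) -> bool:
    """True iff the image sequence over the sorted domain is cyclic (POPI).

    The sequence ``((x_1)f, ..., (x_k)f)`` may have at most one cyclic
    descent, the wrap-around pair ``(x_k, x_1)`` included.  Shared
    regions of two circular genomes occur in the same clockwise cyclic
    order exactly when their alignment map has this property.  Rank <= 2
    maps are vacuously orientation preserving.
    """
    images = [j for _, j in f.pairs]
    k = len(images)
    if k <= 2:
        return True
    descents = 0
    for a in range(k):
        if images[a] > images[(a + 1) % k]:
            descents += 1
            if descents > 1:
                return False
    return True


_OP_TAGS = ("inversion", "deletion", "rotation", "reflection")


@dataclass(frozen=True)
class ElementaryOp:
    """One letter of a rearrangement word: an inversion ``s_{i;n}``,
    deletion ``d_{i;n}``, rotation ``c_n`` or reflection ``alpha_n``.

    ``size`` is the number of positions the operation acts on; ``index``
    is the position parameter (None for rotation/reflection).
    """

    tag: str
    size: int
    index: Optional[int] = None

    def __post_init__(self):
        if self.tag not in _OP_TAGS:
            raise ValueError(f"unknown operation tag {self.tag!r}")
        if self.tag == "inversion":
            if self.index is None or not (1 <= self.index <= self.size):
                raise ValueError(
                    f"inversion index {self.index} outside 1..{self.size}")
        elif self.tag == "deletion":
            if self.size < 2:
                raise ValueError("deletion needs size >= 2")
            if self.index is None or not (1 <= self.index <= self.size):
                raise ValueError(
                    f"deletion index {self.index} outside 1..{self.size}")
        elif self.index is not None:
            raise ValueError(f"{self.tag} takes no index")

    @property
    def source_size(self) -> int:
        return self.size

    @property
    def target_size(self) -> int:
        return self.size - 1 if self.tag == "deletion" else self.size

    @property
    def counts_toward_length(self) -> bool:
        """Only inversions and deletions cost an evolutionary event."""
        return self.tag in ("inversion", "deletion")

    def realize(self) -> PartialPerm:
        if self.tag == "inversion":
            return inversion(self.index, self.size)
        if self.tag == "deletion":
            return deletion(self.index, self.size)
        if self.tag == "rotation":
            return rotation(self.size)
        return reflection(self.size)

    def __str__(self) -> str:
        if self.tag == "inversion":
            return f"s_{{{self.index};{self.size}}}"
        if self.tag == "deletion":
            return f"d_{{{self.index};{self.size}}}"
        if self.tag == "rotation":
            return f"c_{{{self.size}}}"
        return f"a_{{{self.size}}}"


def random_partial_perm(rng, m: int, n: int,
                        rank: Optional[int] = None) -> PartialPerm:
    """Draw a uniform-ish random element of ``I_{m,n}`` (testing helper).

    With ``rank`` given, the domain and image are uniform ``rank``-subsets
    and the bijection between them uniform; otherwise the rank is drawn
    uniformly from ``0..min(m, n)`` first.
    """
    if rank is None:
        rank = rng.randint(0, min(m, n))
    dom = sorted(rng.sample(range(1, m + 1), rank))
    img = rng.sample(range(1, n + 1), rank)
    return PartialPerm(m, n, tuple(zip(dom, img)))
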