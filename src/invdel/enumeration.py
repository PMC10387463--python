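"""Enumeration of the symmetric inverse monoid and its search graphs.

``I_{n,n}`` — all partial permutations of ``{1..n}`` — decomposes by
rank into Green's D-classes; the class of rank ``r`` has
``C(n,r)^2 * r!`` elements, so ``|I_{n,n}| = sum_r C(n,r)^2 r!``.
Enumeration is by direct construction (domain subset x image subset x
bijection), which visits every element exactly once.

The distance search of the solver walks a graph on rank-``r`` elements
whose edges are left multiplications by the inversions ``T_m`` (embedded
into ``I_{n,n}``) and right multiplications by ``T_n``.  Every edge
label is an involution, so the graph is symmetric, and every edge
preserves both the rank and the ``domain <= {1..m}`` constraint.  Left
multiplication is offered at every such vertex (not only inside the
embedded copy of ``I_{m,m}``), which is what the region alignment
problem requires.
"""

from __future__ import annotations

from itertools import combinations, permutations
from math import comb, factorial
from typing import Iterator

from .algebra import (PartialPerm, compose, inversion,
                      transposition_indices)

__all__ = [
    "monoid_size",
    "d_class_size",
    "enumerate_inverse_monoid",
    "enumerate_d_class",
    "embed",
    "SearchGraph",
]


def d_class_size(n: int, r: int) -> int:
    """Number of rank-``r`` elements of ``I_{n,n}``: ``C(n,r)^2 r!``."""
    return comb(n, r) ** 2 * factorial(r)


def monoid_size(n: int) -> int:
    """Order of the symmetric inverse monoid ``I_{n,n}``."""
    return sum(d_class_size(n, r) for r in range(n + 1))


def enumerate_d_class(n: int, r: int) -> Iterator[PartialPerm]:
    """Yield every rank-``r`` element of ``I_{n,n}`` exactly once."""
    positions = range(1, n + 1)
    for dom in combinations(positions, r):
        for img in combinations(positions, r):
            for per in permutations(img):
                yield PartialPerm._unchecked(n, n, tuple(zip(dom, per)))


def enumerate_inverse_monoid(n: int) -> Iterator[PartialPerm]:
    """Yield every element of ``I_{n,n}`` exactly once, by rank."""
    if n < 0:
        raise ValueError("size must be nonnegative")
    for r in range(n + 1):
        yield from enumerate_d_class(n, r)


def embed(f: PartialPerm, n: int) -> PartialPerm:
    """Embed ``f`` from ``I_{m,m'}`` into ``I_{n,n}`` (same pair set).

    Requires both sizes of ``f`` to be at most ``n``; the rank is
    unchanged.  Callers aligning a larger genome against a smaller one
    must invert first so that the smaller side comes first.
    """
    if f.source_size > n or f.target_size > n:
        raise ValueError(
            f"cannot embed a map on {f.source_size}->{f.target_size} "
            f"positions into I_{{{n},{n}}}; swap roles so the smaller "
            f"side comes first")
    return PartialPerm._unchecked(n, n, f.pairs)


class SearchGraph:
    """Neighbourhood structure for the region alignment search.

    Vertices are elements of ``I_{n,n}`` of rank ``r`` with domain
    contained in ``{1..m}`` (the embedded alignment states for a genome
    pair with ``m <= n`` regions).  Edges are labelled ``("L", i)`` for
    left multiplication by the embedded inversion ``s_{i;m}`` and
    ``("R", j)`` for right multiplication by ``s_{j;n}``.

    Neighbourhoods are expanded lazily by default; ``materialize``
    builds the full induced subgraph (practical for n <= 6 only).
    """

    def __init__(self, m: int, n: int, r: int):
        if m > n:
            raise ValueError("require m <= n (swap genome roles first)")
        if r > m:
            raise ValueError("rank cannot exceed the smaller size")
        self.m = m
        self.n = n
        self.r = r
        self._left = [("L", i, embed(inversion(i, m), n))
                      for i in transposition_indices(m)]
        self._right = [("R", j, inversion(j, n))
                       for j in transposition_indices(n)]

    def check_vertex(self, x: PartialPerm) -> None:
        if x.source_size != self.n or x.target_size != self.n:
            raise ValueError(f"vertex must live in I_{{{self.n},{self.n}}}")
        if x.rank != self.r:
            raise ValueError(f"vertex rank {x.rank} != graph rank {self.r}")
        if any(i > self.m for i, _ in x.pairs):
            raise ValueError(f"vertex domain exceeds {{1..{self.m}}}")

    def neighbors(self, x: PartialPerm
                  ) -> list[tuple[tuple[str, int], PartialPerm]]:
        """Labelled neighbours of ``x``; degree <= |T_m| + |T_n|."""
        out = []
        for side, i, s in self._left:
            out.append(((side, i), compose(s, x)))
        for side, j, t in self._right:
            out.append(((side, j), compose(x, t)))
        return out

    def materialize(self, start: PartialPerm):
        """Breadth-first closure of ``start`` as a ``networkx`` graph.

        Nodes are partial permutations; edges carry their move label.
        Guarded to n <= 6, where the largest D-class has 13,327 elements
        or fewer.
        """
        import networkx as nx
        if self.n > 6:
            raise ValueError(
                "materializing the search graph is limited to n <= 6; "
                "use lazy neighbour expansion instead")
        self.check_vertex(start)
        graph = nx.Graph()
        graph.add_node(start)
        frontier = [start]
        while frontier:
            nxt = []
            for x in frontier:
                for label, y in self.neighbors(x):
                    if y not in graph:
                        nxt.append(y)
                        graph.add_node(y)
                    if not graph.has_edge(x, y):
                        graph.add_edge(x, y, label=label)
            frontier = nxt
        return graph
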