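"""Independent brute-force references and seeded evolutionary fixtures.

Everything here re-derives quantities the optimised modules compute, by
a deliberately different route: words of elementary operations are
enumerated breadth-first and realised through the partial-permutation
algebra (``compose``), with no shared traversal logic or state encoding
with the solver's tuple-based search.  These functions are slow on
purpose and guarded to desk-scale inputs; they exist to certify the
solver, the ancestor construction and the deletions-first normal form
on instances small enough to exhaust.

``simulate_history`` generates seeded two-branch evolutionary
scenarios: an ancestor genome, per-branch deletions applied before
inversions, and the two descendant genomes — the setting in which the
reconstructed distance must never exceed the number of simulated
events.
"""

from __future__ import annotations

import random
import string
from collections import deque
from dataclasses import dataclass

from .algebra import (PartialPerm, compose, identity, inversion,
                      is_orientation_preserving, transposition_indices)
from .genomes import Genome, OpWord, ReferenceFrame, apply_word
from .genomes import ElementaryOp

__all__ = [
    "SimulatedHistory",
    "brute_force_mu",
    "brute_force_frame_distance",
    "brute_force_frame_distance_deletions_first",
    "circular_sort_distance",
    "simulate_history",
    "random_genome",
]


class OracleBudgetExceeded(RuntimeError):
    """Raised when a brute-force search exceeds its cap."""


def brute_force_mu(sigma: PartialPerm, m: int, n: int,
                   cap: int = 64) -> int:
    """Exact region-alignment minimum by direct word enumeration.

    Explores products ``t_m * sigma * t_n`` in order of increasing
    total length, realising every step with the algebra's ``compose``;
    the first orientation-preserving product gives the minimum.
    Guarded to ``m + n <= 14``, which covers an 8-region genome against
    a 6-region one.
    """
    if m + n > 14:
        raise ValueError("brute_force_mu is guarded to m + n <= 14")
    if sigma.source_size != m or sigma.target_size != n:
        raise ValueError("sigma sizes disagree with m, n")
    left = [inversion(i, m) for i in transposition_indices(m)]
    right = [inversion(j, n) for j in transposition_indices(n)]
    seen = {sigma}
    frontier = [sigma]
    length = 0
    while frontier:
        for f in frontier:
            if is_orientation_preserving(f):
                return length
        length += 1
        if length > cap:
            raise OracleBudgetExceeded(
                f"brute_force_mu exceeded cap {cap}")
        nxt = []
        for f in frontier:
            for s in left:
                g = compose(s, f)
                if g not in seen:
                    seen.add(g)
                    nxt.append(g)
            for t in right:
                g = compose(f, t)
                if g not in seen:
                    seen.add(g)
                    nxt.append(g)
        frontier = nxt
    raise OracleBudgetExceeded("search space exhausted unexpectedly")


def _inversion_ops(k: int) -> list[ElementaryOp]:
    return [ElementaryOp("inversion", k, i)
            for i in transposition_indices(k)]


def brute_force_frame_distance(frame: ReferenceFrame, target: Genome,
                               cap: int = 16) -> int:
    """Minimum number of inversions and deletions (interleaved freely)
    taking ``frame`` to any reference frame of ``target``.

    Requires the target's regions to be a subset of the frame's (the
    deletion-only reachability setting) and at most 7 regions.  States
    are whole words; deleting a region the target needs is pruned since
    it can never be reinserted.
    """
    if len(frame) > 7:
        raise ValueError("guarded to frames with at most 7 regions")
    if not target.regions <= frame.regions:
        raise ValueError("target regions must be a subset of the frame's")
    needed = target.regions
    start = frame.word
    seen = {start}
    frontier = [start]
    length = 0
    while frontier:
        for word in frontier:
            if Genome(word) == target:
                return length
        length += 1
        if length > cap:
            raise OracleBudgetExceeded(
                f"frame-distance search exceeded cap {cap}")
        nxt = []
        for word in frontier:
            k = len(word)
            for op in _inversion_ops(k):
                new, _ = apply_word(ReferenceFrame(word), OpWord([op]))
                if new.word not in seen:
                    seen.add(new.word)
                    nxt.append(new.word)
            if k > 1:
                for p in range(k):
                    if word[p] in needed:
                        continue
                    new = word[:p] + word[p + 1:]
                    if new not in seen:
                        seen.add(new)
                        nxt.append(new)
        frontier = nxt
    raise OracleBudgetExceeded("search space exhausted unexpectedly")


def brute_force_frame_distance_deletions_first(
        frame: ReferenceFrame, target: Genome, cap: int = 16) -> int:
    """Minimum word length with all deletions before all inversions.

    Deleting a fixed set of regions from a word yields the same subword
    whatever the order, so the deletion phase costs exactly the number
    of private regions and the inversion phase is a breadth-first
    search over words on the target's region set.
    """
    if not target.regions <= frame.regions:
        raise ValueError("target regions must be a subset of the frame's")
    survivors = tuple(tok for tok in frame.word if tok in target.regions)
    n_del = len(frame) - len(survivors)
    if not survivors:
        raise ValueError("deletions may not empty the genome")
    seen = {survivors}
    frontier = [survivors]
    length = 0
    while frontier:
        for word in frontier:
            if Genome(word) == target:
                return n_del + length
        length += 1
        if length > cap:
            raise OracleBudgetExceeded(
                f"deletions-first search exceeded cap {cap}")
        nxt = []
        for word in frontier:
            for op in _inversion_ops(len(word)):
                new, _ = apply_word(ReferenceFrame(word), OpWord([op]))
                if new.word not in seen:
                    seen.add(new.word)
                    nxt.append(new.word)
        frontier = nxt
    raise OracleBudgetExceeded("search space exhausted unexpectedly")


def circular_sort_distance(perm: PartialPerm, cap: int = 32) -> int:
    """Minimum adjacent transpositions (wrap included, either side)
    making a full permutation a rotation of the identity.

    A third, permutation-only route used to triple-check the solver and
    ``brute_force_mu`` on equal-region-set instances: a full alignment
    permutation is orientation preserving exactly when it is a rotation.
    """
    n = perm.source_size
    if perm.target_size != n or perm.rank != n:
        raise ValueError("circular sorting needs a full permutation")
    targets = set()
    rot = identity(n)
    step = PartialPerm(n, n, tuple(sorted((p, p % n + 1)
                                          for p in range(1, n + 1))))
    for _ in range(n):
        targets.add(rot)
        rot = compose(rot, step)
    gens = [inversion(i, n) for i in transposition_indices(n)]
    seen = {perm}
    frontier = [perm]
    length = 0
    while frontier:
        if any(f in targets for f in frontier):
            return length
        length += 1
        if length > cap:
            raise OracleBudgetExceeded(
                f"circular sort search exceeded cap {cap}")
        nxt = []
        for f in frontier:
            for s in gens:
                for g in (compose(s, f), compose(f, s)):
                    if g not in seen:
                        seen.add(g)
                        nxt.append(g)
        frontier = nxt
    raise OracleBudgetExceeded("search space exhausted unexpectedly")


@dataclass(frozen=True)
class SimulatedHistory:
    """A seeded two-branch evolutionary scenario.

    ``events1``/``events2`` are the per-branch operation words
    (deletions first, then inversions) taking ``ancestor_frame`` to the
    recorded descendant frames; replaying them reproduces the
    descendants exactly.
    """

    ancestor: Genome
    ancestor_frame: ReferenceFrame
    events1: OpWord
    events2: OpWord
    descendant1: Genome
    descendant2: Genome
    seed: int

    @property
    def n_events(self) -> int:
        return self.events1.length + self.events2.length


def _region_labels(n: int) -> list[str]:
    letters = string.ascii_lowercase
    if n <= len(letters):
        return list(letters[:n])
    return [f"r{i:02d}" for i in range(1, n + 1)]


def random_genome(rng: random.Random, n_regions: int) -> ReferenceFrame:
    """A uniformly shuffled reference frame on ``n_regions`` labels."""
    labels = _region_labels(n_regions)
    rng.shuffle(labels)
    return ReferenceFrame(labels)


def _random_branch(rng: random.Random, frame: ReferenceFrame,
                   n_inv: int, n_del: int) -> OpWord:
    ops = []
    size = len(frame)
    if size - n_del < 1:
        raise ValueError(
            f"cannot delete {n_del} of {size} regions: a genome must "
            "keep at least one region")
    for _ in range(n_del):
        ops.append(ElementaryOp("deletion", size, rng.randint(1, size)))
        size -= 1
    for _ in range(n_inv):
        ops.append(ElementaryOp("inversion", size, rng.randint(1, size)))
    return OpWord(ops)


def simulate_history(n_regions: int, inv1: int, del1: int,
                     inv2: int, del2: int, seed: int) -> SimulatedHistory:
    """Simulate two descendants of a random ancestor genome.

    Each branch applies its deletions (uniform positions) before its
    inversions (uniform indices, wrap move included) — the normal form
    in which any history can be rewritten without extra cost.  Event
    sampling is uniform purely as a fixture-generation choice.
    Deterministic under ``seed``.
    """
    rng = random.Random(seed)
    ancestor_frame = random_genome(rng, n_regions)
    events1 = _random_branch(rng, ancestor_frame, inv1, del1)
    events2 = _random_branch(rng, ancestor_frame, inv2, del2)
    d1, _ = apply_word(ancestor_frame, events1)
    d2, _ = apply_word(ancestor_frame, events2)
    return SimulatedHistory(
        ancestor=Genome(ancestor_frame.word),
        ancestor_frame=ancestor_frame,
        events1=events1,
        events2=events2,
        descendant1=Genome(d1.word),
        descendant2=Genome(d2.word),
        seed=seed,
    )
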