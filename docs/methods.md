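# Methods

## Model and assumptions

A circular genome is a word of pairwise-distinct region labels modulo
the dihedral group action: rotations and reflections are views of the
same molecule, not events. Two elementary events are modelled, both
arising from site-specific recombination: inversion of exactly two
adjacent regions (the generators `s_{i;n}`, with `s_{n;n} = (1, n)`
closing the circle) and deletion of one region (the order-preserving
partial permutations `d_{i;n}: n -> n-1`). Insertions, duplications,
longer inversions, multi-region deletions, signed/oriented regions and
repeated labels are all outside the model. Distances are parsimony
distances: the minimum number of events, with no rate or likelihood
interpretation.

Two global conventions are fixed once: positions are 1-based, and maps
are written on the right (`compose(f, g)` applies `f` first). Every
interface, error message and witness respects these.

Degenerate sizes are handled explicitly: the inversion set `T_1` is
empty (the only candidate is the identity, a zero-cost move that would
corrupt distance counts) and `T_2` is deduplicated to a single element
(the wrap move coincides with the only adjacent swap). A genome always
keeps at least one region; deletion words that would empty it cannot be
expressed.

## The distance computation

For genomes `G1`, `G2` with region sets `R1`, `R2` the distance to a
most recent common ancestor is `|R1 (+) R2| + min mu(g1, g2)`: each
region private to one genome costs exactly one deletion from the
ancestor, and `mu` — the region alignment minimum — counts the
inversions needed to put the shared regions into a common cyclic order.

*Reference-pair reduction.* The minimum of `mu` over all `2m x 2n`
reference pairs is taken over only the four reflection combinations of
the two canonical frames. Rotations are redundant because conjugating
by the rotation `c_n` permutes the inversion generating set `T_n` into
itself, so rotating a frame relabels a witness without changing its
length; reflections are *not* redundant (a reflection turns cyclic
descents into cyclic ascents). The equivalence with exhaustive
reference-pair enumeration is re-verified by a test over seeded genome
pairs of up to six regions; `genome_distance(..., exhaustive=True)`
remains available as a fallback.

*Search.* `mu` is found by plain breadth-first search from the
alignment map, expanding left multiplications by `T_m` and right
multiplications by `T_n` and stopping at the first
orientation-preserving state. All moves are involutions, so the state
graph is symmetric and BFS depth is the exact distance. States are
encoded as image tuples over the smaller side, which keeps the search
allocation-light. A bidirectional variant was considered and dropped:
at the problem sizes where the exact algorithm is usable at all the
reachable balls are small and `mu` values low, so the added complexity
buys nothing measurable. The depth cap defaults to `m * n`, a safe
overestimate of the search-graph diameter at these sizes; exceeding it
raises an explicit error rather than looping.

*Role swap.* The solver requires the smaller genome on the left. For
`m > n` the problem is solved on the inverse map with the move sets
exchanged; orientation preservation is closed under inversion of
partial permutations, so `mu` is unchanged and witnesses transfer
side-swapped in the same application order.

*Tie-breaking.* Neighbours are expanded left moves first, then right,
index ascending, and the first shortest path found is reported — output
is deterministic for fixed input.

## Ancestor reconstruction

Replaying the witness inversions on the winning reference pair yields
aligned frames `g1'`, `g2'` whose shared regions agree in cyclic order;
the least rotation of `g2'` making the alignment order preserving (a
scan over all `n` rotations) fixes a common reading. The private
regions of genome 2 then fall into blocks `U_0..U_h` between
consecutive shared regions. Each block is inserted contiguously into
`g1'` immediately before the next shared region, `U_0` at the very
start and `U_h` at the very end, preserving the block's internal order
— one deterministic choice among the many valid interleavings (any
placement keeping block order works; a fixed rule is needed for
reproducible output). Deleting genome 2's private regions from the
resulting ancestor frame returns `g1'` and deleting genome 1's returns
the rotated `g2'` exactly, so undoing the witness inversions (inverted,
in reverse order; for genome 2 conjugated by the rotation, which maps
`T_n` into itself) reaches both descendants. The emitted operation
words are deletions-first by construction — the normal form in which
any parsimonious word can be rewritten at no extra cost — with
deletions applied from the highest position down so that earlier
deletions never shift later targets.

When the region sets are disjoint the construction degenerates
(`h = 0`): the ancestor frame is the aligned frame of genome 2 followed
by that of genome 1, the alignment map is empty (vacuously orientation
preserving, `mu = 0`) and the distance is `|R1| + |R2|`. This is an
extension of the generic construction, which presumes at least one
shared region.

Every reconstruction is certified before being returned: both words
are replayed and the length sum is compared with the distance.

## Enumeration

`I_{n,n}` is enumerated by direct construction (domain subset × image
subset × bijection), visiting each element exactly once; the rank-`r`
class has `C(n,r)^2 r!` elements. Full materialization of the
rank-preserving search graph — the literal enumerate-then-shortest-path
pipeline — is available behind `SearchGraph.materialize` (and the CLI
`--materialize` flag) for `n <= 6`, built on `networkx`; the production
solver never needs it, since lazy expansion explores only the reachable
ball. Automorphism-based search pruning is not implemented.

## The NP-completeness reduction

A PARTITION multiset `{a_1..a_n}` maps to `sigma` in `I_m`,
`m = n + sum(a_i)`, whose domain consists of `n` disjoint crossings
`p_j <-> q_j` with `q_j - p_j = a_j`, and budget `k = sum(a_i)`. The
construction is extended through `j = n` (the printed bullet range
stops one short, which would leave `a_n` uncounted while `k` counts it
and the last position unused; the printed example instance `sigma` in
`I_16`, `k = 11` for `{1,1,2,3,4}` comes out exactly right under the
extension).

BALANCEDSORT is decided over the *linear* adjacent transpositions
`s_1..s_{m-1}`. Order preservation is a linear-order target — the
circular wrap is discharged by a rotation before the problem is posed —
and admitting the wrap move would actually falsify the construction on
degenerate instances: for the singleton multiset `{2}` the crossing
`1 <-> 3` in `I_3` can be cleared by one wrap move per side, a balanced
"yes" where no partition exists. With the linear move set each crossing
costs exactly `a_j` moves, clearable wholly on one side, so balanced
solutions within `k` correspond to equal-sum splits.

Two deciders are provided: an exhaustive BFS over
`(state, left-count − right-count)` pairs, guarded to `m <= 8`, and a
structured decider for reduction-built instances that reduces to a
balanced-subset check and certifies every positive answer by
constructing the witness sequences and verifying them against the
semantics. The two agree on every instance where both apply.

## Oracles and simulated data

The oracle module re-derives each optimised quantity by a different
route: `brute_force_mu` enumerates words by increasing length and
realises them through the partial-permutation `compose` (no shared
state encoding with the solver), `brute_force_frame_distance` walks
whole region words under freely interleaved inversions and deletions,
its deletions-first variant stages the phases, and
`circular_sort_distance` is a third, permutation-only check for
equal-region-set instances. All are guarded to sizes where exhaustion
is certain (words of ≤ 7 regions, `m + n <= 14` for the alignment
oracle — enough to cover the 8-versus-6-region worked example).

`simulate_history` generates fixture scenarios: a uniformly shuffled
ancestor, per-branch deletions applied before inversions with uniform
positions/indices, all driven by one explicit integer seed. Uniform
sampling is a fixture choice, not a biological claim: real genomes have
hotspots, length-dependent rates and selection, none of which the
generator emulates. Passing tests therefore certify the combinatorial
guarantees (bounds, symmetry, attainment) on the model's own terms, not
distributional realism. Test and acceptance runs use genomes of 4–8
regions and a handful of events per branch — the scale at which the
exact algorithm and its brute-force oracles can both be exhausted —
with 200-instance seeded batteries for the stochastic suites.

## Known limitations

* Complexity: the exact solver is exponential in genome size; it is a
  desk-scale reference implementation (n ≤ ~8 comfortable), matching
  the scope of the exact algorithm it implements. The balanced variant
  of the alignment problem is NP-complete, so no polynomial exact
  algorithm is expected.
* The ancestor returned is one parsimonious choice among possibly many;
  no enumeration of all optima is attempted.
* Single circular chromosomes only; the file format rejects linear
  topology rather than converting silently.
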