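# invdel

Exact inversion/deletion rearrangement distances and ancestor
reconstruction for circular bacterial genomes, built on the algebra of
partial permutations.

## The problem

Bacterial chromosomes are single circular molecules, and a large share
of their structural variation arises from site-specific recombination,
which produces two kinds of events through the same molecular
mechanism: **inversions** of a short segment (here: exactly two
adjacent conserved regions) and **deletions** of a single region.
Because deletions change gene content, two extant genomes generally
have *different* region sets, and no inversion-only distance applies.
`invdel` compares two such genomes by reconstructing their most recent
common ancestor under the parsimony criterion: the ancestor carries the
union of the region sets, and the distance is the least number of
events producing both descendants from it.

## The model

A genome with region set *R*, |*R*| = *n*, is an equivalence class of
words over *R* under the dihedral group *D_n* (rotations and
reflections are different views of the same circle); one concrete
reading is a *reference frame*, a bijection λ : *R* → {1..*n*}.
Operations compose on the right of λ as elements of the symmetric
inverse category: the adjacent transposition *s<sub>i;n</sub>*
(including the wrap-around pair (1, *n*)) models an inversion, and the
unique order-preserving partial permutation
*d<sub>i;n</sub>* ∈ POI<sub>n,n−1</sub> omitting position *i* models a
deletion.

For a reference pair (*g₁*, *g₂*) the *alignment map*
σ<sub>g₁,g₂</sub> ∈ I<sub>m,n</sub> sends position *i* of *g₁* to the
position of the same region in *g₂*. Shared regions appear in the same
clockwise cyclic order exactly when σ is *orientation preserving*
(image sequence with at most one cyclic descent, class POPI). The
**region alignment problem** asks for sequences *t<sub>m</sub>*,
*t<sub>n</sub>* of inversions acting on either genome, minimising
ℓ(*t<sub>m</sub>*) + ℓ(*t<sub>n</sub>*), such that
*t<sub>m</sub>* σ *t<sub>n</sub>* ∈ POPI<sub>m,n</sub>; the minimum is
μ(*g₁*, *g₂*). The distance to the most recent common ancestor is then

    ℓ(G₁, G₂) = |R₁ ⊖ R₂| + min { μ(g₁, g₂) : (g₁, g₂) ∈ G₁ × G₂ }

— one deletion per private region, plus the minimal inversion count.
The minimum over reference pairs reduces to the four reflection
combinations of the two canonical frames (rotations never change μ),
and μ is computed exactly by breadth-first search over rank-preserving
states. Replaying the witness inversions and interleaving the private
regions of one aligned frame into the other reconstructs an ancestor
that attains the distance, with a deletions-first operation word to
each descendant.

The package also contains the constructive reduction from PARTITION to
BALANCEDSORT (the balanced variant of the alignment problem), which
shows that deciding whether two equal-sized genomes are equidistant
from their ancestor is NP-complete, together with deciders that
validate the reduction on small instances.

## Worked example

Two genome files in the GRIMM-style circular dialect:

```
>G1                      >G2
a b c d e f g h @        e i b a c h @
```

```console
$ invdel distance G1.txt G2.txt
total distance: 6
deletions (symmetric difference): 4
inversions (mu): 2
orientation: ++
inversions on G1: none
inversions on G2: [5, 4]
```

The genomes share five regions {a, b, c, e, h}; regions d, f, g are
private to G1 and i to G2, so 4 deletions are unavoidable, and two
inversions applied to G2 (indices 5 then 4, i.e. *s₅;₆* then *s₄;₆*)
bring the shared regions into a common cyclic order: total 6.

```console
$ invdel mrca G1.txt G2.txt
ancestor: a b i c d e f g h
to G1: d_{3;9}
to G2: d_{8;9} d_{7;8} d_{5;7} s_{4;6} s_{5;6}
total operations: 6
```

The reconstructed ancestor carries all nine regions; deleting `i`
yields G1 (1 operation), and deleting d, f, g then undoing the two
witness inversions yields G2 (5 operations) — together exactly the
distance 6.

Other subcommands: `align` (raw alignment problem on a partial
permutation, with `--materialize` running the fully materialized
search-graph pipeline as a cross-check), `enumerate` (symmetric
inverse monoid sizes, e.g. `|I_{3,3}| = 34`), `reduce` (PARTITION →
BALANCEDSORT instances, e.g. `--set 1,1,2,3,4` gives σ ∈ I₁₆ with
k = 11) and `simulate` (seeded evolutionary fixtures). All subcommands
take `--json` for machine-readable output.

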