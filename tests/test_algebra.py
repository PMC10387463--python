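"""Partial-permutation algebra: composition, inverses, generators,
order/orientation predicates."""

import pytest
from hypothesis import given, strategies as st

from invdel.algebra import (ElementaryOp, PartialPerm, compose, crossings,
                            deletion, identity, inversion, invert,
                            is_order_preserving, is_orientation_preserving,
                            random_partial_perm, reflection, rotation,
                            transpositions)


def small_partial_perm(draw, m, n):
    rank = draw(st.integers(0, min(m, n)))
    dom = draw(st.permutations(list(range(1, m + 1))))[:rank]
    img = draw(st.permutations(list(range(1, n + 1))))[:rank]
    return PartialPerm(m, n, tuple(zip(sorted(dom), img)))


@st.composite
def perms_chain(draw):
    """A chainable triple f: a->b, g: b->c, h: c->d with sizes <= 6."""
    a, b, c, d = (draw(st.integers(1, 6)) for _ in range(4))
    return (small_partial_perm(draw, a, b),
            small_partial_perm(draw, b, c),
            small_partial_perm(draw, c, d))


class TestConstruction:
    def test_invariants_rejected(self):
        with pytest.raises(ValueError, match="mapped twice"):
            PartialPerm(3, 3, [(1, 2), (1, 3)])
        with pytest.raises(ValueError, match="hit twice"):
            PartialPerm(3, 3, [(1, 2), (3, 2)])
        with pytest.raises(ValueError, match="outside"):
            PartialPerm(3, 3, [(4, 1)])
        with pytest.raises(ValueError, match="outside"):
            PartialPerm(3, 3, [(1, 4)])

    def test_structural_equality_and_hash(self):
        f = PartialPerm(3, 4, [(2, 1), (1, 3)])
        g = PartialPerm(3, 4, [(1, 3), (2, 1)])
        assert f == g and hash(f) == hash(g)
        assert f != PartialPerm(3, 5, [(2, 1), (1, 3)])

    def test_rank_bounded_by_sizes(self):
        f = PartialPerm(5, 4, [(2, 2), (4, 3), (5, 4)])
        assert f.rank == 3 <= min(5, 4)
        assert f.domain() == (2, 4, 5)
        assert f.image() == (2, 3, 4)


class TestGenerators:
    def test_deletion_is_the_unique_order_preserving_omission(self):
        d = deletion(2, 5)
        assert d.domain() == (1, 3, 4, 5)
        assert d.image() == (1, 2, 3, 4)
        assert d.mapping == {1: 1, 3: 2, 4: 3, 5: 4}
        assert is_order_preserving(d)

    @pytest.mark.parametrize("i,n", [(1, 2), (3, 5), (5, 5), (1, 1)])
    def test_inversion_is_an_involution(self, i, n):
        s = inversion(i, n)
        assert compose(s, s) == identity(n)
        assert invert(s) == s

    def test_wraparound_inversion_swaps_first_and_last(self):
        s = inversion(4, 4)
        assert s.mapping == {1: 4, 2: 2, 3: 3, 4: 1}

    def test_reflection_even_and_odd(self):
        assert reflection(4).mapping == {1: 4, 2: 3, 3: 2, 4: 1}
        assert reflection(3).mapping == {1: 3, 2: 2, 3: 1}

    def test_rotation_cycles_positions(self):
        assert rotation(4).mapping == {1: 2, 2: 3, 3: 4, 4: 1}

    def test_bounds_errors(self):
        with pytest.raises(ValueError):
            inversion(6, 5)
        with pytest.raises(ValueError):
            deletion(1, 1)
        with pytest.raises(ValueError):
            deletion(0, 5)

    def test_small_inversion_sets_are_deduplicated(self):
        assert transpositions(1) == []
        assert len(transpositions(2)) == 1
        assert len(transpositions(5)) == 5


class TestCompose:
    @pytest.mark.parametrize("lhs,rhs", [
        # the two diagrammatic relation instances, as exact identities
        ((inversion(5, 5), deletion(5, 5)), (deletion(1, 5), rotation(4))),
        ((inversion(3, 5), deletion(2, 5)), (deletion(2, 5), inversion(2, 4))),
    ])
    def test_relation_instances(self, lhs, rhs):
        assert compose(*lhs) == compose(*rhs)

    def test_identity_law(self, rng):
        for _ in range(20):
            f = random_partial_perm(rng, rng.randint(1, 6), 4)
            assert compose(f, identity(4)) == f

    def test_size_mismatch_names_both_sizes(self):
        with pytest.raises(ValueError, match="4.*3|3.*4"):
            compose(identity(4), identity(3))

    def test_elementwise_tracing_oracle(self, rng):
        # trace every source position through both maps by hand
        for _ in range(50):
            f = random_partial_perm(rng, 5, 5)
            g = random_partial_perm(rng, 5, 4)
            expected = set()
            for i in range(1, 6):
                j = f.mapping.get(i)
                if j is not None and g.mapping.get(j) is not None:
                    expected.add((i, g.mapping[j]))
            assert set(compose(f, g).pairs) == expected

    @given(perms_chain())
    def test_associative(self, chain):
        f, g, h = chain
        assert compose(compose(f, g), h) == compose(f, compose(g, h))


class TestInvert:
    def test_identity_and_deletion(self):
        assert invert(identity(4)) == identity(4)
        d = invert(deletion(2, 5))
        assert d.source_size == 4 and d.target_size == 5
        assert d.mapping == {1: 1, 2: 3, 3: 4, 4: 5}

    @given(st.data())
    def test_semigroup_inverse_laws(self, data):
        m = data.draw(st.integers(1, 6))
        n = data.draw(st.integers(1, 6))
        f = small_partial_perm(data.draw, m, n)
        assert compose(f, compose(invert(f), f)) == f
        assert invert(invert(f)) == f


class TestPredicates:
    def test_identity_has_no_crossings(self):
        assert crossings(identity(5)) == set()
        assert is_order_preserving(identity(5))

    def test_crossings_match_exhaustive_pair_scan(self, rng):
        for _ in range(30):
            f = random_partial_perm(rng, 6, 6)
            expected = {(i, j)
                        for i in f.mapping for j in f.mapping
                        if i < j and f.mapping[i] > f.mapping[j]}
            assert crossings(f) == expected
            assert is_order_preserving(f) == (not expected)

    def test_rotation_is_orientation_preserving(self):
        for n in range(1, 8):
            assert is_orientation_preserving(rotation(n))

    def test_rank_two_or_less_is_vacuously_cyclic(self, rng):
        for _ in range(20):
            f = random_partial_perm(rng, 6, 6, rank=rng.randint(0, 2))
            assert is_orientation_preserving(f)

    def test_full_reversal_is_not_orientation_preserving(self):
        # image sequence (3, 2, 1) has two cyclic descents
        assert not is_orientation_preserving(reflection(3))

    @given(st.data())
    def test_order_preserving_implies_orientation_preserving(self, data):
        f = small_partial_perm(data.draw, data.draw(st.integers(1, 6)),
                               data.draw(st.integers(1, 6)))
        if is_order_preserving(f):
            assert is_orientation_preserving(f)


class TestElementaryOp:
    def test_realizations_match_constructors(self):
        assert ElementaryOp("inversion", 5, 3).realize() == inversion(3, 5)
        assert ElementaryOp("deletion", 5, 2).realize() == deletion(2, 5)
        assert ElementaryOp("rotation", 4).realize() == rotation(4)
        assert ElementaryOp("reflection", 4).realize() == reflection(4)

    def test_validation(self):
        with pytest.raises(ValueError):
            ElementaryOp("inversion", 5, 6)
        with pytest.raises(ValueError):
            ElementaryOp("deletion", 1, 1)
        with pytest.raises(ValueError):
            ElementaryOp("rotation", 4, 2)
        with pytest.raises(ValueError):
            ElementaryOp("spin", 4)

    def test_rendering(self):
        assert str(ElementaryOp("deletion", 12, 7)) == "d_{7;12}"
        assert str(ElementaryOp("inversion", 8, 2)) == "s_{2;8}"
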