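"""Circular genomes, reference frames, the alignment map and operation
words."""

from itertools import permutations

import pytest

from invdel.algebra import ElementaryOp, invert
from invdel.genomes import (Genome, OpWord, ReferenceFrame, apply_word,
                            genome_from_word, reference_frames, sigma)
from invdel.oracle import random_genome


class TestGenomeEquivalence:
    def test_rotations_and_reflections_are_the_same_genome(self):
        g = genome_from_word("abcdefgh")
        assert genome_from_word("cdefghab") == g
        assert genome_from_word("hgfedcba") == g

    def test_all_dihedral_images_collapse(self, rng):
        for _ in range(10):
            n = rng.randint(1, 8)
            frame = random_genome(rng, n)
            g = Genome(frame.word)
            for frame2 in g.frames():
                assert Genome(frame2.word) == g

    def test_single_region_genome(self):
        g = genome_from_word("x")
        assert len(reference_frames(g)) == 1

    def test_three_distinct_genomes_on_four_labels(self):
        seen = {Genome(word) for word in permutations("abcd")}
        assert len(seen) == 3  # 4! / (2 * 4)

    def test_duplicate_label_rejected_with_token(self):
        with pytest.raises(ValueError, match="'a'"):
            genome_from_word(["a", "a", "b"])


class TestReferenceFrames:
    def test_orbit_size_is_2n_for_n_at_least_3(self):
        assert len(reference_frames(genome_from_word("abcd"))) == 8
        assert len(reference_frames(genome_from_word("abcdefgh"))) == 16

    def test_degenerate_small_orbits(self):
        assert len(reference_frames(genome_from_word("ab"))) == 2
        assert len(reference_frames(genome_from_word("a"))) == 1

    def test_frames_are_sorted_and_contain_known_readings(self):
        frames = reference_frames(genome_from_word("abcdefgh"))
        words = ["".join(f.word) for f in frames]
        assert words == sorted(words)
        for reading in ("abcdefgh", "cdefghab", "hgfedcba"):
            assert reading in words

    def test_rotate_and_reflect(self):
        f = ReferenceFrame("abcd")
        assert f.rotate(1).word == ("b", "c", "d", "a")
        assert f.reflect().word == ("d", "c", "b", "a")


class TestSigma:
    def test_worked_example_pair(self):
        s = sigma(ReferenceFrame("abcdefgh"), ReferenceFrame("eibach"))
        assert s(1) == 4
        assert s.mapping == {1: 4, 2: 3, 3: 5, 5: 1, 8: 6}
        assert s.rank == 5

    def test_identical_frames_give_identity(self):
        f = ReferenceFrame("abcde")
        assert sigma(f, f).mapping == {i: i for i in range(1, 6)}

    def test_rank_counts_shared_regions(self, rng):
        for _ in range(20):
            f1 = random_genome(rng, rng.randint(2, 7))
            keep = rng.sample(list(f1.regions), rng.randint(1, len(f1)))
            extra = [x for x in "UVWXYZ"][:rng.randint(0, 3)]
            labels = keep + extra
            rng.shuffle(labels)
            f2 = ReferenceFrame(labels)
            assert sigma(f1, f2).rank == len(f1.regions & f2.regions)

    def test_sigma_reverses_under_argument_swap(self, rng):
        for _ in range(10):
            f1 = random_genome(rng, 6)
            f2 = ReferenceFrame(rng.sample(list(f1.regions), 4))
            assert sigma(f2, f1) == invert(sigma(f1, f2))


FIG7_WORD = OpWord([
    ElementaryOp("deletion", 12, 12),
    ElementaryOp("deletion", 11, 7),
    ElementaryOp("deletion", 10, 4),
    ElementaryOp("deletion", 9, 3),
    ElementaryOp("inversion", 8, 2),
])


class TestApplyWord:
    def test_twelve_region_worked_example(self):
        frame = ReferenceFrame("abcdefghijkl")
        out, deleted = apply_word(frame, FIG7_WORD)
        assert out.position_of("a") == 1
        assert out.position_of("e") == 2
        assert out.word == tuple("aebfhijk")
        assert deleted == ["l", "g", "d", "c"]

    def test_empty_word_is_identity(self):
        frame = ReferenceFrame("abc")
        out, deleted = apply_word(frame, OpWord())
        assert out == frame and deleted == []

    def test_single_deletion_shifts_later_regions_down(self, rng):
        for _ in range(10):
            frame = random_genome(rng, rng.randint(2, 8))
            i = rng.randint(1, len(frame))
            out, deleted = apply_word(
                frame, OpWord([ElementaryOp("deletion", len(frame), i)]))
            assert deleted == [frame.word[i - 1]]
            assert out.word == frame.word[:i - 1] + frame.word[i:]

    def test_deletion_only_words_preserve_relative_order(self, rng):
        for _ in range(10):
            frame = random_genome(rng, 7)
            ops, size = [], 7
            for _ in range(rng.randint(1, 4)):
                ops.append(ElementaryOp("deletion", size,
                                        rng.randint(1, size)))
                size -= 1
            out, deleted = apply_word(frame, OpWord(ops))
            survivors = [t for t in frame.word if t not in deleted]
            assert list(out.word) == survivors

    def test_positions_agree_with_the_realized_partial_permutation(
            self, rng):
        # tracing each surviving region through the composed map must
        # land it at the position apply_word reports
        for _ in range(10):
            frame = random_genome(rng, 6)
            word = OpWord([
                ElementaryOp("deletion", 6, rng.randint(1, 6)),
                ElementaryOp("inversion", 5, rng.randint(1, 5)),
                ElementaryOp("rotation", 5),
                ElementaryOp("reflection", 5),
            ])
            out, _ = apply_word(frame, word)
            composed = word.realize()
            for old_pos, tok in enumerate(frame.word, start=1):
                new_pos = composed(old_pos)
                if new_pos is not None:
                    assert out.word[new_pos - 1] == tok

    def test_size_chain_break_rejected(self):
        with pytest.raises(ValueError, match="chain break"):
            OpWord([ElementaryOp("deletion", 5, 1),
                    ElementaryOp("inversion", 5, 1)])
        with pytest.raises(ValueError, match="expects"):
            apply_word(ReferenceFrame("abc"),
                       OpWord([ElementaryOp("inversion", 4, 1)]))

    def test_cannot_empty_the_genome(self):
        # deleting down to a single region is allowed ...
        out, _ = apply_word(ReferenceFrame("ab"),
                            OpWord([ElementaryOp("deletion", 2, 2)]))
        assert out.word == ("a",)
        # ... but the emptying deletion cannot even be expressed
        with pytest.raises(ValueError):
            ElementaryOp("deletion", 1, 1)


class TestOpWord:
    def test_length_counts_only_inversions_and_deletions(self):
        word = OpWord([ElementaryOp("rotation", 5),
                       ElementaryOp("inversion", 5, 2),
                       ElementaryOp("deletion", 5, 1),
                       ElementaryOp("reflection", 4)])
        assert len(word) == 4
        assert word.length == 2

    def test_realize_empty_word_needs_a_size(self):
        from invdel.algebra import identity
        assert OpWord().realize(size=3) == identity(3)
        with pytest.raises(ValueError):
            OpWord().realize()
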