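"""Token BLOSUM construction and Needleman-Wunsch / PT-score."""

import itertools

import numpy as np
import pytest

from protoken.ptscore import (
    AlignmentResult,
    SubstitutionMatrix,
    build_blosum,
    code_cosine_similarity,
    collect_substitution_pairs,
    needleman_wunsch,
    pt_score,
    self_score,
    spearman,
)
from protoken.structure import ValidationError
from protoken.tokenizer import Codebook, TokenSequence


def toks(*indices):
    return TokenSequence(np.array(indices, dtype=np.int64)) if indices else \
        TokenSequence(np.zeros(0, dtype=np.int64))


def simple_matrix(n=3, match=2.0, mismatch=-1.0):
    scores = np.full((n, n), mismatch)
    np.fill_diagonal(scores, match)
    return SubstitutionMatrix(scores=scores, background_freqs=np.full(n, 1 / n))


def brute_force_alignment(a, b, scores, gap_open, gap_extend):
    """Exhaustive enumeration of every global alignment under affine gaps."""
    best = -np.inf

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + scores[a[i], b[j]], "M")
        if i < len(a):
            rec(i + 1, j, score + (gap_extend if last == "X" else gap_open), "X")
        if j < len(b):
            rec(i, j + 1, score + (gap_extend if last == "Y" else gap_open), "Y")

    rec(0, 0, 0.0, "-")
    return best if np.isfinite(best) else 0.0


class TestCollectPairs:
    def test_tm_threshold_is_strict(self):
        pair = (toks(0, 1), toks(0, 1), np.array([100.0, 100.0]), 0.79)
        assert collect_substitution_pairs([pair], 2).sum() == 0
        pair = (toks(0, 1), toks(0, 1), np.array([100.0, 100.0]), 0.8)
        assert collect_substitution_pairs([pair], 2).sum() == 0

    def test_lddt_threshold_is_strict(self):
        pair = (toks(0, 1), toks(1, 0), np.array([80.0, 80.1]), 0.95)
        counts = collect_substitution_pairs([pair], 2)
        # only residue 1 (lddt 80.1) survives: observation (1, 0)
        assert counts[1, 0] == 1 and counts[0, 1] == 1 and counts.sum() == 2

    def test_symmetrized_hand_count(self):
        pair = (toks(1, 1, 2), toks(1, 2, 2), np.full(3, 99.0), 0.9)
        counts = collect_substitution_pairs([pair], 3)
        assert counts[1, 1] == 1
        assert counts[1, 2] == 1 and counts[2, 1] == 1
        assert counts[2, 2] == 1
        assert counts.sum() == 4

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            collect_substitution_pairs(
                [(toks(0, 1), toks(0,), np.array([99.0]), 0.9)], 2
            )


class TestBuildBlosum:
    def test_two_code_hand_example(self):
        # counts: (1,1)=9 observations, (1,2)+(2,1)=2, (2,2)=9
        counts = np.array([[9.0, 1.0], [1.0, 9.0]])
        sm = build_blosum(counts, pseudocount=0.0)
        # q11 = 0.45, f1 = 0.5, e11 = 0.25 -> round(2*log2(1.8)) = 2
        assert sm.scores[0, 0] == 2
        assert sm.scores[1, 1] == 2
        # q12(ordered) = 0.05, e12 = 0.25 -> round(2*log2(0.2)) = -5
        assert sm.scores[0, 1] == -5
        assert np.allclose(sm.background_freqs, [0.5, 0.5])

    def test_uniform_counts_give_zero_matrix(self):
        sm = build_blosum(np.full((4, 4), 7.0), pseudocount=0.0)
        assert np.all(sm.scores == 0)

    def test_symmetry_and_diagonal_dominance(self, rng):
        c = rng.integers(0, 50, (5, 5)).astype(float)
        counts = c + c.T + np.diag(rng.integers(50, 200, 5).astype(float))
        sm = build_blosum(counts, pseudocount=1.0)
        assert np.array_equal(sm.scores, sm.scores.T)
        assert np.diag(sm.scores).mean() >= sm.scores[~np.eye(5, dtype=bool)].mean()

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValidationError):
            build_blosum(np.zeros((3, 3)), pseudocount=0.0)

    def test_self_consistency_recovers_positive_diagonal(self, rng):
        # sample pairs from an implied q with strong diagonal, rebuild, and
        # check the score signs at large n
        q = np.array([[0.4, 0.05], [0.05, 0.5]])
        draws = rng.choice(4, size=100_000, p=q.ravel())
        counts = np.bincount(draws, minlength=4).reshape(2, 2).astype(float)
        counts = (counts + counts.T) / 2
        sm = build_blosum(counts, pseudocount=1.0)
        assert sm.scores[0, 0] > 0 and sm.scores[1, 1] > 0
        assert sm.scores[0, 1] < 0


class TestNeedlemanWunsch:
    def test_gapless_self_alignment(self):
        sm = simple_matrix()
        a = toks(0, 1, 2, 1, 0)
        r = needleman_wunsch(a, a, sm)
        assert r.raw_score == 5 * 2.0
        assert all(p[0] == p[1] for p in r.path)

    def test_empty_sequence_affine_cost(self):
        sm = simple_matrix()
        r = needleman_wunsch(toks(0, 1, 2), toks(), sm, gap_open=-11, gap_extend=-1)
        assert r.raw_score == -11 - 2
        r = needleman_wunsch(toks(), toks(), sm)
        assert r.raw_score == 0.0 and r.path == []

    def test_matches_exhaustive_enumeration(self, rng):
        # all token pairs of lengths <= 4 over a 3-code alphabet, many
        # random integer substitution matrices
        for _ in range(30):
            raw = rng.integers(-5, 6, (3, 3)).astype(float)
            scores = np.round((raw + raw.T) / 2)
            sm = SubstitutionMatrix(scores=scores, background_freqs=np.full(3, 1 / 3))
            go, ge = float(rng.integers(-8, -2)), float(rng.integers(-3, 0))
            for la in range(5):
                for lb in range(5):
                    a = toks(*rng.integers(0, 3, la))
                    b = toks(*rng.integers(0, 3, lb))
                    r = needleman_wunsch(a, b, sm, go, ge)
                    expected = brute_force_alignment(a.indices, b.indices,
                                                     scores, go, ge)
                    assert r.raw_score == pytest.approx(expected, abs=1e-9)

    def test_swap_invariance(self, rng):
        sm = simple_matrix(4)
        for k in range(20):
            a = toks(*rng.integers(0, 4, 6))
            b = toks(*rng.integers(0, 4, 8))
            assert needleman_wunsch(a, b, sm).raw_score == \
                needleman_wunsch(b, a, sm).raw_score

    def test_path_is_monotone_cover(self, rng):
        sm = simple_matrix(4)
        a = toks(*rng.integers(0, 4, 7))
        b = toks(*rng.integers(0, 4, 5))
        r = needleman_wunsch(a, b, sm)
        ai = [p[0] for p in r.path if p[0] is not None]
        bj = [p[1] for p in r.path if p[1] is not None]
        assert ai == list(range(7)) and bj == list(range(5))

    def test_constant_shift_on_gapless_alignment(self):
        sm = simple_matrix()
        a = toks(0, 1, 2, 0)
        base = needleman_wunsch(a, a, sm).raw_score
        shifted = SubstitutionMatrix(scores=sm.scores + 3.0,
                                     background_freqs=sm.background_freqs)
        assert needleman_wunsch(a, a, shifted).raw_score == base + 3.0 * 4

    def test_codebook_mismatch_raises(self):
        sm = simple_matrix()
        a = TokenSequence(np.array([0, 1]), codebook_id="aaa")
        b = TokenSequence(np.array([0, 1]), codebook_id="bbb")
        with pytest.raises(ValidationError):
            needleman_wunsch(a, b, sm)


class TestPtScore:
    def test_self_is_one(self):
        sm = simple_matrix()
        a = toks(0, 1, 2, 1)
        assert pt_score(a, a, sm).pt_score == pytest.approx(1.0)

    def test_symmetry(self, rng):
        sm = simple_matrix(4)
        for _ in range(50):
            a = toks(*rng.integers(0, 4, rng.integers(2, 9)))
            b = toks(*rng.integers(0, 4, rng.integers(2, 9)))
            assert pt_score(a, b, sm).pt_score == \
                pytest.approx(pt_score(b, a, sm).pt_score, abs=1e-12)

    def test_clipped_to_unit_interval(self, rng):
        sm = simple_matrix(3, match=1.0, mismatch=-10.0)
        for _ in range(20):
            a = toks(*rng.integers(0, 3, 6))
            b = toks(*rng.integers(0, 3, 6))
            s = pt_score(a, b, sm).pt_score
            assert 0.0 <= s <= 1.0


class TestSimilarityHelpers:
    def test_cosine_self_similarity(self, rng):
        cb = Codebook.initialize(8, 4, rng)
        cos = code_cosine_similarity(cb)
        assert np.allclose(np.diag(cos), 1.0)
        assert np.allclose(cos, cos.T)

    def test_spearman_identity_and_hand_value(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)
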