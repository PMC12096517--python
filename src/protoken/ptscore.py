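"""Token-level substitution matrix and global alignment (PT-score).

A BLOSUM-style log-odds matrix is built from token pairs observed at
structurally conserved residues of near-identical structure pairs (structure
pairs with TM-score above 0.8; residues with LDDT above 80).  Needleman–
Wunsch global alignment with affine gaps over that matrix yields a raw
similarity, normalized by the larger self-score into the PT-score in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .structure import ValidationError
from .tokenizer import Codebook, TokenSequence

TM_PAIR_THRESHOLD = 0.8     # structure pairs must exceed this TM-score
LDDT_RESIDUE_THRESHOLD = 80.0  # residues must exceed this LDDT (0-100 scale)

DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0


@dataclass
class SubstitutionMatrix:
    """Symmetric half-bit log-odds scores over token pairs."""

    scores: np.ndarray              # (n_codes, n_codes)
    background_freqs: np.ndarray    # (n_codes,)
    scale_lambda: float = 0.5       # half-bit units

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.background_freqs = np.asarray(self.background_freqs, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValidationError("scores must be square")
        if not np.allclose(self.scores, self.scores.T):
            raise ValidationError("scores must be symmetric")
        if abs(self.background_freqs.sum() - 1.0) > 1e-9:
            raise ValidationError("background frequencies must sum to 1")

    @property
    def size(self) -> int:
        return self.scores.shape[0]


@dataclass
class AlignmentResult:
    """Global alignment path and scores.

    ``path`` steps are ``(i, j)`` for a substitution, ``(i, None)`` for a
    deletion (gap in b), ``(None, j)`` for an insertion (gap in a).
    """

    path: list[tuple[int | None, int | None]]
    raw_score: float
    pt_score: float
    gap_params: tuple[float, float]


def collect_substitution_pairs(
    pairs: list[tuple[TokenSequence, TokenSequence, np.ndarray, float]],
    n_codes: int,
) -> np.ndarray:
    """Count co-occurring token pairs at conserved residues.

    Each item is ``(tokens_a, tokens_b, per_residue_lddt, pair_tm)``; LDDT is
    on the 0-100 scale.  A pair contributes only when its TM-score is
    strictly above 0.8, and a residue only when its LDDT is strictly above
    80.  Each surviving observation (a, b) is added to both (a, b) and
    (b, a); diagonal observations are counted once (no doubling).
    """
    counts = np.zeros((n_codes, n_codes))
    for tok_a, tok_b, res_lddt, pair_tm in pairs:
        if len(tok_a) != len(tok_b):
            raise ValidationError("token sequences in a pair must have equal length")
        if pair_tm <= TM_PAIR_THRESHOLD:
            continue
        res_lddt = np.asarray(res_lddt, dtype=float)
        keep = res_lddt > LDDT_RESIDUE_THRESHOLD
        for a, b in zip(tok_a.indices[keep], tok_b.indices[keep]):
            counts[a, b] += 1
            if a != b:
                counts[b, a] += 1
    return counts


def build_blosum(counts: np.ndarray, pseudocount: float = 1.0) -> SubstitutionMatrix:
    """Henikoff log-odds scores from a symmetric count matrix.

    ``s(a, b) = round(2 * log2(q_ab / e_ab))`` where q is the normalized
    (pseudocounted) pair-frequency table and e the product of marginal code
    frequencies (with the usual factor 2 off the diagonal).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValidationError("counts must be square")
    if not np.allclose(counts, counts.T):
        raise ValidationError("counts must be symmetric")
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValidationError("all-zero count matrix")

    work = counts + pseudocount
    # normalize the full symmetric table; the unordered-pair factors of 2
    # cancel between q and e, leaving ratio = Q_ab / (f_a * f_b)
    q = work / work.sum()
    freqs = q.sum(axis=1)
    e = np.outer(freqs, freqs)
    with np.errstate(divide="ignore"):
        ratio = np.where(q > 0, q / e, np.nan)
        raw = 2.0 * np.log2(ratio)
    # pairs never observed even after pseudocounting get the matrix minimum
    if np.isnan(raw).any():
        raw = np.where(np.isnan(raw), np.nanmin(raw), raw)
    scores = np.round(raw)
    return SubstitutionMatrix(scores=scores, background_freqs=freqs)


def needleman_wunsch(
    a: TokenSequence,
    b: TokenSequence,
    matrix: SubstitutionMatrix,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment with affine gaps (Gotoh three-state DP).

    A gap of length k costs ``gap_open + (k - 1) * gap_extend`` (both
    negative).  Ties break deterministically: diagonal first, then a gap in
    ``b`` (deletion), then a gap in ``a`` (insertion).
    """
    if (a.codebook_id is not None and b.codebook_id is not None
            and a.codebook_id != b.codebook_id):
        raise ValidationError("token sequences come from different codebooks")
    sa, sb = a.indices, b.indices
    if (sa >= matrix.size).any() or (sb >= matrix.size).any():
        raise ValidationError("token index out of range for the substitution matrix")
    n, m = len(sa), len(sb)
    NEG = -np.inf

    # states: 0 = M (substitution), 1 = X (gap in b, consumes a),
    #         2 = Y (gap in a, consumes b); argmax over [M, X, Y] realizes
    #         the declared preference order at every tie.
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        cand = (M[i - 1, 0] + gap_open, X[i - 1, 0] + gap_extend, Y[i - 1, 0] + gap_open)
        pX[i, 0] = int(np.argmax(cand))
        X[i, 0] = cand[pX[i, 0]]
    for j in range(1, m + 1):
        cand = (M[0, j - 1] + gap_open, X[0, j - 1] + gap_open, Y[0, j - 1] + gap_extend)
        pY[0, j] = int(np.argmax(cand))
        Y[0, j] = cand[pY[0, j]]
    for i in range(1, n + 1):
        si = sa[i - 1]
        for j in range(1, m + 1):
            cand = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            pM[i, j] = int(np.argmax(cand))
            M[i, j] = cand[pM[i, j]] + matrix.scores[si, sb[j - 1]]
            cand = (M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                    Y[i - 1, j] + gap_open)
            pX[i, j] = int(np.argmax(cand))
            X[i, j] = cand[pX[i, j]]
            cand = (M[i, j - 1] + gap_open, X[i, j - 1] + gap_open,
                    Y[i, j - 1] + gap_extend)
            pY[i, j] = int(np.argmax(cand))
            Y[i, j] = cand[pY[i, j]]

    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))
    raw = finals[state] if (n, m) != (0, 0) else 0.0

    path: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            path.append((i - 1, j - 1))
            state = int(pM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            path.append((i - 1, None))
            state = int(pX[i, j])
            i -= 1
        else:
            path.append((None, j - 1))
            state = int(pY[i, j])
            j -= 1
    path.reverse()
    return AlignmentResult(path=path, raw_score=float(raw), pt_score=float("nan"),
                           gap_params=(gap_open, gap_extend))


def self_score(tokens: TokenSequence, matrix: SubstitutionMatrix) -> float:
    """Gapless self-alignment score (sum of diagonal substitution scores)."""
    return float(matrix.scores[tokens.indices, tokens.indices].sum())


def pt_score(
    a: TokenSequence,
    b: TokenSequence,
    matrix: SubstitutionMatrix,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Normalized global-alignment similarity in [0, 1].

    ``raw(a, b) / max(self(a), self(b))``, clipped below at zero; 1.0 for
    identical sequences.  Symmetric because the normalizer is the max.
    """
    result = needleman_wunsch(a, b, matrix, gap_open, gap_extend)
    denom = max(self_score(a, matrix), self_score(b, matrix))
    score = result.raw_score / denom if denom > 0 else 0.0
    result.pt_score = float(np.clip(score, 0.0, 1.0))
    return result


def code_cosine_similarity(codebook: Codebook) -> np.ndarray:
    """Cosine similarity between all pairs of codebook vectors."""
    c = codebook.codes
    norms = np.linalg.norm(c, axis=1, keepdims=True)
    u = c / np.maximum(norms, 1e-12)
    return u @ u.T


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    rho = spearmanr(np.asarray(x, float), np.asarray(y, float)).statistic
    return float(rho)
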