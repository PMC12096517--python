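"""Mask-conditioned generation over the joint embedding (RePaint).

Inverse folding, structure sampling from sequence, and motif scaffolding are
all the same operation: some entries of the per-residue joint embedding are
fixed as context, the rest are inpainted by the diffusion model.  At every
reverse step the context entries are replaced by forward-noised context at
the matching noise level; resampling jumps re-diffuse and re-denoise to
harmonize context and generated regions, and the final output carries the
context values exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .diffusion import (
    DenoiserParams,
    DiffusionSchedule,
    JointEmbedding,
    SEQUENCE_DIM,
    STRUCTURE_DIM,
    SequenceEmbeddingTable,
    ancestral_sample,
    decode_sequence,
    embedding_to_tokens,
)
from .structure import AMINO_ACIDS, BackboneStructure, ValidationError, sequence_to_names
from .tokenizer import TokenSequence, TokenizerParams, decode, tokenize

DEFAULT_JUMP_LENGTH = 10
DEFAULT_N_RESAMPLE = 5


@dataclass
class ContextMask:
    """Per-residue context flags and values for conditional generation.

    ``fix_structure[i]`` freezes the 32 structure channels of residue i,
    ``fix_sequence[i]`` the 8 sequence channels; ``context`` holds the joint
    values (unflagged entries are ignored).
    """

    fix_structure: np.ndarray   # (n_res,) bool
    fix_sequence: np.ndarray    # (n_res,) bool
    context: np.ndarray         # (n_res, 40)

    def __post_init__(self) -> None:
        self.fix_structure = np.asarray(self.fix_structure, dtype=bool)
        self.fix_sequence = np.asarray(self.fix_sequence, dtype=bool)
        self.context = np.asarray(self.context, dtype=np.float64)
        n = self.fix_structure.shape[0]
        if self.fix_sequence.shape != (n,) or self.context.shape != (
            n, STRUCTURE_DIM + SEQUENCE_DIM
        ):
            raise ValidationError("inconsistent mask shapes")
        flat = self.flat_mask
        if not np.isfinite(self.context[flat]).all():
            raise ValidationError("flagged context entries must be finite")

    @property
    def n_res(self) -> int:
        return self.fix_structure.shape[0]

    @property
    def flat_mask(self) -> np.ndarray:
        """Boolean (n_res, 40) expansion of the factored flags."""
        m = np.zeros((self.n_res, STRUCTURE_DIM + SEQUENCE_DIM), dtype=bool)
        m[:, :STRUCTURE_DIM] = self.fix_structure[:, None]
        m[:, STRUCTURE_DIM:] = self.fix_sequence[:, None]
        return m


def _repaint_time_sequence(T: int, jump_length: int, n_resample: int) -> list[int]:
    """RePaint time-travel schedule: descending steps with resampling jumps."""
    if jump_length < 1 or n_resample < 1:
        return list(range(T, -1, -1))
    jumps = {j: n_resample - 1 for j in range(0, T - jump_length, jump_length)}
    t = T
    ts = [T]
    while t >= 1:
        t -= 1
        ts.append(t)
        if jumps.get(t, 0) > 0:
            jumps[t] -= 1
            for _ in range(jump_length):
                t += 1
                ts.append(t)
    return ts


def repaint_sample(
    eps_fn,
    schedule: DiffusionSchedule,
    mask: np.ndarray,
    context: np.ndarray,
    seed: int | np.random.Generator,
    jump_length: int = DEFAULT_JUMP_LENGTH,
    n_resample: int = DEFAULT_N_RESAMPLE,
) -> np.ndarray:
    """RePaint-conditioned reverse diffusion on a flat boolean mask.

    ``mask``/``context`` have the sample's shape; flagged entries are held to
    ``context``.  With an empty mask this reduces exactly to
    :func:`ancestral_sample` with the same seed; with a full mask the context
    is returned unchanged (with a warning).  The final state carries context
    entries exactly (hard overwrite at t = 0).
    """
    mask = np.asarray(mask, dtype=bool)
    context = np.asarray(context, dtype=np.float64)
    if mask.shape != context.shape:
        raise ValidationError("mask and context shapes differ")
    if not mask.any():
        return ancestral_sample(eps_fn, schedule, mask.shape, seed)
    if mask.all():
        warnings.warn("context mask covers everything; nothing to generate")
        return context.copy()

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(mask.shape)
    ts = _repaint_time_sequence(schedule.T, jump_length, n_resample)
    for t_cur, t_next in zip(ts[:-1], ts[1:]):
        if t_next < t_cur:  # reverse step t_cur -> t_cur - 1 with harmonization
            t = t_cur
            ab = schedule.alpha_bar[t - 1]
            eps = eps_fn(z, t / schedule.T)
            mean = (z - schedule.beta[t - 1] / np.sqrt(1.0 - ab) * eps) \
                / np.sqrt(schedule.alpha[t - 1])
            if t > 1:
                ab_prev = schedule.alpha_bar[t - 2]
                var = (1.0 - ab_prev) / (1.0 - ab) * schedule.beta[t - 1]
                z_unknown = mean + np.sqrt(var) * rng.standard_normal(mask.shape)
                z_known = np.sqrt(ab_prev) * context \
                    + np.sqrt(1.0 - ab_prev) * rng.standard_normal(mask.shape)
            else:
                z_unknown = mean
                z_known = context
            z = np.where(mask, z_known, z_unknown)
        else:  # forward re-diffusion t_cur -> t_cur + 1
            t = t_next
            z = np.sqrt(schedule.alpha[t - 1]) * z \
                + np.sqrt(schedule.beta[t - 1]) * rng.standard_normal(mask.shape)
    return z


def repaint_embedding(
    denoiser: DenoiserParams,
    mask: ContextMask,
    seed: int | np.random.Generator,
    jump_length: int = DEFAULT_JUMP_LENGTH,
    n_resample: int = DEFAULT_N_RESAMPLE,
) -> JointEmbedding:
    """RePaint in normalized channel space, returned in raw units."""
    ctx_norm = denoiser.normalize(mask.context)
    z = repaint_sample(denoiser.eps_fn, denoiser.schedule, mask.flat_mask,
                       ctx_norm, seed, jump_length, n_resample)
    values = denoiser.denormalize(z)
    # hard overwrite in raw units (exact context preservation)
    values[mask.flat_mask] = mask.context[mask.flat_mask]
    return JointEmbedding(values)


def inverse_fold(
    structure: BackboneStructure,
    tokenizer: TokenizerParams,
    denoiser: DenoiserParams,
    table: SequenceEmbeddingTable,
    n_designs: int = 1,
    seed: int = 0,
    jump_length: int = DEFAULT_JUMP_LENGTH,
    n_resample: int = DEFAULT_N_RESAMPLE,
) -> list[str]:
    """Design sequences for a fixed backbone.

    The backbone is tokenized; its structure channels are held as context
    while the sequence channels are inpainted, then decoded by nearest-row
    lookup.  Each design uses an independent seed stream.
    """
    tokens = tokenize(structure, tokenizer)
    n = len(tokens)
    context = np.zeros((n, STRUCTURE_DIM + SEQUENCE_DIM))
    context[:, :STRUCTURE_DIM] = tokenizer.codebook.codes[tokens.indices]
    mask = ContextMask(np.ones(n, bool), np.zeros(n, bool), context)
    designs = []
    for k in range(n_designs):
        emb = repaint_embedding(denoiser, mask, seed + k, jump_length, n_resample)
        designs.append(decode_sequence(emb.sequence_channel, table))
    return designs


def sample_structure(
    sequence: str,
    tokenizer: TokenizerParams,
    denoiser: DenoiserParams,
    table: SequenceEmbeddingTable,
    n_samples: int = 1,
    seed: int = 0,
    jump_length: int = DEFAULT_JUMP_LENGTH,
    n_resample: int = DEFAULT_N_RESAMPLE,
) -> list[BackboneStructure]:
    """Sample backbones compatible with a sequence.

    Sequence channels are held as context while structure channels are
    inpainted, quantized to tokens, and decoded to a backbone.
    """
    names = sequence_to_names(sequence)
    n = len(names)
    context = np.zeros((n, STRUCTURE_DIM + SEQUENCE_DIM))
    for i, letter in enumerate(names):
        context[i, STRUCTURE_DIM:] = table.vectors[AMINO_ACIDS.index(letter)]
    mask = ContextMask(np.zeros(n, bool), np.ones(n, bool), context)
    out = []
    for k in range(n_samples):
        emb = repaint_embedding(denoiser, mask, seed + k, jump_length, n_resample)
        tokens = embedding_to_tokens(emb.structure_channel, tokenizer.codebook)
        out.append(decode(tokens, tokenizer))
    return out


def scaffold_motif(
    motif_tokens: TokenSequence,
    motif_sequence: str,
    position: int,
    total_length: int,
    tokenizer: TokenizerParams,
    denoiser: DenoiserParams,
    table: SequenceEmbeddingTable,
    seed: int = 0,
    jump_length: int = DEFAULT_JUMP_LENGTH,
    n_resample: int = DEFAULT_N_RESAMPLE,
) -> tuple[BackboneStructure, str, TokenSequence]:
    """Generate a protein around a fixed functional motif.

    The motif's tokens and letters occupy ``[position, position + len)`` and
    are preserved exactly; flanking residues are inpainted jointly in both
    channels.  Returns the decoded backbone, the full sequence, and the full
    token sequence.
    """
    names = sequence_to_names(motif_sequence)
    m = len(motif_tokens)
    if len(names) != m:
        raise ValidationError("motif tokens and sequence must have equal length")
    if position < 0 or position + m > total_length:
        raise ValidationError("motif does not fit in the requested length")
    motif_tokens.validate_against(tokenizer.codebook)

    context = np.zeros((total_length, STRUCTURE_DIM + SEQUENCE_DIM))
    fix = np.zeros(total_length, bool)
    fix[position:position + m] = True
    context[position:position + m, :STRUCTURE_DIM] = \
        tokenizer.codebook.codes[motif_tokens.indices]
    for i, letter in enumerate(names):
        context[position + i, STRUCTURE_DIM:] = table.vectors[AMINO_ACIDS.index(letter)]
    mask = ContextMask(fix.copy(), fix.copy(), context)
    emb = repaint_embedding(denoiser, mask, seed, jump_length, n_resample)
    tokens = embedding_to_tokens(emb.structure_channel, tokenizer.codebook)
    sequence = decode_sequence(emb.sequence_channel, table)
    return decode(tokens, tokenizer), sequence, tokens
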