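"""The structure tokenizer: encoder, vector-quantizing bottleneck, decoder.

An SE(3)-invariant encoder maps a backbone to per-residue embeddings, a
vector-quantization (VQ) bottleneck snaps each embedding to its nearest
codebook vector (the residue's discrete structure token), and a decoder folds
the token sequence back into backbone coordinates.  Training minimizes a
frame-aligned reconstruction error plus violation, commitment, alignment and
uniformity regularizers; the codebook is maintained by exponential moving
averages with dead-code reseeding.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import _nn
from ._autodiff import Tensor, concat, cross, norm, stack
from ._autodiff import softmax as _softmax
from .geometry import (
    CLASH_DISTANCE,
    IDEAL_ANGLES,
    IDEAL_BONDS,
    frames_from_backbone,
    invariant_features,
    PAIR_DIM,
    SINGLE_DIM,
)
from .structure import BackboneStructure, CapacityError, ValidationError
from .synthetic import perturb

__all__ = [
    "Codebook", "TokenSequence", "TokenizerConfig", "TokenizerParams",
    "encode", "quantize", "decode", "tokenize", "detokenize",
    "commitment_loss", "alignment_loss", "uniformity_loss",
    "train_tokenizer", "codebook_usage",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class Codebook:
    """Learned discrete vocabulary of residue-level structure codes.

    The codes are the normalized exponential-moving-average cluster centers:
    after every update each code equals ``ema_sums / max(ema_counts, eps)``.
    """

    codes: np.ndarray        # (n_codes, dim)
    ema_counts: np.ndarray   # (n_codes,)
    ema_sums: np.ndarray     # (n_codes, dim)
    eps: float = 1e-5

    @classmethod
    def initialize(cls, n_codes: int, dim: int, rng: np.random.Generator) -> "Codebook":
        if n_codes < 2:
            raise ValidationError("a codebook needs at least 2 codes")
        codes = rng.normal(0.0, 0.5, (n_codes, dim))
        return cls(codes=codes, ema_counts=np.ones(n_codes), ema_sums=codes.copy())

    @property
    def n_codes(self) -> int:
        return self.codes.shape[0]

    @property
    def dim(self) -> int:
        return self.codes.shape[1]

    @property
    def codebook_id(self) -> str:
        """Short content hash identifying this codebook in files."""
        return hashlib.sha256(np.ascontiguousarray(self.codes).tobytes()).hexdigest()[:12]

    def ema_update(self, embeddings: np.ndarray, indices: np.ndarray, decay: float) -> None:
        """Accumulator update; total count mass becomes decay*previous + batch size."""
        counts = np.bincount(indices, minlength=self.n_codes).astype(float)
        sums = np.zeros_like(self.ema_sums)
        np.add.at(sums, indices, embeddings)
        self.ema_counts = decay * self.ema_counts + counts
        self.ema_sums = decay * self.ema_sums + sums
        self.codes = self.ema_sums / np.maximum(self.ema_counts, self.eps)[:, None]

    def reseed_code(self, index: int, embedding: np.ndarray) -> None:
        self.ema_counts[index] = 1.0
        self.ema_sums[index] = embedding
        self.codes[index] = embedding


@dataclass
class TokenSequence:
    """Per-residue token indices of one encoded structure."""

    indices: np.ndarray
    source_length: int = 0
    codebook_id: str | None = None
    name: str = "protein"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 1:
            raise ValidationError("token indices must be 1-D")
        if self.source_length == 0:
            self.source_length = int(self.indices.shape[0])
        if self.source_length != self.indices.shape[0]:
            raise ValidationError("source_length does not match number of tokens")
        if (self.indices < 0).any():
            raise ValidationError("negative token index")

    def __len__(self) -> int:
        return int(self.indices.shape[0])

    def validate_against(self, codebook: Codebook) -> None:
        if (self.indices >= codebook.n_codes).any():
            bad = int(self.indices[self.indices >= codebook.n_codes][0])
            raise ValidationError(f"token index {bad} >= codebook size {codebook.n_codes}")
        if self.codebook_id is not None and self.codebook_id != codebook.codebook_id:
            raise ValidationError(
                f"token sequence was produced by codebook {self.codebook_id}, "
                f"not {codebook.codebook_id}"
            )


@dataclass
class TokenizerConfig:
    """Architecture and training configuration.

    Defaults are the desk-scale study conditions; the full-scale reference
    values (512 codes, 2/4/2 sandwich, hidden 512-class widths) are reachable
    by overriding the corresponding fields.
    """

    n_codes: int = 64
    code_dim: int = 32
    hidden: int = 64
    n_heads: int = 4
    pair_hidden: int = 16
    sandwich: tuple[int, int, int] = (1, 1, 1)   # full scale: (2, 4, 2)
    torsion_modes: int = 32
    max_len: int = 512
    # training
    learning_rate: float = 3e-3
    epochs: int = 6
    steps_per_epoch: int = 50
    batch_size: int = 4
    w_fape: float = 1.0
    w_torsion: float = 1.0
    w_viol: float = 0.1
    w_commit: float = 0.25
    w_align: float = 0.5
    w_unif: float = 0.01
    commit_beta: float = 0.25
    uniformity_t: float = 2.0
    ema_decay: float = 0.99
    ema_eps: float = 1e-5
    aug_sigma: float = 0.3
    dead_code_steps: int = 50
    kmeans_refit_every: int = 100   # steps between codebook k-means refits (0 = off)
    finetune_frac: float = 0.5      # trailing fraction of epochs with frozen encoder
    seed: int = 0


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------
class _Sandwich(_nn.Module):
    """Stacks of pair-biased attention blocks with pair updates in between."""

    def __init__(self, cfg: TokenizerConfig, rng: np.random.Generator):
        self.stages = [
            _nn.TransformerBlock(cfg.hidden, cfg.n_heads, rng, pair_dim=cfg.pair_hidden)
            for n in cfg.sandwich for _ in range(n)
        ]
        self.pair_updates = [
            _nn.PairUpdate(cfg.hidden, cfg.pair_hidden, rng) for _ in cfg.sandwich
        ]
        self._layout = cfg.sandwich

    def __call__(self, single: Tensor, pair: Tensor,
                 mask: np.ndarray | None = None,
                 return_pair: bool = False):
        k = 0
        for stage, n_blocks in enumerate(self._layout):
            for _ in range(n_blocks):
                single = self.stages[k](single, pair=pair, mask=mask)
                k += 1
            if single.ndim == 2:
                pair = self.pair_updates[stage](single, pair)
        if return_pair:
            return single, pair
        return single


class StructureEncoder(_nn.Module):
    """Invariant features -> sandwich transformer -> embedding head."""

    def __init__(self, cfg: TokenizerConfig, rng: np.random.Generator):
        self.single_in = _nn.Linear(SINGLE_DIM, cfg.hidden, rng)
        self.pair_in = _nn.Linear(PAIR_DIM, cfg.pair_hidden, rng)
        self.sandwich = _Sandwich(cfg, rng)
        self.norm = _nn.LayerNorm(cfg.hidden)
        self.head = _nn.Linear(cfg.hidden, cfg.code_dim, rng)
        # skip path from the raw torsion features: embeddings separate by
        # local geometry already at initialization, which keeps the
        # quantization informative from the first training step
        self.skip = _nn.Linear(SINGLE_DIM, cfg.code_dim, rng)

    def __call__(self, structure: BackboneStructure) -> Tensor:
        feats = invariant_features(structure)
        raw = Tensor(feats.single)
        single = self.single_in(raw)
        pair = self.pair_in(Tensor(feats.pair))
        single = self.sandwich(single, pair)
        return self.head(self.norm(single)) + self.skip(raw)


_N_CA_C = np.radians(IDEAL_ANGLES["N-CA-C"])
#: Ideal atom positions in the residue frame (CA origin, x toward C, N in xy).
_N_LOCAL = IDEAL_BONDS["N-CA"] * np.array([np.cos(_N_CA_C), np.sin(_N_CA_C), 0.0])
_C_LOCAL = np.array([IDEAL_BONDS["CA-C"], 0.0, 0.0])


def _chain_from_torsions(torsions: Tensor) -> Tensor:
    """Differentiable ideal-geometry chain build from (sin, cos) torsions.

    ``torsions`` is (B, n, 6) holding unit (sin, cos) pairs for phi, psi,
    omega; returns atoms (B, n, 4, 3).  The first residue is placed
    canonically; carbonyl O atoms sit anti to the following N.
    """
    B, n, _ = torsions.shape
    b = IDEAL_BONDS

    def place(a, bb, c, bond, angle_deg, sin_t, cos_t):
        theta = np.radians(angle_deg)
        bc = c - bb
        bc = bc / norm(bc, keepdims=True)
        nvec = cross(bb - a, bc)
        nvec = nvec / norm(nvec, keepdims=True)
        m2 = cross(nvec, bc)
        return (c + bond * (-np.cos(theta)) * bc
                + (bond * np.sin(theta)) * (cos_t * m2 + sin_t * nvec))

    n0 = Tensor(np.zeros((B, 3)))
    ca0 = Tensor(np.tile([b["N-CA"], 0.0, 0.0], (B, 1)))
    c0 = Tensor(np.tile([b["N-CA"] + _C_LOCAL[0] * np.cos(np.pi - _N_CA_C),
                         _C_LOCAL[0] * np.sin(np.pi - _N_CA_C), 0.0], (B, 1)))
    ns, cas, cs, os_ = [n0], [ca0], [c0], []
    for i in range(n - 1):
        sphi, cphi = torsions[:, i + 1, 0:1], torsions[:, i + 1, 1:2]
        spsi, cpsi = torsions[:, i, 2:3], torsions[:, i, 3:4]
        somg, comg = torsions[:, i, 4:5], torsions[:, i, 5:6]
        n_next = place(ns[i], cas[i], cs[i], b["C-N"], IDEAL_ANGLES["CA-C-N"], spsi, cpsi)
        ca_next = place(cas[i], cs[i], n_next, b["N-CA"], IDEAL_ANGLES["C-N-CA"], somg, comg)
        c_next = place(cs[i], n_next, ca_next, b["CA-C"], IDEAL_ANGLES["N-CA-C"], sphi, cphi)
        os_.append(place(ns[i], cas[i], cs[i], b["C-O"], IDEAL_ANGLES["CA-C-O"],
                         -1.0 * spsi, -1.0 * cpsi))
        ns.append(n_next)
        cas.append(ca_next)
        cs.append(c_next)
    i = n - 1
    os_.append(place(ns[i], cas[i], cs[i], b["C-O"], IDEAL_ANGLES["CA-C-O"],
                     -1.0 * torsions[:, i, 2:3], -1.0 * torsions[:, i, 3:4]))
    return stack([stack(ns, axis=1), stack(cas, axis=1),
                  stack(cs, axis=1), stack(os_, axis=1)], axis=2)


class StructureDecoder(_nn.Module):
    """Token codes -> sandwich transformer -> torsion head -> chain build.

    A mixture-of-modes torsion head predicts per-residue (phi, psi, omega):
    residues select among shared learned torsion modes (sharp for recurring
    secondary-structure geometry, so per-residue noise cannot creep into
    ideal segments) plus a small learned residual for continuous loop
    torsions.  Integrating the torsions over ideal stereochemistry folds the
    chain, so local geometry is ideal by construction and only the torsions
    are learned.
    """

    def __init__(self, cfg: TokenizerConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.input = _nn.Linear(cfg.code_dim, cfg.hidden, rng)
        self.pair_in = _nn.Linear(2 * 8 + 1, cfg.pair_hidden, rng)
        self.sandwich = _Sandwich(cfg, rng)
        self.norm = _nn.LayerNorm(cfg.hidden)
        self.torsion_modes = Tensor(
            rng.normal(0.0, 0.5, (cfg.torsion_modes, 6)), requires_grad=True
        )
        self.torsion_logits = _nn.Linear(cfg.hidden, cfg.torsion_modes, rng)
        self.torsion_resid = _nn.Linear(cfg.hidden, 6, rng, zero_init=True)

    def _pair_features(self, n: int) -> Tensor:
        idx = np.arange(n)
        sep = np.clip(idx[None, :] - idx[:, None], -8, 8) + 8
        return Tensor(np.eye(17)[sep])

    def forward(self, code_vectors: Tensor, mask: np.ndarray | None = None):
        """Backbone atoms (B, n, 4, 3) and the torsion (sin, cos) triples."""
        squeeze = code_vectors.ndim == 2
        if squeeze:
            code_vectors = code_vectors.reshape(1, *code_vectors.shape)
        B, n, _ = code_vectors.shape
        x = self.input(code_vectors)
        x = x + Tensor(_nn.sinusoidal_embedding(np.arange(n), self.cfg.hidden))
        pair = self.pair_in(self._pair_features(n))
        x = self.sandwich(x, pair, mask=mask)
        x = self.norm(x)

        weights = _softmax(self.torsion_logits(x), axis=-1)
        raw = weights @ self.torsion_modes + self.torsion_resid(x)
        raw = raw.reshape(B, n, 3, 2)
        scale = norm(raw, axis=-1, keepdims=True) + 1e-8
        torsions = (raw / scale).reshape(B, n, 6)
        return _chain_from_torsions(torsions), torsions


@dataclass
class TokenizerParams:
    """Trained tokenizer: encoder, decoder, codebook, and their config."""

    encoder: StructureEncoder
    decoder: StructureDecoder
    codebook: Codebook
    config: TokenizerConfig

    @classmethod
    def initialize(cls, config: TokenizerConfig) -> "TokenizerParams":
        rng = np.random.default_rng(config.seed)
        enc = StructureEncoder(config, rng)
        dec = StructureDecoder(config, rng)
        cb = Codebook.initialize(config.n_codes, config.code_dim, rng)
        cb.eps = config.ema_eps
        return cls(encoder=enc, decoder=dec, codebook=cb, config=config)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def encode(structure: BackboneStructure, params: TokenizerParams) -> np.ndarray:
    """Per-residue continuous embeddings, shape ``(n_res, code_dim)``.

    Deterministic given the parameters and SE(3)-invariant, since the encoder
    consumes only rigid-motion-invariant features.
    """
    if structure.n_res > params.config.max_len:
        raise CapacityError(
            f"structure has {structure.n_res} residues; configured maximum is "
            f"{params.config.max_len}"
        )
    return params.encoder(structure).data.copy()


def quantize(
    embeddings: np.ndarray, codebook: Codebook
) -> tuple[TokenSequence, np.ndarray]:
    """Nearest-code assignment (Euclidean; ties go to the lowest index)."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if embeddings.ndim != 2 or embeddings.shape[1] != codebook.dim:
        raise ValidationError(
            f"embeddings have shape {embeddings.shape}; codebook dim is {codebook.dim}"
        )
    d2 = ((embeddings[:, None, :] - codebook.codes[None, :, :]) ** 2).sum(axis=-1)
    indices = d2.argmin(axis=1)
    tokens = TokenSequence(indices, codebook_id=codebook.codebook_id)
    return tokens, codebook.codes[indices].copy()


def _quantize_st(embeddings: Tensor, codebook: Codebook) -> tuple[np.ndarray, Tensor]:
    """Straight-through quantization: values are codes, gradients pass through."""
    d2 = ((embeddings.data[:, None, :] - codebook.codes[None, :, :]) ** 2).sum(axis=-1)
    indices = d2.argmin(axis=1)
    jump = Tensor(codebook.codes[indices] - embeddings.data)
    return indices, embeddings + jump


def _canonicalize(coords: np.ndarray) -> np.ndarray:
    """Deterministic global frame: CA centroid at origin, principal axes on x/y/z.

    Axis signs are fixed by the sign of the third moment (falling back to the
    largest-magnitude coefficient), and handedness by ``det = +1``.
    """
    ca = coords[:, 1, :]
    center = ca.mean(axis=0)
    x = coords - center
    cov = np.cov(x[:, 1, :].T) if len(ca) > 1 else np.eye(3)
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending variance
    proj = x[:, 1, :] @ v
    for k in range(3):
        m3 = (proj[:, k] ** 3).sum()
        s = np.sign(m3) if abs(m3) > 1e-9 else np.sign(proj[np.abs(proj[:, k]).argmax(), k])
        if s < 0:
            v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return x @ v


def decode(tokens: TokenSequence, params: TokenizerParams) -> BackboneStructure:
    """Fold a token sequence back into backbone coordinates.

    Deterministic; the output is expressed in a canonical global frame so
    repeated decodes of the same tokens are bit-identical.
    """
    tokens.validate_against(params.codebook)
    if len(tokens) > params.config.max_len:
        raise CapacityError(f"token sequence longer than max_len={params.config.max_len}")
    codes = Tensor(params.codebook.codes[tokens.indices])
    atoms, _ = params.decoder.forward(codes)
    return BackboneStructure(_canonicalize(atoms.data[0]))


def tokenize(structure: BackboneStructure, params: TokenizerParams) -> TokenSequence:
    """encode + quantize in one call."""
    tokens, _ = quantize(encode(structure, params), params.codebook)
    return tokens


def detokenize(tokens: TokenSequence, params: TokenizerParams) -> BackboneStructure:
    """Alias of :func:`decode` (CLI vocabulary)."""
    return decode(tokens, params)


# -- losses ----------------------------------------------------------------
def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def commitment_loss(embeddings, quantized, beta: float = 0.25):
    """``beta * mean_r |e_r - sg(c_r)|^2`` (squared gap summed over coords)."""
    e = _as_tensor(embeddings)
    q = _as_tensor(quantized).detach()
    if e.shape != q.shape:
        raise ValidationError(f"shape mismatch {e.shape} vs {q.shape}")
    out = beta * ((e - q) ** 2).sum(axis=-1).mean()
    return out if isinstance(embeddings, Tensor) else float(out.data)


def alignment_loss(emb_a, emb_b):
    """Mean squared difference over residues and coordinates.

    Constrains the embeddings of two structures in the same metastable basin
    (a structure and its perturbation) to coincide.
    """
    a = _as_tensor(emb_a)
    b = _as_tensor(emb_b)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch {a.shape} vs {b.shape}")
    out = ((a - b) ** 2).mean()
    return out if isinstance(emb_a, Tensor) or isinstance(emb_b, Tensor) else float(out.data)


def uniformity_loss(embeddings_batch, t: float = 2.0):
    """Wang–Isola uniformity: ``log mean_{i != j} exp(-t |u_i - u_j|^2)``.

    Rows are L2-normalized first; lower is more uniform on the sphere, which
    encourages spread-out code usage.
    """
    x = _as_tensor(embeddings_batch)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("uniformity needs a batch of at least 2 rows")
    u = x / (norm(x, axis=-1, keepdims=True) + 1e-12)
    g = u @ u.transpose(1, 0)
    sq = (-2.0 * t) * (1.0 - g)          # -t * |u_i-u_j|^2 for unit rows
    n_rows = x.shape[0]
    off = ~np.eye(n_rows, dtype=bool)
    e = sq.exp() * Tensor(off.astype(float))
    out = (e.sum() / float(off.sum())).log()
    return out if isinstance(embeddings_batch, Tensor) else float(out.data)


def codebook_usage(tokens_corpus: list[TokenSequence], codebook: Codebook) -> dict:
    """Empirical usage diagnostics: perplexity and active code fraction."""
    counts = np.zeros(codebook.n_codes)
    for ts in tokens_corpus:
        counts += np.bincount(ts.indices, minlength=codebook.n_codes)
    total = counts.sum()
    if total == 0:
        raise ValidationError("empty token corpus")
    p = counts / total
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    return {"perplexity": float(np.exp(entropy)),
            "active_fraction": float(nz.mean())}


# -- training ---------------------------------------------------------------
def _batched_encoder(params: TokenizerParams,
                     structures: list[BackboneStructure]) -> list[Tensor]:
    return [params.encoder(s) for s in structures]


def _fape_tensor(atoms: Tensor, lengths: list[int],
                 true_locals: list[np.ndarray],
                 clamp: float = 10.0, length_scale: float = 10.0) -> Tensor:
    """Masked batched FAPE of built chains against precomputed true locals."""
    B, n_max = atoms.shape[0], atoms.shape[1]
    n_at = atoms[..., 0, :]
    ca = atoms[..., 1, :]
    c = atoms[..., 2, :]
    # Gram-Schmidt frames of the predicted chain
    e1 = (c - ca)
    e1 = e1 / norm(e1, keepdims=True)
    v2 = n_at - ca
    v2 = v2 - (v2 * e1).sum(axis=-1, keepdims=True) * e1
    e2 = v2 / norm(v2, keepdims=True)
    e3 = cross(e1, e2)
    R = stack([e1, e2, e3], axis=-1)          # (B, n, 3, 3), columns = axes
    flat = atoms.reshape(B, n_max * 4, 3)
    rel = flat.reshape(B, 1, n_max * 4, 3) - ca.reshape(B, n_max, 1, 3)
    local = rel @ R                            # R^T applied to rows
    total = Tensor(np.zeros(()))
    count = 0.0
    for bi, (L, tl) in enumerate(zip(lengths, true_locals)):
        lb = local[bi, :L, : 4 * L, :]
        d = (((lb - Tensor(tl)) ** 2).sum(axis=-1) + 1e-12).sqrt()
        total = total + d.clip_max(clamp).sum()
        count += L * 4 * L
    return total / (count * length_scale)


def _true_locals(structure: BackboneStructure) -> np.ndarray:
    frames = frames_from_backbone(structure)
    return frames.to_local(structure.coords.reshape(-1, 3))


def _torsion_tensor(torsions: Tensor, batch: list[BackboneStructure],
                    n_max: int) -> Tensor:
    """Auxiliary torsion-reconstruction error (masked squared sin/cos gap).

    Supervises the decoder's chain-initialization head directly with the
    training structure's own backbone torsions; undefined angles (termini,
    chain breaks) are masked out.
    """
    from .geometry import backbone_dihedrals

    target = np.zeros((len(batch), n_max, 6))
    weight = np.zeros((len(batch), n_max, 6))
    for bi, s in enumerate(batch):
        ang, valid = backbone_dihedrals(s)
        L = s.n_res
        target[bi, :L, 0::2] = np.sin(ang)
        target[bi, :L, 1::2] = np.cos(ang)
        weight[bi, :L, 0::2] = valid
        weight[bi, :L, 1::2] = valid
    diff = (torsions - Tensor(target)) ** 2 * Tensor(weight)
    return diff.sum() / max(weight.sum(), 1.0)


def _violation_tensor(atoms: Tensor, lengths: list[int]) -> Tensor:
    """Differentiable violation surrogate: peptide-bond stretch + CA clash.

    Intra-residue geometry is ideal by construction in the frame head, so
    only the inter-residue C-N bond and non-bonded CA contacts can violate.
    """
    from .geometry import BOND_TOLERANCE, IDEAL_BONDS as _IB

    B, n_max = atoms.shape[0], atoms.shape[1]
    ca = atoms[..., 1, :]
    diff = ca.reshape(B, n_max, 1, 3) - ca.reshape(B, 1, n_max, 3)
    d = ((diff**2).sum(axis=-1) + 1e-9).sqrt()
    idx = np.arange(n_max)
    base = idx[None, :] - idx[:, None] >= 2
    total = Tensor(np.zeros(()))
    count = 0.0
    for bi, L in enumerate(lengths):
        m = np.zeros((n_max, n_max))
        m[:L, :L] = base[:L, :L]
        total = total + ((CLASH_DISTANCE - d[bi]).relu() * Tensor(m)).sum()
        count += m.sum()
    clash = total / max(count, 1.0)

    pep = atoms[:, 1:, 0, :] - atoms[:, :-1, 2, :]       # N_{i+1} - C_i
    dpep = ((pep**2).sum(axis=-1) + 1e-9).sqrt()
    target = _IB["C-N"]
    excess = (dpep - (target + BOND_TOLERANCE)).relu() \
        + ((target - BOND_TOLERANCE) - dpep).relu()
    total_p = Tensor(np.zeros(()))
    count_p = 0.0
    for bi, L in enumerate(lengths):
        if L >= 2:
            total_p = total_p + excess[bi, :L - 1].sum()
            count_p += L - 1
    return clash + total_p / max(count_p, 1.0)


def train_tokenizer(
    dataset: list[BackboneStructure],
    config: TokenizerConfig | None = None,
    heldout_eval: int = 24,
) -> tuple[TokenizerParams, list[dict]]:
    """Train the tokenizer on a structure corpus.

    Each step draws a minibatch, builds a same-basin perturbation partner per
    structure (alignment pairs), runs the encoder on both, quantizes with
    straight-through gradients, folds the primary batch and applies
    ``w_fape * FAPE + w_viol * clash + w_commit * commitment +
    w_align * alignment + w_unif * uniformity``.  The codebook is EMA-updated
    every step; codes unused for ``dead_code_steps`` consecutive steps are
    reseeded to a random batch embedding.

    Returns the trained parameters and a per-epoch loss trace; the last trace
    entry additionally reports the median held-out reconstruction TM-score
    over freshly perturbed copies of ``heldout_eval`` training folds.
    """
    from .metrics import tm_score  # local import to avoid cycle at module load

    if not dataset:
        raise ValidationError("dataset is empty")
    config = config or TokenizerConfig()
    params = TokenizerParams.initialize(config)
    rng = np.random.default_rng(config.seed + 1)
    trainable = {**{f"enc.{k}": v for k, v in params.encoder.parameters().items()},
                 **{f"dec.{k}": v for k, v in params.decoder.parameters().items()}}
    opt = _nn.Adam(trainable, lr=config.learning_rate)
    unused_steps = np.zeros(config.n_codes, dtype=int)

    def refit_codebook() -> None:
        """k-means refit of the codes to the current embedding distribution.

        EMA vector quantization is online k-means; a periodic global refit
        undoes the code-collapse drift of the online updates and keeps the
        whole vocabulary utilized, which bounds the quantization error that
        the decoder has to absorb.
        """
        from sklearn.cluster import KMeans

        sample = [dataset[i] for i in rng.choice(
            len(dataset), size=min(24, len(dataset)), replace=False)]
        rows = np.concatenate([params.encoder(s).data for s in sample], axis=0)
        # deduplicate near-identical rows so codes are allocated by coverage
        # of embedding space, not by residue-type frequency (otherwise the
        # dominant secondary-structure cluster absorbs most of the codebook)
        scale = max(np.abs(rows).max(), 1e-6)
        _, keep = np.unique(np.round(rows / scale, 2), axis=0, return_index=True)
        unique_rows = rows[np.sort(keep)]
        if unique_rows.shape[0] < config.n_codes:
            extra = rows[rng.choice(rows.shape[0],
                                    config.n_codes - unique_rows.shape[0])]
            unique_rows = np.concatenate(
                [unique_rows, extra + rng.normal(0, 1e-3, extra.shape)], axis=0)
        km = KMeans(n_clusters=config.n_codes, n_init=2,
                    random_state=int(rng.integers(2**31))).fit(unique_rows)
        counts = np.ones(config.n_codes)
        params.codebook.codes = km.cluster_centers_.copy()
        params.codebook.ema_counts = counts
        params.codebook.ema_sums = km.cluster_centers_.copy()

    # data-dependent codebook init over the untrained embedding distribution
    refit_codebook()

    trace: list[dict] = []
    global_step = 0
    phase1_epochs = max(1, int(round(config.epochs * (1.0 - config.finetune_frac))))
    dec_opt: _nn.Adam | None = None
    clean_token_cache: dict[int, np.ndarray] = {}
    for epoch in range(config.epochs):
        phase2 = epoch >= phase1_epochs
        if phase2 and dec_opt is None:
            # decoder fine-tuning phase: encoder and codebook frozen so the
            # token -> fold map is stationary while the decoder converges
            dec_opt = _nn.Adam(params.decoder.parameters(), lr=config.learning_rate)
        sums = {k: 0.0 for k in ("fape", "torsion", "violation",
                                 "commitment", "alignment", "uniformity", "total")}
        for _ in range(config.steps_per_epoch):
            pick = rng.choice(len(dataset), size=min(config.batch_size, len(dataset)),
                              replace=False)
            batch = [dataset[i] for i in pick]
            partners = [
                perturb(s, config.aug_sigma, int(rng.integers(2**31)))
                if (not phase2 or rng.random() < 0.5) else s
                for s in batch
            ]

            if phase2:
                # frozen encoder: plain code-vector inputs, no gradients;
                # clean-structure tokens are cached (they no longer change)
                idx_list = []
                for s, orig_idx in zip(partners, pick):
                    if s is dataset[orig_idx]:
                        if orig_idx not in clean_token_cache:
                            clean_token_cache[orig_idx] = quantize(
                                params.encoder(s).data, params.codebook)[0].indices
                        idx_list.append(clean_token_cache[orig_idx])
                    else:
                        idx_list.append(
                            quantize(params.encoder(s).data,
                                     params.codebook)[0].indices)
                q_list = [Tensor(params.codebook.codes[i]) for i in idx_list]
            else:
                emb = _batched_encoder(params, batch)
                emb_p = _batched_encoder(params, partners)
                all_emb = concat(emb, axis=0)
                # denoising contract: the decoder folds the tokens of the
                # perturbed conformation back to the clean basin representative
                idx_list, q_list = [], []
                for e in emb_p:
                    idx, q = _quantize_st(e, params.codebook)
                    idx_list.append(idx)
                    q_list.append(q)

            lengths = [s.n_res for s in batch]
            n_max = max(lengths)
            padded = []
            for q in q_list:
                pad = n_max - q.shape[0]
                if pad:
                    q = concat([q, Tensor(np.zeros((pad, config.code_dim)))], axis=0)
                padded.append(q)
            qb = stack(padded, axis=0)
            mask = np.zeros((len(batch), n_max), bool)
            for bi, L in enumerate(lengths):
                mask[bi, :L] = True
            atoms, torsions = params.decoder.forward(qb, mask=mask)

            loss_fape = _fape_tensor(atoms, lengths, [_true_locals(s) for s in batch])
            loss_tors = _torsion_tensor(torsions, batch, n_max)
            loss_viol = _violation_tensor(atoms, lengths)
            if phase2:
                loss_commit = Tensor(np.zeros(()))
                loss_align = Tensor(np.zeros(()))
                loss_unif = Tensor(np.zeros(()))
            else:
                loss_commit = sum(
                    (commitment_loss(e, Tensor(params.codebook.codes[i]),
                                     beta=config.commit_beta)
                     for e, i in zip(emb_p, idx_list)),
                    Tensor(np.zeros(())),
                ) * (1.0 / len(emb_p))
                loss_align = sum(
                    (alignment_loss(a, b) for a, b in zip(emb, emb_p)),
                    Tensor(np.zeros(())),
                ) * (1.0 / len(emb))
                loss_unif = uniformity_loss(all_emb, t=config.uniformity_t)

            total = (config.w_fape * loss_fape + config.w_torsion * loss_tors
                     + config.w_viol * loss_viol
                     + config.w_commit * loss_commit + config.w_align * loss_align
                     + config.w_unif * loss_unif)
            for key, value in (("fape", loss_fape), ("torsion", loss_tors),
                               ("violation", loss_viol),
                               ("commitment", loss_commit), ("alignment", loss_align),
                               ("uniformity", loss_unif), ("total", total)):
                v = float(value.data)
                if not np.isfinite(v):
                    raise RuntimeError(f"non-finite {key} loss during tokenizer training")
                sums[key] += v

            active_opt = dec_opt if phase2 else opt
            active_opt.zero_grad()
            total.backward()
            active_opt.step()

            global_step += 1
            if not phase2:
                flat_idx = np.concatenate(idx_list)
                flat_emb = np.concatenate([e.data for e in emb_p], axis=0)
                params.codebook.ema_update(flat_emb, flat_idx, config.ema_decay)
                if (config.kmeans_refit_every
                        and global_step % config.kmeans_refit_every == 0
                        and global_step
                        < phase1_epochs * config.steps_per_epoch
                        - config.kmeans_refit_every // 2):
                    refit_codebook()
                used = np.zeros(config.n_codes, bool)
                used[flat_idx] = True
                unused_steps = np.where(used, 0, unused_steps + 1)
                for code in np.flatnonzero(unused_steps >= config.dead_code_steps):
                    params.codebook.reseed_code(
                        int(code), flat_emb[int(rng.integers(flat_emb.shape[0]))]
                    )
                    unused_steps[code] = 0

        entry = {k: v / config.steps_per_epoch for k, v in sums.items()}
        trace.append(entry)

    # held-out evaluation: freshly perturbed copies of training folds
    eval_rng = np.random.default_rng(config.seed + 99)
    pick = eval_rng.choice(len(dataset), size=min(heldout_eval, len(dataset)),
                           replace=False)
    rtms = []
    for i in pick:
        held = perturb(dataset[i], config.aug_sigma, int(eval_rng.integers(2**31)))
        recon = decode(tokenize(held, params), params)
        rtms.append(tm_score(recon, held))
    trace[-1]["heldout_median_rtm"] = float(np.median(rtms))
    return params, trace
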