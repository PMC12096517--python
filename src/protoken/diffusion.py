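"""Joint sequence–structure diffusion over per-residue embeddings.

Each residue is a 40-dimensional vector: 32 structure channels (the residue's
codebook vector) concatenated with 8 sequence channels (a fixed amino-acid
embedding table).  A DDPM with a transformer noise predictor models the joint
distribution; the probability-flow ODE of the same model gives a
deterministic, invertible map to latent space used for interpolation.

The sampling operations are model-agnostic: they accept any noise predictor
``eps_fn(z, t)`` with ``z`` an ``(..., n, C)`` array and ``t`` a scalar in
``(0, 1]``, which permits analytic (closed-form Gaussian) denoisers in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._autodiff import Tensor
from .structure import AMINO_ACIDS, ValidationError, sequence_to_names
from .tokenizer import Codebook, TokenSequence

STRUCTURE_DIM = 32
SEQUENCE_DIM = 8

#: Full-scale reference architecture from which the desk-scale defaults are
#: shrunk: 24 transformer layers, hidden size 512.
FULL_SCALE_LAYERS = 24
FULL_SCALE_HIDDEN = 512


# ---------------------------------------------------------------------------
# sequence embedding table
# ---------------------------------------------------------------------------
@dataclass
class SequenceEmbeddingTable:
    """Fixed 20 x 8 amino-acid embedding (synthetic-PCA stand-in).

    Rows are the first 8 principal components of the BLOSUM62 substitution
    profile of each amino acid, scaled to unit average row norm.  This gives
    distinct, biochemically structured vectors without any learned model.
    """

    vectors: np.ndarray
    provenance: str = "synthetic-PCA stand-in"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.shape != (20, SEQUENCE_DIM):
            raise ValidationError(f"table must be 20x{SEQUENCE_DIM}")
        d = np.linalg.norm(self.vectors[:, None] - self.vectors[None, :], axis=-1)
        if d[~np.eye(20, dtype=bool)].min() <= 0:
            raise ValidationError("table rows must be pairwise distinct")

    @property
    def min_row_gap(self) -> float:
        d = np.linalg.norm(self.vectors[:, None] - self.vectors[None, :], axis=-1)
        return float(d[~np.eye(20, dtype=bool)].min())

    @classmethod
    def default(cls) -> "SequenceEmbeddingTable":
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        profile = np.array(
            [[blosum[a][b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
        )
        centered = profile - profile.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        comp = centered @ vt[:SEQUENCE_DIM].T
        # deterministic sign convention: largest-magnitude loading positive
        for k in range(SEQUENCE_DIM):
            j = np.abs(comp[:, k]).argmax()
            if comp[j, k] < 0:
                comp[:, k] = -comp[:, k]
        comp /= np.linalg.norm(comp, axis=1).mean()
        return cls(vectors=comp)


# ---------------------------------------------------------------------------
# joint embedding
# ---------------------------------------------------------------------------
@dataclass
class JointEmbedding:
    """Per-residue concatenation of structure and sequence channels."""

    values: np.ndarray                     # (n_res, 40)
    sequence_present: bool = True
    channel_layout: tuple[int, int] = (STRUCTURE_DIM, SEQUENCE_DIM)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != sum(self.channel_layout):
            raise ValidationError(
                f"values must be (n_res, {sum(self.channel_layout)}), got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("embedding contains non-finite values")

    @property
    def n_res(self) -> int:
        return self.values.shape[0]

    @property
    def structure_channel(self) -> np.ndarray:
        return self.values[:, : self.channel_layout[0]]

    @property
    def sequence_channel(self) -> np.ndarray:
        return self.values[:, self.channel_layout[0]:]


def embed_protein(
    tokens: TokenSequence,
    sequence: str | None,
    codebook: Codebook,
    table: SequenceEmbeddingTable,
) -> JointEmbedding:
    """Build the joint per-residue embedding of a (structure, sequence) pair.

    The structure channel holds the codebook vectors of the token indices;
    the sequence channel holds table rows (zeros with ``sequence_present``
    unset when no sequence is given).
    """
    tokens.validate_against(codebook)
    z_x = codebook.codes[tokens.indices]
    if sequence is None:
        z_s = np.zeros((len(tokens), SEQUENCE_DIM))
        return JointEmbedding(np.concatenate([z_x, z_s], axis=1),
                              sequence_present=False)
    names = sequence_to_names(sequence)
    if len(names) != len(tokens):
        raise ValidationError(
            f"sequence length {len(names)} != token length {len(tokens)}"
        )
    rows = []
    for pos, letter in enumerate(names):
        if letter not in AMINO_ACIDS:
            raise ValidationError(f"unknown amino-acid letter {letter!r} at position {pos}")
        rows.append(table.vectors[AMINO_ACIDS.index(letter)])
    return JointEmbedding(np.concatenate([z_x, np.array(rows)], axis=1))


def decode_sequence(z_s: np.ndarray, table: SequenceEmbeddingTable) -> str:
    """Nearest-row decoding of sequence channels; ties go alphabetically."""
    z_s = np.asarray(z_s, dtype=np.float64)
    if z_s.ndim != 2 or z_s.shape[1] != SEQUENCE_DIM:
        raise ValidationError(f"z_s must be (n_res, {SEQUENCE_DIM})")
    d2 = ((z_s[:, None, :] - table.vectors[None, :, :]) ** 2).sum(axis=-1)
    return "".join(AMINO_ACIDS[i] for i in d2.argmin(axis=1))


def embedding_to_tokens(z_x: np.ndarray, codebook: Codebook) -> TokenSequence:
    """Nearest-code decoding of structure channels."""
    from .tokenizer import quantize

    tokens, _ = quantize(np.asarray(z_x, dtype=np.float64), codebook)
    return tokens


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------
@dataclass
class DiffusionSchedule:
    """Discrete DDPM variance schedule with a continuous-time extension.

    ``beta[i]`` is the noise added at step ``i + 1`` of ``T``; ``alpha_bar``
    is the cumulative signal fraction.  The continuous-time rate used by the
    probability-flow ODE is the linear interpolation ``beta_cont(t) =
    T * beta(t * T)``, whose integral is available in closed form.
    """

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.beta.ndim != 1 or self.beta.size < 1:
            raise ValidationError("beta must be a non-empty 1-D array")
        if ((self.beta <= 0) | (self.beta >= 1)).any():
            raise ValidationError("beta values must lie in (0, 1)")
        self.alpha = 1.0 - self.beta
        self.alpha_bar = np.cumprod(self.alpha)
        if not (np.diff(self.alpha_bar) < 0).all():
            raise ValidationError("alpha_bar must be strictly decreasing")

    @property
    def T(self) -> int:
        return int(self.beta.size)

    @classmethod
    def linear(cls, T: int = 100, beta_start: float | None = None,
               beta_end: float | None = None) -> "DiffusionSchedule":
        """Linear schedule; endpoints default to the 1000-step convention
        (1e-4 to 0.02) rescaled by 1000/T so the continuous-time process is
        independent of the step count and ``alpha_bar[T-1]`` is ~4e-5."""
        if beta_start is None:
            beta_start = 1e-4 * (1000.0 / T)
        if beta_end is None:
            beta_end = 0.02 * (1000.0 / T)
        return cls(np.linspace(beta_start, beta_end, T))

    # continuous-time extension (t in [0, 1]): the variance-preserving SDE
    # with linearly interpolated rate, of which the discrete chain is the
    # Euler discretization (agreement is O(beta^2) per step; both signal
    # fractions vanish at the tail)
    def beta_cont(self, t: float) -> float:
        b0, b1 = self.beta[0], self.beta[-1]
        return float(self.T * (b0 + (b1 - b0) * np.clip(t, 0.0, 1.0)))

    def integral_beta(self, t: float) -> float:
        b0, b1 = self.beta[0], self.beta[-1]
        t = float(np.clip(t, 0.0, 1.0))
        return self.T * (b0 * t + 0.5 * (b1 - b0) * t * t)

    def alpha_bar_cont(self, t: float) -> float:
        return float(np.exp(-self.integral_beta(t)))


# ---------------------------------------------------------------------------
# DDPM core
# ---------------------------------------------------------------------------
def ddpm_forward(z0: np.ndarray, t: int, schedule: DiffusionSchedule,
                 noise: np.ndarray) -> np.ndarray:
    """Closed-form forward marginal ``z_t = sqrt(ab_t) z0 + sqrt(1-ab_t) eps``.

    ``t`` is 1-based (``t = 0`` returns ``z0`` unchanged).
    """
    z0 = np.asarray(z0, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != z0.shape:
        raise ValidationError("noise must match z0 shape")
    if t == 0:
        return z0.copy()
    if not 1 <= t <= schedule.T:
        raise ValidationError(f"step {t} outside [0, {schedule.T}]")
    ab = schedule.alpha_bar[t - 1]
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * noise


def noise_matching_loss(eps_fn, z0_batch: np.ndarray, schedule: DiffusionSchedule,
                        rng: np.random.Generator, n_draws: int = 1) -> float:
    """Monte-Carlo noise-matching objective ``E |eps - eps_fn(z_t, t)|^2``.

    The expectation runs over uniform steps and Gaussian noise; the squared
    error is summed over channels and averaged over residues and draws, so a
    zero predictor scores the total channel dimension.
    """
    z0_batch = np.asarray(z0_batch, dtype=np.float64)
    total = 0.0
    count = 0
    for _ in range(n_draws):
        for z0 in z0_batch:
            t = int(rng.integers(1, schedule.T + 1))
            eps = rng.standard_normal(z0.shape)
            zt = ddpm_forward(z0, t, schedule, eps)
            pred = eps_fn(zt, t / schedule.T)
            total += ((eps - pred) ** 2).sum(axis=-1).mean()
            count += 1
    return float(total / count)


def ancestral_sample(eps_fn, schedule: DiffusionSchedule, shape: tuple[int, ...],
                     seed: int | np.random.Generator) -> np.ndarray:
    """Standard DDPM reverse chain from pure noise.

    Posterior variance ``beta_tilde``; the final step adds no noise.
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(shape)
    for t in range(schedule.T, 0, -1):
        ab = schedule.alpha_bar[t - 1]
        alpha = schedule.alpha[t - 1]
        eps = eps_fn(z, t / schedule.T)
        mean = (z - schedule.beta[t - 1] / np.sqrt(1.0 - ab) * eps) / np.sqrt(alpha)
        if t > 1:
            ab_prev = schedule.alpha_bar[t - 2]
            var = (1.0 - ab_prev) / (1.0 - ab) * schedule.beta[t - 1]
            z = mean + np.sqrt(var) * rng.standard_normal(shape)
        else:
            z = mean
    return z


# ---------------------------------------------------------------------------
# probability-flow ODE
# ---------------------------------------------------------------------------
T_MIN = 1e-3   # lower integration limit; ab_cont(t) -> 1 as t -> 0


def _pf_ode_rhs(eps_fn, schedule: DiffusionSchedule, z: np.ndarray, t: float) -> np.ndarray:
    beta = schedule.beta_cont(t)
    ab = schedule.alpha_bar_cont(t)
    score_scale = 1.0 / np.sqrt(max(1.0 - ab, 1e-12))
    return -0.5 * beta * (z - score_scale * eps_fn(z, t))


def _rk4(eps_fn, schedule, z, t0, t1, n_steps):
    h = (t1 - t0) / n_steps
    t = t0
    for _ in range(n_steps):
        k1 = _pf_ode_rhs(eps_fn, schedule, z, t)
        k2 = _pf_ode_rhs(eps_fn, schedule, z + 0.5 * h * k1, t + 0.5 * h)
        k3 = _pf_ode_rhs(eps_fn, schedule, z + 0.5 * h * k2, t + 0.5 * h)
        k4 = _pf_ode_rhs(eps_fn, schedule, z + h * k3, t + h)
        z = z + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return z


def pf_ode_encode(z0: np.ndarray, eps_fn, schedule: DiffusionSchedule,
                  n_steps: int = 100) -> np.ndarray:
    """Deterministic data-to-latent map: integrate the PF-ODE from 0 to 1."""
    return _rk4(eps_fn, schedule, np.asarray(z0, dtype=np.float64), T_MIN, 1.0, n_steps)


def pf_ode_decode(z1: np.ndarray, eps_fn, schedule: DiffusionSchedule,
                  n_steps: int = 100) -> np.ndarray:
    """Inverse of :func:`pf_ode_encode`: integrate from 1 back to 0."""
    return _rk4(eps_fn, schedule, np.asarray(z1, dtype=np.float64), 1.0, T_MIN, n_steps)


def interpolate_latent(zA: np.ndarray, zB: np.ndarray, lambdas, eps_fn,
                       schedule: DiffusionSchedule, n_steps: int = 100) -> list[np.ndarray]:
    """Linear latent interpolation via the PF-ODE.

    Both endpoints are encoded to latents, mixed as ``(1-l) zA(1) + l zB(1)``
    and each mixture decoded by the backward initial-value problem.
    """
    zA = np.asarray(zA, dtype=np.float64)
    zB = np.asarray(zB, dtype=np.float64)
    if zA.shape != zB.shape:
        raise ValidationError("interpolation endpoints must have equal shape")
    lA = pf_ode_encode(zA, eps_fn, schedule, n_steps)
    lB = pf_ode_encode(zB, eps_fn, schedule, n_steps)
    out = []
    for lam in lambdas:
        if not 0.0 <= lam <= 1.0:
            raise ValidationError("lambda values must lie in [0, 1]")
        mix = (1.0 - lam) * lA + lam * lB
        out.append(pf_ode_decode(mix, eps_fn, schedule, n_steps))
    return out


# ---------------------------------------------------------------------------
# transformer noise predictor
# ---------------------------------------------------------------------------
@dataclass
class DenoiserConfig:
    channels: int = STRUCTURE_DIM + SEQUENCE_DIM
    n_layers: int = 2            # full scale: FULL_SCALE_LAYERS
    hidden: int = 64             # full scale: FULL_SCALE_HIDDEN
    n_heads: int = 4
    d_time: int = 32
    T: int = 100
    beta_start: float = 1e-4
    beta_end: float = 0.02
    learning_rate: float = 2e-3
    epochs: int = 5
    steps_per_epoch: int = 40
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_layers, self.hidden, self.n_heads, self.d_time, self.T) < 1:
            raise ValidationError("denoiser config values must be positive")


class DiTNetwork(_nn.Module):
    """Diffusion transformer with adaptive layer-norm time conditioning."""

    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.input = _nn.Linear(cfg.channels, cfg.hidden, rng)
        self.time_mlp = _nn.MLP(cfg.d_time, 2 * cfg.d_time, rng, d_out=cfg.d_time)
        self.blocks = [
            _nn.DiTBlock(cfg.hidden, cfg.n_heads, cfg.d_time, rng)
            for _ in range(cfg.n_layers)
        ]
        self.norm = _nn.LayerNorm(cfg.hidden)
        self.output = _nn.Linear(cfg.hidden, cfg.channels, rng, zero_init=True)

    def __call__(self, z_t: Tensor, t: np.ndarray,
                 mask: np.ndarray | None = None) -> Tensor:
        B, n, _ = z_t.shape
        x = self.input(z_t) + Tensor(_nn.sinusoidal_embedding(np.arange(n), self.cfg.hidden))
        t_emb = self.time_mlp(Tensor(
            _nn.sinusoidal_embedding(np.asarray(t, float) * self.cfg.T, self.cfg.d_time)
        ))
        for block in self.blocks:
            x = block(x, t_emb, mask=mask)
        out = self.output(self.norm(x))
        if mask is not None:
            out = out * Tensor(np.asarray(mask, float)[..., None])
        return out


@dataclass
class DenoiserParams:
    """Trained noise predictor plus its per-channel data normalization."""

    network: DiTNetwork
    config: DenoiserConfig
    schedule: DiffusionSchedule
    channel_mean: np.ndarray
    channel_std: np.ndarray

    @classmethod
    def initialize(cls, config: DenoiserConfig) -> "DenoiserParams":
        rng = np.random.default_rng(config.seed)
        net = DiTNetwork(config, rng)
        sched = DiffusionSchedule.linear(config.T, config.beta_start, config.beta_end)
        c = config.channels
        return cls(network=net, config=config, schedule=sched,
                   channel_mean=np.zeros(c), channel_std=np.ones(c))

    def normalize(self, values: np.ndarray) -> np.ndarray:
        return (values - self.channel_mean) / self.channel_std

    def denormalize(self, values: np.ndarray) -> np.ndarray:
        return values * self.channel_std + self.channel_mean

    def eps_fn(self, z: np.ndarray, t: float) -> np.ndarray:
        """Noise prediction on normalized arrays; accepts (n, C) or (B, n, C)."""
        z = np.asarray(z, dtype=np.float64)
        squeeze = z.ndim == 2
        if squeeze:
            z = z[None]
        out = self.network(Tensor(z), np.full(z.shape[0], t)).data
        return out[0] if squeeze else out


def train_denoiser(
    corpus: list[JointEmbedding],
    config: DenoiserConfig | None = None,
) -> tuple[DenoiserParams, list[dict]]:
    """Train the diffusion transformer on a corpus of joint embeddings.

    Channels are standardized with corpus statistics (stored in the returned
    parameters); variable lengths are padded under a residue mask; each step
    draws one uniform diffusion time per example.  Deterministic per seed.
    """
    if not corpus:
        raise ValidationError("corpus is empty")
    config = config or DenoiserConfig()
    params = DenoiserParams.initialize(config)
    rng = np.random.default_rng(config.seed + 1)

    stacked = np.concatenate([z.values for z in corpus], axis=0)
    params.channel_mean = stacked.mean(axis=0)
    params.channel_std = np.maximum(stacked.std(axis=0), 1e-6)
    data = [params.normalize(z.values) for z in corpus]

    opt = _nn.Adam(params.network.parameters(), lr=config.learning_rate)
    sched = params.schedule
    trace: list[dict] = []
    for _ in range(config.epochs):
        acc = 0.0
        for _ in range(config.steps_per_epoch):
            pick = rng.choice(len(data), size=min(config.batch_size, len(data)),
                              replace=False)
            batch = [data[i] for i in pick]
            n_max = max(b.shape[0] for b in batch)
            B = len(batch)
            z0 = np.zeros((B, n_max, config.channels))
            mask = np.zeros((B, n_max), bool)
            for bi, b in enumerate(batch):
                z0[bi, : b.shape[0]] = b
                mask[bi, : b.shape[0]] = True
            t_idx = rng.integers(1, sched.T + 1, size=B)
            eps = rng.standard_normal(z0.shape)
            ab = sched.alpha_bar[t_idx - 1][:, None, None]
            zt = np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps

            pred = params.network(Tensor(zt), t_idx / sched.T, mask=mask)
            m = mask.astype(float)[..., None]
            # squared error summed over channels, averaged over valid residues
            loss = (((pred - Tensor(eps)) ** 2) * Tensor(m)).sum() / max(mask.sum(), 1)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError("non-finite noise-matching loss during training")
            acc += value
            opt.zero_grad()
            loss.backward()
            opt.step()
        trace.append({"noise_matching": acc / config.steps_per_epoch})
    return params, trace
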