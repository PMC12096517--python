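"""Joint embedding, DDPM closed forms, PF-ODE, and denoiser training."""

import numpy as np
import pytest
from scipy.stats import kstest

from protoken.diffusion import (
    DenoiserConfig,
    DenoiserParams,
    DiffusionSchedule,
    JointEmbedding,
    SEQUENCE_DIM,
    STRUCTURE_DIM,
    SequenceEmbeddingTable,
    ancestral_sample,
    ddpm_forward,
    decode_sequence,
    embed_protein,
    embedding_to_tokens,
    interpolate_latent,
    noise_matching_loss,
    pf_ode_decode,
    pf_ode_encode,
    train_denoiser,
)
from protoken.structure import AMINO_ACIDS, ValidationError
from protoken.tokenizer import Codebook, TokenSequence


@pytest.fixture(scope="module")
def table():
    return SequenceEmbeddingTable.default()


@pytest.fixture(scope="module")
def schedule():
    return DiffusionSchedule.linear(100)


def gaussian_eps_fn(schedule, sigma, mu=0.0, continuous=False):
    """Exact noise predictor for a N(mu, sigma^2 I) data distribution."""

    def eps(z, t):
        if continuous:
            ab = schedule.alpha_bar_cont(t)
        else:
            ab = schedule.alpha_bar[min(int(round(t * schedule.T)) - 1, schedule.T - 1)]
        v = ab * sigma**2 + (1.0 - ab)
        return np.sqrt(1.0 - ab) * (z - np.sqrt(ab) * mu) / v

    return eps


class TestJointEmbedding:
    def test_construction_from_tokens_and_sequence(self, table, rng):
        cb = Codebook.initialize(16, STRUCTURE_DIM, rng)
        tokens = TokenSequence(np.array([3]))
        emb = embed_protein(tokens, "A", cb, table)
        assert np.array_equal(emb.values[0, :STRUCTURE_DIM], cb.codes[3])
        assert np.array_equal(emb.values[0, STRUCTURE_DIM:], table.vectors[0])

    def test_absent_sequence_zeros_and_flag(self, table, rng):
        cb = Codebook.initialize(16, STRUCTURE_DIM, rng)
        emb = embed_protein(TokenSequence(np.array([1, 2])), None, cb, table)
        assert not emb.sequence_present
        assert np.all(emb.values[:, STRUCTURE_DIM:] == 0.0)

    def test_round_trip_recovers_tokens_and_letters(self, table, rng):
        cb = Codebook.initialize(32, STRUCTURE_DIM, rng)
        idx = rng.integers(0, 32, 25)
        seq = "".join(rng.choice(list(AMINO_ACIDS), 25))
        emb = embed_protein(TokenSequence(idx), seq, cb, table)
        back = embedding_to_tokens(emb.structure_channel, cb)
        assert np.array_equal(back.indices, idx)
        assert decode_sequence(emb.sequence_channel, table) == seq

    def test_unknown_letter_reports_position(self, table, rng):
        cb = Codebook.initialize(8, STRUCTURE_DIM, rng)
        with pytest.raises(ValidationError, match="position 1"):
            embed_protein(TokenSequence(np.array([0, 1, 2])), "AXA", cb, table)

    def test_channel_split_enforced(self):
        with pytest.raises(ValidationError):
            JointEmbedding(np.zeros((5, 39)))


class TestDecodeSequence:
    def test_noise_below_half_gap_is_exact(self, table, rng):
        gap = table.min_row_gap
        seq = "ACDEFGHIKLMNPQRSTVWY"
        z = table.vectors.copy()
        noise = rng.standard_normal(z.shape)
        noise *= 0.49 * gap / np.linalg.norm(noise, axis=1, keepdims=True)
        assert decode_sequence(z + noise, table) == seq

    def test_tie_goes_to_alphabetical_first(self, table):
        mid = 0.5 * (table.vectors[0] + table.vectors[1])  # A/C midpoint
        assert decode_sequence(mid[None, :], table)[0] == "A"


class TestSchedule:
    def test_validation(self):
        with pytest.raises(ValidationError):
            DiffusionSchedule(np.array([0.5, 1.5]))
        s = DiffusionSchedule.linear(50)
        assert (np.diff(s.alpha_bar) < 0).all()
        assert s.alpha_bar[0] == pytest.approx(1 - s.beta[0])

    def test_terminal_signal_fraction_is_negligible(self, schedule):
        assert schedule.alpha_bar[-1] < 1e-4

    def test_continuous_extension_tracks_discrete(self, schedule):
        # the discrete chain is the Euler discretization of the continuous
        # process: early agreement is tight, tail deviation stays modest
        assert schedule.alpha_bar_cont(10 / schedule.T) == pytest.approx(
            schedule.alpha_bar[9], rel=0.01
        )
        assert schedule.alpha_bar_cont(0.5) == pytest.approx(
            schedule.alpha_bar[49], rel=0.1
        )
        # at the tail both signal fractions are negligible
        assert schedule.alpha_bar_cont(1.0) < 1e-4
        assert schedule.alpha_bar[-1] < 1e-4


class TestDdpmForward:
    def test_t_zero_identity(self, schedule, rng):
        z0 = rng.standard_normal((7, 4))
        assert np.array_equal(ddpm_forward(z0, 0, schedule, np.zeros_like(z0)), z0)

    def test_terminal_marginal_is_standard_normal(self, schedule, rng):
        z0 = np.full((10_000, 1), 3.0)
        z = ddpm_forward(z0, schedule.T, schedule, rng.standard_normal(z0.shape))
        assert abs(z.mean()) < 3 / np.sqrt(10_000) + 0.05
        assert abs(z.std() - 1.0) < 0.05

    def test_closed_form_matches_sequential_composition(self, schedule, rng):
        z0 = np.zeros((10_000, 1))
        closed = ddpm_forward(z0, schedule.T, schedule, rng.standard_normal(z0.shape))
        seq = z0.copy()
        for t in range(1, schedule.T + 1):
            seq = np.sqrt(schedule.alpha[t - 1]) * seq \
                + np.sqrt(schedule.beta[t - 1]) * rng.standard_normal(z0.shape)
        assert kstest(closed.ravel(), seq.ravel()).pvalue > 0.01


class TestNoiseMatchingLoss:
    def test_oracle_denoiser_is_zero(self, schedule, rng):
        z0 = np.zeros((5, 6, 8))
        # with z0 = 0: z_t = sqrt(1-ab) eps, so eps = z_t / sqrt(1-ab)
        def oracle(z, t):
            ab = schedule.alpha_bar[int(round(t * schedule.T)) - 1]
            return z / np.sqrt(1 - ab)
        assert noise_matching_loss(oracle, z0, schedule, rng) == pytest.approx(0.0)

    def test_zero_denoiser_matches_channel_dimension(self, schedule):
        rng = np.random.default_rng(1)
        z0 = np.zeros((50, 10, 12))
        zero = lambda z, t: np.zeros_like(z)
        loss = noise_matching_loss(zero, z0, schedule, rng, n_draws=20)
        assert loss == pytest.approx(12.0, rel=0.02)

    def test_fixed_seed_determinism(self, schedule, rng):
        z0 = rng.standard_normal((4, 5, 6))
        zero = lambda z, t: np.zeros_like(z)
        a = noise_matching_loss(zero, z0, schedule, np.random.default_rng(7))
        b = noise_matching_loss(zero, z0, schedule, np.random.default_rng(7))
        assert a == b


class TestAncestralSampling:
    def test_gaussian_target_moments(self, schedule):
        mu, sigma = 0.7, 1.2
        eps = gaussian_eps_fn(schedule, sigma, mu)
        s = ancestral_sample(eps, schedule, (20_000, 1), seed=3)
        assert s.mean() == pytest.approx(mu, rel=0.05)
        assert s.std() == pytest.approx(sigma, rel=0.05)

    def test_same_seed_identical(self, schedule):
        eps = gaussian_eps_fn(schedule, 1.0)
        a = ancestral_sample(eps, schedule, (5, 3), seed=11)
        b = ancestral_sample(eps, schedule, (5, 3), seed=11)
        assert np.array_equal(a, b)

    def test_single_step_noise_free_limit(self):
        # T = 1 with tiny beta: output equals the denoiser-implied z0
        sched = DiffusionSchedule(np.array([1e-4]))
        eps = lambda z, t: np.zeros_like(z)
        out = ancestral_sample(eps, sched, (4, 2), seed=0)
        z_T = np.random.default_rng(0).standard_normal((4, 2))
        expected = z_T / np.sqrt(sched.alpha[0])
        assert np.allclose(out, expected)


class TestPfOde:
    def test_matches_closed_form_linear_solution(self, schedule):
        sigma = 1.8
        eps = gaussian_eps_fn(schedule, sigma, continuous=True)
        z0 = np.linspace(-2, 2, 9).reshape(-1, 1)
        encoded = pf_ode_encode(z0, eps, schedule, n_steps=100)
        # for a centred Gaussian the PF-ODE is linear with solution
        # z(t) = sqrt(v(t)/v(t0)) z(t0), v(t) = 1 - (1 - sigma^2) ab(t)
        v = lambda t: 1.0 - (1.0 - sigma**2) * schedule.alpha_bar_cont(t)
        expected = np.sqrt(v(1.0) / v(1e-3)) * z0
        assert np.abs(encoded - expected).max() < 1e-3

    def test_round_trip_identity(self, schedule):
        eps = gaussian_eps_fn(schedule, 1.4, continuous=True)
        z0 = np.random.default_rng(2).standard_normal((6, 3))
        back = pf_ode_decode(pf_ode_encode(z0, eps, schedule), eps, schedule)
        assert np.abs(back - z0).max() < 1e-6

    def test_more_steps_do_not_hurt(self, schedule):
        eps = gaussian_eps_fn(schedule, 1.4, continuous=True)
        z0 = np.random.default_rng(3).standard_normal((4, 2))
        errs = []
        for n in (50, 100, 200):
            back = pf_ode_decode(pf_ode_encode(z0, eps, schedule, n), eps, schedule, n)
            errs.append(np.abs(back - z0).max())
        assert errs[1] <= errs[0] + 1e-9 and errs[2] <= errs[1] + 1e-9

    def test_interpolation_endpoints_and_blend(self, schedule):
        sigma = 1.5
        eps = gaussian_eps_fn(schedule, sigma, continuous=True)
        zA = np.full((5, 2), -1.0)
        zB = np.full((5, 2), 2.0)
        out = interpolate_latent(zA, zB, [0.0, 0.5, 1.0], eps, schedule)
        assert np.abs(out[0] - zA).max() < 1e-6
        assert np.abs(out[2] - zB).max() < 1e-6
        # linear ODE: decoded midpoint equals the data-space midpoint
        assert np.abs(out[1] - 0.5 * (zA + zB)).max() < 1e-3

    def test_length_mismatch_raises(self, schedule):
        eps = gaussian_eps_fn(schedule, 1.0, continuous=True)
        with pytest.raises(ValidationError):
            interpolate_latent(np.zeros((4, 2)), np.zeros((5, 2)), [0.5], eps, schedule)


class TestTrainDenoiser:
    def test_loss_decreases_and_is_deterministic(self, rng):
        corpus = []
        for k in range(30):
            n = int(rng.integers(40, 60))
            base = np.sin(np.arange(n)[:, None] * 0.3 + (k % 2)) * np.ones((1, 40))
            corpus.append(JointEmbedding(base + 0.1 * rng.normal(size=(n, 40))))
        cfg = DenoiserConfig(epochs=3, steps_per_epoch=15, seed=0)
        params, trace = train_denoiser(corpus, cfg)
        assert trace[-1]["noise_matching"] < trace[0]["noise_matching"]
        _, trace2 = train_denoiser(corpus, cfg)
        assert trace == trace2

    def test_untrained_network_sits_at_channel_baseline(self, schedule):
        # zero-initialized output head -> zero prediction -> loss ~ channels
        params = DenoiserParams.initialize(DenoiserConfig(seed=4))
        rng = np.random.default_rng(5)
        z0 = rng.standard_normal((30, 8, 40))
        loss = noise_matching_loss(params.eps_fn, z0, params.schedule, rng, n_draws=5)
        assert loss == pytest.approx(40.0, rel=0.02)
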