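"""Shared fixtures.

The expensive fixtures (trained toy tokenizer, trained diffusion model) are
session-scoped: they are trained once at the study conditions and shared by
every test that needs a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from protoken.diffusion import (
    DenoiserConfig,
    SequenceEmbeddingTable,
    embed_protein,
    train_denoiser,
)
from protoken.synthetic import CorpusConfig, gen_training_corpus
from protoken.tokenizer import TokenizerConfig, tokenize, train_tokenizer

TOY_SEED = 7


@pytest.fixture(scope="session")
def toy_corpus():
    """The bundled study corpus: 200 synthetic folds with planted sequences."""
    return gen_training_corpus(200, CorpusConfig(seed=TOY_SEED))


@pytest.fixture(scope="session")
def toy_tokenizer(toy_corpus):
    """Tokenizer trained at the study conditions (200 structures, 64 codes)."""
    structures = [s for s, _ in toy_corpus]
    config = TokenizerConfig(seed=0, epochs=16, steps_per_epoch=100,
                             batch_size=4, finetune_frac=0.5625)
    params, trace = train_tokenizer(structures, config, heldout_eval=200)
    return params, trace


@pytest.fixture(scope="session")
def seq_table():
    return SequenceEmbeddingTable.default()


@pytest.fixture(scope="session")
def toy_dit(toy_corpus, toy_tokenizer, seq_table):
    """Diffusion model trained on embeddings of the planted corpus."""
    params, _ = toy_tokenizer
    corpus = []
    for structure, seq in toy_corpus[:100]:
        tokens = tokenize(structure, params)
        corpus.append(embed_protein(tokens, seq, params.codebook, seq_table))
    config = DenoiserConfig(seed=0, epochs=6, steps_per_epoch=60, batch_size=8)
    den, trace = train_denoiser(corpus, config)
    return den, trace, corpus


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
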