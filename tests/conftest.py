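import numpy as np
import pytest

from ddipair import synthetic, tokenizer as tk
from ddipair.model import ModelConfig, init_parameters


@pytest.fixture(scope="session")
def tiny_vocab():
    """Vocabulary over a 3-symbol corpus with one merge (C,C) -> CC."""
    return tk.train_bpe(["CCO", "CCN", "CCO", "CCN"], 1)


@pytest.fixture
def toy_config():
    return ModelConfig(
        vocab_size=12, embed_dim=3, lstm_hidden=2, mlp_hidden=3, mlp_out=2,
        mode="sharing", max_len=8,
    )


@pytest.fixture
def toy_params(toy_config):
    return init_parameters(toy_config, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 200-pair noiseless dataset with splits."""
    cfg = synthetic.GeneratorConfig(n_pairs=200, label_noise=0.0, seed=11)
    return synthetic.split_dataset(synthetic.generate_dataset(cfg), seed=11)


def random_seqs(rng, n, vocab_size, max_len):
    """Lexically arbitrary but structurally valid token sequences."""
    out = []
    for _ in range(n):
        k = int(rng.integers(1, max_len - 1))
        content = rng.integers(4, vocab_size, size=k).tolist()
        ids = [tk.BOS_ID, *content, tk.EOS_ID]
        ids += [tk.PAD_ID] * (max_len - len(ids))
        mask = [1] * (k + 2) + [0] * (max_len - k - 2)
        out.append(tk.TokenSequence(tuple(ids), tuple(mask)))
    return out
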