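import numpy as np
import pytest

from ttmpath import Hyperparams, corpus_from_token_lists


@pytest.fixture
def tiny_corpus():
    """1 process, 2 days (t=1,2), tokens [0,1] and [0]; |A|=2, |T|=2."""
    return corpus_from_token_lists([[[0, 1], [0]]], 2)


@pytest.fixture
def small_corpus():
    """2 processes x 2 days x 2 tokens over 3 activities, |T|=2."""
    return corpus_from_token_lists([[[0, 1], [2, 0]], [[1, 1], [2, 2]]], 3)


@pytest.fixture
def small_hyper():
    return Hyperparams(n_topics=2, alpha=1.0, delta=0.5, beta=0.5,
                       iterations=10, burn_in=2, seed=0)


def random_tiny_corpus(rng):
    """Random corpus with K<=3 scale: |A|<=5, |T|<=3, <=10 tokens."""
    n_act = int(rng.integers(2, 6))
    n_ts = int(rng.integers(1, 4))
    token_lists, ts_lists = [], []
    budget = int(rng.integers(3, 11))
    while budget > 0:
        n_days = int(rng.integers(1, n_ts + 1))
        ts = sorted(int(t) for t in
                    rng.choice(np.arange(1, n_ts + 1), n_days, replace=False))
        days = []
        for _ in range(n_days):
            n_tok = int(rng.integers(1, min(3, budget) + 1))
            budget -= n_tok
            days.append([int(a) for a in rng.integers(0, n_act, n_tok)])
            if budget <= 0:
                break
        ts = ts[: len(days)]
        token_lists.append(days)
        ts_lists.append(ts)
    return corpus_from_token_lists(token_lists, n_act, timestamps=ts_lists,
                                   n_timestamps=n_ts)
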