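"""Collapsed-Gibbs LDA over treatment days (timestamp-free baseline).

Identical to the temporal model with the timestamp block removed: each
treatment day is a document, each activity token a word.  Used both as the
comparison baseline and as the |T|=1 reduction oracle — when a corpus has a
single timestamp the temporal model's time factor is identically 1 and the
two samplers must produce bit-identical assignment trajectories under the
same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .corpus import Corpus, EmptyLogError
from .ttm import Hyperparams, _flatten

__all__ = [
    "LDAState",
    "LDAResult",
    "lda_initialize_state",
    "lda_gibbs_conditional",
    "lda_joint_log_prob",
    "lda_sweep",
    "lda_fit",
    "lda_estimate_theta",
    "lda_estimate_phi",
]


@dataclass
class LDAState:
    """Assignments plus the two LDA count structures n[d,k] and m[k,a]."""

    z: np.ndarray
    n: np.ndarray        # (n_days, K)
    m: np.ndarray        # (K, |A|)
    token_day: np.ndarray
    token_act: np.ndarray
    day_ptr: np.ndarray
    m_topic: np.ndarray  # (K,) cache of Σ_a m[k,·]

    @property
    def n_topics(self) -> int:
        return self.n.shape[1]

    def token_index(self, day: int, token_pos: int) -> int:
        return int(self.day_ptr[day]) + token_pos

    def recount(self) -> tuple[np.ndarray, np.ndarray]:
        n = np.zeros_like(self.n)
        m = np.zeros_like(self.m)
        np.add.at(n, (self.token_day, self.z), 1)
        np.add.at(m, (self.z, self.token_act), 1)
        return n, m

    def check_consistency(self) -> None:
        n, m = self.recount()
        if not (np.array_equal(n, self.n) and np.array_equal(m, self.m)):
            raise AssertionError("LDA counts inconsistent with assignments")


@dataclass(frozen=True)
class LDAResult:
    state: LDAState
    theta: np.ndarray    # (n_days, K)
    phi: np.ndarray      # (K, |A|)
    log_joint_trace: np.ndarray


def lda_initialize_state(corpus: Corpus, hyper: Hyperparams,
                         rng: np.random.Generator | None = None) -> LDAState:
    if corpus.n_tokens == 0:
        raise EmptyLogError("cannot initialize sampler on an empty corpus")
    if rng is None:
        rng = np.random.default_rng(hyper.seed)
    token_day, token_act, _day_ts, day_ptr = _flatten(corpus)
    K = hyper.n_topics
    z = rng.integers(0, K, size=token_day.shape[0], dtype=np.int64)
    n = np.zeros((day_ptr.shape[0] - 1, K), dtype=np.int64)
    m = np.zeros((K, corpus.n_activities), dtype=np.int64)
    np.add.at(n, (token_day, z), 1)
    np.add.at(m, (z, token_act), 1)
    return LDAState(z, n, m, token_day, token_act, day_ptr, m.sum(axis=1))


def lda_gibbs_conditional(state: LDAState, day: int, token_pos: int,
                          hyper: Hyperparams) -> np.ndarray:
    """P(z = k | z_{-i}, a): the "-i" counts exclude the current token."""
    i = state.token_index(day, token_pos)
    d = state.token_day[i]
    a = state.token_act[i]
    k0 = state.z[i]
    state.n[d, k0] -= 1
    state.m[k0, a] -= 1
    state.m_topic[k0] -= 1
    try:
        if state.n[d, k0] < 0 or state.m[k0, a] < 0:
            raise AssertionError("negative count after token exclusion")
        K = state.n_topics
        n_act = state.m.shape[1]
        nd = state.n[d].astype(np.float64)
        v = (nd + hyper.alpha) / (nd.sum() + K * hyper.alpha)
        v *= (state.m[:, a] + hyper.beta) / (state.m_topic + n_act * hyper.beta)
        v /= v.sum()
    finally:
        state.n[d, k0] += 1
        state.m[k0, a] += 1
        state.m_topic[k0] += 1
    return v


def lda_joint_log_prob(state: LDAState, hyper: Hyperparams) -> float:
    """Collapsed LDA joint ln P(z, a | α, β) up to the prior normalisers."""
    K = state.n_topics
    n_act = state.m.shape[1]
    lp = gammaln(state.n + hyper.alpha).sum() \
        - gammaln(state.n.sum(axis=1) + K * hyper.alpha).sum()
    lp += gammaln(state.m + hyper.beta).sum() \
        - gammaln(state.m_topic + n_act * hyper.beta).sum()
    return float(lp)


def lda_sweep(state: LDAState, hyper: Hyperparams,
              rng: np.random.Generator) -> LDAState:
    """One full sweep; consumes exactly one uniform per token."""
    uniforms = rng.random(state.z.shape[0])
    _kernels.lda_sweep_kernel(
        state.z, state.token_day, state.token_act,
        state.n, state.m, state.m_topic,
        hyper.alpha, hyper.beta, uniforms,
    )
    return state


def lda_estimate_theta(state: LDAState, hyper: Hyperparams) -> np.ndarray:
    K = state.n_topics
    return (state.n + hyper.alpha) / (
        state.n.sum(axis=1, keepdims=True) + K * hyper.alpha)


def lda_estimate_phi(state: LDAState, hyper: Hyperparams) -> np.ndarray:
    n_act = state.m.shape[1]
    return (state.m + hyper.beta) / (
        state.m_topic[:, None] + n_act * hyper.beta)


def lda_fit(corpus: Corpus, hyper: Hyperparams, *,
            trace: bool = True) -> LDAResult:
    """Random init + ``iterations`` sweeps; estimates from the final state.

    δ in ``hyper`` is ignored.  Final θ and ϕ use full counts (no token
    exclusion), mirroring the temporal model's estimator convention.
    """
    rng = np.random.default_rng(hyper.seed)
    state = lda_initialize_state(corpus, hyper, rng)
    lj = np.empty(hyper.iterations) if trace else np.empty(0)
    for it in range(hyper.iterations):
        lda_sweep(state, hyper, rng)
        if trace:
            lj[it] = lda_joint_log_prob(state, hyper)
    return LDAResult(state, lda_estimate_theta(state, hyper),
                     lda_estimate_phi(state, hyper), lj)
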