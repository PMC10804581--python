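"""Collapsed Gibbs sampler for the temporal topic model (TTM).

The model extends LDA over treatment days with an observed per-day
timestamp ``t`` (day index within the hospital stay).  Each activity token
``i`` of day ``d`` carries a latent treatment topic ``z_{d,i}``; the
generative structure couples three Dirichlet-multinomial blocks:

* θ_d  — topic mixture of day d            (prior α),
* φ_k  — timestamp distribution of topic k (prior δ),
* ϕ_{k,t} — activity distribution of topic k at timestamp t (prior β).

Collapsing θ, φ, ϕ leaves a sampler over the assignments ``z`` driven by
three count structures:

* ``n[d,k]``   — tokens of day d assigned to topic k,
* ``q[k,t]``   — tokens assigned to topic k whose day has timestamp t,
* ``m[k,t,a]`` — tokens of activity a assigned to topic k at timestamp t.

The full conditional for one token (its own assignment excluded from all
counts) is the product of the three smoothed ratios; the posterior point
estimates plug the final counts into the same ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .corpus import Corpus, EmptyLogError

__all__ = [
    "Hyperparams",
    "SamplerState",
    "Posterior",
    "FitResult",
    "initialize_state",
    "gibbs_conditional",
    "joint_log_prob",
    "sweep",
    "fit",
    "estimate_theta",
    "estimate_phi_time",
    "estimate_phi_act",
    "predictive_token_prob",
    "time_order",
]


@dataclass(frozen=True)
class Hyperparams:
    """Sampler configuration.

    Defaults follow the common treatment-log setting: symmetric priors
    α = 1.0 and β = 0.01 with 2000 Gibbs sweeps; the timestamp prior δ
    (which plain LDA lacks) defaults to 0.1.  ``burn_in`` only matters for
    the optional averaged posterior estimator and for diagnostics.
    """

    n_topics: int
    alpha: float = 1.0
    delta: float = 0.1
    beta: float = 0.01
    iterations: int = 2000
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if min(self.alpha, self.delta, self.beta) <= 0:
            raise ValueError("all Dirichlet priors must be strictly positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")

    @property
    def K(self) -> int:  # noqa: N802 - conventional symbol
        return self.n_topics


def _flatten(corpus: Corpus):
    """Flat token/day arrays for the samplers (timestamps made 0-based)."""
    days = corpus.days
    token_day = np.concatenate(
        [np.full(d.n_tokens, j, dtype=np.int64) for j, d in enumerate(days)]
    )
    token_act = np.concatenate(
        [np.asarray(d.tokens, dtype=np.int64) for d in days]
    )
    day_ts = np.asarray([d.timestamp - 1 for d in days], dtype=np.int64)
    day_ptr = np.zeros(len(days) + 1, dtype=np.int64)
    np.cumsum([d.n_tokens for d in days], out=day_ptr[1:])
    return token_day, token_act, day_ts, day_ptr


@dataclass
class SamplerState:
    """Token-level topic assignments plus the three sufficient-count arrays.

    Invariants (checked by :meth:`check_consistency`):
    Σ_k n[d,k] = N_d, Σ_a m[k,t,·] = q[k,t], Σ_t q[k,·] = Σ_d n[·,k], and
    all counts are reconstructible from ``z`` and the flattened corpus.
    """

    z: np.ndarray            # (n_tokens,) topic per token
    n: np.ndarray            # (n_days, K)
    q: np.ndarray            # (K, |T|)
    m: np.ndarray            # (K, |T|, |A|)
    token_day: np.ndarray
    token_act: np.ndarray
    day_ts: np.ndarray       # 0-based timestamp per day
    day_ptr: np.ndarray      # prefix offsets: day j's tokens are ptr[j]:ptr[j+1]
    q_topic: np.ndarray = field(default=None)  # (K,) cache of Σ_t q[k,·]

    def __post_init__(self) -> None:
        if self.q_topic is None:
            self.q_topic = self.q.sum(axis=1)

    @property
    def n_topics(self) -> int:
        return self.n.shape[1]

    def token_index(self, day: int, token_pos: int) -> int:
        return int(self.day_ptr[day]) + token_pos

    def recount(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Rebuild (n, q, m) from assignments alone."""
        K = self.n_topics
        n = np.zeros_like(self.n)
        q = np.zeros_like(self.q)
        m = np.zeros_like(self.m)
        t_of_token = self.day_ts[self.token_day]
        np.add.at(n, (self.token_day, self.z), 1)
        np.add.at(q, (self.z, t_of_token), 1)
        np.add.at(m, (self.z, t_of_token, self.token_act), 1)
        return n, q, m

    def check_consistency(self) -> None:
        """Raise if any count invariant is violated (bug trap)."""
        n, q, m = self.recount()
        if not (np.array_equal(n, self.n) and np.array_equal(q, self.q)
                and np.array_equal(m, self.m)):
            raise AssertionError("sampler counts inconsistent with assignments")
        if (self.n < 0).any() or (self.q < 0).any() or (self.m < 0).any():
            raise AssertionError("negative count in sampler state")
        if not np.array_equal(self.q_topic, self.q.sum(axis=1)):
            raise AssertionError("q_topic cache out of date")

    def copy(self) -> "SamplerState":
        return SamplerState(
            self.z.copy(), self.n.copy(), self.q.copy(), self.m.copy(),
            self.token_day, self.token_act, self.day_ts, self.day_ptr,
            self.q_topic.copy(),
        )


@dataclass(frozen=True)
class Posterior:
    """Smoothed point estimates of the three model distributions.

    theta:    (n_days, K)  day → topic
    phi_time: (K, |T|)     topic → timestamp
    phi_act:  (K, |T|, |A|) (topic, timestamp) → activity
    """

    theta: np.ndarray
    phi_time: np.ndarray
    phi_act: np.ndarray

    @property
    def n_topics(self) -> int:
        return self.theta.shape[1]

    @property
    def n_timestamps(self) -> int:
        return self.phi_time.shape[1]

    @property
    def n_activities(self) -> int:
        return self.phi_act.shape[2]


@dataclass(frozen=True)
class FitResult:
    state: SamplerState
    posterior: Posterior
    log_joint_trace: np.ndarray


def initialize_state(corpus: Corpus, hyper: Hyperparams,
                     rng: np.random.Generator | None = None) -> SamplerState:
    """Assign every token a uniform-random topic and tally the counts."""
    if corpus.n_tokens == 0:
        raise EmptyLogError("cannot initialize sampler on an empty corpus")
    if rng is None:
        rng = np.random.default_rng(hyper.seed)
    token_day, token_act, day_ts, day_ptr = _flatten(corpus)
    K = hyper.n_topics
    z = rng.integers(0, K, size=token_day.shape[0], dtype=np.int64)
    state = SamplerState(
        z=z,
        n=np.zeros((len(day_ts), K), dtype=np.int64),
        q=np.zeros((K, corpus.n_timestamps), dtype=np.int64),
        m=np.zeros((K, corpus.n_timestamps, corpus.n_activities), dtype=np.int64),
        token_day=token_day, token_act=token_act,
        day_ts=day_ts, day_ptr=day_ptr,
    )
    state.n, state.q, state.m = state.recount()
    state.q_topic = state.q.sum(axis=1)
    return state


def gibbs_conditional(state: SamplerState, day: int, token_pos: int,
                      hyper: Hyperparams) -> np.ndarray:
    """Full conditional P(z = k | everything else) for one token.

    The token's current assignment is removed from all three count
    structures before the three smoothed ratios are evaluated (and restored
    afterwards); this is the reference implementation the jitted sweep
    kernel is tested against.
    """
    i = state.token_index(day, token_pos)
    d = state.token_day[i]
    t = state.day_ts[d]
    a = state.token_act[i]
    k0 = state.z[i]
    state.n[d, k0] -= 1
    state.q[k0, t] -= 1
    state.q_topic[k0] -= 1
    state.m[k0, t, a] -= 1
    try:
        if state.n[d, k0] < 0 or state.q[k0, t] < 0 or state.m[k0, t, a] < 0:
            raise AssertionError("negative count after token exclusion")
        v = _conditional_from_counts(state, d, t, a, hyper)
    finally:
        state.n[d, k0] += 1
        state.q[k0, t] += 1
        state.q_topic[k0] += 1
        state.m[k0, t, a] += 1
    return v


def _conditional_from_counts(state: SamplerState, d: int, t: int, a: int,
                             hyper: Hyperparams) -> np.ndarray:
    K = state.n_topics
    n_ts = state.q.shape[1]
    n_act = state.m.shape[2]
    nd = state.n[d].astype(np.float64)
    v = (nd + hyper.alpha) / (nd.sum() + K * hyper.alpha)
    v *= (state.q[:, t] + hyper.delta) / (state.q_topic + n_ts * hyper.delta)
    v *= (state.m[:, t, a] + hyper.beta) / (state.q[:, t] + n_act * hyper.beta)
    return v / v.sum()


def joint_log_prob(state: SamplerState, hyper: Hyperparams) -> float:
    """Log of the collapsed joint P(z, t, a | α, δ, β), up to a constant.

    Sum of the three Dirichlet-multinomial blocks,

        Σ_d [Σ_k lnΓ(n_dk+α) − lnΓ(N_d+Kα)]
      + Σ_k [Σ_t lnΓ(q_kt+δ) − lnΓ(q_k·+|T|δ)]
      + Σ_k Σ_t [Σ_a lnΓ(m_kta+β) − lnΓ(q_kt+|A|β)],

    with the state-independent prior normalisers omitted, so differences
    between assignment states are exact.
    """
    K = state.n_topics
    n_ts = state.q.shape[1]
    n_act = state.m.shape[2]
    a, d, b = hyper.alpha, hyper.delta, hyper.beta
    lp = gammaln(state.n + a).sum() \
        - gammaln(state.n.sum(axis=1) + K * a).sum()
    lp += gammaln(state.q + d).sum() \
        - gammaln(state.q_topic + n_ts * d).sum()
    lp += gammaln(state.m + b).sum() \
        - gammaln(state.q + n_act * b).sum()
    return float(lp)


def sweep(state: SamplerState, hyper: Hyperparams,
          rng: np.random.Generator) -> SamplerState:
    """Resample every token once, in fixed corpus order, in place.

    Consumes exactly one uniform draw per token from ``rng``, so runs with
    the same seed are bit-reproducible.  Returns ``state`` for chaining.
    """
    uniforms = rng.random(state.z.shape[0])
    _kernels.ttm_sweep_kernel(
        state.z, state.token_day, state.token_act, state.day_ts,
        state.n, state.q, state.q_topic, state.m,
        hyper.alpha, hyper.delta, hyper.beta, uniforms,
    )
    return state


def estimate_theta(state: SamplerState, hyper: Hyperparams) -> np.ndarray:
    """θ_{d,k} = (n_dk + α) / (N_d + Kα), from full counts."""
    K = state.n_topics
    return (state.n + hyper.alpha) / (
        state.n.sum(axis=1, keepdims=True) + K * hyper.alpha)


def estimate_phi_time(state: SamplerState, hyper: Hyperparams) -> np.ndarray:
    """φ_{k,t} = (q_kt + δ) / (q_k· + |T|δ), from full counts."""
    n_ts = state.q.shape[1]
    return (state.q + hyper.delta) / (
        state.q_topic[:, None] + n_ts * hyper.delta)


def estimate_phi_act(state: SamplerState, hyper: Hyperparams) -> np.ndarray:
    """ϕ_{k,t,a} = (m_kta + β) / (q_kt + |A|β), from full counts."""
    n_act = state.m.shape[2]
    return (state.m + hyper.beta) / (
        state.q[:, :, None] + n_act * hyper.beta)


def _posterior(state: SamplerState, hyper: Hyperparams) -> Posterior:
    return Posterior(
        estimate_theta(state, hyper),
        estimate_phi_time(state, hyper),
        estimate_phi_act(state, hyper),
    )


def fit(corpus: Corpus, hyper: Hyperparams, *,
        average_posterior: bool = False, thin: int = 10,
        trace: bool = True,
        callback: Callable[[int, SamplerState], None] | None = None) -> FitResult:
    """Run the full sampler: random init, ``iterations`` sweeps, estimates.

    The posterior is computed from the final state by default; with
    ``average_posterior=True`` the smoothed estimates are averaged over
    every ``thin``-th post-burn-in state instead (lower variance, but
    vulnerable to label switching on poorly separated corpora — off by
    default).  ``trace=False`` skips the per-sweep log-joint evaluation.
    """
    rng = np.random.default_rng(hyper.seed)
    state = initialize_state(corpus, hyper, rng)
    lj = np.empty(hyper.iterations) if trace else None
    acc = None
    n_acc = 0
    for it in range(hyper.iterations):
        sweep(state, hyper, rng)
        if trace:
            lj[it] = joint_log_prob(state, hyper)
        if average_posterior and it >= hyper.burn_in \
                and (it - hyper.burn_in) % thin == 0:
            post = _posterior(state, hyper)
            if acc is None:
                acc = [post.theta, post.phi_time, post.phi_act]
            else:
                acc[0] = acc[0] + post.theta
                acc[1] = acc[1] + post.phi_time
                acc[2] = acc[2] + post.phi_act
            n_acc += 1
        if callback is not None:
            callback(it, state)
    if average_posterior:
        posterior = Posterior(acc[0] / n_acc, acc[1] / n_acc, acc[2] / n_acc)
    else:
        posterior = _posterior(state, hyper)
    return FitResult(state, posterior,
                     lj if trace else np.empty(0))


def predictive_token_prob(posterior: Posterior, day: int, timestamp: int,
                          activity: int) -> float:
    """Predictive probability of one activity: Σ_k θ_{d,k} · ϕ_{k,t,a}.

    ``timestamp`` is 1-based (as in the corpus); ``day`` indexes the flat
    day list the posterior was fitted on.
    """
    t = timestamp - 1
    if not 0 <= t < posterior.n_timestamps:
        raise ValueError(f"timestamp {timestamp} outside 1..{posterior.n_timestamps}")
    if not 0 <= activity < posterior.n_activities:
        raise ValueError(f"activity id {activity} outside vocabulary")
    return float(posterior.theta[day] @ posterior.phi_act[:, t, activity])


def time_order(posterior: Posterior) -> np.ndarray:
    """Topic permutation sorted by φ-mean timestamp (for reporting).

    The sampler's topic labels are arbitrary; for human-facing output
    topics are presented in order of their mean timestamp
    Σ_t t·φ_{k,t} (1-based t), so "topic 1" is the earliest-stay topic.
    """
    t = np.arange(1, posterior.n_timestamps + 1)
    mean_ts = posterior.phi_time @ t
    return np.argsort(mean_ts, kind="stable")
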