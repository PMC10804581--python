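"""Numba-jitted Gibbs-sweep inner loops.

The kernels mutate count arrays in place and draw each token's topic by
inverse-CDF sampling from one pre-drawn uniform per token, so a sweep
consumes exactly ``n_tokens`` uniforms and is bit-reproducible given the
uniform stream.  The pure-Python conditional in :mod:`ttmpath.ttm` is the
reference implementation; tests assert the kernels agree with it.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ttm_sweep_kernel(z, token_day, token_act, day_ts, n, q, q_topic, m,
                     alpha, delta, beta, uniforms):
    """One Gibbs sweep of the temporal topic model.

    For each token (visited in fixed corpus order) the current assignment is
    removed from n[d,k], q[k,t], m[k,t,a], the collapsed conditional

        p(k) ∝ (n[d,k]+α) · (q[k,t]+δ)/(Σ_t q[k,t]+|T|δ)
                          · (m[k,t,a]+β)/(Σ_a m[k,t,a]+|A|β)

    is evaluated (the day-level denominator is constant over k and dropped;
    Σ_a m[k,t,·] equals q[k,t] by construction), and a new topic is drawn.
    ``q_topic[k]`` caches Σ_t q[k,t].
    """
    K = n.shape[1]
    n_ts = q.shape[1]
    n_act = m.shape[2]
    cum = np.empty(K, dtype=np.float64)
    for i in range(z.shape[0]):
        d = token_day[i]
        t = day_ts[d]
        a = token_act[i]
        k0 = z[i]
        n[d, k0] -= 1
        q[k0, t] -= 1
        q_topic[k0] -= 1
        m[k0, t, a] -= 1
        total = 0.0
        for k in range(K):
            p = (n[d, k] + alpha) \
                * (q[k, t] + delta) / (q_topic[k] + n_ts * delta) \
                * (m[k, t, a] + beta) / (q[k, t] + n_act * beta)
            total += p
            cum[k] = total
        r = uniforms[i] * total
        k1 = 0
        while k1 < K - 1 and cum[k1] <= r:
            k1 += 1
        z[i] = k1
        n[d, k1] += 1
        q[k1, t] += 1
        q_topic[k1] += 1
        m[k1, t, a] += 1


@njit(cache=True)
def lda_sweep_kernel(z, token_day, token_act, n, m, m_topic,
                     alpha, beta, uniforms):
    """One collapsed-Gibbs sweep of the timestamp-free (plain LDA) model.

    p(k) ∝ (n[d,k]+α) · (m[k,a]+β)/(Σ_a m[k,·]+|A|β);  ``m_topic[k]``
    caches Σ_a m[k,a].
    """
    K = n.shape[1]
    n_act = m.shape[1]
    cum = np.empty(K, dtype=np.float64)
    for i in range(z.shape[0]):
        d = token_day[i]
        a = token_act[i]
        k0 = z[i]
        n[d, k0] -= 1
        m[k0, a] -= 1
        m_topic[k0] -= 1
        total = 0.0
        for k in range(K):
            p = (n[d, k] + alpha) * (m[k, a] + beta) / (m_topic[k] + n_act * beta)
            total += p
            cum[k] = total
        r = uniforms[i] * total
        k1 = 0
        while k1 < K - 1 and cum[k1] <= r:
            k1 += 1
        z[i] = k1
        n[d, k1] += 1
        m[k1, a] += 1
        m_topic[k1] += 1


@njit(cache=True)
def ttm_run_with_histogram(z, token_day, token_act, day_ts, n, q, q_topic, m,
                           alpha, delta, beta, uniforms, hist):
    """Run ``uniforms.shape[0]`` sweeps, histogramming the full assignment.

    After each sweep the assignment vector is encoded as an integer in base
    K (token 0 least significant) and the corresponding ``hist`` bin is
    incremented.  Used to compare the sampler's stationary distribution with
    the exactly enumerated posterior on tiny corpora.
    """
    K = n.shape[1]
    for s in range(uniforms.shape[0]):
        ttm_sweep_kernel(z, token_day, token_act, day_ts, n, q, q_topic, m,
                         alpha, delta, beta, uniforms[s])
        code = 0
        mult = 1
        for i in range(z.shape[0]):
            code += z[i] * mult
            mult *= K
        hist[code] += 1
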