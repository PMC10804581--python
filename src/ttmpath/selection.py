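"""Perplexity and topic-number selection.

Perplexity is the exponentiated negative mean per-token predictive
log-probability over all treatment days,

    exp( − Σ_tokens ln p(a | D) / Σ_days N_d ),

with p(a | D) = Σ_k θ_{d,k} ϕ_{k,t_d,a}.  Lower is better; on training
data it decreases as K grows, so K is chosen at the first knee of the
curve — operationalised as the interior grid point with the largest
positive second difference (discrete maximum curvature).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus
from .ttm import Hyperparams, Posterior, fit, initialize_state, sweep

__all__ = [
    "PerplexityCurve",
    "SelectionResult",
    "perplexity",
    "select_topic_number",
    "fold_in_theta",
]


@dataclass(frozen=True)
class PerplexityCurve:
    """Mean (and spread, when replicated) perplexity per candidate K."""

    k_values: tuple[int, ...]
    perplexities: tuple[float, ...]
    sd: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.k_values) != len(self.perplexities):
            raise ValueError("k_values and perplexities length mismatch")
        if any(b <= a for a, b in zip(self.k_values, self.k_values[1:])):
            raise ValueError("k_values must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        data = {"K": self.k_values, "perplexity": self.perplexities}
        if self.sd:
            data["sd"] = self.sd
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SelectionResult:
    k_star: int
    curve: PerplexityCurve
    flagged: bool  # True when no interior point had curvature above tolerance


def _log_predictive(posterior: Posterior, corpus: Corpus) -> float:
    """Σ_tokens ln p(a|D), vectorised over days."""
    total = 0.0
    for d, day in enumerate(corpus.days):
        p_act = posterior.theta[d] @ posterior.phi_act[:, day.timestamp - 1, :]
        p_tok = p_act[np.asarray(day.tokens)]
        if (p_tok <= 0).any():
            raise ValueError("zero predictive probability (priors must be > 0)")
        total += float(np.log(p_tok).sum())
    return total


def perplexity(posterior: Posterior, corpus: Corpus) -> float:
    """Training-corpus perplexity of a fitted posterior; >= 1."""
    if posterior.n_activities != corpus.n_activities:
        raise ValueError("posterior and corpus vocabulary sizes differ")
    if posterior.n_timestamps != corpus.n_timestamps:
        raise ValueError("posterior and corpus timestamp universes differ")
    return float(np.exp(-_log_predictive(posterior, corpus) / corpus.n_tokens))


def first_inflection(curve: PerplexityCurve, tolerance: float = 1e-9
                     ) -> tuple[int, bool]:
    """Interior K maximising Δ²(K) = p(K−1) − 2p(K) + p(K+1).

    Returns (K*, flagged).  If no interior second difference exceeds
    ``tolerance`` (e.g. an exactly linear curve), K* falls back to the
    smallest grid value and the flag is set.  Ties resolve to the smallest K.
    """
    p = np.asarray(curve.perplexities, dtype=float)
    if p.size < 3:
        raise ValueError("need >= 3 grid points for inflection detection")
    d2 = p[:-2] - 2.0 * p[1:-1] + p[2:]
    if (d2 > tolerance).any():
        return curve.k_values[1 + int(np.argmax(d2))], False
    return curve.k_values[0], True


def select_topic_number(
    corpus: Corpus,
    k_grid: Sequence[int],
    hyper_template: Hyperparams,
    *,
    seeds: Sequence[int] = (0,),
    tolerance: float = 1e-9,
) -> SelectionResult:
    """Fit one model per (K, seed), build the perplexity curve, pick K*.

    ``hyper_template`` supplies everything but ``n_topics`` and ``seed``.
    Perplexity is averaged over the replicate seeds before the knee rule is
    applied.
    """
    k_grid = tuple(int(k) for k in k_grid)
    if len(k_grid) < 3:
        raise ValueError("k_grid must contain at least 3 values")
    means, sds = [], []
    for k in k_grid:
        vals = []
        for s in seeds:
            hyper = replace(hyper_template, n_topics=k, seed=int(s))
            result = fit(corpus, hyper, trace=False)
            vals.append(perplexity(result.posterior, corpus))
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals)))
    curve = PerplexityCurve(k_grid, tuple(means), tuple(sds))
    k_star, flagged = first_inflection(curve, tolerance)
    return SelectionResult(k_star, curve, flagged)


def fold_in_theta(posterior: Posterior, corpus: Corpus, hyper: Hyperparams,
                  *, sweeps: int = 50) -> np.ndarray:
    """Estimate θ for unseen days with φ and ϕ frozen (held-out fold-in).

    Runs a short Gibbs chain over the new days' tokens using
    p(k) ∝ (n[d,k]+α) · φ_{k,t} · ϕ_{k,t,a}; returns the (n_days, K) θ
    estimate.  Used for held-out perplexity.
    """
    rng = np.random.default_rng(hyper.seed)
    K = posterior.n_topics
    theta = np.empty((corpus.n_days, K))
    for d, day in enumerate(corpus.days):
        t = day.timestamp - 1
        acts = np.asarray(day.tokens)
        w = posterior.phi_time[:, t][:, None] * posterior.phi_act[:, t, acts]
        z = rng.integers(0, K, size=acts.shape[0])
        nd = np.bincount(z, minlength=K)
        for _ in range(sweeps):
            for i in range(acts.shape[0]):
                nd[z[i]] -= 1
                p = (nd + hyper.alpha) * w[:, i]
                p /= p.sum()
                z[i] = rng.choice(K, p=p)
                nd[z[i]] += 1
        theta[d] = (nd + hyper.alpha) / (nd.sum() + K * hyper.alpha)
    return theta
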