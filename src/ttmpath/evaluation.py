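"""Topic-quality evaluation: top-activity rankings and NKQM@N.

Domain experts score the top-ranked activities of each discovered topic as
very relevant (2), relevant (1) or not relevant (0); NKQM@N is the mean
over topics of the discounted cumulative score of the top N activities,
normalised by the ideal (all-2) discounted sum — an NDCG variant, hence
values in [0, 1], higher is better.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ttm import Posterior

__all__ = [
    "ScoreTable",
    "top_activities",
    "topic_rankings",
    "nkqm",
    "majority_vote",
    "read_score_table",
    "write_score_table",
    "nkqm_report",
]

VALID_SCORES = frozenset({0, 1, 2})


@dataclass(frozen=True)
class ScoreTable:
    """Per-topic ordered relevance scores: ``scores[k][j]`` is rank j+1."""

    scores: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        for k, row in enumerate(self.scores):
            bad = set(row) - VALID_SCORES
            if bad:
                raise ValueError(f"topic {k}: scores {sorted(bad)} outside {{0,1,2}}")

    @property
    def n_topics(self) -> int:
        return len(self.scores)

    def min_depth(self) -> int:
        return min(len(r) for r in self.scores)


def time_marginal_activity_dist(posterior: Posterior) -> np.ndarray:
    """ϕ̄_k(a) = Σ_t φ_{k,t} · ϕ_{k,t,a}: each topic's overall activity mix.

    Rows are probability distributions (sum to 1)."""
    return np.einsum("kt,kta->ka", posterior.phi_time, posterior.phi_act)


def top_activities(posterior: Posterior, topic: int, n: int
                   ) -> list[tuple[int, float]]:
    """Top-``n`` activities of one topic by time-marginal probability.

    Ties break toward the smaller activity id; returns min(n, |A|) pairs
    of (activity id, marginal probability), probabilities non-increasing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= topic < posterior.n_topics:
        raise ValueError(f"topic {topic} outside 0..{posterior.n_topics - 1}")
    marg = time_marginal_activity_dist(posterior)[topic]
    # stable sort on descending weight preserves ascending-id tie order
    order = np.argsort(-marg, kind="stable")[: min(n, marg.shape[0])]
    return [(int(a), float(marg[a])) for a in order]


def topic_rankings(posterior: Posterior, n: int, *,
                   timestamp: int | None = None) -> list[list[tuple[int, float]]]:
    """Top-``n`` activities for every topic.

    With ``timestamp`` given (1-based), ranks by the per-timestamp slice
    ϕ_{k,t,·} instead of the time marginal.
    """
    if timestamp is None:
        return [top_activities(posterior, k, n)
                for k in range(posterior.n_topics)]
    t = timestamp - 1
    out = []
    for k in range(posterior.n_topics):
        row = posterior.phi_act[k, t]
        order = np.argsort(-row, kind="stable")[: min(n, row.shape[0])]
        out.append([(int(a), float(row[a])) for a in order])
    return out


def nkqm(table: ScoreTable, n: int, *, log_base: float = 2.0) -> float:
    """NKQM@N ∈ [0, 1]: mean over topics of DCG@N / ideal DCG@N.

    DCG@N = Σ_{j=1..N} score(j) / log(j+1); the normaliser Z_N is the
    all-2 ideal ranking's DCG.  The log base (default 2, the NDCG
    convention) cancels between numerator and Z_N only partially, so it is
    configurable but rarely matters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if table.min_depth() < n:
        raise ValueError(
            f"requested N={n} but some topic has only {table.min_depth()} scores")
    discount = np.log(np.arange(2, n + 2)) / np.log(log_base)
    z_n = float((2.0 / discount).sum())
    per_topic = [
        float((np.asarray(row[:n]) / discount).sum()) / z_n
        for row in table.scores
    ]
    return float(np.mean(per_topic))


def majority_vote(rater1: Sequence[int], rater2: Sequence[int],
                  rater3: Sequence[int]) -> tuple[int, ...]:
    """Combine three raters' scores cell-wise by majority.

    A three-way split (one each of 0, 1, 2) resolves to the median, 1.
    """
    if not (len(rater1) == len(rater2) == len(rater3)):
        raise ValueError("rater score lists are misaligned")
    out = []
    for triple in zip(rater1, rater2, rater3):
        bad = set(triple) - VALID_SCORES
        if bad:
            raise ValueError(f"scores {sorted(bad)} outside {{0,1,2}}")
        counts = Counter(triple)
        score, freq = counts.most_common(1)[0]
        out.append(int(score) if freq > 1 else 1)
    return tuple(out)


def read_score_table(source) -> ScoreTable:
    """Read a score table CSV: columns topic, rank, then either ``score``
    or ``rater1, rater2, rater3`` (combined by majority vote)."""
    df = pd.read_csv(source)
    required = {"topic", "rank"}
    if not required <= set(df.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    df = df.sort_values(["topic", "rank"])
    rows = []
    for _, grp in df.groupby("topic", sort=True):
        if "score" in df.columns:
            rows.append(tuple(int(s) for s in grp["score"]))
        elif {"rater1", "rater2", "rater3"} <= set(df.columns):
            rows.append(majority_vote(
                grp["rater1"].tolist(), grp["rater2"].tolist(),
                grp["rater3"].tolist()))
        else:
            raise ValueError("need a 'score' column or rater1..rater3 columns")
    return ScoreTable(tuple(rows))


def write_score_table(table: ScoreTable, sink) -> None:
    rows = [
        {"topic": k, "rank": j + 1, "score": s}
        for k, row in enumerate(table.scores)
        for j, s in enumerate(row)
    ]
    pd.DataFrame(rows).to_csv(sink, index=False)


def nkqm_report(table: ScoreTable, n_values: Sequence[int] = (5, 10, 20),
                *, log_base: float = 2.0) -> pd.DataFrame:
    """NKQM at several cut-offs as a one-row frame (columns ``NKQM@N``)."""
    return pd.DataFrame(
        [{f"NKQM@{n}": nkqm(table, n, log_base=log_base) for n in n_values}]
    )
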