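"""Clinical-pathway extraction from a fitted posterior.

A clinical pathway is summarised as, for each hospital day t up to a
horizon, the probability of each treatment topic being active that day —
a list of (topic, t, p) triples per day.  The day-t topic probabilities
are the renormalised mean of θ over all treatment days observed at
timestamp t; topics are presented in order of their mean timestamp, so
the pathway reads admission → treatment → discharge left to right.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Corpus
from .ttm import Posterior, time_order

__all__ = [
    "ClinicalPathway",
    "extract_pathway",
    "pathway_table",
    "dominant_topic_sequence",
    "plot_pathway",
]


@dataclass(frozen=True)
class ClinicalPathway:
    """Per-day topic probabilities over a horizon of hospital days.

    ``probs[t-1, j]`` is the probability of presented topic j on day t;
    ``source_topics[j]`` maps presented topic j back to the sampler's raw
    topic label.  ``missing[t-1]`` marks days with no observed data (their
    row is uniform).
    """

    horizon: int
    probs: np.ndarray            # (horizon, K), rows sum to 1
    source_topics: tuple[int, ...]
    missing: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.probs.shape != (self.horizon, len(self.source_topics)):
            raise ValueError("probs shape inconsistent with horizon/topics")

    @property
    def n_topics(self) -> int:
        return len(self.source_topics)

    def entries(self) -> list[list[tuple[int, int, float]]]:
        """The triple form: for each day t, K triples (topic, t, p)."""
        return [
            [(j, t + 1, float(self.probs[t, j])) for j in range(self.n_topics)]
            for t in range(self.horizon)
        ]


def extract_pathway(posterior: Posterior, corpus: Corpus,
                    horizon: int | str = "avg_los", *,
                    mode: str = "theta", order_topics: bool = True
                    ) -> ClinicalPathway:
    """Build the pathway from a fitted posterior.

    Parameters
    ----------
    horizon:
        ``"avg_los"`` (default) → ceil of the mean length of stay;
        ``"max_los"`` → the full timestamp universe; or an explicit int.
        Days beyond the horizon are excluded.
    mode:
        ``"theta"`` (default): day-t probabilities are the renormalised
        mean of θ over days observed at t.  ``"phi_time"``: the posterior
        over topics given t implied by φ (∝ φ_{k,t}, uniform topic prior)
        — an alternative view that ignores per-day variation.
    order_topics:
        Present topics sorted by φ-mean timestamp (deterministic column
        order); raw sampler labels are kept in ``source_topics``.
    """
    if horizon == "avg_los":
        h = math.ceil(corpus.mean_length_of_stay)
    elif horizon == "max_los":
        h = corpus.n_timestamps
    else:
        h = int(horizon)
    if h < 1:
        raise ValueError("horizon must be >= 1")
    h = min(h, corpus.n_timestamps)
    K = posterior.n_topics

    if mode == "theta":
        sums = np.zeros((h, K))
        counts = np.zeros(h, dtype=np.int64)
        for d, day in enumerate(corpus.days):
            t = day.timestamp - 1
            if t < h:
                sums[t] += posterior.theta[d]
                counts[t] += 1
        missing = counts == 0
        if missing.any():
            warnings.warn(
                f"no observed treatment days at timestamp(s) "
                f"{[int(t) + 1 for t in np.flatnonzero(missing)]}; "
                "using a uniform topic distribution there",
                stacklevel=2,
            )
            sums[missing] = 1.0
            counts[missing] = K
        probs = sums / counts[:, None]
    elif mode == "phi_time":
        probs = posterior.phi_time[:, :h].T.copy()
        missing = np.zeros(h, dtype=bool)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    probs /= probs.sum(axis=1, keepdims=True)

    order = time_order(posterior) if order_topics else np.arange(K)
    return ClinicalPathway(
        horizon=h,
        probs=probs[:, order],
        source_topics=tuple(int(k) for k in order),
        missing=tuple(bool(b) for b in missing),
    )


def pathway_table(cp: ClinicalPathway) -> pd.DataFrame:
    """The pathway as a (horizon × K) table, one row per hospital day."""
    return pd.DataFrame(
        cp.probs,
        index=pd.Index(range(1, cp.horizon + 1), name="day"),
        columns=[f"topic_{j}" for j in range(cp.n_topics)],
    )


def dominant_topic_sequence(cp: ClinicalPathway) -> list[int]:
    """Most probable presented topic per day; ties go to the lower label."""
    return [int(j) for j in np.argmax(cp.probs, axis=1)]


def plot_pathway(cp: ClinicalPathway, path=None):
    """Stacked-area chart of per-day topic probabilities (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    days = np.arange(1, cp.horizon + 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.stackplot(days, cp.probs.T,
                 labels=[f"topic {j}" for j in range(cp.n_topics)])
    ax.set_xlabel("hospital day")
    ax.set_ylabel("topic probability")
    ax.set_xlim(1, cp.horizon)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize="small")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
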