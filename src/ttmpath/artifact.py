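"""Model artifact persistence: one versioned JSON file per fitted model.

The artifact holds everything needed to reproduce downstream analyses
without the corpus: hyperparameters, vocabulary, |T|, the posterior
arrays, final assignments and the log-joint trace.  Floats survive the
round trip exactly (JSON shortest-repr).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .corpus import ActivityVocabulary
from .lda import LDAResult
from .ttm import FitResult, Hyperparams, Posterior

__all__ = ["ModelArtifact", "save_model", "load_model"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ModelArtifact:
    model_type: str                  # "ttm" | "lda"
    hyper: Hyperparams
    vocabulary: ActivityVocabulary
    n_timestamps: int
    posterior: Posterior             # LDA: phi broadcast over a length-1 t axis? no — see load
    assignments: np.ndarray
    log_joint_trace: np.ndarray
    theta: np.ndarray
    phi_time: np.ndarray | None      # None for LDA
    phi_act: np.ndarray              # (K,T,A) for ttm, (K,A) for lda


def save_model(path, result: FitResult | LDAResult, hyper: Hyperparams,
               vocabulary: ActivityVocabulary, n_timestamps: int) -> None:
    if isinstance(result, FitResult):
        payload = {
            "model_type": "ttm",
            "theta": result.posterior.theta.tolist(),
            "phi_time": result.posterior.phi_time.tolist(),
            "phi_act": result.posterior.phi_act.tolist(),
            "assignments": result.state.z.tolist(),
            "log_joint_trace": result.log_joint_trace.tolist(),
        }
    elif isinstance(result, LDAResult):
        payload = {
            "model_type": "lda",
            "theta": result.theta.tolist(),
            "phi_time": None,
            "phi_act": result.phi.tolist(),
            "assignments": result.state.z.tolist(),
            "log_joint_trace": result.log_joint_trace.tolist(),
        }
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}")
    payload.update(
        schema_version=SCHEMA_VERSION,
        hyperparams=asdict(hyper),
        vocabulary=list(vocabulary.codes),
        n_timestamps=n_timestamps,
    )
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path) -> ModelArtifact:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported artifact schema version {version!r}")
    hyper = Hyperparams(**data["hyperparams"])
    theta = np.asarray(data["theta"])
    phi_act = np.asarray(data["phi_act"])
    phi_time = (None if data["phi_time"] is None
                else np.asarray(data["phi_time"]))
    if data["model_type"] == "ttm":
        posterior = Posterior(theta, phi_time, phi_act)
    else:
        # present LDA as a degenerate one-timestamp posterior for code that
        # expects the temporal layout
        posterior = Posterior(theta, np.ones((theta.shape[1], 1)),
                              phi_act[:, None, :])
    return ModelArtifact(
        model_type=data["model_type"],
        hyper=hyper,
        vocabulary=ActivityVocabulary(tuple(data["vocabulary"])),
        n_timestamps=int(data["n_timestamps"]),
        posterior=posterior,
        assignments=np.asarray(data["assignments"], dtype=np.int64),
        log_joint_trace=np.asarray(data["log_joint_trace"]),
        theta=theta,
        phi_time=phi_time,
        phi_act=phi_act,
    )
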