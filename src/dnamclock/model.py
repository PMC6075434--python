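"""Clock model container and (de)serialization.

A fitted clock is an intercept plus a sparse map of probe weights on the
calibrated age scale, together with the training mean beta of each
weighted probe (used to impute missing probes at prediction time) and the
age transform the clock was trained against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from dnamclock.transform import AgeTransform

__all__ = ["ClockModel", "read_model", "write_model"]


@dataclass
class ClockModel:
    """Sparse linear DNAm-age estimator on the calibrated age scale.

    Attributes
    ----------
    intercept
        Intercept in transformed-age units.
    weights
        Map probe_id -> coefficient (transformed-age units per unit beta).
        Sparse: candidate probes shrunk to exactly zero are omitted.
    probe_means
        Map probe_id -> training mean beta, for imputation.  Every weighted
        probe must have a stored mean.
    transform
        The :class:`AgeTransform` used to calibrate the training target.
    alpha
        Elastic-net mixing parameter used in training (1 = lasso).
    lam
        Selected penalty strength.
    meta
        Free-form training metadata (sample count, seed, CV curve, ...).
    """

    intercept: float
    weights: dict[str, float] = field(default_factory=dict)
    probe_means: dict[str, float] = field(default_factory=dict)
    transform: AgeTransform = field(default_factory=AgeTransform)
    alpha: float = 0.5
    lam: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # Partial models (bare coefficient files) carry no means at all;
        # once any mean is stored, every weighted probe must have one.
        if self.probe_means:
            missing = [p for p in self.weights if p not in self.probe_means]
            if missing:
                raise ValueError(
                    f"every weighted probe needs a stored probe_mean; missing: {missing[:5]}"
                )

    @property
    def n_probes(self) -> int:
        return len(self.weights)


def write_model(model: ClockModel, path) -> None:
    """Serialize a full clock model (weights, means, transform, meta) to JSON."""
    payload = {
        "intercept": model.intercept,
        "weights": model.weights,
        "probe_means": model.probe_means,
        "adult_age": model.transform.adult_age,
        "alpha": model.alpha,
        "lambda": model.lam,
        "meta": model.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_model(path) -> ClockModel:
    """Load a clock model written by :func:`write_model`."""
    payload = json.loads(Path(path).read_text())
    return ClockModel(
        intercept=float(payload["intercept"]),
        weights={k: float(v) for k, v in payload["weights"].items()},
        probe_means={k: float(v) for k, v in payload["probe_means"].items()},
        transform=AgeTransform(float(payload.get("adult_age", 20.0))),
        alpha=float(payload.get("alpha", 0.5)),
        lam=None if payload.get("lambda") is None else float(payload["lambda"]),
        meta=payload.get("meta", {}),
    )
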