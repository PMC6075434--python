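"""Calibrated age transform.

Methylation of clock CpGs changes far faster in childhood than in adult
life, so chronological age is a poor linear target for a clock regression.
The standard remedy in the Illumina-clock lineage is a piecewise
log-linear calibration anchored at an adult age ``A`` (default 20 years):

    F(x) = log((x + 1) / (A + 1))        for x <= A
    F(x) = (x - A) / (A + 1)             for x >  A

``F`` is strictly increasing, continuous, C1 at the anchor (both one-sided
derivatives equal ``1/(A+1)``), zero at ``x = A``, and defined for
``x > -1`` so that gestational offsets expressed as small negative ages
(cord blood) remain in-domain.  Clocks are trained on ``F(age)`` and
predictions are mapped back to years with the exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgeTransform", "transform_age", "inverse_transform_age"]


@dataclass(frozen=True)
class AgeTransform:
    """Piecewise log-linear calibration between years and the clock scale.

    Parameters
    ----------
    adult_age
        Anchor age in years (> 0) at which the transform switches from
        logarithmic to linear and takes the value 0.
    """

    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.adult_age) or self.adult_age <= 0:
            raise ValueError(f"adult_age must be finite and > 0, got {self.adult_age}")

    def __call__(self, age):
        return transform_age(age, self)

    def inverse(self, y):
        return inverse_transform_age(y, self)


def transform_age(age, t: AgeTransform | None = None):
    """Map chronological age (years) to the calibrated clock scale.

    Accepts scalars or array-likes; ages must be > -1 (the log domain).
    """
    t = t or AgeTransform()
    x = np.asarray(age, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= -1):
        raise ValueError("age must be finite and > -1 (years)")
    a1 = t.adult_age + 1.0
    out = np.where(x <= t.adult_age, np.log((x + 1.0) / a1), (x - t.adult_age) / a1)
    return out.item() if np.isscalar(age) or out.ndim == 0 else out


def inverse_transform_age(y, t: AgeTransform | None = None):
    """Map a calibrated-scale value back to age in years (exact inverse)."""
    t = t or AgeTransform()
    z = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("transformed age must be finite")
    a1 = t.adult_age + 1.0
    out = np.where(z <= 0, a1 * np.exp(z) - 1.0, t.adult_age + z * a1)
    return out.item() if np.isscalar(y) or out.ndim == 0 else out
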