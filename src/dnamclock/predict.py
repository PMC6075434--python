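"""Apply a fitted clock to new beta matrices.

DNAm age of a sample is the inverse-calibrated linear predictor

    age_hat = F^{-1}( b0 + sum_j w_j * beta_j )

over the clock's weighted probes.  Probes absent from the matrix, or
missing for a sample, are imputed with the training mean stored in the
model; each sample's imputed fraction is reported, and samples exceeding
``max_missing_frac`` are flagged as failed rather than silently returned.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from dnamclock.io import BetaMatrix
from dnamclock.model import ClockModel
from dnamclock.transform import inverse_transform_age

logger = logging.getLogger(__name__)

__all__ = ["estimate_dnam_age"]


def estimate_dnam_age(
    model: ClockModel, m: BetaMatrix, max_missing_frac: float = 0.2
) -> pd.DataFrame:
    """Estimate DNAm age (years) for every sample in ``m``.

    Returns a DataFrame with columns ``sample_id``, ``dnam_age``,
    ``n_imputed``, ``frac_imputed`` and ``flag`` (``"ok"`` or
    ``"too_many_imputed"``).  Flagged samples keep their estimate but
    should be excluded from downstream statistics.

    Raises if an imputed probe has no stored training mean (partial
    models loaded from bare coefficient files cannot impute).
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0,1]")
    probes = sorted(model.weights)  # fixed order: invariant to matrix layout
    w = np.array([model.weights[p] for p in probes])
    row_of = {p: i for i, p in enumerate(m.probe_ids)}

    n_samples = len(m.sample_ids)
    X = np.empty((n_samples, len(probes)))
    imputed = np.zeros((n_samples, len(probes)), dtype=bool)
    for j, p in enumerate(probes):
        i = row_of.get(p)
        col = m.values[i] if i is not None else np.full(n_samples, np.nan)
        miss = np.isnan(col)
        if miss.any():
            mean = model.probe_means.get(p, np.nan)
            if np.isnan(mean):
                raise ValueError(
                    f"probe {p!r} is missing and the model stores no training "
                    "mean for it (partial coefficient-only model?)"
                )
            col = np.where(miss, mean, col)
        X[:, j] = col
        imputed[:, j] = miss

    lin = model.intercept + X @ w
    ages = np.asarray(inverse_transform_age(lin, model.transform))
    n_imp = imputed.sum(axis=1)
    frac = n_imp / len(probes) if probes else np.zeros(n_samples)
    flag = np.where(frac > max_missing_frac, "too_many_imputed", "ok")
    n_bad = int((flag == "too_many_imputed").sum())
    if n_bad:
        logger.warning("%d/%d samples exceeded max_missing_frac=%.2f",
                       n_bad, n_samples, max_missing_frac)
    return pd.DataFrame(
        {
            "sample_id": list(m.sample_ids),
            "dnam_age": ages,
            "n_imputed": n_imp,
            "frac_imputed": frac,
            "flag": flag,
        }
    )
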