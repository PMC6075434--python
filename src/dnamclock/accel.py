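"""Epigenetic age acceleration.

Acceleration is defined relative to a reference regression of DNAm age on
chronological age fitted through control samples only: a sample's
acceleration is the vertical distance (residual, in years) from that
line, so by construction the mean acceleration of controls is zero.
Positive values mean the sample is epigenetically older than expected.

The module also provides covariate-adjusted OLS models (age, age²,
population-doubling level, disease indicator) for case–control designs in
which proliferation history confounds the raw residual, and the accuracy
metrics conventionally reported for clocks (age correlation and the
median absolute deviation between DNAm age and chronological age).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ReferenceModel",
    "AccelerationResult",
    "fit_reference",
    "residual_acceleration",
    "adjusted_acceleration",
    "accuracy_metrics",
]


@dataclass(frozen=True)
class ReferenceModel:
    """Polynomial map age -> expected DNAm age fitted on controls.

    ``coef`` holds coefficients in ascending powers (intercept first);
    degree 1 is a straight reference line, degree 2 allows curvature.
    """

    coef: tuple[float, ...]

    @property
    def degree(self) -> int:
        return len(self.coef) - 1

    def __call__(self, age):
        x = np.asarray(age, dtype=float)
        return sum(c * x**k for k, c in enumerate(self.coef))


@dataclass
class AccelerationResult:
    """Per-sample residual acceleration plus the fitted reference."""

    samples: pd.DataFrame  # sample_id, age, dnam_age, group, acceleration
    reference: ReferenceModel
    group_summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def fit_reference(ages, dnam_ages, degree: int = 1) -> ReferenceModel:
    """Least-squares polynomial reference through control samples.

    Requires at least ``degree + 2`` samples and a full-rank design
    (degree 1 with a single repeated age value is singular).
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(dnam_ages, dtype=float)
    if degree not in (1, 2):
        raise ValueError("reference degree must be 1 or 2")
    if len(x) != len(y):
        raise ValueError("ages and dnam_ages differ in length")
    if len(x) < degree + 2:
        raise ValueError(
            f"need >= {degree + 2} control samples for degree {degree}, got {len(x)}"
        )
    A = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(A) < degree + 1:
        raise ValueError(
            "singular reference design: control ages do not span the "
            f"degree-{degree} polynomial (e.g. a single repeated age)"
        )
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return ReferenceModel(tuple(float(c) for c in coef))


def residual_acceleration(ref: ReferenceModel, samples: pd.DataFrame) -> AccelerationResult:
    """Acceleration = dnam_age − ref(age) for every sample (cases and controls).

    ``samples`` needs columns ``age`` and ``dnam_age``; optional
    ``sample_id`` and ``group`` (e.g. disease label) columns are carried
    through, and a per-group mean/standard-error summary is computed when
    ``group`` is present.
    """
    df = samples.copy().reset_index(drop=True)
    for col in ("age", "dnam_age"):
        if col not in df.columns:
            raise ValueError(f"samples needs column {col!r}")
    if "sample_id" not in df.columns:
        df["sample_id"] = [f"s{i}" for i in range(len(df))]
    df["acceleration"] = df["dnam_age"].astype(float) - ref(df["age"].to_numpy())
    summary = pd.DataFrame()
    if "group" in df.columns:
        g = df.groupby("group")["acceleration"]
        summary = pd.DataFrame({
            "n": g.size(),
            "mean": g.mean(),
            "se": g.std(ddof=1) / np.sqrt(g.size()),
        })
    keep = [c for c in ("sample_id", "age", "dnam_age", "group", "acceleration")
            if c in df.columns]
    return AccelerationResult(df[keep], ref, summary)


_COVARIATE_BUILDERS = {
    "age": lambda d: d["age"].astype(float),
    "age2": lambda d: d["age"].astype(float) ** 2,
    "pdl": lambda d: d["pdl"].astype(float),
    "disease": lambda d: (d["disease"].astype(str) != "control").astype(float),
}


def adjusted_acceleration(samples: pd.DataFrame, covariates=("age", "age2", "pdl", "disease")) -> pd.DataFrame:
    """OLS of DNAm age on the requested covariates, with t-test p-values.

    ``covariates`` is drawn from {"age", "age2", "pdl", "disease"}; the
    disease indicator is 1 for any non-``control`` label.  Returns a
    coefficient table (estimate, std_error, p_value) indexed by term,
    intercept included.  A rank-deficient design raises, naming the
    collinear columns.
    """
    df = samples.reset_index(drop=True)
    if "dnam_age" not in df.columns:
        raise ValueError("samples needs column 'dnam_age'")
    cols = {}
    for cov in covariates:
        if cov not in _COVARIATE_BUILDERS:
            raise ValueError(f"unknown covariate {cov!r}; choose from {sorted(_COVARIATE_BUILDERS)}")
        cols[cov] = _COVARIATE_BUILDERS[cov](df).to_numpy()
    X = pd.DataFrame(cols)
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        collinear = _find_collinear(Xd)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
    fit = sm.OLS(df["dnam_age"].astype(float).to_numpy(), Xd).fit()
    out = pd.DataFrame({
        "estimate": fit.params,
        "std_error": fit.bse,
        "p_value": fit.pvalues,
    })
    return out.rename(index={"const": "intercept"})


def _find_collinear(Xd: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (reported in rank errors)."""
    full = np.linalg.matrix_rank(Xd.to_numpy())
    out = []
    for col in Xd.columns:
        rest = Xd.drop(columns=[col]).to_numpy()
        if np.linalg.matrix_rank(rest) == full:
            out.append(str(col))
    return out


def accuracy_metrics(ages, dnam_ages) -> tuple[float, float]:
    """Pearson r and the median absolute deviation |DNAm age − age| (years).

    With zero variance in either vector the correlation is undefined and
    returned as NaN; the error is always defined.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(dnam_ages, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 paired values")
    medae = float(np.median(np.abs(y - x)))
    if x.std() == 0 or y.std() == 0:
        return float("nan"), medae
    r = float(np.corrcoef(x, y)[0, 1])
    return r, medae
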