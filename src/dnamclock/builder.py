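"""CpG preselection and elastic-net training of an epigenetic clock.

Training follows the standard two-stage recipe for array clocks:

1. *Preselection* reduces the probe universe to candidates whose beta
   values correlate with calibrated age within each cell-type stratum
   (top ``k_pos`` positively and ``k_neg`` negatively correlated probes
   per stratum), plus ``k_null`` probes with the least significant pooled
   age correlation, which act as a control set the penalty should discard.
2. *Elastic-net regression* of the calibrated age on the candidate betas,

       min over (b0, b) of (1/2n)·Σ(y_i − b0 − x_iᵀb)² + λ·[α·‖b‖₁ + ((1−α)/2)·‖b‖₂²]

   with predictors standardized internally and coefficients returned on
   the original beta scale; λ is chosen by K-fold cross-validation
   (minimum mean squared error), α defaults to 0.5.

The fitted support is sparse; the selected probes are the clock CpGs and
their weighted average (plus intercept) is the clock.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from dnamclock.io import BetaMatrix, validate_annotation
from dnamclock.model import ClockModel
from dnamclock.transform import AgeTransform, transform_age

logger = logging.getLogger(__name__)

__all__ = [
    "PreselectionSpec",
    "preselect_cpgs",
    "fit_elastic_net",
    "train_clock",
    "kkt_residual",
    "default_lambda_grid",
]


@dataclass(frozen=True)
class PreselectionSpec:
    """Candidate-probe selection rule.

    ``k_pos``/``k_neg``: top positively / negatively age-correlated probes
    kept per stratum; ``k_null``: probes with the least significant pooled
    age correlation (a deliberately uninformative control set);
    ``stratify_by``: annotation column defining strata (default tissue).
    """

    k_pos: int = 1000
    k_neg: int = 1000
    k_null: int = 500
    stratify_by: str = "tissue"

    def __post_init__(self) -> None:
        if min(self.k_pos, self.k_neg, self.k_null) < 0:
            raise ValueError("selection counts must be >= 0")
        if self.k_pos + self.k_neg + self.k_null == 0:
            raise ValueError("at least one of k_pos, k_neg, k_null must be positive")


def _corr_with_age(values: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe Pearson r (and two-sided p) with the transformed age vector.

    Missing betas are handled pairwise-complete per probe.  Probes with
    zero variance or fewer than 3 complete pairs get r=0, p=1.
    """
    mask = ~np.isnan(values)
    n = mask.sum(axis=1).astype(float)
    v = np.where(mask, values, 0.0)
    zm = np.where(mask, z[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sv = v.sum(axis=1)
        sz = zm.sum(axis=1)
        svz = (v * zm).sum(axis=1)
        svv = (v * v).sum(axis=1)
        szz = (zm * zm).sum(axis=1)
        cov = svz - sv * sz / n
        var_v = svv - sv**2 / n
        var_z = szz - sz**2 / n
        r = cov / np.sqrt(var_v * var_z)
    bad = (n < 3) | ~np.isfinite(r)
    r = np.where(bad, 0.0, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1)), 0.0)
    p = np.where(bad, 1.0, p)
    return r, p


def _top_k(probe_ids, key, k: int) -> list[str]:
    # sort by key then probe ID: deterministic tie-break
    order = sorted(range(len(probe_ids)), key=lambda i: (key[i], probe_ids[i]))
    return [probe_ids[i] for i in order[:k]]


def preselect_cpgs(
    m: BetaMatrix,
    ann: pd.DataFrame,
    spec: PreselectionSpec | None = None,
    transform: AgeTransform | None = None,
) -> set[str]:
    """Select candidate clock CpGs by within-stratum age correlation.

    Returns the union over strata of the ``k_pos`` most positively and
    ``k_neg`` most negatively correlated probes, plus the ``k_null``
    pooled probes with the largest correlation-test p-value (capped at
    the probe-universe size).  Strata with fewer than 3 aged samples are
    skipped with a warning.
    """
    spec = spec or PreselectionSpec()
    transform = transform or AgeTransform()
    ann = validate_annotation(ann)
    ann = ann[ann["sample_id"].isin(m.sample_ids)]
    col_of = {s: j for j, s in enumerate(m.sample_ids)}
    selected: set[str] = set()
    probe_ids = m.probe_ids

    for stratum, grp in ann.groupby(spec.stratify_by, sort=True):
        if len(grp) < 3:
            warnings.warn(
                f"stratum {stratum!r} has {len(grp)} samples (<3); skipped", stacklevel=2
            )
            continue
        cols = [col_of[s] for s in grp["sample_id"]]
        z = transform_age(grp["age"].to_numpy(), transform)
        r, _ = _corr_with_age(m.values[:, cols], np.asarray(z))
        if spec.k_pos:
            selected.update(_top_k(probe_ids, -r, spec.k_pos))
        if spec.k_neg:
            selected.update(_top_k(probe_ids, r, spec.k_neg))

    if spec.k_null:
        cols = [col_of[s] for s in ann["sample_id"]]
        z = transform_age(ann["age"].to_numpy(), transform)
        _, p = _corr_with_age(m.values[:, cols], np.asarray(z))
        selected.update(_top_k(probe_ids, -p, min(spec.k_null, len(probe_ids))))

    return selected


def default_lambda_grid(X: np.ndarray, y: np.ndarray, alpha: float,
                        n_lambda: int = 100, ratio: float = 1e-4) -> np.ndarray:
    """Decreasing geometric λ grid from the smallest λ zeroing all weights.

    Computed on standardized predictors; for α < 0.001 the grid top uses
    α = 0.001 (the ridge limit has no finite zeroing λ).
    """
    Xs, _, _ = standardize_columns(X)
    n = X.shape[0]
    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / (n * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def standardize_columns(X: np.ndarray):
    """Center and scale columns to unit (population) variance.

    Zero-variance columns are left centered with scale 1 so that they can
    only receive a zero coefficient.  Returns ``(Xs, mean, scale)``.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _solve(Xs: np.ndarray, y: np.ndarray, lam: float, alpha: float, tol: float):
    """Minimize the elastic-net objective on already-standardized predictors."""
    if lam == 0:
        A = np.column_stack([np.ones(len(y)), Xs])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return coef[0], coef[1:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter at tiny λ
        en = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                        max_iter=200_000, tol=tol)
        en.fit(Xs, y)
    return float(en.intercept_), en.coef_.copy()


def _solve_path(Xs: np.ndarray, y: np.ndarray, grid: np.ndarray, alpha: float, tol: float):
    """Warm-started solutions along a decreasing λ grid (for CV speed)."""
    en = ElasticNet(l1_ratio=alpha, fit_intercept=True, max_iter=200_000,
                    tol=tol, warm_start=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lam in grid:
            if lam == 0:
                yield _solve(Xs, y, 0.0, alpha, tol)
            else:
                en.set_params(alpha=lam)
                en.fit(Xs, y)
                yield float(en.intercept_), en.coef_.copy()


def fit_elastic_net(
    X,
    y,
    alpha: float = 0.5,
    lambda_grid=None,
    folds: int = 10,
    seed: int = 0,
    transform: AgeTransform | None = None,
    probe_ids=None,
    tol: float = 1e-12,
    cv_tol: float = 1e-5,
) -> ClockModel:
    """Fit the penalized clock regression and select λ by cross-validation.

    Parameters
    ----------
    X
        Samples x probes predictor matrix (DataFrame with probe columns, or
        array with ``probe_ids``).  No missing values.
    y
        Calibrated (transformed) ages.
    alpha
        Elastic-net mixing in [0, 1]; 1 is the lasso, 0 is ridge.
    lambda_grid
        Decreasing positive penalties to search; default is a 100-point
        geometric grid below the all-zero λ.  A single-element grid skips
        cross-validation.
    folds, seed
        K-fold count and the fold-assignment seed (recorded in the model).

    Returns a :class:`ClockModel` with coefficients on the beta scale and
    training probe means stored for the fitted support.
    """
    if isinstance(X, pd.DataFrame):
        probe_ids = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        probe_ids = list(probe_ids) if probe_ids is not None else [
            f"p{j}" for j in range(X.shape[1])
        ]
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute or drop before fitting")
    if y.std() == 0:
        raise ValueError("no age variation: y is constant")
    n = X.shape[0]
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0,1], got {alpha}")

    grid = (np.asarray(lambda_grid, dtype=float) if lambda_grid is not None
            else default_lambda_grid(X, y, alpha))
    if grid.ndim == 0:
        grid = grid[None]

    cv_mse = None
    if len(grid) > 1:
        if folds < 2:
            raise ValueError("folds must be >= 2")
        if n < folds:
            raise ValueError(f"fewer samples ({n}) than folds ({folds})")
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        sq_err = np.zeros((folds, len(grid)))
        for k, (tr, te) in enumerate(kf.split(X)):
            Xs_tr, mu, sd = standardize_columns(X[tr])
            Xs_te = (X[te] - mu) / sd
            for i, (b0, b) in enumerate(_solve_path(Xs_tr, y[tr], grid, alpha, cv_tol)):
                sq_err[k, i] = np.mean((y[te] - b0 - Xs_te @ b) ** 2)
        cv_mse = sq_err.mean(axis=0)
        lam = float(grid[int(np.argmin(cv_mse))])
    else:
        lam = float(grid[0])

    Xs, mu, sd = standardize_columns(X)
    b0_std, b_std = _solve(Xs, y, lam, alpha, tol)
    coef = b_std / sd
    intercept = float(b0_std - coef @ mu)

    support = np.flatnonzero(b_std != 0)
    weights = {probe_ids[j]: float(coef[j]) for j in support}
    probe_means = {probe_ids[j]: float(mu[j]) for j in support}
    meta = {
        "n_train": int(n),
        "seed": int(seed),
        "folds": int(folds) if len(grid) > 1 else None,
        "n_candidates": len(probe_ids),
        "lambda_grid": [float(v) for v in grid],
        "cv_mse": None if cv_mse is None else [float(v) for v in cv_mse],
    }
    logger.info("elastic net: λ=%.5g, %d/%d non-zero probes", lam, len(weights), len(probe_ids))
    return ClockModel(
        intercept=intercept, weights=weights, probe_means=probe_means,
        transform=transform or AgeTransform(), alpha=alpha, lam=lam, meta=meta,
    )


def kkt_residual(X: np.ndarray, y: np.ndarray, coef: np.ndarray,
                 intercept: float, lam: float, alpha: float) -> float:
    """Largest violation of the elastic-net stationarity conditions.

    For the objective (1/2n)·‖y − b0 − Xb‖² + λ[α‖b‖₁ + (1−α)/2·‖b‖₂²]
    a minimizer satisfies, with g = −Xᵀ(y − b0 − Xb)/n + λ(1−α)b:
    g_j + λα·sign(b_j) = 0 when b_j ≠ 0, and |g_j| ≤ λα when b_j = 0.
    Returns the maximum absolute violation (0 at an exact solution).
    Evaluate on the same predictor scale the solver used.
    """
    r = y - intercept - X @ coef
    g = -X.T @ r / len(y) + lam * (1 - alpha) * coef
    nz = coef != 0
    viol_nz = np.abs(g[nz] + lam * alpha * np.sign(coef[nz]))
    viol_z = np.maximum(np.abs(g[~nz]) - lam * alpha, 0.0)
    viol_int = abs(r.mean())  # intercept stationarity
    return float(max(viol_nz.max(initial=0.0), viol_z.max(initial=0.0), viol_int))


def train_clock(
    m: BetaMatrix,
    ann: pd.DataFrame,
    spec: PreselectionSpec | None = None,
    transform: AgeTransform | None = None,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    lambda_grid=None,
) -> ClockModel:
    """End-to-end clock training: preselect CpGs, impute, fit, log accuracy.

    Missing betas among candidate probes are imputed with the probe's
    training mean before fitting.  Training-set accuracy (Pearson r and
    median absolute deviation between DNAm age and chronological age, in
    years) is stored in ``model.meta['training']``.
    """
    transform = transform or AgeTransform()
    spec = spec or PreselectionSpec()
    ann = validate_annotation(ann)
    ann = ann[ann["sample_id"].isin(m.sample_ids)].reset_index(drop=True)
    if len(ann) == 0:
        raise ValueError("no overlap between matrix samples and annotation")

    candidates = sorted(preselect_cpgs(m, ann, spec, transform))
    df = m.to_dataframe().loc[candidates, ann["sample_id"]].T  # samples x probes
    col_means = df.mean(axis=0)
    df = df.fillna(col_means)
    y = transform_age(ann["age"].to_numpy(), transform)

    model = fit_elastic_net(df, np.asarray(y), alpha=alpha, folds=folds,
                            seed=seed, transform=transform, lambda_grid=lambda_grid)

    from dnamclock.predict import estimate_dnam_age
    from dnamclock.accel import accuracy_metrics

    pred = estimate_dnam_age(model, m, max_missing_frac=1.0)
    pred = pred.set_index("sample_id").loc[ann["sample_id"]]
    r, medae = accuracy_metrics(ann["age"].to_numpy(), pred["dnam_age"].to_numpy())
    model.meta["training"] = {"pearson_r": float(r), "median_abs_dev": float(medae)}
    model.meta["candidate_set_size"] = len(candidates)
    logger.info("trained clock: %d CpGs, training r=%.3f, error=%.2f yr",
                model.n_probes, r, medae)
    return model
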