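"""Association of reconstruction errors with clinical sub-scores.

One LASSO fit per A-T NEST outcome (ataxia, hypermotor, bradykinesia,
dystonia; lower = more severe): the 13 per-feature signed reconstruction
errors are L1-penalized predictors, while the seven demographic covariates
(age, sex, cerebral volume, cerebellar volume, age^2, age*sex, age^2*sex)
enter with penalty factor zero so they are never selected away — they are
adjusted for, not competed against.  Predictors and outcome are
z-standardized, so coefficients are comparable across features; only
coefficients with |beta| > 0.1 are reported.  No multiple-testing
correction is applied (exploratory analysis).

The solver is cyclic coordinate descent on

    (1/2n) ||y - X b||^2 + lambda * sum_j w_j |b_j|

with per-coefficient penalty factors w_j; lambda is chosen by k-fold
cross-validation when not given.  scikit-learn's Lasso does not support
penalty factors, hence the in-house solver; it reduces to OLS at
lambda = 0 and to coordinate-wise soft-thresholding under an orthonormal
design, which the test suite uses as closed-form oracles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import (
    COVARIATE_NAMES,
    NEST_SCORES,
    OUTPUT_FEATURES,
    SubjectRecord,
    engineer_covariates,
)
from .stats import ErrorProfile

logger = logging.getLogger(__name__)

REPORT_THRESHOLD = 0.1
REDUCED_COVARIATES = ("age", "sex", "cerebral_volume")


class DegenerateFitError(ValueError):
    """The outcome (or every predictor) is constant."""


@dataclass
class LassoAssociation:
    outcome: str
    coefficients: pd.Series  # standardized scale, indexed by predictor name
    lam: float
    penalized: list[str]  # names of the L1-penalized predictors

    @property
    def reported(self) -> pd.Series:
        return report_coefficients(self)


def soft_threshold(x: float, t: float) -> float:
    return float(np.sign(x) * max(abs(x) - t, 0.0))


def _coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    w: np.ndarray,
    max_iter: int,
    tol: float,
    beta0: np.ndarray | None = None,
) -> np.ndarray:
    n, p = X.shape
    col_ss = (X * X).sum(axis=0) / n
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    resid = y - X @ beta if beta0 is not None else y.copy()
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if col_ss[j] == 0.0:
                continue
            rho = X[:, j] @ resid / n + col_ss[j] * beta[j]
            new = soft_threshold(rho, lam * w[j]) / col_ss[j]
            delta = new - beta[j]
            if delta != 0.0:
                resid -= delta * X[:, j]
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return beta


def lasso_penalty_factors(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalty_factors: np.ndarray,
    max_iter: int = 20_000,
    tol: float = 1e-10,
    beta0: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted-L1 solver with exact handling of unpenalized coordinates.

    Coordinates with penalty factor zero are concentrated out by least
    squares (the partialling-out identity: minimizing jointly over the
    penalized block b_P and free block b_F equals solving the LASSO on
    covariate-residualized data, then back-solving b_F), so coordinate
    descent runs only on the penalized block and never stalls on the
    degenerate free directions.  Columns are assumed (approximately)
    standardized; zero-variance columns get coefficient 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(penalty_factors, dtype=float)
    free = w == 0.0
    if not free.any():
        return _coordinate_descent(X, y, lam, w, max_iter, tol, beta0)
    pen = ~free
    Xf, Xp = X[:, free], X[:, pen]
    # residual-maker via least squares (rank-safe)
    proj_y = Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]
    proj_Xp = Xf @ np.linalg.lstsq(Xf, Xp, rcond=None)[0]
    b0p = np.asarray(beta0)[pen] if beta0 is not None else None
    beta_p = _coordinate_descent(
        Xp - proj_Xp, y - proj_y, lam, w[pen], max_iter, tol, b0p
    )
    beta_f = np.linalg.lstsq(Xf, y - Xp @ beta_p, rcond=None)[0]
    beta = np.zeros(X.shape[1])
    beta[pen] = beta_p
    beta[free] = beta_f
    return beta


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=0)
    out = np.zeros_like(M, dtype=float)
    nz = sd > 0
    out[:, nz] = (M[:, nz] - mu[nz]) / sd[nz]
    return out, sd


def _cv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    n_folds: int,
    seed: int,
    n_lambdas: int = 20,
) -> float:
    n = len(y)
    penalized = w > 0
    lam_max = np.max(np.abs(X[:, penalized].T @ y) / n) if penalized.any() else 1.0
    lambdas = np.geomspace(lam_max, lam_max * 1e-2, n_lambdas)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 81]))
    folds = np.array_split(rng.permutation(n), n_folds)
    errors = np.zeros(n_lambdas)
    free = w == 0.0
    for fi, val_idx in enumerate(folds):
        tr_idx = np.concatenate([folds[j] for j in range(n_folds) if j != fi])
        Xt, yt = X[tr_idx], y[tr_idx]
        # residualize the free block once per fold, then warm-start the
        # coordinate descent down the descending lambda path
        Xf, Xp = Xt[:, free], Xt[:, ~free]
        cf_y = np.linalg.lstsq(Xf, yt, rcond=None)[0] if free.any() else None
        if free.any():
            cf_X = np.linalg.lstsq(Xf, Xp, rcond=None)[0]
            Rp, ry = Xp - Xf @ cf_X, yt - Xf @ cf_y
        else:
            Rp, ry = Xp, yt
        beta_p = None
        for li, lam in enumerate(lambdas):
            beta_p = _coordinate_descent(
                Rp, ry, lam, w[~free], max_iter=2000, tol=1e-8, beta0=beta_p
            )
            beta = np.zeros(X.shape[1])
            beta[~free] = beta_p
            if free.any():
                beta[free] = np.linalg.lstsq(Xf, yt - Xp @ beta_p, rcond=None)[0]
            pred = X[val_idx] @ beta
            errors[li] += np.sum((y[val_idx] - pred) ** 2)
    best = int(np.argmin(errors))
    return float(lambdas[best])


def fit_lasso(
    outcome: np.ndarray,
    error_predictors: np.ndarray,
    covariates: np.ndarray,
    lam: float | None = None,
    seed: int = 0,
    n_folds: int = 5,
    outcome_name: str = "outcome",
    covariate_names: Sequence[str] = COVARIATE_NAMES,
) -> LassoAssociation:
    """Fit one clinical outcome on standardized error predictors with
    unpenalized covariates.

    ``lam=None`` selects the penalty by ``n_folds``-fold CV minimizing
    validation MSE.  Coefficients are returned on the standardized scale.
    """
    y = np.asarray(outcome, dtype=float)
    E = np.atleast_2d(np.asarray(error_predictors, dtype=float))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    n = len(y)
    if E.shape[0] != n or C.shape[0] != n:
        raise ValueError("predictor row counts must match the outcome length")
    if np.std(y) == 0:
        raise DegenerateFitError(f"outcome {outcome_name!r} is constant")
    if n < 8:
        warnings.warn(
            f"only {n} subjects with scores; association estimates are fragile",
            stacklevel=2,
        )
    names = list(OUTPUT_FEATURES[: E.shape[1]]) + list(covariate_names)
    X = np.hstack([E, C])
    Xs, _ = _standardize(X)
    ys = (y - y.mean()) / y.std(ddof=0)
    w = np.array([1.0] * E.shape[1] + [0.0] * C.shape[1])
    if lam is None:
        lam = _cv_lambda(Xs, ys, w, n_folds=min(n_folds, n), seed=seed)
    beta = lasso_penalty_factors(Xs, ys, lam, w)
    return LassoAssociation(
        outcome=outcome_name,
        coefficients=pd.Series(beta, index=names),
        lam=float(lam),
        penalized=names[: E.shape[1]],
    )


def report_coefficients(
    assoc: LassoAssociation, threshold: float = REPORT_THRESHOLD
) -> pd.Series:
    """Coefficients exceeding the reporting threshold in magnitude,
    sign and magnitude preserved."""
    c = assoc.coefficients
    return c[np.abs(c) > threshold]


def covariate_matrix(
    records: Sequence[SubjectRecord], which: str = "full"
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Covariate design from subject records: "full" (all 7) or
    "reduced" (age, sex, cerebral volume)."""
    cov = np.array([engineer_covariates(r).as_array() for r in records])
    if which == "full":
        return cov, COVARIATE_NAMES
    if which == "reduced":
        idx = [COVARIATE_NAMES.index(c) for c in REDUCED_COVARIATES]
        return cov[:, idx], REDUCED_COVARIATES
    raise ValueError("which must be 'full' or 'reduced'")


def association_matrix(
    profiles: Sequence[ErrorProfile],
    records: Sequence[SubjectRecord],
    lam: float | None = None,
    seed: int = 0,
    covariates: str = "full",
) -> pd.DataFrame:
    """Standardized coefficient matrix: one LASSO fit per NEST outcome.

    Only subjects carrying clinical scores (the A-T participants) enter;
    rows are outcomes, columns the 13 error predictors.  Covariate
    coefficients are fitted but not part of the matrix (they are
    adjustments, not hypotheses).
    """
    by_id = {r.subject_id: r for r in records}
    scored = [
        (p, by_id[p.subject_id])
        for p in profiles
        if p.subject_id in by_id and by_id[p.subject_id].nest
    ]
    if len(scored) == 0:
        raise DegenerateFitError("no subjects with clinical scores")
    outcomes = [
        s
        for s in NEST_SCORES
        if sum(s in r.nest for _, r in scored) == len(scored)
    ]
    if len(outcomes) < 2:
        raise ValueError("need at least 2 outcomes with complete scores")
    E = np.array([p.signed_errors for p, _ in scored])
    C, cov_names = covariate_matrix([r for _, r in scored], which=covariates)
    rows = {}
    for s in outcomes:
        y = np.array([r.nest[s] for _, r in scored])
        fit = fit_lasso(
            y, E, C, lam=lam, seed=seed, outcome_name=s, covariate_names=cov_names
        )
        rows[s] = fit.coefficients[list(OUTPUT_FEATURES)]
    return pd.DataFrame(rows).T
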