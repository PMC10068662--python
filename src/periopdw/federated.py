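"""Federated logistic regression by summary-statistic aggregation.

Horizontally split centers never share row-level data: at each Newton
step every center evaluates, at the shared coefficient vector beta, its
local score U_c = X_c' (y_c - mu_c) and information I_c = X_c' W_c X_c
with mu = logistic(X beta) and W = diag(mu (1 - mu)). Because both are
sums over rows, aggregating the per-center summaries reproduces the
pooled quantities exactly, so the federated Newton–Raphson iterates are
identical (to floating-point) to a centralized fit — the property the
test suite asserts per iteration.

Wald 95 % confidence intervals come from the inverse aggregated
information at convergence. No regularization; perfect separation
surfaces as an explicit SeparationError rather than silent divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

Z_975 = 1.959964  # normal quantile for two-sided 95 % intervals

DEFAULT_TOL = 1e-8    # max-norm of the aggregated gradient
DEFAULT_MAX_ITER = 25


class SeparationError(RuntimeError):
    """Aggregated information became singular — typically quasi-complete
    separation. Drop or combine covariates, or add rows, and refit."""


@dataclass(frozen=True)
class CenterSummary:
    """One center's contribution at a shared beta: sample size, score
    vector, (negative-Hessian) information matrix and local
    log-likelihood. All additive across centers by construction, and all
    aggregates — no row-level data leaves the center."""

    center_id: str
    n: int
    gradient: np.ndarray      # shape (p,)
    information: np.ndarray   # shape (p, p), symmetric PSD
    loglik: float = float("nan")

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("center must hold at least one row")
        if self.information.shape != (len(self.gradient),) * 2:
            raise ValueError("information shape does not match gradient length")


class Center:
    """Holds one center's rows privately; only summaries cross the wire."""

    def __init__(self, center_id: str, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("covariate matrix must be 2-D with >= 1 column")
        if len(y) != X.shape[0]:
            raise ValueError("outcome length does not match covariate rows")
        self.center_id = center_id
        self._X = X
        self._y = y

    @property
    def n(self) -> int:
        return self._X.shape[0]

    @property
    def p(self) -> int:
        return self._X.shape[1]

    def summary(self, beta: np.ndarray) -> CenterSummary:
        return local_summary(self._X, self._y, beta, center_id=self.center_id)


def local_summary(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, center_id: str = "local"
) -> CenterSummary:
    """Exact score and information of the Bernoulli log-likelihood at beta."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("covariate matrix must be 2-D with >= 1 column")
    if X.shape[0] != len(y):
        raise ValueError("outcome length does not match covariate rows")
    if X.shape[1] != len(beta):
        raise ValueError(
            f"beta has length {len(beta)}, covariates have {X.shape[1]} columns"
        )
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    # numerically stable Bernoulli log-likelihood:
    # log(mu) = -log(1 + e^-eta), log(1-mu) = -log(1 + e^eta)
    ll = float(np.sum(-y * np.logaddexp(0.0, -eta) - (1.0 - y) * np.logaddexp(0.0, eta)))
    return CenterSummary(
        center_id=center_id,
        n=X.shape[0],
        gradient=X.T @ (y - mu),
        information=(X * w[:, None]).T @ X,
        loglik=ll,
    )


@dataclass
class FitResult:
    beta: np.ndarray
    covariance: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_iterations: int
    converged: bool
    n_total: int

    def ci_width(self) -> np.ndarray:
        return self.ci_upper - self.ci_lower

    def to_frame(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        p = len(self.beta)
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            },
            index=list(names) if names is not None else [f"x{i}" for i in range(p)],
        )


def federated_fit(
    centers: Sequence[Center],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Newton–Raphson on aggregated per-center summaries, from beta = 0.

    The only quantities exchanged per iteration are CenterSummary
    objects; the aggregation sees no row-level data. Convergence is
    max-norm of the aggregated gradient <= tol; a fit that exhausts
    max_iter returns with converged=False rather than raising.
    """
    if not centers:
        raise ValueError("need at least one center")
    p = centers[0].p
    if any(c.p != p for c in centers):
        raise ValueError("all centers must share the covariate layout")
    for c in centers:
        if c.n < p + 1:
            raise ValueError(
                f"center {c.center_id!r} has {c.n} rows; needs at least p+1 = {p + 1}"
            )

    beta = np.zeros(p)
    converged = False
    n_iter = 0
    info = np.eye(p)
    for n_iter in range(1, max_iter + 1):
        summaries = [c.summary(beta) for c in centers]
        grad = np.sum([s.gradient for s in summaries], axis=0)
        info = np.sum([s.information for s in summaries], axis=0)
        if np.max(np.abs(grad)) <= tol:
            # a vanishing score with essentially zero deviance means every
            # row is fitted with certainty: complete separation
            total_ll = sum(s.loglik for s in summaries)
            if total_ll > -1e-6:
                raise SeparationError(
                    "log-likelihood reached zero: the outcome is perfectly "
                    "separated by the covariates; drop or combine predictors"
                )
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "aggregated information matrix is singular at iteration "
                f"{n_iter}; check for separation or collinear covariates"
            ) from exc
        if not np.all(np.isfinite(step)):
            raise SeparationError(
                f"non-finite Newton step at iteration {n_iter}; "
                "check for separation or extreme covariate scales"
            )
        beta = beta + step

    try:
        covariance = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SeparationError("information matrix singular at convergence") from exc
    se = np.sqrt(np.diag(covariance))
    return FitResult(
        beta=beta,
        covariance=covariance,
        se=se,
        ci_lower=beta - Z_975 * se,
        ci_upper=beta + Z_975 * se,
        n_iterations=n_iter,
        converged=converged,
        n_total=sum(c.n for c in centers),
    )


def centralized_fit(
    X: np.ndarray, y: np.ndarray, tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER
) -> FitResult:
    """Pooled-data fit: the one-center special case of federated_fit."""
    return federated_fit([Center("pooled", X, y)], tol=tol, max_iter=max_iter)


def split_centers(
    X: np.ndarray, y: np.ndarray, k: int, seed: int = 0
) -> list[Center]:
    """Random disjoint, exhaustive, near-equal partition into k centers.

    Deterministic under the seed; sizes differ by at most one row
    (403 rows over 4 centers -> 101, 101, 101, 100).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot split {n} rows among {k} centers")
    if k == 1:
        return [Center("center_1", X, y)]  # the dataset itself, order kept
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    parts = np.array_split(order, k)
    centers = [
        Center(f"center_{i + 1}", X[idx], y[idx]) for i, idx in enumerate(parts)
    ]
    for c in centers:
        if c.n < p + 1:
            raise ValueError(
                f"center {c.center_id!r} received {c.n} rows; needs >= p+1 = {p + 1}"
            )
    return centers


def make_logistic_dataset(
    n: int = 400,
    beta: Sequence[float] = (-0.5, 0.8, -0.6),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Documented synthetic logistic dataset (intercept + standard-normal
    and binary covariates), a stand-in for a clinical extract: it does
    not reproduce any published study's variables or coefficients."""
    beta = np.asarray(beta, dtype=float)
    p = len(beta)
    rng = np.random.default_rng(seed)
    X = np.empty((n, p))
    X[:, 0] = 1.0
    for j in range(1, p):
        if j % 2 == 1:
            X[:, j] = rng.normal(0.0, 1.0, n)
        else:
            X[:, j] = rng.integers(0, 2, n).astype(float)
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < mu).astype(float)
    return X, y
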