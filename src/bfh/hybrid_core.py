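"""Conjugate Gaussian linear regression in three inference modes.

Pseudo-bulk differential expression reduces, per gene, to a small linear
regression ``Y = X beta + eps`` with ``eps ~ N(0, sigma^2 I)``, where Y is a
per-subject expression summary and X holds an intercept, the disease-group
indicator, and optional covariates.  This module provides

* :func:`ols_fit` — ordinary least squares (all coefficients frequentist);
* :func:`bayes_fit` — the conjugate Gaussian posterior for all coefficients;
* :func:`hybrid_em_fit` — the Bayesian-frequentist hybrid (BFH): a subset of
  coefficients carries a Gaussian prior and is estimated by its posterior
  mean, the complement by maximum likelihood, iterated to a joint fixed
  point by an alternating (EM-style) scheme;
* :func:`wald_inference` — z-based p-values and 95% confidence intervals.

The conjugate posterior is, with prior ``beta ~ N(mu, Sigma)``::

    mean = (Sigma^-1 + X'X)^-1 (Sigma^-1 mu + X'Y)
    cov  = (Sigma^-1 + X'X)^-1 sigma^2

in which the prior precision enters unscaled while the posterior covariance
carries sigma^2 — equivalent to a prior covariance of ``Sigma * sigma^2`` in
the textbook parameterisation.  Pass ``scaled_prior=False`` for the textbook
update where the prior covariance is taken at face value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionData",
    "GaussianPrior",
    "FrequentistFit",
    "PosteriorFit",
    "HybridFit",
    "InferenceSummary",
    "RankDeficiencyError",
    "InsufficientDataError",
    "InvalidPriorError",
    "ols_fit",
    "conjugate_posterior",
    "bayes_fit",
    "hybrid_em_fit",
    "wald_inference",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix X'X is singular (collinear columns)."""


class InsufficientDataError(ValueError):
    """Too few observations for the number of coefficients."""


class InvalidPriorError(ValueError):
    """Prior covariance is not symmetric positive-definite."""


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Indices of columns implicated in a rank deficiency (pivoted QR)."""
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    return sorted(int(j) for j in piv[rank:])


@dataclass
class RegressionData:
    """Design matrix and response for one gene's pseudo-bulk regression.

    X has n rows (subjects) and p columns; by convention the first column is
    an all-ones intercept.  ``column_roles`` labels each column as
    ``intercept``, ``group`` or ``covariate``.
    """

    X: np.ndarray
    Y: np.ndarray
    column_roles: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        n, p = self.X.shape
        if self.Y.shape[0] != n:
            raise ValueError(f"X has {n} rows but Y has {self.Y.shape[0]} entries")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.Y)):
            raise ValueError("X and Y must be finite")
        if self.column_roles is not None and len(self.column_roles) != p:
            raise ValueError("column_roles length must equal the number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class GaussianPrior:
    """Conjugate Gaussian prior N(mean, covariance) on regression coefficients."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        p = self.mean.shape[0]
        if self.covariance.shape != (p, p):
            raise InvalidPriorError(
                f"covariance shape {self.covariance.shape} does not match mean length {p}"
            )
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise InvalidPriorError("prior covariance must be symmetric")
        if np.any(linalg.eigvalsh(self.covariance) <= 0):
            raise InvalidPriorError("prior covariance must be positive-definite")

    @property
    def p(self) -> int:
        return self.mean.shape[0]

    def restrict(self, idx) -> "GaussianPrior":
        """Marginal prior on a subset of coordinates."""
        idx = np.asarray(idx, dtype=int)
        return GaussianPrior(self.mean[idx], self.covariance[np.ix_(idx, idx)])


@dataclass
class FrequentistFit:
    """OLS estimate with covariance (X'X)^-1 sigma2 and residual variance."""

    estimate: np.ndarray
    covariance: np.ndarray
    sigma2: float
    dof: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass
class PosteriorFit:
    """Gaussian posterior N(mean, covariance) of the coefficient vector."""

    mean: np.ndarray
    covariance: np.ndarray

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass
class HybridFit:
    """Fixed point of the alternating Bayesian/frequentist updates.

    ``bayes_idx`` coordinates are estimated by their conditional posterior
    mean, the rest by OLS on the residual response.  SEs are the conditional
    posterior sd (Bayesian coords) and sub-regression OLS SEs (frequentist
    coords) at convergence.
    """

    bayes_idx: tuple[int, ...]
    freq_idx: tuple[int, ...]
    estimate: np.ndarray
    se: np.ndarray
    n_iter: int
    converged: bool
    sigma2: float
    trajectory: list = field(default_factory=list, repr=False)


@dataclass
class InferenceSummary:
    """Wald-style point estimate, SE, 95% CI, z and two-sided p."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float


def ols_fit(data: RegressionData) -> FrequentistFit:
    """Ordinary least squares with unbiased residual variance.

    estimate = (X'X)^-1 X'Y, sigma2 = RSS / (n - p),
    covariance = (X'X)^-1 sigma2.
    """
    X, Y = data.X, data.Y
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"need n > p, got n={n}, p={p}")
    xtx = X.T @ X
    if np.linalg.matrix_rank(X) < p:
        cols = _collinear_columns(X)
        raise RankDeficiencyError(
            f"X'X is singular; collinear column(s): {cols}"
        )
    xtx_inv = linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    return FrequentistFit(beta, xtx_inv * sigma2, sigma2, dof)


def conjugate_posterior(
    data: RegressionData,
    prior: GaussianPrior,
    sigma2: float,
    scaled_prior: bool = True,
) -> PosteriorFit:
    """Closed-form Gaussian posterior of the coefficients.

    With ``scaled_prior=True`` (default) the prior precision enters the
    normal equations unscaled and the posterior covariance is multiplied by
    ``sigma2``.  With ``scaled_prior=False`` the prior covariance is used at
    face value (precision weighted by sigma2 in the update).
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    X, Y = data.X, data.Y
    if prior.p != data.p:
        raise InvalidPriorError(
            f"prior dimension {prior.p} does not match design columns {data.p}"
        )
    prior_prec = linalg.inv(prior.covariance)
    if not scaled_prior:
        prior_prec = prior_prec * sigma2
    a = prior_prec + X.T @ X
    a_inv = linalg.inv(a)
    mean = a_inv @ (prior_prec @ prior.mean + X.T @ Y)
    cov = a_inv * sigma2
    return PosteriorFit(mean, (cov + cov.T) / 2.0)


def bayes_fit(
    data: RegressionData, prior: GaussianPrior, scaled_prior: bool = True
) -> PosteriorFit:
    """Full Bayesian fit: sigma2 from the OLS residuals, then the conjugate posterior."""
    sigma2 = ols_fit(data).sigma2
    return conjugate_posterior(data, prior, sigma2, scaled_prior=scaled_prior)


def hybrid_em_fit(
    data: RegressionData,
    bayes_idx,
    prior_B: GaussianPrior,
    tol: float = 1e-8,
    max_iter: int = 1000,
    scaled_prior: bool = True,
) -> HybridFit:
    """Bayesian-frequentist hybrid fit by alternating conditional updates.

    Starting from the OLS estimates (with sigma2 estimated once from the
    full OLS fit and held fixed), each iteration

    1. subtracts the frequentist columns' contribution from Y and sets the
       Bayesian coefficients to the conditional posterior mean given their
       Gaussian prior;
    2. subtracts the Bayesian columns' contribution and sets the frequentist
       coefficients to the OLS estimate of the residual sub-regression;

    until the largest absolute coefficient change falls below ``tol``.
    """
    bayes_idx = tuple(sorted(int(i) for i in np.atleast_1d(bayes_idx)))
    p = data.p
    if len(set(bayes_idx)) != len(bayes_idx) or any(
        i < 0 or i >= p for i in bayes_idx
    ):
        raise IndexError(f"bayes_idx {bayes_idx} out of range for p={p}")
    freq_idx = tuple(i for i in range(p) if i not in bayes_idx)
    if not bayes_idx:
        raise ValueError("bayes_idx is empty: use ols_fit instead")
    if not freq_idx:
        raise ValueError("freq_idx is empty: use bayes_fit instead")
    if prior_B.p != len(bayes_idx):
        raise InvalidPriorError(
            f"prior dimension {prior_B.p} does not match |bayes_idx|={len(bayes_idx)}"
        )

    full = ols_fit(data)  # also validates rank / sample size
    sigma2 = full.sigma2
    X, Y = data.X, data.Y
    XB = X[:, list(bayes_idx)]
    XA = X[:, list(freq_idx)]
    xax_inv = linalg.inv(XA.T @ XA)

    beta = full.estimate.copy()
    trajectory = [beta.copy()]
    prior_prec = linalg.inv(prior_B.covariance)
    if not scaled_prior:
        prior_prec = prior_prec * sigma2
    post_prec = prior_prec + XB.T @ XB
    post_prec_inv = linalg.inv(post_prec)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        beta_new = beta.copy()
        # Step 2: conditional posterior mean of the Bayesian block
        yB = Y - XA @ beta[list(freq_idx)]
        beta_new[list(bayes_idx)] = post_prec_inv @ (
            prior_prec @ prior_B.mean + XB.T @ yB
        )
        # Step 3: OLS of the frequentist block on the residual response
        yF = Y - XB @ beta_new[list(bayes_idx)]
        beta_new[list(freq_idx)] = xax_inv @ (XA.T @ yF)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        trajectory.append(beta.copy())
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"hybrid EM did not converge in {max_iter} iterations", RuntimeWarning
        )
        logger.warning("hybrid EM: no convergence after %d iterations", max_iter)

    se = np.empty(p)
    se[list(bayes_idx)] = np.sqrt(np.diag(post_prec_inv * sigma2))
    se[list(freq_idx)] = np.sqrt(np.diag(xax_inv * sigma2))
    return HybridFit(
        bayes_idx=bayes_idx,
        freq_idx=freq_idx,
        estimate=beta,
        se=se,
        n_iter=n_iter,
        converged=converged,
        sigma2=sigma2,
        trajectory=trajectory,
    )


def wald_inference(estimate: float, se: float) -> InferenceSummary:
    """z-test summary: z = estimate/se, p = 2(1 - Phi(|z|)), CI = estimate -+ 1.96 se."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    z = float(estimate) / float(se)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return InferenceSummary(
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - 1.96 * se),
        ci_high=float(estimate + 1.96 * se),
        z=z,
        p=p,
    )
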