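"""Domain containers for multi-site modified Poisson regression.

The parameter vector ``theta`` is always ordered ``(alpha, beta, gamma_1, ...,
gamma_{p-2})``: intercept first, then the binary exposure of interest, then
the adjustment covariates.  ``exp(beta)`` is the adjusted relative risk of the
exposure; ``exp(gamma_i)`` are the covariate relative risks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "SiteData",
    "LocalFit",
    "GradientPayload",
    "MetaEstimate",
    "FitResult",
    "Z_95",
]

#: critical value for 95% Wald intervals
Z_95 = 1.959964


@dataclass
class SiteData:
    """Subject-level data held by a single site.

    Parameters
    ----------
    outcomes : (n,) array of 0/1 ints
        Binary outcome indicator per subject.
    design : (n, p) float array
        Design matrix whose first column is the constant 1 (intercept),
        second column the binary exposure, remaining columns covariates.
    site_id : str
        Opaque site label.
    column_names : list of str, optional
        Names for the design columns (including ``"(intercept)"``).
    """

    outcomes: np.ndarray
    design: np.ndarray
    site_id: str = "site"
    column_names: list[str] | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.outcomes)
        X = np.asarray(self.design, dtype=float)
        if X.ndim != 2:
            raise ValidationError("design must be a 2-D matrix")
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise ValidationError(
                f"outcomes length {y.shape} does not match design rows {X.shape}"
            )
        if y.shape[0] < 1:
            raise ValidationError("a site must contain at least one subject")
        if not np.isin(y, (0, 1)).all():
            bad = np.flatnonzero(~np.isin(y, (0, 1)))
            raise ValidationError(
                f"outcome entries must be 0/1; offending rows: {bad[:10].tolist()}"
            )
        if not np.all(X[:, 0] == 1.0):
            raise ValidationError("first design column must be identically 1")
        if not np.isfinite(X).all():
            raise ValidationError("design contains non-finite entries")
        self.outcomes = y.astype(np.int8)
        self.design = X

    @property
    def n(self) -> int:
        """Number of subjects at this site."""
        return self.design.shape[0]

    @property
    def p(self) -> int:
        """Number of regression parameters (design columns)."""
        return self.design.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.outcomes.sum())


def check_theta(theta, p: int) -> np.ndarray:
    """Validate and coerce a coefficient vector of expected length ``p``."""
    t = np.asarray(theta, dtype=float).ravel()
    if t.shape[0] != p:
        raise ValidationError(f"theta has length {t.shape[0]}, design expects {p}")
    if not np.isfinite(t).all():
        raise ValidationError("theta contains non-finite entries")
    return t


@dataclass
class LocalFit:
    """A single site's modified-Poisson fit: estimate, robust covariance and
    convergence metadata (the initialization-step artifact)."""

    estimate: np.ndarray
    covariance: np.ndarray
    n: int
    converged: bool
    n_iter: int
    gradient_norm: float
    site_id: str = "site"

    @property
    def variance_diag(self) -> np.ndarray:
        return np.diag(self.covariance).copy()


@dataclass
class GradientPayload:
    """Aggregated statistics one site shares: its average score vector and
    average Hessian of the working Poisson log-likelihood, both evaluated at
    the broadcast initial value ``theta_bar``, plus its sample size."""

    site_id: str
    theta_bar: np.ndarray
    grad1: np.ndarray
    grad2: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.theta_bar = np.asarray(self.theta_bar, dtype=float)
        self.grad1 = np.asarray(self.grad1, dtype=float)
        self.grad2 = np.asarray(self.grad2, dtype=float)
        if not np.allclose(self.grad2, self.grad2.T, atol=1e-10):
            raise ValidationError("payload grad2 must be symmetric")


@dataclass
class MetaEstimate:
    """Fixed-effect inverse-variance combination of site estimates."""

    estimate: np.ndarray
    per_component_variance: np.ndarray
    sites_used: list[str] = field(default_factory=list)
    sites_dropped: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class FitResult:
    """Final estimator output for any of the three analysis routes.

    ``rr`` and the CI bounds cover the non-intercept coefficients only, on the
    relative-risk scale (exp of the coefficient and of its Wald bounds).
    """

    method: str  # "pooled" | "meta" | "odapb"
    estimate: np.ndarray
    covariance: np.ndarray
    rr: np.ndarray
    rr_ci_low: np.ndarray
    rr_ci_high: np.ndarray
    N: int
    K: int
    lead_site: str | None = None
    converged: bool = True
    n_iter: int = 0
    meta: MetaEstimate | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def make_fit_result(
    method: str,
    theta: np.ndarray,
    covariance: np.ndarray,
    N: int,
    K: int,
    lead_site: str | None = None,
    converged: bool = True,
    n_iter: int = 0,
    meta: MetaEstimate | None = None,
) -> FitResult:
    """Assemble a :class:`FitResult`, deriving RR point estimates and 95%
    Wald intervals for the non-intercept coefficients."""
    theta = np.asarray(theta, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    se = np.sqrt(np.clip(np.diag(covariance), 0.0, None))
    slope = theta[1:]
    slope_se = se[1:]
    return FitResult(
        method=method,
        estimate=theta,
        covariance=covariance,
        rr=np.exp(slope),
        rr_ci_low=np.exp(slope - Z_95 * slope_se),
        rr_ci_high=np.exp(slope + Z_95 * slope_se),
        N=int(N),
        K=int(K),
        lead_site=lead_site,
        converged=converged,
        n_iter=n_iter,
        meta=meta,
    )
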