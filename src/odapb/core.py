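"""Modified Poisson regression primitives for one dataset.

Binary outcomes are fit with a Poisson working model under a log link, so
that ``exp`` of a slope coefficient is a relative risk.  Because the Poisson
distribution is deliberately misspecified for 0/1 data, inference uses the
robust sandwich covariance (Zou's estimator) rather than the model-based one.

All likelihood quantities here are averaged per subject (divided by ``n``):
the log-likelihood, score and Hessian of one site are

    l(theta)   = (1/n) sum_j [ y_j eta_j - exp(eta_j) ]
    grad l     = (1/n) sum_j x_j (y_j - exp(eta_j))
    grad^2 l   = -(1/n) sum_j exp(eta_j) x_j x_j^T

with ``eta_j = x_j . theta``.  The ``log y!`` term vanishes for 0/1 outcomes.
Averaging keeps site payloads on a common scale regardless of site size.
"""

from __future__ import annotations

import numpy as np

from .data import LocalFit, SiteData, check_theta
from .errors import (
    LinearPredictorOverflowError,
    NonConvergenceError,
    SingularFitError,
)

__all__ = [
    "log_likelihood",
    "score",
    "hessian",
    "per_subject_scores",
    "fit_mle",
    "sandwich_variance",
    "default_init",
]

# exp() overflows a float64 just above exp(709); 700 leaves headroom for sums.
_ETA_MAX = 700.0


def _eta(data: SiteData, theta) -> np.ndarray:
    theta = check_theta(theta, data.p)
    return data.design @ theta


def log_likelihood(data: SiteData, theta) -> float:
    """Average working Poisson log-likelihood.

    Returns ``-inf`` when a linear predictor overflows ``exp`` — the limit of
    the likelihood as any fitted mean diverges — so line searches can reject
    such steps without corrupting gradients.
    """
    eta = _eta(data, theta)
    if eta.max(initial=-np.inf) > _ETA_MAX:
        return -np.inf
    return float(np.mean(data.outcomes * eta - np.exp(eta)))


def score(data: SiteData, theta) -> np.ndarray:
    """Average score vector ``(1/n) X^T (y - exp(X theta))``."""
    eta = _eta(data, theta)
    _guard(eta)
    return data.design.T @ (data.outcomes - np.exp(eta)) / data.n


def hessian(data: SiteData, theta) -> np.ndarray:
    """Average Hessian ``-(1/n) X^T diag(exp(X theta)) X``; negative
    semidefinite for every ``theta`` (the working likelihood is concave)."""
    eta = _eta(data, theta)
    _guard(eta)
    w = np.exp(eta)
    H = -(data.design.T * w) @ data.design / data.n
    return (H + H.T) / 2.0


def per_subject_scores(data: SiteData, theta) -> np.ndarray:
    """(n, p) matrix of per-subject score contributions ``x_j (y_j - mu_j)``."""
    eta = _eta(data, theta)
    _guard(eta)
    resid = data.outcomes - np.exp(eta)
    return data.design * resid[:, None]


def _guard(eta: np.ndarray) -> None:
    m = np.abs(eta).max(initial=0.0)
    if m > _ETA_MAX:
        raise LinearPredictorOverflowError(
            f"|linear predictor| reached {m:.1f} > {_ETA_MAX:g}; refusing to "
            "evaluate exp() — check the data scaling or the coefficient vector"
        )


def default_init(data: SiteData) -> np.ndarray:
    """Moment-matched start: intercept at log of the event rate (floored at
    1/(2n) so zero-event data do not produce log 0), slopes at 0."""
    theta0 = np.zeros(data.p)
    rate = max(float(np.mean(data.outcomes)), 1.0 / (2 * data.n))
    theta0[0] = np.log(rate)
    return theta0


def sandwich_variance(data: SiteData, theta_hat) -> np.ndarray:
    """Robust (sandwich) covariance of the modified-Poisson estimate.

    ``B^{-1} M B^{-1} / n`` with bread ``B = -hessian(theta_hat)`` and meat
    ``M`` the average outer product of per-subject scores.  Equivalent to the
    textbook HC0 covariance for a Poisson/log-link fit.
    """
    theta_hat = check_theta(theta_hat, data.p)
    B = -hessian(data, theta_hat)
    S = per_subject_scores(data, theta_hat)
    M = S.T @ S / data.n
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise SingularFitError("singular bread matrix in sandwich variance") from exc
    V = Binv @ M @ Binv / data.n
    return (V + V.T) / 2.0


def fit_mle(
    data: SiteData,
    init=None,
    tol: float = 1e-8,
    max_iter: int = 100,
    max_halvings: int = 50,
) -> LocalFit:
    """Maximize the working log-likelihood by Newton–Raphson with step halving.

    The working likelihood is globally concave, so full Newton steps with a
    monotone line search converge to the unique stationary point whenever one
    exists.  Convergence is declared when the max-abs score drops to ``tol``.

    Raises
    ------
    NonConvergenceError
        If no event is present (the intercept diverges to -inf).
    SingularFitError
        If the design is rank deficient or a Hessian solve fails.
    """
    if data.n_events == 0:
        raise NonConvergenceError(
            f"site {data.site_id!r}: no events (all outcomes 0); the working "
            "MLE does not exist"
        )
    if np.linalg.matrix_rank(data.design) < data.p:
        raise SingularFitError(
            f"site {data.site_id!r}: design matrix is rank deficient"
        )

    theta = default_init(data) if init is None else check_theta(init, data.p)
    ll = log_likelihood(data, theta)
    converged = False
    g = score(data, theta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g = score(data, theta)
        if np.abs(g).max() <= tol:
            converged = True
            n_iter -= 1
            break
        H = hessian(data, theta)
        try:
            direction = np.linalg.solve(-H, g)  # ascent direction
        except np.linalg.LinAlgError as exc:
            raise SingularFitError(
                f"site {data.site_id!r}: singular Hessian at iteration {n_iter}"
            ) from exc
        step = 1.0
        for _ in range(max_halvings):
            candidate = theta + step * direction
            ll_new = log_likelihood(data, candidate)
            # >= : near the optimum the gain underflows the double resolution
            # of ll; rejecting those steps would stall above tight tolerances
            if ll_new >= ll:
                break
            step /= 2.0
        else:
            break  # no ascent found within the halving budget
        theta = theta + step * direction
        ll = log_likelihood(data, theta)
    g = score(data, theta)
    if np.abs(g).max() <= tol:
        converged = True

    cov = sandwich_variance(data, theta)
    return LocalFit(
        estimate=theta,
        covariance=cov,
        n=data.n,
        converged=converged,
        n_iter=n_iter,
        gradient_norm=float(np.abs(g).max()),
        site_id=data.site_id,
    )
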