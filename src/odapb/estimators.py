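"""scikit-learn style estimators over the modified Poisson machinery.

These classes adapt the protocol functions to the familiar ``fit(X, y)``
surface so they compose with sklearn pipelines and model selection.  ``X``
is passed WITHOUT an intercept column (one is prepended internally); column
0 of ``X`` is treated as the exposure of interest for relative-risk
reporting.  Multi-site estimators take the site membership as a ``groups``
array, mirroring sklearn's grouped cross-validation conventions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import core, federation
from .data import SiteData, Z_95

__all__ = [
    "ModifiedPoissonRegression",
    "MetaAnalysisPoisson",
    "ODAPBRegression",
]


def _as_site(X, y, site_id="site"):
    X, y = check_X_y(X, y, dtype=float)
    design = np.column_stack([np.ones(len(y)), X])
    return SiteData(outcomes=np.asarray(y, dtype=int), design=design, site_id=site_id)


def _split_sites(X, y, groups):
    X, y = check_X_y(X, y, dtype=float)
    groups = np.asarray(groups)
    if groups.shape[0] != X.shape[0]:
        raise ValueError("groups must have one entry per row of X")
    sites = []
    for g in dict.fromkeys(groups.tolist()):  # first-appearance order
        mask = groups == g
        design = np.column_stack([np.ones(int(mask.sum())), X[mask]])
        sites.append(SiteData(outcomes=y[mask].astype(int), design=design, site_id=str(g)))
    return sites


class _RelativeRiskMixin:
    """Shared post-fit API: coefficients, robust SEs, RRs and Wald CIs."""

    def _finalize(self, theta: np.ndarray, covariance: np.ndarray) -> None:
        self.intercept_ = float(theta[0])
        self.coef_ = theta[1:].copy()
        self.theta_ = theta.copy()
        self.covariance_ = covariance
        self.se_ = np.sqrt(np.clip(np.diag(covariance), 0.0, None))

    def predict(self, X):
        """Predicted outcome risk exp(alpha + X beta); may exceed 1, which is
        intrinsic to the log-link working model."""
        check_is_fitted(self, "theta_")
        X = check_array(X, dtype=float)
        return np.exp(self.intercept_ + X @ self.coef_)

    def relative_risk(self):
        """exp of each slope coefficient (column 0 of X is the exposure)."""
        check_is_fitted(self, "theta_")
        return np.exp(self.coef_)

    def conf_int(self):
        """(p-1, 2) array of 95% Wald CI bounds on the relative-risk scale."""
        check_is_fitted(self, "theta_")
        se = self.se_[1:]
        return np.column_stack(
            [np.exp(self.coef_ - Z_95 * se), np.exp(self.coef_ + Z_95 * se)]
        )


class ModifiedPoissonRegression(_RelativeRiskMixin, BaseEstimator):
    """Single-dataset modified Poisson regression (log link, robust SEs).

    Parameters
    ----------
    tol : float, default 1e-8
        Convergence tolerance on the max-abs average score.
    max_iter : int, default 100
        Newton iteration cap.

    Attributes
    ----------
    coef_, intercept_ : slope coefficients (log-RR scale) and intercept.
    covariance_ : robust sandwich covariance of (intercept, coef_).
    se_ : robust standard errors.
    converged_, n_iter_ : Newton diagnostics.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        data = _as_site(X, y)
        fit = core.fit_mle(data, tol=self.tol, max_iter=self.max_iter)
        self._finalize(fit.estimate, fit.covariance)
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        self.n_features_in_ = data.p - 1
        return self


class MetaAnalysisPoisson(_RelativeRiskMixin, BaseEstimator):
    """Two-step meta-analysis: per-site modified Poisson fits combined by
    fixed-effect inverse-variance weighting, componentwise.

    ``fit`` requires ``groups`` (site label per row).  The covariance is
    diagonal by construction.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("MetaAnalysisPoisson.fit requires groups")
        sites = _split_sites(X, y, groups)
        result = federation.fit_meta(sites, tol=self.tol, max_iter=self.max_iter)
        self._finalize(result.estimate, result.covariance)
        self.result_ = result
        self.sites_dropped_ = result.meta.sites_dropped
        self.n_features_in_ = sites[0].p - 1
        return self


class ODAPBRegression(_RelativeRiskMixin, BaseEstimator):
    """One-shot distributed modified Poisson regression.

    Runs the full four-step protocol in process: per-site fits, fixed-effect
    meta-analysis initial value, gradient payloads, surrogate-likelihood
    solve at the lead site.  Only the lead site's subject-level rows enter
    the final solve; all other sites contribute aggregated gradients.

    Parameters
    ----------
    lead : site label or None
        Which group acts as lead; None means the first group encountered.
    weighting : {"sample_size", "paper"}
        Cross-site gradient aggregation (see ``odapb.federation``).
    variance : {"lead", "aggregated"}
        Robust variance from lead-site quantities only (one-shot budget) or
        with the cross-site bread re-evaluated at the solution.
    """

    def __init__(
        self,
        lead=None,
        weighting: str = "sample_size",
        variance: str = "lead",
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.lead = lead
        self.weighting = weighting
        self.variance = variance
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, groups=None):
        if groups is None:
            groups = np.zeros(len(np.asarray(y)), dtype=int)
        sites = _split_sites(X, y, groups)
        lead_index = 0
        if self.lead is not None:
            ids = [s.site_id for s in sites]
            if str(self.lead) not in ids:
                raise ValueError(f"lead {self.lead!r} not among groups {ids}")
            lead_index = ids.index(str(self.lead))
        result = federation.run_protocol(
            sites,
            lead_index=lead_index,
            weighting=self.weighting,
            tol=self.tol,
            max_iter=self.max_iter,
            variance=self.variance,
        )
        self._finalize(result.estimate, result.covariance)
        self.result_ = result
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.lead_site_ = result.lead_site
        self.n_features_in_ = sites[0].p - 1
        return self
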