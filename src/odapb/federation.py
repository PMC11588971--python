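"""The one-shot distributed protocol.

The pooled working log-likelihood over K sites cannot be formed without
subject-level data.  Instead the lead site builds a surrogate: its own
average log-likelihood, corrected to first and second order so that the
surrogate's gradient and curvature at the shared initial value ``theta_bar``
match the cross-site averages of the site gradients and Hessians,

    ls(theta) = l_lead(theta)
              + (gbar - g_lead)^T theta
              + 1/2 (theta - theta_bar)^T (Hbar - H_lead) (theta - theta_bar)

where ``gbar``/``Hbar`` aggregate the per-site payloads.  Maximizing ``ls``
gives the one-shot estimate; only aggregated statistics ever leave a site.

Two aggregation weightings are supported.  ``"sample_size"`` (default) uses
sum_k (n_k/N) grad_k, which makes the surrogate's gradient at ``theta_bar``
equal the pooled-data score exactly even when site sizes differ.
``"paper"`` is the unweighted (1/K) site average; the two coincide when all
sites are the same size.
"""

from __future__ import annotations

import numpy as np

from . import core
from .data import (
    FitResult,
    GradientPayload,
    LocalFit,
    MetaEstimate,
    SiteData,
    check_theta,
    make_fit_result,
)
from .errors import ProtocolError, SingularFitError

__all__ = [
    "meta_combine",
    "make_payload",
    "surrogate_loglik",
    "surrogate_score",
    "surrogate_hessian",
    "fit_odapb",
    "fit_pooled",
    "fit_meta",
    "fit_odapb_all_leads",
    "run_protocol",
    "concatenate_sites",
]

WEIGHTINGS = ("sample_size", "paper")


# ---------------------------------------------------------------------------
# Step 2: meta-analysis initialization


def meta_combine(fits: list[LocalFit]) -> MetaEstimate:
    """Fixed-effect inverse-variance pooling, componentwise.

    Sites whose local fit did not converge, or whose sandwich variance has a
    non-positive or non-finite diagonal entry, are dropped (with a recorded
    reason) rather than allowed to poison the initial value.
    """
    used: list[LocalFit] = []
    dropped: list[tuple[str, str]] = []
    for f in fits:
        if not f.converged:
            dropped.append((f.site_id, "local fit did not converge"))
            continue
        v = f.variance_diag
        if not np.isfinite(v).all() or (v <= 0).any():
            dropped.append((f.site_id, "non-positive or non-finite variance"))
            continue
        used.append(f)
    if not used:
        raise ProtocolError("meta-analysis has zero usable site fits")
    est = np.stack([f.estimate for f in used])
    w = 1.0 / np.stack([f.variance_diag for f in used])
    wsum = w.sum(axis=0)
    theta_bar = (w * est).sum(axis=0) / wsum
    return MetaEstimate(
        estimate=theta_bar,
        per_component_variance=1.0 / wsum,
        sites_used=[f.site_id for f in used],
        sites_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Step 3: gradient payloads


def make_payload(data: SiteData, theta_bar) -> GradientPayload:
    """Evaluate one site's average score and Hessian at the broadcast
    initial value; this is everything the site shares."""
    theta_bar = check_theta(theta_bar, data.p)
    return GradientPayload(
        site_id=data.site_id,
        theta_bar=theta_bar.copy(),
        grad1=core.score(data, theta_bar),
        grad2=core.hessian(data, theta_bar),
        n=data.n,
    )


def _serialized_theta(theta: np.ndarray) -> tuple[str, ...]:
    # float repr is the shortest exact decimal; equal doubles serialize equal
    return tuple(repr(float(v)) for v in theta)


def _check_payloads(
    lead: SiteData, payloads: list[GradientPayload]
) -> tuple[GradientPayload, np.ndarray]:
    if not payloads:
        raise ProtocolError("no gradient payloads supplied")
    ref = _serialized_theta(payloads[0].theta_bar)
    for p in payloads[1:]:
        if _serialized_theta(p.theta_bar) != ref:
            raise ProtocolError(
                f"payload {p.site_id!r} was evaluated at a different "
                "theta_bar than the others"
            )
    lead_payloads = [p for p in payloads if p.site_id == lead.site_id]
    if not lead_payloads:
        raise ProtocolError(
            f"lead site {lead.site_id!r} has no payload among those supplied"
        )
    theta_bar = check_theta(payloads[0].theta_bar, lead.p)
    return lead_payloads[0], theta_bar


def _aggregate(
    payloads: list[GradientPayload], weighting: str
) -> tuple[np.ndarray, np.ndarray]:
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    if weighting == "paper":
        w = np.full(len(payloads), 1.0 / len(payloads))
    else:
        n = np.array([p.n for p in payloads], dtype=float)
        w = n / n.sum()
    gbar = sum(wk * p.grad1 for wk, p in zip(w, payloads))
    Hbar = sum(wk * p.grad2 for wk, p in zip(w, payloads))
    return gbar, Hbar


# ---------------------------------------------------------------------------
# Step 4: surrogate likelihood and the one-shot estimator


def surrogate_loglik(
    lead: SiteData,
    payloads: list[GradientPayload],
    theta,
    weighting: str = "sample_size",
) -> float:
    """Value of the surrogate log-likelihood at ``theta``."""
    lead_payload, theta_bar = _check_payloads(lead, payloads)
    theta = check_theta(theta, lead.p)
    gbar, Hbar = _aggregate(payloads, weighting)
    d = theta - theta_bar
    dH = Hbar - lead_payload.grad2
    return (
        core.log_likelihood(lead, theta)
        + float((gbar - lead_payload.grad1) @ theta)
        + 0.5 * float(d @ dH @ d)
    )


def surrogate_score(
    lead: SiteData,
    payloads: list[GradientPayload],
    theta,
    weighting: str = "sample_size",
) -> np.ndarray:
    """Gradient of the surrogate log-likelihood at ``theta``."""
    lead_payload, theta_bar = _check_payloads(lead, payloads)
    theta = check_theta(theta, lead.p)
    gbar, Hbar = _aggregate(payloads, weighting)
    return (
        core.score(lead, theta)
        + (gbar - lead_payload.grad1)
        + (Hbar - lead_payload.grad2) @ (theta - theta_bar)
    )


def surrogate_hessian(
    lead: SiteData,
    payloads: list[GradientPayload],
    theta,
    weighting: str = "sample_size",
) -> np.ndarray:
    """Hessian of the surrogate log-likelihood at ``theta``."""
    lead_payload, _ = _check_payloads(lead, payloads)
    theta = check_theta(theta, lead.p)
    gbar, Hbar = _aggregate(payloads, weighting)
    return core.hessian(lead, theta) + (Hbar - lead_payload.grad2)


def fit_odapb(
    lead: SiteData,
    payloads: list[GradientPayload],
    weighting: str = "sample_size",
    tol: float = 1e-8,
    max_iter: int = 100,
    max_halvings: int = 50,
    variance_payloads: list[GradientPayload] | None = None,
) -> FitResult:
    """Maximize the surrogate likelihood from ``theta_bar`` (Newton with
    step halving) and attach the robust one-shot covariance.

    The default covariance uses the lead site's bread and meat at the
    solution, scaled by the total sample size N: ``B^-1 M B^-1 / N`` with
    ``B = -hessian_lead`` and ``M`` the lead's average per-subject score
    outer product.  If ``variance_payloads`` (site Hessians re-evaluated at
    the solution, one extra communication round) are given, the bread is the
    aggregated Hessian instead.
    """
    lead_payload, theta_bar = _check_payloads(lead, payloads)
    gbar, Hbar = _aggregate(payloads, weighting)
    N = int(sum(p.n for p in payloads))
    dH = Hbar - lead_payload.grad2

    def ls(theta: np.ndarray) -> float:
        d = theta - theta_bar
        return (
            core.log_likelihood(lead, theta)
            + float((gbar - lead_payload.grad1) @ theta)
            + 0.5 * float(d @ dH @ d)
        )

    def ls_grad(theta: np.ndarray) -> np.ndarray:
        return (
            core.score(lead, theta)
            + (gbar - lead_payload.grad1)
            + dH @ (theta - theta_bar)
        )

    theta = theta_bar.copy()
    value = ls(theta)
    converged = False
    n_iter = 0
    g = ls_grad(theta)
    for n_iter in range(1, max_iter + 1):
        g = ls_grad(theta)
        if np.abs(g).max() <= tol:
            converged = True
            break
        H = core.hessian(lead, theta) + dH
        try:
            direction = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError as exc:
            raise SingularFitError("singular surrogate Hessian") from exc
        step = 1.0
        for _ in range(max_halvings):
            candidate = theta + step * direction
            v_new = ls(candidate)
            if v_new >= value:  # see core.fit_mle on the >= acceptance
                break
            step /= 2.0
        else:
            break
        theta = theta + step * direction
        value = ls(theta)
    if np.abs(ls_grad(theta)).max() <= tol:
        converged = True

    if variance_payloads is not None:
        _, Hbar_tilde = _aggregate(variance_payloads, weighting)
        B = -Hbar_tilde
    else:
        B = -core.hessian(lead, theta)
    S = core.per_subject_scores(lead, theta)
    M = S.T @ S / lead.n
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise SingularFitError("singular bread in one-shot variance") from exc
    cov = Binv @ M @ Binv / N
    cov = (cov + cov.T) / 2.0
    if not converged:
        cov = np.full_like(cov, np.nan)
    return make_fit_result(
        "odapb",
        theta,
        cov,
        N=N,
        K=len(payloads),
        lead_site=lead.site_id,
        converged=converged,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Baselines


def concatenate_sites(sites: list[SiteData]) -> SiteData:
    """Stack all subject rows into one pseudo-site (pooled analysis input)."""
    if not sites:
        raise ProtocolError("no sites supplied")
    p = sites[0].p
    for s in sites[1:]:
        if s.p != p:
            raise ProtocolError("sites have incompatible design dimensions")
    return SiteData(
        outcomes=np.concatenate([s.outcomes for s in sites]),
        design=np.vstack([s.design for s in sites]),
        site_id="pooled",
        column_names=sites[0].column_names,
    )


def fit_pooled(
    sites: list[SiteData], tol: float = 1e-8, max_iter: int = 100
) -> FitResult:
    """Gold-standard analysis on the concatenated subject-level data."""
    pooled = concatenate_sites(sites)
    fit = core.fit_mle(pooled, tol=tol, max_iter=max_iter)
    return make_fit_result(
        "pooled",
        fit.estimate,
        fit.covariance,
        N=pooled.n,
        K=len(sites),
        converged=fit.converged,
        n_iter=fit.n_iter,
    )


def fit_meta(
    sites: list[SiteData], tol: float = 1e-8, max_iter: int = 100
) -> FitResult:
    """Two-step meta-analysis: per-site fits, then inverse-variance pooling.

    The combined covariance is diagonal because pooling is componentwise.
    Sites that fail to fit are dropped and recorded on the result.
    """
    fits = local_fits(sites, tol=tol, max_iter=max_iter)
    me = meta_combine(fits)
    N = sum(s.n for s in sites)
    return make_fit_result(
        "meta",
        me.estimate,
        np.diag(me.per_component_variance),
        N=N,
        K=len(sites),
        converged=True,
        meta=me,
    )


def local_fits(
    sites: list[SiteData], tol: float = 1e-8, max_iter: int = 100
) -> list[LocalFit]:
    """Step-1 fits for every site; fit failures become non-converged records
    with infinite variance so downstream combination drops them."""
    out: list[LocalFit] = []
    for s in sites:
        try:
            out.append(core.fit_mle(s, tol=tol, max_iter=max_iter))
        except Exception:
            out.append(
                LocalFit(
                    estimate=np.full(s.p, np.nan),
                    covariance=np.full((s.p, s.p), np.inf),
                    n=s.n,
                    converged=False,
                    n_iter=0,
                    gradient_norm=np.inf,
                    site_id=s.site_id,
                )
            )
    return out


def run_protocol(
    sites: list[SiteData],
    lead_index: int = 0,
    weighting: str = "sample_size",
    tol: float = 1e-8,
    max_iter: int = 100,
    init_from_site: str | None = None,
    variance: str = "lead",
) -> FitResult:
    """Execute the full four-step protocol in process.

    Convenience wrapper for simulations and the estimator API: local fits,
    meta-analysis initial value (or a named site's local fit), payloads at
    ``theta_bar``, surrogate solve at the lead site.
    """
    lead = sites[lead_index]
    fits = local_fits(sites, tol=tol, max_iter=max_iter)
    if init_from_site is not None:
        matches = [f for f in fits if f.site_id == init_from_site and f.converged]
        if not matches:
            raise ProtocolError(
                f"no convergent local fit for init site {init_from_site!r}"
            )
        theta_bar = matches[0].estimate
    else:
        theta_bar = meta_combine(fits).estimate
    payloads = [make_payload(s, theta_bar) for s in sites]
    result = fit_odapb(
        lead, payloads, weighting=weighting, tol=tol, max_iter=max_iter
    )
    if variance == "aggregated":
        vp = [make_payload(s, result.estimate) for s in sites]
        result = fit_odapb(
            lead,
            payloads,
            weighting=weighting,
            tol=tol,
            max_iter=max_iter,
            variance_payloads=vp,
        )
    return result


def fit_odapb_all_leads(
    sites: list[SiteData],
    weighting: str = "sample_size",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Run the protocol once with every site as lead and inverse-variance
    combine the K one-shot estimates (componentwise)."""
    fits = local_fits(sites, tol=tol, max_iter=max_iter)
    theta_bar = meta_combine(fits).estimate
    payloads = [make_payload(s, theta_bar) for s in sites]
    results = [
        fit_odapb(lead, payloads, weighting=weighting, tol=tol, max_iter=max_iter)
        for lead in sites
    ]
    pseudo = [
        LocalFit(
            estimate=r.estimate,
            covariance=r.covariance,
            n=r.N,
            converged=r.converged,
            n_iter=r.n_iter,
            gradient_norm=0.0,
            site_id=r.lead_site or "",
        )
        for r in results
    ]
    me = meta_combine(pseudo)
    N = sum(s.n for s in sites)
    return make_fit_result(
        "odapb",
        me.estimate,
        np.diag(me.per_component_variance),
        N=N,
        K=len(sites),
        meta=me,
    )
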