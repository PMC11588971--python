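"""Synthetic multi-site study generator and replication engine.

The generator emulates a clinical-research-network design: K sites of equal
size, a binary exposure X1 ~ Bernoulli(0.3) (e.g. a medication), two binary
covariates Z1 ~ Bernoulli(0.6), Z2 ~ Bernoulli(0.5) (e.g. sex, chronic
condition), one continuous covariate Z3 (an age stand-in, standard normal by
default), and a binary outcome drawn with risk

    P(Y = 1 | X, Z) = exp(alpha + beta1 X1 + gamma1 Z1 + gamma2 Z2 + gamma3 Z3).

With the default negative coefficients and alpha <= -2 the risk stays well
below 1; any row whose linear risk would exceed 1 is clipped to 1 and
counted, and a clip rate above 1% flags the scenario as outside the intended
rare/common-disease regime.

The replication engine fits the pooled, meta-analysis and one-shot
distributed (ODAP-B) estimators on each replicate and records the relative
bias of each federated method's exposure coefficient against the pooled fit,
(beta1_method - beta1_pooled) / |beta1_pooled|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import federation
from .data import SiteData
from .errors import ProtocolError, ValidationError

__all__ = [
    "ScenarioConfig",
    "ReplicationRecord",
    "generate_sites",
    "run_scenario",
    "type1_error",
    "summarize",
]

METHODS = ("pooled", "meta", "odapb")


@dataclass
class ScenarioConfig:
    """Parameters of one simulation scenario.

    Defaults are the common-disease study conditions: 5 sites of 500
    subjects, intercept -2 (marginal event rate ~11-12%), exposure log-RR
    -0.25, covariate log-RRs -0.1 each, 1000 replications.
    """

    K: int = 5
    n_per_site: int = 500
    alpha: float = -2.0
    beta1: float = -0.25
    gamma: tuple[float, float, float] = (-0.1, -0.1, -0.1)
    p_x1: float = 0.3
    p_z1: float = 0.6
    p_z2: float = 0.5
    age_dist: tuple = ("normal", 0.0, 1.0)
    n_reps: int = 1000
    base_seed: int = 20240

    def __post_init__(self) -> None:
        for name in ("p_x1", "p_z1", "p_z2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} must lie in (0, 1)")
        if self.n_per_site < 2:
            raise ValidationError("n_per_site must be >= 2")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if len(self.gamma) != 3:
            raise ValidationError("gamma must have length 3")

    @property
    def theta(self) -> np.ndarray:
        """True coefficient vector (alpha, beta1, gamma1, gamma2, gamma3)."""
        return np.array([self.alpha, self.beta1, *self.gamma], dtype=float)


@dataclass
class ReplicationRecord:
    """Per-replicate estimates and diagnostics."""

    rep_id: int
    seed_entropy: tuple[int, int]
    estimates: dict[str, np.ndarray] = field(default_factory=dict)
    se_beta1: dict[str, float] = field(default_factory=dict)
    converged: dict[str, bool] = field(default_factory=dict)
    relative_bias: dict[str, float] = field(default_factory=dict)
    event_count: int = 0
    clip_count: int = 0


def _draw_age(rng: np.random.Generator, spec: tuple, size: int) -> np.ndarray:
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size)
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size)
    if kind == "empirical":
        values = np.asarray(spec[1], dtype=float)
        return rng.choice(values, size=size, replace=True)
    raise ValidationError(f"unknown age_dist kind {kind!r}")


def generate_sites(
    config: ScenarioConfig, rep_seed: int, return_clip_count: bool = False
):
    """Draw one replicate: a list of K SiteData, deterministic in
    (base_seed, rep_seed, site index)."""
    sites: list[SiteData] = []
    theta = config.theta
    clipped = 0
    for i in range(config.K):
        rng = np.random.default_rng(
            np.random.SeedSequence((config.base_seed, rep_seed, i))
        )
        n = config.n_per_site
        X1 = rng.binomial(1, config.p_x1, n)
        Z1 = rng.binomial(1, config.p_z1, n)
        Z2 = rng.binomial(1, config.p_z2, n)
        Z3 = _draw_age(rng, config.age_dist, n)
        design = np.column_stack([np.ones(n), X1, Z1, Z2, Z3])
        risk = np.exp(design @ theta)
        clipped += int((risk > 1.0).sum())
        y = rng.binomial(1, np.minimum(risk, 1.0))
        sites.append(
            SiteData(
                outcomes=y,
                design=design,
                site_id=f"site{i + 1}",
                column_names=["(intercept)", "x1", "z1", "z2", "z3"],
            )
        )
    total = config.K * config.n_per_site
    if clipped / total > 0.01:
        warnings.warn(
            f"risk clipped to 1 for {clipped}/{total} subjects (> 1%); the "
            "scenario is outside the intended log-link regime",
            RuntimeWarning,
            stacklevel=2,
        )
    if return_clip_count:
        return sites, clipped
    return sites


def _fit_all(
    sites: list[SiteData],
    weighting: str,
    tol: float,
    max_iter: int,
) -> dict[str, federation.FitResult | None]:
    """Fit the three estimators, sharing the step-1 local fits between the
    meta and one-shot routes."""
    out: dict[str, federation.FitResult | None] = {}
    try:
        out["pooled"] = federation.fit_pooled(sites, tol=tol, max_iter=max_iter)
    except Exception:
        out["pooled"] = None
    fits = federation.local_fits(sites, tol=tol, max_iter=max_iter)
    try:
        me = federation.meta_combine(fits)
    except ProtocolError:
        me = None
    if me is None:
        out["meta"] = None
        out["odapb"] = None
        return out
    N = sum(s.n for s in sites)
    out["meta"] = federation.make_fit_result(
        "meta",
        me.estimate,
        np.diag(me.per_component_variance),
        N=N,
        K=len(sites),
        meta=me,
    )
    try:
        payloads = [federation.make_payload(s, me.estimate) for s in sites]
        out["odapb"] = federation.fit_odapb(
            sites[0], payloads, weighting=weighting, tol=tol, max_iter=max_iter
        )
    except Exception:
        out["odapb"] = None
    return out


def run_scenario(
    config: ScenarioConfig,
    n_reps: int | None = None,
    weighting: str = "sample_size",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> list[ReplicationRecord]:
    """Run the replication study: generate, fit all three methods (lead =
    site 1, meta-analysis initialization), record estimates and the relative
    bias of beta1 to the pooled fit.

    Individual fit failures are recorded, not fatal; but if more than 20% of
    pooled fits fail the scenario aborts with a diagnostic.
    """
    reps = config.n_reps if n_reps is None else n_reps
    records: list[ReplicationRecord] = []
    pooled_failures = 0
    for rep in range(reps):
        sites, clipped = generate_sites(config, rep, return_clip_count=True)
        rec = ReplicationRecord(
            rep_id=rep,
            seed_entropy=(config.base_seed, rep),
            event_count=int(sum(s.n_events for s in sites)),
            clip_count=clipped,
        )
        results = _fit_all(sites, weighting, tol, max_iter)
        for m in METHODS:
            r = results[m]
            if r is None:
                rec.estimates[m] = np.full(5, np.nan)
                rec.se_beta1[m] = np.nan
                rec.converged[m] = False
            else:
                rec.estimates[m] = r.estimate
                rec.se_beta1[m] = float(r.se[1])
                rec.converged[m] = bool(r.converged)
        pooled_ok = rec.converged["pooled"]
        if not pooled_ok:
            pooled_failures += 1
        b_pooled = rec.estimates["pooled"][1]
        for m in ("meta", "odapb"):
            if pooled_ok and rec.converged[m] and b_pooled != 0:
                rec.relative_bias[m] = float(
                    (rec.estimates[m][1] - b_pooled) / abs(b_pooled)
                )
            else:
                rec.relative_bias[m] = np.nan
        records.append(rec)
    if pooled_failures > 0.2 * reps:
        raise RuntimeError(
            f"pooled analysis failed in {pooled_failures}/{reps} replications "
            "(> 20%); the scenario is too sparse to serve as a gold standard"
        )
    return records


def type1_error(
    config: ScenarioConfig,
    nominal: float = 0.05,
    n_reps: int | None = None,
    weighting: str = "sample_size",
) -> pd.DataFrame:
    """Empirical size of the Wald test of beta1 = 0 for each method.

    Requires a null configuration (beta1 == 0).  Each method's own standard
    error is used.  Returns per-method rejection proportions with their
    binomial Monte-Carlo standard errors and the number of usable replicates.
    """
    if config.beta1 != 0.0:
        raise ValidationError("type-I error study requires beta1 = 0")
    if not 0.0 < nominal <= 1.0:
        raise ValidationError("nominal level must lie in (0, 1]")
    crit = stats.norm.ppf(1.0 - nominal / 2.0) if nominal < 1.0 else 0.0
    records = run_scenario(config, n_reps=n_reps, weighting=weighting)
    rows = []
    for m in METHODS:
        z = np.array(
            [
                r.estimates[m][1] / r.se_beta1[m] if r.converged[m] else np.nan
                for r in records
            ]
        )
        usable = np.isfinite(z)
        rate = float(np.mean(np.abs(z[usable]) >= crit)) if usable.any() else np.nan
        n_used = int(usable.sum())
        mc_se = (
            float(np.sqrt(rate * (1.0 - rate) / n_used)) if n_used else np.nan
        )
        rows.append(
            {"method": m, "rejection_rate": rate, "mc_se": mc_se, "n_used": n_used}
        )
    return pd.DataFrame(rows).set_index("method")


def summarize(records: list[ReplicationRecord], truth_beta1: float | None = None):
    """Per-method summary of a replication study as a tidy DataFrame:
    mean/median relative bias (and their absolute-value medians), empirical
    SD of the beta1 estimate, MSE against the truth if given, and the
    convergence rate."""
    if not records:
        raise ValidationError("summarize needs at least one record")
    rows = []
    for m in METHODS:
        b1 = np.array([r.estimates[m][1] for r in records])
        conv = np.array([r.converged[m] for r in records])
        ok = conv & np.isfinite(b1)
        row = {
            "method": m,
            "n_reps": len(records),
            "convergence_rate": float(conv.mean()),
            "beta1_mean": float(np.mean(b1[ok])) if ok.any() else np.nan,
            "beta1_sd": float(np.std(b1[ok], ddof=1)) if ok.sum() > 1 else np.nan,
        }
        if truth_beta1 is not None and ok.any():
            row["beta1_mse"] = float(np.mean((b1[ok] - truth_beta1) ** 2))
        else:
            row["beta1_mse"] = np.nan
        if m in ("meta", "odapb"):
            rb = np.array([r.relative_bias[m] for r in records])
            rb = rb[np.isfinite(rb)]
            row["rel_bias_mean"] = float(np.mean(rb)) if rb.size else np.nan
            row["rel_bias_median"] = float(np.median(rb)) if rb.size else np.nan
            row["abs_rel_bias_median"] = (
                float(np.median(np.abs(rb))) if rb.size else np.nan
            )
        else:
            row["rel_bias_mean"] = 0.0 if ok.any() else np.nan
            row["rel_bias_median"] = 0.0 if ok.any() else np.nan
            row["abs_rel_bias_median"] = 0.0 if ok.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")
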