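"""Tests for the one-shot protocol: meta initialization, payloads,
surrogate likelihood and the three fitting routes."""

import numpy as np
import pytest

from odapb import core, federation
from odapb.data import LocalFit, SiteData
from odapb.errors import ProtocolError
from odapb.federation import (
    concatenate_sites,
    fit_meta,
    fit_odapb,
    fit_odapb_all_leads,
    fit_pooled,
    local_fits,
    make_payload,
    meta_combine,
    run_protocol,
    surrogate_loglik,
    surrogate_score,
)

from conftest import random_site
from test_core import numeric_gradient


def _local_fit(est, var, site_id="s", converged=True):
    est = np.atleast_1d(np.asarray(est, dtype=float))
    var = np.atleast_1d(np.asarray(var, dtype=float))
    return LocalFit(
        estimate=est,
        covariance=np.diag(var),
        n=10,
        converged=converged,
        n_iter=3,
        gradient_norm=0.0,
        site_id=site_id,
    )


class TestMetaCombine:
    def test_equal_weights(self):
        me = meta_combine([_local_fit(1.0, 1.0, "a"), _local_fit(3.0, 1.0, "b")])
        assert me.estimate[0] == pytest.approx(2.0)
        assert me.per_component_variance[0] == pytest.approx(0.5)

    def test_identical_fits_collapse(self):
        fits = [_local_fit(0.7, 0.2, f"s{i}") for i in range(4)]
        me = meta_combine(fits)
        assert me.estimate[0] == pytest.approx(0.7)
        assert me.per_component_variance[0] == pytest.approx(0.2 / 4)

    def test_hand_inverse_variance(self):
        me = meta_combine(
            [_local_fit(0.5, 0.25, "a"), _local_fit(1.5, 0.75, "b")]
        )
        assert me.estimate[0] == pytest.approx(0.75)
        assert me.per_component_variance[0] == pytest.approx(0.1875)

    def test_drops_non_converged(self):
        good = _local_fit(1.0, 1.0, "good")
        bad = _local_fit(9.0, 1.0, "bad", converged=False)
        me = meta_combine([good, bad])
        assert me.estimate[0] == pytest.approx(1.0)
        assert me.sites_dropped == [("bad", "local fit did not converge")]

    def test_no_usable_sites_raises(self):
        with pytest.raises(ProtocolError):
            meta_combine([_local_fit(1.0, 1.0, converged=False)])


class TestMakePayload:
    def test_single_row_values(self):
        d = SiteData(outcomes=np.array([0]), design=np.ones((1, 1)), site_id="a")
        p = make_payload(d, [0.0])
        np.testing.assert_allclose(p.grad1, [-1.0])
        np.testing.assert_allclose(p.grad2, [[-1.0]])
        assert p.n == 1

    def test_stationarity_at_own_mle(self, two_group_site):
        fit = core.fit_mle(two_group_site, tol=1e-10)
        p = make_payload(two_group_site, fit.estimate)
        assert np.abs(p.grad1).max() < 1e-9

    def test_is_definitional_wrapper(self, three_sites):
        theta = np.r_[-1.0, 0.1, -0.1, 0.05]
        p = make_payload(three_sites[0], theta)
        assert np.array_equal(p.grad1, core.score(three_sites[0], theta))
        assert np.array_equal(p.grad2, core.hessian(three_sites[0], theta))


class TestSurrogate:
    def test_single_site_reduces_to_local_likelihood(self, three_sites):
        lead = three_sites[0]
        theta_bar = np.r_[-1.0, 0.0, 0.0, 0.0]
        payloads = [make_payload(lead, theta_bar)]
        for shift in (0.0, 0.3, -0.5):
            theta = theta_bar + shift
            assert surrogate_loglik(lead, payloads, theta) == pytest.approx(
                core.log_likelihood(lead, theta), abs=1e-12
            )

    def test_identical_sites_cancel_corrections(self, three_sites):
        lead = three_sites[0]
        theta_bar = np.r_[-1.2, 0.1, 0.0, 0.0]
        payloads = [make_payload(lead, theta_bar) for _ in range(4)]
        theta = theta_bar + np.r_[0.2, -0.1, 0.05, 0.0]
        assert surrogate_loglik(lead, payloads, theta) == pytest.approx(
            core.log_likelihood(lead, theta), abs=1e-12
        )

    def test_gradient_matches_finite_differences(self, three_sites):
        theta_bar = np.r_[-1.0, 0.1, -0.1, 0.0]
        payloads = [make_payload(s, theta_bar) for s in three_sites]
        lead = three_sites[0]
        theta = theta_bar + 0.1
        num = numeric_gradient(
            lambda t: surrogate_loglik(lead, payloads, t), theta
        )
        np.testing.assert_allclose(
            surrogate_score(lead, payloads, theta), num, atol=1e-6
        )

    def test_first_order_matching_exact(self, three_sites):
        # with sample-size weighting the surrogate gradient at theta_bar is
        # the pooled-data score, to floating-point cancellation
        theta_bar = np.r_[-0.8, 0.2, -0.1, 0.05]
        payloads = [make_payload(s, theta_bar) for s in three_sites]
        gs = surrogate_score(three_sites[0], payloads, theta_bar)
        pooled_score = core.score(concatenate_sites(three_sites), theta_bar)
        np.testing.assert_allclose(gs, pooled_score, atol=1e-10)

    def test_weightings_agree_for_equal_sizes(self, three_sites):
        theta_bar = np.r_[-1.0, 0.0, 0.0, 0.0]
        payloads = [make_payload(s, theta_bar) for s in three_sites]
        theta = theta_bar + 0.2
        a = surrogate_loglik(three_sites[0], payloads, theta, "sample_size")
        b = surrogate_loglik(three_sites[0], payloads, theta, "paper")
        assert a == pytest.approx(b, abs=1e-12)

    def test_mismatched_theta_bar_raises(self, three_sites):
        p1 = make_payload(three_sites[0], np.r_[-1.0, 0.0, 0.0, 0.0])
        p2 = make_payload(three_sites[1], np.r_[-1.0, 0.0, 0.0, 1e-9])
        with pytest.raises(ProtocolError, match="theta_bar"):
            surrogate_loglik(three_sites[0], [p1, p2], np.zeros(4))

    def test_missing_lead_payload_raises(self, three_sites):
        theta_bar = np.zeros(4)
        payloads = [make_payload(s, theta_bar) for s in three_sites[1:]]
        with pytest.raises(ProtocolError, match="lead"):
            surrogate_loglik(three_sites[0], payloads, theta_bar)


class TestFitODAPB:
    @pytest.mark.parametrize("seed", range(10))
    def test_single_site_reduction_to_mle(self, seed):
        rng = np.random.default_rng(400 + seed)
        d = random_site(rng, n=80, p=3, site_id="lead")
        # tight solver tolerance so solver slack cannot mask the identity
        local = core.fit_mle(d, tol=1e-11)
        payloads = [make_payload(d, local.estimate + 0.1)]
        result = fit_odapb(d, payloads, tol=1e-11)
        np.testing.assert_allclose(result.estimate, local.estimate, atol=1e-8)

    def test_stationary_at_pooled_mle(self, three_sites):
        pooled = core.fit_mle(concatenate_sites(three_sites), tol=1e-12)
        payloads = [make_payload(s, pooled.estimate) for s in three_sites]
        gs = surrogate_score(three_sites[0], payloads, pooled.estimate)
        assert np.abs(gs).max() < 1e-10
        result = fit_odapb(three_sites[0], payloads)
        np.testing.assert_allclose(result.estimate, pooled.estimate, atol=1e-8)

    def test_privacy_surface_payloads_only(self, three_sites):
        # the solve signature admits only the lead rows plus payloads: run it
        # with the non-lead SiteData objects deleted
        theta_bar = np.r_[-1.0, 0.0, 0.0, 0.0]
        payloads = [make_payload(s, theta_bar) for s in three_sites]
        lead = three_sites[0]
        del three_sites[1:]
        result = fit_odapb(lead, payloads)
        assert result.converged
        assert result.K == 3
        assert result.N == sum(p.n for p in payloads)

    def test_ci_bounds_bracket_rr_and_stay_positive(self, three_sites):
        theta_bar = meta_combine(local_fits(three_sites)).estimate
        payloads = [make_payload(s, theta_bar) for s in three_sites]
        r = fit_odapb(three_sites[0], payloads)
        assert np.all(r.rr_ci_low > 0)
        assert np.all(r.rr_ci_low < r.rr)
        assert np.all(r.rr < r.rr_ci_high)

    def test_lead_site_equivariance_shrinks_near_pooled(self, three_sites):
        # the spread of the K lead-choice estimates shrinks as theta_bar
        # approaches the pooled MLE (the correction is second order)
        pooled = core.fit_mle(concatenate_sites(three_sites), tol=1e-12)

        def spread(theta_bar):
            payloads = [make_payload(s, theta_bar) for s in three_sites]
            ests = [
                fit_odapb(lead, payloads).estimate for lead in three_sites
            ]
            return np.max(np.std(np.stack(ests), axis=0))

        far = spread(pooled.estimate + 0.4)
        near = spread(pooled.estimate + 0.04)
        at = spread(pooled.estimate)
        assert at < near < far


class TestBaselines:
    def test_pooled_single_site_equals_mle(self, three_sites):
        r = fit_pooled(three_sites[:1])
        f = core.fit_mle(three_sites[0])
        np.testing.assert_allclose(r.estimate, f.estimate, atol=1e-12)

    def test_pooled_invariant_to_site_split(self, two_group_site):
        # split the two-group data across two sites: closed form survives
        a = SiteData(
            outcomes=two_group_site.outcomes[:15],
            design=two_group_site.design[:15],
            site_id="a",
        )
        b = SiteData(
            outcomes=two_group_site.outcomes[15:],
            design=two_group_site.design[15:],
            site_id="b",
        )
        r = fit_pooled([a, b])
        assert r.estimate[1] == pytest.approx(np.log(4.0), abs=1e-8)

    def test_pooled_duplicated_sites_halve_variance(self, three_sites):
        r1 = fit_pooled(three_sites)
        r2 = fit_pooled(three_sites + three_sites)
        np.testing.assert_allclose(r1.estimate, r2.estimate, atol=1e-8)
        np.testing.assert_allclose(r1.covariance, 2 * r2.covariance, atol=1e-10)

    def test_meta_identical_sites_equals_single_fit(self, three_sites):
        sites = [
            SiteData(
                outcomes=three_sites[0].outcomes,
                design=three_sites[0].design,
                site_id=f"c{i}",
            )
            for i in range(3)
        ]
        r = fit_meta(sites)
        f = core.fit_mle(sites[0])
        np.testing.assert_allclose(r.estimate, f.estimate, atol=1e-8)

    def test_meta_drops_zero_event_site(self, three_sites):
        dead = SiteData(
            outcomes=np.zeros(50, dtype=int),
            design=np.column_stack(
                [np.ones(50), np.r_[np.ones(25), np.zeros(25)]]
            ),
            site_id="dead",
        )
        live = SiteData(
            outcomes=np.r_[np.ones(4), np.zeros(6), np.ones(2), np.zeros(18)].astype(int),
            design=np.column_stack([np.ones(30), np.r_[np.ones(10), np.zeros(20)]]),
            site_id="live",
        )
        r = fit_meta([live, dead])
        f = core.fit_mle(live)
        np.testing.assert_allclose(r.estimate, f.estimate, atol=1e-10)
        assert len(r.meta.sites_dropped) == 1

    def test_identical_sites_all_methods_collapse(self, three_sites):
        sites = [
            SiteData(
                outcomes=three_sites[0].outcomes,
                design=three_sites[0].design,
                site_id=f"c{i}",
            )
            for i in range(4)
        ]
        pooled = fit_pooled(sites)
        meta = fit_meta(sites)
        odapb = run_protocol(sites)
        np.testing.assert_allclose(pooled.estimate, meta.estimate, atol=1e-6)
        np.testing.assert_allclose(pooled.estimate, odapb.estimate, atol=1e-6)

    def test_all_leads_wrapper_runs(self, three_sites):
        r = fit_odapb_all_leads(three_sites)
        single = run_protocol(three_sites)
        # the combined estimate stays close to the single-lead one
        np.testing.assert_allclose(r.estimate, single.estimate, atol=0.05)
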