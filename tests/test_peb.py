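"""Group-level inference: model reduction, PEB, and Bayesian data
comparison."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import taskdcm as t
from taskdcm import peb as pmod
from taskdcm.dcm import DCMPosterior


def make_posterior(mu, Sigma, names, sid):
    return DCMPosterior(
        mu=np.asarray(mu, float), Sigma=np.asarray(Sigma, float),
        F_trace=(0.0,), step_improvements=(), converged=True,
        param_names=tuple(names), noise_logprec=np.zeros(1), subject_id=sid,
    )


def b_names(p):
    """Synthetic modulatory-parameter names (off-diagonal edge labels)."""
    out = []
    i = 0
    for a in range(20):
        for b in range(20):
            if a != b:
                out.append(f"B1:n{a}->n{b}")
                i += 1
                if i == p:
                    return tuple(out)
    raise ValueError


def synth_cohort(true_beta, sd_between, sd_first, n_sub, seed):
    rng = np.random.default_rng(seed)
    p = len(true_beta)
    names = b_names(p)
    posts = []
    for i in range(n_sub):
        theta = true_beta + rng.normal(0, sd_between, p)
        mu = theta + rng.normal(0, sd_first, p)
        posts.append(
            make_posterior(mu, np.eye(p) * sd_first ** 2, names, f"s{i}")
        )
    return posts


class TestModelReduction:
    def test_matches_numerical_quadrature_1d(self):
        """The Gaussian evidence-reduction identity against brute-force
        integration of E_q[p0r/p0] in one dimension."""
        mu, var = 0.4, 0.04
        mu0, var0 = 0.0, 1.0
        mu0r, var0r = 0.0, 1e-4
        analytic = pmod.reduced_log_evidence(
            np.array([mu]), np.array([[var]]),
            np.array([mu0]), np.array([[var0]]),
            np.array([mu0r]), np.array([[var0r]]),
        )
        integrand = lambda x: (
            norm.pdf(x, mu, np.sqrt(var))
            * norm.pdf(x, mu0r, np.sqrt(var0r))
            / norm.pdf(x, mu0, np.sqrt(var0))
        )
        numeric = np.log(quad(integrand, -2, 2, limit=200)[0])
        assert analytic == pytest.approx(numeric, abs=1e-6)

    def test_unchanged_prior_gives_zero(self):
        mu = np.array([0.3, -0.1])
        S = np.array([[0.05, 0.01], [0.01, 0.04]])
        S0 = np.eye(2)
        d = pmod.reduced_log_evidence(
            mu, S, np.zeros(2), S0, np.zeros(2), S0
        )
        assert d == pytest.approx(0.0, abs=1e-12)


class TestPosteriorProbability:
    def test_half_at_zero_evidence(self):
        # a free-energy difference of zero maps to PP = 0.5 exactly
        assert 1.0 / (1.0 + np.exp(-0.0)) == 0.5

    def test_logistic_of_ln19_is_095(self):
        dF = np.log(19.0)
        assert 1.0 / (1.0 + np.exp(-dF)) == pytest.approx(0.95)

    def test_uninformed_effect_pp_near_half(self):
        # posterior equal to prior on an uncorrelated effect: no evidence
        prior_var = np.array([1.0, 1.0])
        mu = np.array([0.0, 0.5])
        Sigma = np.diag([1.0, 0.01])
        pp = pmod.posterior_probability_from_moments(mu, Sigma, prior_var, 0)
        assert pp == pytest.approx(0.5, abs=0.01)

    def test_strong_effect_pp_near_one(self):
        prior_var = np.array([1.0])
        pp = pmod.posterior_probability_from_moments(
            np.array([0.5]), np.array([[1e-4]]), prior_var, 0
        )
        assert pp > 0.999


class TestPEBFit:
    def test_identical_subjects_recover_common_mean(self):
        names = b_names(4)
        m = np.array([0.2, -0.1, 0.0, 0.3])
        S = np.eye(4) * 0.01
        posts = [make_posterior(m, S, names, f"s{i}") for i in range(6)]
        peb = t.peb_fit(posts, parameter_selection="B")
        sl = peb.covariate_slice("mean")
        np.testing.assert_allclose(peb.mu[sl], m, atol=0.02)

    def test_planted_group_effect_detected(self):
        true = np.zeros(20)
        true[7] = 0.3
        posts = synth_cohort(true, sd_between=0.1, sd_first=0.05,
                             n_sub=30, seed=2)
        peb = t.peb_fit(posts, parameter_selection="B")
        sl = peb.covariate_slice("mean")
        assert peb.mu[sl][7] > 0.15
        assert peb.pp[sl][7] > 0.95

    def test_null_cohort_calibration(self):
        # all true effects zero: very few false PP > 95% calls over 72
        # edges (empirical calibration band)
        counts = []
        for seed in range(3):
            posts = synth_cohort(np.zeros(72), sd_between=0.1,
                                 sd_first=0.05, n_sub=30, seed=10 + seed)
            peb = t.peb_fit(posts, parameter_selection="B")
            counts.append(pmod.count_evident_edges(peb))
        assert max(counts) <= 4  # <= ~5% of 72

    def test_shrinkage_grows_with_between_subject_precision(self):
        true = np.zeros(6)
        posts_loose = synth_cohort(true + 0.1, 0.3, 0.05, 12, seed=3)
        posts_tight = synth_cohort(true + 0.1, 0.01, 0.05, 12, seed=3)
        m_loose = t.peb_fit(posts_loose).mu[:6]
        m_tight = t.peb_fit(posts_tight).mu[:6]
        # looser random effects -> group estimates pulled harder toward 0
        assert np.abs(m_loose).mean() < np.abs(m_tight).mean() + 0.05

    def test_layout_mismatch_reported(self):
        a = make_posterior(np.zeros(2), np.eye(2), ("B1:x->y", "B1:y->x"), "a")
        b = make_posterior(np.zeros(2), np.eye(2), ("B1:x->y", "B1:y->z"), "b")
        with pytest.raises(ValueError, match="B1:y->x"):
            t.peb_fit([a, b])

    def test_needs_two_subjects(self):
        a = make_posterior(np.zeros(2), np.eye(2), ("B1:x->y", "B1:y->x"), "a")
        with pytest.raises(ValueError):
            t.peb_fit([a])


class TestCountEvidentEdges:
    def test_bounds(self):
        posts = synth_cohort(np.full(72, 1.0), 0.01, 0.01, 8, seed=5)
        peb = t.peb_fit(posts)
        assert pmod.count_evident_edges(peb) == 72
        posts0 = synth_cohort(np.zeros(4), 0.5, 0.5, 4, seed=6)
        peb0 = t.peb_fit(posts0)
        assert 0 <= pmod.count_evident_edges(peb0) <= 4

    def test_edge_fraction_arithmetic(self):
        assert pmod.n_offdiagonal_edges(9) == 72
        assert round(pmod.edge_fraction_percent(42)) == 58
        assert round(pmod.edge_fraction_percent(13)) == 18


class TestPEBBetween:
    def test_identical_copies_show_no_differences(self):
        posts = synth_cohort(np.full(10, 0.2), 0.1, 0.05, 15, seed=7)
        copies = [
            make_posterior(p.mu, p.Sigma, p.param_names, f"c-{p.subject_id}")
            for p in posts
        ]
        peb = t.peb_between(posts, copies)
        sl = peb.covariate_slice("group")
        assert (peb.pp[sl] > 0.95).sum() == 0
        np.testing.assert_allclose(peb.mu[sl], 0.0, atol=0.02)

    def test_two_group_difference_detected(self):
        true_a = np.zeros(10)
        true_a[2] = 0.3
        a = synth_cohort(true_a, 0.1, 0.05, 30, seed=8)
        b = synth_cohort(np.zeros(10), 0.1, 0.05, 30, seed=9)
        b = [make_posterior(p.mu, p.Sigma, p.param_names, f"b-{p.subject_id}")
             for p in b]
        peb = t.peb_between(a, b)
        sl = peb.covariate_slice("group")
        assert peb.pp[sl][2] > 0.95
        assert peb.mu[sl][2] > 0.1

    def test_label_swap_flips_signs(self):
        a = synth_cohort(np.full(6, 0.2), 0.1, 0.05, 10, seed=11)
        b = synth_cohort(np.zeros(6), 0.1, 0.05, 10, seed=12)
        b = [make_posterior(p.mu, p.Sigma, p.param_names, f"b-{p.subject_id}")
             for p in b]
        ab = t.peb_between(a, b)
        ba = t.peb_between(b, a)
        sl = ab.covariate_slice("group")
        np.testing.assert_allclose(ab.mu[sl], -ba.mu[sl], atol=1e-6)

    def test_duplicate_subject_rejected(self):
        a = synth_cohort(np.zeros(4), 0.1, 0.05, 3, seed=13)
        with pytest.raises(ValueError, match="twice"):
            t.peb_between(a + [a[0]], a)


class TestBDC:
    def names(self, d):
        return b_names(d)

    def test_identical_posteriors_zero_nats(self):
        names = self.names(5)
        S = np.diag([0.1, 0.2, 0.3, 0.4, 0.5])
        a = [make_posterior(np.zeros(5), S, names, f"s{i}") for i in range(4)]
        res = t.bdc_compare(a, a)
        assert res.certainty_diff_nats == pytest.approx(0.0, abs=1e-12)
        assert res.evidence_class == "none"

    def test_variance_halving_gives_half_ln_two_per_parameter(self):
        d = 10
        names = self.names(d)
        Sb = np.eye(d) * 0.2
        Sa = Sb / 2.0
        a = [make_posterior(np.zeros(d), Sa, names, "s0")]
        b = [make_posterior(np.zeros(d), Sb, names, "s0")]
        res = t.bdc_compare(a, b)
        assert res.certainty_diff_nats == pytest.approx(d * 0.5 * np.log(2.0))
        assert res.certainty_diff_nats == pytest.approx(3.47, abs=0.01)
        assert res.evidence_class == "strong"

    def test_antisymmetry(self):
        rng = np.random.default_rng(14)
        names = self.names(4)
        M = rng.normal(size=(4, 4))
        Sa = M @ M.T + np.eye(4)
        Sb = np.eye(4) * 0.5
        a = [make_posterior(np.zeros(4), Sa, names, "s0")]
        b = [make_posterior(np.zeros(4), Sb, names, "s0")]
        ab = t.bdc_compare(a, b).certainty_diff_nats
        ba = t.bdc_compare(b, a).certainty_diff_nats
        assert ab == pytest.approx(-ba)

    def test_additivity_over_independent_blocks(self):
        names4 = self.names(4)
        Sa1, Sb1 = np.eye(2) * 0.1, np.eye(2) * 0.4
        Sa2, Sb2 = np.eye(2) * 0.2, np.eye(2) * 0.3
        import scipy.linalg as sla

        a = [make_posterior(np.zeros(4), sla.block_diag(Sa1, Sa2), names4, "s")]
        b = [make_posterior(np.zeros(4), sla.block_diag(Sb1, Sb2), names4, "s")]
        whole = t.bdc_compare(a, b).certainty_diff_nats
        a1 = [make_posterior(np.zeros(2), Sa1, names4[:2], "s")]
        b1 = [make_posterior(np.zeros(2), Sb1, names4[:2], "s")]
        a2 = [make_posterior(np.zeros(2), Sa2, names4[2:], "s")]
        b2 = [make_posterior(np.zeros(2), Sb2, names4[2:], "s")]
        part = (
            t.bdc_compare(a1, b1, parameter_selection=names4[:2]).certainty_diff_nats
            + t.bdc_compare(a2, b2, parameter_selection=names4[2:]).certainty_diff_nats
        )
        assert whole == pytest.approx(part)

    def test_evidence_bands(self):
        assert pmod.classify_nats(0.5) == "none"
        assert pmod.classify_nats(2.0) == "positive"
        assert pmod.classify_nats(-2.0) == "positive"
        assert pmod.classify_nats(4.0) == "strong"
        assert pmod.classify_nats(6.0) == "very strong"

    def test_no_common_subjects_error(self):
        names = self.names(2)
        a = [make_posterior(np.zeros(2), np.eye(2), names, "a1")]
        b = [make_posterior(np.zeros(2), np.eye(2), names, "b1")]
        with pytest.raises(ValueError, match="common"):
            t.bdc_compare(a, b)
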