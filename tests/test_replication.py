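import numpy as np
import pytest

from replicor.likelihood import StudySummary, RhoGrid, default_grid, null_density
from replicor.replication import (
    bf10_informed, bf10_uniform, credible_interval, evidence_label,
    likelihood_grid, map_estimate, posterior_from_data, replication_result,
    savage_dickey_bf, uniform_prior, _effective_n, BF_CONVENTION,
)


def test_posterior_concentrates_at_observed_null():
    post = posterior_from_data(StudySummary(0.0, 1000), uniform_prior(0))
    assert map_estimate(post) == pytest.approx(0.0, abs=1e-3)


def test_sequential_update_equals_joint_update():
    """Updating on the original study then the replication gives the same
    posterior as a single update with the product likelihood."""
    s1 = StudySummary(0.37, 52)
    s2 = StudySummary(0.3856, 37)
    seq = posterior_from_data(s2, posterior_from_data(s1, uniform_prior(0)))
    prior = uniform_prior(0)
    joint_like = likelihood_grid(s1, prior.nodes) * likelihood_grid(s2, prior.nodes)
    joint = prior.multiply(joint_like).normalize()
    assert np.max(np.abs(seq.density - joint.density)) < 1e-6


def test_combined_posterior_order_invariant():
    s1 = StudySummary(-0.65, 52)
    s2 = StudySummary(0.0130, 37)
    a = posterior_from_data(s2, posterior_from_data(s1, uniform_prior(0)))
    b = posterior_from_data(s1, posterior_from_data(s2, uniform_prior(0)))
    assert np.max(np.abs(a.density - b.density)) < 1e-9


def test_posterior_mean_matches_importance_sampling():
    """Grid posterior mean agrees with a seeded importance-sampling oracle
    (uniform proposal, exact likelihood weights)."""
    study = StudySummary(0.5, 50)
    post = posterior_from_data(study, uniform_prior(0))
    rng = np.random.default_rng(7)
    draws = rng.uniform(-1, 1, 100_000)
    from replicor.likelihood import r_density
    w = r_density(study.r_obs, draws, _effective_n(study.n, BF_CONVENTION))
    is_mean = np.sum(w * draws) / np.sum(w)
    assert post.mean() == pytest.approx(is_mean, abs=3e-3)


def test_bf_uniform_monotone_in_r():
    bfs = [bf10_uniform(StudySummary(r, 37, 1)) for r in
           np.linspace(0.05, 0.6, 10)]
    assert all(a < b for a, b in zip(bfs, bfs[1:]))


def test_bf_informed_equals_marginal_ratio():
    """Transitivity: the informed BF equals joint marginal over (original
    marginal x replication null density), on random study pairs."""
    rng = np.random.default_rng(11)
    prior = uniform_prior(0)
    for _ in range(5):
        r1, r2 = rng.uniform(-0.7, 0.7, 2)
        n1, n2 = rng.integers(10, 80, 2)
        s1, s2 = StudySummary(r1, int(n1)), StudySummary(r2, int(n2))
        l1 = likelihood_grid(s1, prior.nodes)
        l2 = likelihood_grid(s2, prior.nodes)
        m_joint = np.trapezoid(l1 * l2 * prior.density, prior.nodes)
        m_orig = np.trapezoid(l1 * prior.density, prior.nodes)
        direct = m_joint / (m_orig * null_density(r2, _effective_n(int(n2), "df")))
        assert bf10_informed(s1, s2) == pytest.approx(direct, rel=1e-9)


def test_savage_dickey_matches_marginal_likelihood_bf():
    """Prior/posterior density ratio at rho=0 equals the integrated BF
    (two-sided uniform prior, r=.3, n=40) within 1%."""
    study = StudySummary(0.3, 40, 0)
    prior = uniform_prior(0)
    post = posterior_from_data(study, prior)
    sd = savage_dickey_bf(prior, post)
    assert sd == pytest.approx(bf10_uniform(study, side=0), rel=0.01)


def test_savage_dickey_trivial_cases():
    prior = uniform_prior(0)
    assert savage_dickey_bf(prior, prior) == pytest.approx(1.0)
    post = posterior_from_data(StudySummary(0.0, 400, 0), prior)
    assert savage_dickey_bf(prior, post) < 1


def test_savage_dickey_one_sided_limit_flagged():
    prior = uniform_prior(1)
    post = posterior_from_data(StudySummary(0.3, 40, 1), prior)
    bf = savage_dickey_bf(prior, post)
    assert np.isfinite(bf) and bf > 0
    assert any("one-sided" in f for f in prior.flags)


def test_map_quadratic_refinement_and_flat_fallback():
    nodes = default_grid()
    sym = posterior_from_data(StudySummary(0.0, 200, 0), uniform_prior(0))
    assert map_estimate(sym) == pytest.approx(0.0, abs=1e-6)
    flat = RhoGrid(nodes, np.ones_like(nodes)).normalize()
    assert map_estimate(flat) == pytest.approx(0.0, abs=1e-12)
    assert flat.flags


def test_credible_interval_limits():
    post = posterior_from_data(StudySummary(0.4, 30, 0), uniform_prior(0))
    lo, hi = credible_interval(post, 0.95)
    assert lo <= map_estimate(post) <= hi
    lo1, hi1 = credible_interval(post, 1 - 1e-12)
    assert lo1 < lo and hi1 > hi
    # in the mass->1 limit the interval approaches the grid support
    flat_lo, flat_hi = credible_interval(uniform_prior(0), 1 - 1e-9)
    assert flat_lo == pytest.approx(-0.9999, abs=1e-5)
    assert flat_hi == pytest.approx(0.9999, abs=1e-5)
    with pytest.raises(ValueError):
        credible_interval(post, 1.5)


def test_map_recovers_true_correlation_at_large_n():
    """With r_obs sampled at n=500 around rho=.3, the posterior MAP is an
    essentially unbiased estimate (|mean bias| < .02 over 200 studies)."""
    rng = np.random.default_rng(42)
    rho, n = 0.3, 500
    x = rng.standard_normal((200, n))
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal((200, n))
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    rs = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
    maps = [map_estimate(posterior_from_data(StudySummary(float(r), n),
                                             uniform_prior(0))) for r in rs]
    assert abs(np.mean(maps) - rho) < 0.02


def test_evidence_labels():
    assert evidence_label(5.0) == "substantial for H1"
    assert evidence_label(15.0) == "strong for H1"
    assert evidence_label(50.0) == "very strong for H1"
    assert evidence_label(200.0) == "extreme for H1"
    assert evidence_label(2.0) == "anecdotal for H1"
    assert evidence_label(0.2) == "substantial for H0"
    assert evidence_label(1.0) == "no evidence"
    with pytest.raises(ValueError):
        evidence_label(-1.0)


def test_replication_result_without_original():
    res = replication_result(None, StudySummary(0.4845, 37, 0, "mask peak"))
    assert res.bf10_informed is None and res.evidence_informed is None
    assert res.ci_low < res.map < res.ci_high


def test_uniform_and_informed_bf_internally_consistent():
    """Both Bayes factors of one row come from the same likelihood family:
    the informed BF must equal the uniform-prior BF times the ratio of the
    informed to uniform marginal likelihoods (an identity)."""
    orig = StudySummary(-0.65, 52, -1)
    rep = StudySummary(-0.220, 37, -1)
    prior_u = uniform_prior(-1)
    informed = posterior_from_data(orig, uniform_prior(0))
    l2 = likelihood_grid(rep, prior_u.nodes)
    m_u = np.trapezoid(l2 * prior_u.density, prior_u.nodes)
    m_i = np.trapezoid(l2 * informed.density, informed.nodes)
    assert bf10_informed(orig, rep) == pytest.approx(
        bf10_uniform(rep) * m_i / m_u, rel=1e-9)


def test_degenerate_prior_rejected():
    nodes = default_grid()
    zero = RhoGrid(nodes, np.zeros_like(nodes))
    with pytest.raises(ValueError):
        posterior_from_data(StudySummary(0.3, 20), zero)
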