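import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relbel import (DiscreteDistribution, PoolSpec, consensus_audit,
                    pooled_posterior, pooled_rb, power_pool)
from relbel.models import discrete_predictive, two_point_base

T_VALUES = [-np.inf, -2.0, -1.0, 0.0, 0.5, 1.0, 2.0, np.inf]


def seeded_priors(seed, k=3, m=4):
    rng = np.random.default_rng(seed)
    support = tuple(range(m))
    return [
        DiscreteDistribution(support, rng.dirichlet(np.ones(m)))
        for _ in range(k)
    ]


class TestPowerPool:
    @pytest.mark.parametrize("t", T_VALUES)
    def test_unanimity(self, t):
        """Pooling identical priors returns that prior for every t."""
        p = DiscreteDistribution(("a", "b", "c"), [0.2, 0.3, 0.5])
        pool = power_pool([p, p, p], PoolSpec(t, [0.2, 0.5, 0.3]))
        assert np.allclose(pool.density.mass, p.mass)

    def test_linear_pool_is_arithmetic_mean(self):
        p1 = DiscreteDistribution((0, 1), [0.5, 0.5])
        p2 = DiscreteDistribution((0, 1), [0.25, 0.75])
        pool = power_pool([p1, p2], PoolSpec(1.0, [0.5, 0.5]))
        assert np.allclose(pool.density.mass, [0.375, 0.625])
        assert pool.norm_constant == pytest.approx(1.0)

    def test_geometric_pool_with_categorical_prior(self):
        """With p1=1 the log-pool puts all mass at 'a' for every alpha."""
        p1 = DiscreteDistribution(("a", "b"), [1.0, 0.0])
        p2 = DiscreteDistribution(("a", "b"), [0.5, 0.5])
        for a in (0.2, 0.5, 0.8):
            pool = power_pool([p1, p2], PoolSpec(0.0, [a, 1 - a]))
            assert pool.density.prob("a") == pytest.approx(1.0)

    def test_min_pool_with_categorical_prior(self):
        """t=-inf: min(p1,p2)/(min(p1,p2)+min(1-p1,1-p2)) at p1=1, p2=1/2."""
        p1 = DiscreteDistribution(("a", "b"), [1.0, 0.0])
        p2 = DiscreteDistribution(("a", "b"), [0.5, 0.5])
        pool = power_pool([p1, p2], PoolSpec(-np.inf, [0.3, 0.7]))
        assert pool.density.prob("a") == pytest.approx(1.0)

    def test_geometric_pool_of_disjoint_priors_raises(self):
        p1 = DiscreteDistribution(("a", "b"), [1.0, 0.0])
        p2 = DiscreteDistribution(("a", "b"), [0.0, 1.0])
        with pytest.raises(ValueError, match="identically zero"):
            power_pool([p1, p2], PoolSpec(0.0, [0.5, 0.5]))

    def test_monotone_in_t(self, rng):
        """The unnormalized power mean is nondecreasing in t pointwise."""
        priors = seeded_priors(7)
        alpha = [0.2, 0.5, 0.3]
        from relbel.pooling import _as_table, _power_mean_table

        table = _as_table(priors)
        prev = None
        for t in T_VALUES:
            cur = _power_mean_table(table, PoolSpec(t, alpha))
            if prev is not None:
                assert np.all(cur >= prev - 1e-12)
            prev = cur

    def test_norm_constant_at_least_one_for_small_t(self):
        priors = seeded_priors(13)
        alpha = [1 / 3] * 3
        for t in (-np.inf, -1.0, 0.0, 0.5, 1.0):
            pool = power_pool(priors, PoolSpec(t, alpha))
            assert pool.norm_constant >= 1.0 - 1e-12

    def test_duplicate_priors_collapse(self):
        """Pooling with repeated priors equals pooling distinct ones
        with the corresponding alphas summed."""
        p1, p2, _ = seeded_priors(3)
        for t in (-1.0, 0.0, 0.5, 1.0, 2.0):
            a = power_pool([p1, p1, p2], PoolSpec(t, [0.2, 0.3, 0.5]))
            b = power_pool([p1, p2], PoolSpec(t, [0.5, 0.5]))
            assert np.allclose(a.density.mass, b.density.mass)

    def test_weight_count_mismatch_raises(self):
        priors = seeded_priors(5, k=2)
        with pytest.raises(ValueError):
            power_pool(priors, PoolSpec(1.0, [1 / 3] * 3))


class TestPooledPosterior:
    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**32 - 1),
           st.sampled_from([-2.0, -1.0, 0.0, 0.5, 1.0, 2.0]))
    def test_posterior_is_power_mean_of_posteriors(self, seed, t):
        """Bayes on the t-pool equals the t-power-mean of the component
        posteriors with weights updated by m_i(x)^t."""
        rng = np.random.default_rng(seed)
        priors = seeded_priors(seed)
        alpha = rng.dirichlet(np.ones(3))
        lik = rng.uniform(0.05, 1.0, size=4)
        direct = pooled_posterior(priors, PoolSpec(t, alpha), lik)

        posts = [
            DiscreteDistribution.from_weights(p.support, p.mass * lik)
            for p in priors
        ]
        m = np.array([(p.mass * lik).sum() for p in priors])
        if t == 0.0:
            re_alpha = alpha  # weights unchanged under the log-pool
        else:
            re_alpha = alpha * m**t
            re_alpha = re_alpha / re_alpha.sum()
        re_expressed = power_pool(posts, PoolSpec(t, re_alpha))
        assert np.allclose(direct.mass, re_expressed.density.mass, atol=1e-12)

    def test_dictatorship_returns_component_posterior(self):
        priors = seeded_priors(11)
        lik = np.array([0.3, 0.1, 0.4, 0.2])
        for t in (-1.0, 1.0, 2.0):
            post = pooled_posterior(priors[:2], PoolSpec(t, [1.0, 0.0]), lik)
            expect = DiscreteDistribution.from_weights(
                priors[0].support, priors[0].mass * lik
            )
            assert np.allclose(post.mass, expect.mass)

    def test_zero_likelihood_raises(self):
        priors = seeded_priors(1, k=2)
        with pytest.raises(ValueError, match="zero"):
            pooled_posterior(priors, PoolSpec(1.0, [0.5, 0.5]), np.zeros(4))

    def test_example1_linear_pool_posterior(self, categorical_and_half_bases):
        b1, b2 = categorical_and_half_bases
        post = pooled_posterior(
            [b1.prior, b2.prior], PoolSpec(1.0, [0.5, 0.5]), b1.likelihood
        )
        assert round(post.prob("a"), 2) == 0.53


class TestPooledRB:
    def test_log_pool_degeneracy(self, categorical_and_half_bases):
        """With one categorical prior the log-pool RB(a) is forced to 1."""
        b1, b2 = categorical_and_half_bases
        rb = pooled_rb(
            [b1.prior, b2.prior], PoolSpec(0.0, [0.5, 0.5]), b1.likelihood
        )
        assert rb.value("a") == pytest.approx(1.0)

    def test_linear_pool_example1_value(self, categorical_and_half_bases):
        b1, b2 = categorical_and_half_bases
        rb = pooled_rb(
            [b1.prior, b2.prior], PoolSpec(1.0, [0.5, 0.5]), b1.likelihood
        )
        assert round(rb.value("a"), 2) == 0.71

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**32 - 1),
           st.sampled_from([-2.0, -1.0, 0.0, 0.5, 2.0]))
    def test_proportional_to_linear_pool(self, seed, t):
        """RB_{t,a} = [m_{1,a}(x)/m_{t,a}(x)] RB_{1,a} pointwise."""
        rng = np.random.default_rng(seed)
        priors = seeded_priors(seed)
        alpha = rng.dirichlet(np.ones(3))
        lik = rng.uniform(0.05, 1.0, size=4)
        rb_t = pooled_rb(priors, PoolSpec(t, alpha), lik)
        rb_1 = pooled_rb(priors, PoolSpec(1.0, alpha), lik)
        pool_t = power_pool(priors, PoolSpec(t, alpha))
        pool_1 = power_pool(priors, PoolSpec(1.0, alpha))
        m_t = (pool_t.density.mass * lik).sum()
        m_1 = (pool_1.density.mass * lik).sum()
        assert np.allclose(rb_t.rb, (m_1 / m_t) * rb_1.rb, atol=1e-10)

    def test_argmax_shared_across_t(self, rng):
        """The RB-maximizing value is the linear pool's for every t."""
        for seed in range(20):
            priors = seeded_priors(seed)
            lik = np.random.default_rng(seed + 1).uniform(0.05, 1, 4)
            alpha = [0.3, 0.4, 0.3]
            ref = pooled_rb(priors, PoolSpec(1.0, alpha), lik).argmax()
            for t in (-1.0, 0.0, 0.5, 2.0):
                assert pooled_rb(priors, PoolSpec(t, alpha), lik).argmax() == ref

    def test_strength_event_shared_across_t(self):
        """{RB_t <= RB_t(psi0)} is the same set for every t."""
        priors = seeded_priors(23)
        lik = np.random.default_rng(2).uniform(0.05, 1, 4)
        alpha = [0.3, 0.4, 0.3]
        ref = None
        for t in (-1.0, 0.0, 0.5, 1.0, 2.0):
            rb = pooled_rb(priors, PoolSpec(t, alpha), lik)
            event = rb.rb <= rb.rb[1] + 1e-12
            if ref is None:
                ref = event
            assert np.array_equal(event, ref)

    def test_single_base_identity(self):
        (p,) = seeded_priors(4, k=1)
        lik = np.array([0.3, 0.1, 0.4, 0.2])
        from relbel import relative_belief

        direct = relative_belief(
            p, DiscreteDistribution.from_weights(p.support, p.mass * lik)
        )
        for t in (-1.0, 0.0, 1.0, 2.0):
            rb = pooled_rb([p], PoolSpec(t, [1.0]), lik)
            assert np.allclose(rb.rb, direct.rb)


class TestConsensusAudit:
    def test_log_pool_breaks_consensus_on_categorical_prior(
        self, categorical_and_half_bases
    ):
        """Component pattern (neutral, against) but log-pool neutral: FAIL."""
        b1, b2 = categorical_and_half_bases
        comps = [b1.rb_profile(), b2.rb_profile()]
        lik = b1.likelihood
        combined = pooled_rb(
            [b1.prior, b2.prior], PoolSpec(0.0, [0.5, 0.5]), lik
        )
        audit = consensus_audit(comps, combined)
        assert not audit["consensus_preserving"]
        rec = {r["point"]: r for r in audit["per_point"]}
        assert rec["a"]["pattern"] == "consensus_against"
        assert not rec["a"]["preserved"]

    def test_linear_pool_passes(self, categorical_and_half_bases):
        b1, b2 = categorical_and_half_bases
        comps = [b1.rb_profile(), b2.rb_profile()]
        combined = pooled_rb(
            [b1.prior, b2.prior], PoolSpec(1.0, [0.5, 0.5]), b1.likelihood
        )
        assert consensus_audit(comps, combined)["consensus_preserving"]

    def test_all_neutral_passes(self):
        d = DiscreteDistribution(("a", "b"), [0.4, 0.6])
        from relbel import relative_belief

        flat = relative_belief(d, d)
        audit = consensus_audit([flat, flat], flat)
        assert audit["consensus_preserving"]
        assert all(r["pattern"] == "all_neutral" for r in audit["per_point"])
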