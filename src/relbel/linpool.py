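"""Context I: linear pooling of evidence with data-updated weights.

When k analysts share one sampling model and data but hold different
priors, the linear opinion pool of the priors has posterior weights

    w_i = alpha_i m_i(x) / sum_j alpha_j m_j(x),

where m_i(x) is the i-th prior predictive density at the observed data
— the posterior probability of "analyst i" in the hierarchical reading
where alpha is a prior over the analysts.  The combined relative belief
ratio is then the w-weighted sum of the component RBs, and the combined
posterior the w-weighted mixture of the component posteriors; both are
the genuine RB and posterior of the alpha-mixture prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .discrete import DiscreteDistribution
from .evidence import RBProfile, relative_belief

__all__ = [
    "PosteriorWeights",
    "posterior_weights",
    "combine_rb_linear",
    "combine_posterior_linear",
    "marginalization_commutes",
]


@dataclass(frozen=True)
class PosteriorWeights:
    """Data-updated combination weights ``alpha_i m_i(x) / m_alpha(x)``."""

    prior_alpha: np.ndarray
    predictive_values: np.ndarray
    weights: np.ndarray
    #: per-weight Monte-Carlo standard errors when the predictive values
    #: were themselves estimated; None for closed-form predictives
    standard_errors: Optional[np.ndarray] = None

    @property
    def k(self) -> int:
        return self.weights.size

    def __iter__(self):
        return iter(self.weights)


def posterior_weights(
    alpha: Iterable[float],
    predictive_values: Iterable[float],
    *,
    log: bool = False,
) -> PosteriorWeights:
    """Normalize ``alpha_i * m_i(x)`` into combination weights.

    ``log=True`` reads ``predictive_values`` as log densities and
    normalizes by subtracting the maximum before exponentiating, which
    keeps large-n predictives from underflowing.
    """
    alpha = np.asarray(list(alpha), dtype=float)
    vals = np.asarray(list(predictive_values), dtype=float)
    if alpha.size != vals.size:
        raise ValueError("alpha and predictive values differ in length")
    if np.any(alpha < 0):
        raise ValueError("alpha must be nonnegative")
    if abs(alpha.sum() - 1.0) > 1e-9:
        raise ValueError("alpha must sum to 1")
    if log:
        with np.errstate(invalid="ignore"):
            lw = np.where(alpha > 0, np.log(alpha) + vals, -np.inf)
        if not np.any(np.isfinite(lw)):
            raise ValueError("all weighted predictive values vanish")
        lw = lw - lw[np.isfinite(lw)].max()
        raw = np.exp(lw)
        m = np.exp(vals)
    else:
        if np.any(vals < 0):
            raise ValueError("predictive values must be nonnegative")
        raw = alpha * vals
        if raw.sum() == 0:
            raise ValueError("all weighted predictive values are zero")
        m = vals
    return PosteriorWeights(alpha, m, raw / raw.sum())


def combine_rb_linear(
    weights: PosteriorWeights, component_rbs: Sequence[RBProfile]
) -> RBProfile:
    """Pointwise w-weighted sum of component relative belief ratios.

    The result is itself a valid RB profile: its reference prior is the
    alpha-mixture of the component priors and its reference posterior
    the w-mixture of the component posteriors (an identity of linear
    pooling, asserted by the test suite rather than recomputed here).
    """
    if weights.k != len(component_rbs):
        raise ValueError("weights and component profiles differ in length")
    support = component_rbs[0].support
    for p in component_rbs[1:]:
        if p.support != support:
            raise ValueError("component profiles must share a support")
    mix_prior = combine_prior_linear(
        weights.prior_alpha, [p.prior for p in component_rbs]
    )
    mix_post = combine_posterior_linear(
        weights, [p.posterior for p in component_rbs]
    )
    # the mixture ratio equals the weighted component-RB sum wherever the
    # latter is defined, and extends it to points some component prior
    # misses but the mixture prior covers
    return relative_belief(mix_prior, mix_post)


def combine_prior_linear(
    alpha: Iterable[float], priors: Sequence[DiscreteDistribution]
) -> DiscreteDistribution:
    """The alpha-mixture prior ``sum_i alpha_i pi_i``."""
    alpha = np.asarray(list(alpha), dtype=float)
    support = priors[0].support
    mass = np.zeros(len(support))
    for a, p in zip(alpha, priors):
        if p.support != support:
            raise ValueError("priors must share a support")
        mass += a * p.mass
    return DiscreteDistribution(support, mass)


def combine_posterior_linear(
    weights: PosteriorWeights, component_posteriors: Sequence[DiscreteDistribution]
) -> DiscreteDistribution:
    """Mixture of component posteriors with the data-updated weights.

    Identical to Bayes applied to the alpha-mixture prior.
    """
    if weights.k != len(component_posteriors):
        raise ValueError("weights and posteriors differ in length")
    support = component_posteriors[0].support
    mass = np.zeros(len(support))
    for w, p in zip(weights.weights, component_posteriors):
        if p.support != support:
            raise ValueError("posteriors must share a support")
        mass += w * p.mass
    return DiscreteDistribution(support, mass)


def marginalization_commutes(
    joint_priors: Sequence[DiscreteDistribution],
    alpha: Iterable[float],
    marginal_map: Callable[[object], object],
    *,
    t: float = 1.0,
) -> tuple[bool, float]:
    """Does pooling commute with marginalization at exponent ``t``?

    Maps each joint support point through ``marginal_map``, compares
    marginalize-then-pool with pool-then-marginalize, and returns
    ``(agree_within_1e-12, sup_norm_discrepancy)``.  Exact for the
    linear pool (t=1); generally fails for other exponents.
    """
    from .pooling import PoolSpec, power_pool

    alpha = np.asarray(list(alpha), dtype=float)
    spec = PoolSpec(t, alpha)

    def marginalize(dist: DiscreteDistribution) -> DiscreteDistribution:
        buckets: dict = {}
        for pt, m in zip(dist.support, dist.mass):
            key = marginal_map(pt)
            buckets[key] = buckets.get(key, 0.0) + m
        keys = list(buckets)
        return DiscreteDistribution(keys, [buckets[k] for k in keys])

    pooled_joint = power_pool(list(joint_priors), spec).density
    route_a = marginalize(pooled_joint)
    marginals = [marginalize(p) for p in joint_priors]
    # align supports (bucket order may differ)
    support = route_a.support
    aligned = [
        DiscreteDistribution(support, [m.prob(s) for s in support])
        for m in marginals
    ]
    route_b = power_pool(aligned, spec).density
    disc = float(np.max(np.abs(route_a.mass - route_b.mass)))
    return disc < 1e-12, disc
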