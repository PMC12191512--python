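"""Power-mean opinion pooling of priors and the induced evidence.

For weights ``alpha`` on the simplex and exponent ``t``, the pooled
prior is the normalized power mean of the component priors:

    pi_{t,alpha}(theta)  ~  ( sum_i alpha_i pi_i(theta)^t )^{1/t}

with the weighted geometric mean at ``t = 0`` and the pointwise min/max
at ``t = -inf`` / ``t = +inf``.  ``t = 1`` is the linear opinion pool,
``t = 0`` the logarithmic pool.  The posterior under any t-pool is again
proportional to the same power mean of the component posteriors with
data-updated weights, and every pooled relative belief ratio is a
constant multiple ``m_{1,alpha}(x)/m_{t,alpha}(x)`` of the linear-pool
one — which is why linear pooling determines the RB-maximizing estimate
and the strength event for every t.  Only the linear pool, however, is
consensus preserving; `consensus_audit` checks that property on any
combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .discrete import DiscreteDistribution
from .evidence import (AGAINST, IN_FAVOR, NEUTRAL_TOL, NO_EVIDENCE,
                       RBProfile, classify, relative_belief)

__all__ = [
    "PoolSpec",
    "PooledPrior",
    "power_pool",
    "pooled_posterior",
    "pooled_rb",
    "consensus_audit",
]

_ALPHA_TOL = 1e-12


def _check_alpha(alpha) -> np.ndarray:
    alpha = np.asarray(list(alpha), dtype=float)
    if np.any(alpha < 0):
        raise ValueError("pool weights must be nonnegative")
    if abs(alpha.sum() - 1.0) > 1e-9:
        raise ValueError(f"pool weights sum to {alpha.sum()!r}, not 1")
    return alpha / alpha.sum()


@dataclass(frozen=True)
class PoolSpec:
    """Pooling exponent ``t`` (real or +/-inf) and simplex weights."""

    t: float
    alpha: np.ndarray

    def __init__(self, t: float, alpha: Iterable[float]):
        t = float(t)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "alpha", _check_alpha(alpha))

    @property
    def k(self) -> int:
        return self.alpha.size


@dataclass(frozen=True)
class PooledPrior:
    """A normalized power-mean pool with its normalizing constant.

    ``density`` is the pooled `DiscreteDistribution`; ``norm_constant``
    is the multiplicative constant ``c_t(alpha, pi)`` with the property
    ``c_1 = 1`` exactly.
    """

    density: DiscreteDistribution
    norm_constant: float
    spec: PoolSpec


def _power_mean_table(table: np.ndarray, spec: PoolSpec) -> np.ndarray:
    """Unnormalized power mean of the rows of ``table`` (k x m)."""
    t, alpha = spec.t, spec.alpha
    active = alpha > 0
    tab = table[active]
    al = alpha[active]
    if np.isposinf(t):
        return table.max(axis=0)
    if np.isneginf(t):
        return table.min(axis=0)
    if t == 0.0:
        # limit convention: the geometric term is 0 as soon as any
        # component with positive weight vanishes there
        out = np.zeros(table.shape[1])
        pos = (tab > 0).all(axis=0)
        if pos.any():
            out[pos] = np.exp(
                (al[:, None] * np.log(tab[:, pos])).sum(axis=0)
            )
        return out
    if t < 0:
        # a zero component forces the pooled density to 0 (power-mean limit)
        out = np.zeros(table.shape[1])
        pos = (tab > 0).all(axis=0)
        if pos.any():
            out[pos] = (al[:, None] * tab[:, pos] ** t).sum(axis=0) ** (1.0 / t)
        return out
    return (al[:, None] * tab ** t).sum(axis=0) ** (1.0 / t)


def _as_table(priors: Sequence[DiscreteDistribution]) -> np.ndarray:
    support = priors[0].support
    for p in priors[1:]:
        if p.support != support:
            raise ValueError("all priors must share a support")
    return np.stack([p.mass for p in priors])


def power_pool(
    priors: Sequence[DiscreteDistribution], spec: PoolSpec
) -> PooledPrior:
    """Pool ``k`` priors on a common support with the ``t`` power mean.

    ``k = 1`` degenerates to the identity.  Raises when the pool is
    identically zero (e.g. the geometric pool of priors with disjoint
    supports).
    """
    if len(priors) != spec.k and len(priors) != 1:
        raise ValueError(
            f"{len(priors)} priors but {spec.k} weights"
        )
    if len(priors) == 1:
        return PooledPrior(priors[0], 1.0, spec)
    table = _as_table(priors)
    raw = _power_mean_table(table, spec)
    total = raw.sum()
    if total <= 0:
        raise ValueError("pooled density is identically zero")
    if not np.isfinite(total):
        raise ValueError("pooled density is not normalizable")
    c = 1.0 / total
    return PooledPrior(
        DiscreteDistribution(priors[0].support, raw / total), c, spec
    )


def _check_likelihood(likelihood, m: int) -> np.ndarray:
    lik = np.asarray(list(likelihood), dtype=float)
    if lik.size != m:
        raise ValueError("likelihood length does not match the support")
    if np.any(lik < 0):
        raise ValueError("likelihood values must be nonnegative")
    if lik.sum() == 0:
        raise ValueError("likelihood is identically zero on the support")
    return lik


def pooled_posterior(
    priors: Sequence[DiscreteDistribution],
    spec: PoolSpec,
    likelihood: Iterable[float],
) -> DiscreteDistribution:
    """Bayes applied to the t-pooled prior.

    Equals the power mean of the component posteriors of the same degree
    with data-updated weights proportional to ``alpha_i m_i(x)^t``
    (a property-tested identity).
    """
    pool = power_pool(priors, spec)
    lik = _check_likelihood(likelihood, len(pool.density))
    post = pool.density.mass * lik
    if post.sum() == 0:
        raise ValueError("zero marginal likelihood under the pooled prior")
    return DiscreteDistribution.from_weights(pool.density.support, post)


def pooled_rb(
    priors: Sequence[DiscreteDistribution],
    spec: PoolSpec,
    likelihood: Iterable[float],
) -> RBProfile:
    """Relative belief ratios under the t-pooled prior."""
    pool = power_pool(priors, spec)
    post = pooled_posterior(priors, spec, likelihood)
    return relative_belief(pool.density, post)


def consensus_audit(
    component_rbs: Sequence[RBProfile],
    combined_rb: RBProfile,
    tol: float = NEUTRAL_TOL,
) -> dict:
    """Check consensus preservation of a combination, point by point.

    A rule preserves consensus when, wherever at least one base reports
    evidence in favor (against) and no base reports the opposite, the
    combination reports evidence in favor (against); and wherever every
    base is neutral, so is the combination.  Mixed patterns impose no
    constraint.  Returns per-point records and an overall verdict.
    """
    support = combined_rb.support
    for p in component_rbs:
        if p.support != support:
            raise ValueError("component and combined profiles must share a support")
    records = []
    ok = True
    for i, point in enumerate(support):
        # zero-prior-mass points carry no RB; they impose no constraint
        labels = [
            classify(p.rb[i], tol) if p.defined[i] else "undefined"
            for p in component_rbs
        ]
        if not combined_rb.defined[i]:
            records.append(
                {
                    "point": point,
                    "component_labels": labels,
                    "combined_label": "undefined",
                    "pattern": "undefined",
                    "preserved": True,
                }
            )
            continue
        comb = classify(combined_rb.rb[i], tol)
        effective = [lab for lab in labels if lab != "undefined"]
        has_favor = IN_FAVOR in effective
        has_against = AGAINST in effective
        if has_favor and not has_against:
            pattern = "consensus_favor"
            preserved = comb == IN_FAVOR
        elif has_against and not has_favor:
            pattern = "consensus_against"
            preserved = comb == AGAINST
        elif effective and not has_favor and not has_against:
            pattern = "all_neutral"
            preserved = comb == NO_EVIDENCE
        elif not effective:
            pattern = "undefined"
            preserved = True
        else:
            pattern = "mixed"
            preserved = True
        ok = ok and preserved
        records.append(
            {
                "point": point,
                "component_labels": labels,
                "combined_label": comb,
                "pattern": pattern,
                "preserved": preserved,
            }
        )
    return {"per_point": records, "consensus_preserving": ok}
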