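"""Context II: combining evidence when the sampling models differ.

With a common data set but model/prior pairs that differ across
analysts, the linear-pool arithmetic still applies — the combined
profile is the weighted sum of component RBs and the combined posterior
the weighted mixture of component posteriors — but its justification
changes.  The mixture posterior is Jeffrey conditionalization (update
the partition probabilities to ``alpha_i m_i(x)/m_alpha(x)``, condition
within each cell), and coincides with the Bayesian-model-averaging
posterior.  The combined RB sum is no longer literally a posterior/prior
ratio; profiles built here carry ``is_ratio=False`` to record that.

When models differ, the raw predictive weights may reward a model for
predicting aspects of the data that carry no information about the
parameter.  Conditioning the predictives on an ancillary statistic
(`conditional_weights`) restores comparability, and `star_adjust`
implements the pre-division of the weights by each model's multinomial
ancillary probability that makes the adjusted weights converge to
prior-density-at-truth proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .discrete import DiscreteDistribution
from .evidence import RBProfile, relative_belief
from .linpool import (PosteriorWeights, combine_posterior_linear,
                      combine_prior_linear, posterior_weights)

__all__ = [
    "AncillaryConditioner",
    "StarWeights",
    "combine_rb_context2",
    "jeffrey_posterior",
    "naive_mixture_rb",
    "conditional_weights",
    "star_adjust",
    "combine_multi_dataset",
]


@dataclass
class AncillaryConditioner:
    """Per-base evaluators of the conditional predictive m_i(L(x)|A(x)).

    The invariance ``x <-> (L(x), A(x))`` is the caller's responsibility
    to declare; only dimensions are validated here (ancillarity is not
    checkable in general).  Each evaluator returns either a float (a
    closed-form or quadrature value) or a ``(value, standard_error)``
    pair for Monte-Carlo estimators.
    """

    ancillary_value: object
    conditional_predictive: Sequence[Callable[[], object]]
    method: str = "closed_form"  # closed_form | quadrature | importance_sampling
    mc_samples: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.method not in ("closed_form", "quadrature", "importance_sampling"):
            raise ValueError(f"unknown estimator method {self.method!r}")
        if self.method == "importance_sampling" and self.seed is None:
            raise ValueError("a seed is mandatory for importance sampling")


@dataclass(frozen=True)
class StarWeights:
    """Ancillary-comparable weights alpha_i* / f_i(counts), normalized."""

    alpha_star: np.ndarray
    ancillary_pmf_values: np.ndarray
    adjusted_alpha: np.ndarray


def combine_rb_context2(
    weights: PosteriorWeights, component_rbs: Sequence[RBProfile]
) -> RBProfile:
    """Weighted sum of component RBs over a common interest parameter.

    Reduces exactly to the Context I combination when the models agree;
    in general the result is flagged ``is_ratio=False`` because the sum
    of ratios with differing denominators need not be a posterior/prior
    ratio itself.  It still preserves a consensus of evidence directions
    (its weights are nonnegative and sum to 1).
    """
    if weights.k != len(component_rbs):
        raise ValueError("weights and component profiles differ in length")
    support = component_rbs[0].support
    for p in component_rbs[1:]:
        if p.support != support:
            raise ValueError("component profiles must share a support")
    defined = np.logical_and.reduce([p.defined for p in component_rbs])
    rb = np.zeros(len(support))
    for w, p in zip(weights.weights, component_rbs):
        rb[defined] += w * p.rb[defined]
    mix_prior = combine_prior_linear(
        weights.prior_alpha, [p.prior for p in component_rbs]
    )
    mix_post = combine_posterior_linear(
        weights, [p.posterior for p in component_rbs]
    )
    return RBProfile(support, rb, mix_prior, mix_post, defined, is_ratio=False)


def jeffrey_posterior(
    weights: PosteriorWeights,
    component_posteriors: Sequence[DiscreteDistribution],
) -> DiscreteDistribution:
    """The Jeffrey-conditionalization mixture posterior.

    Arithmetic identical to the Context I mixture; documented separately
    because its justification is Jeffrey's rule on the analyst partition
    (and it coincides with the Bayesian-model-averaging posterior).
    """
    return combine_posterior_linear(weights, component_posteriors)


def naive_mixture_rb(
    weights: PosteriorWeights,
    component_priors_on_psi: Sequence[DiscreteDistribution],
    component_posteriors: Sequence[DiscreteDistribution],
) -> dict:
    """(Jeffrey posterior) / (alpha-mixture prior), for comparison only.

    This is the RB one would write down by treating the alpha-mixture of
    the interest-parameter priors as "the" prior.  Its implicit weights
    depend on the interest value, so it is not a linear pooling of the
    evidence and does not retain the good properties of the recommended
    weighted-sum combination; the report includes the pointwise maximum
    discrepancy between the two.
    """
    mix_prior = combine_prior_linear(weights.prior_alpha, list(component_priors_on_psi))
    mix_post = jeffrey_posterior(weights, component_posteriors)
    naive = relative_belief(mix_prior, mix_post)
    component_rbs = [
        relative_belief(pr, po)
        for pr, po in zip(component_priors_on_psi, component_posteriors)
    ]
    recommended = combine_rb_context2(weights, component_rbs)
    both = naive.defined & recommended.defined
    disc = float(np.max(np.abs(naive.rb[both] - recommended.rb[both])))
    return {
        "profile": naive,
        "recommended": recommended,
        "max_discrepancy": disc,
    }


def conditional_weights(
    alpha: Iterable[float], conditioner: AncillaryConditioner
) -> PosteriorWeights:
    """Weights from ancillary-conditioned predictives alpha_i m_i(L|A).

    Monte-Carlo standard errors, when the evaluators provide them, are
    propagated to per-weight standard errors by the delta method on the
    normalized ratio.
    """
    alpha = np.asarray(list(alpha), dtype=float)
    if alpha.size != len(conditioner.conditional_predictive):
        raise ValueError("alpha and conditional evaluators differ in length")
    vals, ses = [], []
    for ev in conditioner.conditional_predictive:
        out = ev()
        if isinstance(out, tuple):
            v, se = out
        else:
            v, se = out, 0.0
        if v < 0:
            raise ValueError("conditional predictive values must be nonnegative")
        vals.append(float(v))
        ses.append(float(se))
    vals = np.asarray(vals)
    ses = np.asarray(ses)
    if conditioner.method == "importance_sampling" and np.all(ses == 0):
        raise ValueError("importance sampling requires standard errors")
    pw = posterior_weights(alpha, vals)
    if np.any(ses > 0):
        # delta method: w_i = a_i v_i / sum_j a_j v_j with independent v_j
        s = float((alpha * vals).sum())
        grads = np.zeros((alpha.size, alpha.size))
        for i in range(alpha.size):
            for j in range(alpha.size):
                if i == j:
                    grads[i, j] = alpha[i] / s - alpha[i] ** 2 * vals[i] / s**2
                else:
                    grads[i, j] = -alpha[i] * vals[i] * alpha[j] / s**2
        w_se = np.sqrt((grads**2 * ses**2).sum(axis=1))
        pw = PosteriorWeights(pw.prior_alpha, pw.predictive_values, pw.weights, w_se)
    return pw


def star_adjust(
    alpha_star: Iterable[float],
    ancillary_counts: Iterable[int],
    partition_probs: Sequence[Iterable[float]],
) -> StarWeights:
    """Pre-divide weights by each model's multinomial ancillary pmf.

    With a finite ancillary partition common to the k models, the count
    vector of the sample over the partition cells is ancillary, with a
    model-specific multinomial pmf ``f_i``.  Setting
    ``alpha_i  ∝  alpha_i* / f_i(counts)`` removes the reward a model
    would otherwise collect merely for predicting the ancillary, making
    the post-data weights comparable across models.
    """
    a_star = np.asarray(list(alpha_star), dtype=float)
    counts = np.asarray(list(ancillary_counts), dtype=int)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n = int(counts.sum())
    pmfs = []
    for probs in partition_probs:
        p = np.asarray(list(probs), dtype=float)
        if p.size != counts.size:
            raise ValueError("partition probabilities do not match the counts")
        if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("cell probabilities must be positive and sum to 1")
        pmfs.append(float(stats.multinomial.pmf(counts, n, p)))
    pmfs = np.asarray(pmfs)
    if a_star.size != pmfs.size:
        raise ValueError("alpha_star and partition_probs differ in length")
    if np.any(pmfs == 0):
        raise ValueError("zero ancillary pmf at the observed counts")
    raw = a_star / pmfs
    return StarWeights(a_star, pmfs, raw / raw.sum())


def combine_multi_dataset(*args, **kwargs):
    """Combination across distinct data sets — deliberately unsupported.

    A weighted-sum rule over per-dataset predictives suggests itself,
    but the comparability of its weights is unresolved; no behavior is
    provided rather than a misleading one.
    """
    raise NotImplementedError(
        "combining evidence across distinct data sets is unsupported: "
        "the comparability of per-dataset predictive weights is an open problem"
    )
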