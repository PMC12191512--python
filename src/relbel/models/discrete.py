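"""Finite discrete inference bases.

A `DiscreteBase` is one analyst's complete specification for a finite
model: a likelihood table ``f_theta(x)`` over (parameter, outcome)
cells, a prior on the parameter grid, and the observed outcome.  All
evidence quantities are then exact rational arithmetic in floating
point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..discrete import DiscreteDistribution
from ..evidence import RBProfile, relative_belief

__all__ = ["DiscreteBase", "discrete_predictive", "two_point_base"]


@dataclass(frozen=True)
class DiscreteBase:
    """(data, finite sampling model, prior) for one analyst.

    ``sampling_table`` has one row per parameter value and one column
    per outcome; each row must sum to 1.
    """

    sampling_table: np.ndarray
    prior: DiscreteDistribution
    outcomes: tuple
    observed: object

    def __init__(self, sampling_table, prior: DiscreteDistribution,
                 outcomes, observed):
        table = np.asarray(sampling_table, dtype=float)
        outcomes = tuple(outcomes)
        if table.shape != (len(prior), len(outcomes)):
            raise ValueError(
                f"table shape {table.shape} != (n_params={len(prior)}, "
                f"n_outcomes={len(outcomes)})"
            )
        if np.any(table < 0):
            raise ValueError("likelihood values must be nonnegative")
        rows = table.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("each parameter row must sum to 1 over outcomes")
        if observed not in outcomes:
            raise ValueError(f"observed outcome {observed!r} not in outcome set")
        table.flags.writeable = False
        object.__setattr__(self, "sampling_table", table)
        object.__setattr__(self, "prior", prior)
        object.__setattr__(self, "outcomes", outcomes)
        object.__setattr__(self, "observed", observed)

    @property
    def likelihood(self) -> np.ndarray:
        """Likelihood column at the observed outcome."""
        j = self.outcomes.index(self.observed)
        return self.sampling_table[:, j]

    def posterior(self) -> DiscreteDistribution:
        return DiscreteDistribution.from_weights(
            self.prior.support, self.prior.mass * self.likelihood
        )

    def rb_profile(self) -> RBProfile:
        return relative_belief(self.prior, self.posterior())


def discrete_predictive(base: DiscreteBase) -> float:
    """Prior predictive probability of the observed outcome.

    ``m(x_obs) = sum_theta prior(theta) f_theta(x_obs)``.
    """
    return float((base.prior.mass * base.likelihood).sum())


def two_point_base(p_a: float, *, f_a0: float = 0.25, f_b0: float = 2.0 / 3.0,
                   observed: int = 0) -> DiscreteBase:
    """Two-parameter ({a, b}), two-outcome ({0, 1}) base.

    The default likelihoods are ``f_a(0) = 1/4`` and ``f_b(0) = 2/3``;
    ``p_a`` is the prior probability of ``a``.
    """
    table = np.array([[f_a0, 1 - f_a0], [f_b0, 1 - f_b0]])
    prior = DiscreteDistribution(("a", "b"), [p_a, 1 - p_a])
    return DiscreteBase(table, prior, (0, 1), observed)
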