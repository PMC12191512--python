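"""Conjugate normal location bases and prediction.

Model: an i.i.d. sample from N(mu, sigma0^2) with known variance,
reduced to its sufficient statistic xbar ~ N(mu, sigma0^2/n).  Each
analyst holds a N(mu_i, tau_i^2) prior for mu, so everything is closed
form:

* posterior:       N( (n/s0^2 + 1/t^2)^-1 (n xbar/s0^2 + mu_i/t^2),
                      (n/s0^2 + 1/t^2)^-1 )
* prior predictive of xbar:  N(mu_i, s0^2/n + t^2), the density whose
  value at the observed xbar drives the combination weight;
* prediction of a future y ~ N(mu, s0^2):  prior predictive
  N(mu_i, s0^2 + t^2), posterior predictive N(post mean, post var + s0^2).

`NormalMixture` carries the weighted combined posteriors explicitly —
mixtures are never re-fitted to a single normal family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from ..evidence import EvidenceReport, continuous_evidence_report
from ..linpool import PosteriorWeights, posterior_weights

__all__ = [
    "NormalLocationBase",
    "PredictionBase",
    "NormalMixture",
    "normal_location_update",
    "prediction_update",
    "location_weights",
    "location_combination_report",
    "prediction_combination_report",
]


@dataclass(frozen=True)
class NormalLocationBase:
    """One analyst's conjugate spec: prior N(mu, tau2), model N(., sigma02)."""

    prior_mean: float
    prior_var: float
    sigma02: float
    n: int
    xbar: float

    def __post_init__(self):
        if self.prior_var <= 0 or self.sigma02 <= 0:
            raise ValueError("variances must be positive")
        if self.n < 1:
            raise ValueError("n must be at least 1")


class ConjugateUpdate(NamedTuple):
    post_mean: float
    post_var: float
    predictive: float  # prior predictive density at the observed xbar


def normal_location_update(base: NormalLocationBase) -> ConjugateUpdate:
    """Closed-form posterior moments and predictive density at xbar."""
    prec = base.n / base.sigma02 + 1.0 / base.prior_var
    post_var = 1.0 / prec
    post_mean = post_var * (
        base.n * base.xbar / base.sigma02 + base.prior_mean / base.prior_var
    )
    pred = stats.norm.pdf(
        base.xbar,
        base.prior_mean,
        np.sqrt(base.sigma02 / base.n + base.prior_var),
    )
    return ConjugateUpdate(float(post_mean), float(post_var), float(pred))


@dataclass(frozen=True)
class PredictionBase:
    """A location base whose interest is a future y ~ N(mu, sigma0^2)."""

    base: NormalLocationBase


class PredictionUpdate(NamedTuple):
    prior_pred_mean: float
    prior_pred_var: float
    post_pred_mean: float
    post_pred_var: float


def prediction_update(pb: PredictionBase) -> PredictionUpdate:
    """Prior and posterior predictive moments for the future value.

    The posterior predictive variance is the posterior variance of mu
    plus the sampling variance sigma0^2 of the new observation.
    """
    b = pb.base
    upd = normal_location_update(b)
    return PredictionUpdate(
        b.prior_mean,
        b.sigma02 + b.prior_var,
        upd.post_mean,
        upd.post_var + b.sigma02,
    )


class NormalMixture:
    """A finite mixture of normals with explicit components."""

    def __init__(self, means, sds, weights):
        self.means = np.asarray(means, dtype=float)
        self.sds = np.asarray(sds, dtype=float)
        self.weights = np.asarray(weights, dtype=float)
        if not (self.means.size == self.sds.size == self.weights.size):
            raise ValueError("component arrays differ in length")
        if np.any(self.sds <= 0):
            raise ValueError("component sds must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def pdf(self, y):
        y = np.asarray(y, dtype=float)
        comp = stats.norm.pdf(y[..., None], self.means, self.sds)
        return (comp * self.weights).sum(axis=-1)

    def cdf(self, y):
        y = np.asarray(y, dtype=float)
        comp = stats.norm.cdf(y[..., None], self.means, self.sds)
        return (comp * self.weights).sum(axis=-1)

    def interval_content(self, lo: float, hi: float) -> float:
        return float(self.cdf(hi) - self.cdf(lo))


def location_weights(
    bases: Sequence[NormalLocationBase], alpha=None
) -> PosteriorWeights:
    """Data-updated weights from the closed-form prior predictives."""
    k = len(bases)
    if alpha is None:
        alpha = np.full(k, 1.0 / k)
    preds = [normal_location_update(b).predictive for b in bases]
    return posterior_weights(alpha, preds)


def _search_interval(means, sds, half_widths=6.0):
    lo = float(np.min(means - half_widths * sds))
    hi = float(np.max(means + half_widths * sds))
    return lo, hi


def location_combination_report(
    bases: Sequence[NormalLocationBase], alpha=None, *, n_grid: int = 4001
) -> dict:
    """Per-base and linear-pool evidence reports for the location mu.

    All bases must share the model (sigma0^2, n, xbar): this is the
    Context I pipeline.  The combined RB for mu is the likelihood
    N(xbar; mu, sigma0^2/n) divided by the alpha-mixture predictive at
    xbar; its plausible interval is found by root finding and the
    posterior content evaluated under the weighted mixture posterior.
    """
    b0 = bases[0]
    for b in bases[1:]:
        if (b.sigma02, b.n, b.xbar) != (b0.sigma02, b0.n, b0.xbar):
            raise ValueError("Context I requires a common model and data")
    w = location_weights(bases, alpha)
    upds = [normal_location_update(b) for b in bases]
    sd_lik = np.sqrt(b0.sigma02 / b0.n)

    post_means = np.array([u.post_mean for u in upds])
    post_sds = np.sqrt([u.post_var for u in upds])
    lo, hi = _search_interval(post_means, post_sds)

    reports = []
    for b, u in zip(bases, upds):
        rep = continuous_evidence_report(
            prior_density=lambda m, b=b: stats.norm.pdf(
                m, b.prior_mean, np.sqrt(b.prior_var)
            ),
            posterior_density=lambda m, u=u: stats.norm.pdf(
                m, u.post_mean, np.sqrt(u.post_var)
            ),
            search_interval=(lo, hi),
            rb=lambda m, b=b, u=u: stats.norm.pdf(b.xbar, m, sd_lik)
            / u.predictive,
            prior_cdf=lambda m, b=b: stats.norm.cdf(
                m, b.prior_mean, np.sqrt(b.prior_var)
            ),
            posterior_cdf=lambda m, u=u: stats.norm.cdf(
                m, u.post_mean, np.sqrt(u.post_var)
            ),
            n_grid=n_grid,
        )
        reports.append(rep)

    mix_pred = float((w.prior_alpha * w.predictive_values).sum())
    post_mix = NormalMixture(post_means, post_sds, w.weights)
    prior_mix = NormalMixture(
        [b.prior_mean for b in bases],
        np.sqrt([b.prior_var for b in bases]),
        w.prior_alpha,
    )
    combined = continuous_evidence_report(
        prior_density=prior_mix.pdf,
        posterior_density=post_mix.pdf,
        search_interval=(lo, hi),
        rb=lambda m: stats.norm.pdf(b0.xbar, m, sd_lik) / mix_pred,
        prior_cdf=prior_mix.cdf,
        posterior_cdf=post_mix.cdf,
        n_grid=n_grid,
    )
    return {
        "weights": w,
        "component_reports": reports,
        "combined_report": combined,
        "combined_posterior": post_mix,
    }


def prediction_combination_report(
    bases: Sequence[NormalLocationBase], alpha=None, *, n_grid: int = 4001
) -> dict:
    """Per-base and combined evidence reports for a future observation.

    Prediction is Context II even with a common model (the conditional
    models for the data given y differ across priors), so the combined
    profile is the Jeffrey/weighted-sum rule with the same posterior
    weights as the location problem.
    """
    w = location_weights(bases, alpha)
    upds = [prediction_update(PredictionBase(b)) for b in bases]
    prior_means = np.array([u.prior_pred_mean for u in upds])
    prior_sds = np.sqrt([u.prior_pred_var for u in upds])
    post_means = np.array([u.post_pred_mean for u in upds])
    post_sds = np.sqrt([u.post_pred_var for u in upds])
    lo, hi = _search_interval(
        np.concatenate([prior_means, post_means]),
        np.concatenate([prior_sds, post_sds]),
    )

    def rb_i(y, i):
        return stats.norm.pdf(y, post_means[i], post_sds[i]) / stats.norm.pdf(
            y, prior_means[i], prior_sds[i]
        )

    reports = []
    for i in range(len(bases)):
        rep = continuous_evidence_report(
            prior_density=lambda y, i=i: stats.norm.pdf(
                y, prior_means[i], prior_sds[i]
            ),
            posterior_density=lambda y, i=i: stats.norm.pdf(
                y, post_means[i], post_sds[i]
            ),
            search_interval=(lo, hi),
            rb=lambda y, i=i: rb_i(y, i),
            prior_cdf=lambda y, i=i: stats.norm.cdf(
                y, prior_means[i], prior_sds[i]
            ),
            posterior_cdf=lambda y, i=i: stats.norm.cdf(
                y, post_means[i], post_sds[i]
            ),
            n_grid=n_grid,
        )
        reports.append(rep)

    post_mix = NormalMixture(post_means, post_sds, w.weights)
    prior_mix = NormalMixture(prior_means, prior_sds, w.prior_alpha)

    def rb_comb(y):
        return sum(wi * rb_i(y, i) for i, wi in enumerate(w.weights))

    combined = continuous_evidence_report(
        prior_density=prior_mix.pdf,
        posterior_density=post_mix.pdf,
        search_interval=(lo, hi),
        rb=rb_comb,
        prior_cdf=prior_mix.cdf,
        posterior_cdf=post_mix.cdf,
        n_grid=n_grid,
    )
    return {
        "weights": w,
        "component_reports": reports,
        "combined_report": combined,
        "combined_posterior": post_mix,
    }
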