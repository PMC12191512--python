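"""The relative-belief evidence calculus for a single inference base.

The principle of evidence: data provide evidence in favor of a value
``psi`` when the posterior probability of ``psi`` exceeds its prior
probability, evidence against when belief decreased, and no evidence
either way when belief is unchanged.  The relative belief ratio

    RB(psi | x) = posterior(psi) / prior(psi)

measures this with cut-off 1.  From an RB profile the module derives the
relative belief estimate (the RB-maximizing value), the plausible region
``Pl(x) = {psi : RB(psi|x) > 1}`` with its prior and posterior contents,
and the strength of evidence at a hypothesized value, i.e. the posterior
probability of ``{psi : RB(psi|x) <= RB(psi0|x)}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate, optimize

from .discrete import DiscreteDistribution

__all__ = [
    "RBProfile",
    "EvidenceReport",
    "relative_belief",
    "classify",
    "evidence_report",
    "strength",
    "continuous_evidence_report",
    "NEUTRAL_TOL",
]

#: |RB - 1| below this counts as "no evidence either way".  Continuous
#: pipelines never hit 1 exactly; discrete exact arithmetic is unaffected.
NEUTRAL_TOL = 1e-9

IN_FAVOR = "in_favor"
AGAINST = "against"
NO_EVIDENCE = "no_evidence"


@dataclass(frozen=True)
class RBProfile:
    """Pointwise relative belief ratios over a finite support.

    ``rb[i]`` is posterior mass / prior mass where the prior mass is
    positive; points with zero prior mass (necessarily zero posterior
    mass) are flagged in ``defined``.
    """

    support: tuple
    rb: np.ndarray
    prior: DiscreteDistribution
    posterior: DiscreteDistribution
    defined: np.ndarray = field(default=None)
    #: False when the profile is a weighted sum across differing models
    #: and therefore not literally a posterior/prior ratio.
    is_ratio: bool = True

    def __post_init__(self):
        if self.defined is None:
            object.__setattr__(self, "defined", np.ones(len(self.support), bool))

    def value(self, point) -> float:
        i = self.support.index(point)
        if not self.defined[i]:
            raise ValueError(f"RB undefined at {point!r} (zero prior mass)")
        return float(self.rb[i])

    def argmax(self) -> int:
        """Index of the RB-maximizing point (ties: smallest index)."""
        rb = np.where(self.defined, self.rb, -np.inf)
        return int(np.argmax(rb))


@dataclass(frozen=True)
class EvidenceReport:
    """Estimate, plausible/implausible regions and their contents."""

    estimate: object
    plausible_region: tuple
    implausible_region: tuple
    posterior_content: float
    prior_content: float
    strength: Optional[float] = None
    #: True when RB is identically 1 and the data indicate nothing.
    uninformative: bool = False

    def to_json(self, **kwargs) -> str:
        def _clean(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        d = {
            "estimate": _clean(self.estimate),
            "plausible_region": [_clean(p) for p in self.plausible_region],
            "implausible_region": [_clean(p) for p in self.implausible_region],
            "posterior_content": self.posterior_content,
            "prior_content": self.prior_content,
            "strength": self.strength,
            "uninformative": self.uninformative,
        }
        return json.dumps(d, **kwargs)


def relative_belief(
    prior: DiscreteDistribution, posterior: DiscreteDistribution
) -> RBProfile:
    """Pointwise ratio of posterior to prior mass.

    Raises on support mismatch, or when the posterior puts mass where
    the prior puts none (belief cannot appear from nowhere under Bayes).
    Satisfies ``sum(prior * rb) = 1`` on the defined part.
    """
    if not prior.same_support(posterior):
        raise ValueError("prior and posterior must share a support")
    p, q = prior.mass, posterior.mass
    bad = (p == 0) & (q > 0)
    if np.any(bad):
        pts = [prior.support[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"positive posterior mass on zero prior mass at {pts}")
    defined = p > 0
    rb = np.zeros_like(p)
    rb[defined] = q[defined] / p[defined]
    return RBProfile(prior.support, rb, prior, posterior, defined)


def classify(rb_value: float, tol: float = NEUTRAL_TOL) -> str:
    """Direction of the evidence at a single value.

    Returns ``"in_favor"`` when ``rb > 1 + tol``, ``"against"`` when
    ``rb < 1 - tol`` and ``"no_evidence"`` otherwise.
    """
    if rb_value < 0:
        raise ValueError("relative belief ratios are nonnegative")
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    if rb_value > 1.0 + tol:
        return IN_FAVOR
    if rb_value < 1.0 - tol:
        return AGAINST
    return NO_EVIDENCE


def strength(rb_profile: RBProfile, psi0) -> float:
    """Posterior probability of ``{psi : RB(psi) <= RB(psi0)}``.

    Large strength with RB(psi0) > 1 is strong evidence in favor; small
    strength with RB(psi0) < 1 is strong evidence against.
    """
    rb0 = rb_profile.value(psi0)
    mask = rb_profile.defined & (rb_profile.rb <= rb0 + 1e-15)
    return float(rb_profile.posterior.mass[mask].sum())


def evidence_report(
    prior: DiscreteDistribution,
    posterior: DiscreteDistribution,
    *,
    tol: float = NEUTRAL_TOL,
    psi0=None,
) -> EvidenceReport:
    """Full evidential summary of a discrete prior/posterior pair.

    Region membership uses the strict cut-off 1 (modulo the neutrality
    tolerance); the estimate maximizes RB with ties broken by the
    smallest support index.  When ``psi0`` is given, the strength of the
    evidence at ``psi0`` is included.
    """
    profile = relative_belief(prior, posterior)
    return report_from_profile(profile, tol=tol, psi0=psi0)


def report_from_profile(
    profile: RBProfile, *, tol: float = NEUTRAL_TOL, psi0=None
) -> EvidenceReport:
    """Build an `EvidenceReport` from an existing RB profile."""
    labels = [
        classify(r, tol) if d else NO_EVIDENCE
        for r, d in zip(profile.rb, profile.defined)
    ]
    plaus = tuple(
        s for s, lab in zip(profile.support, labels) if lab == IN_FAVOR
    )
    implaus = tuple(
        s for s, lab in zip(profile.support, labels) if lab == AGAINST
    )
    uninformative = not plaus and not implaus
    if uninformative:
        estimate = None
    else:
        estimate = profile.support[profile.argmax()]
    post_c = profile.posterior.prob_of(plaus) if plaus else 0.0
    prior_c = profile.prior.prob_of(plaus) if plaus else 0.0
    stren = strength(profile, psi0) if psi0 is not None else None
    return EvidenceReport(
        estimate=estimate,
        plausible_region=plaus,
        implausible_region=implaus,
        posterior_content=post_c,
        prior_content=prior_c,
        strength=stren,
        uninformative=uninformative,
    )


# ---------------------------------------------------------------------
# continuous embodiment
# ---------------------------------------------------------------------

def _eval_grid(rb: Callable, grid: np.ndarray) -> np.ndarray:
    """Evaluate rb on a grid, vectorized when the callable allows it."""
    try:
        vals = np.asarray(rb(grid), dtype=float)
        if vals.shape == grid.shape:
            return vals
    except Exception:
        pass
    return np.array([float(rb(g)) for g in grid])


def _find_unit_crossings(
    rb: Callable[[float], float], grid: np.ndarray, vals: np.ndarray
) -> list:
    resid = vals - 1.0
    crossings = []
    sign = np.sign(resid)
    for i in range(len(grid) - 1):
        if sign[i] == 0:
            crossings.append(grid[i])
        elif sign[i] * sign[i + 1] < 0:
            crossings.append(
                optimize.brentq(lambda z: float(rb(z)) - 1.0,
                                grid[i], grid[i + 1], xtol=1e-9)
            )
    if sign[-1] == 0:
        crossings.append(grid[-1])
    return crossings


def continuous_evidence_report(
    prior_density: Callable[[float], float],
    posterior_density: Callable[[float], float],
    search_interval: Sequence[float],
    *,
    rb: Optional[Callable[[float], float]] = None,
    prior_cdf: Optional[Callable[[float], float]] = None,
    posterior_cdf: Optional[Callable[[float], float]] = None,
    n_grid: int = 4001,
    tol: float = NEUTRAL_TOL,
) -> EvidenceReport:
    """Evidence report for a 1-D continuous parameter.

    The RB function (``posterior_density / prior_density`` unless an
    explicit ``rb`` is supplied, e.g. a linear-pool combination) is
    scanned on a uniform grid over ``search_interval``; each sign change
    of ``rb - 1`` is refined by bisection to absolute tolerance 1e-9 and
    the plausible region is reported as a union of intervals.  Contents
    are computed from the supplied cdfs when available, otherwise by
    adaptive quadrature of the densities.
    """
    lo, hi = float(search_interval[0]), float(search_interval[1])
    if not hi > lo:
        raise ValueError("search interval must have positive length")
    if rb is None:
        def rb(z):
            p = prior_density(z)
            if p <= 0:
                raise ValueError(f"prior density not positive at {z}")
            return posterior_density(z) / p

    grid = np.linspace(lo, hi, n_grid)
    vals = _eval_grid(rb, grid)
    roots = _find_unit_crossings(rb, grid, vals)
    # assemble intervals where rb > 1
    edges = [lo] + roots + [hi]
    intervals = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < 1e-12:
            continue
        mid = 0.5 * (a + b)
        if float(rb(mid)) > 1.0 + tol:
            intervals.append((a, b))
    # merge touching intervals
    merged = []
    for iv in intervals:
        if merged and abs(iv[0] - merged[-1][1]) < 1e-9:
            merged[-1] = (merged[-1][0], iv[1])
        else:
            merged.append(iv)

    if not merged:
        return EvidenceReport(
            estimate=None,
            plausible_region=(),
            implausible_region=((lo, hi),),
            posterior_content=0.0,
            prior_content=0.0,
            uninformative=False,
        )

    def _content(cdf, density, region):
        total = 0.0
        for a, b in region:
            if cdf is not None:
                total += cdf(b) - cdf(a)
            else:
                val, _ = integrate.quad(density, a, b, limit=200)
                total += val
        return float(total)

    post_c = _content(posterior_cdf, posterior_density, merged)
    prior_c = _content(prior_cdf, prior_density, merged)

    # estimate: leftmost grid point attaining the maximal RB, polished
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(lambda z: -float(rb(z)), bounds=(a, b),
                                   method="bounded")
    estimate = float(res.x)

    implaus = []
    prev = lo
    for a, b in merged:
        if a - prev > 1e-9:
            implaus.append((prev, a))
        prev = b
    if hi - prev > 1e-9:
        implaus.append((prev, hi))
    # only keep stretches where rb actually dips below 1
    implaus = [
        iv for iv in implaus if float(rb(0.5 * (iv[0] + iv[1]))) < 1.0 - tol
    ]

    return EvidenceReport(
        estimate=estimate,
        plausible_region=tuple(merged),
        implausible_region=tuple(implaus),
        posterior_content=post_c,
        prior_content=prior_c,
    )
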