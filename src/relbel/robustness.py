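"""Weight-robustness studies and seeded consistency simulations.

Two questions about a combination are answered empirically here:

* how sensitive are its conclusions to the prior weights alpha?  Draw
  alpha from a Dirichlet centered (in mode) at the working weights and
  tabulate how often the conclusion survives (`dirichlet_robustness`);

* does it concentrate on the truth as data accumulate?  Simulate i.i.d.
  samples of growing size from a finite model, track the data-updated
  weights, the combined RB at a hypothesized value, its strength and
  the plausible region, and compare against the theoretical limits:
  weights tend to alpha_i pi_i(theta_true) proportions among the bases
  whose model contains the truth (weight -> 0 for misspecified bases),
  and the star-adjusted weights do the same with alpha* in place of
  alpha (`consistency_sim`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import special, stats

from .discrete import DiscreteDistribution
from .evidence import classify
from .jeffrey import combine_rb_context2
from .linpool import posterior_weights
from .models.discrete import DiscreteBase
from .models.normal import NormalLocationBase
from .models.regression import haavelmo_bases

__all__ = [
    "RobustnessStudy",
    "ConsistencyTrajectory",
    "FiniteModel",
    "dirichlet_robustness",
    "consistency_sim",
    "make_fixture",
]


@dataclass(frozen=True)
class RobustnessStudy:
    """Design of a Dirichlet sweep over the combination weights.

    The Dirichlet parameters are ``1 + concentration * alpha0``, which
    places the mode exactly at ``alpha0``; larger concentration means a
    tighter sweep.
    """

    alpha0: np.ndarray
    concentration: float
    n_draws: int
    seed: int

    def __init__(self, alpha0, concentration, n_draws, seed):
        alpha0 = np.asarray(list(alpha0), dtype=float)
        if np.any(alpha0 < 0) or abs(alpha0.sum() - 1.0) > 1e-9:
            raise ValueError("alpha0 must lie on the simplex")
        if concentration <= 0:
            raise ValueError("concentration must be positive")
        if n_draws < 1:
            raise ValueError("n_draws must be at least 1")
        object.__setattr__(self, "alpha0", alpha0)
        object.__setattr__(self, "concentration", float(concentration))
        object.__setattr__(self, "n_draws", int(n_draws))
        object.__setattr__(self, "seed", int(seed))


def dirichlet_robustness(
    study: RobustnessStudy, combine_fn: Callable[[np.ndarray], dict]
) -> dict:
    """Rerun a configured combination over Dirichlet-drawn weights.

    ``combine_fn(alpha)`` must return a dict with at least a
    ``"conclusion"`` label; ``"strength"``, ``"estimate"``,
    ``"posterior_content"`` and ``"prior_content"`` are recorded when
    present.  The summary reports the proportion of draws whose
    conclusion agrees with the one at ``alpha0`` and quartile summaries
    of the numeric records.
    """
    rng = np.random.default_rng(study.seed)
    baseline = combine_fn(study.alpha0)
    params = 1.0 + study.concentration * study.alpha0
    draws = rng.dirichlet(params, study.n_draws)
    records = []
    agree = 0
    for alpha in draws:
        out = combine_fn(alpha)
        if out["conclusion"] == baseline["conclusion"]:
            agree += 1
        records.append({"alpha": alpha.tolist(), **out})
    numeric = {}
    for key in ("strength", "estimate", "posterior_content", "prior_content"):
        vals = [
            r[key] for r in records
            if isinstance(r.get(key), (int, float, np.floating))
        ]
        if vals:
            arr = np.asarray(vals, dtype=float)
            numeric[key] = {
                "min": float(arr.min()),
                "q25": float(np.quantile(arr, 0.25)),
                "median": float(np.median(arr)),
                "q75": float(np.quantile(arr, 0.75)),
                "max": float(arr.max()),
            }
    prop = agree / study.n_draws
    return {
        "baseline": baseline,
        "agreement_proportion": prop,
        "sensitive": prop < 1.0,
        "records": records,
        "summaries": numeric,
    }


# ---------------------------------------------------------------------
# consistency simulations on finite models
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class FiniteModel:
    """A finite family of categorical sampling distributions."""

    labels: tuple
    pmfs: np.ndarray  # (n_labels, n_categories), rows sum to 1

    def __init__(self, labels, pmfs):
        labels = tuple(labels)
        pmfs = np.asarray(pmfs, dtype=float)
        if pmfs.shape[0] != len(labels):
            raise ValueError("one pmf row per label required")
        if np.any(pmfs < 0) or np.any(np.abs(pmfs.sum(axis=1) - 1) > 1e-9):
            raise ValueError("rows must be pmfs")
        pmfs.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "pmfs", pmfs)

    def contains(self, pmf: np.ndarray, tol: float = 1e-9):
        """Label of the member matching ``pmf``, or None."""
        for lab, row in zip(self.labels, self.pmfs):
            if np.max(np.abs(row - pmf)) < tol:
                return lab
        return None


@dataclass
class ConsistencyTrajectory:
    """Per-size summaries of a consistency simulation."""

    sizes: list
    weights: np.ndarray          # (n_sizes, k) mean weights
    rb_psi0: np.ndarray          # (n_sizes,) mean combined RB at psi0
    strength_psi0: np.ndarray
    estimate_mode: list          # modal combined estimate per size
    plausible_content: np.ndarray
    plausible_size: np.ndarray   # mean cardinality of the plausible region
    limits: dict = field(default_factory=dict)


def _log_predictive(model: FiniteModel, prior: DiscreteDistribution,
                    counts: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        log_pmf = np.log(model.pmfs)
    ll = counts @ log_pmf.T  # per-label log likelihood
    ll = np.where(np.isnan(ll), -np.inf, ll)
    return float(special.logsumexp(ll, b=prior.mass))


def _posterior(model: FiniteModel, prior: DiscreteDistribution,
               counts: np.ndarray) -> DiscreteDistribution:
    with np.errstate(divide="ignore"):
        log_pmf = np.log(model.pmfs)
    ll = counts @ log_pmf.T
    ll = np.where(np.isnan(ll), -np.inf, ll)
    lw = ll + np.log(prior.mass)
    lw -= lw.max()
    return DiscreteDistribution.from_weights(prior.support, np.exp(lw))


def _marginalize(dist: DiscreteDistribution, psi_map) -> DiscreteDistribution:
    buckets: dict = {}
    for pt, m in zip(dist.support, dist.mass):
        key = psi_map(pt)
        buckets[key] = buckets.get(key, 0.0) + m
    keys = sorted(buckets)
    return DiscreteDistribution(keys, [buckets[k] for k in keys])


def consistency_sim(
    models: Sequence[FiniteModel],
    priors: Sequence[DiscreteDistribution],
    alpha,
    true_pmf,
    sizes: Sequence[int],
    replications: int,
    seed: int,
    *,
    psi0=None,
    psi_map: Callable = None,
    star: Optional[dict] = None,
) -> ConsistencyTrajectory:
    """Track weights and combined evidence along a sample-size ladder.

    ``models[i]`` and ``priors[i]`` define base i; data are i.i.d.
    categorical draws from ``true_pmf``.  ``psi_map`` maps parameter
    labels to the common interest parameter (identity by default);
    ``psi0`` defaults to the interest value of the truth in the first
    base whose model contains it.  With ``star = {"alpha_star": ...,
    "partition": cell_of_category, "probs": per-base cell probs}`` the
    weights are the condition-star adjusted ones.

    Sample sizes must be strictly increasing; all output is a pure
    function of the inputs and the seed.
    """
    sizes = list(sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    k = len(models)
    if len(priors) != k:
        raise ValueError("one prior per model required")
    alpha = np.asarray(list(alpha), dtype=float)
    true_pmf = np.asarray(true_pmf, dtype=float)
    if psi_map is None:
        psi_map = lambda lab: lab  # noqa: E731
    rng = np.random.default_rng(seed)
    m_cat = true_pmf.size

    if star is not None:
        cell_of = np.asarray(star["partition"], dtype=int)
        n_cells = cell_of.max() + 1
        cell_probs = [np.asarray(p, dtype=float) for p in star["probs"]]
        log_alpha_star = np.log(np.asarray(star["alpha_star"], dtype=float))

    # theoretical limits; under the star condition the ancillary part is
    # conditioned away, so containment is judged on the conditional
    # within-cell structure rather than the full category pmf
    if star is None:
        true_labels = [mod.contains(true_pmf) for mod in models]
    else:
        def _conditional(pmf, probs):
            return pmf / probs[cell_of]

        true_labels = []
        for mod, cp in zip(models, cell_probs):
            cond_rows = mod.pmfs / cp[cell_of]
            target = _conditional(true_pmf, np.array([
                true_pmf[cell_of == c].sum() for c in range(n_cells)
            ]))
            lab = None
            for label, row in zip(mod.labels, cond_rows):
                if np.max(np.abs(row - target)) < 1e-9:
                    lab = label
                    break
            true_labels.append(lab)
    J = [i for i, lab in enumerate(true_labels) if lab is not None]
    limits: dict = {"J": J}
    if J:
        base_w = star["alpha_star"] if star is not None else alpha
        lim = np.zeros(k)
        for i in J:
            lim[i] = base_w[i] * priors[i].prob(true_labels[i])
        limits["weights"] = (lim / lim.sum()).tolist()
        psi_true = psi_map(true_labels[J[0]])
        limits["psi_true"] = psi_true
        if psi0 is None:
            psi0 = psi_true

    psi_priors = [_marginalize(p, psi_map) for p in priors]

    n_sizes = len(sizes)
    w_acc = np.zeros((n_sizes, k))
    rb_acc = np.zeros(n_sizes)
    st_acc = np.zeros(n_sizes)
    pc_acc = np.zeros(n_sizes)
    ps_acc = np.zeros(n_sizes)
    est_counts = [dict() for _ in sizes]

    for _ in range(replications):
        full = rng.choice(m_cat, size=sizes[-1], p=true_pmf)
        for si, n in enumerate(sizes):
            counts = np.bincount(full[:n], minlength=m_cat).astype(float)
            log_m = np.array(
                [_log_predictive(models[i], priors[i], counts) for i in range(k)]
            )
            if star is not None:
                cell_counts = np.zeros(n_cells)
                for c in range(m_cat):
                    cell_counts[cell_of[c]] += counts[c]
                log_f = np.array(
                    [
                        stats.multinomial.logpmf(cell_counts, n, cp)
                        for cp in cell_probs
                    ]
                )
                # keep alpha* / f_i in log space: the adjustment can span
                # hundreds of log units and must cancel against log_m
                pw = posterior_weights(
                    np.full(k, 1.0 / k),
                    log_alpha_star - log_f + log_m + np.log(k),
                    log=True,
                )
            else:
                pw = posterior_weights(alpha, log_m, log=True)
            psi_posts = [
                _marginalize(_posterior(models[i], priors[i], counts), psi_map)
                for i in range(k)
            ]
            support = psi_posts[0].support
            psi_posts = [
                DiscreteDistribution(support, [p.prob(s) if s in p.support else 0.0
                                               for s in support])
                if p.support != support else p
                for p in psi_posts
            ]
            psi_priors_al = [
                DiscreteDistribution(support, [p.prob(s) if s in p.support else 0.0
                                               for s in support])
                if p.support != support else p
                for p in psi_priors
            ]
            rbs = []
            for pr, po in zip(psi_priors_al, psi_posts):
                from .evidence import relative_belief
                rbs.append(relative_belief(pr, po))
            comb = combine_rb_context2(pw, rbs)
            w_acc[si] += pw.weights
            i0 = comb.support.index(psi0)
            rb0 = comb.rb[i0]
            rb_acc[si] += rb0
            mask = comb.rb <= rb0 + 1e-12
            st_acc[si] += comb.posterior.mass[mask].sum()
            plaus = comb.rb > 1.0
            pc_acc[si] += comb.posterior.mass[plaus].sum()
            ps_acc[si] += plaus.sum()
            est = comb.support[comb.argmax()]
            est_counts[si][est] = est_counts[si].get(est, 0) + 1

    r = replications
    modal = [max(c, key=c.get) if c else None for c in est_counts]
    return ConsistencyTrajectory(
        sizes=sizes,
        weights=w_acc / r,
        rb_psi0=rb_acc / r,
        strength_psi0=st_acc / r,
        estimate_mode=modal,
        plausible_content=pc_acc / r,
        plausible_size=ps_acc / r,
        limits=limits,
    )


# ---------------------------------------------------------------------
# reproducible fixtures
# ---------------------------------------------------------------------

def make_fixture(kind: str, params: Optional[dict] = None, seed: int = 0):
    """Seed-determined synthetic inference bases.

    ``kind="discrete"``: k two-parameter, two-outcome bases with random
    likelihood tables and priors, sharing the observed outcome.
    ``kind="normal_location"``: conjugate location bases; the default
    parameters are the worked-example triple (12,2), (9,1), (11,4) with
    sigma0=1.  ``kind="regression"``: the income/investment normal-vs-t
    pair.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "discrete":
        k = int(params.get("k", 2))
        bases = []
        for _ in range(k):
            table = rng.dirichlet(np.ones(2), size=2)
            p = rng.uniform(0.05, 0.95)
            prior = DiscreteDistribution(("a", "b"), [p, 1 - p])
            bases.append(DiscreteBase(table, prior, (0, 1), 0))
        return bases
    if kind == "normal_location":
        triples = params.get("priors", [(12.0, 2.0), (9.0, 1.0), (11.0, 4.0)])
        sigma0 = float(params.get("sigma0", 1.0))
        n = int(params.get("n", 10))
        if "xbar" in params:
            xbar = float(params["xbar"])
        else:
            mu_true = float(params.get("mu_true", 10.0))
            xbar = float(rng.normal(mu_true, sigma0 / np.sqrt(n)))
        return [
            NormalLocationBase(m, t2, sigma0**2, n, xbar) for m, t2 in triples
        ]
    if kind == "regression":
        lam = float(params.get("lambda", 10.0))
        return haavelmo_bases(lam)
    raise ValueError(f"unknown fixture kind {kind!r}")
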