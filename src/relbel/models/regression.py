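"""Simple linear regression bases with normal or Student-t errors.

Two analysts share the design, the response, and a conjugate
normal-inverse-gamma prior, but disagree on the error family:
``y = X beta + sigma z`` with ``z_i`` i.i.d. standard normal for one and
i.i.d. standardized Student-t (``t_lambda`` scaled by
``sqrt((lambda-2)/lambda)`` so its variance is 1, hence sigma^2 is the
error variance in both models) for the other.  The design has rows
``(1, x_i)`` with the predictor standardized to mean zero and unit norm.

With ``b`` the least-squares estimate, ``s = ||y - Xb||`` and
``a = (y - Xb)/s`` the residual direction, ``y <-> ((b, s), a)`` and
``a`` is ancillary for both models, so the combination weight of each
model is its conditional prior predictive density of ``(b, s)`` given
``a``.  For fixed ``(beta, sigma)`` that conditional density is
proportional to the kernel

    s^{n-3} sigma^{-n} prod_i f( (b1-beta1)/sigma
                                 + (b2-beta2) x_i / sigma + s a_i / sigma )

whose normalizing constant over ``(b, s)`` is free of ``(beta, sigma)``
(translation/scale invariance), so

    m(b, s | a) = E_prior[ kernel ] / c(a),
    c(a) = int w^{n-3} prod_i f(u + v x_i + w a_i) du dv dw.

``E_prior[kernel]`` is estimated by importance sampling from the
normal-error conjugate posterior; ``c(a)`` is closed form for normal
errors and estimated for t errors as a ratio against the normal case.

`elicit_regression_prior` solves the two gamma-cdf equations that pin
down the inverse-variance prior from an interval (-m0, m0) believed to
contain the regression function and bounds (s1, s2) on the half-length
of a gamma-credible response interval.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from ..linpool import PosteriorWeights

__all__ = [
    "RegressionBase",
    "RegressionPrior",
    "haavelmo",
    "standardize_predictor",
    "haavelmo_bases",
    "elicit_regression_prior",
    "regression_conditional_density",
    "regression_model_weights",
]


@dataclass(frozen=True)
class RegressionPrior:
    """beta | sigma^2 ~ N2(0, tau0^2 sigma^2 I);  1/sigma^2 ~ gamma(a1, rate a2)."""

    tau0: float
    alpha1: float
    alpha2: float

    def __post_init__(self):
        if min(self.tau0, self.alpha1, self.alpha2) <= 0:
            raise ValueError("prior hyperparameters must be positive")


def _error_logpdf(family, z):
    """Log density of a standardized error family on an array."""
    if family == "normal":
        return -0.5 * z**2 - 0.5 * np.log(2.0 * np.pi)
    kind, lam = family
    if kind != "t":
        raise ValueError(f"unknown error family {family!r}")
    c = np.sqrt(lam / (lam - 2.0))
    return stats.t.logpdf(z * c, lam) + np.log(c)


def _check_family(family):
    if family == "normal":
        return family
    try:
        kind, lam = family
    except Exception:
        raise ValueError(f"unknown error family {family!r}") from None
    if kind != "t":
        raise ValueError(f"unknown error family {family!r}")
    lam = float(lam)
    if lam <= 2:
        raise ValueError("t errors need lambda > 2 for a finite variance")
    return ("t", lam)


@dataclass(frozen=True)
class RegressionBase:
    """One analyst's regression spec on shared (design, response, prior)."""

    x: np.ndarray  # standardized predictor: mean zero, unit norm
    y: np.ndarray
    prior: RegressionPrior
    error_family: object = "normal"

    def __init__(self, x, y, prior, error_family="normal"):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if abs(x.sum()) > 1e-10 or abs(x @ x - 1.0) > 1e-10:
            raise ValueError("predictor must have mean zero and unit norm")
        x.flags.writeable = False
        y.flags.writeable = False
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "prior", prior)
        object.__setattr__(self, "error_family", _check_family(error_family))

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def design(self) -> np.ndarray:
        return np.column_stack([np.ones(self.n), self.x])

    def least_squares(self):
        """(b, s, a): coefficient estimate, residual norm, residual direction."""
        X = self.design
        b = np.linalg.solve(X.T @ X, X.T @ self.y)
        resid = self.y - X @ b
        s = float(np.linalg.norm(resid))
        return b, s, resid / s


def standardize_predictor(raw) -> np.ndarray:
    """Center a raw predictor and scale it to unit Euclidean norm."""
    raw = np.asarray(raw, dtype=float)
    centered = raw - raw.mean()
    norm = np.linalg.norm(centered)
    if norm == 0:
        raise ValueError("constant predictor cannot be standardized")
    return centered / norm


def haavelmo() -> pd.DataFrame:
    """US income/investment per capita (deflated), 1922-1941."""
    ref = importlib.resources.files("relbel").joinpath("data/haavelmo.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


def haavelmo_bases(
    lam: float,
    prior: RegressionPrior | None = None,
    *,
    center=(340.0, 3.0),
) -> list:
    """The normal-vs-t(lam) pair of bases on the income/investment data.

    The response is centered on the raw scale, ``y = income - c0 - c1 *
    investment`` (which brings the observations near 0), and the
    investment predictor is standardized to mean zero and unit norm.
    """
    df = haavelmo()
    y = df["income"].to_numpy(float) - center[0] - center[1] * df[
        "investment"
    ].to_numpy(float)
    x = standardize_predictor(df["investment"].to_numpy(float))
    if prior is None:
        prior = RegressionPrior(0.54, 4.05, 140.39)
    return [
        RegressionBase(x, y, prior, "normal"),
        RegressionBase(x, y, prior, ("t", lam)),
    ]


# ---------------------------------------------------------------------
# prior elicitation
# ---------------------------------------------------------------------

class ElicitedPrior(NamedTuple):
    tau0: float
    alpha1: float
    alpha2: float


def _squared_quantile(gamma: float, convention: str) -> float:
    """The squared-threshold constant of the two cdf equations.

    ``"chi2"`` uses the chi-square(1) quantile at (1+gamma)/2, which is
    the convention that reproduces published worked-example values;
    ``"normal"`` uses the literal square of the standard-normal quantile
    z_{(1+gamma)/2}.  The two differ because the chi-square(1) quantile
    at p equals z_{(1+p)/2}^2, not z_p^2.
    """
    if convention == "chi2":
        return float(stats.chi2.ppf((1 + gamma) / 2, 1))
    if convention == "normal":
        return float(stats.norm.ppf((1 + gamma) / 2) ** 2)
    raise ValueError(f"unknown quantile convention {convention!r}")


def elicit_regression_prior(
    gamma: float,
    m0: float,
    s1: float,
    s2: float,
    *,
    zeta0: float | None = None,
    r_max: float | None = None,
    quantile_convention: str = "chi2",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ElicitedPrior:
    """Solve for (tau0, alpha1, alpha2) from interval-based elicitation.

    Inputs: ``gamma`` the virtual-certainty probability; ``m0`` a bound
    such that the regression function lies in (-m0, m0); ``s1 < s2``
    lower and upper bounds on the half-length of the gamma-credible
    response interval.  ``zeta0`` (or ``r_max`` with
    ``zeta0 = sqrt(1 + r_max^2)``) scales ``tau0 = m0/(s2 zeta0)``.

    alpha1 and alpha2 solve, with ``q`` the squared-threshold constant,

        G(alpha1, 1, alpha2 q / s1^2) = (1+gamma)/2
        G(alpha1, 1, alpha2 q / s2^2) = (1-gamma)/2

    by the stated iteration: for trial alpha1, the first equation gives
    alpha2 through a gamma quantile; bisect on alpha1 until the second
    holds.  Both equations are satisfied to ``tol`` on exit.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must be in (0, 1)")
    if not 0 < s1 < s2:
        raise ValueError("need 0 < s1 < s2")
    if m0 <= 0:
        raise ValueError("m0 must be positive")
    if zeta0 is None:
        zeta0 = np.sqrt(1.0 + r_max**2) if r_max is not None else np.sqrt(2.0)
    q = _squared_quantile(gamma, quantile_convention)
    hi_p, lo_p = (1 + gamma) / 2, (1 - gamma) / 2

    def inner_alpha2(a1: float) -> float:
        w = special.gammaincinv(a1, hi_p)
        return w * s1**2 / q

    def residual(a1: float) -> float:
        a2 = inner_alpha2(a1)
        return special.gammainc(a1, a2 * q / s2**2) - lo_p

    # the residual decreases in alpha1: a smaller shape makes the gamma
    # more skewed, widening the quantile ratio the two equations pin down
    lo, hi = 1e-3, 1.0
    it = 0
    while residual(hi) > 0:
        hi *= 2.0
        it += 1
        if it > max_iter:
            raise ArithmeticError("failed to bracket alpha1 from above")
    while residual(lo) < 0:
        lo /= 2.0
        it += 1
        if it > max_iter:
            raise ArithmeticError("failed to bracket alpha1 from below")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(1.0, hi):
            break
    else:
        raise ArithmeticError("alpha1 bisection did not converge")
    a1 = 0.5 * (lo + hi)
    a2 = inner_alpha2(a1)
    eq1 = special.gammainc(a1, a2 * q / s1**2) - hi_p
    eq2 = special.gammainc(a1, a2 * q / s2**2) - lo_p
    if max(abs(eq1), abs(eq2)) > tol:
        raise ArithmeticError("cdf equations not satisfied to tolerance")
    return ElicitedPrior(float(m0 / (s2 * zeta0)), float(a1), float(a2))


# ---------------------------------------------------------------------
# conditional density kernel and model weights
# ---------------------------------------------------------------------

def regression_conditional_density(
    base: RegressionBase,
    b: Sequence[float],
    s: float,
    a: Sequence[float],
    beta: Sequence[float],
    sigma: float,
    *,
    log: bool = False,
) -> float:
    """Unnormalized conditional density of (b, s) given A(y)=a at (beta, sigma).

    ``a`` must be a unit vector orthogonal to both design columns.
    This is the kernel integrated against the prior inside the weight
    computation; ``s = 0`` gives density 0 for n > 3.
    """
    b = np.asarray(b, dtype=float)
    beta = np.asarray(beta, dtype=float)
    a = np.asarray(a, dtype=float)
    n = base.n
    if a.size != n:
        raise ValueError("residual direction has wrong length")
    if (
        abs(a @ np.ones(n)) > 1e-8
        or abs(a @ base.x) > 1e-8
        or abs(a @ a - 1.0) > 1e-8
    ):
        raise ValueError(
            "residual direction must be unit norm and orthogonal to the design"
        )
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if s < 0:
        raise ValueError("s must be nonnegative")
    if s == 0.0:
        return -np.inf if log else 0.0
    z = ((b[0] - beta[0]) + (b[1] - beta[1]) * base.x + s * a) / sigma
    lv = (
        (n - 3) * np.log(s)
        - n * np.log(sigma)
        + _error_logpdf(base.error_family, z).sum()
    )
    return float(lv) if log else float(np.exp(lv))


def _log_c_normal(n: int) -> float:
    """Closed-form log normalizing constant of the normal-error kernel."""
    return (
        -n / 2 * np.log(2 * np.pi)
        + 0.5 * np.log(2 * np.pi / n)
        + 0.5 * np.log(2 * np.pi)
        + (n - 4) / 2 * np.log(2.0)
        + special.gammaln((n - 2) / 2)
    )


def _conjugate_normal_posterior(base: RegressionBase):
    """NIG posterior of (beta, sigma^2) under normal errors (the proposal)."""
    X, y, pr = base.design, base.y, base.prior
    Vinv = X.T @ X + np.eye(2) / pr.tau0**2
    V = np.linalg.inv(Vinv)
    mean = V @ (X.T @ y)
    a1_post = pr.alpha1 + base.n / 2
    a2_post = pr.alpha2 + 0.5 * (y @ y - mean @ Vinv @ mean)
    return mean, V, Vinv, a1_post, a2_post


def _log_mean_exp(lw: np.ndarray):
    """(log mean, relative SE) of exp(lw) from Monte-Carlo draws."""
    m = lw.max()
    vals = np.exp(lw - m)
    est = vals.mean()
    rel_se = vals.std() / (np.sqrt(vals.size) * est)
    ess = vals.sum() ** 2 / (vals**2).sum()
    return m + np.log(est), float(rel_se), float(ess)


def regression_model_weights(
    bases: Sequence[RegressionBase],
    alpha=None,
    *,
    mc_samples: int = 100_000,
    seed: int | None = None,
    min_ess: float = 100.0,
) -> PosteriorWeights:
    """Ancillary-conditioned posterior weights of the regression models.

    All bases must share the design, response and prior, differing only
    in the error family.  Per base, ``E_prior[kernel]`` is estimated by
    importance sampling from the normal-error conjugate posterior of
    (beta, sigma^2) and divided by the conditional normalizing constant
    ``c(a)`` (closed form for normal errors; for others a ratio against
    the normal constant estimated on shared draws from the normal
    configuration measure).  Per-weight standard errors come from the
    delta method on the log predictive estimates.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for the stochastic estimator")
    b0 = bases[0]
    for bb in bases[1:]:
        if not (
            np.array_equal(bb.x, b0.x)
            and np.array_equal(bb.y, b0.y)
            and bb.prior == b0.prior
        ):
            raise ValueError("bases must share design, response and prior")
    k = len(bases)
    if alpha is None:
        alpha = np.full(k, 1.0 / k)
    alpha = np.asarray(alpha, dtype=float)
    n = b0.n
    x = b0.x
    pr = b0.prior
    bhat, s_obs, a_dir = b0.least_squares()

    rng = np.random.default_rng(seed)
    mean, V, Vinv, a1_post, a2_post = _conjugate_normal_posterior(b0)
    sig2 = a2_post / rng.gamma(a1_post, 1.0, mc_samples)
    L = np.linalg.cholesky(V)
    beta = mean + (L @ rng.standard_normal((2, mc_samples))).T * np.sqrt(sig2)[
        :, None
    ]
    sig = np.sqrt(sig2)

    log_prior = (
        stats.norm.logpdf(beta[:, 0], 0.0, pr.tau0 * sig)
        + stats.norm.logpdf(beta[:, 1], 0.0, pr.tau0 * sig)
        + stats.invgamma.logpdf(sig2, pr.alpha1, scale=pr.alpha2)
    )
    dev = beta - mean
    quad = np.einsum("ij,jk,ik->i", dev, Vinv, dev)
    log_prop = (
        -0.5 * quad / sig2
        - np.log(2 * np.pi)
        - 0.5 * np.log(np.linalg.det(V))
        - np.log(sig2)
        + stats.invgamma.logpdf(sig2, a1_post, scale=a2_post)
    )

    z = (
        (bhat[0] - beta[:, 0])[:, None]
        + (bhat[1] - beta[:, 1])[:, None] * x[None, :]
        + s_obs * a_dir[None, :]
    ) / sig[:, None]

    # shared draws from the normal configuration measure for the c-ratios
    u = rng.standard_normal(mc_samples) / np.sqrt(n)
    v = rng.standard_normal(mc_samples)
    w = np.sqrt(rng.chisquare(n - 2, mc_samples))
    zz = u[:, None] + v[:, None] * x[None, :] + w[:, None] * a_dir[None, :]
    log_zz_normal = _error_logpdf("normal", zz).sum(axis=1)
    log_c_norm = _log_c_normal(n)

    log_m, ses = [], []
    for bb in bases:
        lw = (
            (n - 3) * np.log(s_obs)
            - n * np.log(sig)
            + _error_logpdf(bb.error_family, z).sum(axis=1)
            + log_prior
            - log_prop
        )
        lnum, rse_num, ess = _log_mean_exp(lw)
        if ess < min_ess:
            raise ArithmeticError(
                f"degenerate importance weights (ESS={ess:.1f}) for "
                f"{bb.error_family!r}"
            )
        if bb.error_family == "normal":
            lc, rse_c = log_c_norm, 0.0
        else:
            lr = _error_logpdf(bb.error_family, zz).sum(axis=1) - log_zz_normal
            lratio, rse_c, _ = _log_mean_exp(lr)
            lc = log_c_norm + lratio
        log_m.append(lnum - lc)
        ses.append(np.hypot(rse_num, rse_c))
    log_m = np.asarray(log_m)
    ses = np.asarray(ses)

    lw_all = np.log(alpha) + log_m
    lw_all -= lw_all.max()
    wts = np.exp(lw_all)
    wts /= wts.sum()
    # delta method on independent log-predictive errors
    J = np.diag(wts) - np.outer(wts, wts)
    w_se = np.sqrt((J**2 * ses[None, :] ** 2).sum(axis=1))
    return PosteriorWeights(alpha, np.exp(log_m), wts, w_se)
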