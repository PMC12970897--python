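"""Multi-item gamma-Poisson shrinker (MGPS).

The observed count ``a`` for a drug–event pair is modelled as
Poisson(λ·E), with E the count expected under independence of drug and
event margins. The relative-reporting rate λ carries a two-component
gamma mixture prior

    λ ~ w · Gamma(α₁, β₁) + (1 − w) · Gamma(α₂, β₂)      (rate parametrisation)

whose five hyperparameters are estimated by maximising the marginal
likelihood across all pairs in the database — a mixture of negative
binomials. The posterior for each pair is again a gamma mixture with
updated parameters (αᵢ + a, βᵢ + E); EBGM is the geometric mean
exp E[ln λ | a] and EB05 the posterior 5th percentile, solved
numerically. Shrinkage pulls small-count pairs toward the database
grand mean, suppressing false positives among rare events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "GammaPoissonPrior",
    "DEFAULT_PRIOR_START",
    "PriorFitError",
    "fit_gamma_poisson_prior",
    "ebgm",
    "posterior_quantile",
]


@dataclass(frozen=True)
class GammaPoissonPrior:
    """Hyperparameters of the two-component gamma mixture prior on λ."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self):
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("mixture weight w must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.beta1, self.alpha2, self.beta2, self.w])


#: Documented default optimiser start (DuMouchel's canonical choice).
DEFAULT_PRIOR_START = GammaPoissonPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


class PriorFitError(RuntimeError):
    """Non-convergence; carries the best parameters found so far."""

    def __init__(self, message: str, best: GammaPoissonPrior, loglik: float):
        super().__init__(message)
        self.best = best
        self.loglik = loglik


def _nb_logpmf(a, alpha, beta, E):
    """log P(a | α, β, E) for the gamma-Poisson marginal (negative binomial)."""
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    p = beta / (beta + E)
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * np.log(p)
        + a * np.log1p(-p)
    )


def _mixture_loglik(theta, a, E):
    la1, lb1, la2, lb2, logit_w = theta
    w = special.expit(logit_w)
    l1 = _nb_logpmf(a, np.exp(la1), np.exp(lb1), E)
    l2 = _nb_logpmf(a, np.exp(la2), np.exp(lb2), E)
    stacked = np.stack([l1 + np.log(w + 1e-300), l2 + np.log(1 - w + 1e-300)])
    return float(np.sum(special.logsumexp(stacked, axis=0)))


def fit_gamma_poisson_prior(
    a,
    E,
    init: GammaPoissonPrior = DEFAULT_PRIOR_START,
    maxiter: int = 2000,
) -> tuple[GammaPoissonPrior, dict]:
    """Maximum-marginal-likelihood fit of the mixture prior.

    Parameters
    ----------
    a, E : array-like
        Observed and expected counts over all drug–event pairs
        (≥ 2 distinct pairs; all E > 0).

    Returns
    -------
    (prior, info)
        ``info`` holds ``converged``, ``loglik``, ``n_pairs`` and the
        optimiser message. Non-convergence raises :class:`PriorFitError`
        carrying the best parameters found.
    """
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    if a.shape != E.shape or a.size < 2:
        raise ValueError("need >= 2 (a, E) pairs of equal length")
    if np.any(E <= 0):
        raise ValueError("all expected counts must be > 0")

    theta0 = np.array(
        [
            np.log(init.alpha1),
            np.log(init.beta1),
            np.log(init.alpha2),
            np.log(init.beta2),
            special.logit(min(max(init.w, 1e-6), 1 - 1e-6)),
        ]
    )

    def nll(theta):
        return -_mixture_loglik(theta, a, E)

    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        res = optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-7, "fatol": 1e-10},
        )
    la1, lb1, la2, lb2, logit_w = res.x
    prior = GammaPoissonPrior(
        float(np.exp(la1)),
        float(np.exp(lb1)),
        float(np.exp(la2)),
        float(np.exp(lb2)),
        float(special.expit(logit_w)),
    )
    info = {
        "converged": bool(res.success),
        "loglik": float(-res.fun),
        "n_pairs": int(a.size),
        "message": res.message,
    }
    if not res.success:
        raise PriorFitError(f"prior fit did not converge: {res.message}", prior, info["loglik"])
    return prior, info


def _posterior_weights(a: float, E: float, prior: GammaPoissonPrior) -> np.ndarray:
    l1 = _nb_logpmf(a, prior.alpha1, prior.beta1, E) + np.log(prior.w + 1e-300)
    l2 = _nb_logpmf(a, prior.alpha2, prior.beta2, E) + np.log(1 - prior.w + 1e-300)
    m = max(l1, l2)
    q = np.exp(np.array([l1, l2]) - m)
    return q / q.sum()


def ebgm(a: float, E: float, prior: GammaPoissonPrior) -> tuple[float, float]:
    """Posterior EBGM and EB05 for one pair under a fitted prior.

    EBGM = exp E[ln λ | a] over the posterior gamma mixture; EB05 is the
    posterior 5th percentile found by root-finding on the mixture CDF.
    """
    if E <= 0:
        raise ValueError("E must be > 0")
    q = _posterior_weights(a, E, prior)
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + E, prior.beta2 + E])
    mean_log = float(np.sum(q * (special.digamma(shapes) - np.log(rates))))
    eb = float(np.exp(mean_log))
    eb05 = posterior_quantile(0.05, q, shapes, rates)
    return eb, eb05


def posterior_quantile(p: float, q: np.ndarray, shapes: np.ndarray, rates: np.ndarray) -> float:
    """Quantile of a two-component gamma mixture (rate parametrisation)."""
    comp_q = stats.gamma.ppf(p, shapes, scale=1.0 / rates)
    lo = float(np.min(comp_q)) * 0.5
    hi = float(np.max(comp_q)) * 2.0 + 1e-12

    def cdf(x):
        return float(np.sum(q * stats.gamma.cdf(x, shapes, scale=1.0 / rates))) - p

    # widen the bracket if the mixture mass is more spread than either component
    while cdf(lo) > 0 and lo > 1e-300:
        lo *= 0.5
    while cdf(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(cdf, lo, hi, xtol=1e-12, rtol=1e-12))
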