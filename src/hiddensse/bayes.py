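"""Bayesian model comparison with a prior on the sampling fraction.

Reduced-scale arm of the study: a 2-examined x 2-concealed state system,
random-walk MCMC on log-rates and a logit-transformed global sampling
fraction, stepping-stone marginal likelihoods and Bayes-factor model
choice between the trait-dependent and trait-independent parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import NumericalFailureError
from .fit import ModelSpec, get_model
from .likelihood import LikelihoodSettings, loglik
from .states import StateSpace
from .trees import CladeTree

__all__ = [
    "SFPrior",
    "PosteriorSample",
    "log_posterior",
    "run_mcmc",
    "stepping_stone",
    "stepping_stone_logml",
    "bayes_factor_select",
    "default_ladder",
    "BAYES_SPACE",
]

BAYES_SPACE = StateSpace(2, 2)

# rate priors (not dictated by the study design; configurable)
PRIOR_RATE_LAMBDA_MU = 1.0  # exponential with mean 1 on lambda and mu
PRIOR_RATE_Q = 2.0  # exponential with mean 0.5 on q


@dataclass(frozen=True)
class SFPrior:
    """Uniform prior on the global sampling fraction."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper <= 1.0):
            raise ValueError("require 0 < lower < upper <= 1")

    def contains(self, rho: float) -> bool:
        return self.lower <= rho <= self.upper

    def logpdf(self, rho: float) -> float:
        if not self.contains(rho):
            return -np.inf
        return -np.log(self.upper - self.lower)


WIDE_PRIOR = SFPrior(0.3, 0.9)
NARROW_PRIOR = SFPrior(0.5, 0.7)


def _log_rate_priors(rates: np.ndarray, model: ModelSpec) -> float:
    lp = 0.0
    for name, value in zip(model.param_names, rates):
        theta = PRIOR_RATE_Q if name == "q" else PRIOR_RATE_LAMBDA_MU
        if value <= 0:
            return -np.inf
        lp += np.log(theta) - theta * value
    return lp


def log_posterior(
    rates: Sequence[float],
    rho: float,
    clade: CladeTree,
    model: ModelSpec,
    prior: SFPrior,
    condition_on_survival: bool = True,
    ode_rel_tol: float = 1e-6,
    ode_abs_tol: float = 1e-8,
    likelihood_power: float = 1.0,
) -> float:
    """Unnormalized log posterior; -inf outside the prior support."""
    rates = np.asarray(rates, dtype=float)
    if not prior.contains(rho):
        return -np.inf
    lp = _log_rate_priors(rates, model) + prior.logpdf(rho)
    if not np.isfinite(lp):
        return lp
    if likelihood_power == 0.0:
        return lp
    settings = LikelihoodSettings(
        rho=np.full(model.space.n_examined, rho),
        condition_on_survival=condition_on_survival,
        ode_rel_tol=ode_rel_tol,
        ode_abs_tol=ode_abs_tol,
    )
    try:
        ll = loglik(clade, model.to_params(rates), settings)
    except NumericalFailureError:
        return -np.inf
    return lp + likelihood_power * ll


@dataclass
class PosteriorSample:
    """MCMC output: natural-scale draws with posterior/likelihood values."""

    params: np.ndarray  # (n_samples, k_rates + 1); last column is rho
    log_post: np.ndarray
    log_lik: np.ndarray
    acceptance: np.ndarray  # per-coordinate (gibbs) or scalar-wrapped (block)
    param_names: tuple[str, ...]
    power: float = 1.0

    def ess(self) -> dict[str, float]:
        """Effective sample sizes (initial positive sequence estimator)."""
        return {
            name: _ess(self.params[:, j])
            for j, name in enumerate(self.param_names)
        }


def _ess(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for lag in range(1, n // 2):
        pair = acf[2 * lag - 1] + acf[2 * lag] if 2 * lag < len(acf) else 0.0
        if pair <= 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


class _TransformedTarget:
    """Posterior on working coordinates: log rates, logit-scaled rho."""

    def __init__(self, clade, model, prior, likelihood_power=1.0, likelihood_on=True,
                 condition_on_survival=True):
        self.clade = clade
        self.model = model
        self.prior = prior
        self.power = likelihood_power if likelihood_on else 0.0
        self.condition = condition_on_survival
        self.k = model.k + 1
        self.names = model.param_names + ("rho",)

    def to_natural(self, z: np.ndarray) -> tuple[np.ndarray, float]:
        rates = np.exp(z[:-1])
        s = 1.0 / (1.0 + np.exp(-z[-1]))
        rho = self.prior.lower + (self.prior.upper - self.prior.lower) * s
        return rates, rho

    def log_density(self, z: np.ndarray) -> tuple[float, float]:
        """(log target density in z, log likelihood at z)."""
        rates, rho = self.to_natural(z)
        lp = _log_rate_priors(rates, self.model) + self.prior.logpdf(rho)
        # Jacobians: d rate / d log-rate = rate; d rho / d logit = (u-l) s (1-s)
        lp += np.sum(z[:-1])
        s = (rho - self.prior.lower) / (self.prior.upper - self.prior.lower)
        if s <= 0.0 or s >= 1.0:  # logit underflow at extreme working values
            return -np.inf, -np.inf
        lp += np.log(self.prior.upper - self.prior.lower) + np.log(s) + np.log1p(-s)
        if not np.isfinite(lp):
            return -np.inf, -np.inf
        ll = 0.0
        if self.power != 0.0:
            settings = LikelihoodSettings(
                rho=np.full(self.model.space.n_examined, rho),
                condition_on_survival=self.condition,
                ode_rel_tol=1e-6,
                ode_abs_tol=1e-8,
            )
            try:
                ll = loglik(self.clade, self.model.to_params(rates), settings)
            except NumericalFailureError:
                return -np.inf, -np.inf
        elif self.power == 0.0 and self.clade is not None:
            # likelihood still reported (but not used) only when cheap enough;
            # prior-only sampling skips it entirely
            ll = 0.0
        return lp + self.power * ll, ll

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        z = np.concatenate([np.log(rng.uniform(0.05, 0.5, size=self.model.k)), [0.0]])
        return z


def _mcmc_core(
    target: _TransformedTarget,
    n_iter: int,
    rng: np.random.Generator,
    init: Optional[np.ndarray] = None,
    burn_in: Optional[int] = None,
    update: str = "gibbs",
    adapt: bool = True,
):
    """Adaptive random-walk Metropolis; per-coordinate or joint updates."""
    k = target.k
    burn = n_iter // 4 if burn_in is None else burn_in
    z = target.initial(rng) if init is None else np.array(init, dtype=float)
    lp, ll = target.log_density(z)
    tries = 0
    while not np.isfinite(lp):  # find a valid starting point
        z = target.initial(rng)
        lp, ll = target.log_density(z)
        tries += 1
        if tries > 100:
            raise NumericalFailureError("could not initialize MCMC in the support")
    scales = np.full(k, 0.4)
    n_acc = np.zeros(k)
    n_try = np.zeros(k)
    keep_z = np.empty((n_iter, k))
    keep_lp = np.empty(n_iter)
    keep_ll = np.empty(n_iter)
    target_rate = 0.44 if update == "gibbs" else 0.28
    for it in range(burn + n_iter):
        if update == "gibbs":
            order = rng.permutation(k)
            for j in order:
                zprop = z.copy()
                zprop[j] += rng.normal(0.0, scales[j])
                lpp, llp = target.log_density(zprop)
                n_try[j] += 1
                if np.log(rng.random()) < lpp - lp:
                    z, lp, ll = zprop, lpp, llp
                    n_acc[j] += 1
                if adapt and it < burn:
                    rate = n_acc[j] / max(n_try[j], 1)
                    scales[j] *= np.exp((rate - target_rate) / np.sqrt(1.0 + n_try[j] / k))
        else:  # joint spherical update
            zprop = z + rng.normal(0.0, scales[0], size=k)
            lpp, llp = target.log_density(zprop)
            n_try[0] += 1
            if np.log(rng.random()) < lpp - lp:
                z, lp, ll = zprop, lpp, llp
                n_acc[0] += 1
            if adapt and it < burn:
                rate = n_acc[0] / n_try[0]
                scales[0] *= np.exp((rate - target_rate) / np.sqrt(1.0 + n_try[0]))
        if it >= burn:
            keep_z[it - burn] = z
            keep_lp[it - burn] = lp
            keep_ll[it - burn] = ll
    accept = np.where(n_try > 0, n_acc / np.maximum(n_try, 1), np.nan)
    return keep_z, keep_lp, keep_ll, accept[: (k if update == "gibbs" else 1)], z


def run_mcmc(
    clade: Optional[CladeTree],
    model: ModelSpec,
    prior: SFPrior,
    n_iter: int,
    seed: int,
    burn_in: Optional[int] = None,
    likelihood_on: bool = True,
    update: str = "gibbs",
    likelihood_power: float = 1.0,
) -> PosteriorSample:
    """Sample the posterior (or the prior with ``likelihood_on=False``)."""
    rng = np.random.default_rng(seed)
    target = _TransformedTarget(
        clade, model, prior, likelihood_power=likelihood_power, likelihood_on=likelihood_on
    )
    keep_z, keep_lp, keep_ll, accept, _ = _mcmc_core(
        target, n_iter, rng, burn_in=burn_in, update=update
    )
    nat = np.empty_like(keep_z)
    for i in range(keep_z.shape[0]):
        rates, rho = target.to_natural(keep_z[i])
        nat[i, :-1] = rates
        nat[i, -1] = rho
    return PosteriorSample(
        params=nat,
        log_post=keep_lp,
        log_lik=keep_ll,
        acceptance=accept,
        param_names=target.names,
        power=likelihood_power if likelihood_on else 0.0,
    )


def default_ladder(k_rungs: int = 50, shape: float = 0.3) -> np.ndarray:
    """Power ladder 0 = b_0 < ... < b_K = 1 at Beta(shape, 1) quantiles."""
    return (np.arange(k_rungs + 1) / k_rungs) ** (1.0 / shape)


def stepping_stone(
    sample_power_posterior: Callable[[float, int, int, Optional[np.ndarray]], tuple[np.ndarray, Optional[np.ndarray]]],
    betas: np.ndarray,
    n_iter: int,
    seed: int,
) -> tuple[float, float]:
    """Generic stepping-stone estimator.

    ``sample_power_posterior(beta, n_iter, seed, init)`` must return
    ``(log_lik_samples, final_state)`` drawn from the power posterior at
    ``beta``; chains are warm-started rung to rung.  Returns the log
    marginal likelihood and a batch-means standard error.
    """
    betas = np.asarray(betas, dtype=float)
    if betas[0] != 0.0 or betas[-1] != 1.0 or np.any(np.diff(betas) <= 0):
        raise ValueError("ladder must increase strictly from 0 to 1")
    logml = 0.0
    var_total = 0.0
    state: Optional[np.ndarray] = None
    for idx in range(len(betas) - 1):
        b0, b1 = betas[idx], betas[idx + 1]
        ll, state = sample_power_posterior(b0, n_iter, seed + idx, state)
        w = (b1 - b0) * np.asarray(ll, dtype=float)
        m = np.max(w)
        contrib = m + np.log(np.mean(np.exp(w - m)))
        logml += contrib
        # batch-means variance of the log-mean-exp increment
        nb = max(4, int(np.sqrt(len(w))))
        size = len(w) // nb
        if size >= 2:
            bm = []
            for b in range(nb):
                chunk = w[b * size : (b + 1) * size]
                mm = np.max(chunk)
                bm.append(mm + np.log(np.mean(np.exp(chunk - mm))))
            var_total += np.var(bm, ddof=1) / nb
    return float(logml), float(np.sqrt(var_total))


def stepping_stone_logml(
    clade: CladeTree,
    model: ModelSpec,
    prior: SFPrior,
    ladder: Optional[np.ndarray] = None,
    n_iter: int = 500,
    seed: int = 0,
    update: str = "block",
) -> tuple[float, float]:
    """Stepping-stone log marginal likelihood of one SSE parameterization."""
    betas = default_ladder() if ladder is None else np.asarray(ladder, dtype=float)

    def sampler(beta, n, s, init):
        target = _TransformedTarget(clade, model, prior, likelihood_power=beta)
        # power-0 rungs still need the likelihood recorded for the ratio
        if beta == 0.0:
            target.power = 0.0
            target_ll = _TransformedTarget(clade, model, prior, likelihood_power=1.0)
            rng = np.random.default_rng(s)
            z, _, _, _, final = _mcmc_core(target, n, rng, init=init, update=update)
            ll = np.array([target_ll.log_density(z[i])[1] for i in range(len(z))])
            return ll, final
        rng = np.random.default_rng(s)
        z, _, ll, _, final = _mcmc_core(target, n, rng, init=init, update=update)
        return ll, final

    return stepping_stone(sampler, betas, n_iter, seed)


def bayes_factor_select(logml_dependent: float, logml_independent: float) -> tuple[str, float]:
    """Pick the higher-evidence model; ties go to the independent model.

    Returns (selected, 2 * (logML_dependent - logML_independent)).
    """
    if not (np.isfinite(logml_dependent) and np.isfinite(logml_independent)):
        raise ValueError("both log marginal likelihoods must be finite")
    two_delta = 2.0 * (logml_dependent - logml_independent)
    selected = "dependent" if logml_dependent > logml_independent else "independent"
    return selected, float(two_delta)
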