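"""Maximum-likelihood fitting and information-criterion model comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import Bounds, minimize

from .errors import NumericalFailureError
from .likelihood import LikelihoodSettings, loglik
from .states import DEFAULT_SPACE, SSEParams, StateSpace
from .trees import CladeTree

__all__ = [
    "ModelSpec",
    "FitResult",
    "FitSettings",
    "get_model",
    "fit_model",
    "aicc",
    "akaike_weights",
    "select_best",
    "MODEL_ORDER",
]

# fixed tie-break order, most parsimonious interpretation first
MODEL_ORDER = ("CR", "CTD", "ETD", "ECTD")

_PENALTY = 1e10


@dataclass(frozen=True)
class ModelSpec:
    """Mapping from a free-parameter vector to a full combined-state rate set.

    Free parameters are ordered as (speciation block..., mu, q):
    CR has 1 speciation rate, ETD one per examined state, CTD one per
    concealed state, ECTD one per combined state.
    """

    name: str
    space: StateSpace
    param_names: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.param_names)

    @property
    def n_lambda(self) -> int:
        return self.k - 2

    def to_params(self, x: Sequence[float]) -> SSEParams:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.k,):
            raise ValueError(f"{self.name} expects {self.k} free parameters")
        lam_free, mu, q = x[:-2], x[-2], x[-1]
        sp = self.space
        lam = np.empty(sp.n_states)
        for i in range(sp.n_states):
            if self.name == "ETD":
                lam[i] = lam_free[sp.examined_of(i)]
            elif self.name == "CTD":
                lam[i] = lam_free[sp.concealed_of(i)]
            elif self.name == "ECTD":
                lam[i] = lam_free[i]
            else:  # CR
                lam[i] = lam_free[0]
        return SSEParams(lam=lam, mu=np.full(sp.n_states, mu), q=q, space=sp)

    def expand_free(self, lam_scalar: float, mu: float, q: float) -> np.ndarray:
        """Free vector with all speciation rates equal (a CR-compatible point)."""
        return np.concatenate([np.full(self.n_lambda, lam_scalar), [mu, q]])


def get_model(name: str, space: StateSpace | None = None) -> ModelSpec:
    space = space or DEFAULT_SPACE
    name = name.upper()
    if name == "CR":
        lam_names = ("lambda",)
    elif name == "ETD":
        lam_names = tuple(f"lambda_e{i+1}" for i in range(space.n_examined))
    elif name == "CTD":
        lam_names = tuple(f"lambda_c{i+1}" for i in range(space.n_concealed))
    elif name == "ECTD":
        lam_names = tuple(f"lambda_s{i}" for i in range(space.n_states))
    else:
        raise ValueError(f"unknown model {name!r}")
    return ModelSpec(name=name, space=space, param_names=lam_names + ("mu", "q"))


def aicc(lnl: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    model: str
    mle: np.ndarray
    lnl: float
    k: int
    aicc: float
    n_used: int
    converged: bool
    n_cycles_used: int
    param_names: tuple[str, ...] = ()

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, np.asarray(self.mle, dtype=float)))


@dataclass
class FitSettings:
    """Optimizer controls for :func:`fit_model`.

    Rates are optimized on the log scale inside box bounds; each cycle
    beyond the first restarts a simplex search from a jittered copy of the
    incumbent optimum, stopping when a cycle improves the log-likelihood by
    less than ``cycle_tol``.
    """

    max_cycles: int = 10
    cycle_tol: float = 1e-6
    rate_lower: float = 1e-6
    rate_upper: float = 10.0
    maxfev: Optional[int] = None
    jitter_sd: float = 0.5
    simplex_fatol: float = 1e-7
    simplex_xatol: float = 1e-5
    # "hybrid": quasi-Newton descent then a simplex polish; "lbfgs" skips the
    # polish (fastest); "nelder-mead": simplex only.
    method: str = "hybrid"
    # finite-difference step for the quasi-Newton path; must sit well above
    # the ODE-solver noise in the log-likelihood or line searches stall
    gradient_eps: float = 1e-3


def _heuristic_start(model: ModelSpec, n_tips: int, tree_depth: float) -> np.ndarray:
    lam0 = max(np.log(max(n_tips, 3) / 2.0) / max(tree_depth, 1e-6), 1e-3)
    return model.expand_free(lam0, lam0 / 10.0, 0.1)


def fit_model(
    clade: CladeTree,
    model: ModelSpec,
    settings: LikelihoodSettings,
    seed: int | None = None,
    observed: dict[str, int] | None = None,
    extra_starts: Sequence[Sequence[float]] = (),
    opt: FitSettings | None = None,
) -> FitResult:
    """Maximize the hidden-state SSE likelihood for one parameterization.

    ``extra_starts`` takes additional free-parameter vectors on the natural
    rate scale (e.g. the expanded optimum of a nested model) that are added
    to the first optimization cycle.
    """
    opt = opt or FitSettings()
    n_tips = clade.n_tips
    if n_tips <= model.k + 1:
        raise ValueError(
            f"tree has {n_tips} tips; model {model.name} needs more than k+1={model.k + 1}"
        )
    rng = np.random.default_rng(seed)
    depth = float(np.max(clade.tip_depths()))
    lo, hi = np.log(opt.rate_lower), np.log(opt.rate_upper)
    bounds = Bounds(np.full(model.k, lo), np.full(model.k, hi))

    def objective(logx: np.ndarray) -> float:
        try:
            ll = loglik(clade, model.to_params(np.exp(logx)), settings, observed=observed)
        except NumericalFailureError:
            return _PENALTY
        return -ll

    def run_simplex(x0: np.ndarray, maxfev: Optional[int] = None):
        options = {"fatol": opt.simplex_fatol, "xatol": opt.simplex_xatol}
        maxfev = maxfev if maxfev is not None else opt.maxfev
        if maxfev is not None:
            options["maxfev"] = maxfev
        return minimize(objective, x0, method="Nelder-Mead", bounds=bounds, options=options)

    def run_local(x0: np.ndarray):
        x0 = np.clip(x0, lo, hi)
        if opt.method == "nelder-mead":
            return run_simplex(x0)
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"eps": opt.gradient_eps, "maxfun": opt.maxfev or 15000},
        )
        if opt.method == "hybrid":
            polish = run_simplex(res.x, maxfev=40 * model.k)
            if np.isfinite(polish.fun) and polish.fun < res.fun:
                return polish
        return res

    starts0 = [np.log(_heuristic_start(model, n_tips, depth))]
    for s in extra_starts:
        s = np.asarray(s, dtype=float)
        if s.shape == (model.k,) and np.all(s > 0):
            starts0.append(np.log(s))

    best_x: Optional[np.ndarray] = None
    best_f = np.inf
    converged = False
    n_cycles = 0
    for cycle in range(opt.max_cycles):
        n_cycles += 1
        if cycle == 0:
            starts = starts0
        else:
            starts = [best_x + rng.normal(0.0, opt.jitter_sd, size=model.k)]
        cycle_best = np.inf
        cycle_x = None
        cycle_ok = False
        for x0 in starts:
            res = run_local(x0)
            if np.isfinite(res.fun) and res.fun < cycle_best:
                cycle_best = res.fun
                cycle_x = res.x
                cycle_ok = bool(getattr(res, "success", True)) or cycle_ok
        if cycle_x is None:
            continue
        improved = cycle_best < best_f - opt.cycle_tol
        if cycle_best < best_f:
            best_f = cycle_best
            best_x = cycle_x
        if cycle > 0 and not improved:
            converged = True
            break
        if opt.max_cycles == 1:
            # single-cycle budget mode: trust the local optimizer's own
            # convergence report instead of a confirmation restart
            converged = cycle_ok

    if best_x is None or best_f >= _PENALTY:
        return FitResult(
            model=model.name,
            mle=np.full(model.k, np.nan),
            lnl=-np.inf,
            k=model.k,
            aicc=np.inf,
            n_used=n_tips,
            converged=False,
            n_cycles_used=n_cycles,
            param_names=model.param_names,
        )
    lnl = -best_f
    return FitResult(
        model=model.name,
        mle=np.exp(best_x),
        lnl=lnl,
        k=model.k,
        aicc=aicc(lnl, model.k, n_tips),
        n_used=n_tips,
        converged=converged,
        n_cycles_used=n_cycles,
        param_names=model.param_names,
    )


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """Normalized relative model support from AICc values."""
    a = np.asarray(aiccs, dtype=float)
    if a.size < 2 or not np.isfinite(a).any():
        raise ValueError("need at least 2 AICc values with a finite minimum")
    delta = a - np.nanmin(a[np.isfinite(a)])
    w = np.exp(-0.5 * delta)
    w[~np.isfinite(a)] = 0.0
    return w / w.sum()


def select_best(
    fits: dict[str, FitResult], require_converged: bool = True
) -> tuple[str, dict[str, float]]:
    """Pick the AICc-best converged model; ties go to fewer parameters,
    then to the fixed order CR < CTD < ETD < ECTD.

    With ``require_converged=False`` any finite-AICc fit competes (used as
    a fallback when too few fits report convergence).
    """
    usable = {}
    for name, fr in fits.items():
        if np.isfinite(fr.aicc) and (fr.converged or not require_converged):
            usable[name] = fr
        else:
            warnings.warn(f"excluding non-converged fit {name}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least 2 converged fits to compare")
    names = sorted(usable, key=lambda m: MODEL_ORDER.index(m) if m in MODEL_ORDER else 99)
    w = akaike_weights([usable[m].aicc for m in names])
    weights = dict(zip(names, w))
    best = min(names, key=lambda m: (usable[m].aicc, usable[m].k, MODEL_ORDER.index(m)))
    return best, weights
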