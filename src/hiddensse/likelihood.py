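"""Hidden-state SSE likelihood with per-examined-state sampling fractions.

The concealed trait is marginalized: tips carry only an examined state.
Along every branch the standard coupled extinction/partial-likelihood ODE
system is integrated toward the root,

    dE_i/dt = mu_i - (lam_i + mu_i + qr_i) E_i + lam_i E_i^2 + sum_j q_ij E_j
    dD_i/dt = -(lam_i + mu_i + qr_i) D_i + 2 lam_i E_i D_i + sum_j q_ij D_j

with ``q_ij = q * mask_ij`` and ``qr_i = sum_j q_ij``.  Sampling fractions
enter only the tip initial conditions.  The post-order traversal, branch
integration (adaptive Dormand-Prince 4(5)) and node products are jitted
with numba; per-node rescaling keeps partial likelihoods in range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numba
import numpy as np

from .errors import NumericalFailureError
from .states import SSEParams, StateSpace
from .trees import CladeTree, postorder_arrays

__all__ = [
    "LikelihoodSettings",
    "StateProbabilities",
    "tip_initial_conditions",
    "integrate_branch",
    "combine_at_node",
    "loglik",
]

ROOT_FITZJOHN = 0
ROOT_EQUAL = 1
ROOT_FIXED = 2
_ROOT_MODES = {"fitzjohn": ROOT_FITZJOHN, "equal": ROOT_EQUAL, "fixed": ROOT_FIXED}


@dataclass
class LikelihoodSettings:
    """Sampling fractions, conditioning and solver controls.

    ``rho`` holds one sampling fraction per *examined* state.  Root
    weighting follows the likelihood-proportional (FitzJohn) convention by
    default; ``"equal"`` and a fixed probability vector are also available.
    """

    rho: Sequence[float] = (1.0, 1.0, 1.0)
    condition_on_survival: bool = True
    root_weighting: str | Sequence[float] = "fitzjohn"
    ode_rel_tol: float = 1e-8
    ode_abs_tol: float = 1e-10

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(self.rho <= 0) or np.any(self.rho > 1):
            raise ValueError("sampling fractions must lie in (0, 1]")
        if self.ode_rel_tol <= 0 or self.ode_abs_tol <= 0:
            raise ValueError("solver tolerances must be positive")

    def root_mode(self, n_states: int) -> tuple[int, np.ndarray]:
        if isinstance(self.root_weighting, str):
            mode = _ROOT_MODES.get(self.root_weighting)
            if mode is None or mode == ROOT_FIXED:
                raise ValueError(f"unknown root weighting {self.root_weighting!r}")
            return mode, np.zeros(n_states)
        w = np.asarray(self.root_weighting, dtype=float)
        if w.shape != (n_states,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("fixed root weights must be a non-negative vector")
        return ROOT_FIXED, w / w.sum()


@dataclass
class StateProbabilities:
    """Extinction probabilities E and partial likelihoods D at a branch point."""

    E: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.E.shape != self.D.shape:
            raise ValueError("E and D must have the same length")


def tip_initial_conditions(
    observed_state: int,
    settings: LikelihoodSettings,
    space: StateSpace | None = None,
) -> StateProbabilities:
    """Initial (E, D) at an extant tip with an observed examined state.

    E_i(0) = 1 - rho(examined(i)); D_i(0) = rho(observed) on combined states
    whose examined part matches the observation, 0 elsewhere.
    """
    if space is None:
        space = StateSpace(len(settings.rho), len(settings.rho))
    if not 0 <= observed_state < space.n_examined:
        raise ValueError(f"observed state {observed_state} out of range")
    rho = np.asarray(settings.rho, dtype=float)
    if rho.shape != (space.n_examined,):
        raise ValueError("rho must have one entry per examined state")
    exam = np.array([space.examined_of(i) for i in range(space.n_states)])
    E = 1.0 - rho[exam]
    D = np.where(exam == observed_state, rho[observed_state], 0.0)
    return StateProbabilities(E=E, D=D)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@numba.njit(cache=True, inline="always")
def _rhs(y, lam, mu, qmat, qrow, out):
    n = lam.shape[0]
    for i in range(n):
        se = 0.0
        sd = 0.0
        for j in range(n):
            se += qmat[i, j] * y[j]
            sd += qmat[i, j] * y[n + j]
        r = lam[i] + mu[i] + qrow[i]
        e = y[i]
        out[i] = mu[i] - r * e + lam[i] * e * e + se
        out[n + i] = -r * y[n + i] + 2.0 * lam[i] * e * y[n + i] + sd


@numba.njit(cache=True)
def _integrate(y, lam, mu, qmat, qrow, length, rel_tol, abs_tol):
    """Adaptive Dormand-Prince 4(5) on the 2n-vector y over [0, length].

    Modifies ``y`` in place.  Returns 0 on success, 1 on step-size
    underflow / step-count blow-up, 3 on non-finite state.
    """
    if length <= 0.0:
        return 0
    n2 = y.shape[0]
    k1 = np.empty(n2)
    k2 = np.empty(n2)
    k3 = np.empty(n2)
    k4 = np.empty(n2)
    k5 = np.empty(n2)
    k6 = np.empty(n2)
    k7 = np.empty(n2)
    ytmp = np.empty(n2)
    ynew = np.empty(n2)

    # initial step: bounded by the fastest per-state total rate
    rmax = 1e-8
    n = lam.shape[0]
    for i in range(n):
        r = lam[i] + mu[i] + qrow[i]
        if r > rmax:
            rmax = r
    h = min(length, 0.1 / rmax)
    t = 0.0
    _rhs(y, lam, mu, qmat, qrow, k1)
    max_steps = 1_000_000
    for _step in range(max_steps):
        if t >= length:
            return 0
        if h > length - t:
            h = length - t
        # stages
        for i in range(n2):
            ytmp[i] = y[i] + h * (0.2 * k1[i])
        _rhs(ytmp, lam, mu, qmat, qrow, k2)
        for i in range(n2):
            ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _rhs(ytmp, lam, mu, qmat, qrow, k3)
        for i in range(n2):
            ytmp[i] = y[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i] + 32.0 / 9.0 * k3[i])
        _rhs(ytmp, lam, mu, qmat, qrow, k4)
        for i in range(n2):
            ytmp[i] = y[i] + h * (
                19372.0 / 6561.0 * k1[i]
                - 25360.0 / 2187.0 * k2[i]
                + 64448.0 / 6561.0 * k3[i]
                - 212.0 / 729.0 * k4[i]
            )
        _rhs(ytmp, lam, mu, qmat, qrow, k5)
        for i in range(n2):
            ytmp[i] = y[i] + h * (
                9017.0 / 3168.0 * k1[i]
                - 355.0 / 33.0 * k2[i]
                + 46732.0 / 5247.0 * k3[i]
                + 49.0 / 176.0 * k4[i]
                - 5103.0 / 18656.0 * k5[i]
            )
        _rhs(ytmp, lam, mu, qmat, qrow, k6)
        for i in range(n2):
            ynew[i] = y[i] + h * (
                35.0 / 384.0 * k1[i]
                + 500.0 / 1113.0 * k3[i]
                + 125.0 / 192.0 * k4[i]
                - 2187.0 / 6784.0 * k5[i]
                + 11.0 / 84.0 * k6[i]
            )
        _rhs(ynew, lam, mu, qmat, qrow, k7)
        # embedded error estimate
        err = 0.0
        for i in range(n2):
            e = h * (
                71.0 / 57600.0 * k1[i]
                - 71.0 / 16695.0 * k3[i]
                + 71.0 / 1920.0 * k4[i]
                - 17253.0 / 339200.0 * k5[i]
                + 22.0 / 525.0 * k6[i]
                - 1.0 / 40.0 * k7[i]
            )
            sc = abs_tol + rel_tol * max(abs(y[i]), abs(ynew[i]))
            e = e / sc
            err += e * e
        err = (err / n2) ** 0.5
        if not np.isfinite(err):
            return 3
        if err <= 1.0:
            t += h
            for i in range(n2):
                y[i] = ynew[i]
                k1[i] = k7[i]  # FSAL
        factor = 0.9 * (err + 1e-300) ** -0.2
        if factor < 0.2:
            factor = 0.2
        elif factor > 5.0:
            factor = 5.0
        h *= factor
        if h < 1e-14 * max(length, 1.0):
            return 1
    return 1


@numba.njit(cache=True)
def _tree_loglik(
    left,
    right,
    blen,
    tip_obs,
    exam_of,
    lam,
    mu,
    qmat,
    rho_ex,
    rel_tol,
    abs_tol,
    condition,
    root_mode,
    root_weights,
):
    """Post-order pruning pass.  Returns (loglik, status)."""
    n_nodes = left.shape[0]
    n = lam.shape[0]
    qrow = np.zeros(n)
    for i in range(n):
        for j in range(n):
            qrow[i] += qmat[i, j]
    buf = np.empty((n_nodes, 2 * n))
    logscale = 0.0
    root = n_nodes - 1  # postorder: root is last
    for v in range(n_nodes):
        if left[v] < 0:  # tip
            obs = tip_obs[v]
            for i in range(n):
                buf[v, i] = 1.0 - rho_ex[exam_of[i]]
                buf[v, n + i] = rho_ex[obs] if exam_of[i] == obs else 0.0
        else:
            lv = left[v]
            rv = right[v]
            dmax = 0.0
            for i in range(n):
                buf[v, i] = 0.5 * (buf[lv, i] + buf[rv, i])
                d = lam[i] * buf[lv, n + i] * buf[rv, n + i]
                buf[v, n + i] = d
                if d > dmax:
                    dmax = d
            if dmax <= 0.0 or not np.isfinite(dmax):
                return -np.inf, 3
            for i in range(n):
                buf[v, n + i] /= dmax
            logscale += np.log(dmax)
        if v != root and blen[v] > 0.0:
            status = _integrate(buf[v], lam, mu, qmat, qrow, blen[v], rel_tol, abs_tol)
            if status != 0:
                return -np.inf, status
            for i in range(n):
                if buf[v, n + i] < -abs_tol:
                    return -np.inf, 2
                if buf[v, n + i] < 0.0:
                    buf[v, n + i] = 0.0
    # root assembly
    dsum = 0.0
    for i in range(n):
        dsum += buf[root, n + i]
    if dsum <= 0.0 or not np.isfinite(dsum):
        return -np.inf, 3
    lik = 0.0
    for i in range(n):
        if root_mode == 0:
            w = buf[root, n + i] / dsum
        elif root_mode == 1:
            w = 1.0 / n
        else:
            w = root_weights[i]
        if w == 0.0:
            continue
        d = buf[root, n + i]
        if condition:
            om = 1.0 - buf[root, i]
            denom = lam[i] * om * om
            if denom <= 0.0:
                return -np.inf, 3
            lik += w * d / denom
        else:
            lik += w * d
    if lik <= 0.0 or not np.isfinite(lik):
        return -np.inf, 3
    return np.log(lik) + logscale, 0


# ---------------------------------------------------------------------------
# python-level operations
# ---------------------------------------------------------------------------


def integrate_branch(
    init: StateProbabilities,
    params: SSEParams,
    length: float,
    settings: LikelihoodSettings | None = None,
) -> StateProbabilities:
    """Integrate (E, D) along a branch of the given length toward the root."""
    if length < 0:
        raise ValueError("branch length must be non-negative")
    if settings is None:
        settings = LikelihoodSettings(rho=np.ones(params.space.n_examined))
    y = np.concatenate([init.E, init.D]).astype(float)
    qmat = params.q_matrix()
    qrow = qmat.sum(axis=1)
    status = _integrate(
        y, params.lam, params.mu, qmat, qrow, float(length),
        settings.ode_rel_tol, settings.ode_abs_tol,
    )
    if status != 0:
        raise NumericalFailureError(f"branch integration failed (status {status}, length {length})")
    n = params.space.n_states
    D = y[n:]
    if np.any(D < -settings.ode_abs_tol):
        raise NumericalFailureError("negative partial likelihood beyond tolerance")
    return StateProbabilities(E=y[:n], D=np.clip(D, 0.0, None))


def combine_at_node(
    left: StateProbabilities,
    right: StateProbabilities,
    params: SSEParams,
    tol: float = 1e-6,
) -> StateProbabilities:
    """Merge two daughter branches at a speciation node."""
    if np.max(np.abs(left.E - right.E)) > tol:
        raise ValueError("E vectors of sister branches disagree; not the same time point")
    return StateProbabilities(
        E=0.5 * (left.E + right.E),
        D=params.lam * left.D * right.D,
    )


def loglik(
    clade: CladeTree,
    params: SSEParams,
    settings: LikelihoodSettings,
    observed: dict[str, int] | None = None,
) -> float:
    """Log-likelihood of the examined tip states and tree under ``params``.

    ``observed`` may override the tip -> examined-state map (defaults to the
    examined component of ``clade.tip_states``).  Raises
    :class:`NumericalFailureError` when the computation degenerates.
    """
    sp = params.space
    rho = np.asarray(settings.rho, dtype=float)
    if rho.shape != (sp.n_examined,):
        raise ValueError("settings.rho must have one entry per examined state")
    if observed is None:
        # repeated evaluations on the same tree (fitting) reuse the flattening
        cached = getattr(clade, "_postorder_cache", None)
        if cached is None:
            cached = postorder_arrays(clade)
            clade._postorder_cache = cached
        left, right, blen, tip_obs, _ = cached
    else:
        left, right, blen, tip_obs, _ = postorder_arrays(clade, observed)
    exam_of = np.array([sp.examined_of(i) for i in range(sp.n_states)], dtype=np.int64)
    root_mode, root_weights = settings.root_mode(sp.n_states)
    qmat = params.q_matrix()
    ll, status = _tree_loglik(
        left,
        right,
        blen,
        tip_obs,
        exam_of,
        params.lam,
        params.mu,
        qmat,
        rho,
        settings.ode_rel_tol,
        settings.ode_abs_tol,
        settings.condition_on_survival,
        root_mode,
        root_weights,
    )
    if status != 0 or not np.isfinite(ll):
        raise NumericalFailureError(f"likelihood evaluation failed (status {status})")
    return float(ll)
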