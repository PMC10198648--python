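"""Combined state spaces and rate-set containers for hidden-state SSE models.

The examined trait (observed at the tips) and the concealed trait (never
observed) each take a small number of discrete states.  Their Cartesian
product forms the combined state space over which the birth--death process
runs.  Only one trait may change per transition event ("one-step" moves).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateSpace",
    "SSEParams",
    "GeneratingMode",
    "expand_generating_mode",
]

EXAMINED_LABELS = ("1", "2", "3", "4", "5")
CONCEALED_LABELS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class StateSpace:
    """Cartesian product of examined x concealed trait states.

    Combined state ``i`` maps to ``(examined, concealed)`` via
    ``examined = i // n_concealed`` and ``concealed = i % n_concealed``,
    a fixed bijection used everywhere in the package.
    """

    n_examined: int = 3
    n_concealed: int = 3

    def __post_init__(self) -> None:
        if self.n_examined < 1 or self.n_concealed < 1:
            raise ValueError("state counts must be positive")

    @property
    def n_states(self) -> int:
        return self.n_examined * self.n_concealed

    def index(self, examined: int, concealed: int) -> int:
        """Combined index of 0-based (examined, concealed) pair."""
        if not (0 <= examined < self.n_examined and 0 <= concealed < self.n_concealed):
            raise ValueError(f"state pair out of range: ({examined}, {concealed})")
        return examined * self.n_concealed + concealed

    def examined_of(self, i: int) -> int:
        return i // self.n_concealed

    def concealed_of(self, i: int) -> int:
        return i % self.n_concealed

    def label(self, i: int) -> str:
        """Human-readable label, e.g. combined state 0 -> '1A'."""
        return EXAMINED_LABELS[self.examined_of(i)] + CONCEALED_LABELS[self.concealed_of(i)]

    def parse_label(self, label: str) -> int:
        ex = EXAMINED_LABELS.index(label[0])
        co = CONCEALED_LABELS.index(label[1])
        return self.index(ex, co)

    def one_step_mask(self) -> np.ndarray:
        """Boolean adjacency: True iff states differ in exactly one trait.

        Within the changed trait any state-to-state move is allowed (all
        transitions possible at a single symmetric rate); simultaneous
        changes of both traits are forbidden.
        """
        n = self.n_states
        mask = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                de = self.examined_of(i) != self.examined_of(j)
                dc = self.concealed_of(i) != self.concealed_of(j)
                mask[i, j] = de != dc  # exactly one trait differs
        return mask

    def examined_indicator(self) -> np.ndarray:
        """(n_examined, n_states) indicator matrix of examined membership."""
        out = np.zeros((self.n_examined, self.n_states))
        for i in range(self.n_states):
            out[self.examined_of(i), i] = 1.0
        return out


DEFAULT_SPACE = StateSpace(3, 3)


@dataclass
class SSEParams:
    """Full per-combined-state rate set.

    Attributes
    ----------
    lam, mu : arrays of per-state speciation / extinction rates
        (events / lineage / MY).
    q : scalar symmetric transition rate applied to every one-step move.
    space : the combined state space; supplies the one-step mask.
    """

    lam: np.ndarray
    mu: np.ndarray
    q: float
    space: StateSpace = field(default_factory=lambda: DEFAULT_SPACE)

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        n = self.space.n_states
        if self.lam.shape != (n,) or self.mu.shape != (n,):
            raise ValueError(f"rate vectors must have length {n}")
        if np.any(self.lam < 0) or np.any(self.mu < 0) or self.q < 0:
            raise ValueError("all rates must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        return self.space.one_step_mask()

    def q_matrix(self) -> np.ndarray:
        """Off-diagonal transition-rate matrix q * mask (zero diagonal)."""
        return self.q * self.mask.astype(float)

    def total_rates(self) -> np.ndarray:
        """Per-lineage total event rate in each combined state."""
        return self.lam + self.mu + self.q * self.mask.sum(axis=1)


@dataclass
class GeneratingMode:
    """Reduced parameterization used to generate data.

    mode 'ETD': speciation varies with the examined state only;
    mode 'CTD': with the concealed state only; 'CR': constant.
    """

    mode: str
    lambda_values: np.ndarray
    mu_value: float
    q_value: float
    space: StateSpace = field(default_factory=lambda: DEFAULT_SPACE)

    def __post_init__(self) -> None:
        self.mode = self.mode.upper()
        if self.mode not in ("ETD", "CTD", "CR"):
            raise ValueError(f"unknown generating mode {self.mode!r}")
        self.lambda_values = np.atleast_1d(np.asarray(self.lambda_values, dtype=float))
        want = 1 if self.mode == "CR" else (
            self.space.n_examined if self.mode == "ETD" else self.space.n_concealed
        )
        if self.lambda_values.shape != (want,):
            raise ValueError(
                f"mode {self.mode} needs {want} lambda value(s), "
                f"got {self.lambda_values.shape}"
            )
        if np.any(self.lambda_values < 0) or self.mu_value < 0 or self.q_value < 0:
            raise ValueError("all rates must be non-negative")


def expand_generating_mode(mode: GeneratingMode) -> SSEParams:
    """Expand a reduced generating mode into the full combined-state rate set."""
    sp = mode.space
    lam = np.empty(sp.n_states)
    for i in range(sp.n_states):
        if mode.mode == "ETD":
            lam[i] = mode.lambda_values[sp.examined_of(i)]
        elif mode.mode == "CTD":
            lam[i] = mode.lambda_values[sp.concealed_of(i)]
        else:
            lam[i] = mode.lambda_values[0]
    mu = np.full(sp.n_states, mode.mu_value)
    return SSEParams(lam=lam, mu=mu, q=mode.q_value, space=sp)
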