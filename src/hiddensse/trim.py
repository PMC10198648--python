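"""Tip removal to target sampling fractions, random or taxonomically biased.

Tip removal never consults trait states; the achieved sampling fraction is
recorded exactly.  Biased trimming concentrates removal in one or two
sub-clades, then removes background tips to land within +/-2% of the
target fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import IneligibleTreeError, InfeasibleTargetError
from .trees import CladeTree

__all__ = [
    "BiasConfig",
    "SamplingSpec",
    "random_trim",
    "biased_trim",
    "state_proportions",
    "transition_loss_summary",
]

SF_TOLERANCE = 0.02


@dataclass
class BiasConfig:
    """Taxonomic-bias settings.

    ``subclade_frac`` is the eligibility window for a sub-clade's share of
    the full tree; ``removal_frac`` is the fraction of each chosen
    sub-clade's tips removed (a scalar, or a (lo, hi) interval sampled
    uniformly per sub-clade).
    """

    n_subclades: int = 1
    subclade_frac: tuple[float, float] = (0.20, 0.30)
    removal_frac: float | tuple[float, float] = (0.80, 0.90)

    def __post_init__(self) -> None:
        if self.n_subclades not in (1, 2):
            raise ValueError("n_subclades must be 1 or 2")

    def draw_removal(self, rng: np.random.Generator) -> float:
        if np.isscalar(self.removal_frac):
            return float(self.removal_frac)
        lo, hi = self.removal_frac
        return float(rng.uniform(lo, hi))


@dataclass
class SamplingSpec:
    """Record of how a tree was degraded and what the likelihood is told.

    ``true_sf`` is the achieved global sampling fraction; ``specified_sf``
    the per-examined-state fractions later handed to the likelihood
    (defaults to the nominal target in every state).
    """

    true_sf: float
    specified_sf: np.ndarray
    regime: str
    target_sf: float
    bias_config: Optional[BiasConfig] = None
    n_removed_subclades: int = 0
    n_removed_background: int = 0

    def __post_init__(self) -> None:
        spec = np.atleast_1d(np.asarray(self.specified_sf, dtype=float))
        if np.any(spec <= 0) or np.any(spec > 1):
            raise ValueError("specified sampling fractions must lie in (0, 1]")
        if not 0 < self.true_sf <= 1:
            raise ValueError("true_sf must lie in (0, 1]")
        self.specified_sf = spec


def _prune_to(clade: CladeTree, keep_labels: set[str]) -> CladeTree:
    """New CladeTree with only ``keep_labels``; unary nodes collapsed."""
    sub = clade.tree.extract_tree_with_taxa_labels(
        labels=keep_labels, suppress_unifurcations=True
    )
    sub.seed_node.edge.length = None  # no stem above the (possibly new) crown
    return CladeTree(
        tree=sub,
        crown_age=clade.crown_age,
        tip_states={t: clade.tip_states[t] for t in keep_labels},
        space=clade.space,
        event_log=list(clade.event_log),
        lineage_parent=clade.lineage_parent,
        tip_lineage=(
            None
            if clade.tip_lineage is None
            else {t: clade.tip_lineage[t] for t in keep_labels}
        ),
    )


def random_trim(
    clade: CladeTree, target_sf: float, seed: int | np.random.Generator | None = None
) -> tuple[CladeTree, SamplingSpec]:
    """Retain round(target_sf * N) tips chosen uniformly without replacement."""
    if not 0 < target_sf <= 1:
        raise ValueError("target_sf must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    labels = sorted(clade.tip_labels)
    n = len(labels)
    n_keep = int(round(target_sf * n))
    if n_keep < 4:
        raise ValueError(f"target_sf {target_sf} would leave {n_keep} < 4 tips")
    if n_keep == n:
        spec = SamplingSpec(
            true_sf=1.0,
            specified_sf=np.full(clade.space.n_examined, 1.0),
            regime="random",
            target_sf=target_sf,
        )
        return clade.copy(), spec
    keep = set(rng.choice(labels, size=n_keep, replace=False))
    trimmed = _prune_to(clade, keep)
    achieved = n_keep / n
    spec = SamplingSpec(
        true_sf=achieved,
        specified_sf=np.full(clade.space.n_examined, target_sf),
        regime="random",
        target_sf=target_sf,
    )
    return trimmed, spec


def _eligible_subclades(clade: CladeTree, frac_window: tuple[float, float]):
    """Internal nodes whose descendant-tip share falls inside the window."""
    lo, hi = frac_window
    n = clade.n_tips
    out = []
    for node in clade.tree.postorder_internal_node_iter():
        if node is clade.tree.seed_node:
            continue
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if lo <= len(tips) / n <= hi:
            out.append(tips)
    return out


def biased_trim(
    clade: CladeTree,
    target_sf: float,
    bias_config: BiasConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[CladeTree, SamplingSpec]:
    """Heavily trim one or two sub-clades, then top up randomly elsewhere.

    Raises :class:`IneligibleTreeError` when the tree lacks enough
    non-nested eligible sub-clades, and :class:`InfeasibleTargetError` when
    the heavy trim alone overshoots below ``target_sf`` even after one
    redraw of the removal fraction.
    """
    if not 0 < target_sf <= 1:
        raise ValueError("target_sf must lie in (0, 1]")
    cfg = bias_config or BiasConfig()
    rng = np.random.default_rng(seed)
    labels = sorted(clade.tip_labels)
    n = len(labels)
    n_keep_target = int(round(target_sf * n))
    if n_keep_target < 4:
        raise ValueError(f"target_sf {target_sf} would leave {n_keep_target} < 4 tips")

    eligible = _eligible_subclades(clade, cfg.subclade_frac)
    rng.shuffle(eligible)
    chosen: list[frozenset] = []
    for tips in eligible:
        if all(tips.isdisjoint(c) for c in chosen):
            chosen.append(tips)
        if len(chosen) == cfg.n_subclades:
            break
    if len(chosen) < cfg.n_subclades:
        raise IneligibleTreeError(
            f"tree has {len(chosen)} non-nested sub-clades in share window "
            f"{cfg.subclade_frac}, need {cfg.n_subclades}"
        )

    def heavy_removal() -> set[str]:
        removed: set[str] = set()
        for tips in chosen:
            r = cfg.draw_removal(rng)
            k = int(round(r * len(tips)))
            removed |= set(rng.choice(sorted(tips), size=k, replace=False))
        return removed

    def overshoots(rm: set[str]) -> bool:
        return (n - len(rm)) / n < target_sf - SF_TOLERANCE

    removed = heavy_removal()
    if overshoots(removed):  # one redraw allowed before giving up
        removed = heavy_removal()
        if overshoots(removed):
            raise InfeasibleTargetError(
                f"heavy trim removed {len(removed)}/{n} tips, below target {target_sf}"
            )

    background = n - len(removed) - n_keep_target
    if background > 0:
        subclade_tips = set().union(*chosen)
        pool = sorted(set(labels) - subclade_tips - removed)
        take = min(background, len(pool))
        removed |= set(rng.choice(pool, size=take, replace=False))
        short = background - take
        if short > 0:  # background pool exhausted: finish inside sub-clades
            rest = sorted(set(labels) - removed)
            removed |= set(rng.choice(rest, size=short, replace=False))

    keep = set(labels) - removed
    trimmed = _prune_to(clade, keep)
    achieved = len(keep) / n
    if abs(achieved - target_sf) > SF_TOLERANCE + 1e-12:
        raise InfeasibleTargetError(
            f"achieved SF {achieved:.3f} outside +/-{SF_TOLERANCE} of {target_sf}"
        )
    spec = SamplingSpec(
        true_sf=achieved,
        specified_sf=np.full(clade.space.n_examined, target_sf),
        regime="biased",
        target_sf=target_sf,
        bias_config=cfg,
        n_removed_subclades=sum(
            1 for tips in chosen for t in tips if t in removed
        ),
        n_removed_background=len(removed)
        - sum(1 for tips in chosen for t in tips if t in removed),
    )
    return trimmed, spec


def state_proportions(clade: CladeTree) -> np.ndarray:
    """Fraction of tips in each examined state (zeros kept, sums to 1)."""
    if clade.n_tips < 1:
        raise ValueError("need at least one tip")
    counts = np.zeros(clade.space.n_examined)
    for label in clade.tip_labels:
        counts[clade.tip_states[label][0]] += 1
    return counts / counts.sum()


def transition_loss_summary(
    full: CladeTree, trimmed: CladeTree
) -> dict[tuple[str, int, int], int]:
    """Count generating transitions stranded on fully pruned subtrees.

    A transition is *lost* iff the lineage it occurred on has at least one
    extant descendant in the full tree (i.e. it sits on a real branch) but
    none among the trimmed tips.  Returns a count for every ordered state
    pair of both traits.
    """
    if full.lineage_parent is None or full.tip_lineage is None:
        raise ValueError("full tree lacks simulation ancestry (event log required)")
    trimmed_tips = set(trimmed.tip_labels)
    if not trimmed_tips <= set(full.tip_labels):
        raise ValueError("trimmed tips are not a subset of the full tree's tips")

    def ancestors_of(tips: set[str]) -> set[int]:
        seen: set[int] = set()
        for t in tips:
            lid = full.tip_lineage[t]
            while lid != -1 and lid not in seen:
                seen.add(lid)
                lid = full.lineage_parent[lid]
        return seen

    surviving_full = ancestors_of(set(full.tip_labels))
    surviving_trimmed = ancestors_of(trimmed_tips)

    sp = full.space
    counts: dict[tuple[str, int, int], int] = {}
    for trait, ns in (("examined", sp.n_examined), ("concealed", sp.n_concealed)):
        for a in range(ns):
            for b in range(ns):
                if a != b:
                    counts[(trait, a, b)] = 0
    for ev in full.event_log:
        if ev.lineage_id in surviving_full and ev.lineage_id not in surviving_trimmed:
            counts[(ev.trait, ev.from_state, ev.to_state)] += 1
    return counts
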