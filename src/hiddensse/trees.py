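"""Tree container shared by the simulator, trimming and likelihood code.

``CladeTree`` wraps a rooted, binary, ultrametric :class:`dendropy.Tree`
together with the tip trait states and (optionally) the event log of the
generating simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .states import DEFAULT_SPACE, StateSpace

__all__ = ["TransitionRecord", "CladeTree", "postorder_arrays"]

ULTRAMETRIC_TOL = 1e-8


@dataclass(frozen=True)
class TransitionRecord:
    """One trait-state transition recorded during simulation.

    ``time`` is measured from the crown (root) of the clade; ``trait`` is
    either ``"examined"`` or ``"concealed"``; states are 0-based indices
    within the changed trait.
    """

    time: float
    lineage_id: int
    trait: str
    from_state: int
    to_state: int

    def __post_init__(self) -> None:
        if self.trait not in ("examined", "concealed"):
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.from_state == self.to_state:
            raise ValueError("transition must change the state")


@dataclass
class CladeTree:
    """A rooted binary ultrametric tree with tip trait states.

    Attributes
    ----------
    tree : dendropy.Tree
        Topology and branch lengths (MY). Extinct lineages already pruned.
    crown_age : float
        Root-to-tip path length (MY) of the generating simulation.
    tip_states : dict
        tip label -> (examined, concealed) 0-based state pair.  Trees read
        back from disk may carry only examined states (concealed = -1).
    event_log : list of TransitionRecord
        All transitions of the generating simulation (including those on
        lineages later pruned as extinct); empty for trees read from disk.
    lineage_parent / tip_lineage
        Ancestry bookkeeping from the simulator, used to locate which
        branch an event occurred on; ``None`` for trees read from disk.
    """

    tree: dendropy.Tree
    crown_age: float
    tip_states: dict[str, tuple[int, int]]
    space: StateSpace = field(default_factory=lambda: DEFAULT_SPACE)
    event_log: list[TransitionRecord] = field(default_factory=list)
    lineage_parent: Optional[dict[int, int]] = None
    tip_lineage: Optional[dict[str, int]] = None

    # -- basic accessors -------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def examined_states(self) -> dict[str, int]:
        return {t: s[0] for t, s in self.tip_states.items()}

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, suppress_leaf_node_labels=False
        ).strip()

    def copy(self) -> "CladeTree":
        return CladeTree(
            tree=self.tree.clone(depth=1),
            crown_age=self.crown_age,
            tip_states=dict(self.tip_states),
            space=self.space,
            event_log=list(self.event_log),
            lineage_parent=None if self.lineage_parent is None else dict(self.lineage_parent),
            tip_lineage=None if self.tip_lineage is None else dict(self.tip_lineage),
        )

    # -- geometry checks -------------------------------------------------

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths for every extant tip."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        return np.array([leaf.root_distance for leaf in self.tree.leaf_node_iter()])

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return bool(np.ptp(d) <= tol) if d.size else True

    def is_binary(self) -> bool:
        for node in self.tree.preorder_node_iter():
            n = len(node.child_nodes())
            if n not in (0, 2):
                return False
        return True

    def validate(self, tol: float = 1e-6) -> None:
        labels = self.tip_labels
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 extant tips")
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels are not unique")
        if len(self.tree.seed_node.child_nodes()) != 2:
            raise ValueError("root must have exactly 2 children")
        if not self.is_binary():
            raise ValueError("tree is not strictly binary")
        if not self.is_ultrametric(tol):
            raise ValueError("tree is not ultrametric")
        missing = set(labels) - set(self.tip_states)
        if missing:
            raise ValueError(f"tips without states: {sorted(missing)[:5]}...")


def postorder_arrays(
    clade: CladeTree, observed: Optional[dict[str, int]] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Flatten a tree into postorder arrays for the likelihood kernel.

    Returns ``(left, right, blen, tip_obs, tip_order)`` where nodes are
    numbered in postorder, ``left/right`` give child indices (-1 for tips),
    ``blen`` is the branch length above each node (0 for the root) and
    ``tip_obs`` is the observed examined state of each tip node (-1 for
    internal nodes).
    """
    if observed is None:
        observed = clade.examined_states()
    nodes = list(clade.tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n, dtype=np.float64)
    tip_obs = np.full(n, -1, dtype=np.int64)
    tip_order: list[str] = []
    for i, node in enumerate(nodes):
        children = node.child_nodes()
        if children:
            if len(children) != 2:
                raise ValueError("likelihood requires a strictly binary tree")
            left[i] = index[id(children[0])]
            right[i] = index[id(children[1])]
        else:
            label = node.taxon.label
            tip_obs[i] = observed[label]
            tip_order.append(label)
        blen[i] = node.edge.length if node.edge.length is not None else 0.0
    return left, right, blen, tip_obs, tip_order
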