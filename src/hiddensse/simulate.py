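"""Exact continuous-time simulation of clades with joint trait evolution.

The process starts from the two crown lineages at time 0 and runs until the
crown age.  At each step a global waiting time is drawn from an exponential
distribution whose rate is the sum of all per-lineage event rates
(speciation + extinction + trait transitions); a lineage-and-event is then
chosen with probability proportional to its rate.  Lineages in the same
combined state are exchangeable, so the simulator aggregates rates by state
and picks a uniform member of the chosen state, which keeps each step O(1)
in the number of lineages.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import ExtinctCladeError, InfeasibleBandError
from .states import GeneratingMode, SSEParams, expand_generating_mode
from .trees import CladeTree, TransitionRecord

__all__ = ["simulate_clade", "sample_tree_set", "SampleLog"]


class _Lineage:
    __slots__ = ("parent", "t_birth", "t_end", "state", "children", "extant")

    def __init__(self, parent: int, t_birth: float, state: int):
        self.parent = parent
        self.t_birth = t_birth
        self.t_end = np.inf
        self.state = state
        self.children: tuple[int, int] | None = None
        self.extant = False


class _StatePool:
    """Per-state membership with O(1) insert / remove / uniform sample."""

    def __init__(self, n_states: int):
        self.members: list[list[int]] = [[] for _ in range(n_states)]
        self.pos: dict[int, int] = {}

    def add(self, state: int, lid: int) -> None:
        self.pos[lid] = len(self.members[state])
        self.members[state].append(lid)

    def remove(self, state: int, lid: int) -> None:
        lst = self.members[state]
        i = self.pos.pop(lid)
        last = lst.pop()
        if last != lid:
            lst[i] = last
            self.pos[last] = i

    def sample(self, state: int, rng: np.random.Generator) -> int:
        lst = self.members[state]
        return lst[rng.integers(len(lst))]

    def counts(self) -> list[int]:
        return [len(m) for m in self.members]


def simulate_clade(
    params: SSEParams,
    crown_age: float,
    root_state: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> CladeTree:
    """Simulate one clade from its crown age; prune extinct lineages.

    Both crown lineages start in ``root_state`` (drawn uniformly from the
    combined states when ``None``).  Raises :class:`ExtinctCladeError` if
    either crown lineage leaves no extant descendant, so every returned
    tree has the root as its crown node and is ultrametric at ``crown_age``.
    """
    if crown_age <= 0:
        raise ValueError("crown_age must be positive")
    rng = np.random.default_rng(rng)
    sp = params.space
    n = sp.n_states

    mask = params.mask
    neighbors = [np.flatnonzero(mask[s]) for s in range(n)]
    trans_rate = params.q * mask.sum(axis=1).astype(float)  # per-lineage, per state
    lam, mu = params.lam, params.mu

    if root_state is None:
        root_state = int(rng.integers(n))

    lineages: list[_Lineage] = [
        _Lineage(-1, 0.0, root_state),
        _Lineage(-1, 0.0, root_state),
    ]
    pool = _StatePool(n)
    pool.add(root_state, 0)
    pool.add(root_state, 1)

    events: list[TransitionRecord] = []
    t = 0.0
    while True:
        counts = np.array(pool.counts(), dtype=float)
        n_alive = counts.sum()
        if n_alive == 0:
            raise ExtinctCladeError("whole clade went extinct")
        rates = counts * (lam + mu + trans_rate)
        total = rates.sum()
        if total <= 0.0:
            break  # no further events possible; survivors persist to crown age
        t += rng.exponential(1.0 / total)
        if t >= crown_age:
            break
        s = int(rng.choice(n, p=rates / total))
        per = lam[s] + mu[s] + trans_rate[s]
        u = rng.random() * per
        lid = pool.sample(s, rng)
        lin = lineages[lid]
        if u < lam[s]:  # speciation: both daughters inherit the combined state
            lin.t_end = t
            c1, c2 = len(lineages), len(lineages) + 1
            lineages.append(_Lineage(lid, t, s))
            lineages.append(_Lineage(lid, t, s))
            lin.children = (c1, c2)
            pool.remove(s, lid)
            pool.add(s, c1)
            pool.add(s, c2)
        elif u < lam[s] + mu[s]:  # extinction
            lin.t_end = t
            pool.remove(s, lid)
        else:  # one-step trait transition, uniform over the 1-step neighbors
            j = int(rng.choice(neighbors[s]))
            if sp.concealed_of(j) == sp.concealed_of(s):
                events.append(TransitionRecord(t, lid, "examined",
                                               sp.examined_of(s), sp.examined_of(j)))
            else:
                events.append(TransitionRecord(t, lid, "concealed",
                                               sp.concealed_of(s), sp.concealed_of(j)))
            lin.state = j
            pool.remove(s, lid)
            pool.add(j, lid)

    # close extant lineages at the crown age
    for lid, _pos in list(pool.pos.items()):
        lineages[lid].t_end = crown_age
        lineages[lid].extant = True

    return _build_tree(lineages, events, crown_age, params.space)


def _build_tree(
    lineages: list[_Lineage],
    events: list[TransitionRecord],
    crown_age: float,
    space,
) -> CladeTree:
    # keep = has at least one extant descendant (incl. itself)
    keep = np.zeros(len(lineages), dtype=bool)
    for lid in range(len(lineages) - 1, -1, -1):
        lin = lineages[lid]
        if lin.extant:
            keep[lid] = True
        elif lin.children is not None:
            keep[lid] = keep[lin.children[0]] or keep[lin.children[1]]
    if not (keep[0] and keep[1]):
        raise ExtinctCladeError("a crown lineage left no extant descendant")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node

    def attach(parent_node: dendropy.Node, lid: int) -> None:
        lin = lineages[lid]
        node = parent_node.new_child(edge_length=lin.t_end - lin.t_birth)
        if lin.extant:
            node.taxon = taxa.new_taxon(label=f"t{lid}")
        elif lin.children is not None:
            for c in lin.children:
                if keep[c]:
                    attach(node, c)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000 + len(lineages)))
    try:
        attach(root, 0)
        attach(root, 1)
    finally:
        sys.setrecursionlimit(old)
    # merge pruned-away unary nodes (keeps total path lengths)
    tree.suppress_unifurcations()

    tip_states = {
        f"t{lid}": (space.examined_of(lin.state), space.concealed_of(lin.state))
        for lid, lin in enumerate(lineages)
        if lin.extant
    }
    lineage_parent = {lid: lineages[lid].parent for lid in range(len(lineages))}
    tip_lineage = {f"t{lid}": lid for lid, lin in enumerate(lineages) if lin.extant}
    return CladeTree(
        tree=tree,
        crown_age=crown_age,
        tip_states=tip_states,
        space=space,
        event_log=events,
        lineage_parent=lineage_parent,
        tip_lineage=tip_lineage,
    )


@dataclass
class SampleLog:
    """Acceptance bookkeeping of the rejection sampler."""

    n_accepted: int = 0
    n_extinct: int = 0
    n_out_of_band: int = 0

    @property
    def n_attempts(self) -> int:
        return self.n_accepted + self.n_extinct + self.n_out_of_band


def sample_tree_set(
    mode: GeneratingMode,
    crown_age: float,
    size_band: tuple[int, int],
    n_trees: int,
    seed: int,
    max_attempts: int = 10_000,
    acceptance_floor: float = 1e-3,
    log: SampleLog | None = None,
) -> list[CladeTree]:
    """Rejection-sample clades until ``n_trees`` fall inside the tip band.

    Each attempt uses an independent generator seeded from
    ``(seed, tree_index, attempt)`` so a given tree is reproducible
    regardless of how many earlier trees were rejected.
    """
    lo, hi = size_band
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if lo < 2:
        raise ValueError("size band minimum must be >= 2")
    params = expand_generating_mode(mode)
    out: list[CladeTree] = []
    if log is None:
        log = SampleLog()
    attempt = 0
    while len(out) < n_trees:
        rng = np.random.default_rng([seed, len(out), attempt])
        attempt += 1
        if log.n_attempts >= max_attempts and (
            log.n_accepted / max(log.n_attempts, 1) < acceptance_floor
        ):
            raise InfeasibleBandError(
                f"band {size_band} acceptance below {acceptance_floor} "
                f"after {log.n_attempts} attempts"
            )
        try:
            clade = simulate_clade(params, crown_age, rng=rng)
        except ExtinctCladeError:
            log.n_extinct += 1
            continue
        if lo <= clade.n_tips <= hi:
            out.append(clade)
            log.n_accepted += 1
            attempt = 0
        else:
            log.n_out_of_band += 1
    return out
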