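"""Reading and writing trees, tip-state tables and event logs.

Formats: Newick with branch lengths in MY; a tab-delimited state table
``tip_label  examined_state  concealed_state`` using the display labels
(1/2/3 and A/B/C); the event log as CSV ``time,lineage,trait,from,to``.
Trees read from disk carry no event log; state tables may omit the
concealed column (stored as -1).
"""

from __future__ import annotations

import csv
from pathlib import Path

import dendropy
import numpy as np

from .states import CONCEALED_LABELS, DEFAULT_SPACE, EXAMINED_LABELS, StateSpace
from .trees import CladeTree, TransitionRecord

__all__ = [
    "write_newick",
    "read_newick",
    "write_state_table",
    "read_state_table",
    "write_event_log",
    "read_event_log",
    "write_clade",
    "read_clade",
]


def write_newick(clade: CladeTree, path: str | Path) -> None:
    Path(path).write_text(clade.newick() + "\n")


def write_state_table(clade: CladeTree, path: str | Path, examined_only: bool = False) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for label in sorted(clade.tip_labels):
            ex, co = clade.tip_states[label]
            row = [label, EXAMINED_LABELS[ex]]
            if not examined_only:
                row.append(CONCEALED_LABELS[co] if co >= 0 else "?")
            w.writerow(row)


def write_event_log(clade: CladeTree, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["time", "lineage", "trait", "from", "to"])
        for ev in clade.event_log:
            if ev.trait == "examined":
                a, b = EXAMINED_LABELS[ev.from_state], EXAMINED_LABELS[ev.to_state]
            else:
                a, b = CONCEALED_LABELS[ev.from_state], CONCEALED_LABELS[ev.to_state]
            w.writerow([repr(ev.time), ev.lineage_id, ev.trait, a, b])


def read_event_log(path: str | Path) -> list[TransitionRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            trait = row["trait"]
            labels = EXAMINED_LABELS if trait == "examined" else CONCEALED_LABELS
            out.append(
                TransitionRecord(
                    time=float(row["time"]),
                    lineage_id=int(row["lineage"]),
                    trait=trait,
                    from_state=labels.index(row["from"]),
                    to_state=labels.index(row["to"]),
                )
            )
    return out


def read_state_table(path: str | Path) -> dict[str, tuple[int, int]]:
    states: dict[str, tuple[int, int]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            label, ex = row[0], EXAMINED_LABELS.index(row[1])
            co = -1
            if len(row) > 2 and row[2] in CONCEALED_LABELS:
                co = CONCEALED_LABELS.index(row[2])
            states[label] = (ex, co)
    return states


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", rooting="default-rooted")


def write_clade(clade: CladeTree, prefix: str | Path, events: bool = True) -> None:
    """Write <prefix>.nwk, <prefix>.states.tsv and optionally <prefix>.events.csv."""
    prefix = Path(prefix)
    write_newick(clade, prefix.with_suffix(".nwk"))
    write_state_table(clade, prefix.with_name(prefix.name + ".states.tsv"))
    if events and clade.event_log:
        write_event_log(clade, prefix.with_name(prefix.name + ".events.csv"))


def read_clade(
    tree_path: str | Path,
    states_path: str | Path,
    space: StateSpace | None = None,
) -> CladeTree:
    """Assemble a CladeTree from a Newick file and a state table."""
    space = space or DEFAULT_SPACE
    tree = read_newick(tree_path)
    states = read_state_table(states_path)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depths = [leaf.root_distance for leaf in tree.leaf_node_iter()]
    return CladeTree(
        tree=tree,
        crown_age=float(np.max(depths)),
        tip_states=states,
        space=space,
    )
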