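"""Study-level summaries: selection error rates, accuracy, tree imbalance."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trees import CladeTree

__all__ = ["SelectionSummary", "fp_fn_rates", "sackin_index", "estimate_summary"]


@dataclass
class SelectionSummary:
    """Cross-tabulated model-selection outcomes with error rates in percent.

    ``fp_rate``: percent of CTD- or CR-generated datasets on which ETD was
    selected.  ``fn_rate``: percent of ETD-generated datasets on which a
    non-ETD model was selected.  ``None`` marks an undefined rate (no
    datasets of the relevant generating class).
    """

    counts: pd.DataFrame
    fp_rate: Optional[float]
    fn_rate: Optional[float]
    fp_from_ctd: int
    fp_from_cr: int


def fp_fn_rates(records: Sequence[tuple[str, str]]) -> SelectionSummary:
    """Compute false-positive/-negative percentages from (generating, selected) pairs."""
    df = pd.DataFrame(records, columns=["generating", "selected"])
    counts = df.value_counts(["generating", "selected"]).unstack(fill_value=0)

    non_etd = df[df.generating.isin(("CTD", "CR"))]
    fp_rate = None
    fp_ctd = int(((df.generating == "CTD") & (df.selected == "ETD")).sum())
    fp_cr = int(((df.generating == "CR") & (df.selected == "ETD")).sum())
    if len(non_etd):
        fp_rate = 100.0 * (non_etd.selected == "ETD").sum() / len(non_etd)

    etd = df[df.generating == "ETD"]
    fn_rate = None
    if len(etd):
        fn_rate = 100.0 * (etd.selected != "ETD").sum() / len(etd)

    return SelectionSummary(
        counts=counts,
        fp_rate=fp_rate,
        fn_rate=fn_rate,
        fp_from_ctd=fp_ctd,
        fp_from_cr=fp_cr,
    )


def sackin_index(clade: CladeTree, mean: bool = True) -> float:
    """Tree imbalance as root-to-tip path length in node counts.

    For every tip, count the internal nodes (root included) on its root
    path; return the average over tips (``mean=True``, the primary
    statistic) or the classical sum.
    """
    if clade.n_tips < 2:
        raise ValueError("Sackin index needs at least 2 tips")
    depths = []
    for node in clade.tree.preorder_node_iter():
        parent_depth = getattr(node.parent_node, "_sackin_depth", 0)
        if node.is_leaf():
            depths.append(parent_depth)
        else:
            node._sackin_depth = parent_depth + 1
    total = float(np.sum(depths))
    return total / len(depths) if mean else total


def estimate_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter accuracy summary over a set of fits.

    ``table`` is long-format with columns ``param``, ``truth``,
    ``estimate`` (one row per tree x parameter; include *all* generated
    trees, whether or not the generating model won the comparison).
    Returns bias, RMSE, and medians per parameter.
    """
    required = {"param", "truth", "estimate"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table.empty:
        raise ValueError("no fits to summarize")

    def _one(g: pd.DataFrame) -> pd.Series:
        err = g.estimate - g.truth
        return pd.Series(
            {
                "n": len(g),
                "truth_median": g.truth.median(),
                "estimate_median": g.estimate.median(),
                "bias": err.mean(),
                "rmse": np.sqrt((err**2).mean()),
            }
        )

    return table.groupby("param", sort=True).apply(_one, include_groups=False)
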