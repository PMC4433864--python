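"""Condition-specific (dynamic) PPI networks from time-course expression.

A static PPI network is the union of all known interactions for an organism.
At any one condition only part of the proteome is expressed, so the static
network over-represents what can actually interact.  The dynamic network
keeps a protein only when its gene's expression value at the condition of
interest reaches the gene's own temporal mean — a per-gene, scale-free
activity rule that needs no global threshold.

The comparison is ``value >= mean`` (not strict), so a flat constitutive
profile counts as expressed at every time point.  Proteins with no
expression record are treated as never expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = ["ActivityTable", "compute_activity", "build_dynamic"]


@dataclass(frozen=True)
class ActivityTable:
    """Per-gene activity flags and temporal means.

    ``active`` is a boolean gene × time-point frame with
    ``active.loc[g, t] == (value(g, t) >= mean(g))``; ``mean`` is the
    arithmetic mean of each gene over all time points of the series.
    """

    active: pd.DataFrame
    mean: pd.Series

    @property
    def timepoints(self) -> list[str]:
        return list(self.active.columns)


def compute_activity(series: pd.DataFrame) -> ActivityTable:
    """Flag each (gene, time point) as active when the value meets the gene's mean."""
    if series.empty:
        raise ValueError("expression series is empty")
    mean = series.mean(axis=1)
    active = series.ge(mean, axis=0)
    return ActivityTable(active=active, mean=mean)


def build_dynamic(
    static: nx.Graph,
    activity: ActivityTable,
    selection: Iterable[str] | None = None,
    mode: str = "any",
) -> nx.Graph:
    """Restrict a static PPI network to proteins active over selected time points.

    A protein is retained iff its gene is in the expression series and is
    active at *any* (``mode="any"``) or *all* (``mode="all"``) of the
    selected time points.  Edges survive iff both endpoints are retained;
    retained proteins left without any edge are dropped.  ``selection=None``
    means all time points of the series.

    The result is a subgraph of ``static`` carrying a provenance dict in
    ``graph.graph["provenance"]`` with the kept/dropped accounting.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    timepoints = activity.timepoints
    selection = list(selection) if selection is not None else timepoints
    if not selection:
        raise ValueError("time-point selection is empty")
    unknown = [t for t in selection if t not in timepoints]
    if unknown:
        raise ValueError(f"unknown time-point label(s): {unknown}")

    flags = activity.active[selection]
    mask = flags.any(axis=1) if mode == "any" else flags.all(axis=1)
    active_genes = set(mask.index[mask])

    dynamic = nx.Graph()
    for u, v in static.edges():
        if u in active_genes and v in active_genes:
            dynamic.add_edge(u, v)

    retained = set(n for n in static.nodes() if n in active_genes)
    dynamic.graph["provenance"] = {
        "static_nodes": static.number_of_nodes(),
        "static_edges": static.number_of_edges(),
        "selection": list(selection),
        "mode": mode,
        "active_proteins": len(retained),
        "isolated_dropped": len(retained) - dynamic.number_of_nodes(),
        "nodes": dynamic.number_of_nodes(),
        "edges": dynamic.number_of_edges(),
    }
    return dynamic
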