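"""Interface kinetics: retention times and transition networks.

Retention time = contiguous dwell of a labelled trajectory within one
interface cluster; unassigned frames break runs (bridging optional).

The transition net collapses each trajectory's label sequence to its
subsequence of node-set visits (consecutive duplicates merged), counts
ordered pairs of successive visits, and keeps an edge only when it was
observed at least ``min_count`` times (singleton transitions are not
reproducible) and ranks among the ``top_k`` most frequent outgoing
transitions of its source.  Excursions through clusters outside the
node set are invisible ("indirect" transitions); a round trip through
them returns to the same node and is dropped with the self-pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import UNASSIGNED


@dataclass
class LabeledTrajectory:
    """Frame times (ns) with a cluster label per frame."""

    times: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.times) != len(self.labels):
            raise ValueError("times and labels must have equal length")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("need at least 2 frames to infer dt")
        return float(self.times[1] - self.times[0])


def retention_times(
    labeled: LabeledTrajectory,
    unassigned: Hashable = UNASSIGNED,
    bridge: bool = False,
) -> dict[Hashable, list[float]]:
    """Dwell durations per cluster.

    Each contiguous run of ``k`` frames with one label contributes a
    dwell of ``k * dt``.  Unassigned frames break runs; with
    ``bridge=True`` a gap of unassigned frames between identical labels
    is absorbed into the dwell (gap time included, keeping the total
    time conserved).
    """
    labels = list(labeled.labels)
    if not labels:
        raise ValueError("empty trajectory")
    dt = labeled.dt if len(labels) > 1 else 0.0

    if bridge:
        labels = _bridged(labels, unassigned)

    dwells: dict[Hashable, list[float]] = {}
    run_label, run_len = labels[0], 1
    for lab in labels[1:]:
        if lab == run_label:
            run_len += 1
        else:
            if run_label != unassigned:
                dwells.setdefault(run_label, []).append(run_len * dt)
            run_label, run_len = lab, 1
    if run_label != unassigned:
        dwells.setdefault(run_label, []).append(run_len * dt)
    return dwells


def _bridged(labels: list, unassigned: Hashable) -> list:
    out = list(labels)
    i = 0
    while i < len(out):
        if out[i] == unassigned:
            j = i
            while j < len(out) and out[j] == unassigned:
                j += 1
            prev_lab = out[i - 1] if i > 0 else None
            next_lab = out[j] if j < len(out) else None
            if prev_lab is not None and prev_lab == next_lab:
                out[i:j] = [prev_lab] * (j - i)
            i = j
        else:
            i += 1
    return out


def retention_summary(dwells: dict[Hashable, list[float]]) -> pd.DataFrame:
    rows = [
        {
            "cluster": c,
            "n_dwells": len(d),
            "mean_dwell": float(np.mean(d)),
            "total_time": float(np.sum(d)),
            "max_dwell": float(np.max(d)),
        }
        for c, d in sorted(dwells.items(), key=lambda kv: str(kv[0]))
    ]
    return pd.DataFrame(rows)


def collapse_to_node_set(labels: Sequence, node_set: set) -> list:
    """Subsequence of node-set visits with consecutive duplicates merged."""
    out = []
    for lab in labels:
        if lab in node_set and (not out or out[-1] != lab):
            out.append(lab)
    return out


def build_transition_net(
    label_sequences: list[Sequence],
    node_set: Sequence | None = None,
    min_count: int = 2,
    top_k: int = 3,
    unassigned: Hashable = UNASSIGNED,
) -> nx.DiGraph:
    """Directed transition network over interface clusters.

    Counts are pooled across all trajectories before the ``min_count``
    filter.  Kept edges carry ``kept=True``; all observed edges remain
    in the graph with their counts for inspection.  Node attribute
    ``frequency`` is the number of frames carrying that label.

    Ties among equally frequent outgoing edges are broken towards the
    smaller target id (string order for non-numeric labels).
    """
    observed = set()
    for seq in label_sequences:
        observed.update(x for x in seq if x != unassigned)
    if node_set is None:
        node_set = observed
    node_set = set(node_set)
    if not node_set:
        raise ValueError("empty node set")
    if not node_set <= observed and observed:
        missing = node_set - observed
        if missing:
            # allowed: nodes may simply never be visited; they become isolated
            pass

    counts: dict[tuple, int] = {}
    freq: dict[Hashable, int] = {n: 0 for n in node_set}
    for seq in label_sequences:
        for lab in seq:
            if lab in node_set:
                freq[lab] += 1
        visits = collapse_to_node_set(seq, node_set)
        for a, b in zip(visits[:-1], visits[1:]):
            if a != b:
                counts[(a, b)] = counts.get((a, b), 0) + 1

    net = nx.DiGraph()
    for node in sorted(node_set, key=str):
        net.add_node(node, frequency=freq[node])
    # rank outgoing edges per source: by count desc, ties by target id
    by_source: dict[Hashable, list[tuple]] = {}
    for (a, b), c in counts.items():
        by_source.setdefault(a, []).append((b, c))
    for a, out_edges in by_source.items():
        ranked = sorted(out_edges, key=lambda bc: (-bc[1], str(bc[0])))
        top = {b for b, _ in ranked[:top_k]}
        for b, c in out_edges:
            kept = (c >= min_count) and (b in top)
            net.add_edge(a, b, count=c, kept=bool(kept))
    return net


def kept_subgraph(net: nx.DiGraph) -> nx.DiGraph:
    sub = nx.DiGraph()
    sub.add_nodes_from(net.nodes(data=True))
    sub.add_edges_from(
        (a, b, d) for a, b, d in net.edges(data=True) if d.get("kept", False)
    )
    return sub


def is_strongly_connected(net: nx.DiGraph, kept_only: bool = True) -> bool:
    """Whether every cluster is reachable from every other cluster."""
    graph = kept_subgraph(net) if kept_only else net
    if graph.number_of_nodes() == 0:
        return False
    return nx.is_strongly_connected(graph)


def transition_table(net: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {"from": a, "to": b, "count": d["count"], "kept": d["kept"]}
        for a, b, d in net.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["from", "to", "count", "kept"])
    return df.sort_values(["from", "count", "to"], ascending=[True, False, True], key=lambda s: s.astype(str) if s.name in ("from", "to") else s).reset_index(drop=True)
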