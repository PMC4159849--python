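"""Hierarchical clustering of interface contact maps.

Contact maps are flattened to boolean vectors, compared with the dice
dissimilarity

    d(u, v) = (c_TF + c_FT) / (2 c_TT + c_TF + c_FT),

and clustered by average linkage (UPGMA); flat clusters are cut at a
cophenetic distance of 0.5 (inclusive).  Maps with fewer than 19
contacts (no stable dimer) are excluded from clustering and labelled
``UNASSIGNED``.  Cluster ids are assigned by decreasing global size
(ties by first occurrence), so cluster 1 is always the most frequent
interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .contacts import AnalysisConfig, ContactMap, count_contacts

#: label given to maps excluded by the minimum-contact filter
UNASSIGNED = -1


def dice_dissimilarity(u: np.ndarray, v: np.ndarray) -> float:
    """Dice dissimilarity between two boolean vectors.

    Raises ``ValueError`` on length mismatch or when both vectors are
    all-false (the dissimilarity is undefined there).
    """
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    c_tt = int((u & v).sum())
    c_tf = int((u & ~v).sum())
    c_ft = int((~u & v).sum())
    denom = 2 * c_tt + c_tf + c_ft
    if denom == 0:
        raise ValueError("dice dissimilarity undefined for two all-false vectors")
    return (c_tf + c_ft) / denom


@dataclass
class InterfaceClustering:
    """Result of clustering a collection of contact maps.

    ``labels`` holds one cluster id per input map (``UNASSIGNED`` for
    maps that failed the minimum-contact filter); ids are positive
    integers ordered by decreasing cluster size.  ``linkage_matrix`` is
    the scipy linkage over the maps that survived the filter, in the
    order given by ``kept_indices``.
    """

    labels: np.ndarray
    linkage_matrix: np.ndarray | None
    kept_indices: np.ndarray
    cluster_ids: np.ndarray  # ordered by decreasing size
    cluster_sizes: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def members(self, cluster_id: int) -> np.ndarray:
        """Input-map indices belonging to one cluster."""
        return np.flatnonzero(self.labels == cluster_id)


def cluster_interfaces(
    maps: list[ContactMap],
    config: AnalysisConfig | None = None,
    min_contacts: int | None = None,
) -> InterfaceClustering:
    """UPGMA clustering of contact maps on the dice distance.

    Maps with fewer than ``min_contacts`` contacts (default: the
    config's ``stable_contact_min``, 19) are excluded.  Raises
    ``ValueError`` if no map survives the filter.
    """
    config = config or AnalysisConfig()
    if min_contacts is None:
        min_contacts = config.stable_contact_min

    counts = np.array([count_contacts(m) for m in maps])
    kept = np.flatnonzero(counts >= min_contacts)
    if len(kept) == 0:
        raise ValueError(
            f"no contact map with >= {min_contacts} contacts; nothing to cluster"
        )

    labels = np.full(len(maps), UNASSIGNED, dtype=int)
    if len(kept) == 1:
        raw = np.array([1])
        z = None
    else:
        x = np.stack([maps[i].flatten() for i in kept]).astype(bool)
        distances = pdist(x, metric="dice")
        z = linkage(distances, method="average")
        raw = fcluster(z, t=config.cluster_cutoff, criterion="distance")

    relabelled, order, sizes = _relabel_by_size(raw)
    labels[kept] = relabelled
    return InterfaceClustering(labels, z, kept, order, sizes)


def _relabel_by_size(raw: np.ndarray):
    """Map arbitrary flat-cluster ids to 1..K by decreasing size.

    Ties are broken by first occurrence in the input order.
    """
    first_seen = {}
    counts = {}
    for i, r in enumerate(raw):
        counts[r] = counts.get(r, 0) + 1
        first_seen.setdefault(r, i)
    ranked = sorted(counts, key=lambda r: (-counts[r], first_seen[r]))
    mapping = {r: k + 1 for k, r in enumerate(ranked)}
    relabelled = np.array([mapping[r] for r in raw], dtype=int)
    order = np.arange(1, len(ranked) + 1)
    sizes = {mapping[r]: counts[r] for r in ranked}
    return relabelled, order, sizes


def cluster_frequencies(
    labels: np.ndarray | "InterfaceClustering",
    conditions: np.ndarray,
    min_count: int | None = None,
    others_label: str = "others",
    proportions: bool = False,
) -> pd.DataFrame:
    """Per-condition cluster frequency table.

    Rows are cluster ids (ordered by decreasing global frequency),
    columns are conditions.  Maps labelled ``UNASSIGNED`` are excluded.
    Clusters whose global count falls below ``min_count`` are lumped
    into an ``others`` row, mirroring the reporting convention of
    showing only clusters with at least a handful of members.
    """
    if isinstance(labels, InterfaceClustering):
        labels = labels.labels
    labels = np.asarray(labels)
    conditions = np.asarray(conditions)
    if len(labels) != len(conditions):
        raise ValueError("labels and conditions must have equal length")

    mask = labels != UNASSIGNED
    df = pd.DataFrame({"cluster": labels[mask], "condition": conditions[mask]})
    table = df.groupby(["cluster", "condition"]).size().unstack(fill_value=0)
    table = table.loc[table.sum(axis=1).sort_values(ascending=False, kind="stable").index]

    if min_count is not None:
        totals = table.sum(axis=1)
        small = totals < min_count
        if small.any():
            others = table.loc[small].sum(axis=0)
            table = table.loc[~small]
            table.loc[others_label] = others
    if proportions:
        table = table / table.sum(axis=0)
    return table


@dataclass
class ContactFrequencyMap:
    """Per-cluster contact frequencies: entrywise mean of member maps."""

    matrix: np.ndarray
    cluster_id: int
    n_members: int
    residues_a: np.ndarray
    residues_b: np.ndarray


def contact_frequency_map(
    clustering: InterfaceClustering, cluster_id: int, maps: list[ContactMap]
) -> ContactFrequencyMap:
    """Mean contact map over the members of one cluster."""
    members = clustering.members(cluster_id)
    if len(members) == 0:
        raise KeyError(f"unknown or empty cluster {cluster_id}")
    stack = np.stack([maps[i].matrix for i in members]).astype(float)
    return ContactFrequencyMap(
        stack.mean(axis=0),
        cluster_id,
        len(members),
        maps[members[0]].residues_a,
        maps[members[0]].residues_b,
    )
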