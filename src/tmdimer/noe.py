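"""Validation of atomistic dimer structures against NOE distance bounds.

NMR experiments yield maximal inter-atomic distances (NOE constraints)
between the two helices of a dimer.  A structure *fulfills* a
constraint when the corresponding distance does not exceed the bound;
ambiguous selectors (wildcard atom names, e.g. ``HG*``) are resolved to
the minimum distance over all matching atom pairs, the standard
treatment for unassigned methyl/methylene protons.

Structures enter as biotite ``AtomArray`` objects with coordinates in
nm (as produced by :func:`tmdimer.structures.read_pdb_models`); the CG
to atomistic backmapping that produces them is an input boundary, not
part of this package.

Constraint tables are CSV with columns
``res_a, atom_a, res_b, atom_b, d_max_nm, source``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fnmatch import fnmatch
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class NOEConstraint:
    """A maximal inter-helix distance between two (possibly ambiguous) atoms."""

    res_a: int
    atom_a: str
    res_b: int
    atom_b: str
    max_distance: float  # nm
    source: str = ""

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")


def read_constraint_table(path: str | Path) -> list[NOEConstraint]:
    df = pd.read_csv(path)
    required = {"res_a", "atom_a", "res_b", "atom_b", "d_max_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"constraint table misses columns {missing}")
    return [
        NOEConstraint(
            int(row.res_a),
            str(row.atom_a),
            int(row.res_b),
            str(row.atom_b),
            float(row.d_max_nm),
            str(getattr(row, "source", "")),
        )
        for row in df.itertuples()
    ]


def _select(structure, chain_id: str, res_id: int, atom_pattern: str) -> np.ndarray:
    mask = (
        (structure.chain_id == chain_id)
        & (structure.res_id == res_id)
        & np.array([fnmatch(str(a), atom_pattern) for a in structure.atom_name])
    )
    coords = structure.coord[mask]
    if len(coords) == 0:
        raise ValueError(
            f"selector {chain_id}:{res_id}:{atom_pattern!r} matches no atom"
        )
    return coords


def constraint_distance(structure, constraint: NOEConstraint) -> float:
    """Minimum distance (nm) over all atom pairs matching the selectors.

    Helix A is the lexicographically first chain of the structure,
    helix B the second.
    """
    chains = sorted(set(structure.chain_id))
    if len(chains) < 2:
        raise ValueError("structure must contain two chains")
    coords_a = _select(structure, chains[0], constraint.res_a, constraint.atom_a)
    coords_b = _select(structure, chains[1], constraint.res_b, constraint.atom_b)
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).min())


def constraint_fulfilled(structure, constraint: NOEConstraint) -> bool:
    """True iff the (minimum matching) distance is <= the NOE bound."""
    return constraint_distance(structure, constraint) <= constraint.max_distance


def fulfillment_profile(
    grouped_structures: dict, constraints: list[NOEConstraint]
) -> tuple[pd.DataFrame, pd.Series]:
    """Fraction of structures fulfilling each constraint, per cluster.

    Parameters
    ----------
    grouped_structures : dict
        cluster id -> list of atomistic structures.
    constraints : list of NOEConstraint

    Returns
    -------
    fractions : DataFrame
        Rows = cluster ids, columns = constraint index; entries in [0, 1].
    mean_fulfilled : Series
        Average number of constraints fulfilled by one structure, per
        cluster.
    """
    if not grouped_structures:
        raise ValueError("no structure groups given")
    if not constraints:
        raise ValueError("no constraints given")
    frac_rows = {}
    mean_counts = {}
    for cluster, structures in grouped_structures.items():
        if not structures:
            raise ValueError(f"cluster {cluster!r} has no structures")
        fulfilled = np.array(
            [
                [constraint_fulfilled(s, c) for c in constraints]
                for s in structures
            ],
            dtype=float,
        )
        frac_rows[cluster] = fulfilled.mean(axis=0)
        mean_counts[cluster] = float(fulfilled.sum(axis=1).mean())
    fractions = pd.DataFrame.from_dict(frac_rows, orient="index")
    fractions.columns = [
        f"{c.source or 'noe'}:{c.res_a}{c.atom_a}-{c.res_b}{c.atom_b}" for c in constraints
    ]
    return fractions, pd.Series(mean_counts, name="mean_fulfilled")
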