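"""Independent oracles and synthetic builders shared across tests.

Everything here is deliberately naive (exhaustive enumeration, direct
formula evaluation) and independent of the library code paths it is
used to check.
"""

from __future__ import annotations

import itertools

import numpy as np


# -- clustering ------------------------------------------------------------


def dice_formula(u, v) -> float:
    u = np.asarray(u, bool)
    v = np.asarray(v, bool)
    c_tt = int((u & v).sum())
    c_tf = int((u & ~v).sum())
    c_ft = int((~u & v).sum())
    return (c_tf + c_ft) / (2 * c_tt + c_tf + c_ft)


def brute_force_upgma_partition(vectors, cutoff: float):
    """Exhaustive average-linkage agglomeration, cut at ``cutoff``.

    Clusters are merged greedily at the globally smallest mean pairwise
    dice distance (recomputed from scratch each step) while that
    distance is <= cutoff.  Returns a list of frozensets of indices.
    """
    n = len(vectors)
    dist = {
        (i, j): dice_formula(vectors[i], vectors[j])
        for i, j in itertools.combinations(range(n), 2)
    }

    def cluster_distance(a, b):
        return float(
            np.mean([dist[(min(i, j), max(i, j))] for i in a for j in b])
        )

    clusters = [frozenset([i]) for i in range(n)]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = cluster_distance(a, b)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        if d > cutoff:
            break
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return clusters


def same_partition(labels_a, labels_b) -> bool:
    """Whether two labelings induce the same partition (up to renaming)."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if len(labels_a) != len(labels_b):
        return False
    fwd, bwd = {}, {}
    for a, b in zip(labels_a, labels_b):
        if fwd.setdefault(a, b) != b or bwd.setdefault(b, a) != a:
            return False
    return True


# -- stable-dimer window ---------------------------------------------------


def stable_window_oracle(times, counts, span, min_contacts):
    """All-windows enumeration of the stable-dimer rule."""
    times = list(times)
    n = len(times)
    for i in range(n):
        for j in range(i, n):
            if times[j] - times[i] >= span and all(
                counts[k] >= min_contacts for k in range(i, j + 1)
            ):
                return True, times[i]
    return False, None


# -- graph reachability ----------------------------------------------------


def strongly_connected_oracle(nodes, edges) -> bool:
    """Exhaustive reachability: every ordered node pair connected."""
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)

    def reachable(src):
        seen = {src}
        stack = [src]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    return all(set(nodes) <= reachable(n) for n in nodes)


# -- synthetic atomistic structures ---------------------------------------

SEQUENCE_CYCLE = ("LEU", "ILE", "GLY", "VAL", "ALA", "THR", "PHE", "SER")

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def make_atomistic_helix(
    n_res: int,
    chain_id: str = "A",
    first_res: int = 70,
    shift=(0.0, 0.0, 0.0),
    flip_phase: float = 0.0,
):
    """Ideal atomistic alpha-helix (backbone + CB) as a biotite AtomArray.

    Coordinates are in nm (matching the package's internal convention).
    CA atoms lie on a regular helix (radius 0.23 nm, rise 0.15 nm,
    twist 100 deg); N, C, O and CB are placed at fixed offsets in the
    local residue frame so that the backbone centre of mass differs
    from the CA position.
    """
    import biotite.structure as struc

    atoms = []
    shift = np.asarray(shift, float)
    for i in range(n_res):
        res_name = SEQUENCE_CYCLE[i % len(SEQUENCE_CYCLE)]
        theta = np.deg2rad(100.0 * i + flip_phase)
        e_r = np.array([np.cos(theta), np.sin(theta), 0.0])
        e_t = np.array([-np.sin(theta), np.cos(theta), 0.0])
        ca = 0.23 * e_r + np.array([0.0, 0.0, 0.15 * i])
        local = {
            "N": ca - 0.12 * e_t + np.array([0, 0, -0.08]),
            "CA": ca,
            "C": ca + 0.12 * e_t + np.array([0, 0, 0.06]),
            "O": ca + 0.15 * e_t + np.array([0, 0, 0.18]),
        }
        if res_name != "GLY":
            local["CB"] = ca + 0.15 * e_r
        for atom_name, pos in local.items():
            atoms.append(
                struc.Atom(
                    pos + shift,
                    chain_id=chain_id,
                    res_id=first_res + i,
                    res_name=res_name,
                    atom_name=atom_name,
                    element=_ELEMENT[atom_name],
                )
            )
    return struc.array(atoms)


def make_atomistic_dimer(n_res: int = 30, first_res: int = 70, separation: float = 0.9):
    """Two parallel atomistic helices (chains A and B), coordinates in nm."""
    import biotite.structure as struc

    a = make_atomistic_helix(n_res, "A", first_res)
    b = make_atomistic_helix(
        n_res, "B", first_res, shift=(separation, 0.0, 0.0), flip_phase=180.0
    )
    return struc.concatenate([a, b])
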