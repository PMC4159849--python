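"""Residue-residue contact maps and the stable-dimer criterion.

The dimer interface of a frame is summarised as a boolean matrix over
residue pairs: entry (i, j) is true when residue *i* of helix A and
residue *j* of helix B approach each other closer than the contact
cutoff (default 0.6 nm, i.e. 6 A, strict inequality).  The similarity
of a map to a reference interface (e.g. the NMR-derived one) is the
fraction of reference contacts it reproduces,

    similarity = c(TT) / c(ref),

where c(TT) counts contacts present in both maps; extra non-reference
contacts do not lower the score.  A dimer is considered stable when at
least ``stable_contact_min`` contacts (default 19) persist in every
stored frame over a ``stable_span`` (default 100 ns) window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Frame, Trajectory


@dataclass
class AnalysisConfig:
    """Interface-analysis parameters.

    contact_cutoff : nm, residue contact threshold (default 0.6).
    stable_contact_min : minimum contacts for a stable dimer (default 19).
    stable_span : ns the contact criterion must persist (default 100).
    cluster_frame_interval : ns between frames used for clustering (default 50).
    cluster_cutoff : dice-distance cutoff for flat clusters (default 0.5).
    """

    contact_cutoff: float = 0.6
    stable_contact_min: int = 19
    stable_span: float = 100.0
    cluster_frame_interval: float = 50.0
    cluster_cutoff: float = 0.5

    def __post_init__(self):
        for name in (
            "contact_cutoff",
            "stable_contact_min",
            "stable_span",
            "cluster_frame_interval",
            "cluster_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ContactMap:
    """Boolean inter-helix contact matrix.

    Rows are residues of helix A, columns residues of helix B, both in
    ascending author numbering starting at ``residue_offset``.
    """

    matrix: np.ndarray
    residues_a: np.ndarray
    residues_b: np.ndarray
    cutoff: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        self.residues_a = np.asarray(self.residues_a, dtype=int)
        self.residues_b = np.asarray(self.residues_b, dtype=int)
        if self.matrix.shape != (len(self.residues_a), len(self.residues_b)):
            raise ValueError("matrix shape must match residue index arrays")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")

    @property
    def residue_offset(self) -> int:
        return int(self.residues_a[0])

    def flatten(self) -> np.ndarray:
        return self.matrix.ravel()


def compute_contact_map(
    frame: Frame,
    segment: tuple[int, int] | None = None,
    cutoff: float = 0.6,
    distance_mode: str = "min_bead",
) -> ContactMap:
    """Contact map of one frame.

    Parameters
    ----------
    frame : Frame
        Two-chain CG frame; the lexicographically first chain is helix A.
    segment : (first, last), optional
        Residue range to analyse; defaults to all residues.
    cutoff : float
        Contact threshold in nm (strict: distance < cutoff).
    distance_mode : {"min_bead", "BB_only"}
        Inter-residue distance as the minimum over all bead pairs
        (default; side-chain beads carry the packing signal) or over
        backbone beads only.

    If the frame has a box, the minimum-image convention is applied on
    each orthorhombic component.
    """
    if distance_mode not in ("min_bead", "BB_only"):
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    chains = frame.structure.chains
    struct = frame.structure
    parts = []
    for chain in chains[:2]:
        sub = struct.chain(chain)
        if distance_mode == "BB_only":
            sub = sub._subset(sub.bead_names == "BB")
        if segment is not None:
            lo, hi = segment
            mask = (sub.residue_indices >= lo) & (sub.residue_indices <= hi)
            if not mask.any():
                raise ValueError(f"chain {chain} has no residues in segment {segment}")
            sub = sub._subset(mask)
        parts.append(sub)
    sub_a, sub_b = parts
    res_a = np.unique(sub_a.residue_indices)
    res_b = np.unique(sub_b.residue_indices)
    if segment is not None:
        lo, hi = segment
        expected = np.arange(lo, hi + 1)
        for chain, res in zip(chains, (res_a, res_b)):
            if not np.array_equal(res, expected):
                raise ValueError(
                    f"chain {chain} does not cover segment {segment} completely"
                )

    diff = sub_a.positions[:, None, :] - sub_b.positions[None, :, :]
    if frame.box is not None:
        diff = diff - frame.box * np.round(diff / frame.box)
    dist = np.sqrt((diff**2).sum(axis=-1))

    ia = np.searchsorted(res_a, sub_a.residue_indices)
    ib = np.searchsorted(res_b, sub_b.residue_indices)
    min_dist = np.full((len(res_a), len(res_b)), np.inf)
    np.minimum.at(min_dist, (ia[:, None], ib[None, :]), dist)
    return ContactMap(min_dist < cutoff, res_a, res_b, cutoff)


def count_contacts(contact_map: ContactMap) -> int:
    """Total number of inter-helix residue contacts in a map."""
    return int(contact_map.matrix.sum())


def coinciding_contacts(contact_map: ContactMap, reference: ContactMap) -> int:
    """c(TT): contacts present in both the map and the reference."""
    if contact_map.matrix.shape != reference.matrix.shape:
        raise ValueError("contact maps have different shapes")
    return int((contact_map.matrix & reference.matrix).sum())


def similarity_to_reference(contact_map: ContactMap, reference: ContactMap) -> float:
    """Similarity score c(TT) / c(ref), in [0, 1].

    Equals 1 iff every reference contact is reproduced; contacts absent
    from the reference do not change the score.
    """
    c_ref = count_contacts(reference)
    if c_ref == 0:
        raise ValueError("reference map has no contacts")
    return coinciding_contacts(contact_map, reference) / c_ref


def contact_count_series(
    trajectory: Trajectory,
    segment: tuple[int, int] | None = None,
    cutoff: float = 0.6,
    distance_mode: str = "min_bead",
) -> np.ndarray:
    """Per-frame inter-helix contact counts."""
    return np.array(
        [
            count_contacts(compute_contact_map(f, segment, cutoff, distance_mode))
            for f in trajectory
        ]
    )


def detect_stable_dimer(
    trajectory: Trajectory,
    config: AnalysisConfig | None = None,
    segment: tuple[int, int] | None = None,
    distance_mode: str = "min_bead",
    counts: np.ndarray | None = None,
) -> tuple[bool, float | None]:
    """Stable-dimer detection over a sliding window.

    A dimer is stable when a contiguous run of stored frames, spanning
    at least ``stable_span`` ns, all show >= ``stable_contact_min``
    contacts (strictest per-frame reading).  Returns ``(found, start)``
    with the start time of the first qualifying window, or
    ``(False, None)``.

    ``counts`` may supply precomputed per-frame contact counts.
    """
    config = config or AnalysisConfig()
    if trajectory.dt > config.stable_span:
        raise ValueError("trajectory dt must be <= stable_span")
    if counts is None:
        counts = contact_count_series(
            trajectory, segment, config.contact_cutoff, distance_mode
        )
    return first_stable_window(
        trajectory.times, counts, config.stable_span, config.stable_contact_min
    )


def first_stable_window(
    times: np.ndarray, counts: np.ndarray, span: float, min_contacts: int
) -> tuple[bool, float | None]:
    """First contiguous frame run with all counts >= ``min_contacts``
    whose time extent reaches ``span``; returns ``(found, start_time)``."""
    times = np.asarray(times, dtype=float)
    ok = np.asarray(counts) >= min_contacts

    run_start = None
    for i, flag in enumerate(ok):
        if flag:
            if run_start is None:
                run_start = i
            if times[i] - times[run_start] >= span:
                return True, float(times[run_start])
        else:
            run_start = None
    return False, None
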