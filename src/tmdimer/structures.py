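"""Coarse-grained bead structures of two-helix systems.

The package analyses transmembrane-helix dimers in MARTINI-style
coarse-grained (CG) representations: each residue carries one backbone
bead (``BB``) and zero or more side-chain beads (``SC1`` .. ``SC4``).
This module provides the in-memory containers (:class:`BeadStructure`,
:class:`Frame`, :class:`Trajectory`) and the operations that create
them: multi-model PDB reading, atomistic-to-CG mapping (backbone
centre-of-mass or C-alpha placement), segment truncation, and ideal
helix construction.

All coordinates are stored in nanometres; PDB input (angstrom) is
converted on read.  Residue numbering follows the author numbering of
the source structure (for the glycophorin A transmembrane helix the
25mer spans residues 72-96) and is preserved through truncation so that
contact maps remain comparable across structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

NM_PER_ANGSTROM = 0.1

#: atomic masses (u) for the heavy atoms that occur in protein residues
ATOMIC_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: MARTINI 2.x side-chain mapping: residue -> list of bead atom groups
#: (heavy atoms only; ALA and GLY carry no side-chain bead).
MARTINI_SIDE_CHAINS: dict[str, list[list[str]]] = {
    "ALA": [],
    "GLY": [],
    "CYS": [["CB", "SG"]],
    "SER": [["CB", "OG"]],
    "THR": [["CB", "OG1", "CG2"]],
    "VAL": [["CB", "CG1", "CG2"]],
    "LEU": [["CB", "CG", "CD1", "CD2"]],
    "ILE": [["CB", "CG1", "CG2", "CD1"]],
    "MET": [["CB", "CG", "SD", "CE"]],
    "PRO": [["CB", "CG", "CD"]],
    "ASN": [["CB", "CG", "OD1", "ND2"]],
    "GLN": [["CB", "CG", "CD", "OE1", "NE2"]],
    "ASP": [["CB", "CG", "OD1", "OD2"]],
    "GLU": [["CB", "CG", "CD", "OE1", "OE2"]],
    "LYS": [["CB", "CG", "CD"], ["CE", "NZ"]],
    "ARG": [["CB", "CG", "CD"], ["NE", "CZ", "NH1", "NH2"]],
    "HIS": [["CB", "CG"], ["CD2", "NE2"], ["ND1", "CE1"]],
    "PHE": [["CB", "CG"], ["CD1", "CE1"], ["CD2", "CE2", "CZ"]],
    "TYR": [["CB", "CG"], ["CD1", "CE1"], ["CD2", "CE2", "CZ", "OH"]],
    "TRP": [["CB", "CG", "CD2"], ["CD1", "NE1", "CE2"], ["CE3", "CZ3"], ["CZ2", "CH2"]],
}


@dataclass(frozen=True)
class Bead:
    """A single CG pseudo-atom.

    Attributes
    ----------
    residue_index : int
        1-based residue number in the author numbering of the peptide.
    bead_name : str
        ``BB`` for the backbone bead, ``SC1`` .. ``SC4`` for side chains.
    position : ndarray, shape (3,)
        Cartesian position in nm.
    chain_id : str
        Chain label (two-helix systems use ``A`` and ``B``).
    """

    residue_index: int
    bead_name: str
    position: np.ndarray
    chain_id: str


class BeadStructure:
    """An ordered collection of CG beads, stored as parallel arrays.

    Beads are kept sorted by ``(chain_id, residue_index)`` with ``BB``
    preceding the side-chain beads of the same residue.  Each
    ``(chain, residue, bead_name)`` triple must be unique and every
    residue must carry a backbone bead.

    Parameters
    ----------
    chain_ids, residue_indices, bead_names : array-like
        Per-bead metadata.
    positions : ndarray, shape (n, 3)
        Bead coordinates in nm.
    mapping_mode : {"COM", "CA"}
        How backbone beads were placed: backbone centre of mass
        (MARTINI 2.x convention) or at the C-alpha position.
    residue_names : array-like of str, optional
        Three-letter residue names; defaults to ``ALA``.
    """

    def __init__(
        self,
        chain_ids: Sequence[str],
        residue_indices: Sequence[int],
        bead_names: Sequence[str],
        positions: np.ndarray,
        mapping_mode: str = "CA",
        residue_names: Sequence[str] | None = None,
    ):
        if mapping_mode not in ("COM", "CA"):
            raise ValueError(f"mapping_mode must be 'COM' or 'CA', got {mapping_mode!r}")
        chain_ids = np.asarray(chain_ids, dtype=object)
        residue_indices = np.asarray(residue_indices, dtype=int)
        bead_names = np.asarray(bead_names, dtype=object)
        positions = np.asarray(positions, dtype=float)
        if residue_names is None:
            residue_names = np.full(len(chain_ids), "ALA", dtype=object)
        else:
            residue_names = np.asarray(residue_names, dtype=object)
        if positions.shape != (len(chain_ids), 3):
            raise ValueError("positions must have shape (n_beads, 3)")
        if not np.all(np.isfinite(positions)):
            raise ValueError("bead positions must be finite")
        if np.any(residue_indices < 1):
            raise ValueError("residue indices must be >= 1")

        order = _bead_sort_order(chain_ids, residue_indices, bead_names)
        self.chain_ids = chain_ids[order]
        self.residue_indices = residue_indices[order]
        self.bead_names = bead_names[order]
        self.positions = positions[order]
        self.residue_names = residue_names[order]
        self.mapping_mode = mapping_mode

        keys = list(zip(self.chain_ids, self.residue_indices, self.bead_names))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, bead_name) in structure")
        for chain in self.chains:
            mask = self.chain_ids == chain
            residues = set(self.residue_indices[mask])
            bb_residues = set(self.residue_indices[mask & (self.bead_names == "BB")])
            if residues != bb_residues:
                raise ValueError(f"chain {chain}: every residue needs a BB bead")

    # -- accessors ---------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.chain_ids)

    @property
    def chains(self) -> list[str]:
        """Chain labels in sorted order."""
        return sorted(set(self.chain_ids))

    @property
    def beads(self) -> list[Bead]:
        return [
            Bead(int(r), str(b), p.copy(), str(c))
            for c, r, b, p in zip(
                self.chain_ids, self.residue_indices, self.bead_names, self.positions
            )
        ]

    def chain(self, chain_id: str) -> "BeadStructure":
        mask = self.chain_ids == chain_id
        if not mask.any():
            raise KeyError(f"no chain {chain_id!r}")
        return self._subset(mask)

    def residues(self, chain_id: str) -> np.ndarray:
        """Sorted residue indices present in a chain."""
        return np.unique(self.residue_indices[self.chain_ids == chain_id])

    def bb_positions(self, chain_id: str) -> np.ndarray:
        """Backbone-bead coordinates of one chain, ordered by residue."""
        mask = (self.chain_ids == chain_id) & (self.bead_names == "BB")
        return self.positions[mask]

    def _subset(self, mask: np.ndarray) -> "BeadStructure":
        return BeadStructure(
            self.chain_ids[mask],
            self.residue_indices[mask],
            self.bead_names[mask],
            self.positions[mask],
            self.mapping_mode,
            self.residue_names[mask],
        )

    def with_positions(self, positions: np.ndarray) -> "BeadStructure":
        return BeadStructure(
            self.chain_ids,
            self.residue_indices,
            self.bead_names,
            positions,
            self.mapping_mode,
            self.residue_names,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BeadStructure":
        """Apply the rigid-body transform ``x -> R x + t``."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return self.with_positions(self.positions @ rotation.T + translation)

    def relabelled(self, chain_id: str) -> "BeadStructure":
        return BeadStructure(
            np.full(self.n_beads, chain_id, dtype=object),
            self.residue_indices,
            self.bead_names,
            self.positions,
            self.mapping_mode,
            self.residue_names,
        )

    @staticmethod
    def merge(*parts: "BeadStructure") -> "BeadStructure":
        return BeadStructure(
            np.concatenate([p.chain_ids for p in parts]),
            np.concatenate([p.residue_indices for p in parts]),
            np.concatenate([p.bead_names for p in parts]),
            np.concatenate([p.positions for p in parts]),
            parts[0].mapping_mode,
            np.concatenate([p.residue_names for p in parts]),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, BeadStructure):
            return NotImplemented
        return (
            list(self.chain_ids) == list(other.chain_ids)
            and list(self.residue_indices) == list(other.residue_indices)
            and list(self.bead_names) == list(other.bead_names)
            and np.array_equal(self.positions, other.positions)
        )


def _bead_sort_order(chain_ids, residue_indices, bead_names) -> np.ndarray:
    bead_rank = np.array([0 if b == "BB" else int(str(b)[2:]) for b in bead_names])
    return np.lexsort((bead_rank, residue_indices, chain_ids.astype(str)))


@dataclass
class Frame:
    """One stored time point of a two-helix system."""

    structure: BeadStructure
    time: float = 0.0  # ns
    box: np.ndarray | None = None  # orthorhombic box lengths, nm

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("frame time must be >= 0")
        if len(self.structure.chains) != 2:
            raise ValueError(
                f"a Frame needs exactly two chains, got {self.structure.chains}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)


@dataclass
class Trajectory:
    """Time-ordered frames at uniform spacing ``dt`` (ns)."""

    frames: list[Frame]
    dt: float

    def __post_init__(self):
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(steps, self.dt, rtol=1e-6, atol=1e-9):
                raise ValueError("frame spacing must equal dt")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def duration(self) -> float:
        """Total covered time: n_frames * dt (each frame represents one dt slot)."""
        return len(self.frames) * self.dt


# -- operations ------------------------------------------------------------


def read_pdb_models(path: str | Path, model_index: int = 1):
    """Read one model from a (multi-model) PDB file.

    Returns a :class:`biotite.structure.AtomArray` whose coordinates
    have been converted from angstrom to nanometres.  Residue and atom
    names, chain ids and the author residue numbering are preserved.

    Parameters
    ----------
    path : path-like
    model_index : int
        1-based model number (NMR ensembles store several models).

    Raises
    ------
    ValueError
        If the model index is out of range or the file is malformed.
    """
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
    except Exception as exc:  # malformed records
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    n_models = pdb_file.get_model_count()
    if not 1 <= model_index <= n_models:
        raise ValueError(
            f"model {model_index} out of range: {path} holds {n_models} model(s)"
        )
    atoms = pdb_file.get_structure(model=model_index)
    atoms = atoms.copy()
    atoms.coord = atoms.coord * NM_PER_ANGSTROM
    return atoms


def write_pdb(path: str | Path, atoms) -> None:
    """Write an atom array (coordinates in nm) back to PDB (angstrom)."""
    import biotite.structure.io.pdb as pdb

    out = atoms.copy()
    out.coord = out.coord / NM_PER_ANGSTROM
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(out)
    pdb_file.write(str(path))


def coarse_grain(atoms, mapping_mode: str = "COM", side_chains: bool = True) -> BeadStructure:
    """Map an atomistic structure to a MARTINI-style bead structure.

    Parameters
    ----------
    atoms : biotite.structure.AtomArray
        Atomistic coordinates in nm (as returned by :func:`read_pdb_models`).
    mapping_mode : {"COM", "CA"}
        ``COM`` places the backbone bead at the centre of mass of the
        backbone atoms N, CA, C, O (hydrogens ignored); ``CA`` places it
        at the C-alpha position.
    side_chains : bool
        Whether to build side-chain beads (one bead per MARTINI atom
        group, at the group's heavy-atom centre of mass).

    Raises
    ------
    ValueError
        If a residue lacks backbone atoms.
    """
    import biotite.structure as struc

    if mapping_mode not in ("COM", "CA"):
        raise ValueError(f"unknown mapping_mode {mapping_mode!r}")

    chain_ids, residue_indices, bead_names, residue_names = [], [], [], []
    positions = []
    for residue in struc.residue_iter(atoms):
        res_id = int(residue.res_id[0])
        res_name = str(residue.res_name[0])
        chain = str(residue.chain_id[0])
        names = residue.atom_name

        if mapping_mode == "CA":
            ca = residue.coord[names == "CA"]
            if len(ca) == 0:
                raise ValueError(f"residue {chain}:{res_id} {res_name} has no CA atom")
            bb = ca[0]
        else:
            mask = np.isin(names, BACKBONE_ATOMS)
            if mask.sum() < len(BACKBONE_ATOMS):
                missing = set(BACKBONE_ATOMS) - set(names[mask])
                raise ValueError(
                    f"residue {chain}:{res_id} {res_name} misses backbone atoms {missing}"
                )
            bb = _center_of_mass(residue.coord[mask], residue.element[mask])
        chain_ids.append(chain)
        residue_indices.append(res_id)
        bead_names.append("BB")
        residue_names.append(res_name)
        positions.append(bb)

        if side_chains:
            groups = MARTINI_SIDE_CHAINS.get(res_name, [])
            for k, group in enumerate(groups, start=1):
                mask = np.isin(names, group)
                if not mask.any():
                    continue  # atoms absent (e.g. truncated side chain)
                chain_ids.append(chain)
                residue_indices.append(res_id)
                bead_names.append(f"SC{k}")
                residue_names.append(res_name)
                positions.append(_center_of_mass(residue.coord[mask], residue.element[mask]))

    return BeadStructure(
        chain_ids,
        residue_indices,
        bead_names,
        np.array(positions),
        mapping_mode,
        residue_names,
    )


def _center_of_mass(coords: np.ndarray, elements: np.ndarray) -> np.ndarray:
    masses = np.array([ATOMIC_MASSES.get(str(e).capitalize(), 12.011) for e in elements])
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def truncate_to_segment(
    structure: BeadStructure, first_residue: int, last_residue: int
) -> BeadStructure:
    """Keep only residues ``first_residue`` .. ``last_residue`` (inclusive).

    The author residue numbering is preserved, so truncating the 40mer
    NMR construct to 72-96 yields a 25-residue helix still numbered
    72-96.  Raises ``ValueError`` if the segment is not fully contained
    in every chain.
    """
    if first_residue > last_residue:
        raise ValueError("first_residue must be <= last_residue")
    for chain in structure.chains:
        residues = structure.residues(chain)
        if first_residue < residues.min() or last_residue > residues.max():
            raise ValueError(
                f"segment {first_residue}-{last_residue} outside chain {chain} "
                f"({residues.min()}-{residues.max()})"
            )
    mask = (structure.residue_indices >= first_residue) & (
        structure.residue_indices <= last_residue
    )
    return structure._subset(mask)


def build_ideal_cg_helix(
    n_residues: int,
    rise_per_residue: float = 0.15,
    twist_per_residue: float = 100.0,
    bead_radius: float = 0.23,
    chain_id: str = "A",
    first_residue: int = 1,
) -> BeadStructure:
    """Construct an ideal CG alpha-helix of BB beads around the z axis.

    Defaults (0.15 nm rise, 100 deg twist, 0.23 nm radius) are the
    canonical alpha-helix values on the CG backbone.  Bead *i* sits at
    ``(r cos(i*twist), r sin(i*twist), i*rise)``; the helix axis is the
    z axis and the N-terminus is at the origin.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if rise_per_residue <= 0 or twist_per_residue <= 0 or bead_radius < 0:
        raise ValueError("geometric parameters must be positive (radius may be 0)")
    i = np.arange(n_residues)
    theta = np.deg2rad(twist_per_residue) * i
    positions = np.column_stack(
        [bead_radius * np.cos(theta), bead_radius * np.sin(theta), rise_per_residue * i]
    )
    return BeadStructure(
        np.full(n_residues, chain_id, dtype=object),
        i + first_residue,
        np.full(n_residues, "BB", dtype=object),
        positions,
        mapping_mode="CA",
    )
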