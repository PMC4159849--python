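"""File I/O: GRO frames (via MDAnalysis), label sidecars, YAML configs.

Trajectories are exchanged as directories of numbered GRO frames plus a
``labels.csv`` sidecar (frame, time_ns, label).  GRO has no chain
field, so on write the residues of chain B are offset by
``CHAIN_B_RESID_OFFSET``; the reader inverts the convention.  This is a
package convention for synthetic data, not a general GRO round-trip.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .structures import BeadStructure, Frame, Trajectory

CHAIN_B_RESID_OFFSET = 1000
ANGSTROM_PER_NM = 10.0


def write_gro(path: str | Path, frame: Frame) -> None:
    """Write one frame as a GRO file (nm on disk)."""
    import MDAnalysis as mda

    s = frame.structure
    chains = s.chains
    resid_offset = {chains[0]: 0}
    if len(chains) > 1:
        resid_offset[chains[1]] = CHAIN_B_RESID_OFFSET

    residue_keys = []
    atom_resindex = []
    for c, r in zip(s.chain_ids, s.residue_indices):
        key = (c, int(r))
        if key not in residue_keys:
            residue_keys.append(key)
        atom_resindex.append(residue_keys.index(key))

    u = mda.Universe.empty(
        n_atoms=s.n_beads,
        n_residues=len(residue_keys),
        atom_resindex=np.array(atom_resindex),
        residue_segindex=np.zeros(len(residue_keys), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(b) for b in s.bead_names])
    u.add_TopologyAttr("resids", [r + resid_offset[c] for c, r in residue_keys])
    resnames = []
    for key in residue_keys:
        mask = (s.chain_ids == key[0]) & (s.residue_indices == key[1])
        resnames.append(str(s.residue_names[mask][0]))
    u.add_TopologyAttr("resnames", resnames)
    u.atoms.positions = s.positions * ANGSTROM_PER_NM
    if frame.box is not None:
        u.dimensions = [*(np.asarray(frame.box) * ANGSTROM_PER_NM), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis warns about missing box/velocities
        u.atoms.write(str(path))


def read_gro(path: str | Path, time: float = 0.0, mapping_mode: str = "CA") -> Frame:
    """Read one GRO frame written by :func:`write_gro`."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    resids = u.atoms.resids
    chain_ids = np.where(resids >= CHAIN_B_RESID_OFFSET, "B", "A").astype(object)
    residue_indices = np.where(
        resids >= CHAIN_B_RESID_OFFSET, resids - CHAIN_B_RESID_OFFSET, resids
    )
    structure = BeadStructure(
        chain_ids,
        residue_indices,
        [str(n) for n in u.atoms.names],
        u.atoms.positions / ANGSTROM_PER_NM,
        mapping_mode=mapping_mode,
        residue_names=[str(r) for r in u.atoms.resnames],
    )
    box = None
    if u.dimensions is not None and np.any(u.dimensions[:3] > 0):
        box = u.dimensions[:3] / ANGSTROM_PER_NM
    return Frame(structure, time=time, box=box)


def write_trajectory(
    directory: str | Path,
    trajectory: Trajectory,
    labels=None,
    prefix: str = "frame",
) -> Path:
    """Write a trajectory as numbered GRO frames plus a labels sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(trajectory):
        write_gro(directory / f"{prefix}_{k:05d}.gro", frame)
    sidecar = {"frame": np.arange(len(trajectory)), "time_ns": trajectory.times}
    if labels is not None:
        sidecar["label"] = list(labels)
    pd.DataFrame(sidecar).to_csv(directory / "labels.csv", index=False)
    return directory


def read_trajectory(directory: str | Path, prefix: str = "frame") -> tuple[Trajectory, np.ndarray | None]:
    """Read back a trajectory directory written by :func:`write_trajectory`."""
    directory = Path(directory)
    sidecar = pd.read_csv(directory / "labels.csv")
    frames = []
    for k, t in zip(sidecar["frame"], sidecar["time_ns"]):
        frames.append(read_gro(directory / f"{prefix}_{int(k):05d}.gro", time=float(t)))
    times = sidecar["time_ns"].to_numpy()
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    labels = sidecar["label"].to_numpy() if "label" in sidecar.columns else None
    return Trajectory(frames, dt), labels


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path} must hold a YAML mapping")
    return data


def save_contact_map_csv(path: str | Path, matrix: np.ndarray, residues_a, residues_b) -> None:
    df = pd.DataFrame(np.asarray(matrix, dtype=float), index=residues_a, columns=residues_b)
    df.index.name = "resA\\resB"
    df.to_csv(path)


def save_contact_map_png(
    path: str | Path, matrix: np.ndarray, residues_a, residues_b, title: str = ""
) -> None:
    """Grey-scale contact(-frequency) map: black = contact in every member."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(
        1.0 - np.asarray(matrix, dtype=float),
        cmap="gray",
        vmin=0.0,
        vmax=1.0,
        origin="lower",
        extent=(
            residues_b[0] - 0.5,
            residues_b[-1] + 0.5,
            residues_a[0] - 0.5,
            residues_a[-1] + 0.5,
        ),
    )
    ax.set_xlabel("residue, helix B")
    ax.set_ylabel("residue, helix A")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
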