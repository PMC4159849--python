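"""Access to the experimental NMR reference structure of the dimer.

The glycophorin A transmembrane dimer was solved by solution NMR in
micelles (PDB entry 1AFO, a 40-residue construct per chain; the
transmembrane helix proper spans residues 72-96).  Its contact map is
the reference interface against which simulated interfaces are scored,
and its signed crossing angle (about -40 degrees, right-handed) anchors
the sign convention of the geometry module.

The PDB file itself is experimental data and is not shipped with the
package; :func:`load_nmr_reference` looks for a local copy and
otherwise tries to download it from RCSB.  In fully offline
environments the function raises :class:`ReferenceUnavailable`.
"""

from __future__ import annotations

from pathlib import Path

from .contacts import compute_contact_map, count_contacts
from .geometry import dimer_geometry
from .structures import coarse_grain, read_pdb_models, truncate_to_segment

PDB_ID = "1AFO"
RCSB_URL = f"https://files.rcsb.org/download/{PDB_ID}.pdb"
TM_SEGMENT = (72, 96)  # Glu72 to Arg96, the 25-residue transmembrane helix

_SEARCH_PATHS = (
    Path("data") / "1afo.pdb",
    Path.home() / ".cache" / "tmdimer" / "1afo.pdb",
)


class ReferenceUnavailable(RuntimeError):
    """The 1AFO structure is neither cached locally nor downloadable."""


def fetch_1afo(path: str | Path | None = None, timeout: float = 30.0) -> Path:
    """Return a local path to 1AFO, downloading it from RCSB if needed."""
    candidates = [Path(path)] if path is not None else list(_SEARCH_PATHS)
    for candidate in candidates:
        if candidate.is_file():
            return candidate
    target = candidates[-1]
    target.parent.mkdir(parents=True, exist_ok=True)
    try:
        import urllib.request

        with urllib.request.urlopen(RCSB_URL, timeout=timeout) as response:
            target.write_bytes(response.read())
        return target
    except Exception as exc:
        raise ReferenceUnavailable(
            f"PDB {PDB_ID} not found at {[str(c) for c in candidates]} and the "
            f"download from {RCSB_URL} failed ({exc}); place the file at one of "
            "those paths to enable the NMR-reference computations"
        ) from exc


def load_nmr_reference(
    path: str | Path | None = None,
    model_index: int = 1,
    mapping_mode: str = "COM",
    truncate: bool = True,
):
    """Coarse-grained NMR dimer structure (model 1 by default).

    Returns the CG :class:`~tmdimer.structures.BeadStructure`, truncated
    to the transmembrane segment 72-96 unless ``truncate=False``.
    """
    atoms = read_pdb_models(fetch_1afo(path), model_index)
    structure = coarse_grain(atoms, mapping_mode=mapping_mode)
    if truncate:
        structure = truncate_to_segment(structure, *TM_SEGMENT)
    return structure


def nmr_reference_contact_map(
    path: str | Path | None = None,
    model_index: int = 1,
    mapping_mode: str = "COM",
    distance_mode: str = "min_bead",
    cutoff: float = 0.6,
):
    """Contact map of the NMR transmembrane dimer (the reference interface)."""
    from .structures import Frame

    structure = load_nmr_reference(path, model_index, mapping_mode)
    return compute_contact_map(
        Frame(structure), segment=TM_SEGMENT, cutoff=cutoff, distance_mode=distance_mode
    )


def nmr_reference_summary(path: str | Path | None = None, model_index: int = 1) -> dict:
    """Reference contact count and signed crossing angle of the NMR dimer."""
    from .structures import Frame

    structure = load_nmr_reference(path, model_index)
    cmap = nmr_reference_contact_map(path, model_index)
    geo = dimer_geometry(Frame(structure))
    return {
        "n_contacts": count_contacts(cmap),
        "crossing_angle_deg": geo.crossing_angle,
    }
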