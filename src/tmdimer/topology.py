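"""Elastic-network augmentation of CG protein topologies (GROMACS ITP).

Standard MARTINI helices maintain their secondary structure through
dihedral potentials, which lets the helix stretch beyond the length
seen in experimental structures of dimerising transmembrane helices.
A light-weight remedy is to append harmonic bonds between backbone
beads i and i+3 / i+4 / i+5 with equilibrium lengths taken from known
structures (0.49, 0.61 and 0.82 nm respectively) and to screen the
force constants over {None, 500, 1000, 5000, 10000} kJ mol^-1 nm^-2.

The augmentation is append-only and line-preserving: the output ITP is
the input plus the new bond lines (tagged with a comment), so the
change is reversible and diffable.  The screening driver consumes
helix-length distributions (from external simulation output or a
synthetic surrogate) and never runs MD itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .geometry import LengthDistribution, distribution_difference

#: equilibrium lengths (nm) for BB i -> i+offset elastic bonds,
#: averages over known dimerising transmembrane-helix structures
DEFAULT_EQUILIBRIUM_LENGTHS = {3: 0.49, 4: 0.61, 5: 0.82}

#: force constants screened for each offset (None = bond omitted)
FORCE_CONSTANT_GRID = (None, 500.0, 1000.0, 5000.0, 10000.0)

ELASTIC_TAG = "; tmdimer elastic bond"


@dataclass(frozen=True)
class ElasticBondSpec:
    """One family of elastic bonds: BB i -> i+offset."""

    offset: int
    equilibrium_length: float | None = None
    force_constant: float | None = None

    def __post_init__(self):
        if self.offset not in (3, 4, 5):
            raise ValueError("offset must be 3, 4 or 5")
        if self.force_constant is not None:
            length = self.resolved_length
            if length is None or length <= 0:
                raise ValueError("equilibrium_length must be > 0 when a force constant is set")

    @property
    def resolved_length(self) -> float | None:
        if self.equilibrium_length is not None:
            return self.equilibrium_length
        return DEFAULT_EQUILIBRIUM_LENGTHS.get(self.offset)


def elastic_specs(fc3=None, fc4=None, fc5=None) -> list[ElasticBondSpec]:
    """Convenience constructor for the three bond families."""
    return [
        ElasticBondSpec(3, force_constant=fc3),
        ElasticBondSpec(4, force_constant=fc4),
        ElasticBondSpec(5, force_constant=fc5),
    ]


class ItpTopology:
    """A GROMACS ITP file kept as raw lines with parsed atom records."""

    def __init__(self, lines: list[str]):
        self.lines = list(lines)

    @classmethod
    def from_text(cls, text: str) -> "ItpTopology":
        return cls(text.splitlines())

    @classmethod
    def read(cls, path: str | Path) -> "ItpTopology":
        return cls(Path(path).read_text().splitlines())

    @property
    def text(self) -> str:
        return "\n".join(self.lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.text)

    # -- parsing -----------------------------------------------------------

    def _section_spans(self) -> list[tuple[str, int, int]]:
        """(name, first_content_line, end_line) for each section."""
        spans = []
        current = None
        start = None
        for i, line in enumerate(self.lines):
            m = re.match(r"\s*\[\s*(\w+)\s*\]", line)
            if m:
                if current is not None:
                    spans.append((current, start, i))
                current = m.group(1).lower()
                start = i + 1
        if current is not None:
            spans.append((current, start, len(self.lines)))
        return spans

    def _section_lines(self, name: str) -> list[tuple[int, str]]:
        out = []
        for sec, start, end in self._section_spans():
            if sec == name:
                for i in range(start, end):
                    content = self.lines[i].split(";", 1)[0].strip()
                    if content:
                        out.append((i, content))
        return out

    def atoms(self) -> pd.DataFrame:
        """Parsed [atoms] records (nr, type, resnr, residue, atom, cgnr)."""
        rows = []
        for _, content in self._section_lines("atoms"):
            fields = content.split()
            if len(fields) < 6:
                raise ValueError(f"malformed atom record: {content!r}")
            rows.append(
                {
                    "nr": int(fields[0]),
                    "type": fields[1],
                    "resnr": int(fields[2]),
                    "residue": fields[3],
                    "atom": fields[4],
                    "cgnr": int(fields[5]),
                }
            )
        if not rows:
            raise ValueError("topology has no [atoms] section or it is empty")
        return pd.DataFrame(rows)

    def backbone_indices(self) -> list[int]:
        """Atom numbers of BB beads in residue order."""
        atoms = self.atoms()
        bb = atoms[atoms["atom"] == "BB"].sort_values("resnr")
        if bb.empty:
            raise ValueError("topology has no BB beads")
        return [int(x) for x in bb["nr"]]

    def bond_pairs(self) -> set[tuple[int, int]]:
        pairs = set()
        for _, content in self._section_lines("bonds"):
            fields = content.split()
            if len(fields) >= 2:
                i, j = int(fields[0]), int(fields[1])
                pairs.add((min(i, j), max(i, j)))
        return pairs


def augment_topology(
    topology: ItpTopology | str | Path, specs: list[ElasticBondSpec]
) -> ItpTopology:
    """Append elastic BB bonds to a topology.

    For every spec carrying a force constant, one harmonic bond
    (function type 1) is added per valid (i, i+offset) backbone pair.
    The original lines are untouched; new lines are appended at the end
    of the [bonds] section (the section is created if absent).  A bond
    that already exists in the input raises ``ValueError`` (duplicate
    bond collision).
    """
    if isinstance(topology, (str, Path)):
        topology = ItpTopology.read(topology)
    active = [s for s in specs if s.force_constant is not None]
    if not active:
        return ItpTopology(topology.lines)

    bb = topology.backbone_indices()
    existing = topology.bond_pairs()
    new_lines = []
    collisions = []
    for spec in active:
        length = spec.resolved_length
        for i in range(len(bb) - spec.offset):
            ai, aj = bb[i], bb[i + spec.offset]
            key = (min(ai, aj), max(ai, aj))
            if key in existing:
                collisions.append((ai, aj, spec.offset))
                continue
            existing.add(key)
            new_lines.append(
                f"{ai:5d} {aj:5d}    1  {length:.4f}  {spec.force_constant:g} "
                f"{ELASTIC_TAG} i,i+{spec.offset}"
            )
    if collisions:
        raise ValueError(f"duplicate bond collision for pairs {collisions}")

    lines = list(topology.lines)
    bonds_end = None
    for sec, start, end in topology._section_spans():
        if sec == "bonds":
            bonds_end = end
    if bonds_end is None:
        if lines and lines[-1].strip():
            lines.append("")
        lines.append("[ bonds ]")
        lines.extend(new_lines)
    else:
        # insert before trailing blank lines of the section
        insert_at = bonds_end
        while insert_at > 0 and not lines[insert_at - 1].strip():
            insert_at -= 1
        lines[insert_at:insert_at] = new_lines
    return ItpTopology(lines)


def count_elastic_bonds(topology: ItpTopology) -> int:
    return sum(1 for line in topology.lines if ELASTIC_TAG in line)


def strip_elastic_bonds(topology: ItpTopology) -> ItpTopology:
    """Reverse :func:`augment_topology` by removing tagged bond lines."""
    return ItpTopology([l for l in topology.lines if ELASTIC_TAG not in l])


def minimal_helix_itp(n_residues: int, molecule_name: str = "HELIX") -> ItpTopology:
    """A minimal single-chain helix ITP (BB beads and i,i+1 bonds only).

    Useful as a test scaffold and as a template for augmentation; not a
    full MARTINI parameterisation.
    """
    lines = [
        "; minimal CG helix topology",
        "[ moleculetype ]",
        f"{molecule_name}  1",
        "",
        "[ atoms ]",
    ]
    for i in range(1, n_residues + 1):
        lines.append(f"{i:5d}  P5  {i:4d}  ALA  BB  {i:5d}  0.0")
    lines.append("")
    lines.append("[ bonds ]")
    for i in range(1, n_residues):
        lines.append(f"{i:5d} {i + 1:5d}    1  0.3100  1250")
    return ItpTopology(lines)


# -- force-constant screen -------------------------------------------------


@dataclass
class ScreenResult:
    """Distribution-difference scores over a force-constant grid."""

    table: pd.DataFrame  # columns fc3, fc4, fc5, score, error
    best: dict | None  # grid point with the smallest score

    @property
    def complete(self) -> bool:
        return bool(self.table["error"].isna().all())


def screen_bond_parameters(
    distribution_provider,
    grid,
    reference: LengthDistribution,
    scale: float = 1.0,
) -> ScreenResult:
    """Score every grid point against a reference length distribution.

    ``distribution_provider(fc3, fc4, fc5)`` must return the
    :class:`LengthDistribution` simulated (or surrogated) with those
    elastic force constants.  Provider failures are recorded per grid
    point and the screen continues.  ``grid`` is an iterable of
    ``(fc3, fc4, fc5)`` tuples (``None`` = bond omitted); the full
    5 x 5 x 5 default grid is ``default_screen_grid()``.
    """
    rows = []
    for fc3, fc4, fc5 in grid:
        row = {"fc3": fc3, "fc4": fc4, "fc5": fc5, "score": None, "error": None}
        try:
            dist = distribution_provider(fc3, fc4, fc5)
            row["score"] = distribution_difference(dist, reference, scale=scale)
        except Exception as exc:  # record and continue
            row["error"] = str(exc)
        rows.append(row)
    # object dtype keeps the None ("bond omitted") grid entries as None
    table = pd.DataFrame(rows, dtype=object)
    table["score"] = pd.to_numeric(table["score"])
    valid = table[table["score"].notna()]
    best = None
    if not valid.empty:
        best = valid.loc[valid["score"].idxmin()].to_dict()
    return ScreenResult(table, best)


def default_screen_grid():
    return [
        (fc3, fc4, fc5)
        for fc3 in FORCE_CONSTANT_GRID
        for fc4 in FORCE_CONSTANT_GRID
        for fc5 in FORCE_CONSTANT_GRID
    ]
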