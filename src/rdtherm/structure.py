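"""PDB-format structure I/O and typed atom selection.

Reads and writes fixed-column PDB files (ATOM/HETATM/CRYST1/TER/END),
carrying unit-cell metadata and an externally supplied temperature label.
Only the first alternate location ('A' or blank) of each atom is kept,
matching single-conformer crystallographic models.  Coordinates are in Å,
B-factors in Å², residue numbering is 1-based PDB convention.
"""

from __future__ import annotations

import fnmatch
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

WATER_RESNAMES = frozenset({"HOH"})

#: Selector wildcard: matches any chain / resseq / atom name.
ANY = "*"


class PDBParseError(ValueError):
    """Raised when a fixed-width PDB field cannot be parsed; names the line."""


class PDBFormatError(ValueError):
    """Raised when a model cannot be represented in fixed-column PDB format."""


@dataclass(frozen=True)
class Atom:
    """One heavy (or hydrogen) atom of a crystallographic model."""

    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    record: str = "ATOM"

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.bfactor < 0:
            raise ValueError(f"negative B-factor for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy outside [0,1] for atom {self.name}")
        if self.record not in ("ATOM", "HETATM"):
            raise ValueError(f"record must be ATOM or HETATM, got {self.record}")

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def is_hydrogen(self) -> bool:
        el = self.element.strip() or self.name.lstrip("0123456789")[:1]
        return el.upper() in ("H", "D")

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.name)


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit-cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"unit-cell angle {ang} outside (0, 180)")
        ca, cb, cg = (math.cos(math.radians(v))
                      for v in (self.alpha, self.beta, self.gamma))
        if 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg <= 0:
            raise ValueError("unit-cell angles give a non-positive volume")


@dataclass
class StructureModel:
    """One crystal structure: atoms, optional unit cell, and its temperature."""

    atoms: tuple[Atom, ...]
    cell: UnitCell | None = None
    temperature: float = 293.0
    label: str = ""

    def __post_init__(self) -> None:
        self.atoms = tuple(self.atoms)
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        seen: set[tuple[str, int, str]] = set()
        for atom in self.atoms:
            k = atom.key()
            if k in seen:
                raise ValueError(f"duplicate atom key {k} in model {self.label!r}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)


def _parse_float(line: str, lineno: int, lo: int, hi: int, fieldname: str,
                 default: float | None = None) -> float:
    raw = line[lo:hi].strip()
    if not raw:
        if default is not None:
            return default
        raise PDBParseError(f"line {lineno}: empty {fieldname} field")
    try:
        return float(raw)
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: malformed {fieldname} field {raw!r}") from exc


def _parse_int(line: str, lineno: int, lo: int, hi: int, fieldname: str) -> int:
    raw = line[lo:hi].strip()
    try:
        return int(raw)
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: malformed {fieldname} field {raw!r}") from exc


def parse_pdb(text: str, temperature: float, label: str = "") -> StructureModel:
    """Parse a fixed-column PDB string into a :class:`StructureModel`.

    Temperature is supplied by the caller (REMARK dialects vary too much to
    read it from the file).  Alternate locations other than blank or 'A' are
    dropped.  A missing CRYST1 record yields ``cell=None``.
    """
    atoms: list[Atom] = []
    cell: UnitCell | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            cell = UnitCell(
                a=_parse_float(line, lineno, 6, 15, "a"),
                b=_parse_float(line, lineno, 15, 24, "b"),
                c=_parse_float(line, lineno, 24, 33, "c"),
                alpha=_parse_float(line, lineno, 33, 40, "alpha"),
                beta=_parse_float(line, lineno, 40, 47, "beta"),
                gamma=_parse_float(line, lineno, 47, 54, "gamma"),
            )
        elif rec in ("ATOM", "HETATM"):
            altloc = line[16:17]
            if altloc not in (" ", "", "A"):
                continue
            atoms.append(Atom(
                serial=_parse_int(line, lineno, 6, 11, "serial"),
                name=line[12:16].strip(),
                resname=line[17:20].strip(),
                chain=line[21:22].strip() or " ",
                resseq=_parse_int(line, lineno, 22, 26, "resseq"),
                x=_parse_float(line, lineno, 30, 38, "x"),
                y=_parse_float(line, lineno, 38, 46, "y"),
                z=_parse_float(line, lineno, 46, 54, "z"),
                occupancy=_parse_float(line, lineno, 54, 60, "occupancy",
                                       default=1.0),
                bfactor=_parse_float(line, lineno, 60, 66, "bfactor",
                                     default=0.0),
                element=line[76:78].strip(),
                record=rec,
            ))
    if not atoms:
        raise PDBParseError("no ATOM or HETATM records found")
    return StructureModel(atoms=tuple(atoms), cell=cell,
                          temperature=temperature, label=label)


def _format_atom_name(atom: Atom) -> str:
    name = atom.name
    if len(name) > 4:
        raise PDBFormatError(f"atom name {name!r} longer than 4 characters")
    # Standard alignment: 1-2 letter elements start in column 14 unless the
    # name already fills 4 characters.
    if len(name) < 4 and len(atom.element.strip()) < 2:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: StructureModel) -> str:
    """Serialize a model to a fixed-column PDB string (CRYST1 + atoms + END).

    Round-trip contract: re-parsing preserves atom count, names, coordinates
    to 3 decimals and B-factors to 2 decimals.
    """
    lines: list[str] = []
    if model.cell is not None:
        c = model.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} P 1           1")
    last_polymer_idx = max(
        (i for i, a in enumerate(model.atoms) if a.record == "ATOM"),
        default=None)
    for i, atom in enumerate(model.atoms):
        lines.append(
            f"{atom.record:<6s}{atom.serial:5d} {_format_atom_name(atom)}"
            f" {atom.resname:>3s} {atom.chain:1s}{atom.resseq:4d}    "
            f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
            f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
            f"          {atom.element:>2s}")
        if i == last_polymer_idx:
            lines.append(f"TER   {atom.serial + 1:5d}      {atom.resname:>3s} "
                         f"{atom.chain:1s}{atom.resseq:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


Selector = tuple  # (chain, resseq, name) with '*' wildcards


def _match_field(pattern, value) -> bool:
    if pattern == ANY or pattern is None:
        return True
    if isinstance(pattern, int) or (isinstance(pattern, str)
                                    and pattern.lstrip("-").isdigit()):
        return int(pattern) == value
    return fnmatch.fnmatchcase(str(value), str(pattern))


def select_atoms(model: StructureModel, chain=ANY, resseq=ANY,
                 name=ANY) -> list[Atom]:
    """Return atoms matching (chain, resseq, name) patterns, in file order.

    Patterns support fnmatch wildcards, e.g. ``name="OD*"`` for the two
    aspartate carboxylate oxygens.  An empty selection is valid.  A 3-tuple
    may be passed as the single ``chain`` argument.
    """
    if isinstance(chain, (tuple, list)) and resseq == ANY and name == ANY:
        chain, resseq, name = chain
    return [a for a in model.atoms
            if _match_field(chain, a.chain)
            and _match_field(resseq, a.resseq)
            and _match_field(name, a.name)]


def water_count(model: StructureModel) -> int:
    """Number of crystallographically defined waters: distinct HOH residues."""
    return len({(a.chain, a.resseq) for a in model.atoms
                if a.is_water and a.record == "HETATM"})
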