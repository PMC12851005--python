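"""Per-structure geometric and disorder metrics.

Kabsch superposition, metal-site coordination statistics, triclinic
unit-cell volume, grid-based van der Waals protein volume, and per-residue
Cα B-factor profiles with z-score normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .structure import ANY, StructureModel, UnitCell, select_atoms

logger = logging.getLogger(__name__)

#: van der Waals radii (Å) used by the grid volume; default covers other elements.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "ZN": 1.39, "FE": 1.47}
DEFAULT_VDW_RADIUS = 1.70


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit of a mobile onto a reference atom set."""

    rmsd: float
    rotation: np.ndarray  # 3x3, proper orthonormal
    translation: np.ndarray  # applied after rotation
    n_atoms: int


@dataclass(frozen=True)
class BFactorProfile:
    """Per-residue Cα B-factors (Å²) of one structure at one temperature."""

    values: dict  # resseq -> bfactor
    temperature: float
    normalized: bool = False


def _resolve_selection(model: StructureModel, selection) -> list:
    if isinstance(selection, (tuple, list)) and len(selection) == 3:
        return select_atoms(model, *selection)
    raise ValueError("selection must be a (chain, resseq, name) pattern tuple")


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set `mobile` onto `reference`.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits `reference`.  The SVD
    determinant correction guarantees a proper rotation (no reflection).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return R, t, rmsd


def superpose_kabsch(mobile: StructureModel, reference: StructureModel,
                     selection=(ANY, ANY, "CA")) -> SuperpositionResult:
    """Superpose `mobile` onto `reference` over a shared atom selection.

    The selection must resolve to the same ordered atom correspondence in
    both models (checked by count and by (chain, resseq, name) keys).
    """
    ma = _resolve_selection(mobile, selection)
    ra = _resolve_selection(reference, selection)
    if len(ma) != len(ra):
        raise ValueError(
            f"selection mismatch: {len(ma)} mobile vs {len(ra)} reference atoms")
    for a, b in zip(ma, ra):
        if a.key() != b.key():
            raise ValueError(f"atom correspondence broken at {a.key()} vs {b.key()}")
    R, t, rmsd = kabsch(np.array([a.coord for a in ma]),
                        np.array([a.coord for a in ra]))
    return SuperpositionResult(rmsd=rmsd, rotation=R, translation=t,
                               n_atoms=len(ma))


def coordination_stats(model: StructureModel, center, ligands
                       ) -> tuple[float, np.ndarray]:
    """Distances from a single central atom (e.g. Zn) to its ligand shell.

    Returns (mean distance, per-ligand distances) in Å.
    """
    catoms = _resolve_selection(model, center)
    latoms = _resolve_selection(model, ligands)
    if len(catoms) != 1:
        raise ValueError(f"center selector resolved to {len(catoms)} atoms, need 1")
    if not latoms:
        raise ValueError("ligand selector resolved to no atoms")
    c = catoms[0].coord
    d = np.array([np.linalg.norm(a.coord - c) for a in latoms])
    return float(d.mean()), d


def unit_cell_volume(cell: UnitCell) -> float:
    """Triclinic unit-cell volume V = abc·√(1 − Σcos² + 2·cosα·cosβ·cosγ)."""
    ca, cb, cg = (math.cos(math.radians(v))
                  for v in (cell.alpha, cell.beta, cell.gamma))
    radicand = 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
    if radicand <= 0:
        raise ValueError("unit-cell angles give a non-positive volume radicand")
    return cell.a * cell.b * cell.c * math.sqrt(radicand)


def protein_volume(model: StructureModel, spacing: float = 0.5) -> float:
    """Grid-based van der Waals volume (Å³) of non-water, non-H heavy atoms.

    Counts grid points (default 0.5 Å spacing) inside any atom sphere, using
    a fixed per-element radius table.  Absolute values carry ~grid-level
    error; relative changes across a temperature series are the meaningful
    output.
    """
    atoms = [a for a in model.atoms if not a.is_water and not a.is_hydrogen]
    if not atoms:
        raise ValueError("model has no non-water heavy atoms")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([VDW_RADII.get(a.element.strip().upper()
                                    or a.name.strip()[:1].upper(),
                                    DEFAULT_VDW_RADIUS) for a in atoms])
    rmax = radii.max()
    lo = coords.min(axis=0) - rmax - spacing
    hi = coords.max(axis=0) + rmax + spacing
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    occupied = np.zeros(n, dtype=bool)
    for c, r in zip(coords, radii):
        i0 = np.floor((c - r - lo) / spacing).astype(int)
        i1 = np.ceil((c + r - lo) / spacing).astype(int) + 1
        i0 = np.clip(i0, 0, n - 1)
        i1 = np.clip(i1, 0, n)
        gx = lo[0] + spacing * np.arange(i0[0], i1[0])
        gy = lo[1] + spacing * np.arange(i0[1], i1[1])
        gz = lo[2] + spacing * np.arange(i0[2], i1[2])
        dx2 = (gx - c[0]) ** 2
        dy2 = (gy - c[1]) ** 2
        dz2 = (gz - c[2]) ** 2
        inside = (dx2[:, None, None] + dy2[None, :, None]
                  + dz2[None, None, :]) <= r * r
        occupied[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= inside
    return float(occupied.sum()) * spacing ** 3


def bfactor_profile(model: StructureModel) -> BFactorProfile:
    """Per-residue Cα B-factor profile, in residue order.

    Residues without a Cα (waters, ions) are skipped; a protein residue
    lacking one triggers a logged warning.
    """
    values: dict[int, float] = {}
    protein_residues = {}
    for a in model.atoms:
        if a.record == "ATOM" and not a.is_water:
            protein_residues.setdefault((a.chain, a.resseq), a.resname)
        if a.name == "CA" and a.record == "ATOM":
            values[a.resseq] = a.bfactor
    if not values:
        raise ValueError("model has no Cα atoms")
    for (chain, resseq), resname in protein_residues.items():
        if resseq not in values:
            logger.warning("residue %s %s%d lacks a CA atom; skipped",
                           resname, chain, resseq)
    return BFactorProfile(values=dict(sorted(values.items())),
                          temperature=model.temperature)


def normalize_bfactors(profile: BFactorProfile) -> BFactorProfile:
    """Per-structure z-score: (B − mean)/sd over the profile's residues.

    Makes disorder profiles comparable across structures collected at
    different temperatures.  Output has mean 0 and (population) sd 1.
    """
    if len(profile.values) < 2:
        raise ValueError("normalization needs at least 2 residues")
    v = np.array(list(profile.values.values()), dtype=float)
    sd = v.std()  # population sd so the output sd is exactly 1
    if sd == 0:
        raise ValueError("zero B-factor spread; cannot normalize")
    z = (v - v.mean()) / sd
    return BFactorProfile(
        values=dict(zip(profile.values.keys(), z.tolist())),
        temperature=profile.temperature, normalized=True)


def bfactor_to_msd(bfactor: float) -> float:
    """Convert an isotropic B-factor (Å²) to mean-square displacement ⟨u²⟩.

    Uses B = 8π²⟨u²⟩/3.  Exposed as a documented conversion helper; headline
    outputs report B directly.
    """
    return 3.0 * bfactor / (8.0 * math.pi ** 2)


def msd_to_bfactor(msd: float) -> float:
    """Inverse of :func:`bfactor_to_msd`."""
    return 8.0 * math.pi ** 2 * msd / 3.0
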