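"""Hydrogen-bond network detection and partner-switch tabulation.

Direct H-bonds use a heavy-atom distance-only criterion (default 3.5 Å):
the crystallographic models carry no hydrogens, so donor/acceptor roles are
not resolved and polar heavy-atom proximity is the operational definition.
Water-mediated bridges (≤2 waters) are found by path search over the polar
contact graph.  The partner-switch table tracks, across a temperature
series, which acceptor a configured donor (by default the Asp-19
carboxylate) engages: e.g. Trp-37 Nε at low temperature versus Tyr-11 OH —
directly or through one or two bridging waters — at high temperature.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import ANY, Atom, StructureModel, select_atoms

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 3.5  # Å, heavy-atom donor-acceptor distance

# Polar heavy atoms able to donate or accept an H-bond, per residue type.
# Editable: pass a modified copy to detect_hbonds.  Proline backbone N has
# no amide hydrogen and is excluded.  Both carboxylate oxygens of Asp/Glu
# are listed — partner identity, not oxygen identity, defines a contact.
SIDECHAIN_POLAR: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1", "ND2"), "GLN": ("OE1", "NE2"),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "TRP": ("NE1",),
    "HOH": ("O",),
}
MAINCHAIN_POLAR = ("N", "O", "OXT")


def polar_atoms(model: StructureModel,
                table: dict[str, tuple[str, ...]] | None = None) -> list[Atom]:
    """All polar heavy atoms of a model according to the chemistry table."""
    table = SIDECHAIN_POLAR if table is None else table
    out = []
    for a in model.atoms:
        if a.is_hydrogen:
            continue
        if a.is_water:
            if a.name == "O":
                out.append(a)
            continue
        if a.record == "ATOM" and a.name in MAINCHAIN_POLAR:
            if a.name == "N" and a.resname == "PRO":
                continue
            out.append(a)
        elif a.name in table.get(a.resname, ()):
            out.append(a)
    return out


@dataclass(frozen=True)
class HBond:
    """A direct polar-polar contact within the distance cutoff.

    Without hydrogens the donor/acceptor orientation is conventional:
    atoms are stored in file order.
    """

    donor: Atom
    acceptor: Atom
    distance: float
    kind: str = "direct"

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("H-bond distance must be positive")
        if self.donor.key() == self.acceptor.key():
            raise ValueError("H-bond endpoints must differ")


@dataclass(frozen=True)
class BridgePath:
    """A donor→acceptor path through 0–2 bridging water oxygens."""

    endpoints: tuple[Atom, Atom]
    waters: tuple[Atom, ...]
    leg_distances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.leg_distances) != len(self.waters) + 1:
            raise ValueError("leg count must be waters + 1")

    @property
    def n_waters(self) -> int:
        return len(self.waters)

    @property
    def total_length(self) -> float:
        return float(sum(self.leg_distances))


def _same_residue(a: Atom, b: Atom) -> bool:
    return a.chain == b.chain and a.resseq == b.resseq


def _peptide_no_pair(a: Atom, b: Atom) -> bool:
    """Mainchain O(i)-N(i+1) of one peptide bond: covalently constrained."""
    if a.chain != b.chain:
        return False
    for o, n in ((a, b), (b, a)):
        if (o.name == "O" and n.name == "N"
                and o.record == "ATOM" and n.record == "ATOM"
                and n.resseq == o.resseq + 1):
            return True
    return False


def detect_hbonds(model: StructureModel, cutoff: float = DEFAULT_CUTOFF,
                  table: dict[str, tuple[str, ...]] | None = None
                  ) -> list[HBond]:
    """All polar-polar heavy-atom pairs within `cutoff`, sorted by distance.

    Intra-residue pairs and the covalently adjacent mainchain O(i)-N(i+1)
    of each peptide bond are excluded.  An empty list is a valid result.
    """
    atoms = polar_atoms(model, table)
    if len(atoms) < 2:
        return []
    coords = np.array([a.coord for a in atoms])
    tree = cKDTree(coords)
    bonds = []
    for i, j in tree.query_pairs(cutoff):
        a, b = atoms[i], atoms[j]
        if _same_residue(a, b) or _peptide_no_pair(a, b):
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        first, second = (a, b) if a.serial <= b.serial else (b, a)
        bonds.append(HBond(donor=first, acceptor=second, distance=d))
    bonds.sort(key=lambda h: h.distance)
    return bonds


def water_bridges(model: StructureModel, endpointA, endpointB,
                  max_waters: int = 2, cutoff: float = DEFAULT_CUTOFF
                  ) -> list[BridgePath]:
    """All simple paths endpointA→endpointB through ≤ `max_waters` waters.

    Nodes are the endpoint atoms plus all water oxygens; edges join nodes
    within `cutoff`.  Paths are returned shortest first (fewest waters,
    then total length).  A 0-water path is a direct contact.
    """
    if not 0 <= max_waters <= 2:
        raise ValueError("max_waters must be in 0..2")
    aset = select_atoms(model, endpointA) if isinstance(endpointA, (tuple, list)) \
        else list(endpointA)
    bset = select_atoms(model, endpointB) if isinstance(endpointB, (tuple, list)) \
        else list(endpointB)
    if not aset or not bset:
        raise ValueError("bridge endpoints resolved to no atoms")
    waters = [a for a in model.atoms if a.is_water and a.name == "O"
              and a.key() not in {x.key() for x in aset + bset}]
    nodes = {a.key(): a for a in itertools.chain(aset, waters, bset)}
    keys = list(nodes)
    coords = np.array([nodes[k].coord for k in keys])
    G = nx.Graph()
    G.add_nodes_from(keys)
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff):
        G.add_edge(keys[i], keys[j],
                   weight=float(np.linalg.norm(coords[i] - coords[j])))
    akeys = {a.key() for a in aset}
    bkeys = {b.key() for b in bset}
    wkeys = {w.key() for w in waters}
    paths: list[BridgePath] = []
    for ak in sorted(akeys & set(G.nodes)):
        for bk in sorted(bkeys & set(G.nodes)):
            if ak == bk:
                continue
            for path in nx.all_simple_paths(G, ak, bk, cutoff=max_waters + 1):
                interior = path[1:-1]
                if not all(k in wkeys for k in interior):
                    continue
                legs = tuple(G.edges[u, v]["weight"]
                             for u, v in zip(path, path[1:]))
                paths.append(BridgePath(
                    endpoints=(nodes[ak], nodes[bk]),
                    waters=tuple(nodes[k] for k in interior),
                    leg_distances=legs))
    paths.sort(key=lambda p: (p.n_waters, p.total_length))
    return paths


@dataclass
class PartnerTable:
    """Per-temperature classification of a donor's competing H-bond partners."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["temperature_K", "partner", "kind",
                                "min_distance_A", "n_waters", "ambiguous"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.3f")

    def assignment(self, temperature: float) -> dict[str, str]:
        """partner -> kind at one temperature."""
        return {r["partner"]: r["kind"] for r in self.rows
                if r["temperature_K"] == temperature}


def _min_pair_distance(aset: list[Atom], bset: list[Atom]) -> float:
    A = np.array([a.coord for a in aset])
    B = np.array([b.coord for b in bset])
    return float(np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2)
                         .sum(axis=2)).min())


def partner_switch_table(series: list[StructureModel], donor,
                         partners: dict[str, tuple],
                         cutoff: float = DEFAULT_CUTOFF,
                         max_waters: int = 2) -> PartnerTable:
    """Classify each partner at each temperature as direct / n-water / none.

    `partners` maps a display name (e.g. "W37") to its selector.  When more
    than one partner is directly bonded at the same temperature, all rows
    are flagged ambiguous rather than forcing a single winner.
    """
    temps = [m.temperature for m in series]
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate temperatures in structure series")
    table = PartnerTable()
    for model in sorted(series, key=lambda m: m.temperature):
        rows_here = []
        for pname, psel in partners.items():
            aset = select_atoms(model, donor)
            bset = select_atoms(model, psel)
            if not aset or not bset:
                raise ValueError(
                    f"selector for {pname} resolved to no atoms at "
                    f"{model.temperature} K")
            paths = water_bridges(model, donor, psel,
                                  max_waters=max_waters, cutoff=cutoff)
            if paths:
                best = paths[0]
                kind = ("direct" if best.n_waters == 0
                        else f"{best.n_waters}-water")
                n_w = best.n_waters
            else:
                kind, n_w = "none", None
            rows_here.append({
                "temperature_K": model.temperature,
                "partner": pname,
                "kind": kind,
                "min_distance_A": _min_pair_distance(aset, bset),
                "n_waters": n_w,
                "ambiguous": False,
            })
        n_direct = sum(r["kind"] == "direct" for r in rows_here)
        if n_direct > 1:
            logger.warning("multiple direct partners at %.1f K",
                           model.temperature)
            for r in rows_here:
                r["ambiguous"] = True
        table.rows.extend(rows_here)
    return table
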