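"""Synthetic test-data generators for the rubredoxin temperature analysis.

Two generators:

* :func:`generate_structure_series` emits a series of schematic 54-residue
  rubredoxin-like crystal structures with programmed temperature-dependent
  features — a tetrahedral Zn(S-Cys)₄ site, the Asp-19 carboxylate that
  H-bonds the Trp-37 indole nitrogen at low temperature and the Tyr-11
  hydroxyl at high temperature (via two then one bridging waters at
  intermediate temperatures), a conserved Glu-15 contact network, B-factors
  growing with temperature, a water count dropping sharply near 240 K, and
  unit-cell / protein volumes expanding linearly.

* :func:`simulate_three_state_markov` emits three-state (W ⇌ I ⇌ Y) Markov
  distance trajectories whose stationary W/Y ratio obeys a configured
  van't Hoff law, with state-conditional truncated-normal distance
  emissions — the generating process for the occupancy / dwell-time /
  van't Hoff estimators.

The structural geometry is *schematic*: local geometry is exact for every
measured feature (bond distances, bridge legs, coordination shell), but the
fold as a whole is a serpentine Cα trace with functional-site clusters
placed off the backbone.  It supports the analysis operations; it is not a
model of the real protein and must not be used as one.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .structure import Atom, StructureModel, UnitCell, write_pdb
from .trajectory import GAS_CONSTANT, DistanceTrace, StateSeries

logger = logging.getLogger(__name__)

# Pyrococcus furiosus rubredoxin sequence, Met1..Asp54 numbering.
PF_RD_SEQUENCE = "MAKWVCKICGYIYDEDAGDPDNGISPGTKFEELPDDWVCPICGAPKSEFEKLED"

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

DEFAULT_TEMPERATURES = (100.0, 140.0, 180.0, 220.0, 240.0, 260.0, 293.0,
                        323.0, 353.0, 363.0, 383.0, 393.0)

LOOP_A = range(16, 28)   # Asp-16 .. Gly-27
LOOP_B = range(30, 39)   # Phe-30 .. Val-38
TERMINI = (1, 2, 53, 54)
CYS_RESIDUES = (6, 9, 39, 42)


@dataclass(frozen=True)
class WaterCountModel:
    """Continuous two-slope decline of ordered waters with a kink at `t_transition`.

    Steep loss below the transition, shallow loss above — the shape of a
    sharp drop-off whose changepoint a two-segment fit can recover.  `width`
    (K) optionally rounds the kink by linear interpolation across
    [t−width, t+width].  `knee_fraction` sets the count at the kink as a
    fraction of the cold-hot span above the hot count.
    """

    n_cold: int = 60
    n_hot: int = 15
    t_transition: float = 240.0
    width: float = 0.0
    knee_fraction: float = 0.25
    t_ref_low: float = 100.0
    t_ref_high: float = 393.0

    def count(self, temperature: float) -> int:
        n_knee = self.n_hot + self.knee_fraction * (self.n_cold - self.n_hot)

        def _piece(t: float) -> float:
            if t <= self.t_transition:
                f = (t - self.t_ref_low) / (self.t_transition - self.t_ref_low)
                return self.n_cold + min(max(f, 0.0), 1.0) * (n_knee - self.n_cold)
            f = ((t - self.t_transition)
                 / (self.t_ref_high - self.t_transition))
            return n_knee + min(max(f, 0.0), 1.0) * (self.n_hot - n_knee)

        if self.width > 0:
            lo = _piece(temperature - self.width)
            hi = _piece(temperature + self.width)
            return int(round(0.5 * (lo + hi)))
        return int(round(_piece(temperature)))


@dataclass(frozen=True)
class FixtureConfig:
    """Ground-truth parameters of the synthetic crystal-structure series."""

    temperatures: tuple = DEFAULT_TEMPERATURES
    switch_temperature: float = 300.0   # D19 partner switch: Y11 at/above
    two_water_max_temperature: float = 240.0  # 2-water Y11 bridge at/below
    bonded_distance: float = 2.88       # Å, D19 OD – W37 NE1 at low T
    y11_bonded_distance: float = 2.70   # Å, D19 OD – Y11 OH at high T
    bridge_leg: float = 2.80            # Å, per-leg water bridge distance
    contact_distance: float = 2.90      # Å, E15 network contacts
    zn_s_distance: float = 2.34         # Å, tetrahedral Zn–SG
    b_base: dict = field(default_factory=lambda: {"core": 5.0, "loop": 8.0})
    b_slope: dict = field(default_factory=lambda: {"core": 0.04, "loop": 0.10})
    water_count_model: WaterCountModel = WaterCountModel()
    cell0: UnitCell = UnitCell(34.0, 35.0, 44.0, 90.0, 90.0, 90.0)
    cell_expansion: float = 0.028 / 293.0  # volume fraction per K above Tmin
    volume_slope: float = 0.48          # Å³/K, protein-volume trend
    volume0: float = 8000.0             # Å³ at the minimum temperature
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("fixture temperatures must be distinct")
        for d in (self.bonded_distance, self.y11_bonded_distance,
                  self.bridge_leg, self.zn_s_distance, self.contact_distance):
            if d <= 0:
                raise ValueError("all programmed distances must be positive")

    @property
    def t_min(self) -> float:
        return min(self.temperatures)

    def cell_at(self, temperature: float) -> UnitCell:
        scale = (1.0 + self.cell_expansion * (temperature - self.t_min)) ** (1 / 3)
        c = self.cell0
        return UnitCell(c.a * scale, c.b * scale, c.c * scale,
                        c.alpha, c.beta, c.gamma)

    def backbone_scale(self, temperature: float) -> float:
        vol_frac = self.volume_slope / self.volume0
        return (1.0 + vol_frac * (temperature - self.t_min)) ** (1 / 3)

    def bfactor(self, resseq: int, temperature: float) -> float:
        cls = ("loop" if resseq in LOOP_A or resseq in LOOP_B
               or resseq in TERMINI else "core")
        return self.b_base[cls] + self.b_slope[cls] * temperature

    def volume_series_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Noiseless analytic protein-volume series (the generator truth)."""
        t = np.array(sorted(self.temperatures))
        return t, self.volume0 + self.volume_slope * (t - self.t_min)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def bridge_water_positions(p: np.ndarray, q: np.ndarray, n_waters: int,
                           leg: float) -> list[np.ndarray]:
    """Positions of 1 or 2 bridge waters linking p→q with equal legs.

    Waters sit on a symmetric kink out of the p–q chord (out-of-plane +z
    direction when the chord is not parallel to z).  Raises if the chord is
    too long for the requested number of legs.
    """
    span = float(np.linalg.norm(q - p))
    n_legs = n_waters + 1
    if span > n_legs * leg:
        raise ValueError(f"span {span:.2f} Å too long for {n_legs} legs of {leg} Å")
    chord = _unit(q - p)
    perp = np.cross(chord, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(chord, [0.0, 1.0, 0.0])
    out = _unit(np.cross(perp, chord))  # in-plane with z where possible
    if n_waters == 1:
        h = math.sqrt(leg ** 2 - (span / 2) ** 2)
        return [p + chord * (span / 2) + out * h]
    if n_waters == 2:
        a = (span - leg) / 2.0
        if a > leg:
            raise ValueError("two-water bridge infeasible for this span")
        h = math.sqrt(leg ** 2 - a ** 2)
        return [p + chord * a + out * h, q - chord * a + out * h]
    raise ValueError("n_waters must be 1 or 2")


def _backbone_positions() -> dict[int, np.ndarray]:
    """Serpentine Cα trace: rows of 8 residues, 3.8 Å spacing, 4.8 Å rows."""
    ca = {}
    for resseq in range(1, 55):
        row, j = divmod(resseq - 1, 8)
        x = 3.8 * (j + 1) if row % 2 == 0 else 3.8 * (8 - j)
        ca[resseq] = np.array([x, 4.8 * row, 0.0])
    return ca


class _ModelBuilder:
    def __init__(self, temperature: float, config: FixtureConfig):
        self.t = temperature
        self.cfg = config
        self.atoms: list[Atom] = []
        self._serial = 0

    def add(self, name: str, resname: str, resseq: int, pos, *,
            chain: str = "A", record: str = "ATOM",
            element: str | None = None, bfactor: float | None = None) -> None:
        self._serial += 1
        if element is None:
            element = name[0]
        if bfactor is None:
            bfactor = self.cfg.bfactor(resseq, self.t) if record == "ATOM" \
                else 20.0 + 0.05 * self.t
        self.atoms.append(Atom(
            serial=self._serial, name=name, resname=resname, chain=chain,
            resseq=resseq, x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
            occupancy=1.0, bfactor=bfactor, element=element, record=record))


def _site_geometry(temperature: float, cfg: FixtureConfig) -> dict:
    """Absolute positions of the D19/W37/Y11 switch-site atoms at one T."""
    S0 = np.array([20.0, 9.6, 8.0])
    ne1 = S0 + np.array([0.0, 0.0, 0.0])          # Trp-37 NE1
    oh = S0 + np.array([5.5, 1.5, 0.0])           # Tyr-11 OH
    out = {"W37_NE1": ne1, "Y11_OH": oh}
    if temperature >= cfg.switch_temperature:
        od1 = oh + cfg.y11_bonded_distance * _unit([-0.2, 0.93, 0.31])
        od2 = od1 + 2.2 * _unit([0.9, 0.3, 0.3])
        waters = []
    else:
        od1 = ne1 + cfg.bonded_distance * _unit([-0.5, math.sqrt(3) / 2, 0.0])
        if temperature <= cfg.two_water_max_temperature:
            od2 = od1 + np.array([0.0, 2.2, 0.0])
            waters = bridge_water_positions(od2, oh, 2, cfg.bridge_leg)
        else:
            u = _unit(_unit(oh - od1) + np.array([0.0, 0.28, 0.0]))
            od2 = od1 + 2.2 * u
            waters = bridge_water_positions(od2, oh, 1, cfg.bridge_leg)
    out["D19_OD1"], out["D19_OD2"] = od1, od2
    out["D19_CG"] = 0.5 * (od1 + od2) + np.array([0.0, 0.0, -0.8])
    out["D19_CB"] = out["D19_CG"] + np.array([0.0, -0.6, -1.2])
    out["bridge_waters"] = waters
    return out


def _clash_check(atoms: list[Atom], min_dist: float = 1.0) -> None:
    """Fail if two non-bonded heavy atoms come closer than `min_dist` Å."""
    from scipy.spatial import cKDTree
    heavy = [a for a in atoms if not a.is_hydrogen]
    coords = np.array([a.coord for a in heavy])
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(min_dist):
        a, b = heavy[i], heavy[j]
        if a.chain == b.chain and a.resseq == b.resseq:
            continue  # same residue: covalent
        names = {a.name, b.name}
        if (a.chain == b.chain and abs(a.resseq - b.resseq) == 1
                and names == {"C", "N"}):
            continue  # peptide bond
        if names == {"ZN", "SG"}:
            continue  # coordination bond
        d = float(np.linalg.norm(a.coord - b.coord))
        raise RuntimeError(
            f"atom clash: {a.resname}{a.resseq}:{a.name} — "
            f"{b.resname}{b.resseq}:{b.name} at {d:.2f} Å")


def build_structure(temperature: float, config: FixtureConfig,
                    rng: np.random.Generator | None = None) -> StructureModel:
    """One schematic crystal structure at `temperature`.

    Deterministic given (temperature, config.seed): the solvent placement
    RNG is derived from both.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed,
                                   spawn_key=(int(round(temperature * 10)),)))
    b = _ModelBuilder(temperature, config)
    ca = _backbone_positions()
    scale = config.backbone_scale(temperature)
    centroid = np.mean(list(ca.values()), axis=0)
    ca = {r: centroid + scale * (p - centroid) for r, p in ca.items()}

    # mainchain
    dirs = {}
    for r in range(1, 55):
        nxt = ca[r + 1] if r < 54 else None
        dirs[r] = _unit(nxt - ca[r]) if nxt is not None else dirs[r - 1]
    n_pos = {r: ca[r] - 1.2 * dirs[r] for r in ca}
    c_pos = {r: ca[r] + 1.3 * dirs[r] for r in ca}
    o_pos = {r: c_pos[r] + np.array([0.0, 0.0, -1.23]) for r in ca}
    # programmed Glu-15 amide to Ala-2 carbonyl contact
    o_pos[2] = n_pos[15] + config.contact_distance * np.array([0.0, -1.0, 0.0])

    site = _site_geometry(temperature, config)
    e15_oe1 = np.array([8.5, 7.2, 1.5])
    w4_ne1 = e15_oe1 + config.contact_distance * _unit([0.0, 0.32, 0.947])
    f30_n = n_pos[30]
    e15_oe2 = f30_n + config.contact_distance * _unit([0.0, 0.6, 0.8])

    zn_center = np.array([20.0, 19.2, 9.0])
    tet = [_unit(v) for v in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1])]
    sg = {r: zn_center + config.zn_s_distance * t
          for r, t in zip(CYS_RESIDUES, tet)}

    for r in range(1, 55):
        resname = _ONE_TO_THREE[PF_RD_SEQUENCE[r - 1]]
        b.add("N", resname, r, n_pos[r])
        b.add("CA", resname, r, ca[r])
        b.add("C", resname, r, c_pos[r])
        b.add("O", resname, r, o_pos[r])
        if resname != "GLY":
            b.add("CB", resname, r, ca[r] + np.array([0.0, 0.0, 1.5]))
        if r in sg:
            b.add("SG", "CYS", r, sg[r], element="S")
        if r == 4:
            b.add("NE1", "TRP", r, w4_ne1)
        if r == 11:
            b.add("OH", "TYR", r, site["Y11_OH"])
        if r == 15:
            b.add("OE1", "GLU", r, e15_oe1)
            b.add("OE2", "GLU", r, e15_oe2)
        if r == 19:
            b.add("CG", "ASP", r, site["D19_CG"])
            b.add("OD1", "ASP", r, site["D19_OD1"])
            b.add("OD2", "ASP", r, site["D19_OD2"])
        if r == 37:
            b.add("NE1", "TRP", r, site["W37_NE1"])

    b.add("ZN", "ZN", 55, zn_center, record="HETATM", element="ZN")

    wat_resseq = 95
    for w in site["bridge_waters"]:
        b.add("O", "HOH", wat_resseq, w, chain="S", record="HETATM")
        wat_resseq += 1

    # bulk solvent: seeded rejection sampling away from the programmed sites
    n_total = config.water_count_model.count(temperature)
    n_bulk = max(0, n_total - len(site["bridge_waters"]))
    protein_coords = np.array([a.coord for a in b.atoms])
    guarded = np.array([site["W37_NE1"], site["Y11_OH"], site["D19_OD1"],
                        site["D19_OD2"], e15_oe1, e15_oe2, w4_ne1,
                        n_pos[15], o_pos[2], f30_n]
                       + [np.asarray(w) for w in site["bridge_waters"]])
    lo = protein_coords.min(axis=0) - 4.0
    hi = protein_coords.max(axis=0) + 4.0
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_bulk:
        attempts += 1
        if attempts > 200 * max(1, n_bulk):
            raise RuntimeError("could not place bulk waters without clashes")
        p = lo + rng.random(3) * (hi - lo)
        if np.min(np.linalg.norm(protein_coords - p, axis=1)) < 3.0:
            continue
        if np.min(np.linalg.norm(guarded - p, axis=1)) < 4.5:
            continue
        if placed and np.min(np.linalg.norm(np.array(placed) - p, axis=1)) < 2.8:
            continue
        placed.append(p)
    wat_resseq = 101
    for p in placed:
        b.add("O", "HOH", wat_resseq, p, chain="S", record="HETATM")
        wat_resseq += 1

    _clash_check(b.atoms)
    return StructureModel(atoms=tuple(b.atoms),
                          cell=config.cell_at(temperature),
                          temperature=temperature,
                          label=f"synthetic Zn rubredoxin fixture {temperature:g} K")


def generate_structure_series(config: FixtureConfig | None = None
                              ) -> list[StructureModel]:
    """The full programmed temperature series, sorted by temperature.

    On the rare event of a solvent-placement clash, regenerates that
    structure with jittered RNG streams, up to 10 attempts.
    """
    config = config or FixtureConfig()
    models = []
    for t in sorted(config.temperatures):
        last_err: Exception | None = None
        for attempt in range(10):
            rng = np.random.default_rng(np.random.SeedSequence(
                config.seed, spawn_key=(int(round(t * 10)), attempt)))
            try:
                models.append(build_structure(t, config, rng=rng))
                break
            except RuntimeError as err:  # clash: jitter and retry
                last_err = err
                logger.warning("regenerating %g K structure (attempt %d): %s",
                               t, attempt + 1, err)
        else:
            raise RuntimeError(
                f"structure generation failed at {t} K after 10 attempts"
            ) from last_err
    return models


def write_fixture(config: FixtureConfig, outdir) -> Path:
    """Write one PDB per temperature plus a manifest JSON; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for model in generate_structure_series(config):
        name = f"rd_{model.temperature:g}K.pdb"
        (outdir / name).write_text(write_pdb(model))
        files[name] = model.temperature
    manifest = {
        "files": files,
        "seed": config.seed,
        "truth": {
            "switch_temperature": config.switch_temperature,
            "bonded_distance": config.bonded_distance,
            "zn_s_distance": config.zn_s_distance,
            "cell_expansion_per_K": config.cell_expansion,
            "volume_slope": config.volume_slope,
            "volume0": config.volume0,
            "water_transition_K": config.water_count_model.t_transition,
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


# ---------------------------------------------------------------------------
# Three-state Markov trajectory generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionModel:
    """State-conditional H-bond distance emissions (truncated normals, Å)."""

    bonded_mean: float = 2.9
    bonded_sd: float = 0.15
    bonded_min: float = 2.4
    unbonded_mean: float = 6.5
    unbonded_sd: float = 1.0
    unbonded_min: float = 4.0

    def sample(self, bonded: np.ndarray, rng: np.random.Generator
               ) -> np.ndarray:
        """Distances for a boolean bonded-mask array."""
        out = np.empty(bonded.shape, dtype=float)
        for mask, mean, sd, lower in (
                (bonded, self.bonded_mean, self.bonded_sd, self.bonded_min),
                (~bonded, self.unbonded_mean, self.unbonded_sd,
                 self.unbonded_min)):
            n = int(mask.sum())
            if n:
                a = (lower - mean) / sd
                out[mask] = truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                          size=n, random_state=rng)
        return out


@dataclass(frozen=True)
class MarkovConfig:
    """Ground truth for the three-state (W ⇌ I ⇌ Y) switching process.

    The stationary distribution has intermediate mass `pi_I` and a W/Y
    split following the van't Hoff law K(T) = exp(−ΔH/RT + ΔS/R); direct
    W↔Y transitions are forbidden by default (the carboxylate must pass
    through the broken-bond intermediate).  `occupancies` overrides the
    stationary distribution explicitly (π_W, π_I, π_Y).
    """

    deltaH: float = 31000.0        # J mol^-1
    deltaS: float = 108.0          # J K^-1 mol^-1
    temperature: float = 293.0
    pi_I: float = 0.6
    mean_dwell_ns: float = 100.0
    frame_interval_ns: float = 0.1
    n_frames: int = 100_000
    emission: EmissionModel = EmissionModel()
    occupancies: tuple | None = None
    allow_direct_WY: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_I < 1.0:
            raise ValueError("pi_I must lie strictly inside (0, 1)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")

    def equilibrium_constant(self, temperature: float | None = None) -> float:
        t = self.temperature if temperature is None else temperature
        return math.exp(-self.deltaH / (GAS_CONSTANT * t)
                        + self.deltaS / GAS_CONSTANT)


def analytic_occupancies(temperature: float, config: MarkovConfig
                         ) -> tuple[float, float, float]:
    """Closed-form stationary occupancies (π_W, π_I, π_Y); sums to 1 exactly."""
    if config.occupancies is not None:
        pw, pi, py = config.occupancies
        return float(pw), float(pi), float(py)
    K = config.equilibrium_constant(temperature)
    pi = config.pi_I
    py = (1.0 - pi) * K / (1.0 + K)
    pw = (1.0 - pi) / (1.0 + K)
    return pw, pi, py


def transition_matrix(config: MarkovConfig,
                      temperature: float | None = None) -> np.ndarray:
    """Per-frame transition matrix over (W, I, Y) satisfying detailed balance.

    Exit probabilities from W and Y are 1/mean_dwell (in frames); the
    I-state branch probabilities follow from detailed balance with the
    stationary distribution.
    """
    t = config.temperature if temperature is None else temperature
    pw, pi, py = analytic_occupancies(t, replace(config, temperature=t))
    dwell_frames = config.mean_dwell_ns / config.frame_interval_ns
    p_exit = 1.0 / dwell_frames
    if p_exit > 1.0:
        raise ValueError("mean dwell shorter than one frame")
    p_iw = pw * p_exit / pi
    p_iy = py * p_exit / pi
    if p_iw + p_iy > 1.0:
        raise ValueError("stationary distribution infeasible for this dwell time")
    P = np.array([
        [1.0 - p_exit, p_exit, 0.0],
        [p_iw, 1.0 - p_iw - p_iy, p_iy],
        [0.0, p_exit, 1.0 - p_exit],
    ])
    if config.allow_direct_WY:
        # move a small probability mass onto the direct channel, preserving
        # detailed balance (symmetric fraction of the smaller flux)
        eps = 0.1 * p_exit
        P[0, 2] += eps * py / (pw + py)
        P[2, 0] += eps * pw / (pw + py)
        P[0, 0] = 1.0 - P[0, 1] - P[0, 2]
        P[2, 2] = 1.0 - P[2, 1] - P[2, 0]
    return P


def _simulate_states(P: np.ndarray, stationary: np.ndarray, n_frames: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Segment-wise simulation: geometric dwells + categorical jumps."""
    states = np.empty(n_frames, dtype=np.int8)
    s = int(rng.choice(3, p=stationary))
    pos = 0
    while pos < n_frames:
        p_stay = P[s, s]
        if p_stay >= 1.0:
            states[pos:] = s
            break
        run = int(rng.geometric(1.0 - p_stay))
        end = min(pos + run, n_frames)
        states[pos:end] = s
        pos = end
        jump = P[s].copy()
        jump[s] = 0.0
        jump /= jump.sum()
        s = int(rng.choice(3, p=jump))
    return states


def simulate_three_state_markov(config: MarkovConfig,
                                rng: np.random.Generator | None = None
                                ) -> tuple[StateSeries, tuple[DistanceTrace,
                                                              DistanceTrace]]:
    """Simulate the switching chain and emit (d_W, d_Y) distance traces.

    The chain starts from its stationary distribution.  Reproducible given
    `config.seed` (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    P = transition_matrix(config)
    pw, pi, py = analytic_occupancies(config.temperature, config)
    stationary = np.array([pw, pi, py])
    idx = _simulate_states(P, stationary, config.n_frames, rng)
    dW = config.emission.sample(idx == 0, rng)
    dY = config.emission.sample(idx == 2, rng)
    labels = np.array(["W", "I", "Y"])[idx]
    series = StateSeries(states=labels, temperature=config.temperature,
                         frame_interval_ns=config.frame_interval_ns)
    traceW = DistanceTrace(label="D19:Oc-W37:Ne1",
                           temperature=config.temperature,
                           frame_interval_ns=config.frame_interval_ns,
                           values=dW)
    traceY = DistanceTrace(label="D19:Oc-Y11:OH",
                           temperature=config.temperature,
                           frame_interval_ns=config.frame_interval_ns,
                           values=dY)
    return series, (traceW, traceY)


def sample_emission_frames(occupancies: tuple, n_frames: int,
                           temperature: float,
                           emission: EmissionModel = EmissionModel(),
                           rng: np.random.Generator | int | None = None,
                           frame_interval_ns: float = 0.1
                           ) -> tuple[StateSeries, tuple[DistanceTrace,
                                                         DistanceTrace]]:
    """Independent frames from the emission model at fixed state fractions.

    Unlike the Markov simulator, frames are i.i.d. multinomial draws, so the
    empirical fractions fluctuate at the binomial scale — the generator for
    scatter-plot style occupancy checks.
    """
    pw, pi, py = occupancies
    if not math.isclose(pw + pi + py, 1.0, abs_tol=1e-9):
        raise ValueError("occupancies must sum to 1")
    rng = np.random.default_rng(rng)
    idx = rng.choice(3, size=n_frames, p=[pw, pi, py])
    dW = emission.sample(idx == 0, rng)
    dY = emission.sample(idx == 2, rng)
    labels = np.array(["W", "I", "Y"])[idx]
    series = StateSeries(states=labels, temperature=temperature,
                         frame_interval_ns=frame_interval_ns)
    traceW = DistanceTrace(label="D19:Oc-W37:Ne1", temperature=temperature,
                           frame_interval_ns=frame_interval_ns, values=dW)
    traceY = DistanceTrace(label="D19:Oc-Y11:OH", temperature=temperature,
                           frame_interval_ns=frame_interval_ns, values=dY)
    return series, (traceW, traceY)


#: Default protocol temperatures for the van't Hoff analysis (K).
VANT_HOFF_TEMPERATURES = (245.0, 260.0, 275.0, 293.0, 308.0, 323.0)
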