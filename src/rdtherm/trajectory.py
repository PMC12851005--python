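"""Trajectory-derived analysis of the Asp-19 H-bond partner exchange.

Reduces coordinate frames (or pre-computed distance tables) to labeled
distance traces, classifies each frame into three states — W (donor bonded
to the Trp-37 indole nitrogen), Y (bonded to the Tyr-11 hydroxyl), or I
(both H-bonds broken) — and estimates the thermodynamics of the W⇌Y
exchange by a van't Hoff fit of ln K against 1/T, where K = π_Y/π_W is the
occupancy ratio of the two bonded states.  Uncertainties come from the OLS
regression and, when frame-level state series are available, from a
moving-block bootstrap that respects trajectory autocorrelation.  Also
provides state dwell-time statistics and per-residue RMSF profiles after
Kabsch superposition onto the mean structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import kabsch
from .structure import ANY, StructureModel, select_atoms

logger = logging.getLogger(__name__)

#: CODATA gas constant, J mol^-1 K^-1 — fixed everywhere in this package.
GAS_CONSTANT = 8.314462618

STATES = ("W", "I", "Y")
_CARBOXYLATE_PAIRS = ({"OD1", "OD2"}, {"OE1", "OE2"})


@dataclass(frozen=True)
class DistanceTrace:
    """Per-frame distance (Å) of one labeled atom pair at one temperature."""

    label: str
    temperature: float
    frame_interval_ns: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("trace needs at least one frame")
        if np.any(v <= 0):
            raise ValueError("distances must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class StateSeries:
    """Per-frame categorical state with empirical occupancy fractions."""

    states: np.ndarray  # '<U1' array over {'W','I','Y'}
    temperature: float
    frame_interval_ns: float = 0.1
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.states)
        if s.ndim != 1 or s.size < 1:
            raise ValueError("state series needs at least one frame")
        bad = set(np.unique(s)) - set(STATES)
        if bad:
            raise ValueError(f"unknown states {bad}")
        object.__setattr__(self, "states", s)

    @property
    def n_frames(self) -> int:
        return int(self.states.size)

    @property
    def occupancies(self) -> tuple[float, float, float]:
        """(π_W, π_I, π_Y) as empirical frame frequencies; sums to 1."""
        n = self.states.size
        return tuple(float((self.states == s).sum()) / n for s in STATES)


@dataclass(frozen=True)
class VantHoffFit:
    """ΔH/ΔS of an occupancy-ratio equilibrium from ln K vs 1/T OLS."""

    delta_H: float  # J mol^-1
    delta_S: float  # J K^-1 mol^-1
    se_delta_H: float
    se_delta_S: float
    temperatures: np.ndarray
    K_values: np.ndarray
    n_excluded: int = 0
    se_method: str = "ols"
    R: float = GAS_CONSTANT

    def K_fitted(self, temperature: np.ndarray) -> np.ndarray:
        t = np.asarray(temperature, dtype=float)
        return np.exp(-self.delta_H / (self.R * t) + self.delta_S / self.R)


@dataclass(frozen=True)
class DwellTimes:
    """Mean dwell time (ns) per state from maximal same-state runs."""

    mean_ns: dict
    n_runs: dict
    n_censored: int  # runs truncated by the series ends (still counted)


@dataclass
class Trajectory:
    """Coordinate frames sharing one atom template.

    `coords` has shape (n_frames, n_atoms, 3) and row i of each frame
    corresponds to ``template.atoms[i]``.
    """

    template: StructureModel
    coords: np.ndarray
    temperature: float = 293.0
    frame_interval_ns: float = 0.1

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if c.shape[1] != len(self.template.atoms):
            raise ValueError("coords second axis must match template atoms")
        self.coords = c

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    def atom_indices(self, selector) -> list[int]:
        selected = {a.key() for a in select_atoms(self.template, selector)}
        return [i for i, a in enumerate(self.template.atoms)
                if a.key() in selected]


def _resolve_pair_indices(traj: Trajectory, selector, role: str) -> list[int]:
    idx = traj.atom_indices(selector)
    if len(idx) == 1:
        return idx
    if len(idx) == 2:
        names = {traj.template.atoms[i].name for i in idx}
        residues = {(traj.template.atoms[i].chain, traj.template.atoms[i].resseq)
                    for i in idx}
        if len(residues) == 1 and names in _CARBOXYLATE_PAIRS:
            return idx  # carboxylate: per-frame minimum over the two oxygens
    raise ValueError(
        f"{role} selector resolved to {len(idx)} atoms; only a single atom "
        "or one Asp/Glu carboxylate oxygen pair is allowed")


def extract_distance_trace(frames, pairA=None, pairB=None, label: str = "",
                           distance_column: str | None = None
                           ) -> DistanceTrace:
    """Per-frame distance between two selected atoms.

    `frames` is either a :class:`Trajectory` (distances computed from
    coordinates; a carboxylate-oxygen pair on either side contributes its
    per-frame minimum distance) or a pandas DataFrame distance table, which
    is passed through unchanged (`distance_column` names the column; columns
    `temperature_K` and `time_ns` supply metadata when present).
    """
    if isinstance(frames, pd.DataFrame):
        col = distance_column or [c for c in frames.columns
                                  if c.startswith("d_")][0]
        interval = 0.1
        if "time_ns" in frames.columns and len(frames) > 1:
            interval = float(np.diff(frames["time_ns"].to_numpy()[:2])[0])
        temp = (float(frames["temperature_K"].iloc[0])
                if "temperature_K" in frames.columns else 293.0)
        return DistanceTrace(label=label or col, temperature=temp,
                             frame_interval_ns=interval,
                             values=frames[col].to_numpy(dtype=float))
    ia = _resolve_pair_indices(frames, pairA, "pairA")
    ib = _resolve_pair_indices(frames, pairB, "pairB")
    A = frames.coords[:, ia, :]  # (n, |A|, 3)
    B = frames.coords[:, ib, :]
    d = np.linalg.norm(A[:, :, None, :] - B[:, None, :, :], axis=3)
    dmin = d.reshape(frames.n_frames, -1).min(axis=1)
    return DistanceTrace(label=label, temperature=frames.temperature,
                         frame_interval_ns=frames.frame_interval_ns,
                         values=dmin)


def classify_three_state(traceW: DistanceTrace, traceY: DistanceTrace,
                         cutoff: float = 3.5) -> StateSeries:
    """Assign each frame to W, Y, or I by the two H-bond distances.

    W if d_W ≤ cutoff < d_Y; Y if d_Y ≤ cutoff < d_W; I if both exceed the
    cutoff.  If both distances are within the cutoff the closer partner
    wins and the frame is counted as ambiguous.
    """
    if traceW.n_frames != traceY.n_frames:
        raise ValueError("traces differ in frame count")
    if traceW.temperature != traceY.temperature:
        raise ValueError("traces differ in temperature")
    dW, dY = traceW.values, traceY.values
    w_in, y_in = dW <= cutoff, dY <= cutoff
    states = np.full(dW.shape, "I", dtype="<U1")
    states[w_in & ~y_in] = "W"
    states[y_in & ~w_in] = "Y"
    both = w_in & y_in
    states[both & (dW <= dY)] = "W"
    states[both & (dY < dW)] = "Y"
    n_amb = int(both.sum())
    if n_amb:
        logger.info("%d frames had both H-bonds within cutoff", n_amb)
    return StateSeries(states=states, temperature=traceW.temperature,
                       frame_interval_ns=traceW.frame_interval_ns,
                       n_ambiguous=n_amb)


def occupancy_ratio(series: StateSeries) -> float:
    """K = π_Y / π_W — intermediate frames excluded from the ratio."""
    pi_W, _, pi_Y = series.occupancies
    if pi_W == 0:
        raise ValueError(
            f"no W-state frames at {series.temperature} K; K undefined")
    return pi_Y / pi_W


def integrated_autocorrelation_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time τ of a series, in frames.

    τ = 1/2 + Σρ(t) summed until the autocorrelation first drops below
    zero (initial-positive-sequence estimator); FFT-based.  Returns ≥ 0.5.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0 or n < 2:
        return 0.5
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    tau = 0.5
    for t in range(1, n):
        if rho[t] <= 0:
            break
        tau += rho[t]
    return float(tau)


def _fit_lnK(temps: np.ndarray, Ks: np.ndarray):
    invT = 1.0 / temps
    lnK = np.log(Ks)
    res = stats.linregress(invT, lnK)
    dH = -res.slope * GAS_CONSTANT
    dS = res.intercept * GAS_CONSTANT
    return dH, dS, res


def _block_bootstrap_K(states: np.ndarray, block_length: int,
                       rng: np.random.Generator) -> float | None:
    """One moving-block bootstrap replicate of K = n_Y/n_W."""
    n = states.size
    L = min(block_length, n)
    n_blocks = int(math.ceil(n / L))
    isW = (states == "W").astype(np.int64)
    isY = (states == "Y").astype(np.int64)
    cW = np.concatenate([[0], np.cumsum(isW)])
    cY = np.concatenate([[0], np.cumsum(isY)])
    starts = rng.integers(0, n - L + 1, size=n_blocks)
    nW = int((cW[starts + L] - cW[starts]).sum())
    nY = int((cY[starts + L] - cY[starts]).sum())
    if nW == 0:
        return None
    return nY / nW


def vant_hoff_fit(points, state_series: list[StateSeries] | None = None,
                  n_boot: int = 200, block_length: int | None = None,
                  rng: np.random.Generator | int | None = None) -> VantHoffFit:
    """OLS fit of ln K on 1/T: ΔH = −slope·R, ΔS = intercept·R.

    `points` is a sequence of (temperature_K, K) pairs; entries with K ≤ 0
    are excluded with a warning and at least 3 valid points are required.
    When per-temperature frame-level `state_series` are supplied, standard
    errors come from a moving-block bootstrap (block length 10× the
    integrated autocorrelation time of the state indicator, capped so each
    replicate draws at least 10 blocks; `n_boot` replicates); otherwise
    from the regression standard errors.
    """
    pts = [(float(t), float(k)) for t, k in points]
    valid = [(t, k) for t, k in pts if k > 0]
    n_excluded = len(pts) - len(valid)
    if n_excluded:
        logger.warning("excluded %d points with K ≤ 0 from van't Hoff fit",
                       n_excluded)
    if len(valid) < 3:
        raise ValueError("van't Hoff fit needs at least 3 points with K > 0")
    temps = np.array([t for t, _ in valid])
    Ks = np.array([k for _, k in valid])
    dH, dS, res = _fit_lnK(temps, Ks)
    se_dH = abs(res.stderr) * GAS_CONSTANT
    se_dS = abs(res.intercept_stderr) * GAS_CONSTANT
    se_method = "ols"

    if state_series is not None:
        rng = np.random.default_rng(rng)
        series_by_T = {s.temperature: s for s in state_series}
        blocks = {}
        for t in temps:
            s = series_by_T[t]
            if block_length is None:
                ind = (s.states == "Y").astype(float)
                tau = integrated_autocorrelation_time(ind)
                L = int(round(10 * tau))
            else:
                L = block_length
            blocks[t] = int(np.clip(L, 1, max(1, s.n_frames // 10)))
        reps_dH, reps_dS = [], []
        for _ in range(n_boot):
            bpts = []
            for t in temps:
                K = _block_bootstrap_K(series_by_T[t].states, blocks[t], rng)
                if K is not None and K > 0:
                    bpts.append((t, K))
            if len(bpts) < 3:
                continue
            bt = np.array([p[0] for p in bpts])
            bk = np.array([p[1] for p in bpts])
            bdH, bdS, _ = _fit_lnK(bt, bk)
            reps_dH.append(bdH)
            reps_dS.append(bdS)
        if len(reps_dH) >= max(10, n_boot // 4):
            se_dH = float(np.std(reps_dH, ddof=1))
            se_dS = float(np.std(reps_dS, ddof=1))
            se_method = "block-bootstrap"
        else:
            logger.warning("bootstrap produced too few valid replicates "
                           "(%d); falling back to OLS errors", len(reps_dH))
    return VantHoffFit(delta_H=dH, delta_S=dS, se_delta_H=se_dH,
                       se_delta_S=se_dS, temperatures=temps, K_values=Ks,
                       n_excluded=n_excluded, se_method=se_method)


def dwell_times(series: StateSeries) -> DwellTimes:
    """Mean maximal same-state run length × frame interval, per state.

    Runs truncated by the series ends are included in the means and
    counted in `n_censored`.  Frame order matters, by construction.
    """
    s = series.states
    boundaries = np.flatnonzero(s[1:] != s[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [s.size]])
    runs: dict[str, list[int]] = {st: [] for st in STATES}
    for a, b in zip(starts, ends):
        runs[s[a]].append(b - a)
    n_censored = int(len(starts) >= 1) + int(len(starts) >= 2)
    if len(starts) == 1:
        n_censored = 1  # single run censored at both ends: one flagged run
    mean_ns = {st: (float(np.mean(r)) * series.frame_interval_ns
                    if r else float("nan"))
               for st, r in runs.items()}
    n_runs = {st: len(r) for st, r in runs.items()}
    if n_censored:
        logger.info("%d dwell run(s) truncated by series ends", n_censored)
    return DwellTimes(mean_ns=mean_ns, n_runs=n_runs, n_censored=n_censored)


@dataclass(frozen=True)
class RMSFProfile:
    """Per-residue Cα root-mean-square fluctuation (Å) about the mean."""

    values: dict  # resseq -> rmsf
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"resseq": list(self.values.keys()),
                             "rmsf_A": list(self.values.values())})


def rmsf_profile(traj: Trajectory, selection=(ANY, ANY, "CA")) -> RMSFProfile:
    """RMSF of selected atoms after superposition onto the mean structure.

    Each frame is Kabsch-fitted to the frame average; the mean is then
    recomputed from the fitted frames and the fit repeated once, removing
    rigid-body drift before measuring per-atom fluctuations.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = traj.atom_indices(selection)
    if len(idx) < 3:
        raise ValueError("selection must resolve ≥3 atoms for superposition")
    X = traj.coords[:, idx, :].copy()
    mean = X.mean(axis=0)
    for _ in range(2):  # fit → new mean → fit
        for f in range(X.shape[0]):
            R, t, _ = kabsch(X[f], mean)
            X[f] = X[f] @ R.T + t
        mean = X.mean(axis=0)
    rmsf = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))
    resseqs = [traj.template.atoms[i].resseq for i in idx]
    return RMSFProfile(values=dict(zip(resseqs, rmsf.tolist())),
                       n_frames=traj.n_frames)


def traces_to_frame(traceW: DistanceTrace, traceY: DistanceTrace,
                    states: StateSeries | None = None) -> pd.DataFrame:
    """Tabulate paired traces (and states) as frame, time_ns, d_W_A, d_Y_A."""
    n = traceW.n_frames
    out = pd.DataFrame({
        "frame": np.arange(n),
        "time_ns": np.arange(n) * traceW.frame_interval_ns,
        "d_W_A": traceW.values,
        "d_Y_A": traceY.values,
    })
    if states is not None:
        out["state"] = states.states
    return out
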