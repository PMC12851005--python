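"""Reference analysis protocols built from the library operations.

These functions wire the generators and estimators together under the
package's default study conditions: six trajectory temperatures spanning
245–323 K, 10⁵ frames at 0.1 ns per temperature, the default van't Hoff
parameters (ΔH = 31 kJ mol⁻¹, ΔS = 108 J K⁻¹ mol⁻¹), and 20 replicate
chains.  They are used by the acceptance checks and are convenient entry
points for exploring estimator behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import (EmissionModel, MarkovConfig, VANT_HOFF_TEMPERATURES,
                        sample_emission_frames, simulate_three_state_markov)
from .trajectory import (StateSeries, VantHoffFit, classify_three_state,
                         occupancy_ratio, vant_hoff_fit)

DEFAULT_DELTA_H = 31_000.0   # J mol^-1
DEFAULT_DELTA_S = 108.0      # J K^-1 mol^-1
N_REPLICATES = 20
FRAMES_PER_TEMPERATURE = 100_000


def scatter_occupancies(temperature: float,
                        config: MarkovConfig | None = None
                        ) -> tuple[float, float, float]:
    """Reference (π_W, π_I, π_Y) mixes for the scatter-classification checks.

    At 293 K the mix is (0.07, 0.64, 0.29) — the dominant bonded
    conformation is Y with a small W remnant.  At 240 K the W fraction is
    0.49 and the Y fraction follows from the default van't Hoff law
    (π_Y = K(240)·π_W); the rest is the broken-bond intermediate.
    """
    config = config or MarkovConfig(deltaH=DEFAULT_DELTA_H,
                                    deltaS=DEFAULT_DELTA_S)
    if temperature == 293.0:
        return (0.07, 0.64, 0.29)
    K = config.equilibrium_constant(temperature)
    pw = 0.49
    py = K * pw
    return (pw, 1.0 - pw - py, py)


def classify_scatter(temperature: float, n_frames: int,
                     rng: np.random.Generator | int | None,
                     cutoff: float = 3.5) -> StateSeries:
    """Generate i.i.d. emission-model frames at a reference mix and classify."""
    _, (tw, ty) = sample_emission_frames(
        scatter_occupancies(temperature), n_frames, temperature, rng=rng)
    return classify_three_state(tw, ty, cutoff=cutoff)


def simulate_and_classify(temperature: float, n_frames: int,
                          rng: np.random.Generator,
                          cutoff: float = 3.5,
                          deltaH: float = DEFAULT_DELTA_H,
                          deltaS: float = DEFAULT_DELTA_S) -> StateSeries:
    """One Markov switching trajectory, classified at the distance cutoff."""
    cfg = MarkovConfig(deltaH=deltaH, deltaS=deltaS, temperature=temperature,
                       n_frames=n_frames)
    _, (tw, ty) = simulate_three_state_markov(cfg, rng=rng)
    return classify_three_state(tw, ty, cutoff=cutoff)


def replicate_vant_hoff(entropy, n_frames: int = FRAMES_PER_TEMPERATURE,
                        temperatures=VANT_HOFF_TEMPERATURES,
                        bootstrap: bool = True) -> VantHoffFit:
    """Simulate one replicate (all temperatures) and fit the van't Hoff line.

    `entropy` seeds a SeedSequence; per-temperature streams are spawned
    from it, as is the bootstrap stream.
    """
    points, series = [], []
    for t in temperatures:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy, spawn_key=(int(t),)))
        st = simulate_and_classify(t, n_frames, rng)
        try:
            points.append((t, occupancy_ratio(st)))
            series.append(st)
        except ValueError:
            continue
    boot_rng = np.random.default_rng(
        np.random.SeedSequence(entropy, spawn_key=(999,)))
    return vant_hoff_fit(points, state_series=series if bootstrap else None,
                         rng=boot_rng)


@dataclass(frozen=True)
class PooledVantHoff:
    """Pooled multi-replicate estimate with per-replicate coverage counts."""

    fit: VantHoffFit
    n_replicates: int
    total_frames: int


def pooled_vant_hoff(entropies, n_frames: int = FRAMES_PER_TEMPERATURE,
                     temperatures=VANT_HOFF_TEMPERATURES) -> PooledVantHoff:
    """Pool state counts over replicate chains, then fit once.

    K per temperature is formed from the summed Y and W frame counts of
    all replicates — the low-variance estimate of the equilibrium ratio.
    """
    nY = {t: 0 for t in temperatures}
    nW = {t: 0 for t in temperatures}
    n_rep = 0
    for entropy in entropies:
        n_rep += 1
        for t in temperatures:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy, spawn_key=(int(t),)))
            st = simulate_and_classify(t, n_frames, rng)
            nY[t] += int((st.states == "Y").sum())
            nW[t] += int((st.states == "W").sum())
    points = [(t, nY[t] / nW[t]) for t in temperatures if nW[t] > 0]
    fit = vant_hoff_fit(points)
    return PooledVantHoff(fit=fit, n_replicates=n_rep,
                          total_frames=n_rep * n_frames * len(temperatures))
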