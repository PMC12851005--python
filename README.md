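# rdtherm

Temperature-series structural analysis of a hyperthermophile rubredoxin —
hydrogen-bond networks across 100–393 K, crystallographic disorder and
thermal-expansion trends, and van't Hoff thermodynamics of a conformational
H-bond switch estimated from trajectory occupancies.

## Who this is for

Structural biologists and simulators comparing protein crystal structures
collected over a wide temperature range (cryogenic to near-boiling), and
relating them to molecular-dynamics observables.  The concrete system is a
54-residue Zn-substituted rubredoxin from *Pyrococcus furiosus*, whose
Asp-19 carboxylate hydrogen-bonds the Trp-37 indole nitrogen (Nε) at low
temperature and switches to the Tyr-11 hydroxyl at high temperature, with
one- and two-water bridges at intermediate temperatures.  All analyses work
on any PDB-format structure series, and a synthetic-data generator provides
a fully programmed test system.

## What it computes

**Per structure** (`rdtherm.structure`, `rdtherm.geometry`,
`rdtherm.hbonds`):

* fixed-column PDB I/O with unit-cell metadata and wildcard atom selection;
* Kabsch (SVD) superposition RMSD, metal-site coordination distances,
  triclinic unit-cell volume, grid-based van der Waals protein volume;
* per-residue Cα B-factor profiles and their per-structure z-score
  normalization, `z = (B − ⟨B⟩)/σ_B`;
* direct H-bonds by a heavy-atom distance criterion (default 3.5 Å — the
  models carry no hydrogens) and water-mediated bridges (≤ 2 waters) by
  path search over the polar contact graph.

**Across temperatures** (`rdtherm.trends`):

* partner-switch tables (which acceptor a donor engages at each T);
* ordinary least-squares expansion fits with the relative slope in %/100 K,
  and a continuous two-segment piecewise-linear changepoint fit used to
  locate the ~240 K drop in crystallographically ordered waters (the
  protein dynamical transition).

**From trajectories** (`rdtherm.trajectory`):

* distance traces (with the carboxylate minimum-distance rule: the partner,
  not the oxygen, defines the state), three-state classification into
  W-bonded / intermediate / Y-bonded, dwell times, and per-residue RMSF;
* van't Hoff estimation: with K = π_Y/π_W the occupancy ratio of the two
  bonded states,

      ln K = −ΔH/(R·T) + ΔS/R

  fitted by OLS of ln K on 1/T, with uncertainties from a moving-block
  bootstrap over the trajectory frames.

**Generators** (`rdtherm.synthetic`): a schematic rubredoxin-like crystal
series with every feature above programmed as ground truth, and a
three-state Markov distance-trajectory simulator whose stationary W/Y ratio
obeys a configured van't Hoff law.

## Worked example

```python
from rdtherm import (generate_structure_series, partner_switch_table,
                     collect_series, changepoint_fit)
from rdtherm.synthetic import FixtureConfig
from rdtherm.protocols import pooled_vant_hoff

models = generate_structure_series(FixtureConfig(seed=1))
table = partner_switch_table(models, ("A", 19, "OD*"),
                             {"W37": ("A", 37, "NE1"),
                              "Y11": ("A", 11, "OH")})
print(table.to_frame().head(4).to_string(index=False))

fit = changepoint_fit(collect_series(models, "waters"))
print(f"water changepoint: {fit.breakpoint:.0f} K")

pooled = pooled_vant_hoff([1000 + i for i in range(1, 21)])
print(f"dH = {pooled.fit.delta_H/1000:.1f} kJ/mol, "
      f"dS = {pooled.fit.delta_S:.0f} J/K/mol")
```

prints

```
 temperature_K partner    kind  min_distance_A  n_waters  ambiguous
         100.0     W37  direct        2.880000       0.0      False
         100.0     Y11 2-water        7.010844       2.0      False
         140.0     W37  direct        2.880000       0.0      False
         140.0     Y11 2-water        7.010844       2.0      False
water changepoint: 240 K
dH = 30.3 kJ/mol, dS = 105 J/K/mol
```

At 100–140 K the Asp-19 carboxylate is directly bonded to Trp-37 Nε at the
programmed 2.88 Å while Tyr-11 is reached only through a two-water bridge;
the ordered-water count kinks at the programmed 240 K transition; and the
van't Hoff fit over 20 simulated switching trajectories (10⁵ frames at each
of six temperatures, 245–323 K) recovers enthalpy and entropy differences
close to the generating ΔH = 31 kJ mol⁻¹ and ΔS = 108 J K⁻¹ mol⁻¹.

The same analyses are available from the shell:

```sh
rdtherm fixture --seed 1 --out fix/
rdtherm hbond --in fix/manifest.json --out out/
rdtherm trends --in fix/manifest.json --out out/
rdtherm report --fixture-seed 1 --out report/
```

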