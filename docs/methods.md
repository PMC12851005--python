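# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `rdtherm`.  Nothing here states an empirical result
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## System and scope

The package analyzes a temperature series of crystal structures of a small
(54-residue) rubredoxin-like protein with a tetrahedral Zn(S-Cys)₄ site,
together with trajectory-derived distance series for one conformational
equilibrium: the Asp-19 carboxylate hydrogen-bonding either the Trp-37
indole nitrogen (state **W**) or the Tyr-11 hydroxyl (state **Y**), with a
broken-bond intermediate (**I**) in between.  It does not run molecular
dynamics, refine crystallographic data, or assign secondary structure.

## Structure I/O

Fixed-column PDB (ATOM/HETATM/CRYST1/TER/END).  Only alternate location
blank or 'A' is kept, matching single-conformer refinement.  Temperature is
supplied by the caller, never read from REMARK records (dialects vary).
Coordinates are Å, B-factors Å², residue numbering 1-based (Met1…Asp54;
waters are HOH with a single O).  Round trip preserves coordinates to
3 decimals and B to 2 decimals, and a second round trip is byte-exact.
Hydrogens, if present, parse but are ignored by all geometry operations.

## Hydrogen bonds

Criterion: two polar heavy atoms within a cutoff, default **3.5 Å**,
configurable.  No donor–hydrogen–acceptor angle is evaluated because X-ray
models at this resolution carry no hydrogens; consequently donor/acceptor
roles are conventional, not chemical.  Intra-residue pairs and the
covalently constrained mainchain O(i)–N(i+1) of each peptide bond are
excluded.  The per-residue polar-atom table is a module-level constant
(`rdtherm.hbonds.SIDECHAIN_POLAR`) that callers may copy and edit; both
carboxylate oxygens of Asp/Glu are listed because the partner, not the
oxygen, defines a contact (the carboxylate can rotate).  Water bridges are
simple paths through ≤ 2 water oxygens in the graph whose edges join polar
atoms within the cutoff; results are ordered by (number of waters, total
path length).  Bonds are computed within the asymmetric unit only — no
crystal-symmetry expansion.  When two competing partners are both directly
bonded at one temperature, the partner table flags the rows ambiguous
rather than choosing a winner.

## Geometry and disorder metrics

* **Superposition** — Kabsch via SVD with the determinant correction, so the
  returned rotation is always proper; degenerate (collinear, < 3 point)
  inputs are rejected.  Verified in tests against a rotation-grid search
  and an independent library implementation.
* **Unit-cell volume** — the closed triclinic form
  `V = abc·√(1 − cos²α − cos²β − cos²γ + 2cosα·cosβ·cosγ)`, cross-checked
  against the lattice-vector triple product.
* **Protein volume** — grid-occupancy van der Waals volume of non-water
  heavy atoms at 0.5 Å spacing with fixed radii (C 1.70, N 1.55, O 1.52,
  S 1.80, Zn 1.39, Fe 1.47, default 1.70 Å).  Absolute values carry
  grid-level error (a few percent on small systems, < 1% on a full model);
  only relative changes across a series are meaningful output.
* **B-factors** — per-residue Cα profiles; normalization is the
  per-structure z-score over the profile's residues (population σ, so the
  output has mean 0 and σ 1 exactly), which makes disorder profiles
  comparable across structures at different temperatures.  The isotropic
  conversion B = 8π²⟨u²⟩/3 is exposed as a helper but not used in headline
  outputs.

## Thermal trends

Expansion is ordinary least squares of value on temperature.  The relative
slope is reported in %/100 K **relative to the fitted value at the series'
minimum temperature**, matching the "from T_min to T_max we observed an x%
increase" convention; the endpoint percent change uses the raw first/last
values.  The changepoint fit is a continuous two-segment piecewise-linear
model `v = c₀ + c₁T + c₂·max(0, T−b)` with the breakpoint scanned
exhaustively on a 1 K grid between the 2nd and (n−1)th temperatures; ties
resolve to the lowest breakpoint, and a fit whose SSE improves on a single
line by less than a relative 1e-8 is flagged `no_changepoint`.  These are
the simplest fits supporting slope and inflection claims; no attempt is
made to model refinement-level error bars.

## Three-state trajectory thermodynamics

Frames are classified from the two H-bond distances: W if d_W ≤ cutoff
< d_Y, Y symmetrically, I if both exceed the cutoff; if both are within the
cutoff the closer partner wins and the frame is counted ambiguous.  For
carboxylate donors the per-frame distance is the **minimum over the two
oxygens**.  The equilibrium constant is the pure two-state ratio
K = π_Y/π_W — intermediate frames are excluded, because the quantity of
interest is the W ⇌ Y exchange.  The van't Hoff fit is OLS of ln K on 1/T
with ΔH = −slope·R and ΔS = intercept·R, R = 8.314462618 J mol⁻¹ K⁻¹
everywhere.  Temperatures with K ≤ 0 (no Y frames) or no W frames are
excluded with a warning; at least three valid temperatures are required.
The default protocol uses T ∈ {245, 260, 275, 293, 308, 323} K.

Uncertainties: when frame-level state series are available, a moving-block
bootstrap (200 replicates) resamples contiguous blocks of length 10× the
integrated autocorrelation time of the state indicator
(initial-positive-sequence estimator), capped at n/10 so every replicate
draws at least 10 blocks — below that the SE estimate itself becomes too
unstable to be useful.  Replicates that lose a state entirely are dropped;
if fewer than a quarter survive, the fit falls back to OLS standard errors.

Dwell times are mean maximal same-state run lengths × frame interval; runs
truncated by the series ends are included and counted as censored.  Dwell
statistics depend on frame order (occupancies do not).  RMSF superposes
every frame onto the frame average by Kabsch, recomputes the average, fits
once more, then takes per-atom RMS deviations — so rigid-body motion never
inflates the profile.

## Synthetic structure series (what it emulates, and what not)

The generator realizes, as programmed ground truth: the D19 partner switch
(W37-direct below 300 K with a two-water Y11 bridge at ≤ 240 K and a
one-water bridge between; Y11-direct at/above 300 K), the D19–W37 distance
2.88 Å, a conserved E15 contact network (E15 N–A2 O, E15 OE1–W4 Nε,
E15 OE2–F30 N, all 2.90 Å at every temperature), a tetrahedral Zn site
with mean Zn–S 2.34 Å, per-residue-class B-factors growing linearly with
temperature (core 5 + 0.04·T Å², loops/termini 8 + 0.10·T Å²), an
ordered-water count declining with a kink at 240 K (60 → 15 waters), a
unit cell whose volume grows linearly to +2.8% at 393 K, and a protein
volume series with slope 0.48 Å³/K on an 8000 Å³ baseline (0.6%/100 K).

The water-count curve is deliberately a continuous **two-slope** decline
(steep to the 240 K kink, shallow after) rather than a smooth sigmoid
between plateaus: a two-segment changepoint fit on a plateau–sigmoid–
plateau shape locks onto the end of the drop, not its center, so a kinked
generator is the shape whose transition temperature the trend fitter can
actually recover.  An optional `width` rounds the kink.

**The geometry is schematic.**  The backbone is a serpentine Cα trace with
generic mainchain atoms; the functional sites (Zn cluster, D19 switch site,
E15 network) are placed at absolute positions with exact local geometry for
every measured feature but no claim of a realistic fold — sidechain atoms
are not at bonded distance from their own backbone.  Global thermal
expansion scales backbone and solvent coordinates about the centroid while
functional-site internal distances stay fixed (covalent and coordination
bonds do not expand).  Note that the measured grid vdW volume of the
fixture grows much more slowly (~0.2%/100 K) than the coordinate envelope
(0.6%/100 K linear in volume), because atom-sphere volumes are invariant
under coordinate scaling; the analytic volume series
(`FixtureConfig.volume_series_values`) carries the exact programmed trend.
Passing tests on this fixture therefore demonstrate correctness of the
measurement pipeline against known truth — not realism of the structural
model, and not agreement with any experimental volume scale.

Bulk waters are placed by seeded rejection sampling ≥ 3.0 Å from protein
atoms, ≥ 2.8 Å from each other, and ≥ 4.5 Å from all programmed polar
sites so that no accidental bridge can form.  A clash (< 1.0 Å between
non-bonded heavy atoms) triggers regeneration with a jittered stream, then
an error after 10 attempts.  Identical seeds give bit-identical output.

## Three-state Markov generator

A discrete-time chain on {W, I, Y} with W↔I↔Y transitions only — the
carboxylate must pass through the broken-bond intermediate (a direct W↔Y
channel can be enabled for robustness experiments; it preserves detailed
balance).  Exit probability from W and Y is frame_interval/mean_dwell
(defaults 0.1 ns and 100 ns — switching on the hundred-nanosecond scale);
the I-branch probabilities follow from detailed balance with the stationary
distribution, which has intermediate mass `pi_I` (default 0.6, the middle
of the observed ~50–70% range, held temperature-independent by default)
and π_Y/π_W = exp(−ΔH/RT + ΔS/R) with defaults ΔH = 31 kJ mol⁻¹,
ΔS = 108 J K⁻¹ mol⁻¹.  Chains start from the stationary distribution (no
burn-in needed; a burn-in from a fixed state is the documented
alternative).  Emissions are state-conditional truncated normals:
bonded ~ N(2.9, 0.15²) Å truncated below at 2.4, unbonded ~ N(6.5, 1.0²)
truncated below at 4.0 — so classification at 3.5 Å recovers the latent
state with error ~3·10⁻⁵ per frame.

A separate i.i.d. sampler (`sample_emission_frames`) draws frames
multinomially at fixed state fractions for scatter-style occupancy checks,
where fluctuations must be at the binomial scale rather than inflated by
chain autocorrelation.  For the 293 K reference mix the two bonded
fractions are (π_W, π_Y) = (0.07, 0.29); for 240 K the W fraction is 0.49
and the Y fraction is completed from the default van't Hoff law
(π_Y = K(240)·π_W ≈ 0.038), the remainder being intermediate.  These two
published-style panel mixes are not mutually consistent with a single
van't Hoff line — the 293 K ratio 29/7 implies a larger K than the default
law gives at 293 K; the package treats the mixes and the law as separate
inputs and does not reconcile them.  Occupancy fractions are treated as
fractions of **all** frames (the alternative, fractions of classified
frames only, would raise each bonded fraction by ~1/(1−π_I)).

## Study conditions and problem sizes

The reference estimation protocol (`rdtherm.protocols`) uses 10⁵ frames
per temperature at 0.1 ns intervals, six temperatures (245–323 K), and 20
replicate chains; the pooled estimate forms K per temperature from summed
Y and W counts over replicates before the single OLS fit — the
low-variance version of the estimator.  Single-replicate fits at these
conditions have bootstrap SEs of several kJ mol⁻¹ on ΔH (the minor bonded
state is visited only a handful of times per chain at the temperature
extremes); the recovery contract is therefore statistical — truth within
3 bootstrap SE per replicate — while the pooled estimate lands within a
few percent.  The command-line `report` defaults to 5·10⁴ frames per
temperature for quicker turnaround; frames and dwell time are
configurable.

## Known limitations

* No mmCIF, no ANISOU, no symmetry-related contacts, no occupancy handling
  beyond the altloc rule.
* Distance-only H-bond criterion: over-inclusive versus angle-aware
  definitions; all partner-level claims are relative to the 3.5 Å default.
* Grid vdW volume is not a solvent-excluded or Voronoi volume; only trends
  should be compared across methods.
* The fixture's schematic geometry means B-factor and RMSF *profiles* have
  programmed, not physical, shapes; they exercise bookkeeping, ordering
  and normalization, nothing more.
* The bootstrap block length depends on an estimated autocorrelation time;
  for chains much shorter than ~20 dwell times the SE becomes unreliable
  and the code falls back to regression errors with a warning.
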