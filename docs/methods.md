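# Methods

This note records the model implemented by `parchscale`, the meaning and
default of every parameter, the numerical choices made where the method
description leaves freedom, what the synthetic generator does and does not
emulate, and the known limitations.

## Model and procedure

The parch protocol ranks residues of a folded protein by how tenaciously
they hold first-shell water under heating:

1. **System construction.** The protein is solvated with a thin water
   shell (not a full box of water: the point is that shell water can
   evaporate into vacuum as the system heats), neutralized with
   counterions placed far from the protein, and centred in a cubic box
   large enough that evaporated water does not immediately re-encounter
   the protein through periodic images.
2. **Annealing.** Constant-volume MD with the protein and ions position-
   restrained, temperature ramped linearly 300 → 800 K at 1 K per 10 ps
   (5 ns total). Restraints keep the conformation fixed so the signal is
   water kinetics, not unfolding. Running the MD is outside this
   package's scope; the package writes the input deck and consumes the
   trajectory.
3. **Counting.** For each residue and frame, the number of distinct water
   molecules with an atom (by default the oxygen) within `d_water` of any
   residue atom.
4. **Statistic.** Running-minimum monotonization of each count series,
   normalized autocorrelation, time-averaged autocorrelation C̄, and the
   parch value PV = 10 · C̄ / C̄_ref against a reference residue. Free
   lysine — the strongest water retainer among the free amino acids — is
   the calibration reference, so PV is anchored at 10 for
   lysine-like retention and at 0 for a residue that never contacts
   water.
5. **Reporting.** Low/medium/high categories with edges at PV = 0.1 and
   0.8, and a residue-type × PV-bin histogram (0.1-wide bins over [0, 3],
   with an explicit overflow warning for PV > 3).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `d_shell` | 0.415 | nm | solvation-shell thickness around the protein surface; thick enough for a full first hydration layer, thin enough to evaporate on the ramp |
| `shell_density` | 0.977 | g cm⁻³ | water density of the placed shell (slightly below bulk, appropriate for interfacial water at 300 K) |
| `clash_cutoff` | 0.24 | nm | minimum water–protein heavy-atom distance when tiling the shell; avoids steric overlap |
| `d_ion` | 3.0 | nm | counterion sphere sits this far outside the protein's radial extent d_max, so ions neutralize the box without perturbing the shell |
| `d_b` | 3.0 | nm | vacuum buffer between the ion sphere and the box face |
| box edge | 2·(d_max + d_ion + d_b) | nm | d_max is the largest residue-COG to protein-COG distance; the formula guarantees the buffer in every direction from the centred protein |
| `min_ion_separation` | 4.0 | nm | ions must be mutually far apart so no local field develops |
| restraint constant | 1000 | kJ mol⁻¹ nm⁻² | position restraints on all protein atoms and ions during the ramp |
| ramp | 300 → 800 K at 0.1 K ps⁻¹ | — | slow enough for quasi-equilibrium evaporation, hot enough to strip every residue by the end |
| `sample_interval_ps` | 50 | ps | count sampling period; 101 frames over the 5 ns ramp |
| `d_water` | 0.315 | nm | water-counting cutoff — the first minimum of the residue–water oxygen radial distribution function. Some write-ups of the protocol print this as 3.15 nm; that value is an order of magnitude larger than a hydrogen bond and inconsistent with a 0.415 nm shell, so 0.315 nm (the RDF first-shell distance) is the default. The parameter is fully configurable for users who want the literal printed value. |
| category edges | 0.1, 0.8 | PV | low/medium/high boundaries of the published scale |

## Numerical choices

- **Cutoff convention.** Counting uses an inclusive cutoff
  (distance ≤ `d_water`). Ties at exactly the cutoff are counted in.
- **Neighbour search.** `scipy.spatial.cKDTree` with `boxsize=` for
  periodic (minimum-image) queries; coordinates are wrapped into the box
  first. A vectorized brute-force minimum-image implementation ships in
  the same module (`method="brute"`) and the test suite asserts exact
  equality between the two on random systems, with and without PBC.
- **Monotonization.** `np.minimum.accumulate`. The test suite checks this
  against an exhaustive search for the largest non-increasing series
  bounded by the input, over all short integer series.
- **Autocorrelation.** FFT-free `np.correlate` with the unbiased
  1/(T−τ) normalization, then divided by the lag-0 value. An identically
  zero series (a residue that never sees water) is defined to have
  C(τ) ≡ 0, hence C̄ = 0 and PV = 0, rather than raising on 0/0.
- **Time average.** Trapezoid rule over all available lags,
  divided by τ_max (the largest lag). Closed-form limits are tested:
  a constant series gives C̄ = 1; a linearly decaying normalized ACF
  gives C̄ = 1/2.
- **Shell tiling.** A cubic lattice at the target-density spacing is
  coarser than the habitable shell (thickness d_shell − clash_cutoff ≈
  0.175 nm) and undersamples it. Instead, a 4×-finer jittered lattice is
  used as a volume quadrature (shell volume = number of habitable fine
  sites × fine-cell volume), and a seeded random subset of exactly
  round(volume × number density) sites is kept. This hits the target
  density to within a site, uniformly, for arbitrarily non-convex protein
  surfaces; tests compare against a Monte-Carlo volume oracle.
- **Ion placement.** Candidate points on the sphere of radius
  d_max + d_ion via a Fibonacci lattice, a seeded farthest-point greedy
  pick, then a short Thomson-style pairwise repulsion relaxation on the
  sphere. Greedy alone cannot reach the 4.0 nm pairwise floor when the
  required packing approaches the optimal spherical code (e.g. six ions
  on a ~3.2 nm sphere need near-octahedral placement); the relaxation
  finds it. If the floor is geometrically impossible the builder raises
  and suggests a larger `d_ion`.
- **Replicates.** With multiple count tables (trajectory replicates) the
  default policy averages C̄ across replicates before scaling
  (`mean-of-Cbar`); averaging the counts first is available as an
  alternative policy. For identical replicates the two commute, which is
  tested.
- **PV > 10.** Nothing forces C̄ ≤ C̄_ref for an arbitrary residue, so
  PV > 10 is possible; the package warns rather than clamps.

## What the synthetic generator emulates — and what it does not

`parchscale.synthetic` exists so every downstream stage can be tested
against known ground truth without an MD engine.

Emulated:

- Per-residue water counts that decay as the ramp passes a residue's
  characteristic **retention temperature** (a logistic in
  T − T_retention with width 30 K — a smooth stand-in for the sharp but
  noisy evaporation transition).
- Bounded integer counting noise (uniform in [−noise, +noise], clipped at
  zero). Its upward component is exactly what the monotonization step is
  designed to remove.
- Coordinate-level trajectories: one-atom residue "sites" on a line with
  waters that start inside the counting shell and, upon escape, teleport
  beyond 2.5·`d_water` and walk outward along a direction with a strong
  out-of-plane component, so an escaped water never crosses a
  neighbouring residue's shell. Sites are spaced at least 4·`d_water`
  apart, so the generator's survival ledger and the geometric count
  coincide exactly — an end-to-end oracle for the counter.

Not emulated: real water structure or dynamics, hydrogen bonding,
protein flexibility, re-adsorption of escaped water, ions, or any
temperature dependence beyond the logistic survival curve. The generator
validates the *pipeline*, not the physics.

Problem sizes in the tests and the reproduction script (numbers of
residues, waters per residue, batch sizes) are this package's own
choices, picked to exercise the code well within a single-CPU budget.

## Limitations

- **Dominance is not universal.** The normalized ACF of a non-increasing
  series can exceed the reference's at short lags
  (counterexample: η = [2, 2, 2, 2, 1] has C(1)/C(0) = 3.5/3.4 > 1), so
  C̄_i ≤ C̄_ref — and hence PV ≤ 10 — is only guaranteed for residues
  whose normalized ACF is pointwise dominated by the reference's. The
  reproduction script filters on that dominance condition explicitly;
  outside it, PV > 10 triggers a warning.
- The statistic inherits the protocol's assumptions: a rigid
  (restrained) protein, a thin shell rather than bulk solvent, and a
  specific ramp rate. Changing any of these changes the scale's
  calibration, including C̄_ref.
- PDB/GRO parsing is fixed-column and single-model-per-frame; exotic
  records (insertion codes beyond blank, multi-character altlocs) are not
  handled. Binary trajectory formats require registering an adapter.
- The builder places shell water as oxygen sites only; a downstream
  topology step must add hydrogens before running MD.
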