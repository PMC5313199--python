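# Methods

This note documents the model implemented by `replicadock`, the
parameter choices that matter, what the synthetic systems do and do not
emulate, and the numerical decisions a maintainer should know about.

## Units

Å, kcal/mol, ps, amu, Kelvin; k_B = 0.0019872041 kcal mol⁻¹ K⁻¹.
Accelerations use the conversion 1 kcal mol⁻¹ Å⁻¹ / amu = 418.4 Å ps⁻².

## Surface groups and the contact-pair list

The ambiguity restraint acts between two groups of solvent-exposed
heavy atoms chosen **once**, from the starting conformation, and held
fixed for the whole run.  An atom qualifies if its solvent-accessible
surface area is at least 10 Å² with a 1.5 Å probe, computed on the
*isolated* partner — so interface atoms of a bound starting pose still
count as surface.  Hydrogens are excluded from both the selection and
the occlusion calculation; for heavy-atom-only bead systems this is a
no-op, and for all-atom structures it makes the areas insensitive to
hydrogen placement.

SASA is evaluated by Shrake–Rupley sphere-point sampling on a fixed
Fibonacci lattice (default 960 points per atom).  The lattice is
deterministic, so selections are bit-reproducible; resolution-dependent
error at 960 points is well under the 2% level that matters for a 10 Å²
threshold.  Van der Waals radii come from the Bondi table; unknown
elements fall back to 1.7 Å with a warning.

At every dynamics step the restraint sums only over receptor–ligand
surface pairs strictly closer than 10 Å.  The pair list is rebuilt from
scratch each step (an O(N_r·N_l) distance matrix; group sizes here are
tens of atoms).  A pair crossing the cutoff changes the sum
discontinuously; the jump is negligible because an entering pair
contributes (d_min/10)¹² ≪ 1 to a sum dominated by the closest contact.

## The weighted ambiguity distance

With M the number of in-range pairs,

d_ave-p = [ (1/M) Σ_k d_k^(−p) ]^(−1/p),  p ∈ {6, 12}.

The defining formulas normalize by N_r·N_l, but the sum here is
restricted to the in-range pairs, and dividing the restricted sum by the
full group product would inflate d_ave above the scale of the window
bounds whenever few pairs are in range.  The default therefore divides
by the restricted count M, which keeps d_ave an actual distance: a
single contact at distance d gives d_ave = d regardless of group sizes.
The alternative normalization is available as
`normalization="full"`.

Numerics: the minimum distance is factored out,
d_ave-p = d_min·[(1/M) Σ (d_min/d_k)^p]^(−1/p), so only powers of ratios
≤ 1 are taken and the evaluation cannot overflow for d ≥ 0.05 Å
(distances below that raise).  The analytic gradient
∂d_ave/∂d_k = (d_min/d_k)^(p+1)·A^(−(p+1)/p)/M uses the same factoring.
Forces are strictly pairwise, so net force and net torque vanish
identically.

## Bias windows, ladder, guard

Each replica carries a flat-bottomed window (d_low, d_up) on d_ave-12:
zero inside, k_f(d_ave − bound)² outside; C¹ at both edges.  Ladder
invariants: d_low strictly increasing with replica index, consecutive
windows overlapping (d_low[i+1] < d_up[i]).  Three published
protein-scale ladders (6, 10 and 12 replicas, reference window
4.0/6.0 Å) ship verbatim under `LADDER_PRESETS`; they are stored with a
`verbatim` flag because published tables are not edited to satisfy
validators.

The dissociation guard activates exactly when the pair list is empty:
a harmonic restraint k(d_min − 10)² on the single closest surface pair
(ties broken toward the lowest (receptor, ligand) index pair), pulling
the partners back into restraint range.  The two textual descriptions
of the trigger differ ("every pair beyond 10 Å" vs "d_ave-12 > 10 Å");
the empty-pair-list reading is the default because under the restricted
normalization d_ave-12 never exceeds the largest in-range distance, so
the two conditions coincide there.  The alternative trigger is
available via `guard_trigger="d_ave"` and only behaves differently
under the full normalization.  The guard force constant defaults to the
replica's k_f.

## Engine

Bead-level force field: 12-6 Lennard-Jones cross terms between every
receptor and ligand bead (per-receptor-bead well depths encode sticky
sites), optional intra-ligand LJ, harmonic bonds, positional restraints
k|x − x_ref|² and pair-distance restraints k(d − d_ref)² (the Amber
convention without the ½, so a 0.5 kcal mol⁻¹ Å⁻² restraint displaced
2 Å stores 2.0 kcal/mol).  No non-bonded cutoff: the systems are tiny
and the reported receptor–ligand interaction energies are therefore
"infinite cutoff" values.

Integration is the BAOAB splitting of Langevin dynamics, chosen for its
configurational-sampling accuracy at practical time steps; with γ = 0
it reduces to velocity Verlet (drift ≤ 1e-4 kcal/mol over 10⁴ steps of
an LJ dimer at dt = 1e-4 ps).  Defaults: dt = 0.01 ps for beads of mass
12 amu (about 20 steps per period of the stiffest default site well),
γ = 0.1 ps⁻¹ (the low-viscosity thermostat setting of the original
protocol), T = 300 K.  A per-degree-of-freedom frozen mask supports
fixed beads and 1-D test systems.  All randomness flows through
explicit NumPy generators; trajectories are bit-reproducible by seed.

## Replica exchange

All replicas share temperature, force field and restraints; only the
bias window differs, so the Metropolis exponent reduces to the four
bias energies Δ = β[E_i(x_j) + E_j(x_i) − E_i(x_i) − E_j(x_j)].
Attempts alternate between even (0-1, 2-3, …) and odd (1-2, 3-4, …)
neighbour pairs at a configurable interval (default 250 steps; the
bead-scale protocols use 50 to exchange on the conformational
timescale of the small systems).  On acceptance, coordinates and
velocities move between replica slots while windows stay attached to
slots, so slot 0 is always the reference condition; velocities are not
rescaled (equal temperatures).  Each replica and the exchange-decision
stream draw from independent children of one master seed.  Replicas
run sequentially in-process; the contract (bitwise determinism for a
fixed seed) is what any future concurrent executor must preserve.

Correctness is validated where it can be validated exactly: on a
harmonic pair system whose mobile bead is confined to a line, the
per-replica stationary densities under any window (guard included) are
1-D quadratures, and 10⁵-sample runs match them within KS distance 0.03
(reference and biased replica alike).

## Synthetic systems

**Sticky shell.**  64 receptor beads on a 5 Å Fibonacci sphere
(spacing ≈ 2.2 Å < σ = 3 Å, so the shell is impenetrable), interior
filled with inert core beads — without the filling, the long attractive
LJ tails of a hollow shell make its centre the global minimum, which no
real protein has.  Core beads are buried and drop out of the surface
groups through the SASA selection.  One native site (ε = 15 kcal/mol)
and four decoys (ε = 6, ratio 2.5:1) are spread by farthest-point
selection; remaining beads get ε = 0.5.  The receptor is positionally
restrained (0.5 kcal mol⁻¹ Å⁻²), mirroring the backbone restraints used
to keep binding partners folded.  The ligand (a single bead by default;
bonded bead polygons are supported) starts antipodal to the native
site — with five maximally spread sites, one decoy sits almost exactly
at the start position, so an unbiased trajectory begins its search from
inside a trap.  Depths were calibrated once so that conventional
Langevin dynamics at 300 K traps at decoys on the benchmark timescale
(≈6.5 kcal/mol effective decoy well, escape times of order the full
budget) while the bias can still eject the ligand; the native basin
(−18 kcal/mol relaxed) holds on all timescales simulated.  Every
generated system carries a certificate: an exhaustive rigid placement
scan (surface and interior radii) must find its global minimum at the
declared native pose, which is itself the L-BFGS-relaxed bottom of that
basin.

The default ligand is a single bead because ligand RMSD is
atom-indexed: a symmetric bead polygon has index-permuted orientations
that are physically identical but register RMSDs of order the bond
length, which would blur the near-native statistics the benchmark
counts.

**Harmonic pair.**  One frozen bead plus one bead moving on a line,
with U = ½k(r − x₀)² implemented as a pair-distance restraint of
constant k/2; exact densities by quadrature, as above.  This is the
detailed-balance oracle.

**What the toys do not emulate:** conformational flexibility of the
partners, solvent, electrostatics, rugged all-atom energy landscapes,
and any specific chemistry.  Passing tests demonstrate that the bias,
exchange and analysis machinery are statistically and mechanically
correct and that the method's search advantage materializes on a
landscape engineered to exhibit the trapping failure mode — not that
any particular protein complex would be docked successfully.

## Ladder calibration

The bead-scale ladder `toy4` — (3.0, 6.0), (4.2, 5.4), (4.55, 5.75),
(4.9, 6.1) Å with k_f = 5 — was tuned once on the default sticky shell
and then frozen.  Two lessons from the calibration: (i) k_f at the
bottom of the usual range cannot eject a ligand from multi-kcal sticky
sites, so the toy ladder uses the top of the range; (ii) wide windows
produce bimodal bound/detached populations at the rung where ejection
first succeeds, collapsing exchange acceptance there — narrow, closely
spaced upper windows keep the transition gradual and every
neighbour-pair acceptance mid-range (0.3–0.75 in 50 000-step runs).
The reference window (3.0, 6.0) admits contact (d_ave-12 ≈ 3.4 Å at a
bound pose) without penalty.

## Benchmark protocol

Per seed, the replica-exchange arm runs 4 replicas × 25 000 steps; the
conventional-MD arm spends the identical budget as 4 independent
unbiased trajectories of 25 000 steps (with only the dissociation
tether active), the parallel-wall-clock analogue of comparing one REMD
run against a batch of plain-MD runs.  Success is a ligand RMSD below
one bead diameter (3 Å) in the reference replica (any trajectory, for
the cMD arm) before the budget; the benchmark reports per-arm success
counts over 10 seeds, first-passage steps, and near-native fractions.
Problem sizes (85 beads, 25 000 steps, 10 seeds) are chosen so the
whole benchmark runs in minutes on one CPU while leaving a wide margin
between the arms.

## Analysis conventions

Ligand RMSD superposes the receptor selection first (Kabsch via SVD,
proper rotation enforced) and never re-fits the ligand.  Near-native
fractions use strict `<` thresholds (2 and 4 Å by default) and
half-open frame windows.  Clustering is the deterministic leader
algorithm in trajectory order with a 4 Å pairwise ligand-RMSD radius —
the cheapest algorithm with a certifiable post-condition (every member
within the radius of its cluster leader); it is a documented choice,
not an inference about how anyone else clusters.  Interaction-energy
series contain the receptor–ligand cross LJ term only.

## Known limitations

- Replicas run sequentially; wall-clock scaling with replica count is
  linear.
- The toy engine has no electrostatics, implicit solvent or constraint
  algorithm; dt must resolve the stiffest LJ well (deep site wells at
  dt = 0.01 ps are near the comfort limit — the engine is validated at
  the shipped parameters, not arbitrary ones).
- PDB systems can be read, surface-selected and analyzed, but dynamics
  requires a bead force field; there is no all-atom backend.
- Free-energy estimates across replicas (reweighting) are out of scope.
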