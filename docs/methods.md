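# Methods

This note records the models implemented in `gpcrkit`, their assumptions,
the parameters that matter, and the design choices made where more than one
defensible construction existed.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Units and constants

Energies kcal/mol, lengths Å, time ps, masses amu, temperature K;
k_B = 0.0019872041 kcal mol⁻¹ K⁻¹; the single conversion needed for
dynamics is 1 kcal/mol = 418.4 amu Å² ps⁻². The default temperature is
310 K everywhere (NVT).

## Accelerated sampling (`gamd`)

**Boost.** Below a threshold E the potential is raised by
ΔV = ½ k (E − V)²; at or above E the boost is zero (both branches agree at
V = E exactly, so the boundary assignment is immaterial).  The force is
modified by pure rescaling, λ = 1 − k(E − V); in dual mode the total-term
scale multiplies the full force and the soft-term boost adds
(λ_soft − 1)·F_soft.

**Parameter selection.** From running statistics (V_max, V_min, V_avg, σ_V):
lower bound E = V_max with k₀ = min(1, (σ₀/σ_V)·(V_max−V_min)/(V_max−V_avg));
upper bound E = V_min + 1/k with k₀″ = (1 − σ₀/σ_V)·(V_max−V_min)/(V_avg−V_min),
accepted only if 0 < k₀″ ≤ 1 and otherwise falling back to the lower-bound
formula (the fallback convention of the original accelerated-sampling
literature).  Algebraic identities asserted in tests: the linearized boost
SD k(E−V_avg)σ_V never exceeds σ₀, and equals σ₀ exactly whenever the
selection is not clamped at k₀ = 1.  σ_V is the population SD (divide by
n), matching a running-moment implementation.

**Protocol.** Stage 1 (plain MD) accumulates statistics; stage 2 applies
the boost and re-selects (E, k) from *cumulative* statistics at a fixed
cadence — cumulative rather than windowed because it is monotone-stable and
the alternative is underdetermined; stage 3 freezes the parameters and runs
replicas that differ only in their velocity seeds, analyzed jointly.
Desk-scale defaults: 0.01 ps step, friction 1 ps⁻¹, re-selection every
10 000 steps (the production-scale convention of re-estimating every
800 000 steps scaled proportionally to stage length), σ₀ = 6 kcal/mol for
both terms, lower bound, dual boost for the bead model and single boost for
1-D systems.

**Integrator.** BAOAB splitting, chosen for accurate configurational
sampling near the stability limit; no energy-conservation claim is made
(Langevin).  Sampling accuracy is instead asserted via equipartition
(⟨x²⟩ = k_BT/κ within 5% on a harmonic well over 10⁶ steps) and a KS test
of the harmonic marginal against the analytic Gaussian.  Seeding: one
master seed spawns independent streams (SeedSequence) for the main
trajectory and each replica; identical seeds give bit-identical output, and
mode "none" reduces bit-exactly to plain Langevin dynamics.

## Reweighting (`reweight`)

Per included bin j: F(j) = −k_BT ln p*(j) − C(j), min-normalized, where
C(j) is either the second-order cumulant ⟨ΔV⟩_j + Var(ΔV)_j/2k_BT or the
exact, overflow-guarded log-mean-exp average (the brute-force oracle).
Bins with fewer frames than the cutoff are masked, never assigned a
ceiling.  Defaults follow the production conventions: bin sizes 1.0 Å for
distances and 6.0° for angles, cutoff 500 frames for 2-D surfaces; 1-D
surfaces default to 50 frames (no convention exists; configurable).
Blocked bootstrap over frames (200 resamples) supplies error bars on
request.

**Anharmonicity.** γ = ½ ln(2πe σ²) − H(ΔV), the entropy deficit relative
to a Gaussian of equal variance, with H estimated by the Vasicek spacing
estimator (scipy); zero-variance bins give γ = 0 by convention and the
trust threshold is 0.1.

**Where estimator equivalence is checked.** The cumulant-vs-exponential
agreement criterion is meaningful only where (a) per-bin boosts are
near-Gaussian and (b) the exponential average itself is well sampled —
⟨e^{βΔV}⟩ needs on the order of e^{(βσ)²} samples.  The desk-scale
mechanical toys violate one or the other: a 1-D potential makes the
per-bin boost a narrow slice of a deterministic function (shape-wise
uniform, γ ≈ 0.18 regardless of its tiny width), a 2-D one leaves it
visibly skewed (γ ≈ 0.9), and the 15-bead system reaches γ ≈ 0.03 but with
σ_ΔV ≈ 3 k_BT, beyond what the exponential oracle can average at 10⁵
frames.  The equivalence suite therefore uses controlled synthetic boosts
(per-bin Gaussian, σ ≈ 1 k_BT, 2×10⁵ frames — the multi-bin generalization
of the single-bin lognormal identity, which is also asserted separately),
plus a bead-model check that γ is small in the many-term regime where
cumulant reweighting is the trusted estimator.  This is a real limitation
of few-degree-of-freedom toys, not of the estimators.

**Basins.** Local minima are found by flooding bins in order of increasing
F with union-find merging; a minimum survives if separated from deeper ones
by a barrier of at least the depth threshold (persistence).  Nucleotide
displacement is classified Bound / Partially Released / Released with
default thresholds 5 and 10 Å, motivated by the ~8 Å vs ~12 Å excursion
contrast the analysis is meant to resolve.

## Synthetic systems (`potentials`, `helix`, spectrum/trace generators)

**Analytic potentials.** 1-D quartic double well V = a(x²−b²)² (barrier
a·b⁴) and 2-D sums of attractive Gaussian wells in a soft quartic box.
Reference free energies come from midpoint quadrature of exp(−V/k_BT) on
per-bin sub-grids that nest under bin refinement (≥400 points per
dimension changes the result by < 10⁻³ kcal/mol).  Forces are analytic and
checked against central differences to 10⁻⁴ relative everywhere.

**Bead model.** Five beads: a tethered core, a two-bead α5 arm whose hinge
angle has a quartic double well (defaults 110°/150°, 3 kcal/mol barrier),
an AHD bead whose polar orientation has a double well (20°/50°,
2 kcal/mol), and a nucleotide bead in a radial pocket: a shallow bound well
(1.5 kcal/mol, width 2.5 Å), a Gaussian barrier ring of height
`pocket_barrier` at 6 Å (width 1.2 Å) and a quartic wall at 13 Å.  The
"soft" (dihedral-analog) boost term collects the hinge, AHD and pocket
potentials; bonds, tether and wall form the rest.  The two presets differ
only in the ring height: 2 kcal/mol for the activated-like system and
12 kcal/mol for the intermediate-like one.  These are free design
parameters, set once from Kramers-rate estimates so that, at the stage
lengths used (5k/10k/35k steps, dual boost), a ~3 k_BT boosted ring is
crossed many times per run while a ~10 k_BT one is practically never
crossed yet still allows partial excursions into the 5–10 Å zone.  What
the passing contrast shows is that the pipeline resolves a designed
barrier difference under matched sampling; it says nothing about the
absolute barrier heights of any real G protein.

**Helix fixtures.** Ideal Cα helices (rise 1.5 Å, twist 100°, radius
2.3 Å by default) with a recorded ground-truth motion.  The spin
convention, used consistently by fixtures and the analysis, is clockwise
when looking down the N→C axis (deposited structures carry no viewpoint,
so the convention is stated rather than inferred; recovered magnitudes are
convention-independent).

**Spectra and traces.** Spectra are sums of area-parameterized Lorentzians
plus additive homoscedastic Gaussian noise scaled to the tallest peak;
FIDs are sums of decaying complex exponentials with decay rate π·FWHM;
kinetic traces add Gaussian noise to the ODE signal.  Homoscedastic
additive noise is the simplest model consistent with least-squares
fitting; real detectors (shot noise, baseline wander, photobleaching) are
out of scope, so passing recovery tests bound estimator error under ideal
noise, not instrument systematics.

## Structure analysis (`structure`, `selections`, `cv`, `compare`)

gemmi parses PDB and mmCIF (author numbering, so residues match published
numbers); altloc policy (highest occupancy by default) is applied exactly
once at read time.  Kabsch superposition is delegated to
scipy's `Rotation.align_vectors` with the post-fit RMSD recomputed
explicitly; the test suite checks it against an independent zooming
rotational grid search to 10⁻⁴ Å.

**Helix decomposition.** The axis is the principal direction of
sliding-window (4-residue) Cα midpoints, oriented N→C; spin is the
circular mean of paired-Cα angular offsets about the mean axis; retraction
is the centroid displacement projected on the axis, oriented away from the
core (the alignment-selection centroid) when one is available.

**Domain angle.** The Ras selection of the current model is aligned onto
the reference; the reported angle is between the AHD-center→anchor vector
of the aligned current structure and the same vector in the reference
(identical structures give 0°).  The Ras-center→anchor vector is validated
(degenerate-anchor errors) and fixes the opening plane; the absolute
within-structure angle between the two vectors is exposed separately as
`domain_opening_angle`.  A published variant constructs both vectors
against an inactive reference structure; that option is noted but not
implemented.

**Interactions.** Heavy-atom criteria (no hydrogens required): salt bridge
≤ 4.0 Å between charged-group atoms (Arg/Lys vs Asp/Glu), H-bond ≤ 3.5 Å
and weak H-bond ≤ 4.0 Å between donor and acceptor heavy atoms (each
residue pair classified once, by its shortest contact), cation-π ≤ 6.0 Å
and ≤ 30° off the ring normal, CH₃-π ≤ 4.5 Å to the ring centroid.  Ring
templates: 6-rings for Phe/Tyr and the Trp benzene ring, the His 5-ring.
Unknown residues are skipped with a warning, never silently.  Reports are
deterministic with canonical ordering.

**COM conventions.** Mass-weighted centers over all selected atoms by
default (geometric and Cα-only modes available); generic-position
(Ballesteros–Weinstein) numbering is always supplied by the caller as an
explicit map, never inferred from sequence.

## Kinetics (`kinetics`)

Scheme: P + N ⇌ P·N(site1) → P·N(site2), with site-2 entry access2·ktrans,
site-2 release access2·koff2 and irreversible hydrolysis khyd at site 2
only; free, site-1, site-2 and hydrolyzed pools for labeled and unlabeled
nucleotide, one nucleotide per protein.  The access2 scalar gates *both*
passages through the canonical-site gate: a steric restriction impedes
entry and exit alike, and this is what makes the chase half-time increase
monotonically as access2 decreases (entry-only gating provably gives the
opposite, because restricted access leaves the label parked in the
fast-off peripheral site).  Hydrolysis is taken as zero at site 1 ("low
affinity and hydrolysis" read as negligible hydrolysis there).  No rate
constant is asserted from experiment; all are free parameters.

Integration uses LSODA with rtol 10⁻¹⁰ and an absolute tolerance keyed to
the smallest relevant pool, which keeps nucleotide conservation at the
10⁻⁸ relative level and lets true pseudo-first-order setups match the
closed form k_obs = kon1·[L] + koff1 to 10⁻⁶.  Association fits run on a
unit-scaled signal (scale-free tolerances), two-phase fits order k_fast >
k_slow and carry an F-test against the nested one-phase form; rate
recovery from noisy traces refits the full ODE in log-rate space with
multi-starts.  Fluorescence is proportional to total bound labeled
nucleotide with unit gain; quench/enhancement photophysics are out of
scope.

## ¹⁹F processing and deconvolution (`nmr`)

Processing is zero-filling (integer factor) followed by FFT and zero-order
phasing (synthetic data are phase-correct by construction; first-point
artifacts are absorbed by the fitted baseline).  Exponential apodization
multiplies by e^(−π·LB·t) and adds LB to every Lorentzian width — asserted
as 15 ± 1 Hz on a 30 Hz line, the processing convention of ¹⁹F receptor
work (200 ms acquisition, 15 kHz spectral width defaults).

Deconvolution fits area-parameterized Lorentzians (areas, not heights,
because populations are the quantity of interest and their covariance is
then direct) on a flat (default) or linear baseline, initialized by peak
picking after light smoothing with five jittered multi-starts.  Population
SDs come from the residual-variance-scaled parameter covariance through
the delta method for normalized fractions.  A pure Lorentzian lineshape is
assumed (consistent with exponential apodization); Voigt profiles are not
modeled.  Pairs whose lineshape correlation exceeds 0.45 flag the report
ill-conditioned — populations are still returned, with the covariance
already inflated.  Linewidth comparison calls a resonance "broadened" when
ΔFWHM exceeds twice its propagated SD.

## Problem sizes

Chosen so the full suite and the acceptance script each run in minutes on
one CPU: 2×10⁶ total steps for the double-well pipeline (three production
replicas), 20 paired 50k-step runs for the release contrast, 50 seeds for
kinetic-rate and population recovery, 10⁵–2×10⁵ samples for estimator and
entropy checks.  These sizes leave comfortable statistical margins for
every tolerance asserted; enlarging them tightens nothing qualitative.

## Known limitations

- Few-dof toys cannot exhibit the near-Gaussian total-energy fluctuations
  of solvated all-atom systems; see the estimator-equivalence note above.
- The bead model's released state is bounded by a wall at 13 Å, so maximum
  displacements saturate near 13–14 Å by construction.
- The helix spin/retraction decomposition assumes an essentially rigid
  helix; large internal deformations would mix tilt and spin.
- Interaction detection is geometric only — no energetics, no hydrogen
  positions, no solvent screening.
- The kinetics scheme enforces one nucleotide per protein; simultaneous
  double occupancy of both sites is not modeled, and the physical identity
  of the peripheral site is deliberately left open.
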