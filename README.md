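# gpcrkit

A desk-scale Python toolkit for the computational characterization of
**intermediate GPCR–G-protein complexes** — the partially coupled states a
receptor passes through between the inactive receptor and the fully
activated nucleotide-free ternary complex.  It is aimed at structural
biologists and simulators who want tested, reproducible implementations of
the four analyses this problem typically combines:

1. **Gaussian-accelerated enhanced sampling with energetic reweighting.**
   A harmonic boost ΔV(V) = ½ k (E − V)² is added wherever the potential V
   falls below a threshold E, with (E, k) chosen from running potential
   statistics so that k₀ = k (V_max − V_min) ∈ (0, 1] and the boost SD stays
   below a user limit σ₀ (here 6 kcal/mol, the dual-boost convention: one
   boost on the soft conformational term, one on the total potential).
   Unbiased free-energy surfaces over collective variables are recovered per
   histogram bin by second-order cumulant reweighting,
   F(ξ) = −k_BT ln p*(ξ) − [⟨ΔV⟩_ξ + Var(ΔV)_ξ / 2k_BT],
   cross-checked against an exact log-mean-exp estimator and an
   anharmonicity (entropy-deficit) diagnostic γ.  Dynamics are BAOAB
   Langevin at 310 K with a 1 ps⁻¹ thermostat.

2. **Inter-state structural geometry.**  PDB/mmCIF reading (gemmi), Kabsch
   superposition, helix-axis extraction and the decomposition of a helix
   motion into axis tilt, about-axis spin and axial retraction (the
   α5-helix of Gα retracts ~2 Å and spins ~2° between the intermediate and
   fully activated complexes); detection of salt bridges, strong/weak
   hydrogen bonds, cation-π and CH₃-π contacts; conserved microswitch
   (PIF, Y–Y lock, CWxP) reports; COM/Cα reaction coordinates and the
   AHD–Ras domain-orientation angle.

3. **Two-site nucleotide-exchange kinetics.**  A mass-action ODE scheme in
   which nucleotide binds a peripheral site 1 (kon1/koff1) and relocates
   through a sterically gated opening into the canonical site 2
   (access2·ktrans in, access2·koff2 out, irreversible hydrolysis khyd at
   site 2), with one-/two-phase association fitting (y = y₀ + A(1 −
   e^(−k_obs t)), F-test for the second phase) and GDP→GTP chase half-times.

4. **¹⁹F spectrum deconvolution.**  FID synthesis, zero-filling,
   exponential apodization (LB Hz adds LB to every Lorentzian width), and
   least-squares deconvolution into area-parameterized Lorentzians whose
   normalized areas are conformational-state populations with
   covariance-derived uncertainties.

All-atom simulation systems and wet-lab data are replaced by a first-class
synthetic-systems module: analytic double/multi-well potentials with
numerically exact quadrature reference free energies, a five-bead
receptor–G-protein caricature (α5 hinge, AHD orientation well, nucleotide
pocket with tunable escape barrier), ideal-helix fixtures with ground-truth
transforms, and synthetic spectra/kinetic traces with stored truth.

## Worked example

```bash
python examples/01_accelerated_double_well.py
```

prints, for a 1 kcal/mol double well sampled with the staged protocol
(50k-step plain MD for statistics, 100k-step boosted equilibration, 3 ×
200k-step production replicas):

```
boost parameters: E = 6.904 kcal/mol, k0 = 1.000
60000 production frames over 3 replicas
max |reweighted - exact| on bins below 3 kcal/mol: 0.084 kcal/mol
```

k₀ = 1 means the selection was clamped at the maximal allowed acceleration
(the boost SD stayed well under σ₀ on this small system); the last line is
the end-to-end error of sampling + boosting + cumulant reweighting against
the exact quadrature profile — an order of magnitude below thermal energy,
i.e. the boost is fully corrected for.  The other examples cover the
nucleotide-release contrast in the bead model, helix spin/retraction
recovery, interaction detection, exchange kinetics and spectrum
deconvolution, each printing the numbers it computes and one line on what
they mean.

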