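# Methods

## Scope and model hierarchy

memscale implements a three-tier description of protein–membrane
association: a coarse-grained (CG) tier in which ~4 heavy atoms map to
one interaction bead and a minimal MD engine samples membrane
self-assembly and interfacial anchoring; an atomistic tier that is only
*constructed* (back-mapped, solvated, ionized) — atomistic dynamics is
delegated to external engines by design; and an analysis tier that
quantifies the resulting complexes and confronts them with
deuterium-exchange (DXMS) protection data.

## Units

One internal unit system throughout: Å, fs, amu, kJ mol⁻¹, K, bar, e.
The two non-trivial conversion factors (force→acceleration 10⁻⁴
Å fs⁻² per (kJ mol⁻¹ Å⁻¹)/amu; kinetic energy 10⁴ kJ mol⁻¹ per
amu Å² fs⁻²) and the pressure conversion live only in
`memscale/units.py`.

## Coarse-grained mapping

One backbone bead per residue at the centre of mass of the backbone
atoms present (N, CA, C, O); 0–2 side-chain beads per residue at the
centre of mass of template-defined parent atoms.  Placing the backbone
bead at the backbone c.o.m. (rather than at CA) follows the 4:1
philosophy consistently; the back-mapper compensates, fitting Cα atoms
onto the beads, and the resulting sub-Å systematic offset is absorbed
by the least-squares fit.  Bead masses are sums of matched parent-atom
masses, so mapped mass, per-residue centres of mass, and molecular
charge (for zwitterionic species) are conserved exactly — these are
tested invariants.  The residue → bead tables are packaged data
(`memscale/data/protein_beads.txt`, `lipids.txt`), not code: classes
follow side-chain hydrophobicity (aromatic/aliphatic → C, small polar →
P, Asp/Glu/Lys/Arg termini → Q ± 1), large side chains get two beads.
They are editable and deliberately *not* a reproduction of any
published CG parameter set.

## Elastic network

Harmonic restraints E = ½k(r−r₀)² with k = 10 kJ mol⁻¹ Å⁻² between all
backbone-bead pairs within 7 Å in the reference structure.  The ½k
convention is stated explicitly because "force constant" is ambiguous
by a factor of two.  Sequence-adjacent pairs are excluded by default —
they are already held by backbone bonds — with `include_bonded=True` as
the alternative reading.  Side-chain beads never participate.

## CG engine

**Nonbonded terms.** 12-6 LJ and screened Coulomb (uniform relative
dielectric ε_r = 15), each multiplied into the standard cubic/quartic
force-shift polynomial: for an inverse-power term 1/r^α, F(r) = α/r^(α+1)
+ A(r−r₁)² + B(r−r₁)³ on (r₁, r_c) with A, B solved from
F(r_c) = F′(r_c) = 0 and the energy constant from V(r_c) = 0.  LJ uses
(r₁, r_c) = (9, 12) Å, Coulomb (0, 12) Å.  The coefficients are solved
numerically from the boundary conditions at force-field construction
and validated against the closed form and numerical differentiation in
the tests.  Energy and force are continuous everywhere and identically
zero beyond 12 Å.

**Integration.** Leapfrog at dt = 25 fs.  On-step velocities for
reporting are reconstructed as v(t) = v(t−dt/2) + (dt/2)a(t); with the
thermostat off this gives a secular energy drift of ~2×10⁻³
kJ mol⁻¹ bead⁻¹ per 10⁴ steps on the packaged toy system (measured by
the acceptance script as the linear-fit slope — the conserved-quantity
criterion).

**Thermostat.** Stochastic velocity rescaling toward the target kinetic
energy K̄ = ½N_df k_B T with the exact rescaling factor
α² = (√c + √((1−c)K̄/(N_df K))·R₁)² + (1−c)(K̄/(N_df K))·S,
c = e^(−dt/τ), R₁ ~ N(0,1), S ~ χ²(N_df−1); τ defaults to 1 ps (the
cited thermostat family leaves τ free).  This samples the canonical
kinetic-energy distribution rather than merely clamping T.

**Barostat.** First-order Berendsen scaling per box axis,
μ_a = 1 − (κ·dt)/(3τ_p)·(p_ref − P_aa), from the instantaneous
pressure-tensor diagonal (kinetic + pairwise virial); τ_p = 10 ps,
κ = 3×10⁻⁵ bar⁻¹, p_ref = 1 bar.  μ = 1 exactly at P = p_ref, and μ is
clamped to [0.98, 1.02] per step for robustness.  Axes scale
independently ("anisotropic"); a semi-isotropic option collapses the
diagonal to its mean.

**Neighbor search.** KD-tree over wrapped coordinates with a 2 Å Verlet
skin, rebuilt when any bead moves beyond skin/2 or the box changes by
more than 0.5 %; bonded 1–2 and angle 1–3 pairs are excluded from
nonbonded interactions.  Minimum-image convention, orthorhombic boxes.

**Minimization.** Steepest descent with an adaptive step (accepted ×1.2,
rejected ×0.2) and per-bead force capping so randomly built boxes with
hard-core overlaps start finite; 5000 steps by default.

**Determinism.** All stochastic elements draw from one
`numpy.random.Generator` seeded by `IntegratorConfig.seed`; identical
seeds give bitwise-identical trajectories.

## Toy force field and fixture calibration

The packaged class table (`memscale/data/toy_forcefield.txt`) is the
package's own reduced parameter set: σ = 4.7 Å everywhere, ε between
1.2 and 4.5 kJ mol⁻¹, bead mass 54 amu.  It was chosen once so that
the behavioral contract holds at desk scale — the toy lipid (one
intermediate-polarity head bead, three apolar tail beads)
self-assembles into a bilayer from a random box within ~15 000 × 25 fs
steps, and an amphipathic helix at the bilayer surface orients its
hydrophobic face toward the tails.  The load-bearing contrasts are
C–W ≪ C–C (hydrophobic effect) and P–W ≥ P–head (polar face prefers
water, hydrophobic face gains tail contacts).  Behavior, not any
particular ε value, is the contract; the table is data and swappable.

Problem sizes used by the tests and the acceptance script: 64-lipid +
200-water random boxes (38 Å box) for self-assembly, 15 000 steps,
5 seeds; a 72-lipid pre-formed bilayer + helix + lattice water
(~460 beads) for anchoring, 9 000 steps, 5 seeds; 38-bead boxes for the
NVE (10⁴ steps) and thermostat (10⁵ steps) checks.  These sizes give
each stochastic check a few minutes of compute while leaving the
physics qualitatively intact.

## What the fixtures emulate — and what they do not

The fixtures reproduce the *structure* of the study system: a
332-residue-scale protein numbered in full-protein coordinates (so
ranges like 710–724 work verbatim), an anchor helix whose hydrophobic
residues (711, 714, 715, 717, 721, 722) cluster on one helical face,
POPC-like and toy lipids, random self-assembly boxes, and a DXMS
fragment pattern with one strongly protected anchor fragment (708–730)
and three weakly protected cavity fragments.  They do not emulate real
force-field energetics, lipid conformational entropy, secondary
structure formation, or exchange kinetics.  Consequently, passing tests
demonstrate correctness of the algorithms and the qualitative physics
(self-assembly, amphipathic orientation, tense-state relaxation,
protection-pattern discrimination) — not quantitative agreement with
production-scale simulations of the real enzyme.  Headline
production-scale numbers (insertion angle 67 ± 8°, microsecond
anchoring times, 18.9 Å phosphate peak) are therefore *not* asserted
anywhere; the per-residue depth table of the anchor region is shipped
as published reference data and the package recomputes its class
summaries from the rows.

## Analysis conventions

* **Membrane frame** — bilayer centre = lipid z-c.o.m.; leaflet planes =
  mean phosphate z after a two-means split; the normal is +z by
  convention.
* **Insertion angle** — principal direction (largest singular vector) of
  the centred helix coordinates vs the membrane plane, folded into
  [0°, 90°] since the SVD axis sign is arbitrary.  The estimator carries
  a small bias from the helical pitch (≈0.4° for a 36-residue helix,
  ≈1.7° for 18 residues), which bounds fixture lengths in the tests.
* **Depth** — anchor-region depth uses the z-c.o.m. of Cα atoms;
  per-residue tables use the side-chain c.o.m. (whole-residue as the
  documented fallback), matching the two stated definitions where each
  applies.  Standard deviations over frames use the population (÷N)
  convention.
* **H-bonds** — donor–acceptor ≤ 3.5 Å and donor–H···acceptor ≥ 150°
  (common practice; configurable); a distance-only mode serves models
  without hydrogens.
* **Implicit probe map** — single-site LJ probe (methane-like defaults
  ε = 1.23 kJ mol⁻¹, σ = 3.73 Å), Lorentz–Berthelot combination, 12 Å
  cutoff, Boltzmann-averaged over frames; orientational averaging is a
  no-op for a spherical probe.  ΔE is clamped at 500 k_BT before
  exponentiation; never-accessible voxels are +∞.  Grid spacing below
  0.1 Å is refused as a resource guard.
* **Burial** — depth rule: side-chain c.o.m. beyond the proximal
  leaflet's phosphate plane (the leaflet on the protein's side); SASA
  rule (atomistic models only): per-residue solvent-accessible area
  below a threshold with a 1.4 Å probe.

## DXMS consistency score

Exchange data are fragment-level and qualitative; the score makes them
quantitative in a declared, configurable way.  Fragments classify by
decrement: ≥70 % strong, (0, 40) % weak, [40, 70) % intermediate, 0 %
none.  A fragment is predicted protected when its mean per-residue
burial fraction ≥ 0.5.  Strong↔protected and none↔exposed matches carry
weight 1; weak/intermediate fragments carry weight ½ and match when
partially buried (0 < fraction < 0.5), reflecting the transient-lipid
interpretation of weak protection.  The overall score is matched weight
over total weight.  This construction is the package's own; absolute
deuterium-exchange counts are deliberately not modelled, since mapping
burial to exchange numbers would require a rate model the data here do
not constrain.

## Numerical and degenerate-input choices

Two-means leaflet splits refuse separations under 5 Å; insertion angle
refuses <4 points or coincident points; empty density groups return
flat zero profiles with a warning; residues without side-chain atoms
fall back to whole-residue c.o.m. with a warning; fragments outside the
model are listed unscored; a protein touching the membrane yields an
empty water-exclusion region with a warning.  The 0.6 Å lipid-pruning
criterion is a strict any-atom inequality.  Ion counts are
round(c·N_A·V_solvent) per species plus counter-ions for the net solute
charge; "42 of each species" corresponds to ~0.1 mol/L in the ~7×10⁵ Å³
solvent volume of the reference build.

## Known limitations

Orthorhombic boxes only; no Ewald electrostatics (the CG model is
cutoff-based by construction); no constraint algorithms (atomistic
dynamics is out of scope); single-threaded; the engine is a reference
implementation tuned for hundreds to ~a thousand beads, not a
production MD code.  CG time is reported unscaled; diffusive dynamics
of CG water models is known to run ~4× faster than real water, and a
reporting convention for that factor is left to the caller.
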