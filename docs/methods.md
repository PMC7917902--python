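# Methods

## The system

`dendrisorb` models the adsorption of a single silicon-containing dendrimer
onto a flat, impenetrable, weakly attractive surface.  Four homologous
series are built programmatically:

| series | core | spacer | branching point | end segments |
|--------|------|--------|-----------------|--------------|
| C4 | Si, f_c = 4 | –(CH₂)₃– | ≡Si(CH₃) | two butyls –(CH₂)₃–CH₃ |
| C3 | Si(CH₃), f_c = 3 | –(CH₂)₃– | ≡Si(CH₃) | two butyls |
| S  | Si(CH₃), f_c = 3 | –O– | ≡Si(CH₃) | two methyls (Si(CH₃)₃) |
| L  | Si(CH₃), f_c = 3 | –O–Si(CH₃)₂–O– | ≡Si(CH₃) | two methyls |

CH₂ and CH₃ are united atoms (14.027 / 15.035 Da); Si and O are explicit
(28.086 / 15.999 Da).  A generation-G molecule is a tree: the core carries
f_c dendrons, every branching Si carries one methyl and two outgoing
spacers, repeated to depth G, where the branching Si instead carry two
terminal segments.  Closed forms follow: f_c·2^(k−1) branching Si at depth
k and f_c·2^G terminal segments.

**Structural layers.**  Layer 0 is the core atom plus its outgoing spacers;
layer k ≥ 1 is the set of depth-k branching Si, their methyls and their
outgoing spacers (at k = G, their terminal segments).  Equivalently — and
this is how `assign_layers` recomputes labels independently of the builder —
an atom's layer is the number of branching Si on its path from the core,
itself included.  Interior layers double exactly from layer 2 on; the
terminal layer deviates from exact doubling because the end-group chemistry
differs from the spacer chemistry (butyls are heavier than one spacer,
methyl caps lighter), which is why the doubling checks in the tests stop at
the last interior layer for the C and L series.

**Open choices made here.**  The core of the three-functional series
carries one methyl to fill the Si valence.  Depth-G carbosilane Si carry
two butyls each.  Both choices are configuration-level conventions; none of
the adsorption observables depend on them qualitatively.

## Potential energy

All terms act between united atoms:

* bonds: U12 = Σ k_b (b − b₀)², harmonic;
* angles: U13 = Σ k_θ (θ − θ₀)², harmonic;
* torsions: U14 = Σ k_φ (1 + cos 3φ), carbosilane backbones only;
* van der Waals: Uvw, Lennard-Jones 12-6 with Lorentz–Berthelot mixing,
  10.5 Å cutoff, energy-shifted to zero at the cutoff, 1-2/1-3 pairs
  excluded, 1-4 pairs scaled by 0.5;
* electrostatics: Uqq, screened Coulomb with a distance-dependent
  dielectric (U ∝ q_i q_j / r²), also truncated-and-shifted.  Carbosilanes
  carry no charges; siloxanes use q_O = −0.4 e with the compensating +0.2 e
  per Si–O bond on silicon, so every molecule is neutral.

Parameter values (in `src/dendrisorb/data/default_forcefield.yaml`) are
nominal united-atom literature values for Si–C/Si–O/C–C chemistry — e.g.
C–C 1.53 Å / 310 kcal mol⁻¹ Å⁻², Si–O 1.64 Å / 350, tetrahedral angles at
109.47°, a soft Si–O–Si angle at 144° (15 kcal mol⁻¹ rad⁻²), OPLS-UA-like
LJ wells.  They are deliberately configuration, not fitted constants: every
conclusion the package draws is a trend or a conservation law, not an
absolute energy.

**The adsorbing wall** is the 9-3 potential

    U_ads(z) = 0.5 ε ((R_min/z)⁹ − 3 (R_min/z)³),

the lateral integral of an atom–half-space LJ attraction, acting on every
united atom identically with R_min = 3 Å and a 130 Å cutoff (far beyond the
largest molecule, so the whole dendrimer feels the wall).  Its minimum is
−ε at z = R_min, its zero at R_min·3^(−1/6) ≈ 2.498 Å; the plane at z = 0
is impenetrable (reaching z ≤ 0 aborts the run).  The working range of the
study is ε = 0.4–3 kcal/mol: below 0.4 adsorption is intermittent, above
≈ 3–5 the wall visibly deforms bonds and angles and the harmonic force
field stops being trustworthy — the per-atom energy audit quantifies
exactly this.

## Dynamics

Velocity-Verlet integration at dt = 1 fs (the stiffest bond period is
≈ 33 fs) in units Å / ps / Da / kcal mol⁻¹.  A Verlet pair list
(1.5 Å skin, rebuilt every 25 steps) accelerates the non-bonded sum; the
drift between rebuilds is an order of magnitude below the skin.

Temperature is held at 350 K by a collisional thermostat: each step, every
atom independently collides with probability λ·dt with a virtual particle
of mass m₀ = 1 Da whose velocity is Maxwell-distributed at T; the elastic
collision v′ = ((m − m₀)v + 2m₀u)/(m + m₀) conserves the pair momentum.
λ = 55 ps⁻¹ by default.  With λ = 0 the integrator is plain NVE and
conserves energy to < 0.1 % of the kinetic energy over 10⁴ steps (tested).

**Protocol.**  (1) *relax*: free-space equilibration of the embedded
molecule.  (2) *adsorb*: the equilibrated molecule is rotated uniformly at
random, translated so its lowest atom sits 5 Å above the plane — the gap
is configurable; 5 Å starts the closest atoms at the edge of the
adsorption layer — and integrated with the wall on.
Observables are averaged over a trailing production window and over
replicas that share the equilibrated structure but differ in orientation,
initial velocities and thermostat noise; replica SEM uses n−1.

## Initial structures

Conformations are embedded by recursive placement — equilibrium bond
lengths, per-type equilibrium valence angles, random torsions — followed by
staged relaxation: steepest descent on LJ cores scaled to 0.8 σ, steepest
descent on the full potential, and (for dense high-generation globules that
remain entangled) a short 2 ps thermostatted push-off on the softened cores
before a final minimisation.  An embedding is accepted when every bond is
within 10 % of b₀ and no non-excluded pair is closer than 0.8 σ_ij.  The
whole procedure is deterministic in the seed.

## Observables

* **Contacts**: an atom is adsorbed when z ≤ 5 Å (boundary inclusive).
  M is the adsorbed count, M/N the fraction; per-layer counts partition M.
* **Perpendicular profile** ρ⊥(H): mass per flat slab of width dH = 0.2 Å —
  a linear density (Da/Å) whose integral is the molecular mass.
* **Parallel profile** ρ∥(R): mass per annulus of width dR = 1 Å around
  the *instantaneous* lateral centre of mass (recomputed per frame so
  lateral diffusion does not smear the profile), divided by the annulus
  area.  Σ ρ∥ S_i likewise recovers the molecular mass.
* **Energy audit**: per-atom means of U12…Uqq over the production window
  per ε, with percent changes relative to the unadsorbed ε = 0 reference,
  (⟨U⟩_ε − ⟨U⟩₀)/|⟨U⟩₀| × 100.  The wall term is excluded from the
  percent comparison.
* **Shape**: mass-weighted gyration tensor eigenvalues, Rg, height
  (max z − min z), in-plane radius, asphericity λ₃ − (λ₁ + λ₂)/2.

## Problem sizes and what the tests show

The full study design — G4–G7, 20 ns trajectories, eight replicas, the ε
schedule 0→1 by 0.2 and 1→3 by 0.5 — is expressible in one `StudyConfig`
and is what `run_study` executes given cluster time.  The shipped tests and
the acceptance script run the same physics at desk scale: G2–G5,
0.04–0.5 ns, one to three replicas, chosen so the whole
suite fits in minutes on one CPU.  At this scale the package demonstrates:

* ⟨M⟩ grows with ε (C4 G2; means ≈ 2 → 14 → 38 across ε = 0.4/1.5/3);
* ⟨M/N⟩ falls with generation at fixed ε (S series G2→G4);
* carbosilanes adsorb through their peripheral layers — the per-layer
  contact fraction increases monotonically with the layer index (C4 G3);
* at matched generation (G4) and strong adsorption the short-spacer
  S-dendrimer keeps a smaller contact fraction than the spreading
  long-spacer L-dendrimer — the contrast needs ≈ 0.5 ns and replica
  averaging to emerge because the L-series spreads slowly and its
  spreading rate varies strongly with the starting orientation;
* bonded deformation grows with the wall strength once ε ≳ 5 (per-atom
  U13 and Uvw percent changes vs ε ∈ {0, 5, 10}).

Short trajectories measure adsorption *onset*, not the fully spread
equilibrium state; the absolute M/N values here are therefore lower bounds
on the long-time values, and quantities reported by the acceptance script
are stochastic estimates under this scaled-down protocol.  Equally, the
nominal force field means absolute energies are not comparable to runs with
the original (unpublished) AMBER/PCFF parameterisation — which is why every
acceptance check is a property, trend, conservation law or analytic value
rather than an absolute-number match.

## Numerical choices

* Non-bonded truncation is energy-shifted (continuous energy, negligible
  force discontinuity) to keep NVE conservation clean; the LJ contact
  minimum therefore sits ~1 % above −ε at the default 10.5 Å cutoff.
* Angle forces guard the sin θ denominator at 10⁻⁸; torsion forces use the
  standard two-normal formulation and skip degenerate (collinear) frames.
* Replica seeds derive from `SeedSequence(master, series, generation, ε,
  replica)`, keeping runs independent yet bit-reproducible; all seeds stay
  below 2³¹.
* Density histograms use `numpy.histogram` with bin edges anchored at 0, so
  rebinning conserves mass exactly.
* SEM is reported only for ≥ 2 replicas.

## Known limitations

Single molecule in vacuum above an unstructured wall: no solvent, no
surface corrugation, no distinction between atom types in the wall
interaction (by design), no periodic boundaries, no long-range
electrostatics.  Generations above 7 are unsupported by default.  The
embedding is a structure generator, not a conformational sampler — the
relax stage is what produces equilibrated ensembles.
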