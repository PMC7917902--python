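# Nominal united-atom force field for silicon-containing dendrimers.
# Energies kcal/mol, lengths Å, angles degrees.  These are representative
# literature values for Si-C / Si-O / C-C chemistry (harmonic bonds and
# angles, OPLS-UA-like Lennard-Jones, 3-fold torsions for the carbosilane
# backbone); every entry is configuration, not a fitted constant.
bonds:
  C-C:  {b0: 1.53, k: 310.0}
  C-Si: {b0: 1.87, k: 190.0}
  O-Si: {b0: 1.64, k: 350.0}
angles:
  C-C-C:   {theta0: 112.0, k: 60.0}
  C-C-Si:  {theta0: 112.0, k: 50.0}
  C-Si-C:  {theta0: 109.47, k: 50.0}
  Si-O-Si: {theta0: 144.0, k: 15.0}
  O-Si-O:  {theta0: 109.47, k: 70.0}
  C-Si-O:  {theta0: 109.47, k: 50.0}
dihedrals:
  X-X-X-X: {k: 0.7, n: 3, delta: 0.0}
lj:
  CH3: {epsilon: 0.175, sigma: 3.905}
  CH2: {epsilon: 0.118, sigma: 3.905}
  Si:  {epsilon: 0.200, sigma: 4.000}
  O:   {epsilon: 0.150, sigma: 3.000}
nonbonded:
  cutoff: 10.5
  scale14: 0.5
  dielectric_scale: 1.0   # screened Coulomb: U = C q_i q_j / (s · r²)
  shift: true             # energy-shift LJ and Coulomb to zero at the cutoff
wall:
  epsilon: 1.0
  r_min: 3.0
  cutoff: 130.0
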