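"""Internal unit system: length Å, time ps, mass Da, energy kcal/mol.

In these units 1 kcal/mol = 418.4 Da Å²/ps², so forces in kcal/mol/Å are
multiplied by :data:`KCAL_TO_INTERNAL` before dividing by mass to get
accelerations in Å/ps².
"""

#: Da Å²/ps² per kcal/mol  (4184 J/mol ÷ 10 J/mol per Da Å²/ps²)
KCAL_TO_INTERNAL = 418.4

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: Coulomb prefactor, kcal Å / (mol e²)
COULOMB = 332.0637

#: fs → ps
FS = 1e-3
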