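"""Per-atom potential-energy audit versus adsorption strength.

Runs C4 G2 at ε ∈ {0, 5, 10} (the wide range over which bonded deformation
becomes visible above thermal noise at this scale) and tabulates each
energy term per atom together with its percent change relative to the
unadsorbed ε = 0 reference.  Writes results/energy_audit.csv.

The audit is the model-validity check of the study design: bond and angle
terms must stay nearly unperturbed in the working window ε ≤ 3 for the
harmonic force field to remain trustworthy, while at ε ≳ 5 the wall
visibly deforms the internal geometry.
"""

import pathlib

import pandas as pd

from dendrisorb.analysis import energy_audit
from dendrisorb.forcefield import ForceFieldParams
from dendrisorb.protocols import adsorption_sweep

pathlib.Path("results").mkdir(exist_ok=True)

ff = ForceFieldParams.default()
trajs = adsorption_sweep("C4", 2, [0.0, 5.0, 10.0], seeds=[11, 22],
                         relax_ps=10.0, adsorb_ps=60.0, ff=ff, base_seed=101)

# average the two replicas term by term before the percent comparison
tables = []
for rep in (0, 1):
    tables.append(energy_audit({e: trajs[(e, rep)] for e in (0.0, 5.0, 10.0)},
                               production=0.5))
table = (tables[0] + tables[1]) / 2.0
table.round(4).to_csv("results/energy_audit.csv")
print(table.round(3).to_string())
print("""
Bond (U12) and angle (U13) energies grow with ε as the wall flattens the
molecule against the surface; van der Waals energy (Uvw) responds as
neighbour shells rearrange.  The percent changes quantify how far the
harmonic approximation is being stretched at each adsorption strength.
""")
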