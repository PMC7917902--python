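"""Characterise the 9-3 adsorption wall over the study's ε schedule.

For each ε the potential U(z) = 0.5 ε ((R_min/z)^9 − 3 (R_min/z)^3) has its
minimum at z = R_min = 3 Å with depth −ε and crosses zero at
z = R_min·3^(−1/6) ≈ 2.673 Å.  Writes results/wall_potential.csv.
"""

import pathlib

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from dendrisorb import WallParams, wall_energy_force
from dendrisorb.pipeline import EPSILON_SCHEDULE

pathlib.Path("results").mkdir(exist_ok=True)

rows = []
for eps in EPSILON_SCHEDULE:
    wall = WallParams(epsilon=eps)
    if eps > 0:
        zmin = minimize_scalar(lambda z: wall_energy_force(z, wall)[0],
                               bounds=(1.0, 10.0), method="bounded").x
        zzero = brentq(lambda z: wall_energy_force(z, wall)[0], 1.5, 2.9)
        umin, _ = wall_energy_force(zmin, wall)
    else:
        zmin, zzero, umin = np.nan, np.nan, 0.0
    u5, f5 = wall_energy_force(5.0, wall)
    rows.append({"epsilon": eps, "z_min_A": zmin, "U_min_kcal": umin,
                 "z_zero_A": zzero, "U_at_5A": u5, "Fz_at_5A": f5})

table = pd.DataFrame(rows).round(6)
table.to_csv("results/wall_potential.csv", index=False)
print(table.to_string(index=False))
print("\nMinimum sits at R_min = 3 Å with depth −ε for every ε;"
      " zero crossing at 3·3^(-1/6) = "
      f"{3 * 3 ** (-1 / 6):.4f} Å; potential vanishes past the 130 Å cutoff.")
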