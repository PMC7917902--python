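"""Series contrast under strong adsorption: short-spacer (S) versus
long-spacer (L) siloxane dendrimers at matched generation.

Runs G4 of both series at ε = 3 with three replicas of 0.5 ns and compares
the relative number of contacts.  The long –O–Si(CH3)2–O– spacer lets the
L-dendrimer spread over the plane and expose interior atoms, so its M/N
overtakes the stiff short-spacer S-dendrimer, whose compact structure
limits the contact fraction.  The spreading is slow and depends on the
starting orientation, which is why this comparison needs the longest runs
and replica averaging of the whole study.  Writes
results/series_contrast.csv.
"""

import pathlib

import pandas as pd

from dendrisorb.analysis import aggregate, contacts_over_frames
from dendrisorb.forcefield import ForceFieldParams
from dendrisorb.protocols import adsorption_run, equilibrate

pathlib.Path("results").mkdir(exist_ok=True)

ff = ForceFieldParams.default()
rows, means = [], {}
for series in ("S", "L"):
    eq = equilibrate(series, 4, seed=101, relax_ps=10.0, ff=ff)
    fractions = []
    for seed in (11, 22, 33):
        traj = adsorption_run(eq, epsilon=3.0, seed=seed, adsorb_ps=500.0, ff=ff)
        c = contacts_over_frames(traj, production=0.25)
        fractions.append(c.fraction)
        rows.append({"series": series, "generation": 4, "epsilon": 3.0,
                     "replica": seed, "N": c.N, "M": c.M,
                     "fraction": c.fraction})
    agg = aggregate({"fraction": fractions})
    means[series] = agg.loc["fraction", "mean"]
    print(f"{series} G4, eps=3: M/N = {agg.loc['fraction', 'mean']:.3f} "
          f"± {agg.loc['fraction', 'sem']:.3f} (3 replicas, 0.5 ns)")

table = pd.DataFrame(rows)
table.to_csv("results/series_contrast.csv", index=False)
lo, hi = ("S", "L") if means["S"] < means["L"] else ("L", "S")
print(f"\n{lo}-series mean contact fraction ({means[lo]:.3f}) is below the "
      f"{hi}-series one ({means[hi]:.3f}) at matched generation and strong "
      "adsorption.")
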