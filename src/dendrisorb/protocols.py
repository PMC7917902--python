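"""Canonical run recipes: build → embed → relax → adsorb, with bookkeeping.

These helpers standardise the study protocol (equilibrate in free space,
drop at a random orientation 5 Å above the plane, integrate with the wall
on) so that sweeps in scripts and tests run identical physics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .builder import Conformation, DendrimerSpec, build_topology, embed_3d
from .forcefield import ForceFieldParams, WallParams
from .md import SimulationParams, Trajectory, adsorb, relax


def equilibrate(series: str, generation: int, seed: int,
                relax_ps: float = 10.0,
                ff: ForceFieldParams | None = None) -> Conformation:
    """Build, embed and thermally equilibrate one dendrimer at 350 K."""
    ff = ff or ForceFieldParams.default()
    top = build_topology(DendrimerSpec(series, generation))
    conf = embed_3d(top, seed=seed, forcefield=ff)
    traj = relax(conf, ff, SimulationParams(duration_ps=relax_ps, seed=seed))
    return traj.final_conformation()


def adsorption_run(eq_conf: Conformation, epsilon: float, seed: int,
                   adsorb_ps: float = 50.0,
                   ff: ForceFieldParams | None = None,
                   snapshot_every_ps: float = 1.0) -> Trajectory:
    """One adsorption trajectory from an equilibrated conformation."""
    ff = ff or ForceFieldParams.default()
    wall = WallParams(epsilon=epsilon)
    params = SimulationParams(duration_ps=adsorb_ps, seed=seed,
                              snapshot_every_ps=snapshot_every_ps)
    return adsorb(eq_conf, ff, wall, params)


def adsorption_sweep(series: str, generation: int, epsilons, seeds,
                     relax_ps: float = 10.0, adsorb_ps: float = 50.0,
                     ff: ForceFieldParams | None = None,
                     base_seed: int = 0) -> dict[tuple[float, int], Trajectory]:
    """Replicated ε-sweep for one molecule; returns {(ε, replica): trajectory}.

    All replicas start from the same equilibrated conformation but use
    different adsorption seeds (orientation + velocities + thermostat noise);
    seeds are shared across ε so that the ε-comparison is paired.
    """
    ff = ff or ForceFieldParams.default()
    eq = equilibrate(series, generation, base_seed, relax_ps, ff)
    out = {}
    for eps in epsilons:
        for rep, seed in enumerate(seeds):
            out[(eps, rep)] = adsorption_run(eq, eps, seed, adsorb_ps, ff)
    return out
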