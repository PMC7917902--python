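"""Study orchestration: build → relax → ε-sweep adsorption × replicas → analysis.

A single YAML config drives the whole study.  Replica seeds are derived
deterministically from the master seed and the run coordinates
(series, generation, ε, replica), so re-running a config reproduces every
trajectory bit for bit, and completed runs are skipped on resume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .builder import DendrimerSpec, build_topology, embed_3d
from .forcefield import ForceFieldParams, WallParams
from .md import SimulationParams, Trajectory, adsorb, relax
from .analysis import contacts_over_frames

#: the study's ε schedule: 0→1 in steps of 0.2, then 1→3 in steps of 0.5
EPSILON_SCHEDULE = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.5, 2.0, 2.5, 3.0)

_KNOWN_KEYS = {
    "dendrimers", "epsilons", "replicas", "master_seed", "output_dir",
    "relax_ps", "adsorb_ps", "timestep_fs", "temperature",
    "thermostat_lambda", "thermostat_m0", "snapshot_every_ps",
    "z_cut", "dH", "dR", "production_fraction", "initial_gap",
    "forcefield", "wall_r_min", "wall_cutoff",
}


@dataclass
class StudyConfig:
    dendrimers: list[DendrimerSpec]
    epsilons: tuple[float, ...] = EPSILON_SCHEDULE
    replicas: int = 3
    master_seed: int = 0
    output_dir: str = "results/study"
    relax_ps: float = 20.0
    adsorb_ps: float = 50.0
    timestep_fs: float = 1.0
    temperature: float = 350.0
    thermostat_lambda: float = 55.0
    thermostat_m0: float = 1.0
    snapshot_every_ps: float = 1.0
    z_cut: float = 5.0
    dH: float = 0.2
    dR: float = 1.0
    production_fraction: float = 0.25
    initial_gap: float = 5.0
    forcefield: str | None = None       # path to a parameter YAML, or None
    wall_r_min: float = 3.0
    wall_cutoff: float = 130.0

    def __post_init__(self):
        if any(e < 0 for e in self.epsilons):
            raise ValueError("epsilon values must be non-negative")
        if self.replicas < 1:
            raise ValueError("replicas must be >= 1")
        self.epsilons = tuple(sorted(set(float(e) for e in self.epsilons)))
        if not self.dendrimers:
            raise ValueError("at least one dendrimer spec is required")

    def load_forcefield(self) -> ForceFieldParams:
        if self.forcefield:
            return ForceFieldParams.load(self.forcefield)
        return ForceFieldParams.default()

    def sim_params(self, duration_ps: float, seed: int) -> SimulationParams:
        return SimulationParams(
            timestep_fs=self.timestep_fs, temperature=self.temperature,
            thermostat_m0=self.thermostat_m0,
            thermostat_lambda=self.thermostat_lambda,
            duration_ps=duration_ps,
            snapshot_every_ps=self.snapshot_every_ps,
            initial_gap=self.initial_gap, seed=seed,
        )


def replica_seed(master_seed: int, series: str, generation: int,
                 eps: float, replica: int) -> int:
    """Deterministic per-run seed below 2³¹."""
    key = [master_seed, sum(ord(c) for c in series), generation,
           int(round(eps * 1000)) + 10 ** 6, replica]
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def validate_config(path) -> StudyConfig:
    """Load and validate a YAML study config; unknown keys are fatal."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    errors = [f"unknown config key: {k!r}" for k in raw if k not in _KNOWN_KEYS]
    dendrimers = []
    for d in raw.get("dendrimers", [{"series": "C4", "generation": 2}]):
        try:
            dendrimers.append(DendrimerSpec(
                series=d["series"], generation=int(d["generation"]),
                core_functionality=d.get("core_functionality"),
            ))
        except (KeyError, ValueError) as exc:
            errors.append(f"bad dendrimer entry {d!r}: {exc}")
    kwargs = {k: v for k, v in raw.items() if k != "dendrimers" and k in _KNOWN_KEYS}
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    try:
        return StudyConfig(dendrimers=dendrimers, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def run_study(config: StudyConfig, keep_trajectories: bool = False,
              progress: bool = False) -> Path:
    """Execute the full sweep and write analysis tables.

    Layout: ``<out>/<series>-G<g>/eps<ε>/rep<k>/`` holds per-run outputs;
    ``<out>/contacts.csv`` and ``<out>/summary.json`` aggregate everything.
    Completed runs (marker file present) are skipped.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ff = config.load_forcefield()
    rows = []
    layer_rows = []

    for spec in config.dendrimers:
        mol_dir = out / spec.label
        mol_dir.mkdir(exist_ok=True)
        eq_conf = _equilibrated(spec, config, ff, mol_dir, progress)
        for eps in config.epsilons:
            wall = WallParams(epsilon=eps, r_min=config.wall_r_min,
                              cutoff=config.wall_cutoff)
            for rep in range(config.replicas):
                seed = replica_seed(config.master_seed, spec.series,
                                    spec.generation, eps, rep)
                run_dir = mol_dir / f"eps{eps:g}" / f"rep{rep}"
                run_dir.mkdir(parents=True, exist_ok=True)
                marker = run_dir / "contacts.json"
                if marker.exists():
                    rec = json.loads(marker.read_text())
                else:
                    if progress:
                        print(f"  adsorb {spec.label} eps={eps:g} rep={rep}")
                    traj = adsorb(eq_conf, ff, wall,
                                  config.sim_params(config.adsorb_ps, seed))
                    rec = _analyze_run(traj, config, spec, eps, rep, seed)
                    if keep_trajectories:
                        traj.save_npz(run_dir / "trajectory.npz")
                    marker.write_text(json.dumps(rec, indent=1))
                rows.append({k: v for k, v in rec.items() if k != "layer_fractions"})
                for layer, frac in rec["layer_fractions"].items():
                    layer_rows.append({
                        "series": spec.series, "generation": spec.generation,
                        "epsilon": eps, "replica": rep,
                        "layer": int(layer), "contact_fraction": frac,
                    })

    contacts = pd.DataFrame(rows)
    contacts.to_csv(out / "contacts.csv", index=False)
    layers = pd.DataFrame(layer_rows)
    layers.to_csv(out / "layer_contacts.csv", index=False)

    summary = (
        contacts.groupby(["series", "generation", "epsilon"])
        .agg(M_mean=("M", "mean"), M_sem=("M", "sem"),
             frac_mean=("fraction", "mean"), frac_sem=("fraction", "sem"),
             n_replicas=("replica", "count"))
        .reset_index()
    )
    summary.to_csv(out / "summary.csv", index=False)
    payload = {
        "version": __version__,
        "master_seed": config.master_seed,
        "epsilons": list(config.epsilons),
        "replicas": config.replicas,
        "records": summary.to_dict(orient="records"),
    }
    (out / "summary.json").write_text(json.dumps(payload, indent=1))
    return out


def _equilibrated(spec, config, ff, mol_dir, progress):
    seed = replica_seed(config.master_seed, spec.series, spec.generation, -1.0, 0)
    top = build_topology(spec)
    if progress:
        print(f"build+relax {spec.label} (N={top.n_atoms})")
    conf = embed_3d(top, seed=seed, forcefield=ff)
    traj = relax(conf, ff, config.sim_params(config.relax_ps, seed))
    return traj.final_conformation()


def _analyze_run(traj: Trajectory, config, spec, eps, rep, seed) -> dict:
    contacts = contacts_over_frames(traj, config.z_cut, config.production_fraction)
    return {
        "series": spec.series, "generation": spec.generation,
        "epsilon": eps, "replica": rep, "seed": seed,
        "version": __version__,
        "M": contacts.M, "N": contacts.N, "fraction": contacts.fraction,
        "layer_fractions": {str(k): v for k, v in contacts.layer_fractions.items()},
        "mean_temperature": float(traj.temperatures.mean()),
    }
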