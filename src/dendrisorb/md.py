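"""MD engine: velocity-Verlet integration with a collisional thermostat.

The thermostat follows the collisional scheme: at every step each atom
independently suffers, with probability λ·dt, an elastic head-on collision
with a virtual particle of mass m0 drawn from a Maxwell distribution at the
target temperature.  Each collision conserves the momentum of the
(atom + virtual particle) pair; the ensemble of collisions drives the system
to the canonical distribution at T.

Two protocols mirror the adsorption study: :func:`relax` equilibrates a
dendrimer in free space, :func:`adsorb` drops the equilibrated molecule at a
random orientation next to the adsorbing plane and integrates with the 9-3
wall switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .builder import Conformation, MolecularTopology
from .forcefield import (CompiledSystem, EnergyBreakdown, ForceFieldParams,
                         WallParams, total_forces)
from .units import FS, KB, KCAL_TO_INTERNAL


@dataclass
class SimulationParams:
    timestep_fs: float = 1.0
    temperature: float = 350.0         # K
    thermostat_m0: float = 1.0         # Da, virtual-particle mass
    thermostat_lambda: float = 55.0    # ps⁻¹, collision frequency (0 = NVE)
    duration_ps: float = 100.0
    snapshot_every_ps: float = 1.0
    initial_gap: float = 5.0           # Å between lowest atom and the plane
    seed: int = 0

    def __post_init__(self):
        if self.timestep_fs <= 0 or self.duration_ps <= 0:
            raise ValueError("timestep and duration must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_steps(self) -> int:
        return max(1, round(self.duration_ps / (self.timestep_fs * FS)))

    @property
    def sample_every(self) -> int:
        return max(1, round(self.snapshot_every_ps / (self.timestep_fs * FS)))


@dataclass
class Frame:
    time_ps: float
    coords: np.ndarray
    velocities: np.ndarray
    energies: EnergyBreakdown
    temperature: float


@dataclass
class Trajectory:
    topology: MolecularTopology
    times: np.ndarray                  # (nf,) ps
    coords: np.ndarray                 # (nf, N, 3) Å
    velocities: np.ndarray             # (nf, N, 3) Å/ps
    energies: np.ndarray               # (nf, 6): U12 U13 U14 Uvw Uqq U_ads
    temperatures: np.ndarray           # (nf,) K
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> Frame:
        return Frame(
            time_ps=float(self.times[i]),
            coords=self.coords[i],
            velocities=self.velocities[i],
            energies=EnergyBreakdown.from_array(self.energies[i]),
            temperature=float(self.temperatures[i]),
        )

    def final_conformation(self) -> Conformation:
        return Conformation(self.topology, self.coords[-1].copy())

    def production_slice(self, fraction: float = 0.25) -> slice:
        """Trailing window used for observable averaging."""
        start = int(np.ceil(self.n_frames * (1.0 - fraction)))
        return slice(min(start, self.n_frames - 1), self.n_frames)

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            times=self.times,
            coords=self.coords,
            velocities=self.velocities,
            energies=self.energies,
            temperatures=self.temperatures,
        )

    def write_xyz(self, path) -> None:
        from .structure_io import write_xyz_frames
        write_xyz_frames(self.topology, self.coords, path, times=self.times)


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous temperature from equipartition, K."""
    ke = 0.5 * (masses[:, None] * velocities ** 2).sum() / KCAL_TO_INTERNAL
    ndof = 3 * len(masses)
    return float(2.0 * ke / (ndof * KB))


def maxwell_velocities(masses: np.ndarray, temperature: float, rng) -> np.ndarray:
    """Draw velocities (Å/ps) from the Maxwell distribution at T."""
    sd = np.sqrt(KB * temperature * KCAL_TO_INTERNAL / masses)
    return rng.normal(size=(len(masses), 3)) * sd[:, None]


# --- single-step operations (exposed for tests; the fused numba loop below
#     repeats the same update for speed) --------------------------------------

def step(conf: Conformation, velocities: np.ndarray, forces: np.ndarray,
         ff: ForceFieldParams, params: SimulationParams,
         wall: WallParams | None = None, system: CompiledSystem | None = None):
    """One velocity-Verlet update; returns (conf, velocities, forces, energies)."""
    dt = params.timestep_fs * FS
    masses = conf.topology.masses[:, None]
    acc = forces * KCAL_TO_INTERNAL / masses
    v_half = velocities + 0.5 * dt * acc
    new_coords = conf.coords + dt * v_half
    if not np.isfinite(new_coords).all():
        raise FloatingPointError("non-finite coordinates during integration")
    new_conf = Conformation(conf.topology, new_coords)
    new_forces, energies = total_forces(new_conf, ff, wall, system)
    new_vel = v_half + 0.5 * dt * new_forces * KCAL_TO_INTERNAL / masses
    return new_conf, new_vel, new_forces, energies


def thermostat_collide(velocities: np.ndarray, masses: np.ndarray,
                       params: SimulationParams, rng) -> np.ndarray:
    """Apply one sweep of stochastic virtual-particle collisions.

    With per-step probability λ·dt each atom's velocity v becomes
    ((m − m0) v + 2 m0 u)/(m + m0) with u ~ Maxwell(T, m0): the outcome of an
    elastic collision that conserves the pair momentum m v + m0 u.
    """
    lam = params.thermostat_lambda
    dt = params.timestep_fs * FS
    if lam == 0.0:
        return velocities
    out = velocities.copy()
    m0 = params.thermostat_m0
    hit = rng.random(len(masses)) < lam * dt
    if hit.any():
        sd = np.sqrt(KB * params.temperature * KCAL_TO_INTERNAL / m0)
        u = rng.normal(size=(int(hit.sum()), 3)) * sd
        m = masses[hit, None]
        out[hit] = ((m - m0) * out[hit] + 2.0 * m0 * u) / (m + m0)
    return out


# --- protocols --------------------------------------------------------------

def _run(conf: Conformation, ff: ForceFieldParams, params: SimulationParams,
         wall: WallParams | None, initial_velocities: np.ndarray | None,
         provenance: dict) -> Trajectory:
    top = conf.topology
    sysc = CompiledSystem(top, ff)
    rng = np.random.default_rng(params.seed)
    if initial_velocities is None:
        vels = maxwell_velocities(top.masses, params.temperature, rng)
    else:
        vels = initial_velocities.copy()

    dt = params.timestep_fs * FS
    kernel_seed = int(rng.integers(0, 2 ** 31 - 1))
    (out_coords, out_vels, out_energies, out_kin, n_sampled, status) = _kernels.run_md(
        conf.coords.astype(np.float64, copy=True),
        vels.astype(np.float64, copy=True),
        sysc.masses, dt, params.n_steps, params.sample_every,
        *sysc.kernel_args(wall),
        params.thermostat_lambda, params.thermostat_m0, params.temperature,
        kernel_seed,
    )
    if status == 1:
        raise FloatingPointError("non-finite coordinates during integration")
    if status == 2:
        raise ValueError("atom reached z <= 0: impenetrable plane violated")

    ndof = 3 * top.n_atoms
    temps = 2.0 * out_kin[:n_sampled] / (ndof * KB)
    dt_sample = params.sample_every * dt
    times = dt_sample * np.arange(1, n_sampled + 1)
    return Trajectory(
        topology=top,
        times=times,
        coords=out_coords[:n_sampled],
        velocities=out_vels[:n_sampled],
        energies=out_energies[:n_sampled],
        temperatures=temps,
        provenance=provenance,
    )


def relax(conf: Conformation, ff: ForceFieldParams,
          params: SimulationParams) -> Trajectory:
    """Thermostatted free-space equilibration (no wall)."""
    prov = {"protocol": "relax", "spec": conf.topology.spec.label,
            "params": asdict(params)}
    return _run(conf, ff, params, None, None, prov)


def random_orientation(conf: Conformation, gap: float, rng) -> Conformation:
    """Uniformly random rotation about the COM, lowest atom at z = gap."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2 ** 31)))
    m = conf.topology.masses
    com = (conf.coords * m[:, None]).sum(0) / m.sum()
    coords = (conf.coords - com) @ rot.as_matrix().T
    coords[:, 2] += gap - coords[:, 2].min()
    return Conformation(conf.topology, coords)


def adsorb(conf: Conformation, ff: ForceFieldParams, wall: WallParams,
           params: SimulationParams) -> Trajectory:
    """Adsorption run: random orientation next to the plane, wall on."""
    rng = np.random.default_rng(params.seed)
    start = random_orientation(conf, params.initial_gap, rng)
    prov = {"protocol": "adsorb", "spec": conf.topology.spec.label,
            "wall_epsilon": wall.epsilon, "params": asdict(params)}
    return _run(start, ff, params, wall, None, prov)
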