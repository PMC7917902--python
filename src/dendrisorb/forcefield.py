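"""Force-field parameters and energy/force evaluation.

The potential has the standard united-atom form: harmonic bond stretching
(U12) and angle bending (U13), a 3-fold cosine torsion (U14, carbosilane
backbones only), Lennard-Jones van der Waals interactions (Uvw) and a
screened Coulomb term (Uqq) with a distance-dependent dielectric, plus the
9-3 wall adsorption potential

    U_ads(z) = 0.5 ε ((R_min/z)^9 − 3 (R_min/z)^3),

which is the lateral integral of an atom–half-space LJ attraction.  The wall
acts identically on every united atom regardless of type.

Parameter values live in a YAML file (see ``data/default_forcefield.yaml``)
and round-trip exactly through :meth:`ForceFieldParams.save` /
:meth:`ForceFieldParams.load`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _kernels
from .builder import Conformation, MolecularTopology

ENERGY_COMPONENTS = ("U12", "U13", "U14", "Uvw", "Uqq", "U_ads")


@dataclass(frozen=True)
class WallParams:
    """9-3 adsorption wall at z = 0."""

    epsilon: float = 1.0      # kcal/mol, well depth per atom
    r_min: float = 3.0        # Å, location of the minimum
    cutoff: float = 130.0     # Å

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("wall epsilon must be >= 0")
        if self.r_min <= 0:
            raise ValueError("R_min must be > 0")
        if self.cutoff <= self.r_min:
            raise ValueError("wall cutoff must exceed R_min")


@dataclass
class EnergyBreakdown:
    """Totals (kcal/mol) of every potential term for one configuration."""

    U12: float = 0.0
    U13: float = 0.0
    U14: float = 0.0
    Uvw: float = 0.0
    Uqq: float = 0.0
    U_ads: float = 0.0

    @property
    def total(self) -> float:
        return self.U12 + self.U13 + self.U14 + self.Uvw + self.Uqq + self.U_ads

    def per_atom(self, n: int) -> dict[str, float]:
        return {k: getattr(self, k) / n for k in ENERGY_COMPONENTS}

    @classmethod
    def from_array(cls, arr) -> "EnergyBreakdown":
        return cls(*(float(x) for x in arr))

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in ENERGY_COMPONENTS}
        d["total"] = self.total
        return d


@dataclass
class ForceFieldParams:
    bonds: dict[str, dict[str, float]]
    angles: dict[str, dict[str, float]]
    dihedrals: dict[str, dict[str, float]]
    lj: dict[str, dict[str, float]]
    cutoff: float = 10.5
    scale14: float = 0.5
    dielectric_scale: float = 1.0
    shift: bool = True
    wall: WallParams = field(default_factory=WallParams)

    def __post_init__(self):
        for tag, p in self.bonds.items():
            if p["k"] <= 0 or p["b0"] <= 0:
                raise ValueError(f"bond {tag}: b0 and k must be > 0")
        for tag, p in self.angles.items():
            if p["k"] <= 0:
                raise ValueError(f"angle {tag}: k must be > 0")
        if self.cutoff <= 0:
            raise ValueError("nonbonded cutoff must be > 0")

    # -- file IO --------------------------------------------------------

    @classmethod
    def default(cls) -> "ForceFieldParams":
        ref = importlib.resources.files("dendrisorb.data") / "default_forcefield.yaml"
        with importlib.resources.as_file(ref) as path:
            return cls.load(path)

    @classmethod
    def load(cls, path) -> "ForceFieldParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        nb = raw.get("nonbonded", {})
        wall = raw.get("wall", {})
        return cls(
            bonds=raw["bonds"],
            angles=raw["angles"],
            dihedrals=raw.get("dihedrals", {}),
            lj=raw["lj"],
            cutoff=float(nb.get("cutoff", 10.5)),
            scale14=float(nb.get("scale14", 0.5)),
            dielectric_scale=float(nb.get("dielectric_scale", 1.0)),
            shift=bool(nb.get("shift", True)),
            wall=WallParams(
                epsilon=float(wall.get("epsilon", 1.0)),
                r_min=float(wall.get("r_min", 3.0)),
                cutoff=float(wall.get("cutoff", 130.0)),
            ),
        )

    def save(self, path) -> None:
        raw = {
            "bonds": self.bonds,
            "angles": self.angles,
            "dihedrals": self.dihedrals,
            "lj": self.lj,
            "nonbonded": {
                "cutoff": self.cutoff,
                "scale14": self.scale14,
                "dielectric_scale": self.dielectric_scale,
                "shift": self.shift,
            },
            "wall": {
                "epsilon": self.wall.epsilon,
                "r_min": self.wall.r_min,
                "cutoff": self.wall.cutoff,
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    # -- lookups --------------------------------------------------------

    def bond_length(self, tag: str) -> float:
        return self.bonds[tag]["b0"]

    def angle_theta0(self, tag: str) -> float:
        return self.angles[tag]["theta0"]


class CompiledSystem:
    """Flat-array view of (topology, force field) consumed by the kernels."""

    def __init__(self, topology: MolecularTopology, ff: ForceFieldParams):
        self.topology = topology
        self.ff = ff
        n = topology.n_atoms

        try:
            self.bond_b0 = np.array([ff.bonds[t]["b0"] for t in topology.bond_types])
            self.bond_k = np.array([ff.bonds[t]["k"] for t in topology.bond_types])
            self.angle_th0 = np.deg2rad(
                [ff.angles[t]["theta0"] for t in topology.angle_types]
            )
            self.angle_k = np.array([ff.angles[t]["k"] for t in topology.angle_types])
            self.dih_k = np.array([ff.dihedrals[t]["k"] for t in topology.dihedral_types])
            self.dih_n = np.array([ff.dihedrals[t]["n"] for t in topology.dihedral_types])
            self.dih_delta = np.deg2rad(
                [ff.dihedrals[t]["delta"] for t in topology.dihedral_types]
            )
            self.lj_eps = np.array([ff.lj[t]["epsilon"] for t in topology.types])
            self.lj_sig = np.array([ff.lj[t]["sigma"] for t in topology.types])
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"force field lacks parameters for type tag {exc}") from exc

        self.bonds = np.ascontiguousarray(topology.bonds, dtype=np.int64)
        self.angles = np.ascontiguousarray(topology.angles, dtype=np.int64)
        self.dihedrals = np.ascontiguousarray(topology.dihedrals, dtype=np.int64)
        self.charges = topology.charges.astype(np.float64)
        self.masses = topology.masses.astype(np.float64)
        self.excl = build_exclusions(topology)

    def kernel_args(self, wall: WallParams | None):
        ff = self.ff
        wall_on = wall is not None
        w = wall if wall is not None else WallParams()
        return (
            self.bonds, self.bond_b0, self.bond_k,
            self.angles, self.angle_th0, self.angle_k,
            self.dihedrals, self.dih_k, self.dih_n, self.dih_delta,
            self.lj_eps, self.lj_sig, self.charges, self.excl,
            ff.cutoff, ff.scale14, ff.dielectric_scale, ff.shift,
            wall_on, w.epsilon, w.r_min, w.cutoff,
        )


def build_exclusions(topology: MolecularTopology) -> np.ndarray:
    """N×N exclusion codes: 1-2 and 1-3 fully excluded, 1-4 scaled."""
    n = topology.n_atoms
    adj = [[] for _ in range(n)]
    for i, j in topology.bonds:
        adj[i].append(int(j))
        adj[j].append(int(i))
    excl = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        # BFS to topological distance 3; paths in a tree are unique
        dist = {i: 0}
        frontier = [i]
        for d in (1, 2, 3):
            nxt = []
            for a in frontier:
                for b in adj[a]:
                    if b not in dist:
                        dist[b] = d
                        nxt.append(b)
            frontier = nxt
        for j, d in dist.items():
            if j == i:
                continue
            excl[i, j] = _kernels.EXCL_FULL if d <= 2 else _kernels.EXCL_14
    return excl


# --- spec-level operations --------------------------------------------------

def wall_energy_force(z, wall: WallParams):
    """Energy (kcal/mol) and z-force (kcal/mol/Å) of the 9-3 wall on one atom.

    Vectorised over `z`.  Raises for z ≤ 0 (the plane is impenetrable).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("atom at z <= 0: impenetrable plane violated")
    s3 = (wall.r_min / z) ** 3
    s9 = s3 ** 3
    energy = 0.5 * wall.epsilon * (s9 - 3.0 * s3)
    force = 4.5 * wall.epsilon * (s9 - s3) / z
    beyond = z > wall.cutoff
    energy = np.where(beyond, 0.0, energy)
    force = np.where(beyond, 0.0, force)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def _compute(conf: Conformation, ff: ForceFieldParams, wall: WallParams | None,
             system: CompiledSystem | None = None):
    sysc = system if system is not None else CompiledSystem(conf.topology, ff)
    forces, energies, ok = _kernels.compute_all(
        np.ascontiguousarray(conf.coords, dtype=np.float64), *sysc.kernel_args(wall)
    )
    if not ok:
        raise ValueError("atom at z <= 0: impenetrable plane violated")
    return forces, EnergyBreakdown.from_array(energies)


def bonded_energy(conf: Conformation, ff: ForceFieldParams) -> EnergyBreakdown:
    """U12/U13/U14 only (other components zeroed)."""
    _, e = _compute(conf, ff, None)
    return EnergyBreakdown(U12=e.U12, U13=e.U13, U14=e.U14)


def nonbonded_energy(conf: Conformation, ff: ForceFieldParams) -> EnergyBreakdown:
    """Uvw/Uqq only (other components zeroed)."""
    _, e = _compute(conf, ff, None)
    return EnergyBreakdown(Uvw=e.Uvw, Uqq=e.Uqq)


def total_forces(conf: Conformation, ff: ForceFieldParams,
                 wall: WallParams | None = None,
                 system: CompiledSystem | None = None):
    """Per-atom forces (kcal/mol/Å) and the full energy breakdown."""
    return _compute(conf, ff, wall, system)


# --- embedding support ------------------------------------------------------

def bond_deviations(conf: Conformation, ff: ForceFieldParams) -> np.ndarray:
    """|b − b0| / b0 for every bond."""
    top = conf.topology
    b0 = np.array([ff.bonds[t]["b0"] for t in top.bond_types])
    d = conf.coords[top.bonds[:, 1]] - conf.coords[top.bonds[:, 0]]
    b = np.linalg.norm(d, axis=1)
    return np.abs(b - b0) / b0


def min_separation_ratio(conf: Conformation, ff: ForceFieldParams) -> float:
    """min over non-excluded pairs of r_ij / σ_ij (σ by Lorentz mixing)."""
    top = conf.topology
    sig = np.array([ff.lj[t]["sigma"] for t in top.types])
    excl = build_exclusions(top)
    diff = conf.coords[:, None, :] - conf.coords[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    sij = 0.5 * (sig[:, None] + sig[None, :])
    ratio = r / sij
    mask = (excl == _kernels.EXCL_NONE) & ~np.eye(top.n_atoms, dtype=bool)
    return float(ratio[mask].min()) if mask.any() else np.inf


def minimize(conf: Conformation, ff: ForceFieldParams, max_steps: int = 2000,
             ftol: float = 1.0) -> Conformation:
    """Steepest-descent relaxation with an adaptive step and force capping.

    Good enough to remove embedding clashes; not a production minimiser.
    """
    sysc = CompiledSystem(conf.topology, ff)
    coords = conf.coords.copy()
    step = 1e-3
    f, e = _compute(Conformation(conf.topology, coords), ff, None, sysc)
    last = e.total
    for _ in range(max_steps):
        fmag = np.linalg.norm(f, axis=1)
        fmax = fmag.max()
        if fmax < ftol:
            break
        cap = np.minimum(fmag, 50.0) / np.maximum(fmag, 1e-12)
        trial = coords + step * f * cap[:, None]
        ft, et = _compute(Conformation(conf.topology, trial), ff, None, sysc)
        if et.total < last:
            coords, f, last = trial, ft, et.total
            step = min(step * 1.2, 2e-2)
        else:
            step *= 0.5
            if step < 1e-8:
                break
    return Conformation(conf.topology, coords)
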