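"""Generator for silicon-containing dendrimer topologies and start conformations.

Four homologous series are supported:

* ``C4`` / ``C3`` — carbosilane dendrimers with a four- or three-functional
  core Si, trimethylene –(CH2)3– spacers, three-functional Si(CH3) branching
  points and two butyl –(CH2)3–CH3 end segments per outermost branching Si.
* ``S`` — siloxane dendrimers with a single-oxygen spacer and methyl ends
  (outermost branching Si become Si(CH3)3).
* ``L`` — siloxane dendrimers with the longer –O–Si(CH3)2–O– spacer and
  methyl ends.

Hydrogens are folded into united CH2/CH3 pseudo-atoms.  The topology is a
tree; every atom carries a *structural layer* index: layer 0 is the core atom
plus the spacers emanating from it, layer k ≥ 1 is the set of depth-k
branching Si together with their methyl and their outgoing spacers (for
k = G, their terminal segments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np


SERIES = ("C4", "C3", "S", "L")

#: united-atom masses, Da
MASSES = {"CH3": 15.035, "CH2": 14.027, "Si": 28.086, "O": 15.999}

#: default siloxane partial charges: each O takes CHARGE_O, each Si gains
#: -CHARGE_O/2 per bonded O, so the molecule is neutral by construction.
CHARGE_O = -0.4

_CARBOSILANE_SPACER = ("CH2", "CH2", "CH2")
_BUTYL = ("CH2", "CH2", "CH2", "CH3")


@dataclass(frozen=True)
class DendrimerSpec:
    """Which dendrimer to build."""

    series: str
    generation: int
    core_functionality: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.series not in SERIES:
            raise ValueError(f"unknown series {self.series!r}; expected one of {SERIES}")
        if self.generation < 1:
            raise ValueError(f"generation must be >= 1, got {self.generation}")
        if self.core_functionality is None:
            object.__setattr__(self, "core_functionality", 4 if self.series == "C4" else 3)
        if self.core_functionality not in (3, 4):
            raise ValueError(f"core functionality must be 3 or 4, got {self.core_functionality}")

    @property
    def label(self) -> str:
        return f"{self.series}-G{self.generation}"


@dataclass
class MolecularTopology:
    """Tree topology of one dendrimer in united-atom representation."""

    spec: DendrimerSpec
    types: list[str]                      # united type per atom
    masses: np.ndarray                    # (N,) Da
    charges: np.ndarray                   # (N,) e
    layers: np.ndarray                    # (N,) structural layer index
    bonds: np.ndarray                     # (nb, 2) atom ids
    bond_types: list[str]
    angles: np.ndarray                    # (na, 3)
    angle_types: list[str]
    dihedrals: np.ndarray                 # (nd, 4); empty for S/L
    dihedral_types: list[str]
    parents: np.ndarray                   # (N,) parent atom id, -1 for core

    @property
    def n_atoms(self) -> int:
        return len(self.types)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def layer_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.layers, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def to_json(self, path) -> None:
        payload = {
            "series": self.spec.series,
            "generation": self.spec.generation,
            "core_functionality": self.spec.core_functionality,
            "n_atoms": self.n_atoms,
            "atoms": [
                {"id": i, "type": t, "mass": float(m), "charge": float(q), "layer": int(k)}
                for i, (t, m, q, k) in enumerate(
                    zip(self.types, self.masses, self.charges, self.layers)
                )
            ],
            "bonds": [[int(i), int(j), t] for (i, j), t in zip(self.bonds, self.bond_types)],
            "layers": {str(k): v for k, v in self.layer_counts().items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class Conformation:
    """Topology plus 3D coordinates (Å) in the non-periodic half-space z > 0."""

    topology: MolecularTopology
    coords: np.ndarray                    # (N, 3) Å

    def copy(self) -> "Conformation":
        return Conformation(self.topology, self.coords.copy())

    def radius_of_gyration(self) -> float:
        m = self.topology.masses
        com = (self.coords * m[:, None]).sum(0) / m.sum()
        d2 = ((self.coords - com) ** 2).sum(1)
        return float(np.sqrt((m * d2).sum() / m.sum()))


class _TreeBuilder:
    def __init__(self):
        self.types: list[str] = []
        self.layers: list[int] = []
        self.parents: list[int] = []
        self.bonds: list[tuple[int, int]] = []

    def add(self, utype: str, parent: int, layer: int) -> int:
        i = len(self.types)
        self.types.append(utype)
        self.layers.append(layer)
        self.parents.append(parent)
        if parent >= 0:
            self.bonds.append((parent, i))
        return i

    def add_chain(self, utypes, parent: int, layer: int) -> int:
        for t in utypes:
            parent = self.add(t, parent, layer)
        return parent


def _spacer_types(series: str) -> tuple[str, ...]:
    if series in ("C4", "C3"):
        return _CARBOSILANE_SPACER
    if series == "S":
        return ("O",)
    return ("O", "Si", "O")  # L; the middle Si carries two methyls


def _grow_spacer(tb: _TreeBuilder, series: str, parent: int, layer: int) -> int:
    """Attach one spacer; return the atom the next branching Si bonds to."""
    if series == "L":
        o1 = tb.add("O", parent, layer)
        si = tb.add("Si", o1, layer)
        tb.add("CH3", si, layer)
        tb.add("CH3", si, layer)
        return tb.add("O", si, layer)
    return tb.add_chain(_spacer_types(series), parent, layer)


def _grow_branch(tb: _TreeBuilder, series: str, attach: int, depth: int, G: int) -> None:
    """Place the depth-`depth` branching Si bonded to `attach` and recurse."""
    si = tb.add("Si", attach, depth)
    tb.add("CH3", si, depth)  # the ≡Si(CH3) methyl
    if depth < G:
        for _ in range(2):
            tail = _grow_spacer(tb, series, si, depth)
            _grow_branch(tb, series, tail, depth + 1, G)
    else:  # terminal segments
        if series in ("C4", "C3"):
            for _ in range(2):
                tb.add_chain(_BUTYL, si, depth)
        else:
            tb.add("CH3", si, depth)
            tb.add("CH3", si, depth)


def build_topology(spec: DendrimerSpec) -> MolecularTopology:
    """Expand a dendrimer spec into a united-atom tree topology.

    Atoms are numbered depth-first from the core, so the numbering is
    deterministic and independent of the seed.
    """
    tb = _TreeBuilder()
    core = tb.add("Si", -1, 0)
    if spec.core_functionality == 3:
        # three-functional core Si keeps one methyl to fill its valence
        tb.add("CH3", core, 0)
    for _ in range(spec.core_functionality):
        tail = _grow_spacer(tb, spec.series, core, 0)
        _grow_branch(tb, spec.series, tail, 1, spec.generation)

    types = tb.types
    n = len(types)
    masses = np.array([MASSES[t] for t in types])
    charges = np.zeros(n)
    if spec.series in ("S", "L"):
        bonded: dict[int, list[int]] = {i: [] for i in range(n)}
        for i, j in tb.bonds:
            bonded[i].append(j)
            bonded[j].append(i)
        for i, t in enumerate(types):
            if t == "O":
                charges[i] = CHARGE_O
            elif t == "Si":
                n_ox = sum(1 for j in bonded[i] if types[j] == "O")
                charges[i] = -CHARGE_O / 2.0 * n_ox

    bonds = np.array(tb.bonds, dtype=np.int64)
    bond_types = [_bond_tag(types[i], types[j]) for i, j in bonds]
    angles, angle_types = _enumerate_angles(types, bonds, n)
    if spec.series in ("C4", "C3"):
        dihedrals, dihedral_types = _enumerate_dihedrals(bonds, n)
    else:
        dihedrals, dihedral_types = np.zeros((0, 4), dtype=np.int64), []

    return MolecularTopology(
        spec=spec,
        types=types,
        masses=masses,
        charges=charges,
        layers=np.array(tb.layers, dtype=np.int64),
        bonds=bonds,
        bond_types=bond_types,
        angles=angles,
        angle_types=angle_types,
        dihedrals=dihedrals,
        dihedral_types=dihedral_types,
        parents=np.array(tb.parents, dtype=np.int64),
    )


def _element(utype: str) -> str:
    return "C" if utype in ("CH2", "CH3") else utype


def _bond_tag(t1: str, t2: str) -> str:
    e1, e2 = sorted((_element(t1), _element(t2)))
    return f"{e1}-{e2}"


def _angle_tag(t_out1: str, t_center: str, t_out2: str) -> str:
    o1, o2 = sorted((_element(t_out1), _element(t_out2)))
    return f"{o1}-{_element(t_center)}-{o2}"


def _adjacency(bonds: np.ndarray, n: int) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def _enumerate_angles(types, bonds, n):
    adj = _adjacency(bonds, n)
    angles, tags = [], []
    for j in range(n):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                angles.append((i, j, k))
                tags.append(_angle_tag(types[i], types[j], types[k]))
    arr = np.array(angles, dtype=np.int64) if angles else np.zeros((0, 3), dtype=np.int64)
    return arr, tags


def _enumerate_dihedrals(bonds, n):
    adj = _adjacency(bonds, n)
    quads, tags = [], []
    for j, k in bonds:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                quads.append((i, j, k, l))
                tags.append("X-X-X-X")
    arr = np.array(quads, dtype=np.int64) if quads else np.zeros((0, 4), dtype=np.int64)
    return arr, tags


def assign_layers(topology: MolecularTopology) -> MolecularTopology:
    """Recompute structural-layer labels from connectivity alone.

    The layer of an atom equals the number of branching Si on the path from
    the core to the atom, the atom itself included.  Branching Si are
    recognised purely from their bonding pattern, so this is an independent
    check of the labels stored at build time.  Returns a new topology with
    the recomputed labels.
    """
    n = topology.n_atoms
    adj = _adjacency(topology.bonds, n)
    types = topology.types
    parents = topology.parents

    def is_branch_si(i: int) -> bool:
        if types[i] != "Si" or parents[i] == -1:
            return False
        children = [j for j in adj[i] if j != parents[i]]
        ch3 = sum(1 for j in children if types[j] == "CH3")
        ox = sum(1 for j in children if types[j] == "O")
        # an L-series spacer Si has exactly two methyls and one onward oxygen
        return not (ch3 == 2 and ox == 1)

    layers = np.zeros(n, dtype=np.int64)
    order = np.argsort(_depths(parents))  # parents precede children
    for i in order:
        p = parents[i]
        if p == -1:
            layers[i] = 0
        else:
            layers[i] = layers[p] + (1 if is_branch_si(i) else 0)
    return replace(topology, layers=layers)


def _depths(parents: np.ndarray) -> np.ndarray:
    depth = np.zeros(len(parents), dtype=np.int64)
    for i, p in enumerate(parents):
        depth[i] = 0 if p == -1 else depth[p] + 1  # parents have smaller ids
    return depth


# --- 3D embedding -----------------------------------------------------------

_TET = np.deg2rad(109.47)


def embed_3d(
    topology: MolecularTopology,
    seed: int,
    forcefield=None,
    max_retries: int = 8,
) -> Conformation:
    """Build a clash-free 3D conformation for a topology.

    Atoms are placed recursively at equilibrium bond lengths with tetrahedral
    (or per-angle-type) valence angles and randomised torsions; the raw
    embedding is then relaxed by steepest descent on the full intramolecular
    potential until no non-bonded pair is closer than 0.8 of its LJ contact
    distance and all bonds are within 10% of equilibrium.

    The result is deterministic for a fixed seed.
    """
    import copy

    from .forcefield import ForceFieldParams, minimize

    ff = forcefield if forcefield is not None else ForceFieldParams.default()
    rng = np.random.default_rng(seed)
    # soften the LJ cores first so dense high-G embeddings can untangle
    soft = copy.deepcopy(ff)
    for t in soft.lj:
        soft.lj[t] = dict(soft.lj[t])
        soft.lj[t]["sigma"] *= 0.8
    budget = 2000 + 8 * topology.n_atoms
    for attempt in range(max_retries):
        coords = _place_atoms(topology, ff, rng)
        conf = Conformation(topology, coords)
        conf = minimize(conf, soft, max_steps=budget // 2)
        conf = minimize(conf, ff, max_steps=budget)
        ok_clash, ok_bond = _check_embedding(conf, ff)
        if not (ok_clash and ok_bond):
            # dense high-G globules: untangle with a short thermostatted
            # push-off on the softened cores, then re-minimise
            conf = _pushoff(conf, soft, seed + 7919 * (attempt + 1))
            conf = minimize(conf, ff, max_steps=budget)
            ok_clash, ok_bond = _check_embedding(conf, ff)
        if ok_clash and ok_bond:
            # recentre with plenty of clearance above the z = 0 plane
            conf.coords -= conf.coords.mean(0)
            conf.coords[:, 2] += np.ptp(conf.coords[:, 2]) + 10.0
            return conf
    raise RuntimeError(
        f"embedding failed for {topology.spec.label} after {max_retries} attempts "
        f"(clash-free={ok_clash}, bonds-ok={ok_bond})"
    )


def _pushoff(conf: Conformation, soft_ff, seed: int) -> Conformation:
    """Short thermostatted run on softened LJ cores to resolve overlaps."""
    from .md import SimulationParams, _run

    params = SimulationParams(timestep_fs=0.5, duration_ps=2.0,
                              snapshot_every_ps=0.5, seed=seed % (2 ** 31 - 1))
    traj = _run(conf, soft_ff, params, None, None, {"protocol": "pushoff"})
    return traj.final_conformation()


def _check_embedding(conf: Conformation, ff) -> tuple[bool, bool]:
    from .forcefield import bond_deviations, min_separation_ratio

    ok_clash = min_separation_ratio(conf, ff) >= 0.8
    ok_bond = bond_deviations(conf, ff).max() <= 0.10
    return ok_clash, ok_bond


def _place_atoms(topology: MolecularTopology, ff, rng) -> np.ndarray:
    n = topology.n_atoms
    coords = np.zeros((n, 3))
    parents = topology.parents
    types = topology.types
    adj = _adjacency(topology.bonds, n)

    placed_children: dict[int, int] = {}
    for i in range(1, n):
        p = parents[i]
        g = parents[p]
        b0 = ff.bond_length(_bond_tag(types[p], types[i]))
        if g == -1 and placed_children.get(p, 0) == 0:
            direction = _random_unit(rng)
        else:
            if g == -1:
                ref = coords[p] - coords[_first_child(parents, p)]
            else:
                ref = coords[p] - coords[g]
            ref = ref / np.linalg.norm(ref)
            theta0 = np.deg2rad(
                ff.angle_theta0(_angle_tag(types[g] if g != -1 else types[p], types[p], types[i]))
                if g != -1
                else 109.47
            )
            direction = _cone_direction(ref, np.pi - theta0, rng)
        coords[i] = coords[p] + b0 * direction
        placed_children[p] = placed_children.get(p, 0) + 1
        # a couple of torsion retries to avoid gross overlaps with earlier atoms
        for _ in range(12):
            d = coords[i] - coords[:i]
            r2 = (d * d).sum(1)
            near = r2 < 4.0  # 2 Å hard floor, excluding the parent
            near[p] = False
            for j in adj[i]:
                if j < i:
                    near[j] = False
            if not near.any():
                break
            if g == -1 and placed_children[p] == 1:
                direction = _random_unit(rng)
            else:
                direction = _cone_direction(ref, np.pi - theta0, rng)
            coords[i] = coords[p] + b0 * direction
    return coords


def _first_child(parents, p):
    hits = np.nonzero(parents == p)[0]
    return int(hits[0])


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _cone_direction(axis: np.ndarray, half_angle: float, rng) -> np.ndarray:
    """Random unit vector at `half_angle` from `axis`."""
    # orthonormal frame around axis
    a = np.array([1.0, 0.0, 0.0])
    if abs(axis @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return (
        np.cos(half_angle) * axis
        + np.sin(half_angle) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    )


# --- closed-form structural counts (used as cross-checks and in reports) ----

def branching_si_count(spec: DendrimerSpec, depth: int) -> int:
    """Number of branching Si at topological depth k: f_c · 2^(k−1)."""
    if not 1 <= depth <= spec.generation:
        raise ValueError("depth outside 1..G")
    return spec.core_functionality * 2 ** (depth - 1)


def terminal_group_count(spec: DendrimerSpec) -> int:
    """Number of terminal segments: f_c · 2^G."""
    return spec.core_functionality * 2 ** spec.generation
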