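"""Structure and trajectory output.

PDB files are written through MDAnalysis with the structural-layer index in
the B-factor column, so molecular viewers can colour the adsorption layer by
layer index directly.  United atoms (CH2/CH3) are exported as carbon
pseudo-atoms.
"""

from __future__ import annotations

import warnings

import numpy as np

from .builder import Conformation, MolecularTopology


def _element(utype: str) -> str:
    return "C" if utype in ("CH2", "CH3") else utype


def write_structure(conf: Conformation, path, fmt: str | None = None) -> None:
    """Write a conformation as PDB or XYZ (inferred from the suffix)."""
    path = str(path)
    if fmt is None:
        fmt = "PDB" if path.lower().endswith(".pdb") else "XYZ"
    fmt = fmt.upper()
    if fmt == "PDB":
        _write_pdb(conf, path)
    elif fmt == "XYZ":
        write_xyz_frames(conf.topology, conf.coords[None], path)
    else:
        raise ValueError(f"unsupported format {fmt!r}; use PDB or XYZ")


def _write_pdb(conf: Conformation, path: str) -> None:
    import MDAnalysis as mda

    top = conf.topology
    n = top.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", [t for t in top.types])
    u.add_TopologyAttr("elements", [_element(t) for t in top.types])
    u.add_TopologyAttr("masses", top.masses)
    u.add_TopologyAttr("tempfactors", top.layers.astype(float))
    u.add_TopologyAttr("resnames", ["DEN"])
    u.atoms.positions = conf.coords.astype(np.float32)
    u.add_bonds(top.bonds.tolist())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)


def read_structure(path, topology: MolecularTopology) -> Conformation:
    """Read coordinates back (PDB or XYZ) for an existing topology."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    coords = u.atoms.positions.astype(np.float64)
    if len(coords) != topology.n_atoms:
        raise ValueError("atom count mismatch between file and topology")
    return Conformation(topology, coords)


def read_pdb_tempfactors(path) -> np.ndarray:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    return u.atoms.tempfactors.copy()


def write_xyz_frames(topology: MolecularTopology, coords_frames: np.ndarray,
                     path, times=None) -> None:
    """Multi-frame XYZ: first line N, comment line carries the time stamp."""
    elements = [_element(t) for t in topology.types]
    with open(path, "w") as fh:
        for f in range(coords_frames.shape[0]):
            fh.write(f"{topology.n_atoms}\n")
            t = f"t={times[f]:.3f} ps" if times is not None else f"frame {f}"
            fh.write(f"{topology.spec.label} {t}\n")
            for el, (x, y, z) in zip(elements, coords_frames[f]):
                fh.write(f"{el} {x:12.6f} {y:12.6f} {z:12.6f}\n")


def read_xyz_frames(path) -> np.ndarray:
    """Read a multi-frame XYZ written by :func:`write_xyz_frames`."""
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                coords[i] = [float(p) for p in parts[1:4]]
            frames.append(coords)
    return np.array(frames)
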