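"""Adsorption observables: contact counts, layer-resolved contacts, density
profiles, per-atom energy audit, shape metrics and replica aggregation.

Conventions follow the study design: an atom is *adsorbed* when its height
above the plane is ≤ z_cut (5 Å by default, boundary inclusive); the
perpendicular profile ρ⊥(H) is the mass per flat slab of width dH (linear
density, Da/Å); the parallel profile ρ∥(R) is the mass per annulus around
the instantaneous lateral centre of mass divided by the annulus area
(areal density, Da/Å²).  Both profiles integrate back to the molecular mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builder import MolecularTopology
from .forcefield import ENERGY_COMPONENTS
from .md import Trajectory

Z_CUT_DEFAULT = 5.0


@dataclass
class ContactResult:
    M: float                            # adsorbed atoms (mean over frames)
    N: int
    fraction: float                     # M / N
    z_cut: float
    layer_counts: dict[int, float]      # adsorbed atoms per layer
    layer_fractions: dict[int, float]   # ... ÷ atoms in that layer
    n_frames: int = 1


@dataclass
class DensityProfiles:
    h_centers: np.ndarray
    dH: float
    rho_perp: np.ndarray                # Da/Å
    r_centers: np.ndarray
    dR: float
    rho_par: np.ndarray                 # Da/Å²
    annulus_areas: np.ndarray           # Å²


def count_adsorbed(coords: np.ndarray, topology: MolecularTopology,
                   z_cut: float = Z_CUT_DEFAULT) -> ContactResult:
    """Contact statistics of a single frame (boundary z = z_cut inclusive)."""
    ads = coords[:, 2] <= z_cut
    m = int(ads.sum())
    layers = topology.layers
    layer_ids = np.unique(layers)
    counts = {int(k): int(ads[layers == k].sum()) for k in layer_ids}
    fracs = {int(k): counts[int(k)] / int((layers == k).sum()) for k in layer_ids}
    return ContactResult(
        M=m, N=topology.n_atoms, fraction=m / topology.n_atoms,
        z_cut=z_cut, layer_counts=counts, layer_fractions=fracs,
    )


def contacts_over_frames(traj: Trajectory, z_cut: float = Z_CUT_DEFAULT,
                         production: float = 0.25) -> ContactResult:
    """Time-averaged contact statistics over the trailing production window."""
    sl = traj.production_slice(production)
    per_frame = [count_adsorbed(traj.coords[i], traj.topology, z_cut)
                 for i in range(sl.start, sl.stop)]
    n = traj.topology.n_atoms
    m = float(np.mean([c.M for c in per_frame]))
    keys = per_frame[0].layer_counts.keys()
    counts = {k: float(np.mean([c.layer_counts[k] for c in per_frame])) for k in keys}
    fracs = {k: float(np.mean([c.layer_fractions[k] for c in per_frame])) for k in keys}
    return ContactResult(M=m, N=n, fraction=m / n, z_cut=z_cut,
                         layer_counts=counts, layer_fractions=fracs,
                         n_frames=len(per_frame))


def layer_contact_fractions(traj: Trajectory, z_cut: float = Z_CUT_DEFAULT,
                            production: float = 0.25) -> pd.Series:
    """Time-averaged fraction of adsorbed atoms per structural layer."""
    c = contacts_over_frames(traj, z_cut, production)
    return pd.Series(c.layer_fractions, name="contact_fraction").sort_index()


def density_perp(coords_frames: np.ndarray, masses: np.ndarray,
                 dH: float = 0.2, h_max: float | None = None):
    """Mass-weighted histogram of heights, averaged over frames: ρ⊥(H).

    `coords_frames` is (nf, N, 3) or (N, 3).  Returns (h_centers, rho).
    """
    if dH <= 0:
        raise ValueError("dH must be > 0")
    frames = coords_frames[None] if coords_frames.ndim == 2 else coords_frames
    z = frames[:, :, 2]
    top = h_max if h_max is not None else float(z.max()) + dH
    edges = np.arange(0.0, top + dH, dH)
    rho = np.zeros(len(edges) - 1)
    for f in range(frames.shape[0]):
        hist, _ = np.histogram(z[f], bins=edges, weights=masses)
        rho += hist
    rho /= frames.shape[0] * dH
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rho


def density_parallel(coords_frames: np.ndarray, masses: np.ndarray,
                     dR: float = 1.0, r_max: float | None = None):
    """Annular areal density around the lateral COM: ρ∥(R).

    The centre of mass is recomputed per frame, so lateral diffusion does
    not smear the profile.  Returns (r_centers, rho, annulus_areas).
    """
    if dR <= 0:
        raise ValueError("dR must be > 0")
    frames = coords_frames[None] if coords_frames.ndim == 2 else coords_frames
    mtot = masses.sum()
    rmax_obs = 0.0
    radii = []
    for f in range(frames.shape[0]):
        com = (frames[f, :, :2] * masses[:, None]).sum(0) / mtot
        r = np.linalg.norm(frames[f, :, :2] - com, axis=1)
        radii.append(r)
        rmax_obs = max(rmax_obs, float(r.max()))
    top = r_max if r_max is not None else rmax_obs + dR
    edges = np.arange(0.0, top + dR, dR)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    rho = np.zeros(len(areas))
    for r in radii:
        hist, _ = np.histogram(r, bins=edges, weights=masses)
        rho += hist
    rho /= len(radii)
    rho /= areas
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rho, areas


def density_profiles(traj: Trajectory, dH: float = 0.2, dR: float = 1.0,
                     production: float = 0.25) -> DensityProfiles:
    sl = traj.production_slice(production)
    frames = traj.coords[sl]
    masses = traj.topology.masses
    h, rp = density_perp(frames, masses, dH)
    r, rl, areas = density_parallel(frames, masses, dR)
    return DensityProfiles(h_centers=h, dH=dH, rho_perp=rp,
                           r_centers=r, dR=dR, rho_par=rl, annulus_areas=areas)


# --- energy audit -----------------------------------------------------------

def energy_audit(trajs_by_eps: dict[float, Trajectory],
                 production: float = 0.25,
                 reference: float | None = None) -> pd.DataFrame:
    """Per-atom potential-energy terms vs wall strength ε, with percent changes.

    Returns a DataFrame indexed by ε with columns ``U12 … U_ads`` (per-atom
    means over the production window, kcal/mol) and ``dU12_pct …`` (percent
    change relative to the reference ε, by default the smallest one present;
    the wall term itself is excluded from the percent comparison).
    """
    if len(trajs_by_eps) < 2:
        raise ValueError("energy audit needs at least two ε values")
    eps_values = sorted(trajs_by_eps)
    ref = reference if reference is not None else eps_values[0]
    if ref not in trajs_by_eps:
        raise ValueError(f"reference ε = {ref} not among trajectories")

    rows = {}
    for eps in eps_values:
        traj = trajs_by_eps[eps]
        sl = traj.production_slice(production)
        mean = traj.energies[sl].mean(0) / traj.topology.n_atoms
        rows[eps] = dict(zip(ENERGY_COMPONENTS, mean))
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "epsilon"
    for comp in ENERGY_COMPONENTS:
        if comp == "U_ads":
            continue
        base = table.loc[ref, comp]
        denom = abs(base) if abs(base) > 1e-12 else np.nan
        table[f"d{comp}_pct"] = (table[comp] - base) / denom * 100.0
    return table


# --- shape ------------------------------------------------------------------

@dataclass
class ShapeMetrics:
    eigenvalues: np.ndarray      # ascending, Å²
    rg: float                    # Å
    height: float                # max z − min z, Å
    lateral_radius: float        # sqrt(λx + λy of in-plane tensor), Å
    asphericity: float           # λ3 − (λ1 + λ2)/2, Å²


def shape_metrics(coords: np.ndarray, masses: np.ndarray) -> ShapeMetrics:
    """Mass-weighted gyration-tensor shape descriptors of one frame."""
    mtot = masses.sum()
    com = (coords * masses[:, None]).sum(0) / mtot
    d = coords - com
    gyr = np.einsum("i,ij,ik->jk", masses, d, d) / mtot
    evals = np.sort(np.linalg.eigvalsh(gyr))
    rg = float(np.sqrt(evals.sum()))
    height = float(coords[:, 2].max() - coords[:, 2].min()) if len(coords) else 0.0
    lateral = float(np.sqrt(gyr[0, 0] + gyr[1, 1]))
    asph = float(evals[2] - 0.5 * (evals[0] + evals[1]))
    return ShapeMetrics(eigenvalues=evals, rg=rg, height=height,
                        lateral_radius=lateral, asphericity=asph)


def frontal_projection(coords: np.ndarray, topology: MolecularTopology,
                       z_cut: float = Z_CUT_DEFAULT) -> pd.DataFrame:
    """x,y positions of atoms inside the adsorption layer, tagged by layer.

    The point set is what a bottom view of the adsorption layer shows; it can
    be scattered colour-coded by ``layer`` to visualise which structural
    layers touch the surface.
    """
    mask = coords[:, 2] <= z_cut
    return pd.DataFrame({
        "x": coords[mask, 0],
        "y": coords[mask, 1],
        "layer": topology.layers[mask],
        "atom_id": np.nonzero(mask)[0],
    })


# --- replica aggregation ----------------------------------------------------

def aggregate(values: dict[str, list[float]] | pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error over replicas for each named observable.

    SEM uses n−1 normalisation and is reported only when ≥ 2 replicas are
    present.  Input: mapping observable → list of per-replica values (or an
    equivalent DataFrame with one row per replica).
    """
    df = pd.DataFrame(values)
    out = pd.DataFrame({"mean": df.mean(0), "n": df.count()})
    sem = df.std(0, ddof=1) / np.sqrt(df.count())
    out["sem"] = sem.where(df.count() >= 2)
    return out
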