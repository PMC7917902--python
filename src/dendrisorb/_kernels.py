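"""Numba-compiled energy/force kernels and the fused MD inner loop.

All kernels work on plain float64/int64 arrays prepared by
:mod:`dendrisorb.forcefield`.  Energies are kcal/mol, forces kcal/mol/Å;
the integrator converts to internal units (Da Å²/ps²) via ``KCAL``.
"""

import numpy as np
from numba import njit

KCAL = 418.4          # Da Å²/ps² per kcal/mol
KB = 0.0019872041     # kcal/mol/K
COULOMB = 332.0637    # kcal Å/(mol e²)

# exclusion codes
EXCL_NONE = 0
EXCL_FULL = 1
EXCL_14 = 2


@njit(cache=True)
def bonded_forces(coords, bonds, bond_b0, bond_k, angles, angle_th0, angle_k,
                  dihedrals, dih_k, dih_n, dih_delta, forces):
    """Accumulate U12/U13/U14 contributions into `forces`; return energies."""
    u12 = 0.0
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        db = r - bond_b0[b]
        u12 += bond_k[b] * db * db
        f = -2.0 * bond_k[b] * db / r
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz

    u13 = 0.0
    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        r1x = coords[i, 0] - coords[j, 0]
        r1y = coords[i, 1] - coords[j, 1]
        r1z = coords[i, 2] - coords[j, 2]
        r2x = coords[k, 0] - coords[j, 0]
        r2y = coords[k, 1] - coords[j, 1]
        r2z = coords[k, 2] - coords[j, 2]
        n1 = np.sqrt(r1x * r1x + r1y * r1y + r1z * r1z)
        n2 = np.sqrt(r2x * r2x + r2y * r2y + r2z * r2z)
        ct = (r1x * r2x + r1y * r2y + r1z * r2z) / (n1 * n2)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        dth = theta - angle_th0[a]
        u13 += angle_k[a] * dth * dth
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-8:
            st = 1e-8
        coef = 2.0 * angle_k[a] * dth / st
        inv12 = 1.0 / (n1 * n2)
        inv11 = ct / (n1 * n1)
        inv22 = ct / (n2 * n2)
        dix = coef * (r2x * inv12 - r1x * inv11)
        diy = coef * (r2y * inv12 - r1y * inv11)
        diz = coef * (r2z * inv12 - r1z * inv11)
        dkx = coef * (r1x * inv12 - r2x * inv22)
        dky = coef * (r1y * inv12 - r2y * inv22)
        dkz = coef * (r1z * inv12 - r2z * inv22)
        forces[i, 0] += dix
        forces[i, 1] += diy
        forces[i, 2] += diz
        forces[k, 0] += dkx
        forces[k, 1] += dky
        forces[k, 2] += dkz
        forces[j, 0] -= dix + dkx
        forces[j, 1] -= diy + dky
        forces[j, 2] -= diz + dkz

    u14 = 0.0
    for t in range(dihedrals.shape[0]):
        i, j, k, l = dihedrals[t, 0], dihedrals[t, 1], dihedrals[t, 2], dihedrals[t, 3]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        c1x = b1y * b2z - b1z * b2y
        c1y = b1z * b2x - b1x * b2z
        c1z = b1x * b2y - b1y * b2x
        c2x = b2y * b3z - b2z * b3y
        c2y = b2z * b3x - b2x * b3z
        c2z = b2x * b3y - b2y * b3x
        n1sq = c1x * c1x + c1y * c1y + c1z * c1z
        n2sq = c2x * c2x + c2y * c2y + c2z * c2z
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-10 or n2sq < 1e-10:
            continue
        cxx = c1y * c2z - c1z * c2y
        cxy = c1z * c2x - c1x * c2z
        cxz = c1x * c2y - c1y * c2x
        sphi = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        cphi = c1x * c2x + c1y * c2y + c1z * c2z
        phi = np.arctan2(sphi, cphi)
        u14 += dih_k[t] * (1.0 + np.cos(dih_n[t] * phi - dih_delta[t]))
        dudphi = -dih_k[t] * dih_n[t] * np.sin(dih_n[t] * phi - dih_delta[t])
        # dphi/dr per the two-normal formulation
        ai = -nb2 / n1sq
        al = nb2 / n2sq
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        gix = -dudphi * ai * c1x
        giy = -dudphi * ai * c1y
        giz = -dudphi * ai * c1z
        glx = -dudphi * al * c2x
        gly = -dudphi * al * c2y
        glz = -dudphi * al * c2z
        forces[i, 0] += gix
        forces[i, 1] += giy
        forces[i, 2] += giz
        forces[l, 0] += glx
        forces[l, 1] += gly
        forces[l, 2] += glz
        forces[j, 0] += (-1.0 - p) * gix + q * glx
        forces[j, 1] += (-1.0 - p) * giy + q * gly
        forces[j, 2] += (-1.0 - p) * giz + q * glz
        forces[k, 0] += p * gix + (-1.0 - q) * glx
        forces[k, 1] += p * giy + (-1.0 - q) * gly
        forces[k, 2] += p * giz + (-1.0 - q) * glz
    return u12, u13, u14


@njit(cache=True)
def nonbonded_forces(coords, lj_eps, lj_sig, charges, excl, cutoff, scale14,
                     diel_scale, shift, forces):
    """Pairwise LJ + screened Coulomb with 1-2/1-3 exclusion, scaled 1-4."""
    n = coords.shape[0]
    uvw = 0.0
    uqq = 0.0
    cut2 = cutoff * cutoff
    for i in range(n):
        for j in range(i + 1, n):
            code = excl[i, j]
            if code == EXCL_FULL:
                continue
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > cut2:
                continue
            scale = scale14 if code == EXCL_14 else 1.0
            eps = np.sqrt(lj_eps[i] * lj_eps[j])
            sig = 0.5 * (lj_sig[i] + lj_sig[j])
            s2 = sig * sig / r2
            s6 = s2 * s2 * s2
            u = 4.0 * eps * (s6 * s6 - s6)
            if shift:
                sc2 = sig * sig / cut2
                sc6 = sc2 * sc2 * sc2
                u -= 4.0 * eps * (sc6 * sc6 - sc6)
            uvw += scale * u
            # (F/r) along r_ij so components are f·(dx,dy,dz)
            f = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
            qq = charges[i] * charges[j]
            if qq != 0.0:
                # screened Coulomb: distance-dependent dielectric ⇒ U ∝ 1/r²
                uq = COULOMB * qq / (diel_scale * r2)
                if shift:
                    uq -= COULOMB * qq / (diel_scale * cut2)
                uqq += scale * uq
                f += 2.0 * COULOMB * qq / (diel_scale * r2 * r2)
            fx = scale * f
            forces[j, 0] += fx * dx
            forces[j, 1] += fx * dy
            forces[j, 2] += fx * dz
            forces[i, 0] -= fx * dx
            forces[i, 1] -= fx * dy
            forces[i, 2] -= fx * dz
    return uvw, uqq


@njit(cache=True)
def build_pairs(coords, excl, r_list):
    """Verlet pair list: non-excluded pairs within r_list (cutoff + skin)."""
    n = coords.shape[0]
    r2max = r_list * r_list
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if excl[i, j] == EXCL_FULL:
                continue
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            if dx * dx + dy * dy + dz * dz <= r2max:
                count += 1
    pi = np.empty(count, dtype=np.int64)
    pj = np.empty(count, dtype=np.int64)
    pc = np.empty(count, dtype=np.int8)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            code = excl[i, j]
            if code == EXCL_FULL:
                continue
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            if dx * dx + dy * dy + dz * dz <= r2max:
                pi[k] = i
                pj[k] = j
                pc[k] = code
                k += 1
    return pi, pj, pc


@njit(cache=True)
def nonbonded_pairs(coords, lj_eps, lj_sig, charges, pi, pj, pc, cutoff,
                    scale14, diel_scale, shift, forces):
    """Same physics as `nonbonded_forces` but over a precomputed pair list."""
    uvw = 0.0
    uqq = 0.0
    cut2 = cutoff * cutoff
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cut2:
            continue
        scale = scale14 if pc[k] == EXCL_14 else 1.0
        eps = np.sqrt(lj_eps[i] * lj_eps[j])
        sig = 0.5 * (lj_sig[i] + lj_sig[j])
        s2 = sig * sig / r2
        s6 = s2 * s2 * s2
        u = 4.0 * eps * (s6 * s6 - s6)
        if shift:
            sc2 = sig * sig / cut2
            sc6 = sc2 * sc2 * sc2
            u -= 4.0 * eps * (sc6 * sc6 - sc6)
        uvw += scale * u
        f = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
        qq = charges[i] * charges[j]
        if qq != 0.0:
            uq = COULOMB * qq / (diel_scale * r2)
            if shift:
                uq -= COULOMB * qq / (diel_scale * cut2)
            uqq += scale * uq
            f += 2.0 * COULOMB * qq / (diel_scale * r2 * r2)
        fx = scale * f
        forces[j, 0] += fx * dx
        forces[j, 1] += fx * dy
        forces[j, 2] += fx * dz
        forces[i, 0] -= fx * dx
        forces[i, 1] -= fx * dy
        forces[i, 2] -= fx * dz
    return uvw, uqq


@njit(cache=True)
def wall_forces(coords, eps, r_min, cutoff, forces):
    """9-3 wall at z = 0: U(z) = 0.5 ε ((R/z)^9 − 3 (R/z)^3), zero past cutoff.

    Returns (U_ads, ok); ok is False if any atom sits at z ≤ 0.
    """
    u = 0.0
    if eps == 0.0:
        return 0.0, True
    for i in range(coords.shape[0]):
        z = coords[i, 2]
        if z <= 0.0:
            return u, False
        if z > cutoff:
            continue
        s3 = (r_min / z) ** 3
        s9 = s3 * s3 * s3
        u += 0.5 * eps * (s9 - 3.0 * s3)
        # F_z = −dU/dz = 0.5 ε (9 s9 − 9 s3)/z
        forces[i, 2] += 4.5 * eps * (s9 - s3) / z
    return u, True


@njit(cache=True)
def compute_all(coords, bonds, bond_b0, bond_k, angles, angle_th0, angle_k,
                dihedrals, dih_k, dih_n, dih_delta,
                lj_eps, lj_sig, charges, excl, cutoff, scale14, diel_scale,
                shift, wall_on, wall_eps, wall_rmin, wall_cut):
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    u12, u13, u14 = bonded_forces(coords, bonds, bond_b0, bond_k, angles,
                                  angle_th0, angle_k, dihedrals, dih_k, dih_n,
                                  dih_delta, forces)
    uvw, uqq = nonbonded_forces(coords, lj_eps, lj_sig, charges, excl, cutoff,
                                scale14, diel_scale, shift, forces)
    uads = 0.0
    ok = True
    if wall_on:
        uads, ok = wall_forces(coords, wall_eps, wall_rmin, wall_cut, forces)
    energies = np.array([u12, u13, u14, uvw, uqq, uads])
    return forces, energies, ok


@njit(cache=True)
def run_md(coords, vels, masses, dt, n_steps, sample_every,
           bonds, bond_b0, bond_k, angles, angle_th0, angle_k,
           dihedrals, dih_k, dih_n, dih_delta,
           lj_eps, lj_sig, charges, excl, cutoff, scale14, diel_scale, shift,
           wall_on, wall_eps, wall_rmin, wall_cut,
           thermo_lambda, thermo_m0, temperature, seed):
    """Velocity-Verlet loop with a collisional thermostat.

    Each step, every atom independently collides with probability λ·dt with a
    virtual particle of mass m0 whose velocity is Maxwell-distributed at T;
    the elastic collision conserves the pair momentum.  Returns sampled
    frames and a status flag (0 ok, 1 non-finite, 2 wall penetration).
    """
    np.random.seed(seed)
    n = coords.shape[0]
    n_samples = n_steps // sample_every
    out_coords = np.zeros((n_samples, n, 3))
    out_vels = np.zeros((n_samples, n, 3))
    out_energies = np.zeros((n_samples, 6))
    out_kin = np.zeros(n_samples)

    skin = 1.5  # Å; rebuild interval below keeps max drift well under skin/2
    rebuild_every = 25
    pi, pj, pc = build_pairs(coords, excl, cutoff + skin)

    forces = np.zeros((n, 3))
    energies = np.zeros(6)
    u12, u13, u14 = bonded_forces(coords, bonds, bond_b0, bond_k, angles,
                                  angle_th0, angle_k, dihedrals, dih_k, dih_n,
                                  dih_delta, forces)
    uvw, uqq = nonbonded_pairs(coords, lj_eps, lj_sig, charges, pi, pj, pc,
                               cutoff, scale14, diel_scale, shift, forces)
    uads = 0.0
    ok = True
    if wall_on:
        uads, ok = wall_forces(coords, wall_eps, wall_rmin, wall_cut, forces)
    energies[0] = u12
    energies[1] = u13
    energies[2] = u14
    energies[3] = uvw
    energies[4] = uqq
    energies[5] = uads
    if not ok:
        return out_coords, out_vels, out_energies, out_kin, 0, 2

    p_collide = thermo_lambda * dt
    kT = KB * temperature
    isample = 0
    for step in range(n_steps):
        for i in range(n):
            inv_m = KCAL / masses[i]
            for d in range(3):
                vels[i, d] += 0.5 * dt * forces[i, d] * inv_m
                coords[i, d] += dt * vels[i, d]
        if (step + 1) % rebuild_every == 0:
            pi, pj, pc = build_pairs(coords, excl, cutoff + skin)
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        u12, u13, u14 = bonded_forces(coords, bonds, bond_b0, bond_k, angles,
                                      angle_th0, angle_k, dihedrals, dih_k,
                                      dih_n, dih_delta, forces)
        uvw, uqq = nonbonded_pairs(coords, lj_eps, lj_sig, charges, pi, pj, pc,
                                   cutoff, scale14, diel_scale, shift, forces)
        uads = 0.0
        ok = True
        if wall_on:
            uads, ok = wall_forces(coords, wall_eps, wall_rmin, wall_cut, forces)
        energies[0] = u12
        energies[1] = u13
        energies[2] = u14
        energies[3] = uvw
        energies[4] = uqq
        energies[5] = uads
        if not ok:
            return out_coords, out_vels, out_energies, out_kin, isample, 2
        for i in range(n):
            inv_m = KCAL / masses[i]
            for d in range(3):
                vels[i, d] += 0.5 * dt * forces[i, d] * inv_m
        if not np.isfinite(coords).all():
            return out_coords, out_vels, out_energies, out_kin, isample, 1
        if p_collide > 0.0:
            for i in range(n):
                if np.random.random() < p_collide:
                    m = masses[i]
                    sd = np.sqrt(kT * KCAL / thermo_m0)
                    for d in range(3):
                        u = np.random.normal(0.0, sd)
                        vels[i, d] = ((m - thermo_m0) * vels[i, d]
                                      + 2.0 * thermo_m0 * u) / (m + thermo_m0)
        if (step + 1) % sample_every == 0:
            kin = 0.0
            for i in range(n):
                kin += 0.5 * masses[i] * (vels[i, 0] ** 2 + vels[i, 1] ** 2
                                          + vels[i, 2] ** 2)
            out_coords[isample] = coords
            out_vels[isample] = vels
            out_energies[isample] = energies
            out_kin[isample] = kin / KCAL  # kcal/mol
            isample += 1
    return out_coords, out_vels, out_energies, out_kin, isample, 0
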