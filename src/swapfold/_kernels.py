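"""Numba force and Langevin-integrator kernels.

All arrays are float64/int64; coordinates in nm, energies kcal/mol, time
ps, mass in kcal-consistent units (u / 4.184).  The integrator is BAOAB
underdamped Langevin; noise is pre-generated per chunk by the caller from
a seeded numpy Generator, which makes trajectories bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KB = 0.0019872  # kcal/mol/K
RESIDUE_MASS = 110.0 / 4.184  # kcal-consistent mass units


@njit(cache=True)
def compute_forces(
    coords,
    bond_i, bond_j, bond_r0, bond_k,
    ang_i, ang_j, ang_k, ang_theta0, ang_kth,
    dih_i, dih_j, dih_k, dih_l, dih_phi0, dih_k1, dih_k3,
    con_i, con_j, con_eps, con_r0,
    sigma, native_mask, min_seq_sep,
    teth_k, teth_center,
    bias_i, bias_j, bias_r0, bias_kappa, bias_q0, bias_beta, bias_lam,
    forces,
):
    n = coords.shape[0]
    for a in range(n):
        for d in range(3):
            forces[a, d] = 0.0
    energy = 0.0

    # bonds
    for b in range(bond_i.shape[0]):
        i, j = bond_i[b], bond_j[b]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        energy += 0.5 * bond_k[b] * dr * dr
        f = -bond_k[b] * dr / r
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz

    # angles
    for b in range(ang_i.shape[0]):
        i, j, k = ang_i[b], ang_j[b], ang_k[b]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[k, 0] - coords[j, 0]
        vy = coords[k, 1] - coords[j, 1]
        vz = coords[k, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        # cap the 1/sin factor near collinearity: the harmonic energy stays
        # exact, the force is merely bounded there
        if s < 0.1:
            s = 0.1
        dth = theta - ang_theta0[b]
        energy += 0.5 * ang_kth[b] * dth * dth
        dvdth = ang_kth[b] * dth
        coef = dvdth / s
        # dc/dri = (v_hat - c*u_hat)/nu ; F_i = coef * dc/dri
        fix = coef * (vx / (nu * nv) - c * ux / (nu * nu))
        fiy = coef * (vy / (nu * nv) - c * uy / (nu * nu))
        fiz = coef * (vz / (nu * nv) - c * uz / (nu * nu))
        fkx = coef * (ux / (nu * nv) - c * vx / (nv * nv))
        fky = coef * (uy / (nu * nv) - c * vy / (nv * nv))
        fkz = coef * (uz / (nu * nv) - c * vz / (nv * nv))
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz

    # dihedrals
    for b in range(dih_i.shape[0]):
        if dih_k1[b] == 0.0 and dih_k3[b] == 0.0:
            continue
        i, j, k, l = dih_i[b], dih_j[b], dih_k[b], dih_l[b]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        m1x = n1y * b2z - n1z * b2y
        m1y = n1z * b2x - n1x * b2z
        m1z = n1x * b2y - n1y * b2x
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = (m1x * n2x + m1y * n2y + m1z * n2z) / nb2
        phi = np.arctan2(y, x)
        dphi = phi - dih_phi0[b]
        energy += dih_k1[b] * (1.0 - np.cos(dphi)) + dih_k3[b] * (1.0 - np.cos(3.0 * dphi))
        dvdphi = dih_k1[b] * np.sin(dphi) + 3.0 * dih_k3[b] * np.sin(3.0 * dphi)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        # near-collinear backbone: the dihedral is ill-defined; drop the
        # force (energy unchanged) rather than divide by ~0
        if n1sq < 1e-5 or n2sq < 1e-5:
            continue
        fix = -dvdphi * nb2 / n1sq * n1x
        fiy = -dvdphi * nb2 / n1sq * n1y
        fiz = -dvdphi * nb2 / n1sq * n1z
        flx = dvdphi * nb2 / n2sq * n2x
        fly = dvdphi * nb2 / n2sq * n2y
        flz = dvdphi * nb2 / n2sq * n2z
        t = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        u = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        fjx = -(1.0 + t) * fix + u * flx
        fjy = -(1.0 + t) * fiy + u * fly
        fjz = -(1.0 + t) * fiz + u * flz
        fkx = t * fix - (1.0 + u) * flx
        fky = t * fiy - (1.0 + u) * fly
        fkz = t * fiz - (1.0 + u) * flz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[j, 0] += fjx
        forces[j, 1] += fjy
        forces[j, 2] += fjz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz

    # native contact wells: -eps*(5 s^12 - 6 s^10), s = r0/r, eps < 0
    for b in range(con_i.shape[0]):
        i, j = con_i[b], con_j[b]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 0.05:
            r = 0.05
        s = con_r0[b] / r
        s2 = s * s
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        energy += -con_eps[b] * (5.0 * s12 - 6.0 * s10)
        # dV/dr = 60*eps*(s12 - s10)/r ; f = -dV/dr / r (radial coefficient)
        dvdr = 60.0 * con_eps[b] * (s12 - s10) / r
        f = -dvdr / r
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz

    # excluded volume for non-native pairs with j - i >= min_seq_sep
    eps_rep = 0.2
    for i in range(n):
        for j in range(i + min_seq_sep, n):
            if native_mask[i, j]:
                continue
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            sig = 0.5 * (sigma[i] + sigma[j])
            if r2 > 4.0 * sig * sig:
                continue
            r = np.sqrt(r2)
            if r < 0.3 * sig:
                r = 0.3 * sig
            sr = sig / r
            sr12 = (sr * sr * sr) ** 4
            energy += eps_rep * sr12
            f = 12.0 * eps_rep * sr12 / (r * r)
            forces[j, 0] += f * dx
            forces[j, 1] += f * dy
            forces[j, 2] += f * dz
            forces[i, 0] -= f * dx
            forces[i, 1] -= f * dy
            forces[i, 2] -= f * dz

    # optional per-bead isotropic tether (test systems)
    for a in range(teth_k.shape[0]):
        if teth_k[a] == 0.0:
            continue
        for d in range(3):
            dr = coords[a, d] - teth_center[a, d]
            energy += 0.5 * teth_k[a] * dr * dr
            forces[a, d] -= teth_k[a] * dr

    # optional harmonic umbrella bias on the contact coordinate Q
    if bias_kappa > 0.0 and bias_i.shape[0] > 0:
        nb = bias_i.shape[0]
        q = 0.0
        fvals = np.empty(nb)
        rvals = np.empty(nb)
        for b in range(nb):
            i, j = bias_i[b], bias_j[b]
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            xarg = bias_beta * (r - bias_lam * bias_r0[b])
            if xarg > 60.0:
                fc = 0.0
            elif xarg < -60.0:
                fc = 1.0
            else:
                fc = 1.0 / (1.0 + np.exp(xarg))
            fvals[b] = fc
            rvals[b] = r
            q += fc
        q /= nb
        energy += 0.5 * bias_kappa * (q - bias_q0) ** 2
        pref = bias_kappa * (q - bias_q0) / nb
        for b in range(nb):
            fc = fvals[b]
            if fc <= 0.0 or fc >= 1.0:
                continue
            i, j = bias_i[b], bias_j[b]
            r = rvals[b]
            dqdr = -bias_beta * fc * (1.0 - fc)
            coef = -pref * dqdr / r  # radial force coefficient on j
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            forces[j, 0] += coef * dx
            forces[j, 1] += coef * dy
            forces[j, 2] += coef * dz
            forces[i, 0] -= coef * dx
            forces[i, 1] -= coef * dy
            forces[i, 2] -= coef * dz

    return energy


@njit(cache=True)
def baoab_chunk(
    coords, vel, noise, dt, friction, kbt, mass,
    bond_i, bond_j, bond_r0, bond_k,
    ang_i, ang_j, ang_k, ang_theta0, ang_kth,
    dih_i, dih_j, dih_k, dih_l, dih_phi0, dih_k1, dih_k3,
    con_i, con_j, con_eps, con_r0,
    sigma, native_mask, min_seq_sep,
    teth_k, teth_center,
    bias_i, bias_j, bias_r0, bias_kappa, bias_q0, bias_beta, bias_lam,
    forces,
):
    """Advance ``noise.shape[0]`` BAOAB steps in place; returns final energy."""
    n = coords.shape[0]
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kbt / mass)
    half = 0.5 * dt
    energy = compute_forces(
        coords,
        bond_i, bond_j, bond_r0, bond_k,
        ang_i, ang_j, ang_k, ang_theta0, ang_kth,
        dih_i, dih_j, dih_k, dih_l, dih_phi0, dih_k1, dih_k3,
        con_i, con_j, con_eps, con_r0,
        sigma, native_mask, min_seq_sep,
        teth_k, teth_center,
        bias_i, bias_j, bias_r0, bias_kappa, bias_q0, bias_beta, bias_lam,
        forces,
    )
    for step in range(noise.shape[0]):
        for a in range(n):
            for d in range(3):
                vel[a, d] += half * forces[a, d] / mass
                coords[a, d] += half * vel[a, d]
                vel[a, d] = c1 * vel[a, d] + c2 * noise[step, a, d]
                coords[a, d] += half * vel[a, d]
        energy = compute_forces(
            coords,
            bond_i, bond_j, bond_r0, bond_k,
            ang_i, ang_j, ang_k, ang_theta0, ang_kth,
            dih_i, dih_j, dih_k, dih_l, dih_phi0, dih_k1, dih_k3,
            con_i, con_j, con_eps, con_r0,
            sigma, native_mask, min_seq_sep,
            teth_k, teth_center,
            bias_i, bias_j, bias_r0, bias_kappa, bias_q0, bias_beta, bias_lam,
            forces,
        )
        for a in range(n):
            for d in range(3):
                vel[a, d] += half * forces[a, d] / mass
    return energy
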