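"""Numba force/integration kernels.

All masses are unity (segments and fluid particles share the same mass in
this model; core and anchors are frozen so their mass never enters).
Pair interactions use the shifted-force LJ form; directly bonded (1-2)
pairs are excluded from the pair sum and interact only through the
harmonic spring.

Status codes returned by :func:`integrate`:
0 ok, 1 overlap singularity, 2 instability (per-step displacement > 0.5).
"""

import numpy as np
from numba import njit

__all__ = ["forces_n2", "forces_cell", "integrate"]


@njit(cache=True)
def _pair_sf(r2, ti, tj, c12, c6, rc2, rcm, fcm, ucm):
    """Shifted-force LJ: returns (u, F/r) for one pair inside cutoff."""
    r6 = r2 * r2 * r2
    r12 = r6 * r6
    a = c12[ti, tj]
    b = c6[ti, tj]
    r = np.sqrt(r2)
    u_lj = a / r12 - b / r6
    f_lj = (12.0 * a / r12 - 6.0 * b / r6) / r
    fc = fcm[ti, tj]
    u = u_lj - ucm[ti, tj] + (r - rcm[ti, tj]) * fc
    fr = (f_lj - fc) / r
    return u, fr


@njit(cache=True)
def _bond_accum(pos, bonds, kbond, r0b, L, per, forces):
    epot = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if per[0]:
            dx -= L[0] * np.floor(dx / L[0] + 0.5)
        if per[1]:
            dy -= L[1] * np.floor(dy / L[1] + 0.5)
        if per[2]:
            dz -= L[2] * np.floor(dz / L[2] + 0.5)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0b
        epot += kbond * dr * dr
        fmag = -2.0 * kbond * dr / r
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return epot


@njit(cache=True)
def forces_n2(pos, species, L, per, c12, c6, rc2, rcm, fcm, ucm, excl,
              bonds, kbond, r0b, forces):
    """O(N^2) pair sum with minimum image; returns potential energy.

    Returns NaN on an overlap singularity (r^2 < 1e-12).
    """
    N = pos.shape[0]
    for i in range(N):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    epot = 0.0
    for i in range(N):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        ti = species[i]
        for j in range(i + 1, N):
            if j == excl[i, 0] or j == excl[i, 1]:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if per[0]:
                dx -= L[0] * np.floor(dx / L[0] + 0.5)
            if per[1]:
                dy -= L[1] * np.floor(dy / L[1] + 0.5)
            if per[2]:
                dz -= L[2] * np.floor(dz / L[2] + 0.5)
            tj = species[j]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2[ti, tj]:
                continue
            if r2 < 1e-12:
                return np.nan
            u, fr = _pair_sf(r2, ti, tj, c12, c6, rc2, rcm, fcm, ucm)
            epot += u
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
    epot += _bond_accum(pos, bonds, kbond, r0b, L, per, forces)
    return epot


@njit(cache=True)
def forces_cell(pos, species, L, c12, c6, rc2, rcm, fcm, ucm, excl,
                bonds, kbond, r0b, forces, ncell, head, nxt):
    """Cell-list pair sum for a fully periodic box (>= 4 cells per axis)."""
    N = pos.shape[0]
    ncx, ncy, ncz = ncell[0], ncell[1], ncell[2]
    for i in range(N):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for c in range(ncx * ncy * ncz):
        head[c] = -1
    for i in range(N):
        cx = int(pos[i, 0] / L[0] * ncx)
        cy = int(pos[i, 1] / L[1] * ncy)
        cz = int(pos[i, 2] / L[2] * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i

    # half-stencil: each unordered neighbor-cell pair visited once
    offs = np.array(
        [
            (0, 0, 0),
            (1, -1, -1), (1, -1, 0), (1, -1, 1),
            (1, 0, -1), (1, 0, 0), (1, 0, 1),
            (1, 1, -1), (1, 1, 0), (1, 1, 1),
            (0, 1, -1), (0, 1, 0), (0, 1, 1),
            (0, 0, 1),
        ],
        dtype=np.int64,
    )
    epot = 0.0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c1 = (cx * ncy + cy) * ncz + cz
                for k in range(offs.shape[0]):
                    same = k == 0
                    nx = (cx + offs[k, 0]) % ncx
                    ny = (cy + offs[k, 1]) % ncy
                    nz = (cz + offs[k, 2]) % ncz
                    c2 = (nx * ncy + ny) * ncz + nz
                    i = head[c1]
                    while i >= 0:
                        ti = species[i]
                        j = head[c2] if not same else nxt[i]
                        while j >= 0:
                            if not (j == excl[i, 0] or j == excl[i, 1]):
                                dx = pos[i, 0] - pos[j, 0]
                                dy = pos[i, 1] - pos[j, 1]
                                dz = pos[i, 2] - pos[j, 2]
                                dx -= L[0] * np.floor(dx / L[0] + 0.5)
                                dy -= L[1] * np.floor(dy / L[1] + 0.5)
                                dz -= L[2] * np.floor(dz / L[2] + 0.5)
                                tj = species[j]
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 < rc2[ti, tj]:
                                    if r2 < 1e-12:
                                        return np.nan
                                    u, fr = _pair_sf(
                                        r2, ti, tj, c12, c6, rc2, rcm, fcm, ucm
                                    )
                                    epot += u
                                    forces[i, 0] += fr * dx
                                    forces[i, 1] += fr * dy
                                    forces[i, 2] += fr * dz
                                    forces[j, 0] -= fr * dx
                                    forces[j, 1] -= fr * dy
                                    forces[j, 2] -= fr * dz
                            j = nxt[j]
                        i = nxt[i]
    per3 = np.array([True, True, True])
    epot += _bond_accum(pos, bonds, kbond, r0b, L, per3, forces)
    return epot


@njit(cache=True)
def _kinetic2(vel, mobile):
    k2 = 0.0
    for i in range(vel.shape[0]):
        if mobile[i]:
            k2 += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
    return k2


@njit(cache=True)
def _nh_half(vel, mobile, dt, T, ndof, Q, vxi):
    """Half step of a single Nose-Hoover thermostat (MTK splitting)."""
    k2 = _kinetic2(vel, mobile)
    G = (k2 - ndof * T) / Q
    vxi[0] += 0.25 * dt * G
    s = np.exp(-0.5 * dt * vxi[0])
    for i in range(vel.shape[0]):
        if mobile[i]:
            vel[i, 0] *= s
            vel[i, 1] *= s
            vel[i, 2] *= s
    k2 *= s * s
    G = (k2 - ndof * T) / Q
    vxi[0] += 0.25 * dt * G


@njit(cache=True)
def integrate(pos, vel, forces, species, mobile, L, per,
              c12, c6, rc2, rcm, fcm, ucm, excl, bonds, kbond, r0b,
              dt, nsteps, use_cell, ncell, head, nxt,
              thermostat_on, T_target, ndof, Q, vxi,
              slab, wall_off):
    """Velocity-Verlet NVT/NVE for ``nsteps`` steps, in place.

    ``wall_off[t]`` is the half-diameter wall offset of species ``t`` for
    slab geometry (specular reflection at z = off and z = Lz - off).
    Returns (epot, ekin, status).
    """
    N = pos.shape[0]
    if use_cell:
        epot = forces_cell(pos, species, L, c12, c6, rc2, rcm, fcm, ucm,
                           excl, bonds, kbond, r0b, forces, ncell, head, nxt)
    else:
        epot = forces_n2(pos, species, L, per, c12, c6, rc2, rcm, fcm, ucm,
                         excl, bonds, kbond, r0b, forces)
    if np.isnan(epot):
        return epot, 0.0, 1

    for _step in range(nsteps):
        if thermostat_on:
            _nh_half(vel, mobile, dt, T_target, ndof, Q, vxi)
        maxd2 = 0.0
        for i in range(N):
            if mobile[i]:
                vel[i, 0] += 0.5 * dt * forces[i, 0]
                vel[i, 1] += 0.5 * dt * forces[i, 1]
                vel[i, 2] += 0.5 * dt * forces[i, 2]
                dx = dt * vel[i, 0]
                dy = dt * vel[i, 1]
                dz = dt * vel[i, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > maxd2:
                    maxd2 = d2
                pos[i, 0] += dx
                pos[i, 1] += dy
                pos[i, 2] += dz
                if per[0]:
                    pos[i, 0] -= L[0] * np.floor(pos[i, 0] / L[0])
                if per[1]:
                    pos[i, 1] -= L[1] * np.floor(pos[i, 1] / L[1])
                if per[2]:
                    pos[i, 2] -= L[2] * np.floor(pos[i, 2] / L[2])
                if slab:
                    off = wall_off[species[i]]
                    if pos[i, 2] < off:
                        pos[i, 2] = 2.0 * off - pos[i, 2]
                        vel[i, 2] = -vel[i, 2]
                    hi = L[2] - off
                    if pos[i, 2] > hi:
                        pos[i, 2] = 2.0 * hi - pos[i, 2]
                        vel[i, 2] = -vel[i, 2]
        if maxd2 > 0.25:
            return epot, 0.5 * _kinetic2(vel, mobile), 2
        if use_cell:
            epot = forces_cell(pos, species, L, c12, c6, rc2, rcm, fcm, ucm,
                               excl, bonds, kbond, r0b, forces, ncell, head, nxt)
        else:
            epot = forces_n2(pos, species, L, per, c12, c6, rc2, rcm, fcm, ucm,
                             excl, bonds, kbond, r0b, forces)
        if np.isnan(epot):
            return epot, 0.0, 1
        for i in range(N):
            if mobile[i]:
                vel[i, 0] += 0.5 * dt * forces[i, 0]
                vel[i, 1] += 0.5 * dt * forces[i, 1]
                vel[i, 2] += 0.5 * dt * forces[i, 2]
        if thermostat_on:
            _nh_half(vel, mobile, dt, T_target, ndof, Q, vxi)
    return epot, 0.5 * _kinetic2(vel, mobile), 0
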