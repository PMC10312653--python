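"""Numba kernels: neighbor lists, forces, Langevin integration, minimization.

All arrays are float64 / int64.  Periodic boundaries are orthorhombic with
minimum-image convention; positions are kept unwrapped (molecules stay whole)
and wrapped copies are used only for cell binning.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KB = 0.00831446261815324  # kJ/mol/K


@njit(cache=True, inline="always")
def _min_image(d, box):
    for k in range(3):
        d[k] -= box[k] * np.rint(d[k] / box[k])
    return d


@njit(cache=True)
def _is_excluded(i, j, excl_codes, n):
    if i > j:
        i, j = j, i
    code = i * n + j
    lo, hi = 0, len(excl_codes)
    while lo < hi:
        mid = (lo + hi) // 2
        if excl_codes[mid] < code:
            lo = mid + 1
        else:
            hi = mid
    return lo < len(excl_codes) and excl_codes[lo] == code


@njit(cache=True, fastmath={"contract", "reassoc", "nsz", "arcp"})
def build_pairs(pos, box, rlist, excl_codes, excl_max_sep, pairs_i, pairs_j):
    """Fill pair arrays with all non-excluded pairs within rlist.

    Uses a cell list when the box supports >=3 cells per dimension, otherwise
    falls back to an all-pairs scan.  Returns the pair count, or -1 when the
    provided arrays are too small (caller grows and retries).
    """
    n = pos.shape[0]
    cap = pairs_i.shape[0]
    ncx = max(1, int(box[0] / rlist))
    ncy = max(1, int(box[1] / rlist))
    ncz = max(1, int(box[2] / rlist))
    r2 = rlist * rlist
    count = 0
    if ncx < 3 or ncy < 3 or ncz < 3:
        for i in range(n):
            for j in range(i + 1, n):
                d0 = pos[i, 0] - pos[j, 0]
                d1 = pos[i, 1] - pos[j, 1]
                d2 = pos[i, 2] - pos[j, 2]
                d0 -= box[0] * np.rint(d0 / box[0])
                d1 -= box[1] * np.rint(d1 / box[1])
                d2 -= box[2] * np.rint(d2 / box[2])
                if d0 * d0 + d1 * d1 + d2 * d2 <= r2:
                    sep = j - i if j > i else i - j
                    if sep > excl_max_sep or not _is_excluded(i, j, excl_codes, n):
                        if count >= cap:
                            return -1
                        pairs_i[count] = i
                        pairs_j[count] = j
                        count += 1
        return count

    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] % box[0]) / box[0] * ncx) % ncx
        cy = int((pos[i, 1] % box[1]) / box[1] * ncy) % ncy
        cz = int((pos[i, 2] % box[2]) / box[2] * ncz) % ncz
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        nxt[i] = head[c]
        head[c] = i

    # half list of neighbor-cell offsets (13) plus the home cell
    offsets = np.array(
        [
            [0, 0, 1],
            [0, 1, -1],
            [0, 1, 0],
            [0, 1, 1],
            [1, -1, -1],
            [1, -1, 0],
            [1, -1, 1],
            [1, 0, -1],
            [1, 0, 0],
            [1, 0, 1],
            [1, 1, -1],
            [1, 1, 0],
            [1, 1, 1],
        ],
        dtype=np.int64,
    )
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                i = head[c]
                while i >= 0:
                    j = nxt[i]
                    while j >= 0:
                        d0 = pos[i, 0] - pos[j, 0]
                        d1 = pos[i, 1] - pos[j, 1]
                        d2 = pos[i, 2] - pos[j, 2]
                        d0 -= box[0] * np.rint(d0 / box[0])
                        d1 -= box[1] * np.rint(d1 / box[1])
                        d2 -= box[2] * np.rint(d2 / box[2])
                        if d0 * d0 + d1 * d1 + d2 * d2 <= r2:
                            sep = j - i if j > i else i - j
                            if sep > excl_max_sep or not _is_excluded(i, j, excl_codes, n):
                                if count >= cap:
                                    return -1
                                pairs_i[count] = i
                                pairs_j[count] = j
                                count += 1
                        j = nxt[j]
                    i = nxt[i]
                for o in range(13):
                    cx2 = (cx + offsets[o, 0]) % ncx
                    cy2 = (cy + offsets[o, 1]) % ncy
                    cz2 = (cz + offsets[o, 2]) % ncz
                    c2 = (cx2 * ncy + cy2) * ncz + cz2
                    i = head[c]
                    while i >= 0:
                        j = head[c2]
                        while j >= 0:
                            d0 = pos[i, 0] - pos[j, 0]
                            d1 = pos[i, 1] - pos[j, 1]
                            d2 = pos[i, 2] - pos[j, 2]
                            d0 -= box[0] * np.rint(d0 / box[0])
                            d1 -= box[1] * np.rint(d1 / box[1])
                            d2 -= box[2] * np.rint(d2 / box[2])
                            if d0 * d0 + d1 * d1 + d2 * d2 <= r2:
                                sep = j - i if j > i else i - j
                                if sep > excl_max_sep or not _is_excluded(i, j, excl_codes, n):
                                    if count >= cap:
                                        return -1
                                    pairs_i[count] = i
                                    pairs_j[count] = j
                                    count += 1
                            j = nxt[j]
                        i = nxt[i]
    return count


@njit(cache=True, fastmath={"contract", "reassoc", "nsz", "arcp"})
def compute_forces(
    pos,
    box,
    forces,
    pairs_i,
    pairs_j,
    npairs,
    sticky_code,
    chain_ids,
    allow_intrachain,
    eps_att,
    eps_rep,
    sigma,
    rc,
    bonds,
    bond_r0,
    bond_k,
    angles,
    angle_t0,
    angle_k,
    torsions,
    tors_cos_phis,
    tors_sin_phis,
    tors_k,
    tors_mult,
    fcap,
):
    """Potential energy + forces (exact negative gradient of the potential).

    Nonbonded: truncated-shifted LJ; attraction (eps_att) only for sticky
    beads of identical coil type on different chains, else eps_rep.  Pair
    forces larger than fcap are capped (count returned) to survive overlaps.
    Returns (potential, n_capped).
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    pe = 0.0
    ncapped = 0
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    rc2 = rc * rc
    src = sigma / rc
    c6 = src ** 6
    cshift = 4.0 * (c6 * c6 - c6)
    for p in range(npairs):
        i = pairs_i[p]
        j = pairs_j[p]
        d0 = pos[i, 0] - pos[j, 0]
        d1 = pos[i, 1] - pos[j, 1]
        d2 = pos[i, 2] - pos[j, 2]
        if d0 > hx:
            d0 -= box[0]
        elif d0 < -hx:
            d0 += box[0]
        if d1 > hy:
            d1 -= box[1]
        elif d1 < -hy:
            d1 += box[1]
        if d2 > hz:
            d2 -= box[2]
        elif d2 < -hz:
            d2 += box[2]
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        if r2 >= rc2 or r2 == 0.0:
            continue
        eps = eps_rep
        si = sticky_code[i]
        if si >= 0 and si == sticky_code[j]:
            if allow_intrachain or chain_ids[i] != chain_ids[j]:
                eps = eps_att
        inv_r2 = 1.0 / r2
        s2 = sigma * sigma * inv_r2
        s6 = s2 * s2 * s2
        pe += 4.0 * eps * (s6 * s6 - s6) - eps * cshift
        fmag = 24.0 * eps * (2.0 * s6 * s6 - s6) * inv_r2  # (1/r) dV/dr with sign
        r = np.sqrt(r2)
        if fmag * r > fcap:
            fmag = fcap / r
            ncapped += 1
        forces[i, 0] += fmag * d0
        forces[i, 1] += fmag * d1
        forces[i, 2] += fmag * d2
        forces[j, 0] -= fmag * d0
        forces[j, 1] -= fmag * d1
        forces[j, 2] -= fmag * d2

    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        d0 = pos[i, 0] - pos[j, 0]
        d1 = pos[i, 1] - pos[j, 1]
        d2 = pos[i, 2] - pos[j, 2]
        if d0 > hx:
            d0 -= box[0]
        elif d0 < -hx:
            d0 += box[0]
        if d1 > hy:
            d1 -= box[1]
        elif d1 < -hy:
            d1 += box[1]
        if d2 > hz:
            d2 -= box[2]
        elif d2 < -hz:
            d2 += box[2]
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        dr = r - bond_r0[b]
        pe += 0.5 * bond_k[b] * dr * dr
        if r > 1e-12:
            fmag = -bond_k[b] * dr / r
            forces[i, 0] += fmag * d0
            forces[i, 1] += fmag * d1
            forces[i, 2] += fmag * d2
            forces[j, 0] -= fmag * d0
            forces[j, 1] -= fmag * d1
            forces[j, 2] -= fmag * d2

    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k2 = angles[a, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k2, 0] - pos[j, 0]
        by = pos[k2, 1] - pos[j, 1]
        bz = pos[k2, 2] - pos[j, 2]
        if ax > hx:
            ax -= box[0]
        elif ax < -hx:
            ax += box[0]
        if ay > hy:
            ay -= box[1]
        elif ay < -hy:
            ay += box[1]
        if az > hz:
            az -= box[2]
        elif az < -hz:
            az += box[2]
        if bx > hx:
            bx -= box[0]
        elif bx < -hx:
            bx += box[0]
        if by > hy:
            by -= box[1]
        elif by < -hy:
            by += box[1]
        if bz > hz:
            bz -= box[2]
        elif bz < -hz:
            bz += box[2]
        lij = np.sqrt(ax * ax + ay * ay + az * az)
        lkj = np.sqrt(bx * bx + by * by + bz * bz)
        cost = (ax * bx + ay * by + az * bz) / (lij * lkj)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = np.arccos(cost)
        dtheta = theta - angle_t0[a]
        pe += 0.5 * angle_k[a] * dtheta * dtheta
        sint = np.sqrt(1.0 - cost * cost)
        if sint < 1e-8:
            continue
        coef = angle_k[a] * dtheta / sint
        ci = coef / lij
        ck = coef / lkj
        fix = ci * (bx / lkj - cost * ax / lij)
        fiy = ci * (by / lkj - cost * ay / lij)
        fiz = ci * (bz / lkj - cost * az / lij)
        fkx = ck * (ax / lij - cost * bx / lkj)
        fky = ck * (ay / lij - cost * by / lkj)
        fkz = ck * (az / lij - cost * bz / lkj)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k2, 0] += fkx
        forces[k2, 1] += fky
        forces[k2, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz

    for t in range(torsions.shape[0]):
        ia = torsions[t, 0]
        ib = torsions[t, 1]
        ic = torsions[t, 2]
        idd = torsions[t, 3]
        b1x = pos[ib, 0] - pos[ia, 0]
        b1y = pos[ib, 1] - pos[ia, 1]
        b1z = pos[ib, 2] - pos[ia, 2]
        b2x = pos[ic, 0] - pos[ib, 0]
        b2y = pos[ic, 1] - pos[ib, 1]
        b2z = pos[ic, 2] - pos[ib, 2]
        b3x = pos[idd, 0] - pos[ic, 0]
        b3y = pos[idd, 1] - pos[ic, 1]
        b3z = pos[idd, 2] - pos[ic, 2]
        if b1x > hx:
            b1x -= box[0]
        elif b1x < -hx:
            b1x += box[0]
        if b1y > hy:
            b1y -= box[1]
        elif b1y < -hy:
            b1y += box[1]
        if b1z > hz:
            b1z -= box[2]
        elif b1z < -hz:
            b1z += box[2]
        if b2x > hx:
            b2x -= box[0]
        elif b2x < -hx:
            b2x += box[0]
        if b2y > hy:
            b2y -= box[1]
        elif b2y < -hy:
            b2y += box[1]
        if b2z > hz:
            b2z -= box[2]
        elif b2z < -hz:
            b2z += box[2]
        if b3x > hx:
            b3x -= box[0]
        elif b3x < -hx:
            b3x += box[0]
        if b3y > hy:
            b3y -= box[1]
        elif b3y < -hy:
            b3y += box[1]
        if b3z > hz:
            b3z -= box[2]
        elif b3z < -hz:
            b3z += box[2]
        # n1 = b1 x b2, n2 = b2 x b3
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        lb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-18 or n2sq < 1e-18 or lb2 < 1e-12:
            continue
        # phi via atan2((n1 x n2) . b2hat, n1 . n2) -- same convention as the builder
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        y = (cxx * b2x + cxy * b2y + cxz * b2z) / lb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        rinv = 1.0 / np.sqrt(x * x + y * y)
        cphi = x * rinv
        sphi = y * rinv
        m = tors_mult[t]
        # sin/cos of m*phi by repeated angle addition
        cm = cphi
        sm = sphi
        for _ in range(m - 1):
            cm, sm = cm * cphi - sm * sphi, sm * cphi + cm * sphi
        # arg = m*phi - phi_s
        cs = tors_cos_phis[t]
        ss = tors_sin_phis[t]
        cosarg = cm * cs + sm * ss
        sinarg = sm * cs - cm * ss
        pe += tors_k[t] * (1.0 + cosarg)
        dvdphi = -tors_k[t] * m * sinarg
        # gradient distribution: dphi/dr_a = -(|b2|/|n1|^2) n1,
        # dphi/dr_d = (|b2|/|n2|^2) n2, with b/c terms projected along b2
        ga_c = -lb2 / n1sq
        gd_c = lb2 / n2sq
        tdot = (b1x * b2x + b1y * b2y + b1z * b2z) / (lb2 * lb2)
        sdot = (b3x * b2x + b3y * b2y + b3z * b2z) / (lb2 * lb2)
        gax = ga_c * n1x
        gay = ga_c * n1y
        gaz = ga_c * n1z
        gdx = gd_c * n2x
        gdy = gd_c * n2y
        gdz = gd_c * n2z
        gbx = (-1.0 - tdot) * gax + sdot * gdx
        gby = (-1.0 - tdot) * gay + sdot * gdy
        gbz = (-1.0 - tdot) * gaz + sdot * gdz
        gcx = tdot * gax + (-1.0 - sdot) * gdx
        gcy = tdot * gay + (-1.0 - sdot) * gdy
        gcz = tdot * gaz + (-1.0 - sdot) * gdz
        forces[ia, 0] -= dvdphi * gax
        forces[ia, 1] -= dvdphi * gay
        forces[ia, 2] -= dvdphi * gaz
        forces[ib, 0] -= dvdphi * gbx
        forces[ib, 1] -= dvdphi * gby
        forces[ib, 2] -= dvdphi * gbz
        forces[ic, 0] -= dvdphi * gcx
        forces[ic, 1] -= dvdphi * gcy
        forces[ic, 2] -= dvdphi * gcz
        forces[idd, 0] -= dvdphi * gdx
        forces[idd, 1] -= dvdphi * gdy
        forces[idd, 2] -= dvdphi * gdz
    return pe, ncapped


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def remove_com_velocity(vel):
    n = vel.shape[0]
    for k in range(3):
        m = 0.0
        for i in range(n):
            m += vel[i, k]
        m /= n
        for i in range(n):
            vel[i, k] -= m


@njit(cache=True, fastmath={"contract", "reassoc", "nsz", "arcp"})
def integrate_chunk(
    pos,
    vel,
    forces,
    box,
    n_steps,
    dt,
    gamma,
    kT,
    mass,
    com_interval,
    step_offset,
    noise,
    pos_ref,
    skin,
    rlist,
    excl_codes,
    excl_max_sep,
    pairs_i,
    pairs_j,
    npairs_box,
    sticky_code,
    chain_ids,
    allow_intrachain,
    eps_att,
    eps_rep,
    sigma,
    rc,
    bonds,
    bond_r0,
    bond_k,
    angles,
    angle_t0,
    angle_k,
    torsions,
    tors_cos_phis,
    tors_sin_phis,
    tors_k,
    tors_mult,
    fcap,
):
    """BAOAB Langevin steps; gamma=0 reduces to velocity Verlet (NVE).

    ``forces`` must be valid for ``pos`` on entry and stays valid on exit.
    ``noise`` holds (n_steps, n, 3) standard normals (unused when gamma=0).
    The neighbor list is refreshed at the top of a step whenever any bead has
    moved more than half the Verlet skin since the last rebuild, so no
    eligible pair can be missed.  Returns (steps_done, pe_last, ncapped,
    status): status 0=ok, 1=pair-list overflow (caller grows and resumes at
    steps_done), 2=NaN abort.
    """
    n = pos.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sv = np.sqrt(kT / mass)
    half = 0.5 * dt
    inv_m = 1.0 / mass
    skin_half2 = (0.5 * skin) ** 2
    pe = 0.0
    ncapped_tot = 0
    for s in range(n_steps):
        maxd2 = 0.0
        for i in range(n):
            d2 = 0.0
            for k in range(3):
                dd = pos[i, k] - pos_ref[i, k]
                d2 += dd * dd
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > skin_half2:
            for i in range(n):
                for k in range(3):
                    pos[i, k] = pos[i, k] % box[k]
            cnt = build_pairs(pos, box, rlist, excl_codes, excl_max_sep, pairs_i, pairs_j)
            if cnt < 0:
                return s, pe, ncapped_tot, 1
            npairs_box[0] = cnt
            for i in range(n):
                for k in range(3):
                    pos_ref[i, k] = pos[i, k]
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * forces[i, k] * inv_m
                pos[i, k] += half * vel[i, k]
        if c2 > 0.0:
            for i in range(n):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k] + c2 * sv * noise[s, i, k]
        for i in range(n):
            for k in range(3):
                pos[i, k] += half * vel[i, k]
        pe, ncapped = compute_forces(
            pos, box, forces, pairs_i, pairs_j, npairs_box[0], sticky_code,
            chain_ids, allow_intrachain, eps_att, eps_rep, sigma, rc,
            bonds, bond_r0, bond_k, angles, angle_t0, angle_k,
            torsions, tors_cos_phis, tors_sin_phis, tors_k, tors_mult, fcap,
        )
        ncapped_tot += ncapped
        if not np.isfinite(pe):
            return s, pe, ncapped_tot, 2
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * forces[i, k] * inv_m
        if (step_offset + s + 1) % com_interval == 0:
            remove_com_velocity(vel)
    return n_steps, pe, ncapped_tot, 0
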