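"""JIT-compiled inner loops of the Gibbs-ensemble Monte Carlo engine.

All state lives in flat preallocated numpy arrays indexed by box (0/1) and
particle slot; functions here mutate those arrays in place.  Energies are
tracked incrementally and are exact sums of well depths, so equality against
an O(N^2) recomputation is a meaningful invariant check.

Cell lists use a cell edge >= the interaction range sigma + lam; boxes too
small for a 3x3x3 cell decomposition fall back to brute-force neighbour loops.

Randomness comes from numba's internal np.random state, seeded once per run
through :func:`seed_rng`; a fixed seed gives bit-identical trajectories.
"""

import math

import numpy as np
from numba import njit

# attempt outcome codes
REJECT_OVERLAP = 0
REJECT_METROPOLIS = 1
ACCEPT = 2

MAXNC = 8  # cells per dimension cap
MAXCELLS = MAXNC * MAXNC * MAXNC


@njit(cache=True, fastmath=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always", fastmath=True)
def _cell_of(x, y, z, L, nc):
    ix = int(x * nc / L)
    iy = int(y * nc / L)
    iz = int(z * nc / L)
    if ix >= nc:
        ix = nc - 1
    if iy >= nc:
        iy = nc - 1
    if iz >= nc:
        iz = nc - 1
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    return (ix * nc + iy) * nc + iz


@njit(cache=True, fastmath=True)
def choose_nc(L, rcut):
    nc = int(L / rcut)
    if nc > MAXNC:
        nc = MAXNC
    return nc


@njit(cache=True, fastmath=True)
def build_cells(b, pos, n, L, nc, head, nxt):
    ncd = nc[b]
    for c in range(ncd * ncd * ncd):
        head[b, c] = -1
    for i in range(n[b]):
        c = _cell_of(pos[b, i, 0], pos[b, i, 1], pos[b, i, 2], L[b], ncd)
        nxt[b, i] = head[b, c]
        head[b, c] = i


@njit(cache=True, fastmath=True)
def _unlink(b, i, c, head, nxt):
    j = head[b, c]
    if j == i:
        head[b, c] = nxt[b, i]
        return
    while nxt[b, j] != i:
        j = nxt[b, j]
    nxt[b, j] = nxt[b, i]


@njit(cache=True, inline="always", fastmath=True)
def _rotate(qw, qx, qy, qz, vx, vy, vz):
    # v' = v + 2 w (u x v) + 2 u x (u x v)
    tx = 2.0 * (qy * vz - qz * vy)
    ty = 2.0 * (qz * vx - qx * vz)
    tz = 2.0 * (qx * vy - qy * vx)
    ox = vx + qw * tx + (qy * tz - qz * ty)
    oy = vy + qw * ty + (qz * tx - qx * tz)
    oz = vz + qw * tz + (qx * ty - qy * tx)
    return ox, oy, oz


@njit(cache=True, fastmath=True)
def _set_patches(patch_row, q, ref, m):
    for a in range(m):
        px, py, pz = _rotate(
            q[0], q[1], q[2], q[3], ref[a, 0], ref[a, 1], ref[a, 2]
        )
        patch_row[a, 0] = px
        patch_row[a, 1] = py
        patch_row[a, 2] = pz


@njit(cache=True, inline="always", fastmath=True)
def _pair_bonded(dx, dy, dz, inv_r, pbuf_i, mi, cth_i, patch_j, mj, cth_j):
    rx = dx * inv_r
    ry = dy * inv_r
    rz = dz * inv_r
    ok_i = False
    for a in range(mi):
        if pbuf_i[a, 0] * rx + pbuf_i[a, 1] * ry + pbuf_i[a, 2] * rz > cth_i:
            ok_i = True
            break
    if not ok_i:
        return False
    for bt in range(mj):
        if -(patch_j[bt, 0] * rx + patch_j[bt, 1] * ry + patch_j[bt, 2] * rz) > cth_j:
            return True
    return False


@njit(cache=True, fastmath=True)
def particle_energy(
    b, i_skip, x, y, z, pbuf, si,
    pos, patch, spec, n, L,
    head, nxt, nc,
    sigma2, rc2, cth, mvec, eps,
):
    """Interaction energy of a (possibly virtual) particle at (x, y, z).

    Returns (energy, overlap) where overlap means some pair distance <= sigma.
    ``i_skip`` is excluded (-1 to include everyone).
    """
    e = 0.0
    Lb = L[b]
    halfL = 0.5 * Lb
    mi = mvec[si]
    cth_i = cth[si]
    ncd = nc[b]
    if ncd >= 3:
        cx = int(x * ncd / Lb)
        cy = int(y * ncd / Lb)
        cz = int(z * ncd / Lb)
        if cx >= ncd:
            cx = ncd - 1
        if cy >= ncd:
            cy = ncd - 1
        if cz >= ncd:
            cz = ncd - 1
        for ox in range(-1, 2):
            ix = (cx + ox) % ncd
            for oy in range(-1, 2):
                iy = (cy + oy) % ncd
                for oz in range(-1, 2):
                    iz = (cz + oz) % ncd
                    j = head[b, (ix * ncd + iy) * ncd + iz]
                    while j >= 0:
                        if j != i_skip:
                            dx = pos[b, j, 0] - x
                            dy = pos[b, j, 1] - y
                            dz = pos[b, j, 2] - z
                            if dx > halfL:
                                dx -= Lb
                            elif dx < -halfL:
                                dx += Lb
                            if dy > halfL:
                                dy -= Lb
                            elif dy < -halfL:
                                dy += Lb
                            if dz > halfL:
                                dz -= Lb
                            elif dz < -halfL:
                                dz += Lb
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 <= sigma2:
                                return 0.0, True
                            if r2 <= rc2:
                                sj = spec[b, j]
                                epsij = eps[si, sj]
                                if epsij != 0.0:
                                    inv_r = 1.0 / math.sqrt(r2)
                                    if _pair_bonded(
                                        dx, dy, dz, inv_r, pbuf, mi, cth_i,
                                        patch[b, j], mvec[sj], cth[sj],
                                    ):
                                        e -= epsij
                        j = nxt[b, j]
    else:
        for j in range(n[b]):
            if j == i_skip:
                continue
            dx = pos[b, j, 0] - x
            dy = pos[b, j, 1] - y
            dz = pos[b, j, 2] - z
            if dx > halfL:
                dx -= Lb
            elif dx < -halfL:
                dx += Lb
            if dy > halfL:
                dy -= Lb
            elif dy < -halfL:
                dy += Lb
            if dz > halfL:
                dz -= Lb
            elif dz < -halfL:
                dz += Lb
            r2 = dx * dx + dy * dy + dz * dz
            if r2 <= sigma2:
                return 0.0, True
            if r2 <= rc2:
                sj = spec[b, j]
                epsij = eps[si, sj]
                if epsij != 0.0:
                    inv_r = 1.0 / math.sqrt(r2)
                    if _pair_bonded(
                        dx, dy, dz, inv_r, pbuf, mi, cth_i,
                        patch[b, j], mvec[sj], cth[sj],
                    ):
                        e -= epsij
    return e, False


@njit(cache=True, fastmath=True)
def box_energy(
    b, pos, patch, spec, n, L, head, nxt, nc, sigma2, rc2, cth, mvec, eps
):
    """Total energy of one box (each pair counted once); (energy, overlap)."""
    tot = 0.0
    Lb = L[b]
    halfL = 0.5 * Lb
    ncd = nc[b]
    for i in range(n[b]):
        si = spec[b, i]
        mi = mvec[si]
        cth_i = cth[si]
        x = pos[b, i, 0]
        y = pos[b, i, 1]
        z = pos[b, i, 2]
        if ncd >= 3:
            cx = int(x * ncd / Lb)
            cy = int(y * ncd / Lb)
            cz = int(z * ncd / Lb)
            if cx >= ncd:
                cx = ncd - 1
            if cy >= ncd:
                cy = ncd - 1
            if cz >= ncd:
                cz = ncd - 1
            for ox in range(-1, 2):
                ix = (cx + ox) % ncd
                for oy in range(-1, 2):
                    iy = (cy + oy) % ncd
                    for oz in range(-1, 2):
                        iz = (cz + oz) % ncd
                        j = head[b, (ix * ncd + iy) * ncd + iz]
                        while j >= 0:
                            if j > i:
                                dx = pos[b, j, 0] - x
                                dy = pos[b, j, 1] - y
                                dz = pos[b, j, 2] - z
                                if dx > halfL:
                                    dx -= Lb
                                elif dx < -halfL:
                                    dx += Lb
                                if dy > halfL:
                                    dy -= Lb
                                elif dy < -halfL:
                                    dy += Lb
                                if dz > halfL:
                                    dz -= Lb
                                elif dz < -halfL:
                                    dz += Lb
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 <= sigma2:
                                    return 0.0, True
                                if r2 <= rc2:
                                    sj = spec[b, j]
                                    epsij = eps[si, sj]
                                    if epsij != 0.0:
                                        inv_r = 1.0 / math.sqrt(r2)
                                        if _pair_bonded(
                                            dx, dy, dz, inv_r,
                                            patch[b, i], mi, cth_i,
                                            patch[b, j], mvec[sj], cth[sj],
                                        ):
                                            tot -= epsij
                            j = nxt[b, j]
        else:
            for j in range(i + 1, n[b]):
                dx = pos[b, j, 0] - x
                dy = pos[b, j, 1] - y
                dz = pos[b, j, 2] - z
                if dx > halfL:
                    dx -= Lb
                elif dx < -halfL:
                    dx += Lb
                if dy > halfL:
                    dy -= Lb
                elif dy < -halfL:
                    dy += Lb
                if dz > halfL:
                    dz -= Lb
                elif dz < -halfL:
                    dz += Lb
                r2 = dx * dx + dy * dy + dz * dz
                if r2 <= sigma2:
                    return 0.0, True
                if r2 <= rc2:
                    sj = spec[b, j]
                    epsij = eps[si, sj]
                    if epsij != 0.0:
                        inv_r = 1.0 / math.sqrt(r2)
                        if _pair_bonded(
                            dx, dy, dz, inv_r, patch[b, i], mi, cth_i,
                            patch[b, j], mvec[sj], cth[sj],
                        ):
                            tot -= epsij
    return tot, False


@njit(cache=True, fastmath=True)
def count_bond_pairs(b, pos, patch, spec, n, L, sigma2, rc2, cth, mvec):
    """Geometric bonded-pair counts of one box by class: (PP, PR, RR)."""
    cpp = 0
    cpr = 0
    crr = 0
    Lb = L[b]
    halfL = 0.5 * Lb
    for i in range(n[b]):
        si = spec[b, i]
        for j in range(i + 1, n[b]):
            dx = pos[b, j, 0] - pos[b, i, 0]
            dy = pos[b, j, 1] - pos[b, i, 1]
            dz = pos[b, j, 2] - pos[b, i, 2]
            if dx > halfL:
                dx -= Lb
            elif dx < -halfL:
                dx += Lb
            if dy > halfL:
                dy -= Lb
            elif dy < -halfL:
                dy += Lb
            if dz > halfL:
                dz -= Lb
            elif dz < -halfL:
                dz += Lb
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > sigma2 and r2 <= rc2:
                sj = spec[b, j]
                inv_r = 1.0 / math.sqrt(r2)
                if _pair_bonded(
                    dx, dy, dz, inv_r, patch[b, i], mvec[si], cth[si],
                    patch[b, j], mvec[sj], cth[sj],
                ):
                    if si == 0 and sj == 0:
                        cpp += 1
                    elif si == 1 and sj == 1:
                        crr += 1
                    else:
                        cpr += 1
    return cpp, cpr, crr


@njit(cache=True, fastmath=True)
def _random_unit_quat(qout):
    s = 0.0
    while s < 1e-12:
        for k in range(4):
            qout[k] = np.random.normal()
        s = math.sqrt(
            qout[0] ** 2 + qout[1] ** 2 + qout[2] ** 2 + qout[3] ** 2
        )
    for k in range(4):
        qout[k] /= s


@njit(cache=True, fastmath=True)
def attempt_displacement(
    pos, quat, patch, spec, n, L, energy,
    head, nxt, nc,
    sigma2, rc2, cth, mvec, eps, refP, refR,
    T, max_tr, max_rot, qbuf, pbuf,
):
    """One combined translation+rotation attempt on a uniformly chosen particle.

    Returns (outcome, dU); dU is the proposed energy change (0 when the
    proposal overlapped).
    """
    ntot = n[0] + n[1]
    if ntot == 0:
        return REJECT_OVERLAP, 0.0
    k = int(np.random.random() * ntot)
    if k >= ntot:
        k = ntot - 1
    if k < n[0]:
        b = 0
        i = k
    else:
        b = 1
        i = k - n[0]
    si = spec[b, i]
    e_old, _ = particle_energy(
        b, i, pos[b, i, 0], pos[b, i, 1], pos[b, i, 2], patch[b, i], si,
        pos, patch, spec, n, L, head, nxt, nc, sigma2, rc2, cth, mvec, eps,
    )
    Lb = L[b]
    halfL = 0.5 * Lb
    xn = (pos[b, i, 0] + (2.0 * np.random.random() - 1.0) * max_tr) % Lb
    yn = (pos[b, i, 1] + (2.0 * np.random.random() - 1.0) * max_tr) % Lb
    zn = (pos[b, i, 2] + (2.0 * np.random.random() - 1.0) * max_tr) % Lb
    # random rotation: uniform axis, angle uniform in [0, max_rot]
    ax = np.random.normal()
    ay = np.random.normal()
    az = np.random.normal()
    an = math.sqrt(ax * ax + ay * ay + az * az)
    while an < 1e-12:
        ax = np.random.normal()
        ay = np.random.normal()
        az = np.random.normal()
        an = math.sqrt(ax * ax + ay * ay + az * az)
    ang = np.random.random() * max_rot
    sh = math.sin(0.5 * ang) / an
    dw = math.cos(0.5 * ang)
    dxq = ax * sh
    dyq = ay * sh
    dzq = az * sh
    qw = quat[b, i, 0]
    qx = quat[b, i, 1]
    qy = quat[b, i, 2]
    qz = quat[b, i, 3]
    # q_new = dq * q_old
    nw = dw * qw - dxq * qx - dyq * qy - dzq * qz
    nx = dw * qx + dxq * qw + dyq * qz - dzq * qy
    ny = dw * qy - dxq * qz + dyq * qw + dzq * qx
    nz = dw * qz + dxq * qy - dyq * qx + dzq * qw
    qn = math.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
    qbuf[0] = nw / qn
    qbuf[1] = nx / qn
    qbuf[2] = ny / qn
    qbuf[3] = nz / qn
    if si == 0:
        _set_patches(pbuf, qbuf, refP, mvec[0])
    else:
        _set_patches(pbuf, qbuf, refR, mvec[1])
    e_new, ov = particle_energy(
        b, i, xn, yn, zn, pbuf, si,
        pos, patch, spec, n, L, head, nxt, nc, sigma2, rc2, cth, mvec, eps,
    )
    if ov:
        return REJECT_OVERLAP, 0.0
    dU = e_new - e_old
    if dU > 0.0 and np.random.random() >= math.exp(-dU / T):
        return REJECT_METROPOLIS, dU
    ncd = nc[b]
    if ncd >= 3:
        c_old = _cell_of(pos[b, i, 0], pos[b, i, 1], pos[b, i, 2], Lb, ncd)
        c_new = _cell_of(xn, yn, zn, Lb, ncd)
        if c_old != c_new:
            _unlink(b, i, c_old, head, nxt)
            nxt[b, i] = head[b, c_new]
            head[b, c_new] = i
    pos[b, i, 0] = xn
    pos[b, i, 1] = yn
    pos[b, i, 2] = zn
    for q in range(4):
        quat[b, i, q] = qbuf[q]
    mi = mvec[si]
    for a in range(mi):
        for d in range(3):
            patch[b, i, a, d] = pbuf[a, d]
    energy[b] += dU
    return ACCEPT, dU


@njit(cache=True, fastmath=True)
def attempt_exchange(
    pos, quat, patch, spec, n, nsp, L, energy,
    head, nxt, nc,
    sigma2, rc2, cth, mvec, eps, refP, refR,
    T, qbuf, pbuf,
):
    """One particle-transfer attempt between the boxes.

    Species is chosen uniformly among species present in the whole system;
    source box uniformly; the attempt is rejected if the source box holds no
    particle of that species.  Acceptance uses the standard Gibbs-transfer
    ratio N_s,src V_dest / ((N_s,dest + 1) V_src) * exp(-dU/T).
    """
    ntotP = nsp[0, 0] + nsp[1, 0]
    ntotR = nsp[0, 1] + nsp[1, 1]
    if ntotP == 0 and ntotR == 0:
        return REJECT_OVERLAP, 0.0
    if ntotP > 0 and ntotR > 0:
        s = 0 if np.random.random() < 0.5 else 1
    elif ntotP > 0:
        s = 0
    else:
        s = 1
    src = 0 if np.random.random() < 0.5 else 1
    dest = 1 - src
    ns_src = nsp[src, s]
    if ns_src == 0:
        return REJECT_OVERLAP, 0.0
    k = int(np.random.random() * ns_src)
    if k >= ns_src:
        k = ns_src - 1
    if ns_src == n[src]:
        i = k
    else:
        i = -1
        cnt = -1
        for idx in range(n[src]):
            if spec[src, idx] == s:
                cnt += 1
                if cnt == k:
                    i = idx
                    break
    e_rem, _ = particle_energy(
        src, i, pos[src, i, 0], pos[src, i, 1], pos[src, i, 2],
        patch[src, i], s,
        pos, patch, spec, n, L, head, nxt, nc, sigma2, rc2, cth, mvec, eps,
    )
    Ld = L[dest]
    xn = np.random.random() * Ld
    yn = np.random.random() * Ld
    zn = np.random.random() * Ld
    _random_unit_quat(qbuf)
    if s == 0:
        _set_patches(pbuf, qbuf, refP, mvec[0])
    else:
        _set_patches(pbuf, qbuf, refR, mvec[1])
    e_ins, ov = particle_energy(
        dest, -1, xn, yn, zn, pbuf, s,
        pos, patch, spec, n, L, head, nxt, nc, sigma2, rc2, cth, mvec, eps,
    )
    if ov:
        return REJECT_OVERLAP, 0.0
    dU = e_ins - e_rem
    v_src = L[src] ** 3
    v_dest = Ld**3
    ratio = (ns_src * v_dest) / ((nsp[dest, s] + 1.0) * v_src)
    acc = ratio * math.exp(-dU / T)
    if np.random.random() >= acc:
        return REJECT_METROPOLIS, dU
    # remove from src: move last slot into i
    last = n[src] - 1
    if last != i:
        for d in range(3):
            pos[src, i, d] = pos[src, last, d]
        for q in range(4):
            quat[src, i, q] = quat[src, last, q]
        for a in range(4):
            for d in range(3):
                patch[src, i, a, d] = patch[src, last, a, d]
        spec[src, i] = spec[src, last]
    n[src] = last
    nsp[src, s] -= 1
    # insert into dest
    j = n[dest]
    pos[dest, j, 0] = xn
    pos[dest, j, 1] = yn
    pos[dest, j, 2] = zn
    for q in range(4):
        quat[dest, j, q] = qbuf[q]
    mi = mvec[s]
    for a in range(mi):
        for d in range(3):
            patch[dest, j, a, d] = pbuf[a, d]
    spec[dest, j] = s
    n[dest] = j + 1
    nsp[dest, s] += 1
    energy[src] -= e_rem
    energy[dest] += e_ins
    build_cells(src, pos, n, L, nc, head, nxt)
    build_cells(dest, pos, n, L, nc, head, nxt)
    return ACCEPT, dU


@njit(cache=True, fastmath=True)
def attempt_volume(
    pos, patch, spec, n, L, energy,
    head, nxt, nc,
    sigma2, rc2, cth, mvec, eps,
    T, max_dlnv, rcut,
    pos_buf, head_buf, nxt_buf, nc_buf, L_buf, n_buf,
):
    """Symmetric volume-exchange attempt in ln(V_I / V_II).

    Total volume is conserved exactly; positions rescale affinely.  The
    acceptance weight carries (N_b + 1) exponents from the ln-volume proposal.
    """
    v0 = L[0] ** 3
    v1 = L[1] ** 3
    vtot = v0 + v1
    delta = math.log(v0 / v1) + (2.0 * np.random.random() - 1.0) * max_dlnv
    ed = math.exp(delta)
    v0n = vtot * ed / (1.0 + ed)
    v1n = vtot - v0n
    L_buf[0] = v0n ** (1.0 / 3.0)
    L_buf[1] = v1n ** (1.0 / 3.0)
    n_buf[0] = n[0]
    n_buf[1] = n[1]
    e_new = np.empty(2)
    for b in range(2):
        scale = L_buf[b] / L[b]
        for i in range(n[b]):
            for d in range(3):
                pos_buf[b, i, d] = pos[b, i, d] * scale
        nc_buf[b] = choose_nc(L_buf[b], rcut)
        build_cells(b, pos_buf, n_buf, L_buf, nc_buf, head_buf, nxt_buf)
        eb, ov = box_energy(
            b, pos_buf, patch, spec, n_buf, L_buf,
            head_buf, nxt_buf, nc_buf, sigma2, rc2, cth, mvec, eps,
        )
        if ov:
            return REJECT_OVERLAP, 0.0
        e_new[b] = eb
    dU = (e_new[0] + e_new[1]) - (energy[0] + energy[1])
    ln_acc = (
        (n[0] + 1.0) * math.log(v0n / v0)
        + (n[1] + 1.0) * math.log(v1n / v1)
        - dU / T
    )
    if ln_acc < 0.0 and math.log(np.random.random() + 1e-300) >= ln_acc:
        return REJECT_METROPOLIS, dU
    for b in range(2):
        L[b] = L_buf[b]
        nc[b] = nc_buf[b]
        for i in range(n[b]):
            for d in range(3):
                pos[b, i, d] = pos_buf[b, i, d]
        build_cells(b, pos, n, L, nc, head, nxt)
        energy[b] = e_new[b]
    return ACCEPT, dU


@njit(cache=True, fastmath=True)
def run_cycles(
    pos, quat, patch, spec, n, nsp, L, energy,
    head, nxt, nc,
    sigma2, rc2, cth, mvec, eps, refP, refR,
    T, rcut,
    n_disp, n_exch, n_vol,
    step,  # [max_translation, max_rotation, max_dln_volume]
    n_cycles, cycle0, adapt, stride, samples, sample_start, check_every,
    pos_buf, head_buf, nxt_buf, nc_buf, L_buf, n_buf,
):
    """Run ``n_cycles`` full cycles; returns the number of samples written.

    A cycle is a randomly interleaved sequence of n_disp displacement,
    n_exch exchange and n_vol volume attempts.  With ``adapt`` true the
    translation/rotation steps are tuned toward 30-50% acceptance (use only
    during equilibration).  With ``stride > 0`` one sample row is written
    every ``stride`` cycles: [cycle, then per box: N_P, N_R, V, E, PP, PR, RR
    geometric bonded-pair counts].
    """
    n_attempts = n_disp + n_exch + n_vol
    movetype = np.empty(n_attempts, dtype=np.int64)
    for a in range(n_attempts):
        if a < n_disp:
            movetype[a] = 0
        elif a < n_disp + n_exch:
            movetype[a] = 1
        else:
            movetype[a] = 2
    qbuf = np.empty(4)
    pbuf = np.empty((4, 3))
    acc_d = 0
    att_d = 0
    nsamp = 0
    for cyc in range(n_cycles):
        # Fisher-Yates shuffle of the attempt sequence
        for a in range(n_attempts - 1, 0, -1):
            j = int(np.random.random() * (a + 1))
            if j > a:
                j = a
            tmp = movetype[a]
            movetype[a] = movetype[j]
            movetype[j] = tmp
        for a in range(n_attempts):
            mt = movetype[a]
            if mt == 0:
                out, _ = attempt_displacement(
                    pos, quat, patch, spec, n, L, energy, head, nxt, nc,
                    sigma2, rc2, cth, mvec, eps, refP, refR,
                    T, step[0], step[1], qbuf, pbuf,
                )
                att_d += 1
                if out == ACCEPT:
                    acc_d += 1
            elif mt == 1:
                attempt_exchange(
                    pos, quat, patch, spec, n, nsp, L, energy, head, nxt, nc,
                    sigma2, rc2, cth, mvec, eps, refP, refR, T, qbuf, pbuf,
                )
            else:
                attempt_volume(
                    pos, patch, spec, n, L, energy, head, nxt, nc,
                    sigma2, rc2, cth, mvec, eps, T, step[2], rcut,
                    pos_buf, head_buf, nxt_buf, nc_buf, L_buf, n_buf,
                )
        if adapt and att_d >= 100 * n_disp and n_disp > 0:
            rate = acc_d / att_d
            lmin = L[0] if L[0] < L[1] else L[1]
            if rate < 0.3:
                step[0] *= 0.9
                step[1] *= 0.9
            elif rate > 0.5:
                step[0] = min(step[0] * 1.1, 0.25 * lmin)
                step[1] = min(step[1] * 1.1, math.pi)
            acc_d = 0
            att_d = 0
        if check_every > 0 and (cyc + 1) % check_every == 0:
            for b in range(2):
                eb, ov = box_energy(
                    b, pos, patch, spec, n, L, head, nxt, nc,
                    sigma2, rc2, cth, mvec, eps,
                )
                if ov or abs(eb - energy[b]) > 1e-6:
                    raise RuntimeError(
                        "incremental energy cache diverged from recomputation"
                    )
        if stride > 0 and (cyc + 1) % stride == 0:
            row = sample_start + nsamp
            samples[row, 0] = cycle0 + cyc
            col = 1
            for b in range(2):
                cpp, cpr, crr = count_bond_pairs(
                    b, pos, patch, spec, n, L, sigma2, rc2, cth, mvec
                )
                samples[row, col] = nsp[b, 0]
                samples[row, col + 1] = nsp[b, 1]
                samples[row, col + 2] = L[b] ** 3
                samples[row, col + 3] = energy[b]
                samples[row, col + 4] = cpp
                samples[row, col + 5] = cpr
                samples[row, col + 6] = crr
                col += 7
            nsamp += 1
    return nsamp
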