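"""Numba kernels: forces, constrained Langevin propagation, minimization.

All arrays are float64/int64 and contiguous.  The scaffold is static, so
its cell decomposition is computed once on the Python side and passed in
as a flat cell list (origin, cell size, dims, per-cell start/count into a
sorted bead-index array).

Force-field terms (energies kJ/mol, lengths nm):
  angle      V = 0.5 k (theta - theta0)^2
  dihedral   V = k [(1 - cos(phi - phi0)) + 0.5 (1 - cos 3(phi - phi0))]
  contact    V = eps [5 (r0/r)^12 - 6 (r0/r)^10]
  repulsion  V = eps [(s/r)^12 - 2 (s/r)^10 + (s/r)^6], s = (si + sj)/2
  hp (LJ)    V = 4 eps [(s/r)^12 - (s/r)^6]
  tether     V = 0.5 ks (x - x0)^2
  umbrella   V = 0.5 k_umb (Q - Q0)^2 on the smooth Q
"""

import numpy as np
from numba import njit

REP_CUTOFF_FACTOR = 1.4  # excluded-volume cutoff (multiple of s); V there is ~1e-4 eps


@njit(cache=True)
def _forces(pos, frc,
            ang_idx, theta0, k_ang,
            dih_idx, phi0, k_dih,
            con_idx, con_r0, con_eps,
            rep_idx, rep_sig, eps_rep,
            sc_pos, sc_sig_row, grid_origin, grid_cell, grid_dims,
            cell_start, cell_count, cell_beads,
            hp_idx, hp_sigma, hp_eps,
            teth_i, anchor, ks, x0,
            q_gamma, q_lam, k_umb, q0, k_coop, q0_coop):
    """Fill ``frc`` with -grad V; return (epot, Q, tether extension x)."""
    n = pos.shape[0]
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0
    epot = 0.0

    # angles
    for a in range(ang_idx.shape[0]):
        i, j, k = ang_idx[a, 0], ang_idx[a, 1], ang_idx[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-8:
            st = 1e-8
        th = np.arccos(ct)
        epot += 0.5 * k_ang[a] * (th - theta0[a]) ** 2
        coef = -k_ang[a] * (th - theta0[a])
        # dtheta/d(a) = (ct*uhat - vhat) / (nu*st)
        dax = (ct * ux / nu - vx / nv) / (nu * st)
        day = (ct * uy / nu - vy / nv) / (nu * st)
        daz = (ct * uz / nu - vz / nv) / (nu * st)
        dcx = (ct * vx / nv - ux / nu) / (nv * st)
        dcy = (ct * vy / nv - uy / nu) / (nv * st)
        dcz = (ct * vz / nv - uz / nu) / (nv * st)
        frc[i, 0] += coef * dax
        frc[i, 1] += coef * day
        frc[i, 2] += coef * daz
        frc[k, 0] += coef * dcx
        frc[k, 1] += coef * dcy
        frc[k, 2] += coef * dcz
        frc[j, 0] -= coef * (dax + dcx)
        frc[j, 1] -= coef * (day + dcy)
        frc[j, 2] -= coef * (daz + dcz)

    # dihedrals
    for a in range(dih_idx.shape[0]):
        i, j, k, l = dih_idx[a, 0], dih_idx[a, 1], dih_idx[a, 2], dih_idx[a, 3]
        b1 = pos[j] - pos[i]
        b2 = pos[k] - pos[j]
        b3 = pos[l] - pos[k]
        n1x = b1[1] * b2[2] - b1[2] * b2[1]
        n1y = b1[2] * b2[0] - b1[0] * b2[2]
        n1z = b1[0] * b2[1] - b1[1] * b2[0]
        n2x = b2[1] * b3[2] - b2[2] * b3[1]
        n2y = b2[2] * b3[0] - b2[0] * b3[2]
        n2z = b2[0] * b3[1] - b2[1] * b3[0]
        nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-14 or n2sq < 1e-14:
            continue
        # phi via atan2
        mx = n1y * b2[2] - n1z * b2[1]
        my = n1z * b2[0] - n1x * b2[2]
        mz = n1x * b2[1] - n1y * b2[0]
        x_ = n1x * n2x + n1y * n2y + n1z * n2z
        y_ = (mx * n2x + my * n2y + mz * n2z) / nb2
        phi = np.arctan2(y_, x_)
        dphi = phi - phi0[a]
        epot += k_dih[a] * ((1.0 - np.cos(dphi))
                            + 0.5 * (1.0 - np.cos(3.0 * dphi)))
        dv = k_dih[a] * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        # dphi/dri etc. (verified against central differences)
        tix = nb2 / n1sq * n1x
        tiy = nb2 / n1sq * n1y
        tiz = nb2 / n1sq * n1z
        tlx = -nb2 / n2sq * n2x
        tly = -nb2 / n2sq * n2y
        tlz = -nb2 / n2sq * n2z
        s12 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (nb2 * nb2)
        s32 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (nb2 * nb2)
        tjx = -(1.0 + s12) * tix + s32 * tlx
        tjy = -(1.0 + s12) * tiy + s32 * tly
        tjz = -(1.0 + s12) * tiz + s32 * tlz
        tkx = s12 * tix - (1.0 + s32) * tlx
        tky = s12 * tiy - (1.0 + s32) * tly
        tkz = s12 * tiz - (1.0 + s32) * tlz
        frc[i, 0] -= dv * tix
        frc[i, 1] -= dv * tiy
        frc[i, 2] -= dv * tiz
        frc[j, 0] -= dv * tjx
        frc[j, 1] -= dv * tjy
        frc[j, 2] -= dv * tjz
        frc[k, 0] -= dv * tkx
        frc[k, 1] -= dv * tky
        frc[k, 2] -= dv * tkz
        frc[l, 0] -= dv * tlx
        frc[l, 1] -= dv * tly
        frc[l, 2] -= dv * tlz

    # native contacts (12-10 wells) + smooth Q + optional umbrella bias
    ncon = con_idx.shape[0]
    q_sum = 0.0
    for a in range(ncon):
        i, j = con_idx[a, 0], con_idx[a, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        s = con_r0[a] / r
        s2 = s * s
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        epot += con_eps[a] * (5.0 * s12 - 6.0 * s10)
        dvdr = -60.0 * con_eps[a] * s10 * (s2 - 1.0) / r
        # Q switching term
        ex = np.exp(q_gamma * (r - q_lam * con_r0[a]))
        sw = 1.0 / (1.0 + ex)
        q_sum += sw
        fx = -dvdr * dx / r
        fy = -dvdr * dy / r
        fz = -dvdr * dz / r
        frc[i, 0] += fx
        frc[i, 1] += fy
        frc[i, 2] += fz
        frc[j, 0] -= fx
        frc[j, 1] -= fy
        frc[j, 2] -= fz
    q_val = q_sum / ncon if ncon > 0 else 0.0
    # biases acting on Q: umbrella restraint plus the (destabilizing-at-
    # midpoint) many-body cooperativity term; forces by chain rule
    if (k_umb != 0.0 or k_coop != 0.0) and ncon > 0:
        epot += 0.5 * k_umb * (q_val - q0) ** 2 \
            + 0.5 * k_coop * (q_val - q0_coop) ** 2
        pref = -(k_umb * (q_val - q0)
                 + k_coop * (q_val - q0_coop)) / ncon
        for a in range(ncon):
            i, j = con_idx[a, 0], con_idx[a, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            ex = np.exp(q_gamma * (r - q_lam * con_r0[a]))
            sw = 1.0 / (1.0 + ex)
            dswdr = -q_gamma * sw * sw * ex
            coef = pref * dswdr  # force magnitude along rhat
            frc[i, 0] += coef * dx / r
            frc[i, 1] += coef * dy / r
            frc[i, 2] += coef * dz / r
            frc[j, 0] -= coef * dx / r
            frc[j, 1] -= coef * dy / r
            frc[j, 2] -= coef * dz / r

    # intra-chain excluded volume
    for a in range(rep_idx.shape[0]):
        i, j = rep_idx[a, 0], rep_idx[a, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        sig = rep_sig[a]
        if r2 > (REP_CUTOFF_FACTOR * sig) ** 2:
            continue
        r = np.sqrt(r2)
        u = sig / r
        u2 = u * u
        u6 = u2 * u2 * u2
        u10 = u6 * u2 * u2
        u12 = u10 * u2
        epot += eps_rep * (u12 - 2.0 * u10 + u6)
        dvdr = eps_rep * (-12.0 * u12 + 20.0 * u10 - 6.0 * u6) / r
        fx = -dvdr * dx / r
        fy = -dvdr * dy / r
        fz = -dvdr * dz / r
        frc[i, 0] += fx
        frc[i, 1] += fy
        frc[i, 2] += fz
        frc[j, 0] -= fx
        frc[j, 1] -= fy
        frc[j, 2] -= fz

    # mobile-scaffold excluded volume via the static cell list
    ns = sc_pos.shape[0]
    if ns > 0:
        for i in range(n):
            cx = int((pos[i, 0] - grid_origin[0]) / grid_cell)
            cy = int((pos[i, 1] - grid_origin[1]) / grid_cell)
            cz = int((pos[i, 2] - grid_origin[2]) / grid_cell)
            for ox in range(-1, 2):
                gx = cx + ox
                if gx < 0 or gx >= grid_dims[0]:
                    continue
                for oy in range(-1, 2):
                    gy = cy + oy
                    if gy < 0 or gy >= grid_dims[1]:
                        continue
                    for oz in range(-1, 2):
                        gz = cz + oz
                        if gz < 0 or gz >= grid_dims[2]:
                            continue
                        flat = (gx * grid_dims[1] + gy) * grid_dims[2] + gz
                        start = cell_start[flat]
                        for b in range(cell_count[flat]):
                            j = cell_beads[start + b]
                            dx = pos[i, 0] - sc_pos[j, 0]
                            dy = pos[i, 1] - sc_pos[j, 1]
                            dz = pos[i, 2] - sc_pos[j, 2]
                            r2 = dx * dx + dy * dy + dz * dz
                            sig = sc_sig_row[i * ns + j]
                            if r2 > (REP_CUTOFF_FACTOR * sig) ** 2:
                                continue
                            r = np.sqrt(r2)
                            u = sig / r
                            u2 = u * u
                            u6 = u2 * u2 * u2
                            u10 = u6 * u2 * u2
                            u12 = u10 * u2
                            epot += eps_rep * (u12 - 2.0 * u10 + u6)
                            dvdr = eps_rep * (-12.0 * u12 + 20.0 * u10
                                              - 6.0 * u6) / r
                            frc[i, 0] -= dvdr * dx / r
                            frc[i, 1] -= dvdr * dy / r
                            frc[i, 2] -= dvdr * dz / r

    # hydrophobic surface attractions (12-6 LJ, mobile vs scaffold bead)
    for a in range(hp_idx.shape[0]):
        i, j = hp_idx[a, 0], hp_idx[a, 1]
        dx = pos[i, 0] - sc_pos[j, 0]
        dy = pos[i, 1] - sc_pos[j, 1]
        dz = pos[i, 2] - sc_pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        u = hp_sigma / r
        u2 = u * u
        u6 = u2 * u2 * u2
        u12 = u6 * u6
        epot += 4.0 * hp_eps * (u12 - u6)
        dvdr = 4.0 * hp_eps * (-12.0 * u12 + 6.0 * u6) / r
        frc[i, 0] -= dvdr * dx / r
        frc[i, 1] -= dvdr * dy / r
        frc[i, 2] -= dvdr * dz / r

    # force-reporting tether (the one unconstrained bond)
    x_teth = 0.0
    if teth_i >= 0:
        dx = pos[teth_i, 0] - anchor[0]
        dy = pos[teth_i, 1] - anchor[1]
        dz = pos[teth_i, 2] - anchor[2]
        x_teth = np.sqrt(dx * dx + dy * dy + dz * dz)
        epot += 0.5 * ks * (x_teth - x0) ** 2
        if x_teth > 1e-12:
            coef = -ks * (x_teth - x0) / x_teth
            frc[teth_i, 0] += coef * dx
            frc[teth_i, 1] += coef * dy
            frc[teth_i, 2] += coef * dz

    return epot, q_val, x_teth


@njit(cache=True)
def _shake(pos, cons_idx, cons_r0, invm, tol, max_iter):
    """Iterative bond-length projection; returns worst residual."""
    worst = 0.0
    for it in range(max_iter):
        worst = 0.0
        for a in range(cons_idx.shape[0]):
            i, j = cons_idx[a, 0], cons_idx[a, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            diff = r - cons_r0[a]
            ad = abs(diff)
            if ad > worst:
                worst = ad
            if ad > tol:
                wi = invm[i]
                wj = invm[j]
                g = diff / (r * (wi + wj))
                pos[i, 0] -= g * wi * dx
                pos[i, 1] -= g * wi * dy
                pos[i, 2] -= g * wi * dz
                pos[j, 0] += g * wj * dx
                pos[j, 1] += g * wj * dy
                pos[j, 2] += g * wj * dz
        if worst <= tol:
            break
    return worst


@njit(cache=True)
def _rattle_vel(pos, vel, cons_idx, cons_r0, invm, tol, max_iter):
    """Remove relative velocities along constrained bonds."""
    for it in range(max_iter):
        worst = 0.0
        for a in range(cons_idx.shape[0]):
            i, j = cons_idx[a, 0], cons_idx[a, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            dvx = vel[i, 0] - vel[j, 0]
            dvy = vel[i, 1] - vel[j, 1]
            dvz = vel[i, 2] - vel[j, 2]
            proj = (dvx * dx + dvy * dy + dvz * dz) / r2
            if abs(proj) > worst:
                worst = abs(proj)
            wi = invm[i]
            wj = invm[j]
            g = proj / (wi + wj)
            vel[i, 0] -= g * wi * dx
            vel[i, 1] -= g * wi * dy
            vel[i, 2] -= g * wi * dz
            vel[j, 0] += g * wj * dx
            vel[j, 1] += g * wj * dy
            vel[j, 2] += g * wj * dz
        if worst <= tol:
            break


@njit(cache=True)
def run_md(pos, vel, mass, dt, gamma, kT, n_steps, stride, seed,
           ang_idx, theta0, k_ang,
           dih_idx, phi0, k_dih,
           con_idx, con_r0, con_eps,
           rep_idx, rep_sig, eps_rep,
           sc_pos, sc_sig_row, grid_origin, grid_cell, grid_dims,
           cell_start, cell_count, cell_beads,
           hp_idx, hp_sigma, hp_eps,
           teth_i, anchor, ks, x0,
           q_gamma, q_lam, k_umb, q0, k_coop, q0_coop,
           cons_idx, cons_r0, cons_tol,
           rec_t, rec_q, rec_x, rec_dx, rec_e, save_pos, rec_pos):
    """Constrained BAOAB Langevin propagation with reduced-record output.

    Records (t, Q, tether extension, total energy) every ``stride`` steps;
    optionally full positions.  Returns the number of records written, or
    -1 on numerical divergence (non-finite coordinates).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    invm = 1.0 / mass
    frc = np.zeros((n, 3))
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    max_cons_iter = 500
    epot, q_val, x_teth = _forces(
        pos, frc, ang_idx, theta0, k_ang, dih_idx, phi0, k_dih,
        con_idx, con_r0, con_eps, rep_idx, rep_sig, eps_rep,
        sc_pos, sc_sig_row, grid_origin, grid_cell, grid_dims,
        cell_start, cell_count, cell_beads, hp_idx, hp_sigma, hp_eps,
        teth_i, anchor, ks, x0, q_gamma, q_lam, k_umb, q0, k_coop, q0_coop)
    nrec = 0
    half = 0.5 * dt
    old = np.zeros((n, 3))
    for step in range(n_steps):
        # B
        for i in range(n):
            vel[i, 0] += half * frc[i, 0] * invm[i]
            vel[i, 1] += half * frc[i, 1] * invm[i]
            vel[i, 2] += half * frc[i, 2] * invm[i]
        if cons_idx.shape[0] > 0:
            _rattle_vel(pos, vel, cons_idx, cons_r0, invm, 1e-10,
                        max_cons_iter)
        # A (half drift) + SHAKE
        for i in range(n):
            old[i, 0] = pos[i, 0]
            old[i, 1] = pos[i, 1]
            old[i, 2] = pos[i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if cons_idx.shape[0] > 0:
            _shake(pos, cons_idx, cons_r0, invm, cons_tol, max_cons_iter)
            for i in range(n):
                vel[i, 0] = (pos[i, 0] - old[i, 0]) / half
                vel[i, 1] = (pos[i, 1] - old[i, 1]) / half
                vel[i, 2] = (pos[i, 2] - old[i, 2]) / half
        # O (Ornstein-Uhlenbeck)
        if gamma > 0.0:
            for i in range(n):
                sd = np.sqrt(kT * invm[i])
                vel[i, 0] = c1 * vel[i, 0] + c2 * sd * np.random.normal()
                vel[i, 1] = c1 * vel[i, 1] + c2 * sd * np.random.normal()
                vel[i, 2] = c1 * vel[i, 2] + c2 * sd * np.random.normal()
            if cons_idx.shape[0] > 0:
                _rattle_vel(pos, vel, cons_idx, cons_r0, invm, 1e-10,
                            max_cons_iter)
        # A (half drift) + SHAKE
        for i in range(n):
            old[i, 0] = pos[i, 0]
            old[i, 1] = pos[i, 1]
            old[i, 2] = pos[i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if cons_idx.shape[0] > 0:
            _shake(pos, cons_idx, cons_r0, invm, cons_tol, max_cons_iter)
            for i in range(n):
                vel[i, 0] = (pos[i, 0] - old[i, 0]) / half
                vel[i, 1] = (pos[i, 1] - old[i, 1]) / half
                vel[i, 2] = (pos[i, 2] - old[i, 2]) / half
        # forces at the new positions
        epot, q_val, x_teth = _forces(
            pos, frc, ang_idx, theta0, k_ang, dih_idx, phi0, k_dih,
            con_idx, con_r0, con_eps, rep_idx, rep_sig, eps_rep,
            sc_pos, sc_sig_row, grid_origin, grid_cell, grid_dims,
            cell_start, cell_count, cell_beads, hp_idx, hp_sigma, hp_eps,
            teth_i, anchor, ks, x0, q_gamma, q_lam, k_umb, q0, k_coop, q0_coop)
        # B
        for i in range(n):
            vel[i, 0] += half * frc[i, 0] * invm[i]
            vel[i, 1] += half * frc[i, 1] * invm[i]
            vel[i, 2] += half * frc[i, 2] * invm[i]
        if cons_idx.shape[0] > 0:
            _rattle_vel(pos, vel, cons_idx, cons_r0, invm, 1e-10,
                        max_cons_iter)
        if not np.isfinite(pos[0, 0]):
            return -1
        if (step + 1) % stride == 0:
            ekin = 0.0
            for i in range(n):
                ekin += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                         + vel[i, 2] ** 2)
            rec_t[nrec] = (step + 1) * dt
            rec_q[nrec] = q_val
            rec_x[nrec] = x_teth
            if teth_i >= 0:
                rec_dx[nrec, 0] = pos[teth_i, 0] - anchor[0]
                rec_dx[nrec, 1] = pos[teth_i, 1] - anchor[1]
                rec_dx[nrec, 2] = pos[teth_i, 2] - anchor[2]
            rec_e[nrec] = epot + ekin
            if save_pos:
                for i in range(n):
                    rec_pos[nrec, i, 0] = pos[i, 0]
                    rec_pos[nrec, i, 1] = pos[i, 1]
                    rec_pos[nrec, i, 2] = pos[i, 2]
            nrec += 1
    return nrec


@njit(cache=True)
def minimize(pos, mass, n_iter, max_disp,
             ang_idx, theta0, k_ang,
             dih_idx, phi0, k_dih,
             con_idx, con_r0, con_eps,
             rep_idx, rep_sig, eps_rep,
             sc_pos, sc_sig_row, grid_origin, grid_cell, grid_dims,
             cell_start, cell_count, cell_beads,
             hp_idx, hp_sigma, hp_eps,
             teth_i, anchor, ks, x0,
             q_gamma, q_lam, k_umb, q0, k_coop, q0_coop,
             cons_idx, cons_r0, cons_tol):
    """Displacement-capped steepest descent with constraint projection."""
    n = pos.shape[0]
    invm = 1.0 / mass
    frc = np.zeros((n, 3))
    e_prev = 1e300
    for it in range(n_iter):
        epot, q_val, x_teth = _forces(
            pos, frc, ang_idx, theta0, k_ang, dih_idx, phi0, k_dih,
            con_idx, con_r0, con_eps, rep_idx, rep_sig, eps_rep,
            sc_pos, sc_sig_row, grid_origin, grid_cell, grid_dims,
            cell_start, cell_count, cell_beads, hp_idx, hp_sigma, hp_eps,
            teth_i, anchor, ks, x0, q_gamma, q_lam, k_umb, q0, k_coop, q0_coop)
        fmax = 0.0
        for i in range(n):
            for d in range(3):
                af = abs(frc[i, d])
                if af > fmax:
                    fmax = af
        if fmax < 1e-6:
            break
        scale = max_disp / fmax
        for i in range(n):
            for d in range(3):
                pos[i, d] += scale * frc[i, d]
        if cons_idx.shape[0] > 0:
            _shake(pos, cons_idx, cons_r0, invm, cons_tol, 500)
        e_prev = epot
    return e_prev


@njit(cache=True)
def kmc_four_state(kf, ku, ke_u, ke_f, t_total, n_replicas, seed):
    """BKL kinetic Monte Carlo on {UA, FA, UR, FR}; UR/FR absorbing.

    Returns per-replica escape times (inf if still arrested at t_total).
    State coding: 0 = UA, 1 = FA.  Transition selection uses a uniform
    random number against the cumulative rates; the waiting time is
    dt = -ln(delta') / sum(k).
    """
    np.random.seed(seed)
    out = np.full(n_replicas, np.inf)
    for r in range(n_replicas):
        t = 0.0
        state = 0
        while t < t_total:
            if state == 0:
                k1 = kf      # UA -> FA
                k2 = ke_u    # UA -> UR (absorbing)
            else:
                k1 = ku      # FA -> UA
                k2 = ke_f    # FA -> FR (absorbing)
            ktot = k1 + k2
            if ktot <= 0.0:
                return np.full(1, -1.0)  # zero outflow: flagged to caller
            delta = np.random.random()
            absorb = delta * ktot >= k1
            t += -np.log(np.random.random()) / ktot
            if absorb:
                if t <= t_total:
                    out[r] = t
                break
            state = 1 - state
    return out
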