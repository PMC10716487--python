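"""Numba kernels for Brownian-dynamics photon emission.

The production FCS simulator fuses trajectory propagation and photon
emission in a single pass (storing full trajectories for minutes-long
acquisitions is infeasible), drawing all randomness from one generator in a
fixed order: per time step, per emitter — three motion normals, then the
emission draws.  Detection is the "nested-volume" model: photons are
generated from the largest (sum 5×5) 3D-Gaussian detection volume and
assigned to the inner volumes by hierarchical thinning with probability
W_inner(r)/W_outer(r), which makes each merged virtual volume an *exact*
3D Gaussian at its calibrated waist.

Tier codes emitted: 0 = central element, 1 = inner 3×3 ring, 2 = outer ring,
3 = single-element (red) detector.
"""

import numpy as np
from numba import njit

TIER_CENTRAL = 0
TIER_RING3 = 1
TIER_OUTER = 2
TIER_RED = 3

KIND_FREE = 0
KIND_TRAP = 1
KIND_HOP = 2


@njit(cache=True, inline="always")
def _wrap(x, L):
    # periodic wrap into [-L/2, L/2); single-step displacements are far
    # smaller than the box, so one conditional suffices (no fmod)
    if x >= 0.5 * L:
        return x - L
    if x < -0.5 * L:
        return x + L
    return x


@njit(cache=True, inline="always")
def _hop_axis(x_old, x_new, L, mesh, p_hop):
    # mesh planes at multiples of `mesh` in box coordinates [0, L)
    u_old = x_old + 0.5 * L
    u_new = x_new + 0.5 * L
    c_old = np.floor(u_old / mesh)
    c_new = np.floor(u_new / mesh)
    if c_old != c_new:
        if np.random.random() >= p_hop:
            # reflect across the crossed plane
            if c_new > c_old:
                b = (c_old + 1.0) * mesh
            else:
                b = c_old * mesh
            u_new = 2.0 * b - u_new
            # guard against pathological double crossings
            if np.floor(u_new / mesh) != c_old:
                u_new = u_old
    return u_new - 0.5 * L


@njit(cache=True)
def fcs_block_kernel(
    seed,
    dt,
    step0,
    pos,
    box,
    kind,
    mp,
    trapped,
    dom_center,
    normals,
    cxs,
    cys,
    n_co,
    n_green,
    bg5_dt,
    inv2w5,
    inv2z5,
    a3,
    d3w,
    d3z,
    ac,
    dcw,
    dcz,
    br_dt,
    inv2wr,
    inv2zr,
    r2cut,
    z2cut,
    times,
    tiers,
    count,
):
    """Fused Brownian motion + nested-volume photon emission, one block.

    Motion standard normals are supplied in ``normals`` (n_block, n_em, 3)
    — bulk generation outside the kernel is far faster than scalar draws —
    while the rare emission draws (Poisson counts, photon times, thinning)
    use the kernel RNG seeded once per block.  ``pos`` (n_em, 3) is
    advanced in place; emitters are ordered [dual-color, green-only,
    red-only]: indices < n_co emit both colors, [n_co, n_green) green
    only, >= n_green red only.  ``cxs``/``cys`` give the scan-centre path
    per step.  Returns the running photon count, or -1 on overflow.
    """
    np.random.seed(seed)
    n_block = normals.shape[0]
    n_em = pos.shape[0]
    cap = times.size
    for bs in range(n_block):
        step = step0 + bs
        cx = cxs[bs]
        cy = cys[bs]
        for i in range(n_em):
            # ---- motion -------------------------------------------------
            if kind == KIND_FREE:
                sigma = mp[0]
                pos[i, 0] = _wrap(pos[i, 0] + sigma * normals[bs, i, 0], box[0])
                pos[i, 1] = _wrap(pos[i, 1] + sigma * normals[bs, i, 1], box[1])
                pos[i, 2] = _wrap(pos[i, 2] + sigma * normals[bs, i, 2], box[2])
            elif kind == KIND_TRAP:
                sigma_out = mp[0]
                sigma_in = mp[1]
                radius = mp[2]
                spacing = mp[3]
                p_trap = mp[4]
                p_escape = mp[5]
                if trapped[i] == 1:
                    dx = sigma_in * normals[bs, i, 0]
                    dy = sigma_in * normals[bs, i, 1]
                    dz = sigma_in * normals[bs, i, 2]
                    if np.random.random() < p_escape:
                        trapped[i] = 0
                        pos[i, 0] = _wrap(pos[i, 0] + dx, box[0])
                        pos[i, 1] = _wrap(pos[i, 1] + dy, box[1])
                        pos[i, 2] = _wrap(pos[i, 2] + dz, box[2])
                    else:
                        nx = pos[i, 0] + dx - dom_center[i, 0]
                        ny = pos[i, 1] + dy - dom_center[i, 1]
                        nz = pos[i, 2] + dz - dom_center[i, 2]
                        r = np.sqrt(nx * nx + ny * ny + nz * nz)
                        if r > radius:
                            # radial reflection at the domain boundary
                            rr = 2.0 * radius - r
                            if rr < 0.0:
                                rr = radius
                            scale = rr / r
                            nx *= scale
                            ny *= scale
                            nz *= scale
                        pos[i, 0] = dom_center[i, 0] + nx
                        pos[i, 1] = dom_center[i, 1] + ny
                        pos[i, 2] = dom_center[i, 2] + nz
                else:
                    x = _wrap(pos[i, 0] + sigma_out * normals[bs, i, 0], box[0])
                    y = _wrap(pos[i, 1] + sigma_out * normals[bs, i, 1], box[1])
                    z = _wrap(pos[i, 2] + sigma_out * normals[bs, i, 2], box[2])
                    pos[i, 0] = x
                    pos[i, 1] = y
                    pos[i, 2] = z
                    # domains on a periodic cubic lattice of pitch `spacing`
                    gx = np.round(x / spacing) * spacing
                    gy = np.round(y / spacing) * spacing
                    gz = np.round(z / spacing) * spacing
                    ddx = x - gx
                    ddy = y - gy
                    ddz = z - gz
                    if ddx * ddx + ddy * ddy + ddz * ddz < radius * radius:
                        if np.random.random() < p_trap:
                            trapped[i] = 1
                            dom_center[i, 0] = gx
                            dom_center[i, 1] = gy
                            dom_center[i, 2] = gz
            else:  # KIND_HOP
                sigma = mp[0]
                mesh = mp[1]
                p_hop = mp[2]
                for ax in range(3):
                    xo = pos[i, ax]
                    xn = xo + sigma * normals[bs, i, ax]
                    xn = _hop_axis(xo, xn, box[ax], mesh, p_hop)
                    pos[i, ax] = _wrap(xn, box[ax])

            # ---- emission -----------------------------------------------
            x = pos[i, 0] - cx
            y = pos[i, 1] - cy
            z = pos[i, 2]
            r2 = x * x + y * y
            z2 = z * z
            if r2 > r2cut or z2 > z2cut:
                continue
            if bg5_dt > 0.0 and i < n_green:
                lam = bg5_dt * np.exp(-r2 * inv2w5 - z2 * inv2z5)
                n_ph = np.random.poisson(lam)
                for _ in range(n_ph):
                    if count >= cap:
                        return -1
                    times[count] = (step + np.random.random()) * dt
                    p3 = a3 * np.exp(-r2 * d3w - z2 * d3z)
                    if np.random.random() < p3:
                        pc = ac * np.exp(-r2 * dcw - z2 * dcz)
                        if np.random.random() < pc:
                            tiers[count] = TIER_CENTRAL
                        else:
                            tiers[count] = TIER_RING3
                    else:
                        tiers[count] = TIER_OUTER
                    count += 1
            if br_dt > 0.0 and (i < n_co or i >= n_green):
                lam = br_dt * np.exp(-r2 * inv2wr - z2 * inv2zr)
                n_ph = np.random.poisson(lam)
                for _ in range(n_ph):
                    if count >= cap:
                        return -1
                    times[count] = (step + np.random.random()) * dt
                    tiers[count] = TIER_RED
                    count += 1
    return count


@njit(cache=True)
def traj_from_normals(dt, pos, box, kind, mp, trapped, dom_center, normals, seed, out):
    """Motion-only propagation storing every position (small problems).

    Same motion code and normal-consumption order as the block kernel;
    trap/hop decision uniforms come from the kernel RNG seeded here.
    """
    np.random.seed(seed)
    n_steps = normals.shape[0]
    n_em = pos.shape[0]
    out[0] = pos
    for bs in range(n_steps):
        for i in range(n_em):
            if kind == KIND_FREE:
                sigma = mp[0]
                pos[i, 0] = _wrap(pos[i, 0] + sigma * normals[bs, i, 0], box[0])
                pos[i, 1] = _wrap(pos[i, 1] + sigma * normals[bs, i, 1], box[1])
                pos[i, 2] = _wrap(pos[i, 2] + sigma * normals[bs, i, 2], box[2])
            elif kind == KIND_TRAP:
                sigma_out = mp[0]
                sigma_in = mp[1]
                radius = mp[2]
                spacing = mp[3]
                p_trap = mp[4]
                p_escape = mp[5]
                if trapped[i] == 1:
                    dx = sigma_in * normals[bs, i, 0]
                    dy = sigma_in * normals[bs, i, 1]
                    dz = sigma_in * normals[bs, i, 2]
                    if np.random.random() < p_escape:
                        trapped[i] = 0
                        pos[i, 0] = _wrap(pos[i, 0] + dx, box[0])
                        pos[i, 1] = _wrap(pos[i, 1] + dy, box[1])
                        pos[i, 2] = _wrap(pos[i, 2] + dz, box[2])
                    else:
                        nx = pos[i, 0] + dx - dom_center[i, 0]
                        ny = pos[i, 1] + dy - dom_center[i, 1]
                        nz = pos[i, 2] + dz - dom_center[i, 2]
                        r = np.sqrt(nx * nx + ny * ny + nz * nz)
                        if r > radius:
                            rr = 2.0 * radius - r
                            if rr < 0.0:
                                rr = radius
                            scale = rr / r
                            nx *= scale
                            ny *= scale
                            nz *= scale
                        pos[i, 0] = dom_center[i, 0] + nx
                        pos[i, 1] = dom_center[i, 1] + ny
                        pos[i, 2] = dom_center[i, 2] + nz
                else:
                    x = _wrap(pos[i, 0] + sigma_out * normals[bs, i, 0], box[0])
                    y = _wrap(pos[i, 1] + sigma_out * normals[bs, i, 1], box[1])
                    z = _wrap(pos[i, 2] + sigma_out * normals[bs, i, 2], box[2])
                    pos[i, 0] = x
                    pos[i, 1] = y
                    pos[i, 2] = z
                    gx = np.round(x / spacing) * spacing
                    gy = np.round(y / spacing) * spacing
                    gz = np.round(z / spacing) * spacing
                    ddx = x - gx
                    ddy = y - gy
                    ddz = z - gz
                    if ddx * ddx + ddy * ddy + ddz * ddz < radius * radius:
                        if np.random.random() < p_trap:
                            trapped[i] = 1
                            dom_center[i, 0] = gx
                            dom_center[i, 1] = gy
                            dom_center[i, 2] = gz
            else:
                sigma = mp[0]
                mesh = mp[1]
                p_hop = mp[2]
                for ax in range(3):
                    xo = pos[i, ax]
                    xn = xo + sigma * normals[bs, i, ax]
                    xn = _hop_axis(xo, xn, box[ax], mesh, p_hop)
                    pos[i, ax] = _wrap(xn, box[ax])
        out[bs + 1] = pos
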