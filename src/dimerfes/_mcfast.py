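"""Numba-compiled inner loop for the rigid-dimer Monte Carlo sampler.

The kernel advances the chain by one chunk (at most one deposition stride) so
that the Python driver can deposit hills — and thereby change the bias — only
at chunk boundaries, keeping the bias frozen inside the kernel. All
randomness is pre-drawn from the caller's seeded Generator, so trajectories
are reproducible bit-for-bit regardless of chunking.

Geometry bookkeeping: world coordinates are mutated in place; each molecule's
ring-plane normal is carried along and rotated with the molecule, which is
exact for rigid bodies and avoids a singular-value decomposition per frame.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Recorded columns: dist, torsion, nangle, bias.

_TWO_PI = 2.0 * np.pi


@njit(cache=True, fastmath=False)
def _pair_energy(ca, cb, sigma_ij, eps_ij, qq_ij, box, cutoff2, k_rf, c_rf):
    e = 0.0
    na, nb = ca.shape[0], cb.shape[0]
    for i in range(na):
        for j in range(nb):
            dx = ca[i, 0] - cb[j, 0]
            dy = ca[i, 1] - cb[j, 1]
            dz = ca[i, 2] - cb[j, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < 1e-12:
                return np.inf  # overlap: infinitely unfavourable, always rejected
            if r2 <= cutoff2:
                r = np.sqrt(r2)
                s = sigma_ij[i, j] / r
                s6 = s * s * s
                s6 = s6 * s6
                e += 4.0 * eps_ij[i, j] * (s6 * s6 - s6)
                q = qq_ij[i, j]
                if q != 0.0:
                    e += q * (1.0 / r + k_rf * r2 - c_rf)
    return e


@njit(cache=True, fastmath=False)
def _cog(coords, ring):
    x = 0.0
    y = 0.0
    z = 0.0
    for k in range(ring.shape[0]):
        i = ring[k]
        x += coords[i, 0]
        y += coords[i, 1]
        z += coords[i, 2]
    n = ring.shape[0]
    return x / n, y / n, z / n


@njit(cache=True, fastmath=False)
def _dihedral_scalar(p0, p1, p2, p3):
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.sqrt(b1[0] ** 2 + b1[1] ** 2 + b1[2] ** 2)
    b1n = b1 / nb1
    dot0 = b0[0] * b1n[0] + b0[1] * b1n[1] + b0[2] * b1n[2]
    v = b0 - dot0 * b1n
    dot2 = b2[0] * b1n[0] + b2[1] * b1n[1] + b2[2] * b1n[2]
    w = b2 - dot2 * b1n
    x = v[0] * w[0] + v[1] * w[1] + v[2] * w[2]
    cx = b1n[1] * v[2] - b1n[2] * v[1]
    cy = b1n[2] * v[0] - b1n[0] * v[2]
    cz = b1n[0] * v[1] - b1n[1] * v[0]
    y = cx * w[0] + cy * w[1] + cz * w[2]
    ang = np.arctan2(y, x)
    if ang == -np.pi:
        ang = np.pi
    return ang


@njit(cache=True, fastmath=False)
def _bias_interp(values, lo0, ds0, n0, lo1, ds1, n1, s0, s1):
    """Bilinear interpolation: axis 0 bounded (clamped), axis 1 periodic."""
    u = (s0 - lo0) / ds0
    if u < 0.0:
        u = 0.0
    elif u > n0 - 1:
        u = float(n0 - 1)
    i0 = int(u)
    if i0 > n0 - 2:
        i0 = n0 - 2
    fx = u - i0
    v = (s1 - lo1) / ds1
    v = v - np.floor(v / n1) * n1
    j0 = int(v) % n1
    j1 = (j0 + 1) % n1
    fy = v - np.floor(v)
    return (
        (1.0 - fx) * ((1.0 - fy) * values[i0, j0] + fy * values[i0, j1])
        + fx * ((1.0 - fy) * values[i0 + 1, j0] + fy * values[i0 + 1, j1])
    )


@njit(cache=True, fastmath=False)
def run_chunk(
    coords_a,
    coords_b,
    normal_a,
    normal_b,
    ring_a,
    ring_b,
    anchor_a,
    anchor_b,
    sigma_ij,
    eps_ij,
    qq_ij,
    box,
    cutoff2,
    k_rf,
    c_rf,
    wall_r0,
    wall_k,
    kt,
    has_bias,
    bias_values,
    lo0,
    ds0,
    n0,
    lo1,
    ds1,
    n1,
    uniforms,
    gauss,
    n_steps,
    step0,
    max_trans,
    max_rot,
    record_stride,
    rec_t,
    rec_cv,
    rec_bias,
    cur_energy,
):
    """Advance n_steps MC moves; returns (accepted, n_recorded, cur_energy)."""
    accepted = 0
    n_rec = 0
    prop_a = np.empty_like(coords_a)
    prop_b = np.empty_like(coords_b)
    for k in range(n_steps):
        gstep = step0 + k + 1
        translate = gstep % 2 == 1
        move_b = uniforms[k, 0] < 0.5
        src = coords_b if move_b else coords_a
        prop = prop_b if move_b else prop_a
        nmol = src.shape[0]
        if translate:
            tx = (2.0 * uniforms[k, 1] - 1.0) * max_trans
            ty = (2.0 * uniforms[k, 2] - 1.0) * max_trans
            tz = (2.0 * uniforms[k, 3] - 1.0) * max_trans
            for i in range(nmol):
                prop[i, 0] = src[i, 0] + tx
                prop[i, 1] = src[i, 1] + ty
                prop[i, 2] = src[i, 2] + tz
            new_nx, new_ny, new_nz = 0.0, 0.0, 0.0
        else:
            ax = gauss[k, 0]
            ay = gauss[k, 1]
            az = gauss[k, 2]
            an = np.sqrt(ax * ax + ay * ay + az * az)
            if an < 1e-12:
                an = 1.0
            ax /= an
            ay /= an
            az /= an
            ang = (2.0 * uniforms[k, 1] - 1.0) * max_rot
            ca_ = np.cos(ang)
            sa_ = np.sin(ang)
            omc = 1.0 - ca_
            # Rodrigues rotation matrix
            m00 = ca_ + ax * ax * omc
            m01 = ax * ay * omc - az * sa_
            m02 = ax * az * omc + ay * sa_
            m10 = ay * ax * omc + az * sa_
            m11 = ca_ + ay * ay * omc
            m12 = ay * az * omc - ax * sa_
            m20 = az * ax * omc - ay * sa_
            m21 = az * ay * omc + ax * sa_
            m22 = ca_ + az * az * omc
            ring = ring_b if move_b else ring_a
            cgx, cgy, cgz = _cog(src, ring)
            for i in range(nmol):
                x = src[i, 0] - cgx
                y = src[i, 1] - cgy
                z = src[i, 2] - cgz
                prop[i, 0] = m00 * x + m01 * y + m02 * z + cgx
                prop[i, 1] = m10 * x + m11 * y + m12 * z + cgy
                prop[i, 2] = m20 * x + m21 * y + m22 * z + cgz
            nrm = normal_b if move_b else normal_a
            new_nx = m00 * nrm[0] + m01 * nrm[1] + m02 * nrm[2]
            new_ny = m10 * nrm[0] + m11 * nrm[1] + m12 * nrm[2]
            new_nz = m20 * nrm[0] + m21 * nrm[1] + m22 * nrm[2]

        if move_b:
            ca = coords_a
            cb = prop
        else:
            ca = prop
            cb = coords_b

        # distance between ring COGs, minimum image
        ax0, ay0, az0 = _cog(ca, ring_a)
        bx0, by0, bz0 = _cog(cb, ring_b)
        dxx = bx0 - ax0
        dyy = by0 - ay0
        dzz = bz0 - az0
        sx = -box * np.rint(dxx / box)
        sy = -box * np.rint(dyy / box)
        sz = -box * np.rint(dzz / box)
        dxx += sx
        dyy += sy
        dzz += sz
        dist = np.sqrt(dxx * dxx + dyy * dyy + dzz * dzz)
        if dist < 1e-9:
            continue  # reject: coincident COGs, CVs undefined
        u = _pair_energy(ca, cb, sigma_ij, eps_ij, qq_ij, box, cutoff2, k_rf, c_rf)
        if u == np.inf:
            continue  # reject: atom overlap
        dr = dist - wall_r0
        if dr > 0.0:
            u += 0.5 * wall_k * dr * dr
        torsion = 0.0
        if has_bias:
            p0 = np.empty(3)
            p1 = np.empty(3)
            p2 = np.empty(3)
            p3 = np.empty(3)
            p0[0] = ca[anchor_a, 0]
            p0[1] = ca[anchor_a, 1]
            p0[2] = ca[anchor_a, 2]
            p1[0] = ax0
            p1[1] = ay0
            p1[2] = az0
            p2[0] = ax0 + dxx
            p2[1] = ay0 + dyy
            p2[2] = az0 + dzz
            p3[0] = cb[anchor_b, 0] + sx
            p3[1] = cb[anchor_b, 1] + sy
            p3[2] = cb[anchor_b, 2] + sz
            torsion = _dihedral_scalar(p0, p1, p2, p3)
            u += _bias_interp(bias_values, lo0, ds0, n0, lo1, ds1, n1, dist, torsion)

        d_u = u - cur_energy
        accept = d_u <= 0.0 or uniforms[k, 4] < np.exp(-d_u / kt)
        if accept:
            accepted += 1
            cur_energy = u
            if move_b:
                for i in range(coords_b.shape[0]):
                    coords_b[i, 0] = prop[i, 0]
                    coords_b[i, 1] = prop[i, 1]
                    coords_b[i, 2] = prop[i, 2]
                if not translate:
                    normal_b[0] = new_nx
                    normal_b[1] = new_ny
                    normal_b[2] = new_nz
            else:
                for i in range(coords_a.shape[0]):
                    coords_a[i, 0] = prop[i, 0]
                    coords_a[i, 1] = prop[i, 1]
                    coords_a[i, 2] = prop[i, 2]
                if not translate:
                    normal_a[0] = new_nx
                    normal_a[1] = new_ny
                    normal_a[2] = new_nz

        if record_stride > 0 and gstep % record_stride == 0:
            # current-state CVs (recompute; state may be old on rejection)
            ax0, ay0, az0 = _cog(coords_a, ring_a)
            bx0, by0, bz0 = _cog(coords_b, ring_b)
            dxx = bx0 - ax0
            dyy = by0 - ay0
            dzz = bz0 - az0
            sx = -box * np.rint(dxx / box)
            sy = -box * np.rint(dyy / box)
            sz = -box * np.rint(dzz / box)
            dxx += sx
            dyy += sy
            dzz += sz
            dist_c = np.sqrt(dxx * dxx + dyy * dyy + dzz * dzz)
            p0 = np.empty(3)
            p1 = np.empty(3)
            p2 = np.empty(3)
            p3 = np.empty(3)
            p0[0] = coords_a[anchor_a, 0]
            p0[1] = coords_a[anchor_a, 1]
            p0[2] = coords_a[anchor_a, 2]
            p1[0] = ax0
            p1[1] = ay0
            p1[2] = az0
            p2[0] = ax0 + dxx
            p2[1] = ay0 + dyy
            p2[2] = az0 + dzz
            p3[0] = coords_b[anchor_b, 0] + sx
            p3[1] = coords_b[anchor_b, 1] + sy
            p3[2] = coords_b[anchor_b, 2] + sz
            tors_c = _dihedral_scalar(p0, p1, p2, p3)
            dot = (
                normal_a[0] * normal_b[0]
                + normal_a[1] * normal_b[1]
                + normal_a[2] * normal_b[2]
            )
            if dot < 0.0:
                dot = -dot
            if dot > 1.0:
                dot = 1.0
            nang = np.arccos(dot)
            b_now = 0.0
            if has_bias:
                b_now = _bias_interp(
                    bias_values, lo0, ds0, n0, lo1, ds1, n1, dist_c, tors_c
                )
            rec_t[n_rec] = gstep
            rec_cv[n_rec, 0] = dist_c
            rec_cv[n_rec, 1] = tors_c
            rec_cv[n_rec, 2] = nang
            rec_bias[n_rec] = b_now
            n_rec += 1
    return accepted, n_rec, cur_energy
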