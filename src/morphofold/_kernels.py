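"""Numba inner loops for the finite-element solver.

Everything here is scalar-unrolled 3x3 arithmetic: the solver spends almost
all of its time in ``internal_forces``, so per-element temporaries are kept
in registers rather than small arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def internal_forces(pos, tets, Bm, V0, Nel, ga, gb, mu, K, out_f):
    """Accumulate elastic nodal forces for linear tets, one quadrature point.

    Parameters
    ----------
    pos : (n, 3) current node positions
    tets : (m, 4) element connectivity
    Bm : (m, 3, 3) inverse reference shape matrices
    V0 : (m,) reference element volumes
    Nel : (m, 3) reference growth normals
    ga, gb : (m,) current normal / tangential growth stretches (1 + lam*s)
    mu, K : (m,) shear and bulk moduli per element
    out_f : (n, 3) output, zeroed and accumulated in place

    Returns ``(bad, energy)``: the index of the first inverted element
    (det Fe <= 0, energy then invalid) or -1, and the total stored elastic
    energy (Psi integrated over grown volume).
    """
    out_f[:] = 0.0
    energy = 0.0
    m = tets.shape[0]
    for e in range(m):
        i0 = tets[e, 0]
        i1 = tets[e, 1]
        i2 = tets[e, 2]
        i3 = tets[e, 3]
        x0 = pos[i0, 0]
        y0 = pos[i0, 1]
        z0 = pos[i0, 2]
        # Ds columns: edge vectors from node 0
        d00 = pos[i1, 0] - x0
        d10 = pos[i1, 1] - y0
        d20 = pos[i1, 2] - z0
        d01 = pos[i2, 0] - x0
        d11 = pos[i2, 1] - y0
        d21 = pos[i2, 2] - z0
        d02 = pos[i3, 0] - x0
        d12 = pos[i3, 1] - y0
        d22 = pos[i3, 2] - z0
        b00 = Bm[e, 0, 0]
        b01 = Bm[e, 0, 1]
        b02 = Bm[e, 0, 2]
        b10 = Bm[e, 1, 0]
        b11 = Bm[e, 1, 1]
        b12 = Bm[e, 1, 2]
        b20 = Bm[e, 2, 0]
        b21 = Bm[e, 2, 1]
        b22 = Bm[e, 2, 2]
        # F = Ds @ Bm
        f00 = d00 * b00 + d01 * b10 + d02 * b20
        f01 = d00 * b01 + d01 * b11 + d02 * b21
        f02 = d00 * b02 + d01 * b12 + d02 * b22
        f10 = d10 * b00 + d11 * b10 + d12 * b20
        f11 = d10 * b01 + d11 * b11 + d12 * b21
        f12 = d10 * b02 + d11 * b12 + d12 * b22
        f20 = d20 * b00 + d21 * b10 + d22 * b20
        f21 = d20 * b01 + d21 * b11 + d22 * b21
        f22 = d20 * b02 + d21 * b12 + d22 * b22
        # Fg^{-1} = (1/gb) I + (1/ga - 1/gb) N N^T  (symmetric)
        nx = Nel[e, 0]
        ny = Nel[e, 1]
        nz = Nel[e, 2]
        ia = 1.0 / ga[e]
        ib = 1.0 / gb[e]
        c = ia - ib
        g00 = ib + c * nx * nx
        g01 = c * nx * ny
        g02 = c * nx * nz
        g11 = ib + c * ny * ny
        g12 = c * ny * nz
        g22 = ib + c * nz * nz
        Jg = ga[e] * gb[e] * gb[e]
        # Fe = F @ Fg^{-1}
        e00 = f00 * g00 + f01 * g01 + f02 * g02
        e01 = f00 * g01 + f01 * g11 + f02 * g12
        e02 = f00 * g02 + f01 * g12 + f02 * g22
        e10 = f10 * g00 + f11 * g01 + f12 * g02
        e11 = f10 * g01 + f11 * g11 + f12 * g12
        e12 = f10 * g02 + f11 * g12 + f12 * g22
        e20 = f20 * g00 + f21 * g01 + f22 * g02
        e21 = f20 * g01 + f21 * g11 + f22 * g12
        e22 = f20 * g02 + f21 * g12 + f22 * g22
        # cofactors and determinant of Fe
        c00 = e11 * e22 - e12 * e21
        c01 = e12 * e20 - e10 * e22
        c02 = e10 * e21 - e11 * e20
        J = e00 * c00 + e01 * c01 + e02 * c02
        if J <= 0.0:
            return e, 0.0
        c10 = e02 * e21 - e01 * e22
        c11 = e00 * e22 - e02 * e20
        c12 = e01 * e20 - e00 * e21
        c20 = e01 * e12 - e02 * e11
        c21 = e02 * e10 - e00 * e12
        c22 = e00 * e11 - e01 * e10
        # Fe^{-T} = cof(Fe) / J  (cofactor matrix, not transposed)
        iJ = 1.0 / J
        t00 = c00 * iJ
        t01 = c10 * iJ
        t02 = c20 * iJ
        t10 = c01 * iJ
        t11 = c11 * iJ
        t12 = c21 * iJ
        t20 = c02 * iJ
        t21 = c12 * iJ
        t22 = c22 * iJ
        # note: cof layout above gives inv(Fe) = cof^T / J, so Fe^{-T} = cof/J;
        # t is written as cof^T/J = Fe^{-1}; fix: we need Fe^{-T} = (Fe^{-1})^T
        # Fe^{-1} rows were assembled in t; transpose on use below.
        I1 = (
            e00 * e00
            + e01 * e01
            + e02 * e02
            + e10 * e10
            + e11 * e11
            + e12 * e12
            + e20 * e20
            + e21 * e21
            + e22 * e22
        )
        k1 = mu[e] * J ** (-2.0 / 3.0)
        k2 = K[e] * (J - 1.0)
        third = I1 / 3.0
        psi = 0.5 * mu[e] * (I1 * J ** (-2.0 / 3.0) - 3.0) + K[e] * (
            J - np.log(J) - 1.0
        )
        energy += psi * V0[e] * Jg
        # P = k1*(Fe - third*Fe^{-T}) + k2*Fe^{-T}
        q = k2 - k1 * third
        # Fe^{-T}[i,j] = Fe^{-1}[j,i] = t[j,i]
        p00 = k1 * e00 + q * t00
        p01 = k1 * e01 + q * t10
        p02 = k1 * e02 + q * t20
        p10 = k1 * e10 + q * t01
        p11 = k1 * e11 + q * t11
        p12 = k1 * e12 + q * t21
        p20 = k1 * e20 + q * t02
        p21 = k1 * e21 + q * t12
        p22 = k1 * e22 + q * t22
        # G = P @ Fg^{-T} = P @ Fg^{-1} (symmetric)
        G00 = p00 * g00 + p01 * g01 + p02 * g02
        G01 = p00 * g01 + p01 * g11 + p02 * g12
        G02 = p00 * g02 + p01 * g12 + p02 * g22
        G10 = p10 * g00 + p11 * g01 + p12 * g02
        G11 = p10 * g01 + p11 * g11 + p12 * g12
        G12 = p10 * g02 + p11 * g12 + p12 * g22
        G20 = p20 * g00 + p21 * g01 + p22 * g02
        G21 = p20 * g01 + p21 * g11 + p22 * g12
        G22 = p20 * g02 + p21 * g12 + p22 * g22
        w = -V0[e] * Jg
        # H = w * G @ Bm^T ; columns are forces on nodes 1..3
        h00 = w * (G00 * b00 + G01 * b01 + G02 * b02)
        h10 = w * (G10 * b00 + G11 * b01 + G12 * b02)
        h20 = w * (G20 * b00 + G21 * b01 + G22 * b02)
        h01 = w * (G00 * b10 + G01 * b11 + G02 * b12)
        h11 = w * (G10 * b10 + G11 * b11 + G12 * b12)
        h21 = w * (G20 * b10 + G21 * b11 + G22 * b12)
        h02 = w * (G00 * b20 + G01 * b21 + G02 * b22)
        h12 = w * (G10 * b20 + G11 * b21 + G12 * b22)
        h22 = w * (G20 * b20 + G21 * b21 + G22 * b22)
        out_f[i1, 0] += h00
        out_f[i1, 1] += h10
        out_f[i1, 2] += h20
        out_f[i2, 0] += h01
        out_f[i2, 1] += h11
        out_f[i2, 2] += h21
        out_f[i3, 0] += h02
        out_f[i3, 1] += h12
        out_f[i3, 2] += h22
        out_f[i0, 0] -= h00 + h01 + h02
        out_f[i0, 1] -= h10 + h11 + h12
        out_f[i0, 2] -= h20 + h21 + h22
    return -1, energy


@njit(cache=True)
def _closest_point_triangle(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Closest point on triangle abc to point p; returns (x, y, z, wa, wb, wc)."""
    abx = bx - ax
    aby = by - ay
    abz = bz - az
    acx = cx - ax
    acy = cy - ay
    acz = cz - az
    apx = px - ax
    apy = py - ay
    apz = pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return ax, ay, az, 1.0, 0.0, 0.0
    bpx = px - bx
    bpy = py - by
    bpz = pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bx, by, bz, 0.0, 1.0, 0.0
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        return ax + v * abx, ay + v * aby, az + v * abz, 1.0 - v, v, 0.0
    cpx = px - cx
    cpy = py - cy
    cpz = pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cx, cy, cz, 0.0, 0.0, 1.0
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        return ax + w * acx, ay + w * acy, az + w * acz, 1.0 - w, 0.0, w
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return (
            bx + w * (cx - bx),
            by + w * (cy - by),
            bz + w * (cz - bz),
            0.0,
            1.0 - w,
            w,
        )
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return (
        ax + abx * v + acx * w,
        ay + aby * v + acy * w,
        az + abz * v + acz * w,
        1.0 - v - w,
        v,
        w,
    )


@njit(cache=True)
def contact_forces(pos, tris, cand_node, cand_tri, stiffness, crange, out_f):
    """Node–triangle penalty forces for pre-filtered candidate pairs.

    Linear spring of the given stiffness acting when the node lies within
    ``crange`` of the triangle; equal and opposite force distributed to the
    triangle vertices with barycentric weights.
    """
    n_active = 0
    for q in range(cand_node.shape[0]):
        n = cand_node[q]
        t = cand_tri[q]
        ia = tris[t, 0]
        ib = tris[t, 1]
        ic = tris[t, 2]
        px = pos[n, 0]
        py = pos[n, 1]
        pz = pos[n, 2]
        qx, qy, qz, wa, wb, wc = _closest_point_triangle(
            px,
            py,
            pz,
            pos[ia, 0],
            pos[ia, 1],
            pos[ia, 2],
            pos[ib, 0],
            pos[ib, 1],
            pos[ib, 2],
            pos[ic, 0],
            pos[ic, 1],
            pos[ic, 2],
        )
        dx = px - qx
        dy = py - qy
        dz = pz - qz
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d >= crange:
            continue
        if d > 1e-12:
            ux = dx / d
            uy = dy / d
            uz = dz / d
        else:
            # node on the triangle plane: push along the triangle normal
            e1x = pos[ib, 0] - pos[ia, 0]
            e1y = pos[ib, 1] - pos[ia, 1]
            e1z = pos[ib, 2] - pos[ia, 2]
            e2x = pos[ic, 0] - pos[ia, 0]
            e2y = pos[ic, 1] - pos[ia, 1]
            e2z = pos[ic, 2] - pos[ia, 2]
            ux = e1y * e2z - e1z * e2y
            uy = e1z * e2x - e1x * e2z
            uz = e1x * e2y - e1y * e2x
            nn = np.sqrt(ux * ux + uy * uy + uz * uz)
            if nn < 1e-300:
                continue
            ux /= nn
            uy /= nn
            uz /= nn
        fmag = stiffness * (crange - d)
        fx = fmag * ux
        fy = fmag * uy
        fz = fmag * uz
        out_f[n, 0] += fx
        out_f[n, 1] += fy
        out_f[n, 2] += fz
        out_f[ia, 0] -= wa * fx
        out_f[ia, 1] -= wa * fy
        out_f[ia, 2] -= wa * fz
        out_f[ib, 0] -= wb * fx
        out_f[ib, 1] -= wb * fy
        out_f[ib, 2] -= wb * fz
        out_f[ic, 0] -= wc * fx
        out_f[ic, 1] -= wc * fy
        out_f[ic, 2] -= wc * fz
        n_active += 1
    return n_active


@njit(cache=True, inline="always")
def _sym_eigs(a, b, c, d, e, f):
    """Eigenvalues (descending) of [[a,d,f],[d,b,e],[f,e,c]], trigonometric form."""
    p1 = d * d + f * f + e * e
    if p1 < 1e-300:
        x = a
        y = b
        z = c
        if x < y:
            x, y = y, x
        if y < z:
            y, z = z, y
        if x < y:
            x, y = y, x
        return x, y, z
    q = (a + b + c) / 3.0
    aa = a - q
    bb = b - q
    cc = c - q
    p2 = aa * aa + bb * bb + cc * cc + 2.0 * p1
    p = np.sqrt(p2 / 6.0)
    ip = 1.0 / p
    m00 = aa * ip
    m11 = bb * ip
    m22 = cc * ip
    m01 = d * ip
    m12 = e * ip
    m02 = f * ip
    r = (
        m00 * (m11 * m22 - m12 * m12)
        - m01 * (m01 * m22 - m12 * m02)
        + m02 * (m01 * m12 - m11 * m02)
    ) / 2.0
    if r <= -1.0:
        phi = np.pi / 3.0
    elif r >= 1.0:
        phi = 0.0
    else:
        phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    return e1, e2, e3


@njit(cache=True)
def symmetric_eigvals_3x3(h00, h01, h02, h11, h12, h22, k1, k2, k3):
    """Eigenvalues of flat symmetric 3x3 fields, written sorted descending.

    Trigonometric closed form (stable for the smooth Hessian fields used in
    blob detection); avoids per-voxel LAPACK calls.
    """
    n = h00.shape[0]
    for i in range(n):
        e1, e2, e3 = _sym_eigs(h00[i], h11[i], h22[i], h01[i], h12[i], h02[i])
        k1[i] = e1
        k2[i] = e2
        k3[i] = e3
    return 0


@njit(cache=True, fastmath=True)
def blob_score_from_smoothed(G, ks):
    """Blob score from a pre-smoothed volume in one fused pass.

    Central-difference Hessian (unit voxel spacing), negated, eigenvalues by
    the closed form, ``ks = (k1+ k2+ k3+)^(1/3)``. Border voxels get 0.
    """
    nz, ny, nx = G.shape
    ks[:, :, :] = 0.0
    for z in range(1, nz - 1):
        for y in range(1, ny - 1):
            for x in range(1, nx - 1):
                g = G[z, y, x]
                h00 = G[z + 1, y, x] - 2.0 * g + G[z - 1, y, x]
                h11 = G[z, y + 1, x] - 2.0 * g + G[z, y - 1, x]
                h22 = G[z, y, x + 1] - 2.0 * g + G[z, y, x - 1]
                h01 = 0.25 * (
                    G[z + 1, y + 1, x]
                    - G[z + 1, y - 1, x]
                    - G[z - 1, y + 1, x]
                    + G[z - 1, y - 1, x]
                )
                h02 = 0.25 * (
                    G[z + 1, y, x + 1]
                    - G[z + 1, y, x - 1]
                    - G[z - 1, y, x + 1]
                    + G[z - 1, y, x - 1]
                )
                h12 = 0.25 * (
                    G[z, y + 1, x + 1]
                    - G[z, y + 1, x - 1]
                    - G[z, y - 1, x + 1]
                    + G[z, y - 1, x - 1]
                )
                e1, e2, e3 = _sym_eigs(-h00, -h11, -h22, -h01, -h12, -h02)
                if e3 > 0.0:
                    ks[z, y, x] = (e1 * e2 * e3) ** (1.0 / 3.0)
                elif e1 > 0.0 and e2 > 0.0:
                    ks[z, y, x] = 0.0
    return 0
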