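"""Numba kernels for the two hot paths: Gaussian basis evaluation on large
point batches and trilinear gradient ascent for basin-boundary refinement."""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def eval_basis(points, centers, shell_center, shell_l, shell_pstart, shell_nprim,
               prim_exp, prim_coef, comp_lx, comp_ly, comp_lz, comp_off,
               comp_scale, shell_ao, nbf, phi, gx, gy, gz):
    """Basis values and gradients at points; arrays preallocated (npts, nbf)."""
    npts = points.shape[0]
    nshell = shell_l.shape[0]
    phi[:, :] = 0.0
    gx[:, :] = 0.0
    gy[:, :] = 0.0
    gz[:, :] = 0.0
    for ish in range(nshell):
        l = shell_l[ish]
        A = centers[shell_center[ish]]
        p0 = shell_pstart[ish]
        npr = shell_nprim[ish]
        o = shell_ao[ish]
        nc = 1 if l == 0 else (3 if l == 1 else 6)
        for ip in range(npts):
            dx = points[ip, 0] - A[0]
            dy = points[ip, 1] - A[1]
            dz = points[ip, 2] - A[2]
            r2 = dx * dx + dy * dy + dz * dz
            rad = 0.0
            drad = 0.0
            for k in range(npr):
                e = prim_coef[p0 + k] * np.exp(-prim_exp[p0 + k] * r2)
                rad += e
                drad += -2.0 * prim_exp[p0 + k] * e
            for cc in range(nc):
                i = comp_off[l] + cc
                lx = comp_lx[i]
                ly = comp_ly[i]
                lz = comp_lz[i]
                mx = dx ** lx
                my = dy ** ly
                mz = dz ** lz
                mono = mx * my * mz
                s = comp_scale[o + cc]
                phi[ip, o + cc] = s * mono * rad
                tx = mono * drad * dx
                if lx > 0:
                    tx += lx * dx ** (lx - 1) * my * mz * rad
                ty = mono * drad * dy
                if ly > 0:
                    ty += ly * dy ** (ly - 1) * mx * mz * rad
                tz = mono * drad * dz
                if lz > 0:
                    tz += lz * dz ** (lz - 1) * mx * my * rad
                gx[ip, o + cc] = s * tx
                gy[ip, o + cc] = s * ty
                gz[ip, o + cc] = s * tz


@njit(cache=True, fastmath=True, inline='always')
def _trilinear(f, x, y, z, nx, ny, nz):
    i = int(x)
    j = int(y)
    k = int(z)
    if i > nx - 2:
        i = nx - 2
    if j > ny - 2:
        j = ny - 2
    if k > nz - 2:
        k = nz - 2
    tx = x - i
    ty = y - j
    tz = z - k
    c00 = f[i, j, k] * (1 - tx) + f[i + 1, j, k] * tx
    c10 = f[i, j + 1, k] * (1 - tx) + f[i + 1, j + 1, k] * tx
    c01 = f[i, j, k + 1] * (1 - tx) + f[i + 1, j, k + 1] * tx
    c11 = f[i, j + 1, k + 1] * (1 - tx) + f[i + 1, j + 1, k + 1] * tx
    c0 = c00 * (1 - ty) + c10 * ty
    c1 = c01 * (1 - ty) + c11 * ty
    return c0 * (1 - tz) + c1 * tz


@njit(cache=True, fastmath=True)
def ascend(gx, gy, gz, interior_label, pos, spx, spy, spz, h, max_steps, out):
    """Gradient ascent of points (index units) until an interior voxel of one
    basin is reached; writes that basin id (or -9) into out."""
    nx, ny, nz = interior_label.shape
    npts = pos.shape[0]
    for ip in range(npts):
        x = pos[ip, 0]
        y = pos[ip, 1]
        z = pos[ip, 2]
        lab = -9
        for _ in range(max_steps):
            vx = _trilinear(gx, x, y, z, nx, ny, nz) / spx
            vy = _trilinear(gy, x, y, z, nx, ny, nz) / spy
            vz = _trilinear(gz, x, y, z, nx, ny, nz) / spz
            norm = np.sqrt(vx * vx + vy * vy + vz * vz)
            if norm < 1e-14:
                break
            x += h * vx / norm
            y += h * vy / norm
            z += h * vz / norm
            if x < 0.0:
                x = 0.0
            elif x > nx - 1:
                x = nx - 1.0
            if y < 0.0:
                y = 0.0
            elif y > ny - 1:
                y = ny - 1.0
            if z < 0.0:
                z = 0.0
            elif z > nz - 1:
                z = nz - 1.0
            l_here = interior_label[int(round(x)), int(round(y)), int(round(z))]
            if l_here >= 0:
                lab = l_here
                break
        out[ip] = lab


@njit(cache=True, fastmath=True)
def ascend_handoff(gx, gy, gz, interior_label, pos, sp_fine, orig_g, scale,
                   h, max_steps, out_label, out_pos):
    """Ascent on a locally refined gradient field.

    pos: (n, 3) in fine-grid index units.  Termination: a global-grid voxel
    whose interior_label >= 0 (write label), a vanishing gradient (-9), or
    leaving the fine box (-8, exit point in global index units in out_pos).
    Global index = orig_g + pos / scale.
    """
    nx, ny, nz = gx.shape
    NX, NY, NZ = interior_label.shape
    npts = pos.shape[0]
    for ip in range(npts):
        x = pos[ip, 0]
        y = pos[ip, 1]
        z = pos[ip, 2]
        lab = -9
        for _ in range(max_steps):
            vx = _trilinear(gx, x, y, z, nx, ny, nz) / sp_fine[0]
            vy = _trilinear(gy, x, y, z, nx, ny, nz) / sp_fine[1]
            vz = _trilinear(gz, x, y, z, nx, ny, nz) / sp_fine[2]
            norm = np.sqrt(vx * vx + vy * vy + vz * vz)
            if norm < 1e-14:
                break
            x += h * vx / norm
            y += h * vy / norm
            z += h * vz / norm
            if (x < 0.0 or x > nx - 1 or y < 0.0 or y > ny - 1
                    or z < 0.0 or z > nz - 1):
                lab = -8
                if x < 0.0:
                    x = 0.0
                elif x > nx - 1:
                    x = nx - 1.0
                if y < 0.0:
                    y = 0.0
                elif y > ny - 1:
                    y = ny - 1.0
                if z < 0.0:
                    z = 0.0
                elif z > nz - 1:
                    z = nz - 1.0
                break
            gi = int(round(orig_g[0] + x / scale[0]))
            gj = int(round(orig_g[1] + y / scale[1]))
            gk = int(round(orig_g[2] + z / scale[2]))
            if gi < 0:
                gi = 0
            elif gi > NX - 1:
                gi = NX - 1
            if gj < 0:
                gj = 0
            elif gj > NY - 1:
                gj = NY - 1
            if gk < 0:
                gk = 0
            elif gk > NZ - 1:
                gk = NZ - 1
            l_here = interior_label[gi, gj, gk]
            if l_here >= 0:
                lab = l_here
                break
        out_label[ip] = lab
        out_pos[ip, 0] = orig_g[0] + x / scale[0]
        out_pos[ip, 1] = orig_g[1] + y / scale[1]
        out_pos[ip, 2] = orig_g[2] + z / scale[2]
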