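"""Numba kernels: exact Siddon voxel traversal and XFET exit-path sampling."""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def siddon_ray(x0, y0, x1, y1, gx, gy, px, py, nx, ny,
               idx_i, idx_j, seg_len):
    """Exact voxel intersection lengths of one 2D ray (Siddon traversal).

    Endpoints must lie outside the grid.  Fills ``idx_i``/``idx_j``/``seg_len``
    and returns the number of crossed voxels.
    """
    dx = x1 - x0
    dy = y1 - y0
    length = np.sqrt(dx * dx + dy * dy)
    if length < _EPS:
        return -1

    a_min = 0.0
    a_max = 1.0
    # slab clipping per axis
    for (p0, d, g, n, pitch) in ((x0, dx, gx, nx, px), (y0, dy, gy, ny, py)):
        lo = g
        hi = g + n * pitch
        if abs(d) < _EPS:
            if p0 <= lo or p0 >= hi:
                return 0
        else:
            a1 = (lo - p0) / d
            a2 = (hi - p0) / d
            if a1 > a2:
                a1, a2 = a2, a1
            if a1 > a_min:
                a_min = a1
            if a2 < a_max:
                a_max = a2
    if a_min >= a_max:
        return 0

    a = a_min
    # entry voxel from a point slightly inside
    mid = a_min + 1e-10
    i = int((x0 + mid * dx - gx) / px)
    j = int((y0 + mid * dy - gy) / py)
    if i < 0:
        i = 0
    if i > nx - 1:
        i = nx - 1
    if j < 0:
        j = 0
    if j > ny - 1:
        j = ny - 1

    step_i = 1 if dx > 0 else -1
    step_j = 1 if dy > 0 else -1
    if abs(dx) > _EPS:
        nxt = gx + (i + (1 if dx > 0 else 0)) * px
        ax = (nxt - x0) / dx
        dax = px / abs(dx)
    else:
        ax = 1e30
        dax = 1e30
    if abs(dy) > _EPS:
        nxt = gy + (j + (1 if dy > 0 else 0)) * py
        ay = (nxt - y0) / dy
        day = py / abs(dy)
    else:
        ay = 1e30
        day = 1e30

    count = 0
    while a < a_max - 1e-12:
        if ax < ay:
            a_next = ax if ax < a_max else a_max
        else:
            a_next = ay if ay < a_max else a_max
        seg = (a_next - a) * length
        if seg > 0:
            idx_i[count] = i
            idx_j[count] = j
            seg_len[count] = seg
            count += 1
        if ax < ay:
            i += step_i
            ax += dax
        else:
            j += step_j
            ay += day
        a = a_next
        if i < 0 or i >= nx or j < 0 or j >= ny:
            break
    return count


@njit(cache=True)
def project_bases(maps, gx, gy, px, py, srcs, dsts, out):
    """Line integrals of several 2D basis maps along many rays.

    ``maps``: (n_basis, nx, ny); ``srcs``/``dsts``: (n_rays, 2);
    ``out``: (n_rays, n_basis) filled with sum(map * length).
    """
    n_basis, nx, ny = maps.shape
    max_vox = nx + ny + 3
    idx_i = np.empty(max_vox, dtype=np.int64)
    idx_j = np.empty(max_vox, dtype=np.int64)
    seg = np.empty(max_vox, dtype=np.float64)
    for r in range(srcs.shape[0]):
        n = siddon_ray(srcs[r, 0], srcs[r, 1], dsts[r, 0], dsts[r, 1],
                       gx, gy, px, py, nx, ny, idx_i, idx_j, seg)
        for b in range(n_basis):
            acc = 0.0
            for v in range(n):
                acc += maps[b, idx_i[v], idx_j[v]] * seg[v]
            out[r, b] = acc


@njit(cache=True)
def exit_integrals(dens, gx, gy, px, py, pos_x, pos_y, dir_x, dir_y,
                   step, out):
    """Transverse exit-path density integrals from beam positions.

    ``dens``: (n_basis, nx, ny, nz) partial densities; ``out``:
    (n_pos, n_dir, n_basis, nz) integrals in g/cm^3 * mm, sampled midpoint at
    ``step`` mm.  The sample path in (x, y) is shared by all z slices.
    """
    n_basis, nx, ny, nz = dens.shape
    n_dir = dir_x.shape[0]
    max_s = int(2.2 * max(nx * px, ny * py) / step) + 2
    six = np.empty(max_s, dtype=np.int64)
    siy = np.empty(max_s, dtype=np.int64)
    for p in range(pos_x.shape[0]):
        for k in range(n_dir):
            ns = 0
            t = 0.5 * step
            while ns < max_s:
                x = pos_x[p] + t * dir_x[k]
                y = pos_y[p] + t * dir_y[k]
                i = int((x - gx) / px)
                j = int((y - gy) / py)
                if x < gx or y < gy or i >= nx or j >= ny:
                    break
                six[ns] = i
                siy[ns] = j
                ns += 1
                t += step
            for b in range(n_basis):
                for z in range(nz):
                    out[p, k, b, z] = 0.0
                for s in range(ns):
                    row = dens[b, six[s], siy[s]]
                    for z in range(nz):
                        out[p, k, b, z] += row[z]
                for z in range(nz):
                    out[p, k, b, z] *= step
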