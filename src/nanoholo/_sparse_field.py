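"""Numba core of the sparse-field level-set evolution.

The level-set function ``phi`` (negative inside) is maintained only on a
thin layered band around the zero crossing: active voxels (interface-
adjacent, |phi| <= 1) plus two rings at ~1.5 and ~2.5, everything else
frozen at +-3.5.  Each iteration updates the active list with a normalized
two-phase region force plus a zeta-weighted mean-curvature term, flips
voxels whose phi crosses zero, and locally rebuilds the band around the
flipped voxels — so work per iteration scales with the interface size, not
the volume.

All arrays are flat; ``(sz, sy, sx)`` are the strides of the padded
``(nz, ny, nx)`` grid.  A one-voxel pad ring (``valid == 0``) provides the
outside boundary condition and makes neighbor access branch-free.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-8
_DT = 0.45
_KMAX = 2.0  # curvature clamp; a 1-voxel-radius appendage reaches ~2


@njit(cache=True, inline="always")
def _is_interface(inside, i, sz, sy, sx, use_z):
    side = inside[i]
    if inside[i + sx] != side or inside[i - sx] != side:
        return True
    if inside[i + sy] != side or inside[i - sy] != side:
        return True
    if use_z and (inside[i + sz] != side or inside[i - sz] != side):
        return True
    return False


@njit(cache=True, inline="always")
def _curvature(phi, i, sz, sy, sx, use_z):
    gx = (phi[i + sx] - phi[i - sx]) * 0.5
    gy = (phi[i + sy] - phi[i - sy]) * 0.5
    pc = phi[i]
    pxx = phi[i + sx] - 2.0 * pc + phi[i - sx]
    pyy = phi[i + sy] - 2.0 * pc + phi[i - sy]
    pxy = (phi[i + sy + sx] - phi[i + sy - sx]
           - phi[i - sy + sx] + phi[i - sy - sx]) * 0.25
    if use_z:
        gz = (phi[i + sz] - phi[i - sz]) * 0.5
        pzz = phi[i + sz] - 2.0 * pc + phi[i - sz]
        pxz = (phi[i + sz + sx] - phi[i + sz - sx]
               - phi[i - sz + sx] + phi[i - sz - sx]) * 0.25
        pyz = (phi[i + sz + sy] - phi[i + sz - sy]
               - phi[i - sz + sy] + phi[i - sz - sy]) * 0.25
        g2 = gx * gx + gy * gy + gz * gz
        num = (pxx * (gy * gy + gz * gz) + pyy * (gx * gx + gz * gz)
               + pzz * (gx * gx + gy * gy)
               - 2.0 * (gx * gy * pxy + gx * gz * pxz + gy * gz * pyz))
    else:
        g2 = gx * gx + gy * gy
        num = pxx * gy * gy - 2.0 * gx * gy * pxy + pyy * gx * gx
    return num / (g2 * np.sqrt(g2) + _EPS)


@njit(cache=True)
def _build_band(phi, inside, valid, sz, sy, sx, use_z, active, in_list):
    """Initial layered phi and active list; returns the active count."""
    n = phi.size
    count = 0
    for i in range(n):
        if valid[i] == 0:
            phi[i] = 3.5
            continue
        if _is_interface(inside, i, sz, sy, sx, use_z):
            phi[i] = -0.5 if inside[i] else 0.5
            active[count] = i
            in_list[i] = 1
            count += 1
        else:
            phi[i] = -3.5 if inside[i] else 3.5
    # two rings outside the active layer
    for ring in (1.5, 2.5):
        prev = ring - 1.0
        for i in range(n):
            if valid[i] == 0 or abs(phi[i]) < 3.0:
                continue
            near = (abs(phi[i + sx]) <= prev or abs(phi[i - sx]) <= prev
                    or abs(phi[i + sy]) <= prev or abs(phi[i - sy]) <= prev)
            if not near and use_z:
                near = abs(phi[i + sz]) <= prev or abs(phi[i - sz]) <= prev
            if near:
                phi[i] = -ring if inside[i] else ring
    return count


@njit(cache=True)
def _evolve(img, inside, valid, phi, sz, sy, sx, use_z, n_iter, zeta, touched,
            fixed_means, c_in_fixed, c_out_fixed):
    """Run ``n_iter`` sparse-field iterations in place; returns final count."""
    n = img.size
    active = np.empty(n, np.int64)
    spare = np.empty(n, np.int64)
    in_list = np.zeros(n, np.uint8)
    force = np.empty(n, np.float32)
    flipped = np.empty(n, np.int64)
    count = _build_band(phi, inside, valid, sz, sy, sx, use_z, active, in_list)

    sum_all = 0.0
    cnt_valid = 0
    sum_in = 0.0
    cnt_in = 0
    for i in range(n):
        if valid[i]:
            sum_all += img[i]
            cnt_valid += 1
            if inside[i]:
                sum_in += img[i]
                cnt_in += 1

    for _ in range(n_iter):
        if count == 0:
            break
        if fixed_means:
            c_in = c_in_fixed
            c_out = c_out_fixed
        else:
            c_in = sum_in / cnt_in if cnt_in > 0 else 0.0
            cnt_out = cnt_valid - cnt_in
            c_out = (sum_all - sum_in) / cnt_out if cnt_out > 0 else 0.0

        # region force, normalized by its max over the active set
        maxf = 0.0
        for k in range(count):
            i = active[k]
            v = img[i]
            f = (v - c_in) * (v - c_in) - (v - c_out) * (v - c_out)
            force[i] = f
            if abs(f) > maxf:
                maxf = abs(f)
        inv = 1.0 / maxf if maxf > 0 else 0.0

        # combined update, computed from the pre-update phi
        for k in range(count):
            i = active[k]
            kap = _curvature(phi, i, sz, sy, sx, use_z)
            if kap > _KMAX:
                kap = _KMAX
            elif kap < -_KMAX:
                kap = -_KMAX
            speed = (force[i] * inv + zeta * kap) / (1.0 + _KMAX * zeta)
            force[i] = _DT * speed  # reuse buffer for the increment
        nflip = 0
        for k in range(count):
            i = active[k]
            p = phi[i] + force[i]
            if p > 1.0:
                p = 1.0
            elif p < -1.0:
                p = -1.0
            phi[i] = p
            touched[i] = 1
            if inside[i] == 1 and p > 0.0:
                inside[i] = 0
                sum_in -= img[i]
                cnt_in -= 1
                flipped[nflip] = i
                nflip += 1
            elif inside[i] == 0 and p < 0.0:
                inside[i] = 1
                sum_in += img[i]
                cnt_in += 1
                flipped[nflip] = i
                nflip += 1

        # rebuild the active list: keep surviving actives ...
        newcount = 0
        for k in range(count):
            i = active[k]
            if _is_interface(inside, i, sz, sy, sx, use_z):
                spare[newcount] = i
                newcount += 1
            else:
                in_list[i] = 0
                phi[i] = -1.5 if inside[i] else 1.5
                touched[i] = 1
        # ... and activate interface neighbors of flipped voxels
        for j in range(nflip):
            base = flipped[j]
            for d in range(7):
                if d == 0:
                    u = base
                elif d == 1:
                    u = base + sx
                elif d == 2:
                    u = base - sx
                elif d == 3:
                    u = base + sy
                elif d == 4:
                    u = base - sy
                elif use_z and d == 5:
                    u = base + sz
                elif use_z and d == 6:
                    u = base - sz
                else:
                    continue
                if valid[u] == 0 or in_list[u] == 1:
                    continue
                if _is_interface(inside, u, sz, sy, sx, use_z):
                    in_list[u] = 1
                    phi[u] = -0.5 if inside[u] else 0.5
                    touched[u] = 1
                    spare[newcount] = u
                    newcount += 1
        count = newcount
        tmp = active
        active = spare
        spare = tmp
    return count


@njit(cache=True)
def _region_grow(img, labels, seeds, tolerance, sz, sy, sx):
    """Sequential flood fill with a running region mean, 6-connectivity.

    ``labels`` must be zero-initialized (flat, padded; pad marked -1).
    Seeds are flat indices; each grows its own label ``1 + seed_index``.
    """
    n = img.size
    queue = np.empty(n, np.int64)
    for s in range(seeds.size):
        start = seeds[s]
        lab = s + 1
        if labels[start] != 0:
            continue
        labels[start] = lab
        region_sum = float(img[start])
        region_cnt = 1
        queue[0] = start
        head = 0
        tail = 1
        while head < tail:
            i = queue[head]
            head += 1
            mean = region_sum / region_cnt
            for d in range(6):
                if d == 0:
                    u = i + sx
                elif d == 1:
                    u = i - sx
                elif d == 2:
                    u = i + sy
                elif d == 3:
                    u = i - sy
                elif d == 4:
                    u = i + sz
                else:
                    u = i - sz
                if labels[u] != 0:
                    continue
                if abs(img[u] - mean) <= tolerance:
                    labels[u] = lab
                    region_sum += img[u]
                    region_cnt += 1
                    queue[tail] = u
                    tail += 1
    return labels
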