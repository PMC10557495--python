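"""Multi-stencils fast marching on 3D grids.

Solves |grad T| * F = 1 with T(source) = 0 using upwind finite differences on
several rotated lattice stencils and taking the minimum trial value across
stencils.  Eight orthogonal frames are used: the coordinate axes, the three
face-diagonal frames, and four cube-diagonal frames, so every one of the 26
lattice directions lies in some stencil's span.  Anisotropic voxel spacing is
handled through per-direction physical step lengths.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# Orthogonal stencils: each row is a frame of three mutually orthogonal
# lattice directions.  The first four cover the axes and face diagonals; the
# last four give the cube diagonals their own frame — d = (1, s, t) with
# u = (1, -s, 0) and v = d x u = (st, t, -2s) — without which fronts running
# down a narrow diagonal tube are badly overestimated.
_STENCILS = np.array(
    [
        [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
        [[0, 1, 1], [0, 1, -1], [1, 0, 0]],
        [[1, 0, 1], [1, 0, -1], [0, 1, 0]],
        [[1, 1, 0], [1, -1, 0], [0, 0, 1]],
        [[1, 1, 1], [1, -1, 0], [1, 1, -2]],
        [[1, 1, -1], [1, -1, 0], [-1, -1, -2]],
        [[1, -1, 1], [1, 1, 0], [-1, 1, 2]],
        [[1, -1, -1], [1, 1, 0], [1, -1, 2]],
    ],
    dtype=np.int64,
)


def _neighbor_offsets() -> np.ndarray:
    offs = set()
    for s in _STENCILS:
        for e in s:
            offs.add(tuple(e))
            offs.add(tuple(-e))
    return np.array(sorted(offs), dtype=np.int64)


_OFFSETS = _neighbor_offsets()

FAR, NARROW, FROZEN = np.uint8(0), np.uint8(1), np.uint8(2)


@njit(cache=True)
def _heap_push(ht, hi, size, t, i):
    ht[size] = t
    hi[size] = i
    j = size
    while j > 0:
        p = (j - 1) // 2
        if ht[p] <= ht[j]:
            break
        ht[p], ht[j] = ht[j], ht[p]
        hi[p], hi[j] = hi[j], hi[p]
        j = p
    return size + 1


@njit(cache=True)
def _heap_pop(ht, hi, size):
    t, i = ht[0], hi[0]
    size -= 1
    ht[0], hi[0] = ht[size], hi[size]
    j = 0
    while True:
        l, r = 2 * j + 1, 2 * j + 2
        m = j
        if l < size and ht[l] < ht[m]:
            m = l
        if r < size and ht[r] < ht[m]:
            m = r
        if m == j:
            break
        ht[m], ht[j] = ht[j], ht[m]
        hi[m], hi[j] = hi[j], hi[m]
        j = m
    return t, i, size


@njit(cache=True)
def _trial(T, status, F, sp, stencils, z, y, x, second_order):
    nz, ny, nx = T.shape
    f = F[z, y, x]
    rhs = 1.0 / (f * f)
    best = np.inf
    alphas = np.empty(3)
    betas = np.empty(3)
    avals = np.empty(3)
    hvals = np.empty(3)
    for s in range(stencils.shape[0]):
        n = 0
        for k in range(3):
            e0, e1, e2 = stencils[s, k, 0], stencils[s, k, 1], stencils[s, k, 2]
            h = np.sqrt((e0 * sp[0]) ** 2 + (e1 * sp[1]) ** 2 + (e2 * sp[2]) ** 2)
            a1 = np.inf
            sgn = 0
            for sg in (-1, 1):
                zz, yy, xx = z + sg * e0, y + sg * e1, x + sg * e2
                if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                    if status[zz, yy, xx] == 2 and T[zz, yy, xx] < a1:
                        a1 = T[zz, yy, xx]
                        sgn = sg
            if a1 == np.inf:
                continue
            use2 = False
            t2 = 0.0
            if second_order:
                z2, y2, x2 = z + 2 * sgn * e0, y + 2 * sgn * e1, x + 2 * sgn * e2
                if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx:
                    if status[z2, y2, x2] == 2 and T[z2, y2, x2] <= a1:
                        use2 = True
                        t2 = T[z2, y2, x2]
            if use2:
                alphas[n] = 1.5 / h
                betas[n] = (4.0 * a1 - t2) / (2.0 * h)
            else:
                alphas[n] = 1.0 / h
                betas[n] = a1 / h
            avals[n] = a1
            hvals[n] = h
            n += 1
        if n == 0:
            continue
        # sort terms by upwind value (n <= 3: insertion sort)
        for i in range(1, n):
            j = i
            while j > 0 and avals[j - 1] > avals[j]:
                avals[j - 1], avals[j] = avals[j], avals[j - 1]
                alphas[j - 1], alphas[j] = alphas[j], alphas[j - 1]
                betas[j - 1], betas[j] = betas[j], betas[j - 1]
                hvals[j - 1], hvals[j] = hvals[j], hvals[j - 1]
                j -= 1
        t_s = np.inf
        m = n
        while m > 0:
            A = 0.0
            B = 0.0
            C = -rhs
            for i in range(m):
                A += alphas[i] * alphas[i]
                B -= 2.0 * alphas[i] * betas[i]
                C += betas[i] * betas[i]
            disc = B * B - 4.0 * A * C
            if disc >= 0.0:
                t = (-B + np.sqrt(disc)) / (2.0 * A)
                if t >= avals[m - 1]:
                    t_s = t
                    break
            m -= 1
        if t_s == np.inf:
            t_s = avals[0] + hvals[0] * np.sqrt(rhs)
        if t_s < best:
            best = t_s
    return best


@njit(cache=True)
def _march(F, sp, src_z, src_y, src_x, stencils, offsets, second_order):
    nz, ny, nx = F.shape
    T = np.full(F.shape, np.inf)
    status = np.zeros(F.shape, np.uint8)
    n_active = 0
    for i in range(F.size):
        if F.flat[i] > 0.0:
            n_active += 1
    cap = 16 * n_active + 1024
    ht = np.empty(cap)
    hi = np.empty(cap, np.int64)
    size = 0
    for i in range(src_z.shape[0]):
        idx = (src_z[i] * ny + src_y[i]) * nx + src_x[i]
        T[src_z[i], src_y[i], src_x[i]] = 0.0
        status[src_z[i], src_y[i], src_x[i]] = 1
        size = _heap_push(ht, hi, size, 0.0, idx)
    while size > 0:
        t, idx, size = _heap_pop(ht, hi, size)
        z = idx // (ny * nx)
        y = (idx // nx) % ny
        x = idx % nx
        if status[z, y, x] == 2:
            continue
        status[z, y, x] = 2
        for o in range(offsets.shape[0]):
            zz = z + offsets[o, 0]
            yy = y + offsets[o, 1]
            xx = x + offsets[o, 2]
            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                continue
            if status[zz, yy, xx] == 2 or F[zz, yy, xx] <= 0.0:
                continue
            tt = _trial(T, status, F, sp, stencils, zz, yy, xx, second_order)
            if tt < T[zz, yy, xx]:
                T[zz, yy, xx] = tt
                status[zz, yy, xx] = 1
                if size >= cap:
                    new_cap = cap * 2
                    ht2 = np.empty(new_cap)
                    hi2 = np.empty(new_cap, np.int64)
                    ht2[:size] = ht[:size]
                    hi2[:size] = hi[:size]
                    ht, hi, cap = ht2, hi2, new_cap
                size = _heap_push(ht, hi, size, tt, idx_of(zz, yy, xx, ny, nx))
    return T


@njit(cache=True)
def idx_of(z, y, x, ny, nx):
    return (z * ny + y) * nx + x


def march(
    speed: np.ndarray,
    spacing,
    sources: np.ndarray,
    second_order: bool = False,
) -> np.ndarray:
    """Arrival-time map from ``sources`` (N x 3 voxel indices) under ``speed``.

    Voxels with speed <= 0 are never reached (T = inf).  First-order updates
    are the default: the second-order extrapolation loses causality in the
    oblique stencil frames near strongly curved fronts and can undershoot.
    """
    speed = np.ascontiguousarray(speed, dtype=np.float64)
    sources = np.atleast_2d(np.asarray(sources, dtype=np.int64))
    for s in sources:
        if speed[s[0], s[1], s[2]] <= 0.0:
            raise ValueError(f"source {tuple(int(v) for v in s)} has non-positive speed")
    sp = np.asarray(spacing, dtype=np.float64)
    return _march(
        speed, sp,
        np.ascontiguousarray(sources[:, 0]),
        np.ascontiguousarray(sources[:, 1]),
        np.ascontiguousarray(sources[:, 2]),
        _STENCILS, _OFFSETS, second_order,
    )
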