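"""Compiled inner loops for 2D interacting-particle runs.

Everything here mirrors the public numpy implementations in ``engine`` and
``profiles`` exactly (same profile formulas, same update rule, same collision
contract); the test suite asserts the equivalence on small states.  Cell
lists make the Lennard-Jones sum and the hard-core collision pass O(N) per
step for short-ranged cutoffs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# profile kind codes (shared with profiles.py)
KIND_CONSTANT = 0
KIND_PATCH = 1
KIND_GAUSSIAN = 2


@njit(cache=True, inline="always")
def _wrap1(u, L):
    return (u + L) % (2.0 * L) - L


@njit(cache=True, inline="always")
def _mi(u, L):
    """Minimum-image correction for a difference of in-domain coordinates
    (|u| < 2L); branches instead of fmod for speed in the pair loops."""
    if u >= L:
        return u - 2.0 * L
    if u < -L:
        return u + 2.0 * L
    return u


@njit(cache=True, inline="always")
def _amp_grad(kind, params, x, y, L):
    """Amplitude and its per-axis partials at one point."""
    if kind == KIND_CONSTANT:
        return params[0], 0.0, 0.0
    elif kind == KIND_PATCH:
        D0, r, cx, cy, h, w = params[0], params[1], params[2], params[3], params[4], params[5]
        depth = D0 * (1.0 - 1.0 / r)
        dx = _wrap1(x - cx, L)
        dy = _wrap1(y - cy, L)
        # compact C2 smoothstep band straddling the nominal edge
        zx = (h + 0.5 * w - abs(dx)) / w
        if zx <= 0.0:
            fx, dsx = 0.0, 0.0
        elif zx >= 1.0:
            fx, dsx = 1.0, 0.0
        else:
            fx = zx * zx * zx * (10.0 + zx * (-15.0 + 6.0 * zx))
            dsx = 30.0 * zx * zx * (1.0 - zx) * (1.0 - zx)
        dfx = -(1.0 if dx > 0 else (-1.0 if dx < 0 else 0.0)) * dsx / w
        zy = (h + 0.5 * w - abs(dy)) / w
        if zy <= 0.0:
            fy, dsy = 0.0, 0.0
        elif zy >= 1.0:
            fy, dsy = 1.0, 0.0
        else:
            fy = zy * zy * zy * (10.0 + zy * (-15.0 + 6.0 * zy))
            dsy = 30.0 * zy * zy * (1.0 - zy) * (1.0 - zy)
        dfy = -(1.0 if dy > 0 else (-1.0 if dy < 0 else 0.0)) * dsy / w
        a = D0 - depth * fx * fy
        return a, -depth * dfx * fy, -depth * fx * dfy
    else:
        D0, d, omega = params[0], params[1], params[2]
        m = int(params[3])
        K = int(params[4])
        acc = 0.0
        gx = 0.0
        gy = 0.0
        for i in range(K):
            cx = params[5 + 2 * i]
            cy = params[6 + 2 * i]
            dx = _wrap1(x - cx, L)
            dy = _wrap1(y - cy, L)
            sx = 0.0
            dsx = 0.0
            sy = 0.0
            dsy = 0.0
            for k in range(-m, m + 1):
                vx = dx + 2.0 * L * k
                e = np.exp(-vx * vx / omega)
                sx += e
                dsx += (-2.0 * vx / omega) * e
                vy = dy + 2.0 * L * k
                e = np.exp(-vy * vy / omega)
                sy += e
                dsy += (-2.0 * vy / omega) * e
            acc += 1.0 - d * sx * sy
            gx += -d * dsx * sy
            gy += -d * sx * dsy
        return D0 * acc / K, D0 * gx / K, D0 * gy / K


@njit(cache=True)
def _build_cells(pos, L, min_cell):
    """Linked-list cell decomposition; actual cell size >= min_cell."""
    n = pos.shape[0]
    ncx = int((2.0 * L) / min_cell)
    if ncx < 1:
        ncx = 1
    cs = 2.0 * L / ncx
    head = -np.ones(ncx * ncx, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    for i in range(n):
        cxi = int((pos[i, 0] + L) / cs)
        cyi = int((pos[i, 1] + L) / cs)
        if cxi >= ncx:
            cxi = ncx - 1
        if cyi >= ncx:
            cyi = ncx - 1
        c = cxi * ncx + cyi
        nxt[i] = head[c]
        head[c] = i
    return head, nxt, ncx, cs


@njit(cache=True)
def _lj_drift(pos, L, dt, eps, sigma, cutoff, mobility_weighted,
              kind, params, drift_cap):
    """Deterministic displacement dt * D(X_j) * sum_i f(r_ij) u_ij.

    Forces below r = 0.5 sigma are clamped to their value at 0.5 sigma; the
    per-particle displacement norm is capped at drift_cap to keep the
    explicit step stable against the stiff repulsive branch.
    """
    n = pos.shape[0]
    disp = np.zeros((n, 2))
    head, nxt, ncx, cs = _build_cells(pos, L, cutoff)
    rmin = 0.5 * sigma
    for j in range(n):
        xj = pos[j, 0]
        yj = pos[j, 1]
        fx = 0.0
        fy = 0.0
        if ncx < 3:
            # grid too coarse for a 3x3 stencil: plain all-pairs sum
            for i in range(n):
                if i != j:
                    ux = _mi(xj - pos[i, 0], L)
                    uy = _mi(yj - pos[i, 1], L)
                    r2 = ux * ux + uy * uy
                    if r2 < cutoff * cutoff and r2 > 0.0:
                        r = np.sqrt(r2)
                        reff = r if r > rmin else rmin
                        s6 = (sigma / reff) ** 6
                        f = (12.0 * eps / reff) * (s6 * s6 - s6)
                        fx += f * ux / r
                        fy += f * uy / r
            cxj = 0
            cyj = 0
        else:
            cxj = int((xj + L) / cs)
            cyj = int((yj + L) / cs)
            if cxj >= ncx:
                cxj = ncx - 1
            if cyj >= ncx:
                cyj = ncx - 1
        for ox in range(-1, 2):
            if ncx < 3:
                break
            for oy in range(-1, 2):
                c = ((cxj + ox) % ncx) * ncx + (cyj + oy) % ncx
                i = head[c]
                while i >= 0:
                    if i != j:
                        ux = _mi(xj - pos[i, 0], L)
                        uy = _mi(yj - pos[i, 1], L)
                        r2 = ux * ux + uy * uy
                        if r2 < cutoff * cutoff and r2 > 0.0:
                            r = np.sqrt(r2)
                            reff = r if r > rmin else rmin
                            s6 = (sigma / reff) ** 6
                            f = (12.0 * eps / reff) * (s6 * s6 - s6)
                            fx += f * ux / r
                            fy += f * uy / r
                    i = nxt[i]
        if mobility_weighted:
            a, _, _ = _amp_grad(kind, params, xj, yj, L)
            mob = a * a
        else:
            mob = 1.0
        dx = dt * mob * fx
        dy = dt * mob * fy
        norm = np.sqrt(dx * dx + dy * dy)
        if norm > drift_cap:
            scale = drift_cap / norm
            dx *= scale
            dy *= scale
        disp[j, 0] = dx
        disp[j, 1] = dy
    return disp


@njit(cache=True)
def _step(pos, Z, perm, dt, L, kind, params, stratonovich,
          eps, sigma, cutoff, mobility_weighted,
          core, collisions_on, drift_cap):
    """One integrator step, in place.

    Z: (N, 2) standard-normal draws; perm: processing order for the
    collision pass (ignored when collisions are off).
    """
    n = pos.shape[0]
    sq = np.sqrt(dt)
    if eps > 0.0:
        disp = _lj_drift(pos, L, dt, eps, sigma, cutoff, mobility_weighted,
                         kind, params, drift_cap)
    else:
        disp = np.zeros((n, 2))
    proposed = np.empty((n, 2))
    for i in range(n):
        a, gx, gy = _amp_grad(kind, params, pos[i, 0], pos[i, 1], L)
        dx = disp[i, 0] + sq * a * Z[i, 0]
        dy = disp[i, 1] + sq * a * Z[i, 1]
        if stratonovich:
            dx += 0.5 * dt * a * gx * Z[i, 0] * Z[i, 0]
            dy += 0.5 * dt * a * gy * Z[i, 1] * Z[i, 1]
        proposed[i, 0] = _wrap1(pos[i, 0] + dx, L)
        proposed[i, 1] = _wrap1(pos[i, 1] + dy, L)
    if not collisions_on:
        for i in range(n):
            pos[i, 0] = proposed[i, 0]
            pos[i, 1] = proposed[i, 1]
        return
    # hard-core pass: process in random order, reject any move that would
    # land within `core` of another particle's current position
    dmax = 0.0
    for i in range(n):
        ux = _mi(proposed[i, 0] - pos[i, 0], L)
        uy = _mi(proposed[i, 1] - pos[i, 1], L)
        dcur = np.sqrt(ux * ux + uy * uy)
        if dcur > dmax:
            dmax = dcur
    R = core + 2.0 * dmax + 1e-12
    head, nxt, ncx, cs = _build_cells(pos, L, R)
    for k in range(n):
        j = perm[k]
        px = proposed[j, 0]
        py = proposed[j, 1]
        ok = True
        if ncx < 3:
            for i in range(n):
                if i != j:
                    ux = _mi(px - pos[i, 0], L)
                    uy = _mi(py - pos[i, 1], L)
                    if ux * ux + uy * uy < core * core:
                        ok = False
                        break
        else:
            cxj = int((px + L) / cs)
            cyj = int((py + L) / cs)
            if cxj >= ncx:
                cxj = ncx - 1
            if cyj >= ncx:
                cyj = ncx - 1
            for ox in range(-1, 2):
                for oy in range(-1, 2):
                    c = ((cxj + ox) % ncx) * ncx + (cyj + oy) % ncx
                    i = head[c]
                    while i >= 0:
                        if i != j:
                            ux = _mi(px - pos[i, 0], L)
                            uy = _mi(py - pos[i, 1], L)
                            if ux * ux + uy * uy < core * core:
                                ok = False
                                break
                        i = nxt[i]
                    if not ok:
                        break
                if not ok:
                    break
        if ok:
            pos[j, 0] = px
            pos[j, 1] = py


@njit(cache=True)
def run_interacting(pos0, n_steps, sample_every, dt, L, kind, params,
                    stratonovich, eps, sigma, cutoff, mobility_weighted,
                    core, collisions_on, drift_cap, seed):
    """Integrate ``n_steps`` steps from ``pos0``; returns samples of shape
    (n_steps // sample_every, N, 2) taken every ``sample_every`` steps.

    One seeded legacy RNG; draw order fixed (per step: the (N, 2) normal
    block, then the collision permutation) for reproducibility.
    """
    np.random.seed(seed)
    n = pos0.shape[0]
    pos = pos0.copy()
    n_samples = n_steps // sample_every
    samples = np.empty((n_samples, n, 2))
    si = 0
    for k in range(n_steps):
        Z = np.random.standard_normal((n, 2))
        if collisions_on:
            perm = np.random.permutation(n)
        else:
            perm = np.empty(0, dtype=np.int64)
        _step(pos, Z, perm, dt, L, kind, params, stratonovich,
              eps, sigma, cutoff, mobility_weighted,
              core, collisions_on, drift_cap)
        if (k + 1) % sample_every == 0:
            samples[si] = pos
            si += 1
    return samples
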