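"""Vectorized fixed-step integrator for the reconstitution model.

The population machinery (importance sampling, simulation, forecasting,
visual predictive checks) needs thousands of trajectory solves that differ
only in their parameter vectors.  Solving them one at a time with an
adaptive solver is prohibitively slow in Python, so this module integrates
the whole batch simultaneously with a classical 4th-order Runge-Kutta
scheme on a shared non-uniform grid (finer early, never coarser than 4
days).  Requested output times are read off by linear interpolation between
grid nodes (error far below the solver tolerance at these step sizes), and
with the per-capita rate cap from :mod:`cd4recon.kinetics` the scheme is
stable even for extreme random-effect draws.  Agreement with the production
adaptive solver is well under 0.1% for realistic parameters (asserted in
the test suite).

Components are organised in "blocks": a block is a set of consecutive
columns sharing an age at transplant and a set of evaluation times
(typically: one subject, many random-effect draws).  Reference curves
depend on age only, so they are evaluated per block and gathered, which is
where most of the speed comes from.
"""

from __future__ import annotations

import math

import numpy as np

from .reference import AgeReferenceConstants, DEFAULT_CONSTANTS, thymic_output_multiplier

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is an optional speed-up
    njit = None

__all__ = ["solve_blocks", "PARAM_ORDER"]

#: Below this batch width the compiled scalar kernel beats the vectorized
#: numpy path (whose cost is dominated by per-step call overhead).
_NUMBA_MAX_BATCH = 600

PARAM_ORDER = ("lambda0", "d0", "p0", "x0", "lambda_h", "lambda_r", "cp", "cd")

# Per-capita proliferation/loss cap (per day) inside the batched integrator;
# far beyond any biologically plausible rate, it only bites for extreme
# importance-sampling draws and keeps h * rate inside the RK4 stability
# region for the largest step below.
_RATE_CAP = 0.5

_EXP_CLIP = 50.0

# Piecewise maximum step sizes (days): fine while thymic output switches on,
# coarser once the trajectory is smooth.
_SEGMENTS = ((40.0, 0.5), (200.0, 1.0), (730.0, 2.0), (np.inf, 4.0))


def _build_grid(horizon: float) -> np.ndarray:
    pieces = [np.array([horizon])]
    lo = 0.0
    for hi, step in _SEGMENTS:
        hi = min(hi, horizon)
        if hi > lo:
            pieces.append(np.arange(lo, hi, step))
        lo = hi
        if lo >= horizon:
            break
    return np.unique(np.concatenate(pieces))


def solve_blocks(params: dict, age0_blocks, times_blocks, counts,
                 consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Integrate many trajectories at once, grouped in blocks.

    params       -- mapping with arrays of shape (B,) for every name in
                    :data:`PARAM_ORDER`; B = sum(counts)
    age0_blocks  -- age at transplant (days) per block
    times_blocks -- evaluation times (days, >= 0) per block
    counts       -- number of consecutive columns per block

    Returns a list with one (len(times), count) array of concentrations per
    block.
    """
    counts = [int(k) for k in counts]
    B = int(sum(counts))
    NB = len(counts)
    starts = np.concatenate([[0], np.cumsum(counts)])
    # clip parameters to generous physical bounds: extreme heavy-tailed
    # proposal draws (t3 with tiny chi-square denominators) can otherwise
    # overflow exp(); any draw this far out carries zero posterior weight
    lam0 = np.clip(np.ascontiguousarray(params["lambda0"], float), 0.0, 1e8)
    d0 = np.clip(np.ascontiguousarray(params["d0"], float), 0.0, 1e8)
    p0 = np.clip(np.ascontiguousarray(params["p0"], float), 0.0, 1e8)
    x0 = np.clip(np.ascontiguousarray(params["x0"], float), 1e-9, 1e9)
    lh = np.clip(np.ascontiguousarray(params["lambda_h"], float), 1e-3, 1e7)
    lr = np.clip(np.ascontiguousarray(params["lambda_r"], float), 1e-6, 1e5)
    cp = np.ascontiguousarray(params["cp"], float)
    cd = np.ascontiguousarray(params["cd"], float)
    if lam0.shape != (B,):
        raise ValueError("parameter arrays must have shape (sum(counts),)")

    age0 = np.asarray(age0_blocks, float)
    bid = np.repeat(np.arange(NB), counts)

    times_blocks = [np.asarray(t, float) for t in times_blocks]
    horizon = max((float(t[-1]) for t in times_blocks if len(t)), default=1.0)
    grid = _build_grid(max(horizon, 1.0))

    # recording plan: out[b][row] = (1-frac) * x[node j-1] + frac * x[node j]
    plan: dict[int, list] = {}
    for b, t in enumerate(times_blocks):
        j = np.searchsorted(grid, t, side="left")
        j = np.clip(j, 0, len(grid) - 1)
        for row, (tj, jj) in enumerate(zip(t, j)):
            if jj == 0:
                plan.setdefault(0, []).append((b, row, 1.0))
            else:
                frac = (tj - grid[jj - 1]) / (grid[jj] - grid[jj - 1])
                plan.setdefault(int(jj), []).append((b, row, float(frac)))

    out = [np.empty((len(t), counts[b])) for b, t in enumerate(times_blocks)]

    c = DEFAULT_CONSTANTS if consts is None else consts
    mult = thymic_output_multiplier(c)

    if njit is not None and B <= _NUMBA_MAX_BATCH:
        # flatten the recording plan into CSR form for the compiled kernel
        n_entries = sum(len(v) for v in plan.values())
        rec_ptr = np.zeros(len(grid) + 1, np.int64)
        rec_col = np.empty(n_entries, np.int64)
        rec_cnt = np.empty(n_entries, np.int64)
        rec_frac = np.empty(n_entries, float)
        rec_off = np.empty(n_entries, np.int64)
        out_offsets = np.concatenate(
            [[0], np.cumsum([len(t) * counts[b]
                             for b, t in enumerate(times_blocks)])])
        e = 0
        for j in range(len(grid)):
            rec_ptr[j] = e
            for b, row, frac in plan.get(j, ()):
                rec_col[e] = starts[b]
                rec_cnt[e] = counts[b]
                rec_frac[e] = frac
                rec_off[e] = out_offsets[b] + row * counts[b]
                e += 1
        rec_ptr[len(grid)] = e
        out_flat = np.empty(int(out_offsets[-1]))
        _kernel(grid, np.repeat(np.arange(NB), counts).astype(np.int64),
                age0, lam0, d0, p0, x0.copy(), lh, lr, cp, cd,
                mult, c.ki67_at_birth, c.ki67_decay_rate,
                c.n_total_asymptote, c.n_total_amplitude, c.n_total_rate,
                c.n_naive_asymptote, c.n_naive_amplitude, c.n_naive_rate,
                _RATE_CAP, rec_ptr, rec_col, rec_cnt, rec_frac, rec_off,
                out_flat)
        for b, t in enumerate(times_blocks):
            out[b][...] = out_flat[out_offsets[b]:out_offsets[b + 1]].reshape(
                len(t), counts[b])
        return out

    def block_refs(t):
        """Reference curves per block at elapsed time t."""
        tau = age0 + t
        y = c.ki67_at_birth * np.exp(-c.ki67_decay_rate * tau)
        n = c.n_total_asymptote + c.n_total_amplitude * np.exp(-c.n_total_rate * tau)
        nn = c.n_naive_asymptote + c.n_naive_amplitude * np.exp(-c.n_naive_rate * tau)
        return y, n, mult * y * nn

    def sigmoid(t):
        num = -np.expm1(-2.0 * t / lh)
        den = 1.0 + np.exp(np.clip(lr * (1.0 - t / lh), -700.0, 700.0))
        return num / den

    def rhs(x, y, n, lam_age, sig):
        ratio = x / n
        p = np.minimum(p0 * y * np.exp(np.clip(cp * (1.0 - ratio), -_EXP_CLIP, _EXP_CLIP)), _RATE_CAP)
        d = np.minimum(d0 * y * np.exp(np.clip(cd * (ratio - 1.0), -_EXP_CLIP, _EXP_CLIP)), _RATE_CAP)
        return lam0 * lam_age * sig + (p - d) * x

    def record(j, x_prev, x_new):
        for b, row, frac in plan.get(j, ()):
            sl = slice(starts[b], starts[b + 1])
            out[b][row] = x_prev[sl] * (1.0 - frac) + x_new[sl] * frac

    x = x0.copy()
    record(0, x, x)
    for j in range(1, len(grid)):
        t0, t1 = grid[j - 1], grid[j]
        h = t1 - t0
        tm = t0 + 0.5 * h
        y0, n0, la0 = block_refs(t0)
        ym, nm, lam = block_refs(tm)
        y1, n1, la1 = block_refs(t1)
        y0, n0, la0 = y0[bid], n0[bid], la0[bid]
        ym, nm, lam = ym[bid], nm[bid], lam[bid]
        y1, n1, la1 = y1[bid], n1[bid], la1[bid]
        s0, sm, s1 = sigmoid(t0), sigmoid(tm), sigmoid(t1)
        k1 = rhs(x, y0, n0, la0, s0)
        k2 = rhs(x + 0.5 * h * k1, ym, nm, lam, sm)
        k3 = rhs(x + 0.5 * h * k2, ym, nm, lam, sm)
        k4 = rhs(x + h * k3, y1, n1, la1, s1)
        x_new = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.clip(x_new, 1e-9, 1e12, out=x_new)
        record(j, x, x_new)
        x = x_new
    return out


def _make_kernel():
    if njit is None:
        return None

    @njit(cache=True, fastmath=True)
    def kernel(grid, bid, age0, lam0, d0, p0, x, lh, lr, cp, cd,
               mult, kb, kr, na, namp, nrate, nna, nnamp, nnrate, cap,
               rec_ptr, rec_col, rec_cnt, rec_frac, rec_off, out_flat):
        B = x.size
        NB = age0.size
        G = grid.size
        y0 = np.empty(NB); n0 = np.empty(NB); la0 = np.empty(NB)
        ym = np.empty(NB); nm = np.empty(NB); lam = np.empty(NB)
        y1 = np.empty(NB); n1 = np.empty(NB); la1 = np.empty(NB)
        for b in range(NB):
            tau = age0[b]
            y1[b] = kb * math.exp(-kr * tau)
            n1[b] = na + namp * math.exp(-nrate * tau)
            la1[b] = mult * y1[b] * (nna + nnamp * math.exp(-nnrate * tau))
        x_new = np.empty(B)
        # recording at t = 0
        for e in range(rec_ptr[0], rec_ptr[1]):
            for i in range(rec_cnt[e]):
                out_flat[rec_off[e] + i] = x[rec_col[e] + i]
        for j in range(1, G):
            t0 = grid[j - 1]
            t1 = grid[j]
            h = t1 - t0
            tm = t0 + 0.5 * h
            for b in range(NB):
                y0[b] = y1[b]; n0[b] = n1[b]; la0[b] = la1[b]
                tau = age0[b] + tm
                ym[b] = kb * math.exp(-kr * tau)
                nm[b] = na + namp * math.exp(-nrate * tau)
                lam[b] = mult * ym[b] * (nna + nnamp * math.exp(-nnrate * tau))
                tau = age0[b] + t1
                y1[b] = kb * math.exp(-kr * tau)
                n1[b] = na + namp * math.exp(-nrate * tau)
                la1[b] = mult * y1[b] * (nna + nnamp * math.exp(-nnrate * tau))
            for i in range(B):
                b = bid[i]
                # thymic-recovery sigmoid at the three stage times
                a0 = lr[i] * (1.0 - t0 / lh[i])
                if a0 > 700.0:
                    a0 = 700.0
                elif a0 < -700.0:
                    a0 = -700.0
                s0 = -math.expm1(-2.0 * t0 / lh[i]) / (1.0 + math.exp(a0))
                am = lr[i] * (1.0 - tm / lh[i])
                if am > 700.0:
                    am = 700.0
                elif am < -700.0:
                    am = -700.0
                sm = -math.expm1(-2.0 * tm / lh[i]) / (1.0 + math.exp(am))
                a1 = lr[i] * (1.0 - t1 / lh[i])
                if a1 > 700.0:
                    a1 = 700.0
                elif a1 < -700.0:
                    a1 = -700.0
                s1 = -math.expm1(-2.0 * t1 / lh[i]) / (1.0 + math.exp(a1))

                xi = x[i]
                k1 = _rate(xi, y0[b], n0[b], la0[b], s0,
                           lam0[i], d0[i], p0[i], cp[i], cd[i], cap)
                k2 = _rate(xi + 0.5 * h * k1, ym[b], nm[b], lam[b], sm,
                           lam0[i], d0[i], p0[i], cp[i], cd[i], cap)
                k3 = _rate(xi + 0.5 * h * k2, ym[b], nm[b], lam[b], sm,
                           lam0[i], d0[i], p0[i], cp[i], cd[i], cap)
                k4 = _rate(xi + h * k3, y1[b], n1[b], la1[b], s1,
                           lam0[i], d0[i], p0[i], cp[i], cd[i], cap)
                xn = xi + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                if xn < 1e-9:
                    xn = 1e-9
                elif xn > 1e12:
                    xn = 1e12
                x_new[i] = xn
            if rec_ptr[j + 1] > rec_ptr[j]:
                for e in range(rec_ptr[j], rec_ptr[j + 1]):
                    f = rec_frac[e]
                    for i in range(rec_cnt[e]):
                        col = rec_col[e] + i
                        out_flat[rec_off[e] + i] = (
                            x[col] * (1.0 - f) + x_new[col] * f)
            for i in range(B):
                x[i] = x_new[i]
        return out_flat

    return kernel


if njit is not None:
    @njit(cache=True, fastmath=True, inline="always")
    def _rate(xi, y, n, la, sig, lam0, d0, p0, cp, cd, cap):
        ratio = xi / n
        ep = cp * (1.0 - ratio)
        if ep > _EXP_CLIP:
            ep = _EXP_CLIP
        elif ep < -_EXP_CLIP:
            ep = -_EXP_CLIP
        ed = cd * (ratio - 1.0)
        if ed > _EXP_CLIP:
            ed = _EXP_CLIP
        elif ed < -_EXP_CLIP:
            ed = -_EXP_CLIP
        p = p0 * y * math.exp(ep)
        if p > cap:
            p = cap
        d = d0 * y * math.exp(ed)
        if d > cap:
            d = cap
        return lam0 * la * sig + (p - d) * xi


_kernel = _make_kernel()
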