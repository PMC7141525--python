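"""Compiled integration kernels for ensemble simulation.

All kernels operate on packed parameter arrays (node order / edge order of
the owning network) so that one compiled function serves every topology.
Cooperativities are small integers, so powers are computed by repeated
multiplication rather than ``pow``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "integrate_ensemble",
    "em_trajectory",
]


@njit(cache=True, inline="always")
def _ipow(x: float, n: int) -> float:
    r = 1.0
    for _ in range(n):
        r *= x
    return r


@njit(cache=True, inline="always")
def _rhs(x, g, k, lam, nn, b0n, src, tgt, out):
    for i in range(g.shape[0]):
        out[i] = 1.0
    for e in range(src.shape[0]):
        xn = _ipow(x[src[e]], nn[e])
        hm = b0n[e] / (b0n[e] + xn)
        out[tgt[e]] *= hm + lam[e] * (1.0 - hm)
    for i in range(g.shape[0]):
        out[i] = g[i] * out[i] - k[i] * x[i]


@njit(cache=True)
def _merge_endpoint(l2, states, basins, count, max_keep, merge_rtol, merge_floor):
    """Merge a converged endpoint (log2 levels) into the running state list.

    Two states are identical when every node agrees within a relative
    tolerance in log2 space (absolute floor near log2 = 0).  Matches update
    the stored state to the basin-weighted centroid.  Returns the updated
    distinct-state count; at most ``max_keep`` states are stored but the
    count keeps increasing beyond it.
    """
    N = l2.shape[0]
    stored = min(count, max_keep)
    for s in range(stored):
        same = True
        for i in range(N):
            a = states[s, i]
            b = l2[i]
            tol = merge_rtol * max(abs(a), abs(b))
            if tol < merge_floor:
                tol = merge_floor
            if abs(a - b) > tol:
                same = False
                break
        if same:
            w = basins[s]
            for i in range(N):
                states[s, i] = (states[s, i] * w + l2[i]) / (w + 1.0)
            basins[s] += 1.0
            return count
    if count < max_keep:
        for i in range(N):
            states[count, i] = l2[i]
        basins[count] = 1.0
    return count + 1


@njit(cache=True)
def _euler_converge(x, g, k, lam, nn, b0n, src, tgt, dt, max_steps, check_every, conv_tol, f):
    """Fixed-step Euler to steady state; returns True when converged."""
    N = x.shape[0]
    xprev = x.copy()
    for step in range(1, max_steps + 1):
        _rhs(x, g, k, lam, nn, b0n, src, tgt, f)
        for i in range(N):
            x[i] += dt * f[i]
            if x[i] < 0.0:
                x[i] = 0.0
        if step % check_every == 0:
            rel = 0.0
            for i in range(N):
                d = abs(x[i] - xprev[i]) / (abs(xprev[i]) + 1e-300)
                if d > rel:
                    rel = d
            if rel < conv_tol:
                return True
            for i in range(N):
                xprev[i] = x[i]
    return False


# Cash-Karp embedded Runge-Kutta 4(5) tableau
_CK_C2, _CK_C3, _CK_C4, _CK_C5, _CK_C6 = 0.2, 0.3, 0.6, 1.0, 0.875
_CK_B = np.array(
    [37.0 / 378.0, 0.0, 250.0 / 621.0, 125.0 / 594.0, 0.0, 512.0 / 1771.0]
)
_CK_BS = np.array(
    [2825.0 / 27648.0, 0.0, 18575.0 / 48384.0, 13525.0 / 55296.0, 277.0 / 14336.0, 0.25]
)
_CK_A = np.array(
    [
        [0.2, 0.0, 0.0, 0.0, 0.0],
        [3.0 / 40.0, 9.0 / 40.0, 0.0, 0.0, 0.0],
        [0.3, -0.9, 1.2, 0.0, 0.0],
        [-11.0 / 54.0, 2.5, -70.0 / 27.0, 35.0 / 27.0, 0.0],
        [
            1631.0 / 55296.0,
            175.0 / 512.0,
            575.0 / 13824.0,
            44275.0 / 110592.0,
            253.0 / 4096.0,
        ],
    ]
)


@njit(cache=True)
def _rk45_converge(
    x, g, k, lam, nn, b0n, src, tgt, t_max, probe_dt, conv_tol, a, b, bs, rtol, atol
):
    """Adaptive Cash-Karp RK45 to steady state; probe-window convergence test."""
    N = x.shape[0]
    ks = np.empty((6, N))
    xtmp = np.empty(N)
    xprev = x.copy()
    t = 0.0
    h = 0.01
    t_probe = probe_dt
    while t < t_max:
        if h > t_max - t:
            h = t_max - t
        _rhs(x, g, k, lam, nn, b0n, src, tgt, ks[0])
        for s in range(1, 6):
            for i in range(N):
                acc = 0.0
                for j in range(s):
                    acc += a[s - 1, j] * ks[j, i]
                v = x[i] + h * acc
                xtmp[i] = v if v > 0.0 else 0.0
            _rhs(xtmp, g, k, lam, nn, b0n, src, tgt, ks[s])
        errnorm = 0.0
        for i in range(N):
            x5 = 0.0
            x4 = 0.0
            for s in range(6):
                x5 += b[s] * ks[s, i]
                x4 += bs[s] * ks[s, i]
            xtmp[i] = x[i] + h * x5
            err = h * abs(x5 - x4)
            sc = atol + rtol * max(abs(x[i]), abs(xtmp[i]))
            e = err / sc
            if e > errnorm:
                errnorm = e
        if errnorm <= 1.0:
            t += h
            for i in range(N):
                x[i] = xtmp[i] if xtmp[i] > 0.0 else 0.0
            if t >= t_probe:
                rel = 0.0
                for i in range(N):
                    d = abs(x[i] - xprev[i]) / (abs(xprev[i]) + 1e-300)
                    if d > rel:
                        rel = d
                if rel < conv_tol:
                    return True
                for i in range(N):
                    xprev[i] = x[i]
                t_probe = t + probe_dt
        fac = 0.9 * errnorm ** -0.2 if errnorm > 1e-10 else 5.0
        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        h *= fac
        if h < 1e-6:
            h = 1e-6
    return False


@njit(cache=True)
def integrate_ensemble(
    G,
    K,
    LAM,
    NN,
    B0,
    src,
    tgt,
    X0,
    dt,
    t_max,
    check_every,
    conv_tol,
    merge_rtol,
    merge_floor,
    max_keep,
    use_rk45,
    rk_rtol,
    rk_atol,
):
    """Integrate every (model, initial condition) pair to steady state.

    Parameters are per-model arrays: ``G, K`` of shape (n_models, N);
    ``LAM, NN, B0`` of shape (n_models, E); ``X0`` of shape
    (n_models, n_init, N).  Converged endpoints are merged per model in
    log2 space.

    Returns ``(counts, n_converged, states, basins)`` where ``counts`` is the
    uncapped number of distinct states per model, ``states`` holds up to
    ``max_keep`` of them (log2 levels, basin-weighted centroids) and
    ``basins`` the number of initial conditions that reached each.
    """
    nm, ni, N = X0.shape
    E = src.shape[0]
    counts = np.zeros(nm, dtype=np.int64)
    nconv = np.zeros(nm, dtype=np.int64)
    states = np.zeros((nm, max_keep, N))
    basins = np.zeros((nm, max_keep))
    max_steps = int(t_max / dt)
    f = np.empty(N)
    b0n = np.empty(E)
    x = np.empty(N)
    l2 = np.empty(N)
    for m in range(nm):
        for e in range(E):
            b0n[e] = _ipow(B0[m, e], NN[m, e])
        count = 0
        for j in range(ni):
            for i in range(N):
                x[i] = X0[m, j, i]
            if use_rk45:
                ok = _rk45_converge(
                    x, G[m], K[m], LAM[m], NN[m], b0n, src, tgt,
                    t_max, check_every * dt, conv_tol, _CK_A, _CK_B, _CK_BS,
                    rk_rtol, rk_atol,
                )
            else:
                ok = _euler_converge(
                    x, G[m], K[m], LAM[m], NN[m], b0n, src, tgt,
                    dt, max_steps, check_every, conv_tol, f,
                )
            if not ok:
                continue
            nconv[m] += 1
            for i in range(N):
                l2[i] = np.log2(x[i] + 1e-300)
            count = _merge_endpoint(
                l2, states[m], basins[m], count, max_keep, merge_rtol, merge_floor
            )
        counts[m] = count
    return counts, nconv, states, basins


@njit(cache=True)
def em_trajectory(g, k, lam, nn, b0, src, tgt, x0, dt, n_steps, amps, xi, save_every):
    """Euler-Maruyama integration of the noisy system.

    ``xi`` is a pre-drawn (n_steps, N) array of standard normals; the update
    is ``x += f(x) dt + amps * xi * sqrt(dt)`` with clipping at 0.  Every
    ``save_every``-th state (plus the initial one) is recorded.
    """
    N = x0.shape[0]
    E = src.shape[0]
    b0n = np.empty(E)
    for e in range(E):
        b0n[e] = _ipow(b0[e], nn[e])
    sq = np.sqrt(dt)
    n_saved = n_steps // save_every + 1
    out = np.empty((n_saved, N))
    x = x0.copy()
    for i in range(N):
        out[0, i] = x[i]
    f = np.empty(N)
    row = 1
    for step in range(1, n_steps + 1):
        _rhs(x, g, k, lam, nn, b0n, src, tgt, f)
        for i in range(N):
            x[i] += f[i] * dt + amps[i] * xi[step - 1, i] * sq
            if x[i] < 0.0:
                x[i] = 0.0
        if step % save_every == 0:
            for i in range(N):
                out[row, i] = x[i]
            row += 1
    return out
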