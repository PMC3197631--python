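"""Compiled inner loops (numba) for the sequential scans.

Each kernel mirrors the reference numpy semantics exactly (same update
order, same buffer convention); the test suite checks the fast paths against
the composed reference operations.  Only the strictly sequential recursions
live here — batched tensor contractions stay in numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# selector codes for Lyapunov separation measurement
SEL_ENTIRE = 0
SEL_MIDDLE = 1
SEL_HIGHER = 2
SEL_EXPERT = 3


@njit(cache=True)
def expert_scan(Wr, u0, inX, al):
    """Forward recursion of all experts: u[t+1] = (1-al) u[t] + al (Wr tanh(u[t]) + inX[t])."""
    S = inX.shape[0]
    E, N = u0.shape
    u = np.empty((S + 1, E, N))
    u[0] = u0
    for t in range(S):
        for e in range(E):
            r = np.tanh(u[t, e])
            d = Wr[e] @ r + inX[t, e]
            u[t + 1, e] = (1.0 - al) * u[t, e] + al * d
    return u


@njit(cache=True)
def expert_backscan(Wr, du_out, th, al):
    """Reverse accumulation of dL/du_t; returns the per-step adjoints and dL/du_0."""
    S, E, N = du_out.shape
    lam_store = np.zeros((S + 1, E, N))
    for e in range(E):
        lam_store[S, e] = du_out[S - 1, e]
    for t in range(S - 1, 0, -1):
        for e in range(E):
            back = Wr[e].T @ (al * lam_store[t + 1, e])
            lam_store[t, e] = (du_out[t - 1, e] + (1.0 - al) * lam_store[t + 1, e]
                               + (1.0 - th[t, e] ** 2) * back)
    du0 = np.empty((E, N))
    for e in range(E):
        back = Wr[e].T @ (al * lam_store[1, e])
        du0[e] = (1.0 - al) * lam_store[1, e] + (1.0 - th[0, e] ** 2) * back
    return lam_store, du0


@njit(cache=True)
def gating_scan(A, B, Eh, Fh, bh, inmid, mid0, high0, am, ah):
    """Forward recursion of the gating network (synchronous mid/high update)."""
    S = inmid.shape[0]
    mid = np.empty((S + 1, mid0.shape[0]))
    high = np.empty((S + 1, high0.shape[0]))
    mid[0] = mid0
    high[0] = high0
    for t in range(S):
        tm = np.tanh(mid[t])
        th = np.tanh(high[t])
        mid[t + 1] = (1.0 - am) * mid[t] + am * (A @ tm + B @ th + inmid[t])
        high[t + 1] = (1.0 - ah) * high[t] + ah * (Eh @ th + Fh @ tm + bh)
    return mid, high


@njit(cache=True)
def gating_backscan(A, B, Eh, Fh, dmid_out, tmids, thighs, am, ah):
    """Reverse accumulation of the coupled mid/high adjoints."""
    S = dmid_out.shape[0]
    M = tmids.shape[1]
    H = thighs.shape[1]
    Lm = np.zeros((S + 1, M))
    Lh = np.zeros((S + 1, H))
    Lm[S] = dmid_out[S - 1]
    for t in range(S - 1, 0, -1):
        tm2 = 1.0 - tmids[t] ** 2
        th2 = 1.0 - thighs[t] ** 2
        Lm[t] = (dmid_out[t - 1] + (1.0 - am) * Lm[t + 1]
                 + tm2 * (A.T @ (am * Lm[t + 1])) + tm2 * (Fh.T @ (ah * Lh[t + 1])))
        Lh[t] = ((1.0 - ah) * Lh[t + 1] + th2 * (Eh.T @ (ah * Lh[t + 1]))
                 + th2 * (B.T @ (am * Lm[t + 1])))
    tm2 = 1.0 - tmids[0] ** 2
    th2 = 1.0 - thighs[0] ** 2
    du_mid0 = ((1.0 - am) * Lm[1] + tm2 * (A.T @ (am * Lm[1]))
               + tm2 * (Fh.T @ (ah * Lh[1])))
    du_high0 = ((1.0 - ah) * Lh[1] + th2 * (Eh.T @ (ah * Lh[1]))
                + th2 * (B.T @ (am * Lm[1])))
    return Lm, Lh, du_mid0, du_high0


@njit(cache=True)
def _step(Wr, Win, br, Wout, bout, A, B, U, G, bm, Eh, Fh, bh, C,
          al, am, ah, lesioned, u, mid, high, g, buf, x):
    """One whole-model step, in place; returns the combined prediction."""
    L = buf.shape[0]
    if L > 1:
        for i in range(L - 1):
            buf[i] = buf[i + 1]
    buf[L - 1] = x
    xd = buf[0]
    E = u.shape[0]
    D = x.shape[0]
    ys = np.empty((E, D))
    for e in range(E):
        r = np.tanh(u[e])
        d = Wr[e] @ r + Win[e] @ xd + br[e]
        u[e] = (1.0 - al) * u[e] + al * d
        ys[e] = np.tanh(Wout[e] @ np.tanh(u[e]) + bout[e])
    tm = np.tanh(mid)
    th = np.tanh(high)
    mid[:] = (1.0 - am) * mid + am * (A @ tm + B @ th + U @ x + G @ g + bm)
    if lesioned:
        high[:] = 0.0
    else:
        high[:] = (1.0 - ah) * high + ah * (Eh @ th + Fh @ tm + bh)
    z = C @ np.tanh(mid)
    z = z - z.max()
    ez = np.exp(z)
    g[:] = ez / ez.sum()
    yhat = np.zeros(D)
    for e in range(E):
        yhat += g[e] * ys[e]
    return yhat


@njit(cache=True)
def run_scan(Wr, Win, br, Wout, bout, A, B, U, G, bm, Eh, Fh, bh, C,
             al, am, ah, lesioned, u0, mid0, high0, g0, buf0, X, closed):
    """Closed- or open-loop rollout.

    ``X`` is (T, D): in open loop the observations, in closed loop only
    ``X[0]`` is used (as the first input) and subsequent inputs are the
    model's own predictions.  Returns predictions and the higher-level
    trajectory."""
    T = X.shape[0]
    D = X.shape[1]
    u = u0.copy()
    mid = mid0.copy()
    high = high0.copy()
    g = g0.copy()
    buf = buf0.copy()
    Y = np.empty((T, D))
    HI = np.empty((T, high0.shape[0]))
    x = X[0].copy()
    for t in range(T):
        if not closed and t > 0:
            x = X[t].copy()
        y = _step(Wr, Win, br, Wout, bout, A, B, U, G, bm, Eh, Fh, bh, C,
                  al, am, ah, lesioned, u, mid, high, g, buf, x)
        Y[t] = y
        HI[t] = high
        if closed:
            x = y
    return Y, HI


@njit(cache=True)
def benettin_scan(Wr, Win, br, Wout, bout, A, B, U, G, bm, Eh, Fh, bh, C,
                  al, am, ah, lesioned,
                  u_r, mid_r, high_r, g_r, buf_r, x_r,
                  u_p, mid_p, high_p, g_p, buf_p, x_p,
                  horizon, transient, renorm, eps, sel, sel_expert):
    """Two-trajectory Lyapunov accumulation with periodic renormalization.

    Measures the log expansion of the selected subnetwork's state separation
    over each renormalization interval; the full separation (all internal
    units, gate, buffer, feedback input) is rescaled to ``eps`` (full
    internal-state norm) after each interval.  Returns (log_sum, n_steps);
    n_steps < 0 flags separation underflow."""

    def sub_norm(mode, e_idx, du, dm, dh):
        if mode == SEL_MIDDLE:
            return np.sqrt(np.sum(dm ** 2))
        if mode == SEL_HIGHER:
            return np.sqrt(np.sum(dh ** 2))
        if mode == SEL_EXPERT:
            return np.sqrt(np.sum(du[e_idx] ** 2))
        return np.sqrt(np.sum(du ** 2) + np.sum(dm ** 2) + np.sum(dh ** 2))

    log_sum = 0.0
    n_steps = 0
    eps_sub = sub_norm(sel, sel_expert,
                       u_p - u_r, mid_p - mid_r, high_p - high_r)
    for t in range(horizon):
        y_r = _step(Wr, Win, br, Wout, bout, A, B, U, G, bm, Eh, Fh, bh, C,
                    al, am, ah, lesioned, u_r, mid_r, high_r, g_r, buf_r, x_r)
        y_p = _step(Wr, Win, br, Wout, bout, A, B, U, G, bm, Eh, Fh, bh, C,
                    al, am, ah, lesioned, u_p, mid_p, high_p, g_p, buf_p, x_p)
        x_r = y_r
        x_p = y_p
        if (t + 1) % renorm == 0:
            du = u_p - u_r
            dm = mid_p - mid_r
            dh = high_p - high_r
            d_sub = sub_norm(sel, sel_expert, du, dm, dh)
            d_full = sub_norm(SEL_ENTIRE, 0, du, dm, dh)
            if d_sub <= 0.0 or d_full <= 0.0 or eps_sub <= 0.0:
                return 0.0, -1
            if t >= transient:
                log_sum += np.log(d_sub / eps_sub)
                n_steps += renorm
            scale = eps / d_full
            u_p = u_r + scale * du
            mid_p = mid_r + scale * dm
            high_p = high_r + scale * dh
            g_p = g_r + scale * (g_p - g_r)
            buf_p = buf_r + scale * (buf_p - buf_r)
            x_p = x_r + scale * (x_p - x_r)
            eps_sub = sub_norm(sel, sel_expert,
                               u_p - u_r, mid_p - mid_r, high_p - high_r)
    return log_sum, n_steps
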