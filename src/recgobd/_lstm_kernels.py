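"""Compiled inner loops of the LSTM forward/backward passes.

The time-step recursion cannot be vectorized across positions, so the loops
are JIT-compiled with numba; input/output projections stay outside as single
large matrix products.  Gate layout along the last axis: input, forget,
cell candidate, output.  Masked (padded) steps hold state and receive no
gradient, making trailing padding inert.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def lstm_forward_loop(Xp, maskf, Wh, reverse):
    """State recursion for one direction.

    Xp : (B, L, 4H) precomputed input projections (x_t W_x + b)
    maskf : (B, L) 1.0 for valid positions, 0.0 for padding
    Returns per-step gate activations and pre-step states needed for BPTT.
    """
    B, L, H4 = Xp.shape
    H = H4 // 4
    dt = Xp.dtype
    I = np.empty((B, L, H), dt); F = np.empty((B, L, H), dt)
    G = np.empty((B, L, H), dt); O = np.empty((B, L, H), dt)
    Tc = np.empty((B, L, H), dt)
    Cprev = np.empty((B, L, H), dt); Hprev = np.empty((B, L, H), dt)
    Hout = np.empty((B, L, H), dt)
    h = np.zeros((B, H), dt)
    c = np.zeros((B, H), dt)
    for step in range(L):
        t = L - 1 - step if reverse else step
        z = Xp[:, t] + np.dot(h, Wh)
        for b in range(B):
            m = maskf[b, t]
            for j in range(H):
                Cprev[b, t, j] = c[b, j]
                Hprev[b, t, j] = h[b, j]
                i = 1.0 / (1.0 + np.exp(-z[b, j]))
                f = 1.0 / (1.0 + np.exp(-z[b, H + j]))
                g = np.tanh(z[b, 2 * H + j])
                o = 1.0 / (1.0 + np.exp(-z[b, 3 * H + j]))
                c_new = f * c[b, j] + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                c[b, j] = m * c_new + (1.0 - m) * c[b, j]
                h[b, j] = m * h_new + (1.0 - m) * h[b, j]
                I[b, t, j] = i; F[b, t, j] = f; G[b, t, j] = g; O[b, t, j] = o
                Tc[b, t, j] = tc
                Hout[b, t, j] = h[b, j]
    return Hout, I, F, G, O, Tc, Cprev, Hprev


@njit(cache=True, fastmath=True)
def lstm_backward_loop(dHout, maskf, Wh, I, F, G, O, Tc, Cprev, reverse):
    """Backpropagation through time for one direction; returns gate-input
    gradients dZ (B, L, 4H) for the outer weight-gradient matmuls."""
    B, L, H = dHout.shape
    dt = dHout.dtype
    dZ = np.zeros((B, L, 4 * H), dt)
    dh = np.zeros((B, H), dt)
    dc = np.zeros((B, H), dt)
    dzt = np.empty((B, 4 * H), dt)
    WhT = np.ascontiguousarray(Wh.T)
    for step in range(L):
        # reversed processing order
        t = step if reverse else L - 1 - step
        for b in range(B):
            m = maskf[b, t]
            for j in range(H):
                dh_t = dHout[b, t, j] + dh[b, j]
                dh_new = m * dh_t
                dh[b, j] = (1.0 - m) * dh_t
                dc_new = m * dc[b, j]
                dc[b, j] = (1.0 - m) * dc[b, j]
                i = I[b, t, j]; f = F[b, t, j]; g = G[b, t, j]
                o = O[b, t, j]; tc = Tc[b, t, j]
                do = dh_new * tc
                dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
                di = dc_new * g
                df = dc_new * Cprev[b, t, j]
                dg = dc_new * i
                dc[b, j] += dc_new * f
                dzt[b, j] = di * i * (1.0 - i)
                dzt[b, H + j] = df * f * (1.0 - f)
                dzt[b, 2 * H + j] = dg * (1.0 - g * g)
                dzt[b, 3 * H + j] = do * o * (1.0 - o)
        dZ[:, t] = dzt
        dh += np.dot(dzt, WhT)
    return dZ
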