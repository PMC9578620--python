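"""Fused LSTM scan kernels.

The recurrent stacks spend their time in a Python loop over timesteps of
small matrix operations; these kernels compile that loop with numba when
it is available and fall back to plain NumPy otherwise.  Both paths
compute identical quantities (the NumPy path is the reference the test
suite gradient-checks).

Gate layout along the last axis: ``[i, f, g, o]``; the tied variant
derives the input gate from the candidate preactivation.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly wherever numba exists
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _forward_py(xw, wh, tied):
    B, T, G = xw.shape
    H = G // 4
    dtype = xw.dtype
    h = np.zeros((B, H), dtype=dtype)
    c = np.zeros((B, H), dtype=dtype)
    hs = np.empty((B, T, H), dtype=dtype)
    gates = np.empty((B, T, 6, H), dtype=dtype)  # i, f, g, o, c_prev, tanh(c)
    for t in range(T):
        a = xw[:, t, :] + h @ wh
        # one sigmoid evaluation for the [i, f, o] slab
        sig = np.delete(a, np.s_[2 * H:3 * H], axis=1)
        np.negative(sig, out=sig)
        np.exp(sig, out=sig)
        sig += 1.0
        np.reciprocal(sig, out=sig)
        g_ = np.tanh(a[:, 2 * H:3 * H])
        i_ = (1.0 / (1.0 + np.exp(-a[:, 2 * H:3 * H]))) if tied else sig[:, :H]
        f_ = sig[:, H:2 * H]
        o_ = sig[:, 2 * H:]
        gates[:, t, 4] = c
        c = f_ * c + i_ * g_
        tc = np.tanh(c)
        h = o_ * tc
        hs[:, t] = h
        gates[:, t, 0] = i_
        gates[:, t, 1] = f_
        gates[:, t, 2] = g_
        gates[:, t, 3] = o_
        gates[:, t, 5] = tc
    return hs, gates


def _backward_py(gout, hs, gates, wh, tied):
    B, T, H = hs.shape
    dtype = gout.dtype
    dxw = np.zeros((B, T, 4 * H), dtype=dtype)
    dwh = np.zeros_like(wh)
    dh_next = np.zeros((B, H), dtype=dtype)
    dc = np.zeros((B, H), dtype=dtype)
    for t in range(T - 1, -1, -1):
        i_ = gates[:, t, 0]
        f_ = gates[:, t, 1]
        g_ = gates[:, t, 2]
        o_ = gates[:, t, 3]
        c_prev = gates[:, t, 4]
        tc = gates[:, t, 5]
        dh = gout[:, t] + dh_next
        do = dh * tc
        dc = dc + dh * o_ * (1.0 - tc * tc)
        df = dc * c_prev
        di = dc * g_
        dg = dc * i_
        dag = dg * (1.0 - g_ * g_)
        if tied:
            dag = dag + di * i_ * (1.0 - i_)
            dxw[:, t, :H] = 0.0
        else:
            dxw[:, t, :H] = di * i_ * (1.0 - i_)
        dxw[:, t, H:2 * H] = df * f_ * (1.0 - f_)
        dxw[:, t, 2 * H:3 * H] = dag
        dxw[:, t, 3 * H:] = do * o_ * (1.0 - o_)
        h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dtype)
        dwh += h_prev.T @ dxw[:, t]
        dh_next = dxw[:, t] @ wh.T
        dc = dc * f_
    return dxw, dwh


if _HAVE_NUMBA:  # pragma: no branch

    @numba.njit(cache=True, fastmath=False)
    def _backward_nb(gout, hs, gates, wh, tied):  # pragma: no cover - compiled
        B, T, H = hs.shape
        dxw = np.zeros((B, T, 4 * H), dtype=gout.dtype)
        dwh = np.zeros_like(wh)
        dh_next = np.zeros((B, H), dtype=gout.dtype)
        dc = np.zeros((B, H), dtype=gout.dtype)
        for t in range(T - 1, -1, -1):
            for b in range(B):
                for j in range(H):
                    iv = gates[b, t, 0, j]
                    fv = gates[b, t, 1, j]
                    gv = gates[b, t, 2, j]
                    ov = gates[b, t, 3, j]
                    cp = gates[b, t, 4, j]
                    tcv = gates[b, t, 5, j]
                    dh = gout[b, t, j] + dh_next[b, j]
                    dov = dh * tcv
                    dcv = dc[b, j] + dh * ov * (1.0 - tcv * tcv)
                    dfv = dcv * cp
                    div = dcv * gv
                    dgv = dcv * iv
                    dag = dgv * (1.0 - gv * gv)
                    if tied:
                        dag = dag + div * iv * (1.0 - iv)
                        dxw[b, t, j] = 0.0
                    else:
                        dxw[b, t, j] = div * iv * (1.0 - iv)
                    dxw[b, t, H + j] = dfv * fv * (1.0 - fv)
                    dxw[b, t, 2 * H + j] = dag
                    dxw[b, t, 3 * H + j] = dov * ov * (1.0 - ov)
                    dc[b, j] = dcv * fv
            if t > 0:
                dwh += np.dot(hs[:, t - 1].T.copy(), dxw[:, t])
            dh_next = np.dot(dxw[:, t], wh.T.copy())
        return dxw, dwh


def lstm_scan_forward(xw: np.ndarray, wh: np.ndarray, tied: bool):
    """Scan the gate preactivations through time.

    ``xw`` is the precomputed input contribution plus bias, (B, T, 4H);
    ``wh`` the recurrent matrix (H, 4H).  Returns the hidden sequence and
    the gate cache needed by the backward pass.

    The forward path stays in NumPy (vectorized transcendentals beat the
    compiled scalar loop); the arithmetic-only backward is compiled.
    """
    return _forward_py(xw, wh, tied)


def lstm_scan_backward(gout, hs, gates, wh, tied: bool):
    """Backpropagation through time; returns (d_preactivations, d_wh)."""
    gout = np.ascontiguousarray(gout, dtype=hs.dtype)
    if _HAVE_NUMBA:
        return _backward_nb(gout, np.ascontiguousarray(hs),
                            np.ascontiguousarray(gates),
                            np.ascontiguousarray(wh), tied)
    return _backward_py(gout, hs, gates, wh, tied)
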