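"""Numerical kernel: per-lake log-likelihood of the state-space model.

The latent trajectory of each lake is a deterministic function of the
initial state and the lake's rates, so the likelihood is the product of
normal observation densities around the simulated path. This is the hot
loop of the Metropolis-within-Gibbs sampler and is JIT-compiled with numba
when available; a vectorized numpy fallback keeps the package functional
without it.
"""

from __future__ import annotations

import math

import numpy as np

_LOG_2PI = math.log(2.0 * math.pi)


def _lake_logliks_py(c, psi, m, e, x1, y1, obs_x, obs_y, sigma_x, sigma_y):
    L, T = obs_x.shape
    x = x1.copy()
    y = y1.copy()
    rx = (obs_x[:, 0] - x) / sigma_x
    ry = (obs_y[:, 0] - y) / sigma_y
    out = -0.5 * (rx * rx + ry * ry) - math.log(sigma_x) - math.log(sigma_y) - _LOG_2PI
    for t in range(1, T):
        xn = x + psi * x - c * x * y
        yn = y + c * e * x * y - m * y
        np.maximum(xn, 0.0, out=xn)
        np.maximum(yn, 0.0, out=yn)
        x, y = xn, yn
        rx = (obs_x[:, t] - x) / sigma_x
        ry = (obs_y[:, t] - y) / sigma_y
        out += -0.5 * (rx * rx + ry * ry) - math.log(sigma_x) - math.log(sigma_y) - _LOG_2PI
    return out


def _simulate_lakes_py(c, psi, m, e, x1, y1, n_times):
    L = len(x1)
    X = np.empty((L, n_times))
    Y = np.empty((L, n_times))
    X[:, 0] = x1
    Y[:, 0] = y1
    for t in range(1, n_times):
        x, y = X[:, t - 1], Y[:, t - 1]
        X[:, t] = np.maximum(x + psi * x - c * x * y, 0.0)
        Y[:, t] = np.maximum(y + c * e * x * y - m * y, 0.0)
    return X, Y


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    @njit(cache=True, fastmath=False)
    def lake_logliks(c, psi, m, e, x1, y1, obs_x, obs_y, sigma_x, sigma_y):
        L, T = obs_x.shape
        out = np.empty(L)
        base = -math.log(sigma_x) - math.log(sigma_y) - _LOG_2PI
        for j in range(L):
            x = x1[j]
            y = y1[j]
            rx = (obs_x[j, 0] - x) / sigma_x
            ry = (obs_y[j, 0] - y) / sigma_y
            ll = base - 0.5 * (rx * rx + ry * ry)
            for t in range(1, T):
                xn = x + psi[j] * x - c[j] * x * y
                yn = y + c[j] * e * x * y - m[j] * y
                x = xn if xn > 0.0 else 0.0
                y = yn if yn > 0.0 else 0.0
                rx = (obs_x[j, t] - x) / sigma_x
                ry = (obs_y[j, t] - y) / sigma_y
                ll += base - 0.5 * (rx * rx + ry * ry)
            out[j] = ll
        return out

    @njit(cache=True)
    def simulate_lakes(c, psi, m, e, x1, y1, n_times):
        L = len(x1)
        X = np.empty((L, n_times))
        Y = np.empty((L, n_times))
        for j in range(L):
            X[j, 0] = x1[j]
            Y[j, 0] = y1[j]
            for t in range(1, n_times):
                x = X[j, t - 1]
                y = Y[j, t - 1]
                xn = x + psi[j] * x - c[j] * x * y
                yn = y + c[j] * e * x * y - m[j] * y
                X[j, t] = xn if xn > 0.0 else 0.0
                Y[j, t] = yn if yn > 0.0 else 0.0
        return X, Y

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    lake_logliks = _lake_logliks_py
    simulate_lakes = _simulate_lakes_py
    HAVE_NUMBA = False
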