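"""Compiled inner loops: Euler stepping and RK4 flow maps.

These mirror :func:`coolmass.model_core.drift` exactly; the pure-Python
drift is the reference, the kernels are the fast path used by the
simulator, the sweeps and the shooting code.  Coefficients are packed
into flat arrays by :func:`pack_coeffs` so a single compiled function
serves every temperature variant.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model_core import ModelParameters, TemperatureSpec, effective_gain

_EXP_CLIP = 700.0


def pack_coeffs(params: ModelParameters, temp: TemperatureSpec):
    """Flatten model + temperature into the kernel argument tuple.

    Returns ``(A, g, C, e0, v_th, sigma_th, f_int)`` where ``A`` holds the
    four effective (temperature-attenuated) gains, ``g`` the four rate
    constants, ``C`` the seven connectivity counts and ``f_int`` the
    reciprocal intrinsic Q10 factor multiplying the membrane potential in
    the firing response.
    """
    A = np.array([effective_gain(pop, params, temp)
                  for pop in ("PY", "EX", "SIN", "FIN")])
    g = np.array([params.g_PY, params.g_EX, params.g_SIN, params.g_FIN])
    C = np.array([params.C_PY_EX, params.C_EX_PY, params.C_PY_SIN,
                  params.C_PY_FIN, params.C_SIN_PY, params.C_FIN_PY,
                  params.C_SIN_FIN])
    return (A, g, C, params.e0, params.v_th, params.sigma_th,
            temp.intrinsic_factor())


@njit(cache=True, inline="always")
def _sig(v, e0, v_th, sigma_th, f_int):
    x = (v_th - f_int * v) / sigma_th
    if x > _EXP_CLIP:
        x = _EXP_CLIP
    elif x < -_EXP_CLIP:
        x = -_EXP_CLIP
    return 2.0 * e0 / (1.0 + np.exp(x))


@njit(cache=True)
def drift10(x, p, A, g, C, e0, v_th, sigma_th, f_int):
    """Deterministic right-hand side; matches model_core.drift."""
    out = np.empty(10)
    s_py = _sig(x[1] - x[2] - x[3], e0, v_th, sigma_th, f_int)
    s_ex = _sig(C[0] * x[0], e0, v_th, sigma_th, f_int)
    s_sin = _sig(C[2] * x[0], e0, v_th, sigma_th, f_int)
    s_fin = _sig(C[3] * x[0] - C[6] * x[4], e0, v_th, sigma_th, f_int)
    u0 = A[0] * g[0] * s_py
    u1 = A[1] * g[1] * (p + C[1] * s_ex)
    u2 = A[2] * g[2] * C[4] * s_sin
    u3 = A[3] * g[3] * C[5] * s_fin
    u4 = A[2] * g[2] * s_sin
    out[0] = x[5]
    out[1] = x[6]
    out[2] = x[7]
    out[3] = x[8]
    out[4] = x[9]
    out[5] = u0 - 2.0 * g[0] * x[5] - g[0] * g[0] * x[0]
    out[6] = u1 - 2.0 * g[1] * x[6] - g[1] * g[1] * x[1]
    out[7] = u2 - 2.0 * g[2] * x[7] - g[2] * g[2] * x[2]
    out[8] = u3 - 2.0 * g[3] * x[8] - g[3] * g[3] * x[3]
    out[9] = u4 - 2.0 * g[2] * x[9] - g[2] * g[2] * x[4]
    return out


@njit(cache=True)
def euler_path(x0, dt, n_steps, p_arr, A, g, C, e0, v_th, sigma_th, f_int):
    """Fixed-step Euler integration with per-step piecewise-constant input.

    ``p_arr`` supplies the subcortical input rate for each step (a constant
    array gives the deterministic model).  Returns ``(eeg, x_final, bad)``
    where ``eeg[i]`` is the pyramidal membrane potential after step ``i``
    and ``bad`` is the index of the first non-finite step (-1 if none;
    integration stops there).
    """
    x = x0.copy()
    eeg = np.empty(n_steps)
    for i in range(n_steps):
        dx = drift10(x, p_arr[i], A, g, C, e0, v_th, sigma_th, f_int)
        for j in range(10):
            x[j] += dt * dx[j]
        e = x[1] - x[2] - x[3]
        eeg[i] = e
        if not np.isfinite(e):
            return eeg[: i + 1], x, i
    return eeg, x, -1


@njit(cache=True)
def rk4_flow(x0, T, n_steps, p, A, g, C, e0, v_th, sigma_th, f_int):
    """Classical RK4 flow map over time ``T`` with constant input ``p``."""
    x = x0.copy()
    h = T / n_steps
    for _ in range(n_steps):
        k1 = drift10(x, p, A, g, C, e0, v_th, sigma_th, f_int)
        k2 = drift10(x + 0.5 * h * k1, p, A, g, C, e0, v_th, sigma_th, f_int)
        k3 = drift10(x + 0.5 * h * k2, p, A, g, C, e0, v_th, sigma_th, f_int)
        k4 = drift10(x + h * k3, p, A, g, C, e0, v_th, sigma_th, f_int)
        x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return x
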