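"""Independent fixed-step integrators used as numerical oracles.

These deliberately avoid the package's solver path: the mass balances are
re-derived with the volumes integrated as explicit states and advanced with
classic fourth-order Runge-Kutta at a fine fixed step.
"""

from __future__ import annotations

import numpy as np


def rk4_two_pool(
    K: float,
    K21: float,
    V1: float,
    V2: float,
    G: float,
    quf_l_per_min: float,
    c0: float,
    T: float,
    dt: float = 0.01,
):
    """Fixed-step RK4 solution of the two-pool variable-volume balances.

    Returns (times, C1, C2, cumulative_removal) sampled every step.
    Clearances in mL/min, volumes L, concentrations mg/L.
    """
    k = K / 1000.0
    k21 = K21 / 1000.0

    def deriv(y):
        c1, c2, v1, v2, _ = y
        vtot = v1 + v2
        dv1 = -quf_l_per_min * v1 / vtot
        dv2 = -quf_l_per_min * v2 / vtot
        dc1 = (G - k * c1 + k21 * (c2 - c1) - c1 * dv1) / v1
        dc2 = (-k21 * (c2 - c1) - c2 * dv2) / v2
        return np.array([dc1, dc2, dv1, dv2, k * c1])

    n = int(round(T / dt))
    y = np.array([c0, c0, V1, V2, 0.0])
    out = np.empty((n + 1, 5))
    out[0] = y
    for i in range(n):
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = y
    t = np.arange(n + 1) * dt
    return t, out[:, 0], out[:, 1], out[:, 4]


def rk4_single_pool(
    K: float,
    V: float,
    G: float,
    quf_l_per_min: float,
    c0: float,
    T: float,
    dt: float = 0.01,
):
    """Fixed-step RK4 solution of the one-pool balance d(V*C)/dt = G - K*C."""
    k = K / 1000.0

    def deriv(t, y):
        c, _ = y
        v = V - quf_l_per_min * t
        dv = -quf_l_per_min
        dc = (G - k * c - c * dv) / v
        return np.array([dc, k * c])

    n = int(round(T / dt))
    y = np.array([c0, 0.0])
    out = np.empty((n + 1, 2))
    out[0] = y
    for i in range(n):
        t = i * dt
        k1 = deriv(t, y)
        k2 = deriv(t + 0.5 * dt, y + 0.5 * dt * k1)
        k3 = deriv(t + 0.5 * dt, y + 0.5 * dt * k2)
        k4 = deriv(t + dt, y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = y
    return np.arange(n + 1) * dt, out[:, 0], out[:, 1]
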