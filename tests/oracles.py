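"""Independent brute-force oracles used by the tests.

These re-derive the model predictions from the printed equations with a
fixed-step Euler scheme, deliberately sharing no code with the package's
adaptive integrator.
"""

from __future__ import annotations

import math


def euler_adrn_frequency(
    *,
    r: float,
    alpha: float,
    beta: float,
    tau1: float = 0.0,
    tau2: float = 0.0,
    gamma: float = 0.0,
    zeta: float = 0.0,
    on_intervals=(),
    x0: tuple[float, float],
    t0: float,
    t_end: float,
    dt: float = 0.001,
):
    """Forward-Euler integration of the replicator equations.

    Returns (xA, xM) at t_end.  The mean fitness is written out long-hand
    from the equations: phi = xA*(fA) + xM*(fM) where fA carries the
    therapy death term but not the switching outflux, so the switching
    flux cancels in the pair sum.
    """
    xA, xM = x0
    n_steps = round((t_end - t0) / dt)
    for i in range(n_steps):
        t = t0 + i * dt
        on = any(a <= t < b for a, b in on_intervals)
        g = gamma if on else 0.0
        z = zeta if on else 0.0
        fA = r * (1.0 - xA - alpha * xM) - tau1 * xA + tau2 * xM - g
        fM = r * (1.0 - beta * xA - xM) + tau1 * xA - tau2 * xM
        phi = xA * fA + xM * fM
        dxA = xA * (fA - z - phi)
        dxM = xM * (fM - phi) + z * xA
        xA += dt * dxA
        xM += dt * dxM
    return xA, xM


def hand_r_squared(observed, predicted):
    """Textbook R^2 computed with plain Python arithmetic."""
    mean = sum(observed) / len(observed)
    tss = sum((o - mean) ** 2 for o in observed)
    rss = sum((p - o) ** 2 for p, o in zip(predicted, observed))
    return 1.0 - rss / tss


def hand_aic(rss, n, k):
    return n * math.log(rss / n) + 2 * k
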