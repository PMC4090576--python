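"""Deterministic mean-field companions to the stochastic models.

These are *cross-checks*, not the simulator: the Schlögl rate equation
locates the stable/unstable fixed points that the stochastic ensemble
switches between, and the Neurospora ODE system reproduces the limit-cycle
oscillation whose period the SSA ensemble should match.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import argrelmax

from .models import NeurosporaParams, PiecewiseSchedule

__all__ = ["schlogl_rate", "schlogl_fixed_points", "neurospora_rhs", "neurospora_ode_period"]


def schlogl_rate(a: float) -> float:
    """dA/dt of the Schlögl rate equation (combinatorial convention).

    ``0.03 A^2/2 - 0.0001 A^3/6 + 200 - 3.5 A`` — the large-count limit of
    the combinatorial propensities of the four reactions.
    """
    return 0.015 * a * a - (1e-4 / 6.0) * a**3 + 200.0 - 3.5 * a


def schlogl_fixed_points() -> tuple[list[float], list[float]]:
    """Positive fixed points of the Schlögl rate equation.

    Returns ``(stable, unstable)`` lists sorted ascending; there are two
    stable points (low/high A) separated by one unstable point.
    """
    # -c3 A^3 + c2 A^2 - c1 A + c0 = 0
    coeffs = [-(1e-4) / 6.0, 0.015, -3.5, 200.0]
    roots = np.roots(coeffs)
    real = sorted(r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 0)
    dpoly = np.polyder(np.poly1d(coeffs))
    stable = [r for r in real if dpoly(r) < 0]
    unstable = [r for r in real if dpoly(r) >= 0]
    return stable, unstable


def neurospora_rhs(t: float, y: np.ndarray, p: NeurosporaParams) -> list[float]:
    """Mean-field ODEs for (M, FRQ_cytosolic, FRQ_nuclear), molecule units."""
    m, fc, fn = y
    kin = p.K_I ** p.n
    transcription = p.schedule(t) * kin / (fn ** p.n + kin)
    dm = transcription - p.v_m * m / (p.K_m + m)
    dfc = p.k_s * m - p.v_d * fc / (p.K_d + fc) - p.k_1 * fc + p.k_2 * fn
    dfn = p.k_1 * fc - p.k_2 * fn
    return [dm, dfc, dfn]


def neurospora_ode_period(
    params: NeurosporaParams | None = None,
    t_end: float = 500.0,
    transient: float = 100.0,
    dt: float = 0.01,
) -> float:
    """Oscillation period (hours) of the mean-field model from mRNA maxima."""
    p = params if params is not None else NeurosporaParams(schedule=PiecewiseSchedule.constant(160.0))
    t_eval = np.arange(0.0, t_end, dt)
    sol = solve_ivp(
        neurospora_rhs, (0.0, t_end), [10.0, 10.0, 10.0], args=(p,),
        t_eval=t_eval, rtol=1e-8, atol=1e-8, dense_output=False, method="LSODA",
    )
    m = sol.y[0]
    keep = sol.t >= transient
    peaks = argrelmax(m[keep], order=int(1.0 / dt))[0]
    times = sol.t[keep][peaks]
    if len(times) < 2:
        raise RuntimeError("mean-field model did not oscillate")
    return float(np.mean(np.diff(times)))
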