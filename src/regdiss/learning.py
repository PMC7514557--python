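"""Steady-state learning rate and thermodynamic efficiency.

For a bipartite chain (no simultaneous flips of the two variables) the
stationary entropy production splits over the variable whose jump each
edge represents: ``sigma_ss = sigma_x + sigma_z``.  The learning rate

    l_x = d/dtau I[z_0; x_tau] at tau = 0+,  from the stationary state,

measures how fast the output keeps acquiring information about the
current input; for the no-feedback (sensor-like) models it is bounded by
the output-marginal entropy production, so the efficiency
``eta = l_x / sigma_x`` lies in [0, 1].

Both rates are reported per unit of rescaled time (bits per relaxation
time when ``rescaled=True``, the default); the efficiency is
scale-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuits import Generator4, delayed_joint, relaxation_rate, steady_state
from .info import mi_from_joint

__all__ = ["LearningReport", "learning_rate", "sigma_x", "sigma_z", "efficiency"]

#: edges along which the output x flips (z fixed), as (i, j) index pairs
_X_EDGES = ((0, 1), (1, 0), (2, 3), (3, 2))
_Z_EDGES = ((0, 2), (2, 0), (1, 3), (3, 1))


@dataclass(frozen=True)
class LearningReport:
    l_x: float
    sigma_x: float
    eta: float
    finite_difference_step: float
    base: float = 2.0


def _marginal_sigma(G: Generator4, edges, base: float) -> float:
    p = steady_state(G).p
    total = 0.0
    for i, j in edges:
        w_f, w_b = G.w[i, j], G.w[j, i]
        if w_f <= 0 or p[j] <= 0:
            continue
        if w_b <= 0:
            return math.inf
        total += p[j] * w_f * math.log(w_f / w_b)
    return total / math.log(base)


def sigma_x(G: Generator4, base: float = 2.0) -> float:
    """Stationary entropy production restricted to output-flip edges."""
    return _marginal_sigma(G, _X_EDGES, base)


def sigma_z(G: Generator4, base: float = 2.0) -> float:
    """Stationary entropy production restricted to input-flip edges."""
    return _marginal_sigma(G, _Z_EDGES, base)


def learning_rate(
    G: Generator4,
    base: float = 2.0,
    step: float = 1e-4,
    rescaled: bool = True,
    rtol: float = 1e-4,
) -> float:
    """One-sided derivative of the delayed information at zero delay.

    Evaluates ``I[z_0; x_tau]`` along the stationary process with a
    second-order forward difference and one Richardson extrapolation;
    the step is halved until two successive extrapolations agree to
    ``rtol`` (relative) or 1e-10 (absolute).
    """
    lam = relaxation_rate(G)
    pss = steady_state(G)

    def f(tau: float) -> float:
        t = tau / lam if rescaled else tau
        return mi_from_joint(delayed_joint(G, pss, t), base=base)

    def d2(h: float) -> float:
        # second-order one-sided difference at 0
        return (-3.0 * f(0.0) + 4.0 * f(h) - f(2.0 * h)) / (2.0 * h)

    def richardson(h: float) -> float:
        return (4.0 * d2(h / 2.0) - d2(h)) / 3.0

    prev = richardson(step)
    h = step / 2.0
    for _ in range(8):
        cur = richardson(h)
        if abs(cur - prev) <= max(rtol * abs(cur), 1e-10):
            return cur
        prev, h = cur, h / 2.0
    raise ArithmeticError(
        f"finite-difference derivative did not settle (last two: {prev}, {cur})"
    )


def efficiency(G: Generator4, base: float = 2.0, step: float = 1e-4) -> LearningReport:
    """Learning rate, output-marginal dissipation and their ratio.

    Rates are per rescaled time, so the bound ``eta <= 1`` (no-feedback
    models) can be read off directly.
    """
    lam = relaxation_rate(G)
    lx = learning_rate(G, base=base, step=step, rescaled=True)
    sx = sigma_x(G, base=base) / lam
    eta = lx / sx if sx > 0 else (0.0 if abs(lx) < 1e-12 else math.inf)
    return LearningReport(l_x=lx, sigma_x=sx, eta=eta,
                          finite_difference_step=step, base=base)
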