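"""Delayed mutual information and the thermodynamic coupling function.

Information between the initial input state ``z_0`` and the delayed
output ``x_t`` is measured in bits (base-2 logs; a ``base`` argument
allows nats).  On the symmetric class the 2x2 joint is described by a
single order parameter ``mu`` and the mutual information reduces to

    I(mu) = ((1 + mu) log2(1 + mu) + (1 - mu) log2(1 - mu)) / 2,

which is 0 at ``mu = 0`` (independence) and exactly 1 bit at
``|mu| = 1``.
"""

from __future__ import annotations

import numpy as np

from .circuits import DelayedJoint

__all__ = ["mi_from_mu", "mi_from_joint", "coupling_function"]


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x * log(x) with the continuity convention 0 log 0 = 0."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def mi_from_mu(mu: float, base: float = 2.0) -> float:
    """Mutual information of a symmetric binary-binary joint, in bits.

    Symmetric in ``mu -> -mu``; raises for ``|mu| > 1``.
    """
    if abs(mu) > 1.0 + 1e-12:
        raise ValueError(f"|mu| = {abs(mu)} exceeds 1")
    mu = float(np.clip(mu, -1.0, 1.0))
    val = 0.5 * (_xlogx(np.array(1.0 + mu)) + _xlogx(np.array(1.0 - mu)))
    return float(val / np.log(base))


def mi_from_joint(pxz: DelayedJoint | np.ndarray, base: float = 2.0) -> float:
    """Mutual information of an arbitrary 2x2 joint distribution."""
    p = pxz.pxz if isinstance(pxz, DelayedJoint) else np.asarray(pxz, dtype=float)
    if p.shape != (2, 2) or np.any(p < -1e-12):
        raise ValueError("joint must be a non-negative 2x2 table")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"joint sums to {p.sum()}, not 1")
    p = np.clip(p, 0.0, None)
    pz = p.sum(axis=1, keepdims=True)
    px = p.sum(axis=0, keepdims=True)
    mi = float(np.sum(_xlogx(p)) - np.sum(_xlogx(pz)) - np.sum(_xlogx(px)))
    return max(mi, 0.0) / np.log(base)


def coupling_function(pxz: DelayedJoint | np.ndarray, base: float = 2.0) -> np.ndarray:
    """Per-cell log ratio ``log2 p(x,z) / (p(x) p(z))``.

    The table is identically zero iff the joint factorizes; its
    expectation under the joint is the mutual information.  Cells with
    zero joint mass carry a ``-inf`` sentinel (they contribute nothing
    to information sums, where they enter with weight ``p = 0``).
    """
    p = pxz.pxz if isinstance(pxz, DelayedJoint) else np.asarray(pxz, dtype=float)
    pz = p.sum(axis=1, keepdims=True)
    px = p.sum(axis=0, keepdims=True)
    if np.any(pz <= 0) or np.any(px <= 0):
        raise ValueError("coupling function requires strictly positive marginals")
    with np.errstate(divide="ignore"):
        return np.log(p / (pz * px)) / np.log(base)
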