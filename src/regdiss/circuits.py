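"""Four-state symmetric models of a two-component regulatory circuit.

Two binary variables — an input ``z`` and an output ``x``, each inactive
(``-``) or active (``+``) — evolve as a continuous-time Markov chain on
the four joint states.  The global state order, fixed once here, is

    0: (-,-)    1: (-,+)    2: (+,-)    3: (+,+)

i.e. ``(z, x)`` lexicographic with ``-`` before ``+``.  States 0 and 3
are *aligned* (``z == x``), states 1 and 2 *anti-aligned*.

Without feedback the input flips freely at rate ``u`` in both directions,
while the output aligns to the input at rate ``r`` and anti-aligns at
rate ``s``.  With feedback the input flip rates depend on the output
state: the pair anti-aligns at rate ``alpha`` and aligns at rate ``y``
(the output rates ``s``/``r`` are unchanged).  Setting
``alpha == y == u`` recovers the no-feedback chain.

The generator is stored in the standard convention ``Q[i, j]`` = rate of
jumping from state ``j`` to state ``i`` (columns sum to zero), so the
master equation reads ``dp/dt = Q p``.  Where the relaxation-rate
language of a positive spectrum is convenient, the matrix ``L = -Q`` is
exposed.

The symmetry between the pure states (0, 3) and the mixed states (1, 2)
is preserved by both models, so any symmetric distribution

    p = ((1 + mu)/4, (1 - mu)/4, (1 - mu)/4, (1 + mu)/4)

stays in this one-parameter family; ``mu`` is the alignment order
parameter (aligned mass minus anti-aligned mass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "STATE_LABELS",
    "CircuitParams",
    "Generator4",
    "SymDist",
    "DelayedJoint",
    "build_generator",
    "steady_state",
    "relaxation_rate",
    "propagate",
    "delayed_joint",
    "mu_of",
    "ReducibleGeneratorWarning",
]

#: Fixed global state order: (z, x) lexicographic.
STATE_LABELS = (("-", "-"), ("-", "+"), ("+", "-"), ("+", "+"))

_ALIGNED = (0, 3)
_ANTI = (1, 2)


class ReducibleGeneratorWarning(UserWarning):
    """A zero rate makes the chain reducible; results are limit values."""


@dataclass(frozen=True)
class CircuitParams:
    """Rate parameters of a symmetric four-state circuit.

    Parameters
    ----------
    model_kind:
        ``"no_feedback"`` (models S / S~) or ``"feedback"`` (F / F~).
    u:
        Input flip rate (no-feedback model only).
    s:
        Output anti-align rate.
    r:
        Output align rate; the analysis convention is ``r = 1`` (one rate
        can be fixed without loss of generality).
    alpha, y:
        Feedback-model input rates: ``alpha`` anti-aligns the pair,
        ``y`` aligns it.
    """

    model_kind: str
    s: float
    r: float = 1.0
    u: float | None = None
    alpha: float | None = None
    y: float | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in ("no_feedback", "feedback"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind == "no_feedback":
            if self.u is None:
                raise ValueError("no-feedback model requires rate u")
            rates = {"u": self.u, "s": self.s, "r": self.r}
        else:
            if self.alpha is None or self.y is None:
                raise ValueError("feedback model requires rates alpha and y")
            rates = {"alpha": self.alpha, "y": self.y, "s": self.s, "r": self.r}
        for name, v in rates.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name}={v} must be finite and non-negative")
        if self.r <= 0:
            raise ValueError("align rate r must be strictly positive")

    @classmethod
    def no_feedback(cls, u: float, s: float, r: float = 1.0) -> "CircuitParams":
        return cls(model_kind="no_feedback", u=u, s=s, r=r)

    @classmethod
    def feedback(cls, alpha: float, y: float, s: float, r: float = 1.0) -> "CircuitParams":
        return cls(model_kind="feedback", alpha=alpha, y=y, s=s, r=r)


@dataclass(frozen=True)
class Generator4:
    """Generator of the four-state chain.

    ``w[i, j]`` is the transition rate from state ``j`` to state ``i``
    (off-diagonal; the diagonal of ``w`` is zero).
    """

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (4, 4):
            raise ValueError("rate table must be 4x4")
        if np.any(w < 0) or np.any(np.diag(w) != 0):
            raise ValueError("off-diagonal rates must be >= 0, diagonal zero")
        object.__setattr__(self, "w", w)

    @property
    def Q(self) -> np.ndarray:
        """Full generator: off-diagonals of ``w``, columns summing to zero."""
        Q = self.w.copy()
        Q[np.diag_indices(4)] = -Q.sum(axis=0)
        return Q

    @property
    def L(self) -> np.ndarray:
        """Positive-spectrum matrix ``-Q`` used in relaxation language."""
        return -self.Q


@dataclass(frozen=True)
class SymDist:
    """Symmetric four-state distribution parametrized by ``mu`` in [-1, 1]."""

    mu: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.mu <= 1.0 + 1e-12:
            raise ValueError(f"mu={self.mu} outside [-1, 1]")
        object.__setattr__(self, "mu", float(np.clip(self.mu, -1.0, 1.0)))

    @property
    def p(self) -> np.ndarray:
        a = (1.0 + self.mu) / 4.0
        b = (1.0 - self.mu) / 4.0
        return np.array([a, b, b, a])

    @classmethod
    def from_p(cls, p: np.ndarray, tol: float = 1e-8) -> "SymDist":
        p = np.asarray(p, dtype=float)
        _check_simplex(p)
        if abs(p[0] - p[3]) > tol or abs(p[1] - p[2]) > tol:
            raise ValueError("distribution is not in the symmetric class")
        return cls(mu=2.0 * (p[0] + p[3]) - 1.0)


@dataclass(frozen=True)
class DelayedJoint:
    """Joint distribution of the output at time t and the input at time 0.

    ``pxz[z0, xt]`` with index 0 = ``-`` and 1 = ``+``; ``t`` is the
    physical delay and ``tau`` the rescaled delay ``lambda * t`` when the
    relaxation rate is known (``nan`` otherwise).
    """

    pxz: np.ndarray
    t: float
    tau: float = float("nan")

    def __post_init__(self) -> None:
        pxz = np.asarray(self.pxz, dtype=float)
        if pxz.shape != (2, 2):
            raise ValueError("delayed joint must be 2x2")
        _check_simplex(pxz.ravel())
        object.__setattr__(self, "pxz", pxz)

    def as_vector(self) -> np.ndarray:
        """Flatten to the global (z0, xt) order (-,-), (-,+), (+,-), (+,+)."""
        return self.pxz.ravel()


def _check_simplex(p: np.ndarray, tol: float = 1e-9) -> None:
    if np.any(p < -tol):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")


def build_generator(params: CircuitParams) -> Generator4:
    """Assemble the rate table of the circuit.

    Output transitions (both models): an aligned state loses alignment at
    rate ``s`` (0→1, 3→2) and an anti-aligned state aligns at rate ``r``
    (1→0, 2→3).  Input transitions: without feedback ``z`` flips at ``u``
    in both directions (0↔2, 1↔3); with feedback a ``z`` flip out of an
    aligned state runs at ``alpha`` (0→2, 3→1) and into an aligned state
    at ``y`` (2→0, 1→3).
    """
    w = np.zeros((4, 4))
    s, r = params.s, params.r
    # output (x) flips: z fixed
    w[1, 0] = s  # (-,-) -> (-,+)
    w[0, 1] = r  # (-,+) -> (-,-)
    w[2, 3] = s  # (+,+) -> (+,-)
    w[3, 2] = r  # (+,-) -> (+,+)
    # input (z) flips: x fixed
    if params.model_kind == "no_feedback":
        u = params.u
        w[2, 0] = w[0, 2] = u
        w[3, 1] = w[1, 3] = u
    else:
        a, y = params.alpha, params.y
        w[2, 0] = a  # aligned (-,-) -> anti-aligned (+,-)
        w[0, 2] = y  # anti-aligned -> aligned
        w[1, 3] = a  # aligned (+,+) -> anti-aligned (-,+)
        w[3, 1] = y
    return Generator4(w=w)


def steady_state(G: Generator4) -> SymDist:
    """Stationary distribution as a symmetric-class ``SymDist``.

    The unique probability null vector of the generator for irreducible
    chains.  If zero rates make the chain reducible the null space is
    degenerate; the symmetric combination of the limit distributions is
    returned with a :class:`ReducibleGeneratorWarning`.
    """
    ns = null_space(G.Q, rcond=1e-12)
    if ns.shape[1] == 0:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("generator has no null vector")
    if ns.shape[1] > 1:
        warnings.warn(
            "generator is reducible (degenerate stationary state); "
            "returning the symmetric limit distribution",
            ReducibleGeneratorWarning,
            stacklevel=2,
        )
        # symmetrize: project the null space onto the symmetric class
        basis = [v / v.sum() for v in ns.T if abs(v.sum()) > 1e-12]
        p = np.mean(basis, axis=0)
        p = 0.5 * (p + p[::-1])
    else:
        p = ns[:, 0]
        p = p / p.sum()
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    # both circuit models commute with the pure/mixed state swap, so the
    # stationary state is symmetric up to linear-algebra noise
    p = 0.5 * (p + p[::-1])
    return SymDist.from_p(p, tol=1e-6)


def relaxation_rate(G: Generator4) -> float:
    """Smallest non-zero relaxation rate ``lambda`` of the chain.

    The minimum positive real part among the non-zero eigenvalues of
    ``L = -Q``.  For the no-feedback model with ``r = 1`` this equals
    ``min(1 + s, 2u)``; for the feedback model ``(A - rho)/2`` with
    ``A = 1 + s + y + alpha`` and ``rho = sqrt(A^2 - 8(sy + alpha))``
    whenever ``rho`` is real.
    """
    ev = np.linalg.eigvals(G.L)
    scale = max(np.max(np.abs(ev)), 1.0)
    nonzero = [e.real for e in ev if abs(e) > 1e-10 * scale]
    positive = [x for x in nonzero if x > 0]
    if not positive:
        raise ValueError("degenerate model: no non-zero relaxation eigenvalue")
    return float(min(positive))


def propagate(G: Generator4, p0: SymDist | np.ndarray, t: float) -> np.ndarray:
    """Solve the master equation: ``p(t) = expm(Q t) p0``."""
    if t < 0:
        raise ValueError("time must be non-negative")
    p0 = p0.p if isinstance(p0, SymDist) else np.asarray(p0, dtype=float)
    _check_simplex(p0)
    return expm(G.Q * t) @ p0


def delayed_joint(G: Generator4, p0: SymDist | np.ndarray, t: float) -> DelayedJoint:
    """Joint distribution ``p(x_t, z_0)``.

    Each initial four-state ``(z_0, x_0)`` is propagated as a point mass
    through the conditional propagator, the result marginalized over
    ``(z_t, x_0)`` and weighted by the initial joint ``p0``.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    p0 = p0.p if isinstance(p0, SymDist) else np.asarray(p0, dtype=float)
    _check_simplex(p0)
    T = expm(G.Q * t)  # T[i, j] = p(state i at t | state j at 0)
    pxz = np.zeros((2, 2))
    for j in range(4):
        z0 = j >> 1  # z bit of the initial state
        for i in range(4):
            xt = i & 1  # x bit of the final state
            pxz[z0, xt] += T[i, j] * p0[j]
    return DelayedJoint(pxz=pxz, t=t)


def mu_of(pxz: DelayedJoint, tol: float = 1e-8) -> float:
    """Alignment order parameter of a symmetric-class delayed joint.

    ``mu = 2 (p(-,-) + p(+,+)) - 1``: aligned mass minus anti-aligned
    mass.  Refuses joints outside the symmetric class.
    """
    p = pxz.pxz
    if abs(p[0, 0] - p[1, 1]) > tol:
        raise ValueError(
            "joint violates the pure-state symmetry p(-,-) == p(+,+)"
        )
    if abs(p[0, 1] - p[1, 0]) > tol:
        raise ValueError(
            "joint violates the mixed-state symmetry p(-,+) == p(+,-)"
        )
    return float(np.clip(2.0 * (p[0, 0] + p[1, 1]) - 1.0, -1.0, 1.0))
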