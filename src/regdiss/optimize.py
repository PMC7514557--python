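"""Information-optimal circuits under dissipation constraints.

The central problem: maximize the delayed mutual information
``I[x_tau; z_0]`` (readout at rescaled delay ``tau``) over the circuit
rates (``r = 1`` fixed) — and over the initial condition ``mu0`` for the
out-of-steady-state model variants — optionally subject to a fixed
steady-state dissipation ``sigma_hat_ss`` and/or a fixed average
dissipation ``Sigma_avg(tau_p)``.

Model variants:

    S       no feedback, stationary initial condition
    S_tilde no feedback, free initial condition (mu0 optimized)
    F       feedback, stationary initial condition
    F_tilde feedback, free initial condition

The free-``mu0`` domain defaults to [0, 1]: fixing ``r = 1`` breaks the
clockwise/counter-clockwise symmetry and selects the positive branch
(the negative branch can be opened for studying the two-branch
structure of the constrained problem).

Optimization is multistart SLSQP over log-rates, with equality
constraints handled by the solver.  Because the model classes are
nested (no-feedback = feedback with ``alpha == y``; stationary ``mu0``
is one point of the free-``mu0`` domain), richer variants are
warm-started from the optima of their reduced variants, so the nesting
orderings I(S) <= I(F), I(S) <= I(S~), I(F) <= I(F~), I(S~) <= I(F~)
are respected numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .circuits import (
    CircuitParams,
    SymDist,
    build_generator,
    delayed_joint,
    mu_of,
    relaxation_rate,
    steady_state,
)
from .dissipation import sigma_avg as _sigma_avg_report
from .dissipation import sigma_ss_closed
from .info import mi_from_mu

__all__ = [
    "MODELS",
    "OptProblem",
    "OptResult",
    "optimize",
    "optimize_all_models",
    "sweep_tau",
    "cost_comparison",
    "min_cost_at_info",
    "evaluate_suboptimal",
]

#: model name -> (kind, free initial condition?)
MODELS = {
    "S": ("no_feedback", False),
    "S_tilde": ("no_feedback", True),
    "F": ("feedback", False),
    "F_tilde": ("feedback", True),
}

_AGREE_TOL = 1e-4


@dataclass(frozen=True)
class OptProblem:
    """One optimization run.

    ``sigma_hat_ss_target``/``sigma_avg_target`` switch on equality
    constraints (``constraint_mode="le"`` turns them into upper bounds).
    ``mu0_domain`` restricts the free initial condition; the default
    ``(0, 1)`` is the branch selected by the ``r = 1`` convention.
    """

    model: str
    tau: float
    tau_p: float | None = None
    sigma_hat_ss_target: float | None = None
    sigma_avg_target: float | None = None
    rate_bounds: tuple[float, float] = (1e-3, 1e3)
    s_min: float = 1e-6
    mu0_domain: tuple[float, float] = (0.0, 1.0)
    n_starts: int = 24
    seed: int = 0
    constraint_mode: str = "eq"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {sorted(MODELS)}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.tau_p is not None and self.tau_p < self.tau:
            raise ValueError("reset time tau_p must be >= readout time tau")
        if self.constraint_mode not in ("eq", "le"):
            raise ValueError("constraint_mode must be 'eq' or 'le'")

    @property
    def kind(self) -> str:
        return MODELS[self.model][0]

    @property
    def free_mu0(self) -> bool:
        return MODELS[self.model][1]


@dataclass(frozen=True)
class OptResult:
    """Best circuit found for an :class:`OptProblem`."""

    problem: OptProblem
    params: CircuitParams
    mu0: float
    I_star: float
    sigma_hat_ss: float
    sigma_avg: float | None
    constraint_residual: float
    n_restarts_agreeing: int
    objective_per_start: np.ndarray
    feasible: bool
    on_rate_boundary: bool


def _unpack(problem: OptProblem, x: np.ndarray) -> tuple[CircuitParams, float | None]:
    if problem.kind == "no_feedback":
        params = CircuitParams.no_feedback(u=math.exp(x[0]), s=math.exp(x[1]))
        k = 2
    else:
        params = CircuitParams.feedback(
            alpha=math.exp(x[0]), y=math.exp(x[1]), s=math.exp(x[2])
        )
        k = 3
    mu0 = float(x[k]) if problem.free_mu0 else None
    return params, mu0


def _objective_factory(problem: OptProblem):
    # Fixing r = 1 breaks the clockwise/counter-clockwise symmetry and
    # restricts the admissible alignment to mu in [0, 1]: an anti-aligned
    # readout (mu_t < 0, reached by cycling architectures) is excluded by
    # convention and scores zero information.
    def info_of(x: np.ndarray) -> float:
        params, mu0 = _unpack(problem, x)
        G = build_generator(params)
        lam = relaxation_rate(G)
        p0 = SymDist(mu0) if mu0 is not None else steady_state(G)
        dj = delayed_joint(G, p0, problem.tau / lam)
        return mi_from_mu(max(mu_of(dj, tol=1e-6), 0.0))

    return info_of


def _sigma_hat_of(problem: OptProblem, x: np.ndarray) -> float:
    params, _ = _unpack(problem, x)
    return sigma_ss_closed(params, rescaled=True)


def _sigma_avg_of(problem: OptProblem, x: np.ndarray, rtol: float = 1e-7) -> float:
    params, mu0 = _unpack(problem, x)
    G = build_generator(params)
    p0 = SymDist(mu0) if mu0 is not None else steady_state(G)
    return _sigma_avg_report(G, p0, problem.tau_p, n_trace=2, quad_rtol=rtol).sigma_avg


def _bounds_and_starts(problem: OptProblem, rng: np.random.Generator,
                       warm_starts: list[np.ndarray]) -> tuple[list, list]:
    lo, hi = np.log(problem.rate_bounds[0]), np.log(problem.rate_bounds[1])
    # the anti-align rate s is allowed closer to its irreversible s = 0
    # boundary than the input rates; the unconstrained optimum sits there
    s_lo = min(lo, math.log(problem.s_min))
    if problem.kind == "no_feedback":
        bounds = [(lo, hi), (s_lo, hi)]
    else:
        bounds = [(lo, hi), (lo, hi), (s_lo, hi)]
    if problem.free_mu0:
        bounds.append(problem.mu0_domain)
    starts = []
    for w in warm_starts:
        starts.append(np.clip(w, [b[0] for b in bounds], [b[1] for b in bounds]))
    while len(starts) < problem.n_starts:
        # starts stay log-uniform inside the nominal rate box
        x = [rng.uniform(lo, hi) for _ in bounds[: len(bounds) - problem.free_mu0]]
        if problem.free_mu0:
            x.append(rng.uniform(*problem.mu0_domain))
        starts.append(np.array(x))
    return bounds, starts


def optimize(problem: OptProblem, warm_starts: list[np.ndarray] | None = None) -> OptResult:
    """Multistart constrained maximization of the delayed information.

    An infeasible constraint (e.g. an average-dissipation target the
    circuit cannot reach at the required ``sigma_hat_ss``) yields a
    result with ``feasible=False`` rather than a silent failure.
    """
    rng = np.random.default_rng(problem.seed)
    info_of = _objective_factory(problem)
    bounds, starts = _bounds_and_starts(problem, rng, list(warm_starts or []))

    constraints = []
    if problem.sigma_hat_ss_target is not None:
        tgt = problem.sigma_hat_ss_target
        if problem.constraint_mode == "eq":
            constraints.append(
                {"type": "eq", "fun": lambda x: _sigma_hat_of(problem, x) - tgt}
            )
        else:
            constraints.append(
                {"type": "ineq", "fun": lambda x: tgt - _sigma_hat_of(problem, x)}
            )
    if problem.sigma_avg_target is not None:
        if problem.tau_p is None:
            raise ValueError("sigma_avg_target requires tau_p")
        tgt2 = problem.sigma_avg_target
        if problem.constraint_mode == "eq":
            constraints.append(
                {"type": "eq", "fun": lambda x: _sigma_avg_of(problem, x) - tgt2}
            )
        else:
            constraints.append(
                {"type": "ineq", "fun": lambda x: tgt2 - _sigma_avg_of(problem, x)}
            )

    def residual(x: np.ndarray) -> float:
        if not constraints:
            return 0.0
        return max(
            (abs(c["fun"](x)) if c["type"] == "eq" else max(0.0, -c["fun"](x)))
            for c in constraints
        )

    def evaluate(x: np.ndarray) -> tuple[float, float]:
        try:
            resid = residual(x)
            val = info_of(x) if resid < 1e-6 else -np.inf
        except (ValueError, FloatingPointError, ArithmeticError):
            return -np.inf, np.inf
        return val, resid

    best = None
    per_start = []
    for x0 in starts:
        # the start itself is a candidate: a feasible warm start must never
        # be lost to a local-solver failure
        cand = [x0]
        try:
            res = minimize(
                lambda x: -info_of(x),
                x0,
                method="SLSQP",
                bounds=bounds,
                constraints=constraints,
                options={"maxiter": 200, "ftol": 1e-9},
            )
            cand.append(res.x)
        except (ValueError, FloatingPointError):  # pathological corner of the box
            pass
        scored = [(x,) + evaluate(x)[::-1] for x in cand]
        x, resid, val = max(scored, key=lambda t: t[2])
        per_start.append(val if np.isfinite(val) else np.nan)
        if np.isfinite(val) and (best is None or val > best[0]):
            best = (val, x, resid)

    per_start = np.array(per_start, dtype=float)
    if best is None:
        # no start satisfied the constraints: report the least-violating point
        x_any = starts[0]
        params, mu0 = _unpack(problem, x_any)
        return OptResult(
            problem=problem, params=params, mu0=float("nan"),
            I_star=float("nan"), sigma_hat_ss=float("nan"), sigma_avg=None,
            constraint_residual=float("inf"), n_restarts_agreeing=0,
            objective_per_start=per_start, feasible=False, on_rate_boundary=False,
        )

    val, x, resid = best
    params, mu0 = _unpack(problem, x)
    G = build_generator(params)
    if mu0 is None:
        mu0 = steady_state(G).mu
    shat = sigma_ss_closed(params, rescaled=True)
    savg = None
    if problem.tau_p is not None:
        savg = _sigma_avg_report(G, SymDist(mu0), problem.tau_p, n_trace=2).sigma_avg
    n_rates = 2 if problem.kind == "no_feedback" else 3
    log_rates = x[:n_rates]
    rate_bounds, _ = _bounds_and_starts(problem, np.random.default_rng(0), [])
    on_boundary = bool(
        any(abs(v - b[0]) < 1e-6 or abs(v - b[1]) < 1e-6
            for v, b in zip(log_rates, rate_bounds[:n_rates]))
    )
    agreeing = int(np.sum(np.nan_to_num(per_start, nan=-np.inf) > val - _AGREE_TOL))
    return OptResult(
        problem=problem, params=params, mu0=float(mu0), I_star=float(val),
        sigma_hat_ss=float(shat), sigma_avg=savg,
        constraint_residual=float(resid), n_restarts_agreeing=agreeing,
        objective_per_start=per_start, feasible=True, on_rate_boundary=on_boundary,
    )


def _warm_from(result: OptResult, target: OptProblem) -> np.ndarray:
    """Embed a reduced-model optimum into a richer model's coordinates."""
    p = result.params
    if p.model_kind == "no_feedback":
        logs = [math.log(max(p.u, 1e-300)), math.log(max(p.s, 1e-300))]
        if target.kind == "feedback":
            logs = [logs[0], logs[0], logs[1]]  # alpha = y = u
    else:
        logs = [math.log(max(p.alpha, 1e-300)), math.log(max(p.y, 1e-300)),
                math.log(max(p.s, 1e-300))]
    if target.free_mu0:
        logs.append(float(np.clip(result.mu0, *target.mu0_domain)))
    return np.array(logs)


def optimize_all_models(tau: float, tau_p: float | None = None,
                        sigma_hat_ss_target: float | None = None,
                        n_starts: int = 24, seed: int = 0) -> dict[str, OptResult]:
    """Optimize all four variants with nested warm starts (S -> S~, F; F, S~ -> F~)."""
    base = OptProblem(model="S", tau=tau, tau_p=tau_p,
                      sigma_hat_ss_target=sigma_hat_ss_target,
                      n_starts=n_starts, seed=seed)
    out: dict[str, OptResult] = {}
    out["S"] = optimize(base)
    prob_St = replace(base, model="S_tilde")
    out["S_tilde"] = optimize(prob_St, warm_starts=[_warm_from(out["S"], prob_St)])
    prob_F = replace(base, model="F")
    out["F"] = optimize(prob_F, warm_starts=[_warm_from(out["S"], prob_F)])
    prob_Ft = replace(base, model="F_tilde")
    out["F_tilde"] = optimize(
        prob_Ft,
        warm_starts=[_warm_from(out["F"], prob_Ft), _warm_from(out["S_tilde"], prob_Ft)],
    )
    return out


def sweep_tau(template: OptProblem, taus) -> pd.DataFrame:
    """Re-solve the template problem on a grid of readout times."""
    rows = []
    warm: list[np.ndarray] = []
    for tau in taus:
        prob = replace(template, tau=tau,
                       tau_p=None if template.tau_p is None else max(template.tau_p, tau))
        res = optimize(prob, warm_starts=warm)
        if res.feasible:
            warm = [_warm_from(res, prob)]
        rows.append({
            "model": prob.model, "tau": tau, "I_star": res.I_star,
            "mu0": res.mu0, "sigma_hat_ss": res.sigma_hat_ss,
            "feasible": res.feasible,
            "constraint_residual": res.constraint_residual,
        })
    return pd.DataFrame(rows)


def min_cost_at_info(model: str, tau: float, tau_p: float, info_floor: float,
                     sigma_hat_ss_target: float | None = None,
                     n_starts: int = 12, seed: int = 0,
                     warm_starts: list[np.ndarray] | None = None) -> OptResult | None:
    """Cheapest circuit of a model class transmitting at least ``info_floor``.

    Minimizes ``Sigma_avg(tau_p)`` subject to the steady-state
    dissipation constraint (if any) and ``I(tau) >= info_floor``.  The
    delayed-information maximum is extremely flat near its optimum, so
    the *cost of optimal information* is best characterized this way:
    the max-I point of a richer model class can be more expensive than
    that of a nested class even though the richer class can always match
    the nested class's information at equal or lower cost.
    """
    problem = OptProblem(model=model, tau=tau, tau_p=tau_p,
                         sigma_hat_ss_target=sigma_hat_ss_target,
                         n_starts=n_starts, seed=seed)
    rng = np.random.default_rng(seed)
    info_of = _objective_factory(problem)
    bounds, starts = _bounds_and_starts(problem, rng, list(warm_starts or []))
    constraints = [{"type": "ineq", "fun": lambda x: info_of(x) - info_floor}]
    if sigma_hat_ss_target is not None:
        constraints.append(
            {"type": "eq",
             "fun": lambda x: _sigma_hat_of(problem, x) - sigma_hat_ss_target}
        )
    best = None
    for x0 in starts:
        try:
            res = minimize(lambda x: _sigma_avg_of(problem, x), x0,
                           method="SLSQP", bounds=bounds, constraints=constraints,
                           options={"maxiter": 200, "ftol": 1e-9})
        except (ValueError, FloatingPointError, ArithmeticError):
            continue
        for x in (x0, res.x):
            try:
                ok = info_of(x) >= info_floor - 1e-6 and (
                    sigma_hat_ss_target is None
                    or abs(_sigma_hat_of(problem, x) - sigma_hat_ss_target) < 1e-6
                )
                if not ok:
                    continue
                cost = _sigma_avg_of(problem, x)
            except (ValueError, FloatingPointError, ArithmeticError):
                continue
            if best is None or cost < best[0]:
                best = (cost, x)
    if best is None:
        return None
    cost, x = best
    params, mu0 = _unpack(problem, x)
    if mu0 is None:
        mu0 = steady_state(build_generator(params)).mu
    return OptResult(
        problem=problem, params=params, mu0=float(mu0),
        I_star=float(info_of(x)),
        sigma_hat_ss=float(sigma_ss_closed(params, rescaled=True)),
        sigma_avg=float(cost), constraint_residual=0.0, n_restarts_agreeing=0,
        objective_per_start=np.array([]), feasible=True, on_rate_boundary=False,
    )


def cost_comparison(tau: float, tau_p: float,
                    sigma_hat_ss_target: float | None = None,
                    n_starts: int = 24, seed: int = 0,
                    matched_info: bool = False) -> pd.DataFrame:
    """Information and dissipative cost of the four optimal variants.

    For the stationary-initial-condition models the average dissipation
    equals the steady-state value (the relaxation cost vanishes); the
    information gain column is the free-``mu0`` optimum minus the
    stationary optimum of the same feedback class.  With
    ``matched_info=True`` an extra column reports, for the free-``mu0``
    models, the minimum cost of transmitting at least the no-feedback
    free-``mu0`` optimum's information (see :func:`min_cost_at_info`).
    """
    results = optimize_all_models(tau, tau_p=tau_p,
                                  sigma_hat_ss_target=sigma_hat_ss_target,
                                  n_starts=n_starts, seed=seed)
    matched: dict[str, float] = {}
    if matched_info:
        floor = results["S_tilde"].I_star
        for name in ("S_tilde", "F_tilde"):
            # the embedded no-feedback optimum is always a feasible start
            # for the matched-information problem, so mc(F~) <= mc(S~)
            prob = OptProblem(model=name, tau=tau, tau_p=tau_p,
                              sigma_hat_ss_target=sigma_hat_ss_target)
            warm = [_warm_from(results["S_tilde"], prob),
                    _warm_from(results[name], prob)]
            mc = min_cost_at_info(name, tau, tau_p, floor,
                                  sigma_hat_ss_target=sigma_hat_ss_target,
                                  n_starts=max(n_starts // 4, 4), seed=seed,
                                  warm_starts=warm)
            if mc is not None:
                matched[name] = mc.sigma_avg
    rows = []
    for name, res in results.items():
        gain = None
        if name.endswith("_tilde"):
            gain = res.I_star - results[name[0]].I_star
        savg = res.sigma_avg if res.sigma_avg is not None else float("nan")
        rows.append({
            "model": name, "tau": tau, "tau_p": tau_p,
            "I_star": res.I_star, "mu0": res.mu0,
            "sigma_hat_ss": res.sigma_hat_ss, "sigma_avg": savg,
            "total_cost": tau_p * savg,
            "relaxation_cost": tau_p * (savg - res.sigma_hat_ss),
            "information_gain": gain,
            "matched_info_cost": matched.get(name),
            "feasible": res.feasible,
        })
    return pd.DataFrame(rows)


def evaluate_suboptimal(params: CircuitParams, mu0_grid, tau: float,
                        tau_p: float) -> pd.DataFrame:
    """Fix an optimal circuit's rates and scan the initial condition.

    Reports the transmitted information and the average dissipation for
    each ``mu0``; information peaks at the optimizing ``mu0`` while the
    average dissipation need not.
    """
    G = build_generator(params)
    lam = relaxation_rate(G)
    rows = []
    for mu0 in mu0_grid:
        p0 = SymDist(float(mu0))
        dj = delayed_joint(G, p0, tau / lam)
        rep = _sigma_avg_report(G, p0, tau_p, n_trace=2)
        rows.append({
            "mu0": float(mu0),
            # positive-branch readout, as in the optimization objective
            "I": mi_from_mu(max(mu_of(dj, tol=1e-6), 0.0)),
            "sigma_avg": rep.sigma_avg,
        })
    return pd.DataFrame(rows)
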