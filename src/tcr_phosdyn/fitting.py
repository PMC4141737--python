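"""Parameter estimation for stochastic rule-based models.

Parameters come in three classes: literature-fixed (never varied), derived
(arithmetic expressions over other parameters, evaluated in dependency
order), and fitted.  Fitted parameters are estimated in two stages against
site-level relative time courses: a coarse grid search over the full box,
then quasi-Newton (variable-metric) refinement from the grid optimum.

The objective is the sum over sites and grid times of squared differences
between log2 simulated relative phosphorylation (averaged over ``n_runs``
runs) and log2 measured mean ratios.  Common random numbers — the same base
seed, hence the same per-run seed stream, at every evaluation — make the
Monte Carlo objective a deterministic function of the parameters, which is
what lets a descent method work on it.

Positivity-only parameters are optimized in log10 space; box bounds are
enforced by the bounded quasi-Newton step itself.
"""

from __future__ import annotations

import ast
import itertools
import math
import operator
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .nf_sim import SimProtocol, average_runs, mean_course, simulate
from .rule_model import ModelSpec

__all__ = [
    "ParameterSpec",
    "FitResult",
    "resolve_derived",
    "build_objective",
    "grid_search",
    "refine",
    "fit",
]


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter and how it is determined.

    kind: 'fixed' (literature value, never varied), 'derived' (expression
    over other parameters), or 'fitted'.  Fitted parameters carry bounds;
    (None, None) means positivity-only, handled in log space.
    """

    name: str
    kind: str
    value: Optional[float] = None
    expression: Optional[str] = None
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("fixed", "derived", "fitted"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "derived" and not self.expression:
            raise ValueError(f"derived parameter {self.name} needs an expression")
        if self.kind == "fixed" and self.value is None:
            raise ValueError(f"fixed parameter {self.name} needs a value")


@dataclass
class FitResult:
    parameters: dict[str, float]
    objective: float
    stage: str  # 'grid' | 'refined'
    n_evaluations: int
    base_seed: int
    history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# derived-parameter resolution (safe arithmetic evaluator)

_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
    ast.Pow: operator.pow,
}


def _eval_expr(node: ast.AST, env: Mapping[str, float]) -> float:
    if isinstance(node, ast.Expression):
        return _eval_expr(node.body, env)
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return float(node.value)
    if isinstance(node, ast.Name):
        if node.id not in env:
            raise KeyError(node.id)
        return env[node.id]
    if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        return _BINOPS[type(node.op)](_eval_expr(node.left, env), _eval_expr(node.right, env))
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        return -_eval_expr(node.operand, env)
    raise ValueError(f"unsupported expression construct {ast.dump(node)}")


def _expr_names(expression: str) -> set[str]:
    return {n.id for n in ast.walk(ast.parse(expression, mode="eval")) if isinstance(n, ast.Name)}


def resolve_derived(
    specs: Sequence[ParameterSpec], fitted_values: Mapping[str, float]
) -> dict[str, float]:
    """Full numeric parameter table: fixed values pass through, fitted values
    come from ``fitted_values``, derived expressions evaluate in topological
    order.  A dependency cycle raises with the cycle named.
    """
    env: dict[str, float] = {}
    for s in specs:
        if s.kind == "fixed":
            env[s.name] = float(s.value)
        elif s.kind == "fitted":
            if s.name not in fitted_values:
                raise KeyError(f"no value supplied for fitted parameter {s.name!r}")
            env[s.name] = float(fitted_values[s.name])

    pending = {s.name: s for s in specs if s.kind == "derived"}
    while pending:
        progressed = []
        for name, s in pending.items():
            deps = _expr_names(s.expression)
            if deps <= set(env):
                env[name] = _eval_expr(ast.parse(s.expression, mode="eval"), env)
                progressed.append(name)
        if not progressed:
            unresolved = sorted(pending)
            for name in unresolved:
                missing = _expr_names(pending[name].expression) - set(env)
                if missing - set(pending):
                    raise KeyError(
                        f"derived parameter {name!r} references unknown {sorted(missing - set(pending))}"
                    )
            raise ValueError(f"cyclic derived-parameter definitions among {unresolved}")
        for name in progressed:
            del pending[name]
    return env


# ---------------------------------------------------------------------------
# objective


def build_objective(
    spec_builder: Callable[[Mapping[str, float]], ModelSpec],
    data: Mapping[str, Sequence[float]],
    protocol: SimProtocol,
    n_runs: int,
    base_seed: int,
    eps: float = 0.5,
) -> Callable[[Mapping[str, float]], float]:
    """Sum-of-squares log2 objective over sites and post-baseline grid times.

    ``spec_builder`` maps a fitted-parameter dict to a ModelSpec whose
    observables include every key of ``data``; ``data`` maps observable names
    to measured mean relative ratios on ``protocol.grid`` (the t=0 entry, 1
    by construction, carries no information and is skipped).  Evaluations use
    common random numbers: run i always uses seed ``base_seed + i``.
    """

    def objective(params: Mapping[str, float]) -> float:
        model = spec_builder(params)
        obs_names = {o.name for o in model.observables}
        missing = set(data) - obs_names
        if missing:
            raise KeyError(f"data sites without model observables: {sorted(missing)}")
        trajs = [
            simulate(model, protocol, seed=base_seed + i, run_index=i)
            for i in range(n_runs)
        ]
        averaged = average_runs(trajs)
        total = 0.0
        for site, measured in data.items():
            times, values = mean_course(averaged, site)
            v0 = values[0]
            rel = (values + eps) / (v0 + eps) if v0 == 0 else values / v0
            meas = np.asarray(measured, dtype=float)
            if len(meas) != len(times):
                raise ValueError(f"data for {site} does not match the protocol grid")
            resid = np.log2(np.maximum(rel[1:], 1e-9)) - np.log2(np.maximum(meas[1:], 1e-9))
            total += float((resid ** 2).sum())
        return total

    return objective


# ---------------------------------------------------------------------------
# grid search + variable-metric refinement


def grid_search(
    objective: Callable[[Mapping[str, float]], float],
    grids: Mapping[str, Sequence[float]],
    base_seed: int = 0,
) -> FitResult:
    """Exhaustive evaluation of the Cartesian grid; ties break to the first
    point in enumeration order (sorted parameter names, row-major)."""
    names = sorted(grids)
    if any(len(grids[n]) == 0 for n in names):
        raise ValueError("empty grid")
    best, best_f = None, np.inf
    history = []
    n_eval = 0
    for combo in itertools.product(*(grids[n] for n in names)):
        params = dict(zip(names, combo))
        f = objective(params)
        n_eval += 1
        history.append((params, f))
        if f < best_f:
            best, best_f = params, f
    return FitResult(
        parameters=dict(best),
        objective=float(best_f),
        stage="grid",
        n_evaluations=n_eval,
        base_seed=base_seed,
        history=history,
    )


def refine(
    objective: Callable[[Mapping[str, float]], float],
    start: Mapping[str, float],
    bounds: Optional[Mapping[str, tuple[Optional[float], Optional[float]]]] = None,
    base_seed: int = 0,
    maxiter: int = 40,
    fd_step: float = 1e-6,
    max_evaluations: int = 120,
) -> FitResult:
    """Bounded quasi-Newton (variable-metric) refinement from ``start``.

    Parameters with (None, None) bounds are positivity-only and move in
    log10 space; box-bounded parameters are constrained directly.  Gradients
    are finite-difference with step ``fd_step`` (log10 units for
    positivity-only parameters).  For a common-random-numbers Monte Carlo
    objective — deterministic but jagged at fine scales — pass a coarse step
    (~0.05) so the gradient averages over the jaggedness.  The returned
    point is never worse than the start.
    """
    names = sorted(start)
    bounds = bounds or {}
    logspace = [bounds.get(n, (None, None)) == (None, None) for n in names]

    def encode(params: Mapping[str, float]) -> np.ndarray:
        return np.array(
            [math.log10(params[n]) if ls else params[n] for n, ls in zip(names, logspace)]
        )

    def decode(x: np.ndarray) -> dict[str, float]:
        return {
            n: (10.0 ** xi if ls else float(xi))
            for n, xi, ls in zip(names, x, logspace)
        }

    n_eval = 0

    def f(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return objective(decode(x))

    x0 = encode(start)
    f0 = f(x0)
    if not np.isfinite(f0):
        raise ValueError("objective not finite at the starting point")
    opt_bounds = [
        (None, None) if ls else bounds.get(n, (None, None))
        for n, ls in zip(names, logspace)
    ]
    res = minimize(
        f, x0, method="L-BFGS-B", bounds=opt_bounds,
        options={"maxiter": maxiter, "eps": fd_step, "maxfun": max_evaluations},
    )
    x_best, f_best = (res.x, float(res.fun)) if res.fun <= f0 else (x0, f0)
    return FitResult(
        parameters=decode(x_best),
        objective=f_best,
        stage="refined",
        n_evaluations=n_eval,
        base_seed=base_seed,
    )


def fit(
    objective: Callable[[Mapping[str, float]], float],
    grids: Mapping[str, Sequence[float]],
    bounds: Optional[Mapping[str, tuple[Optional[float], Optional[float]]]] = None,
    base_seed: int = 0,
    fd_step: float = 1e-6,
) -> tuple[FitResult, FitResult]:
    """Coarse grid search followed by variable-metric refinement.

    Returns (grid stage, refined stage); the refined objective never exceeds
    the grid objective.
    """
    grid_result = grid_search(objective, grids, base_seed=base_seed)
    refined = refine(
        objective, grid_result.parameters, bounds=bounds, base_seed=base_seed,
        fd_step=fd_step,
    )
    if refined.objective > grid_result.objective:  # safeguarded by refine already
        refined = FitResult(
            parameters=grid_result.parameters,
            objective=grid_result.objective,
            stage="refined",
            n_evaluations=refined.n_evaluations,
            base_seed=base_seed,
        )
    return grid_result, refined
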