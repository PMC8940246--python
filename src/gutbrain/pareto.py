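"""Multi-objective (pareto) flux optimization for multicellular models.

In a community every cell type carries its own biomass (or maintenance)
objective and is expected to maximize its own growth regardless of the
others.  A pareto-optimal point — a feasible objective vector not dominated
componentwise by any other feasible vector — is found by advancing all
objectives together from their per-objective minima:

* **linear search** (equal weights): all objective lower bounds advance by
  equal per-objective increments of ``(max_i - min_i) / max_iterations``
  until the LP turns infeasible; the last feasible point is returned.
* **binary search** (arbitrary weights): the search ray from the minima has
  direction proportional to the weights (e.g. a 20%:80% abundance split
  advances the two objectives at a 1:4 ratio); the furthest feasible scaling
  along the ray is found by bisection.

Stopping criteria are a maximum iteration count and the Euclidean norm of
the difference between subsequent iterates falling below a tolerance.

Because the feasible region is convex and contains the starting point,
feasibility along the search ray is monotone; the linear scan is therefore
implemented as a bisection over the integer step count, which returns the
identical point with O(log max_iterations) LP solves.

Class-abundance weights follow the community weighting scheme: the host is
fixed at ``host_weight`` (default 1/6) and the remaining share is split
between the beneficial and harmful member classes according to the
beneficial-abundance percentage, equally within each class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
from cobra.core.solution import get_solution

from .core import FluxSolution, _status, verified_feasible

__all__ = [
    "ParetoProblem",
    "ParetoSolution",
    "compute_weights",
    "pareto_linear_search",
    "pareto_binary_search",
    "solve_pareto",
    "fix_pareto_state",
]

_WEIGHT_ATOL = 1e-9


@dataclass
class ParetoProblem:
    """A multi-objective maximization over one stoichiometric model."""

    model: cobra.Model
    objectives: list[str]
    weights: list[float] | None = None
    max_iterations: int = 100
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        for rid in self.objectives:
            if rid not in self.model.reactions:
                raise ValueError(f"objective reaction {rid!r} not in model")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != len(self.objectives):
                raise ValueError("weights and objectives differ in length")
            if (w < -_WEIGHT_ATOL).any() or abs(w.sum() - 1.0) > _WEIGHT_ATOL:
                raise ValueError("weights must be >= 0 and sum to 1")


@dataclass
class ParetoSolution:
    """A feasible, non-dominated objective vector and the fluxes realizing it."""

    objective_ids: list[str]
    objective_fluxes: np.ndarray
    fluxes: pd.Series | None
    iterations: int
    converged: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.objective_ids, map(float, self.objective_fluxes)))


def compute_weights(
    beneficial_percent: float,
    beneficial_ids: Sequence[str],
    harmful_ids: Sequence[str],
    host_id: str | None = None,
    host_weight: float = 1.0 / 6.0,
) -> dict[str, float]:
    """Abundance-derived objective weights for a two-class community + host.

    The host biomass keeps a fixed weight (default 1/6).  The remaining
    ``1 - host_weight`` is split ``beneficial_percent : (100 -
    beneficial_percent)`` between the beneficial and harmful classes and
    divided equally within each class.  The returned weights sum to 1.
    """
    if not 0 <= beneficial_percent <= 100:
        raise ValueError("beneficial_percent must be in [0, 100]")
    if not 0 <= host_weight < 1:
        raise ValueError("host_weight must be in [0, 1)")
    if host_id is None:
        host_weight = 0.0
    remaining = 1.0 - host_weight
    ben_share = remaining * beneficial_percent / 100.0
    harm_share = remaining - ben_share
    if ben_share > 0 and not beneficial_ids:
        raise ValueError("beneficial class share is nonzero but the class is empty")
    if harm_share > 0 and not harmful_ids:
        raise ValueError("harmful class share is nonzero but the class is empty")
    weights: dict[str, float] = {}
    for rid in beneficial_ids:
        weights[rid] = ben_share / len(beneficial_ids)
    for rid in harmful_ids:
        weights[rid] = harm_share / len(harmful_ids)
    if host_id is not None:
        weights[host_id] = host_weight
    return weights


def _objective_bounds(model: cobra.Model, rid: str) -> tuple[float, float]:
    """Min and max of a single objective flux under the current constraints."""
    rxn = model.reactions.get_by_id(rid)
    model.objective = model.problem.Objective(rxn.flux_expression, direction="min")
    lo = model.slim_optimize(error_value=float("nan"))
    if _status(model) != "optimal":
        raise ValueError("no feasible community state")
    model.objective.direction = "max"
    hi = model.slim_optimize(error_value=float("nan"))
    if _status(model) != "optimal":
        if _status(model) == "unbounded":
            raise ValueError(f"objective {rid!r} is unbounded")
        raise ValueError("no feasible community state")
    return float(lo), float(hi)


def _set_floor(rxn, value: float) -> None:
    """Raise a reaction's lower bound to ``value``, snapping to the upper
    bound when the gap is below round-off (hair-width bound pairs can crash
    the LP backend's scaled simplex)."""
    ub = rxn.upper_bound
    v = min(float(value), ub)
    if ub - v < 1e-9 * max(1.0, abs(ub)):
        v = ub
    if v > rxn.lower_bound:
        rxn.lower_bound = v


def _feasible(model: cobra.Model, objectives: Sequence[str], point: np.ndarray) -> bool:
    """Can every objective simultaneously reach at least its target value?"""
    with model:
        for rid, value in zip(objectives, point):
            rxn = model.reactions.get_by_id(rid)
            if value > rxn.upper_bound + 1e-9:
                return False
            _set_floor(rxn, value)
        return verified_feasible(model)


def _solution_at(
    problem: ParetoProblem, point: np.ndarray, iterations: int, converged: bool
) -> ParetoSolution:
    model = problem.model
    scale = max(1.0, float(np.abs(point).max(initial=0.0)))
    solution = None
    # a point sitting exactly on a facet can be rejected by the solver at
    # strict tolerance; back the lower bounds off by a vanishing amount
    for relax in (0.0, 1e-9, 1e-7, 1e-6):
        with model:
            for rid, value in zip(problem.objectives, point):
                rxn = model.reactions.get_by_id(rid)
                _set_floor(rxn, float(value) - relax * scale)
            expr = sum(
                model.reactions.get_by_id(rid).flux_expression
                for rid in problem.objectives
            )
            model.objective = model.problem.Objective(expr, direction="max")
            model.slim_optimize(error_value=float("nan"))
            if _status(model) == "optimal":
                solution = get_solution(model)
                break
    if solution is None:
        raise ValueError("pareto point unexpectedly infeasible")
    fluxes = solution.fluxes
    realized = np.array([fluxes[rid] for rid in problem.objectives], dtype=float)
    return ParetoSolution(
        objective_ids=list(problem.objectives),
        objective_fluxes=realized,
        fluxes=fluxes,
        iterations=iterations,
        converged=converged,
    )


def pareto_linear_search(problem: ParetoProblem) -> ParetoSolution:
    """Equal-weight pareto optimization by linear advance from the minima.

    Starting from the per-objective minimum fluxes, all objective lower
    bounds advance by equal increments of ``(max_i - min_i) /
    max_iterations`` while the LP stays feasible; the last feasible point is
    returned.
    """
    if problem.weights is not None:
        w = np.asarray(problem.weights, dtype=float)
        if not np.allclose(w, w[0]):
            raise ValueError("linear search requires equal weights")
    model = problem.model
    objectives = problem.objectives
    mins, maxs = [], []
    with model:
        for rid in objectives:
            lo, hi = _objective_bounds(model, rid)
            mins.append(lo)
            maxs.append(hi)
    mins = np.asarray(mins)
    maxs = np.asarray(maxs)
    if len(objectives) == 1:
        return _solution_at(problem, maxs, iterations=1, converged=True)
    steps = (maxs - mins) / problem.max_iterations
    step_norm = float(np.linalg.norm(steps))
    if step_norm < problem.tolerance:
        return _solution_at(problem, mins, iterations=0, converged=True)
    # feasibility along the ray is monotone (convex feasible set containing
    # the start), so bisect over the integer step count ...
    lo_k, hi_k = 0, problem.max_iterations
    if _feasible(model, objectives, mins + steps * hi_k):
        lo_k = hi_k
    while hi_k - lo_k > 1:
        mid = (lo_k + hi_k) // 2
        if _feasible(model, objectives, mins + steps * mid):
            lo_k = mid
        else:
            hi_k = mid
    point = mins + steps * lo_k
    iterations = lo_k
    # ... then keep advancing with halved increments until the step norm
    # falls below tolerance, so the returned point sits on the front rather
    # than on the last integer grid point
    step = steps.copy()
    while (
        float(np.linalg.norm(step)) >= problem.tolerance
        and iterations < problem.max_iterations
    ):
        candidate = point + step
        if _feasible(model, objectives, candidate):
            point = candidate
        else:
            step = step / 2.0
        iterations += 1
    converged = float(np.linalg.norm(step)) < problem.tolerance
    return _solution_at(problem, point, iterations=iterations, converged=converged)


def pareto_binary_search(problem: ParetoProblem) -> ParetoSolution:
    """Weighted pareto optimization by bisection along the weight ray.

    The search ray starts at the per-objective minima with direction
    proportional to the weights; bisection finds the furthest feasible
    scaling.  Stops when the remaining interval norm falls below the
    tolerance or ``max_iterations`` is reached.
    """
    if problem.weights is None:
        raise ValueError("binary search requires weights")
    model = problem.model
    objectives = problem.objectives
    d = np.asarray(problem.weights, dtype=float)
    mins, maxs = [], []
    with model:
        for rid in objectives:
            lo, hi = _objective_bounds(model, rid)
            mins.append(lo)
            maxs.append(hi)
    mins = np.asarray(mins)
    maxs = np.asarray(maxs)
    active = d > 0
    if not active.any() or np.allclose(maxs, mins):
        return _solution_at(problem, mins, iterations=0, converged=True)
    t_hi = float(np.max((maxs[active] - mins[active]) / d[active]))
    d_norm = float(np.linalg.norm(d))
    t_lo = 0.0
    if _feasible(model, objectives, mins + t_hi * d):
        t_lo = t_hi
    iterations = 0
    while (t_hi - t_lo) * d_norm > problem.tolerance and iterations < problem.max_iterations:
        mid = 0.5 * (t_lo + t_hi)
        if _feasible(model, objectives, mins + mid * d):
            t_lo = mid
        else:
            t_hi = mid
        iterations += 1
    converged = (t_hi - t_lo) * d_norm <= problem.tolerance
    return _solution_at(problem, mins + t_lo * d, iterations=iterations, converged=converged)


def solve_pareto(problem: ParetoProblem) -> ParetoSolution:
    """Dispatch to linear (equal/absent weights) or binary (weighted) search."""
    if problem.weights is None:
        return pareto_linear_search(problem)
    w = np.asarray(problem.weights, dtype=float)
    if np.allclose(w, w[0]):
        return pareto_linear_search(problem)
    return pareto_binary_search(problem)


def fix_pareto_state(
    model: cobra.Model,
    solution: ParetoSolution,
    slack: float = 0.0,
) -> cobra.Model:
    """Pin each objective reaction's bounds to its pareto flux (in place).

    By default the bounds are pinned exactly (lb = ub = value); a symmetric
    ``slack`` may be supplied to absorb LP round-off.  Raises if the pinned
    state is infeasible beyond tolerance.  Used before toxin FVA or
    secretion maximization so that variability is explored at fixed growth.
    """
    for rid, value in zip(solution.objective_ids, solution.objective_fluxes):
        rxn = model.reactions.get_by_id(rid)
        rxn.bounds = (float(value) - slack, float(value) + slack)
    with model:
        if not verified_feasible(model, tol=max(1e-6, 10 * slack)):
            raise ValueError("pinning the pareto state makes the model infeasible")
    return model
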