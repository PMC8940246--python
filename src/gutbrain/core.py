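"""Core constraint-based model contracts: SBML I/O, FBA, and FVA.

The in-memory model container is :class:`cobra.Model` (stoichiometric matrix
``S``, flux vector ``v``, and per-reaction bounds ``lb <= v <= ub``).  This
module provides the thin, solver-agnostic contracts the rest of the package
is written against:

* :func:`read_sbml` / :func:`write_sbml` — SBML Level 3 + FBC round-trip.
* :func:`solve_fba` — maximize a weighted linear objective ``w^T v`` over the
  steady-state flux polytope ``S v = 0``.
* :func:`run_fva` — per-reaction flux minimization/maximization under a fixed
  network state (flux variability analysis).

Degenerate alternate optima are a fact of FBA: any optimal vertex may be
returned, so downstream code should only rely on solver-invariant quantities
(objective values and FVA ranges).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import cobra
import pandas as pd
from cobra.core.solution import get_solution
from optlang.interface import OPTIMAL

__all__ = [
    "DEFAULT_BOUND",
    "FEASIBILITY_TOLERANCE",
    "FluxSolution",
    "FVAResult",
    "read_sbml",
    "write_sbml",
    "solve_fba",
    "run_fva",
    "validate_model",
]

logger = logging.getLogger(__name__)

#: Default magnitude used when an SBML file carries no flux bounds.
DEFAULT_BOUND = 1000.0

#: Solver feasibility/optimality tolerance used throughout the package.
FEASIBILITY_TOLERANCE = 1e-9


@dataclass
class FluxSolution:
    """Outcome of a single FBA solve.

    ``status`` is one of ``"optimal"``, ``"infeasible"`` or ``"unbounded"``;
    ``fluxes`` is only populated when the solve was optimal.
    """

    objective_value: float
    fluxes: pd.Series | None
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-reaction flux ranges under a fixed network state.

    ``frame`` is indexed by reaction id with columns ``fva_min``, ``fva_max``
    and ``subsystem``; ``fixed_constraints`` records the (lb, ub) overrides
    that defined the state the FVA was run under.
    """

    frame: pd.DataFrame
    fixed_constraints: dict[str, tuple[float, float]] = field(default_factory=dict)

    def range_of(self, reaction_id: str) -> tuple[float, float]:
        row = self.frame.loc[reaction_id]
        return float(row["fva_min"]), float(row["fva_max"])

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.frame.index

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.reset_index().rename(columns={"index": "reaction_id"})
        out.to_csv(path, sep="\t", index=False)


def read_sbml(path: str | Path) -> cobra.Model:
    """Read an SBML (Level 3 + FBC preferred) model.

    Reaction ids, bounds, stoichiometry and subsystem annotations are
    preserved; reactions lacking explicit bounds default to
    ``(-DEFAULT_BOUND, DEFAULT_BOUND)`` with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SBML file not found: {path}")
    model = cobra.io.read_sbml_model(str(path))
    # subsystem labels travel as reaction notes (this package's writer) or
    # as SBML groups (external models); restore them onto reactions
    for rxn in model.reactions:
        if not rxn.subsystem and "SUBSYSTEM" in rxn.notes:
            rxn.subsystem = rxn.notes["SUBSYSTEM"]
    for group in model.groups:
        label = group.name or group.id
        for member in group.members:
            if isinstance(member, cobra.Reaction) and not member.subsystem:
                member.subsystem = label
    for rxn in model.reactions:
        if rxn.lower_bound is None or rxn.upper_bound is None:  # pragma: no cover
            logger.warning("reaction %s missing bounds; defaulting", rxn.id)
            rxn.bounds = (-DEFAULT_BOUND, DEFAULT_BOUND)
        if not rxn.subsystem:
            rxn.subsystem = "unassigned"
    return model


def write_sbml(model: cobra.Model, path: str | Path) -> None:
    """Write a model as SBML Level 3 + FBC (round-trips with read_sbml).

    Subsystem labels are persisted as reaction notes so the output is
    byte-deterministic for identical models.
    """
    needs_notes = [
        r for r in model.reactions
        if r.subsystem and r.notes.get("SUBSYSTEM") != r.subsystem
    ]
    to_write = model
    if needs_notes:
        to_write = model.copy()
        for rxn in to_write.reactions:
            if rxn.subsystem:
                rxn.notes["SUBSYSTEM"] = rxn.subsystem
    cobra.io.write_sbml_model(to_write, str(path))


def _status(model: cobra.Model) -> str:
    status = model.solver.status
    if status == OPTIMAL:
        return "optimal"
    if status in ("infeasible", "undefined"):
        return "infeasible"
    if status == "unbounded":
        return "unbounded"
    return str(status)


def solve_fba(
    model: cobra.Model,
    objective_weights: Mapping[str, float] | str,
) -> FluxSolution:
    """Maximize ``w^T v`` subject to ``S v = 0`` and the model bounds.

    Parameters
    ----------
    model:
        The constraint-based model to solve.
    objective_weights:
        Either a single reaction id (weight 1) or a mapping of reaction id
        to finite weight.  At least one reaction must be named.
    """
    if isinstance(objective_weights, str):
        objective_weights = {objective_weights: 1.0}
    if not objective_weights:
        raise ValueError("objective_weights must name at least one reaction")
    for rid, w in objective_weights.items():
        if not math.isfinite(w):
            raise ValueError(f"non-finite objective weight for {rid!r}")
    with model:
        expr = sum(
            w * model.reactions.get_by_id(rid).flux_expression
            for rid, w in objective_weights.items()
        )
        model.objective = model.problem.Objective(expr, direction="max")
        value = model.slim_optimize(error_value=float("nan"))
        status = _status(model)
        if status != "optimal":
            return FluxSolution(float("nan"), None, status)
        solution = get_solution(model)
    return FluxSolution(float(value), solution.fluxes, "optimal")


def run_fva(
    model: cobra.Model,
    reaction_ids: Sequence[str] | None = None,
    fixed_constraints: Mapping[str, tuple[float, float]] | None = None,
) -> FVAResult:
    """Flux variability analysis under a fixed network state.

    For each reaction the flux is separately minimized and maximized while
    every other constraint (including any ``fixed_constraints`` overrides,
    e.g. biomass pinned to its pareto-optimal value) is held.  The fixed
    state is checked for feasibility before any per-reaction solve.
    """
    fixed_constraints = dict(fixed_constraints or {})
    if reaction_ids is None:
        reaction_ids = [r.id for r in model.reactions]
    rows = []
    with model:
        for rid, (lb, ub) in fixed_constraints.items():
            model.reactions.get_by_id(rid).bounds = (lb, ub)
        model.objective = model.problem.Objective(0, direction="max")
        model.slim_optimize(error_value=float("nan"))
        if _status(model) != "optimal":
            raise ValueError("fixed state is infeasible; FVA aborted")
        for rid in reaction_ids:
            rxn = model.reactions.get_by_id(rid)
            model.objective = model.problem.Objective(
                rxn.flux_expression, direction="min"
            )
            lo = model.slim_optimize(error_value=float("nan"))
            model.objective.direction = "max"
            hi = model.slim_optimize(error_value=float("nan"))
            rows.append(
                {
                    "reaction_id": rid,
                    "fva_min": float(lo),
                    "fva_max": float(hi),
                    "subsystem": rxn.subsystem or "unassigned",
                }
            )
    frame = pd.DataFrame(rows).set_index("reaction_id")
    return FVAResult(frame=frame, fixed_constraints=fixed_constraints)


def _stoichiometry(model: cobra.Model):
    """Dense stoichiometric matrix, cached on the model instance."""
    from cobra.util.array import create_stoichiometric_matrix

    key = (len(model.reactions), len(model.metabolites))
    cached = getattr(model, "_gutbrain_S_cache", None)
    if cached is not None and cached[0] == key:
        return cached[1]
    S = create_stoichiometric_matrix(model, array_type="dense")
    model._gutbrain_S_cache = (key, S)
    return S


def verified_feasible(model: cobra.Model, tol: float = 1e-9) -> bool:
    """Solve a feasibility LP and verify the primal point explicitly.

    Some LP backends accept small constraint violations on near-infeasible
    problems once the problem is auto-scaled, reporting "optimal" for a
    point that violates a mass balance.  This check re-validates the primal
    solution against ``S v = 0`` and the bounds at tolerance ``tol`` scaled
    by the largest flux magnitude, so feasibility decisions are
    solver-independent.
    """
    import numpy as np

    model.objective = model.problem.Objective(0, direction="max")
    model.slim_optimize(error_value=float("nan"))
    if _status(model) != "optimal":
        return False
    S = _stoichiometry(model)
    v = np.array([r.flux for r in model.reactions])
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    scale = max(1.0, float(np.abs(v).max(initial=0.0)))
    residual = float(np.abs(S @ v).max(initial=0.0))
    if residual > tol * scale:
        return False
    if (v < lb - tol * scale).any() or (v > ub + tol * scale).any():
        return False
    return True


def validate_model(model: cobra.Model) -> list[str]:
    """Check the structural invariants every model in this package must hold.

    Returns a list of human-readable problems (empty when the model is valid):
    every reaction references known metabolites (guaranteed by cobra), every
    bound pair satisfies lb <= ub, and every boundary (exchange) reaction
    touches exactly one metabolite.
    """
    problems: list[str] = []
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            problems.append(f"{rxn.id}: lb {rxn.lower_bound} > ub {rxn.upper_bound}")
        if rxn.boundary and len(rxn.metabolites) != 1:
            problems.append(f"{rxn.id}: boundary reaction with {len(rxn.metabolites)} metabolites")
    return problems
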