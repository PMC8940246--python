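"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from cobra import Metabolite, Model, Reaction
from scipy.linalg import null_space

import gutbrain as gb


def build_model(name, metabolite_ids, reactions):
    """Tiny helper: reactions as (id, {met_id: coeff}, lb, ub)."""
    model = Model(name)
    mets = {mid: Metabolite(mid, compartment=mid.rsplit("_", 1)[-1]) for mid in metabolite_ids}
    objs = []
    for rid, stoich, lb, ub in reactions:
        rxn = Reaction(rid, lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites({mets[m]: c for m, c in stoich.items()})
        objs.append(rxn)
    model.add_reactions(objs)
    return model


@pytest.fixture
def capacity_model():
    """Shared-capacity toy: SRC (<=10) feeds V1 and V2 (v1 + v2 <= 10)."""
    return build_model(
        "capacity",
        ["x_c"],
        [
            ("SRC", {"x_c": 1}, 0, 10),
            ("V1", {"x_c": -1}, 0, 100),
            ("V2", {"x_c": -1}, 0, 100),
        ],
    )


@pytest.fixture
def three_way_model():
    """Three objectives sharing substrate capacity 9."""
    return build_model(
        "three_way",
        ["x_c"],
        [
            ("SRC", {"x_c": 1}, 0, 9),
            ("V1", {"x_c": -1}, 0, 100),
            ("V2", {"x_c": -1}, 0, 100),
            ("V3", {"x_c": -1}, 0, 100),
        ],
    )


@pytest.fixture
def chain_model():
    """Linear chain: uptake (<=5) -> A -> B -> C -> export."""
    return build_model(
        "chain",
        ["a_c", "b_c", "c_c"],
        [
            ("EX_a", {"a_c": -1}, -5, 0),
            ("R_ab", {"a_c": -1, "b_c": 1}, 0, 100),
            ("R_bc", {"b_c": -1, "c_c": 1}, 0, 100),
            ("EX_c", {"c_c": -1}, 0, 100),
        ],
    )


@pytest.fixture
def parallel_model():
    """Two redundant paths sharing uptake capacity 10."""
    return build_model(
        "parallel",
        ["a_c", "b_c"],
        [
            ("EX_a", {"a_c": -1}, -10, 0),
            ("P1", {"a_c": -1, "b_c": 1}, 0, 100),
            ("P2", {"a_c": -1, "b_c": 1}, 0, 100),
            ("EX_b", {"b_c": -1}, 0, 100),
        ],
    )


@pytest.fixture
def fixture_spec():
    return gb.FixtureSpec()


@pytest.fixture
def diets():
    high_fiber, western = gb.make_toy_diets()
    return {"high_fiber": high_fiber, "western": western}


@pytest.fixture
def pbpk_params():
    return gb.make_toy_pbpk_params()


@pytest.fixture(scope="session")
def mixed_community_session():
    high_fiber, _ = gb.make_toy_diets()
    return gb.make_toy_community(diet=high_fiber)


# ---------------------------------------------------------------------------
# independent oracles


def enumerate_vertices(S, lb, ub, tol=1e-7):
    """All vertices of {v : S v = 0, lb <= v <= ub} by basis enumeration.

    Parameterizes the flux polytope by the null space of S and intersects
    every choice of d active bound constraints; only valid for small, fully
    bounded toy models.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    N = null_space(S)
    d = N.shape[1]
    A = np.vstack([N, -N])
    b = np.concatenate([ub, -lb])
    vertices = []
    for rows in itertools.combinations(range(A.shape[0]), d):
        M = A[list(rows)]
        if abs(np.linalg.det(M)) < 1e-10:
            continue
        x = np.linalg.solve(M, b[list(rows)])
        if (A @ x <= b + tol).all():
            vertices.append(N @ x)
    return np.array(vertices)


def fva_by_vertex_enumeration(model):
    """Per-reaction flux ranges from exhaustive vertex enumeration."""
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(model, array_type="dense")
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    vertices = enumerate_vertices(S, lb, ub)
    assert len(vertices) > 0, "toy polytope has no vertices"
    return {
        r.id: (float(vertices[:, i].min()), float(vertices[:, i].max()))
        for i, r in enumerate(model.reactions)
    }


def grid_non_dominated(model, objective_ids, point, n_grid=50, tol=1e-6):
    """Check no feasible point on an n_grid x n_grid objective grid
    dominates ``point`` (componentwise >=, at least one strictly > tol)."""
    from gutbrain.pareto import _feasible, _objective_bounds

    point = np.asarray(point, dtype=float)
    axes = []
    with model:
        for rid in objective_ids:
            lo, hi = _objective_bounds(model, rid)
            axes.append(np.linspace(lo, hi, n_grid))
    for candidate in itertools.product(*axes):
        candidate = np.asarray(candidate)
        if (candidate >= point - tol).all() and (candidate > point + tol).any():
            if _feasible(model, objective_ids, candidate):
                return False, candidate
    return True, None
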