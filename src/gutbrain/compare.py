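"""FVA-based comparison of model states and secretion-product ranking.

Two per-reaction statistics compare the flux variability interval of a
reaction between a reference state (1) and a perturbed state (2)::

    mean_shift   = |(max1 + min1)/2 - (max2 + min2)/2|       (always >= 0)
    range_change = (max1 - min1) - (max2 - min2)             (signed)

Reactions are ranked by decreasing mean shift, ties broken by decreasing
range change, residual ties by reaction id.  A subsystem-level *pathway
score* is the fraction of the subsystem's reactions whose mean shift
exceeds a threshold (default 1e-6 flux units, the numerical-noise floor).

The toxic vs non-toxic protocol builds a "toxic" model variant whose toxin
input/output exchange lower bounds are set to steady-state flux values from
the hybrid integration, and a "non-toxic" variant with those bounds scaled
by a low-exchange fraction (default 0), then compares the two by FVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import cobra
import pandas as pd

from .community import CommunityModel
from .core import FVAResult, run_fva, _status
from .pareto import ParetoSolution, fix_pareto_state

__all__ = [
    "ComparisonMetrics",
    "mean_shift",
    "range_change",
    "rank_reactions",
    "pathway_score",
    "compare_states",
    "secretion_products",
    "compare_toxic_nontoxic",
]

SHIFT_THRESHOLD = 1e-6


def _interval(fva: FVAResult, reaction: str) -> tuple[float, float]:
    if reaction not in fva:
        raise KeyError(f"reaction {reaction!r} missing from FVA result")
    return fva.range_of(reaction)


def mean_shift(fva1: FVAResult, fva2: FVAResult, reaction: str) -> float:
    """Absolute shift of the flux interval midpoint between two states."""
    lo1, hi1 = _interval(fva1, reaction)
    lo2, hi2 = _interval(fva2, reaction)
    return abs((hi1 + lo1) / 2.0 - (hi2 + lo2) / 2.0)


def range_change(fva1: FVAResult, fva2: FVAResult, reaction: str) -> float:
    """Signed change of the flux interval width between two states."""
    lo1, hi1 = _interval(fva1, reaction)
    lo2, hi2 = _interval(fva2, reaction)
    return (hi1 - lo1) - (hi2 - lo2)


def rank_reactions(metrics: pd.DataFrame) -> list[str]:
    """Order reaction ids by mean shift desc, range change desc, id asc."""
    frame = metrics.copy()
    frame["_id"] = frame.index
    frame = frame.sort_values(
        by=["mean_shift", "range_change", "_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return list(frame.index)


def pathway_score(
    metrics: pd.DataFrame,
    subsystem_map: Mapping[str, str] | None = None,
    shift_threshold: float = SHIFT_THRESHOLD,
) -> pd.DataFrame:
    """Fraction of each subsystem's reactions with mean shift > threshold.

    ``subsystem_map`` (reaction id -> subsystem) overrides the metrics
    frame's own ``subsystem`` column.  Empty subsystems are absent from the
    result.  Columns: subsystem, shifted, total, score.
    """
    frame = metrics.copy()
    if subsystem_map is not None:
        frame["subsystem"] = [subsystem_map.get(rid, "unassigned") for rid in frame.index]
    frame["shifted"] = frame["mean_shift"] > shift_threshold
    grouped = frame.groupby("subsystem").agg(
        shifted=("shifted", "sum"), total=("shifted", "size")
    )
    grouped["score"] = grouped["shifted"] / grouped["total"]
    return grouped.reset_index()


@dataclass
class ComparisonMetrics:
    """Per-reaction comparison statistics, ranking and pathway scores."""

    per_reaction: pd.DataFrame     # index reaction id: mean_shift, range_change, subsystem
    ranking: list[str]
    pathway_scores: pd.DataFrame   # subsystem, shifted, total, score
    shift_threshold: float = SHIFT_THRESHOLD

    def to_tsv(self, metrics_path: str | Path, pathway_path: str | Path | None = None) -> None:
        out = self.per_reaction.loc[self.ranking].reset_index()
        out.to_csv(metrics_path, sep="\t", index=False)
        if pathway_path is not None:
            self.pathway_scores.to_csv(pathway_path, sep="\t", index=False)


def compare_states(
    fva1: FVAResult,
    fva2: FVAResult,
    shift_threshold: float = SHIFT_THRESHOLD,
    subsystem_map: Mapping[str, str] | None = None,
) -> ComparisonMetrics:
    """Full comparison of two FVA states over their common reaction set."""
    common = [rid for rid in fva1.frame.index if rid in fva2]
    missing = set(fva1.frame.index).symmetric_difference(fva2.frame.index)
    if not common:
        raise ValueError("the two FVA results share no reactions")
    rows = []
    for rid in common:
        rows.append(
            {
                "reaction_id": rid,
                "mean_shift": mean_shift(fva1, fva2, rid),
                "range_change": range_change(fva1, fva2, rid),
                "subsystem": fva1.frame.loc[rid, "subsystem"],
            }
        )
    per_reaction = pd.DataFrame(rows).set_index("reaction_id")
    per_reaction.attrs["asymmetric_reactions"] = sorted(missing)
    return ComparisonMetrics(
        per_reaction=per_reaction,
        ranking=rank_reactions(per_reaction),
        pathway_scores=pathway_score(per_reaction, subsystem_map, shift_threshold),
        shift_threshold=shift_threshold,
    )


def secretion_products(
    community: CommunityModel,
    fixed_state: ParetoSolution | None = None,
) -> pd.DataFrame:
    """Rank community secretion products by their maximal fecal flux.

    FVA is run over the fecal (secretion) exchanges, optionally under a
    pinned pareto growth state; exchanges with nonzero maximum are returned
    ranked by ``fva_max`` descending.  Each product is attributed to members
    via the luminal transport fluxes at the flux-maximizing solution (a
    representative optimum; attribution is unique only when a single member
    can produce the metabolite).
    """
    model = community.model.copy()
    if fixed_state is not None:
        fix_pareto_state(model, fixed_state)
    rows = []
    for base, rid in community.fecal_exchanges.items():
        # close this metabolite's own diet uptake so a pure diet->fecal
        # pass-through is not mistaken for secretion (cross-feeding from
        # other diet components is still allowed)
        diet_id = community.diet_exchanges.get(base)
        fixed = {diet_id: (0.0, 0.0)} if diet_id in model.reactions else {}
        fva = run_fva(model, [rid], fixed_constraints=fixed)
        lo, hi = fva.range_of(rid)
        if hi <= SHIFT_THRESHOLD:
            continue
        contributions: dict[str, float] = {}
        with model:
            for fixed_id, bounds in fixed.items():
                model.reactions.get_by_id(fixed_id).bounds = bounds
            rxn = model.reactions.get_by_id(rid)
            model.objective = model.problem.Objective(rxn.flux_expression, direction="max")
            model.slim_optimize(error_value=float("nan"))
            if _status(model) == "optimal":
                for tag in community.tags:
                    iex = f"IEX_{base}_lu_{tag}"
                    if iex in model.reactions:
                        flux = model.reactions.get_by_id(iex).flux
                        if flux > SHIFT_THRESHOLD:
                            contributions[tag] = float(flux)
        rows.append(
            {
                "metabolite": base,
                "fva_max": hi,
                "fva_min": lo,
                "top_contributor": max(contributions, key=contributions.get)
                if contributions
                else None,
                "contributions": contributions,
            }
        )
    rows.sort(key=lambda r: (-r["fva_max"], r["metabolite"]))
    frame = pd.DataFrame(
        rows, columns=["metabolite", "fva_max", "fva_min", "top_contributor", "contributions"]
    )
    return frame


def compare_toxic_nontoxic(
    model: cobra.Model,
    steady_state_toxin_fluxes: Mapping[str, float],
    low_exchange_fraction: float = 0.0,
    reaction_ids: Sequence[str] | None = None,
    shift_threshold: float = SHIFT_THRESHOLD,
) -> ComparisonMetrics:
    """Compare a toxic vs a non-toxic variant of a model by FVA.

    ``steady_state_toxin_fluxes`` maps toxin input/output exchange reaction
    ids to the steady-state flux values from the hybrid integration; the
    toxic variant sets those reactions' *lower* bounds to these values
    (forcing the steady-state toxin traffic), the non-toxic variant scales
    them by ``low_exchange_fraction``.
    """
    if not 0 <= low_exchange_fraction <= 1:
        raise ValueError("low_exchange_fraction must be in [0, 1]")

    def _variant(fraction: float) -> FVAResult:
        fixed = {}
        for rid, value in steady_state_toxin_fluxes.items():
            rxn = model.reactions.get_by_id(rid)
            lb = float(value) * fraction
            fixed[rid] = (lb, max(rxn.upper_bound, lb))
        return run_fva(model, reaction_ids, fixed_constraints=fixed)

    fva_toxic = _variant(1.0)
    fva_nontoxic = _variant(low_exchange_fraction)
    return compare_states(fva_toxic, fva_nontoxic, shift_threshold)
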