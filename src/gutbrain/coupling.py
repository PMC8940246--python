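"""Discretized coupling of constraint-based organ models to the PBPK model.

The hybrid loop is a static dynamic-FBA scheme: time is discretized into
steps of ``dt`` (default 15 min) over a fixed horizon (default 6 h).  At
the start of each step the current extravascular toxin concentration of
each coupled organ is converted to a maximal uptake (input) flux bound —
the whole extravascular pool may be consumed within one step — the organ's
constraint-based model is solved in stages, and the realized toxin exchange
fluxes are converted back to constant generation/consumption terms that
drive the PBPK ODEs for the remainder of the step (explicit operator
splitting, COBRA first).

Per-step COBRA stages (each a pareto optimization):

1. pareto-optimal growth of all cell objectives (gut: member + host
   biomasses, optionally abundance-weighted; brain: ATP maintenance), then
   pinned;
2. maximal toxin *output* (secretion) exchange fluxes -> generation terms,
   then pinned;
3. maximal toxin *input* (uptake) exchange fluxes -> consumption terms,
   then pinned;
4. optionally (brain) neurotransmitter production, modeled as demand
   reactions for GABA and glutamate, under the fully pinned state.

Unit bridge: model fluxes are mmol/gDW/hr; the concentration/flux
conversion works on a nmol per gram of organ per hour scale with an
explicit 1e9 M->nmol factor, division by the step length in hours, and the
organ gram weight standing in for the model's gDW (rat-scale defaults:
small intestine 7.26 g, brain 2 g).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
import yaml

from .community import CommunityModel, split_reversible_exchange
from .core import _status
from .pareto import ParetoProblem, ParetoSolution, fix_pareto_state, solve_pareto
from .pbpk import PBPKParameters, simulate_pbpk, total_amount, uniform_state

__all__ = [
    "CouplingConfig",
    "OrganCoupling",
    "StepResult",
    "CouplingTrajectory",
    "concentration_to_flux_bound",
    "flux_to_concentration_rate",
    "prepare_gut_organ",
    "prepare_brain_organ",
    "step_cobra_organ",
    "run_integration",
]

logger = logging.getLogger(__name__)

#: nmol per model flux unit (model fluxes are mmol/gDW/hr; 1 mmol = 1e6 nmol).
NMOL_PER_FLUX_UNIT = 1e6


@dataclass
class CouplingConfig:
    """Time grid, species, and unit constants of the hybrid integration."""

    dt_hours: float = 0.25            # 15-min step
    horizon_hours: float = 6.0
    initial_concentration: float = 1e-4   # M, per toxin species
    species: tuple[str, ...] = ("h2o2", "o2s")
    gut_tissue: str = "gut"
    brain_tissue: str = "brain"
    gram_weights: dict[str, float] = field(
        default_factory=lambda: {"gut": 7.26, "brain": 2.0}
    )
    nmol_per_flux_unit: float = NMOL_PER_FLUX_UNIT
    steady_state_tol: float = 1e-6
    pareto_max_iterations: int = 100
    pareto_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.dt_hours <= 0 or self.horizon_hours <= 0:
            raise ValueError("step and horizon must be positive")
        n = self.horizon_hours / self.dt_hours
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dt must divide the horizon evenly")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon_hours / self.dt_hours))


def concentration_to_flux_bound(
    concentration: float,
    extravascular_volume: float,
    gram_weight: float,
    dt_hours: float,
    nmol_per_flux_unit: float = NMOL_PER_FLUX_UNIT,
) -> float:
    """Maximal toxin uptake flux bound from an extravascular concentration.

    ``C (M) * V_EV (L) * 1e9 / gram_weight (g) / dt (hr)`` expresses, on the
    nmol/g/hr scale, the uptake rate that would consume the whole
    extravascular pool within one step (the static-dFBA assumption); the
    result is returned in model flux units (nmol -> model unit via
    ``nmol_per_flux_unit``).
    """
    if concentration < 0 or extravascular_volume < 0:
        raise ValueError("concentration and volume must be >= 0")
    if gram_weight <= 0 or dt_hours <= 0:
        raise ValueError("gram weight and step length must be > 0")
    nmol_per_g_hr = concentration * extravascular_volume * 1e9 / gram_weight / dt_hours
    return nmol_per_g_hr / nmol_per_flux_unit


def flux_to_concentration_rate(
    flux: float,
    gram_weight: float,
    nmol_per_flux_unit: float = NMOL_PER_FLUX_UNIT,
) -> float:
    """Convert a realized exchange flux to a mol/hr PBPK source/sink term.

    ``flux`` is a nonnegative magnitude in model flux units (direction is
    carried separately as generation vs consumption); the term is
    ``flux * nmol_per_flux_unit * gram_weight * 1e-9`` mol/hr.
    """
    if flux < 0:
        raise ValueError("flux magnitude must be >= 0 (direction is separate)")
    if gram_weight <= 0:
        raise ValueError("gram weight must be > 0")
    return flux * nmol_per_flux_unit * gram_weight * 1e-9


@dataclass
class OrganCoupling:
    """A constraint-based organ model prepared for the hybrid loop."""

    name: str
    tissue: str
    model: cobra.Model
    toxin_inputs: dict[str, str]    # species -> input (uptake) reaction id
    toxin_outputs: dict[str, str]   # species -> output (secretion) reaction id
    growth_objectives: list[str]
    growth_weights: list[float] | None = None
    demand_objectives: list[str] = field(default_factory=list)


@dataclass
class StepResult:
    """Realized fluxes (model units) of one COBRA evaluation."""

    consumption: dict[str, float]
    generation: dict[str, float]
    objective_fluxes: dict[str, float]
    demand_fluxes: dict[str, float]


def prepare_gut_organ(
    community: CommunityModel,
    config: CouplingConfig,
    weights: Mapping[str, float] | None = None,
    copy: bool = True,
) -> OrganCoupling:
    """Prepare a gut community for coupling.

    The diet-side exchange of each toxin species is opened to reversibility
    and split into an irreversible input/output pair; the input upper bound
    is then driven by the PBPK extravascular concentration each step.
    ``weights`` (biomass reaction id -> weight) selects weighted pareto
    growth; omitted means equal weighting.
    """
    model = community.model.copy() if copy else community.model
    inputs, outputs = {}, {}
    for sp in config.species:
        ex_id = community.diet_exchanges.get(sp)
        if ex_id is None:
            raise ValueError(f"community has no lumen exchange for toxin {sp!r}")
        rxn = model.reactions.get_by_id(ex_id)
        rxn.bounds = (-1000.0, 1000.0)
        rxn_in, rxn_out = split_reversible_exchange(model, ex_id)
        model.reactions.get_by_id(rxn_in).upper_bound = 0.0
        inputs[sp] = rxn_in
        outputs[sp] = rxn_out
        # close the fecal outlet for coupled toxins: every toxin molecule
        # crossing the organ boundary is accounted to the PBPK pool or to
        # metabolic detoxification, keeping the hybrid toxin budget closed
        fecal_id = community.fecal_exchanges.get(sp)
        if fecal_id is not None and fecal_id in model.reactions:
            model.reactions.get_by_id(fecal_id).upper_bound = 0.0
    objectives = list(community.biomass_reactions.values())
    growth_weights = None
    if weights is not None:
        growth_weights = [float(weights[rid]) for rid in objectives]
    return OrganCoupling(
        name="gut_community",
        tissue=config.gut_tissue,
        model=model,
        toxin_inputs=inputs,
        toxin_outputs=outputs,
        growth_objectives=objectives,
        growth_weights=growth_weights,
    )


def prepare_brain_organ(
    brain_model: cobra.Model,
    config: CouplingConfig,
    maintenance_reaction: str = "ATPM",
    demand_reactions: Sequence[str] = ("DM_gaba", "DM_glu"),
    extracellular: str = "e",
    copy: bool = True,
) -> OrganCoupling:
    """Prepare a brain model: split toxin exchanges, register ATP
    maintenance as the growth-stage objective and GABA/glutamate demand
    reactions as the post-stage objectives."""
    model = brain_model.copy() if copy else brain_model
    inputs, outputs = {}, {}
    for sp in config.species:
        ex_id = f"EX_{sp}_{extracellular}"
        if ex_id not in model.reactions:
            raise ValueError(f"brain model has no exchange {ex_id!r}")
        model.reactions.get_by_id(ex_id).bounds = (-1000.0, 1000.0)
        rxn_in, rxn_out = split_reversible_exchange(model, ex_id)
        model.reactions.get_by_id(rxn_in).upper_bound = 0.0
        inputs[sp] = rxn_in
        outputs[sp] = rxn_out
    return OrganCoupling(
        name="brain",
        tissue=config.brain_tissue,
        model=model,
        toxin_inputs=inputs,
        toxin_outputs=outputs,
        growth_objectives=[maintenance_reaction],
        demand_objectives=[r for r in demand_reactions if r in model.reactions],
    )


def _stage_pareto(
    model: cobra.Model,
    objectives: list[str],
    weights: list[float] | None,
    config: CouplingConfig,
    stage: str,
) -> ParetoSolution:
    problem = ParetoProblem(
        model=model,
        objectives=objectives,
        weights=weights,
        max_iterations=config.pareto_max_iterations,
        tolerance=config.pareto_tolerance,
    )
    try:
        return solve_pareto(problem)
    except ValueError as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def step_cobra_organ(
    organ: OrganCoupling,
    toxin_bounds: Mapping[str, float],
    config: CouplingConfig | None = None,
) -> StepResult:
    """One COBRA evaluation of an organ under given toxin input bounds.

    Growth (or ATP maintenance) is pareto-maximized and pinned; toxin
    outputs are pareto-maximized and pinned (generation); toxin inputs are
    pareto-maximized and pinned (consumption); demand objectives, if any,
    are pareto-maximized last.  All bound changes are rolled back on exit.
    """
    config = config or CouplingConfig()
    model = organ.model
    species = list(organ.toxin_inputs)
    with model:
        for sp in species:
            bound = float(toxin_bounds.get(sp, 0.0))
            if bound < 0:
                raise ValueError(f"toxin bound for {sp!r} must be >= 0")
            if bound < 1e-12:  # snap vanishing pools closed
                bound = 0.0
            model.reactions.get_by_id(organ.toxin_inputs[sp]).upper_bound = bound

        growth = _stage_pareto(
            model, organ.growth_objectives, organ.growth_weights, config, "growth"
        )
        fix_pareto_state(model, growth)

        # maximize toxin outputs with uptake closed so generation reflects
        # internal production, not an uptake->re-export pass-through
        out_ids = [organ.toxin_outputs[sp] for sp in species]
        with model:
            for sp in species:
                model.reactions.get_by_id(organ.toxin_inputs[sp]).upper_bound = 0.0
            out_sol = _stage_pareto(model, out_ids, None, config, "toxin output")
        fix_pareto_state(model, out_sol)
        generation = {
            sp: max(0.0, float(v))
            for sp, v in zip(species, out_sol.objective_fluxes)
        }

        in_ids = [organ.toxin_inputs[sp] for sp in species]
        in_sol = _stage_pareto(model, in_ids, None, config, "toxin input")
        fix_pareto_state(model, in_sol)
        consumption = {
            sp: max(0.0, float(v))
            for sp, v in zip(species, in_sol.objective_fluxes)
        }

        demand_fluxes: dict[str, float] = {}
        if organ.demand_objectives:
            dem = _stage_pareto(model, organ.demand_objectives, None, config, "demand")
            demand_fluxes = {k: float(v) for k, v in dem.as_dict().items()}

    return StepResult(
        consumption=consumption,
        generation=generation,
        objective_fluxes={k: float(v) for k, v in growth.as_dict().items()},
        demand_fluxes=demand_fluxes,
    )


@dataclass
class CouplingTrajectory:
    """Per-step record of the hybrid integration."""

    times: np.ndarray                     # step end times, hr (length n_steps + 1)
    concentrations: pd.DataFrame          # tidy: time, tissue, compartment, species, concentration
    fluxes: pd.DataFrame                  # step, organ, species, bound, consumption, generation
    objectives: pd.DataFrame              # step, organ, reaction, flux
    steady_state_step: int | None
    config: CouplingConfig

    def endpoint(self, species: str, tissue: str, compartment: str = "extravascular") -> float:
        frame = self.concentrations
        sel = frame[
            (frame["species"] == species)
            & (frame["tissue"] == tissue)
            & (frame["compartment"] == compartment)
        ]
        return float(sel.loc[sel["time"].idxmax(), "concentration"])

    def series(self, species: str, tissue: str, compartment: str = "extravascular") -> pd.Series:
        frame = self.concentrations
        sel = frame[
            (frame["species"] == species)
            & (frame["tissue"] == tissue)
            & (frame["compartment"] == compartment)
        ].sort_values("time")
        return pd.Series(sel["concentration"].values, index=sel["time"].values)

    def to_tsv(self, path: str | Path) -> None:
        self.concentrations.to_csv(path, sep="\t", index=False)


def _record_concentrations(rows, time, y_by_species, params: PBPKParameters):
    names = params.tissue_names
    n = len(names)
    for sp, y in y_by_species.items():
        rows.append((time, "blood", "arterial", sp, y[0]))
        for i, name in enumerate(names):
            rows.append((time, name, "vascular", sp, y[1 + i]))
            rows.append((time, name, "extravascular", sp, y[1 + n + i]))


def run_integration(
    organs: Sequence[OrganCoupling] | None = None,
    pbpk_params: PBPKParameters | None = None,
    config: CouplingConfig | None = None,
    *,
    gut_community: CommunityModel | None = None,
    brain_model: cobra.Model | None = None,
    gut_weights: Mapping[str, float] | None = None,
) -> CouplingTrajectory:
    """Run the hybrid COBRA/PBPK integration over the configured horizon.

    Either pass prepared ``organs`` directly, or pass ``gut_community``
    and/or ``brain_model`` to have them prepared with the config defaults.
    Each step: derive toxin input bounds from the organ's current
    extravascular concentrations, evaluate each organ's COBRA stages,
    convert realized fluxes to generation/consumption terms, advance the
    PBPK model one step, and record.  Steady state is reported at the first
    step whose relative concentration change falls below
    ``config.steady_state_tol``.
    """
    config = config or CouplingConfig()
    if pbpk_params is None:
        raise ValueError("pbpk_params is required")
    if organs is None:
        organs = []
        if gut_community is not None:
            organs.append(prepare_gut_organ(gut_community, config, weights=gut_weights))
        if brain_model is not None:
            organs.append(prepare_brain_organ(brain_model, config))
    if not organs:
        raise ValueError("at least one coupled organ is required")
    for organ in organs:
        if organ.tissue not in pbpk_params.tissues:
            raise ValueError(f"organ {organ.name!r} maps to unknown tissue {organ.tissue!r}")

    names = pbpk_params.tissue_names
    n = len(names)
    y = {
        sp: uniform_state(pbpk_params, config.initial_concentration)
        for sp in config.species
    }

    conc_rows: list[tuple] = []
    flux_rows: list[dict] = []
    obj_rows: list[dict] = []
    times = np.arange(config.n_steps + 1) * config.dt_hours
    _record_concentrations(conc_rows, 0.0, y, pbpk_params)
    steady_state_step: int | None = None

    for step in range(config.n_steps):
        generation: dict[str, dict[str, float]] = {sp: {} for sp in config.species}
        consumption: dict[str, dict[str, float]] = {sp: {} for sp in config.species}
        for organ in organs:
            tissue = pbpk_params.tissues[organ.tissue]
            gram_weight = config.gram_weights.get(organ.tissue, tissue.gram_weight)
            i_ev = 1 + n + names.index(organ.tissue)
            bounds = {
                sp: concentration_to_flux_bound(
                    y[sp][i_ev],
                    tissue.extravascular_volume,
                    gram_weight,
                    config.dt_hours,
                    config.nmol_per_flux_unit,
                )
                for sp in config.species
            }
            try:
                result = step_cobra_organ(organ, bounds, config)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"integration aborted at step {step} ({organ.name}): {exc}"
                ) from exc
            for sp in config.species:
                generation[sp][organ.tissue] = flux_to_concentration_rate(
                    result.generation.get(sp, 0.0), gram_weight, config.nmol_per_flux_unit
                )
                consumption[sp][organ.tissue] = flux_to_concentration_rate(
                    result.consumption.get(sp, 0.0), gram_weight, config.nmol_per_flux_unit
                )
                flux_rows.append(
                    {
                        "step": step,
                        "organ": organ.name,
                        "species": sp,
                        "input_bound": bounds[sp],
                        "consumption": result.consumption.get(sp, 0.0),
                        "generation": result.generation.get(sp, 0.0),
                    }
                )
            for rid, v in {**result.objective_fluxes, **result.demand_fluxes}.items():
                obj_rows.append(
                    {"step": step, "organ": organ.name, "reaction": rid, "flux": v}
                )

        y_prev = {sp: arr.copy() for sp, arr in y.items()}
        traj = simulate_pbpk(
            pbpk_params,
            y,
            duration=config.dt_hours,
            generation=generation,
            consumption=consumption,
        )
        y = {sp: traj.states[sp][-1].copy() for sp in config.species}
        _record_concentrations(conc_rows, times[step + 1], y, pbpk_params)

        if steady_state_step is None:
            prev = np.concatenate([y_prev[sp] for sp in config.species])
            curr = np.concatenate([y[sp] for sp in config.species])
            denom = max(float(np.linalg.norm(prev)), 1e-30)
            if float(np.linalg.norm(curr - prev)) / denom < config.steady_state_tol:
                steady_state_step = step

    concentrations = pd.DataFrame(
        conc_rows, columns=["time", "tissue", "compartment", "species", "concentration"]
    )
    return CouplingTrajectory(
        times=times,
        concentrations=concentrations,
        fluxes=pd.DataFrame(flux_rows),
        objectives=pd.DataFrame(obj_rows),
        steady_state_step=steady_state_step,
        config=config,
    )
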