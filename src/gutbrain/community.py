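"""Gut community assembly: members + host joined through a shared lumen.

A community model merges N bacterial models and one host (enterocyte) model
into a single stoichiometric model.  Every member/host reaction and
metabolite id is suffixed with the member tag; each extracellular metabolite
of each member gains a reversible *luminal transport* reaction into the
shared lumen compartment ``lu``; every lumen metabolite gains a *diet*
exchange (uptake side, closed until a diet is applied) and a *fecal*
exchange (secretion side, open).

Naming conventions (chosen so AGORA-style external models drop in):

* member metabolite ``glc_e`` tagged ``bv`` becomes ``glc_e_bv``;
* its luminal transport reaction is ``IEX_glc_lu_bv`` with stoichiometry
  ``glc_e_bv -> glc_lu`` (positive flux = secretion into the lumen,
  negative = uptake from the lumen);
* lumen boundary reactions are ``EX_glc_lu_diet`` (lb set to minus the diet
  uptake allowance) and ``EX_glc_lu_fecal`` (0..1000, secretion only).

Diet uptake allowances are in mmol/hr per community; member abundances are
encoded in pareto objective weights, not in the stoichiometry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import cobra
import pandas as pd
from cobra import Metabolite, Reaction

__all__ = [
    "LUMEN",
    "CommunityModel",
    "DietSpec",
    "build_community",
    "apply_diet",
    "set_oxygen_condition",
    "split_reversible_exchange",
    "load_diet",
]

logger = logging.getLogger(__name__)

LUMEN = "lu"
_WIDE = 1000.0


@dataclass
class DietSpec:
    """A diet: maximum uptake allowance per lumen metabolite (mmol/hr).

    Metabolites not listed are closed for uptake.
    """

    name: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        for met, value in self.entries.items():
            if value < 0:
                raise ValueError(f"diet {self.name!r}: uptake for {met!r} must be >= 0")


@dataclass
class CommunityModel:
    """Tagged member models + host merged via a lumen compartment."""

    model: cobra.Model
    member_tags: list[str]
    host_tag: str
    biomass_reactions: dict[str, str]
    transport_reactions: dict[str, list[str]]
    lumen_metabolites: list[str]
    diet_exchanges: dict[str, str]
    fecal_exchanges: dict[str, str]
    n_transport_added: int = 0
    diet_name: str | None = None

    @property
    def tags(self) -> list[str]:
        return self.member_tags + [self.host_tag]

    def build_report(self) -> dict:
        return {
            "members": self.member_tags,
            "host": self.host_tag,
            "n_transport_reactions": self.n_transport_added,
            "n_lumen_metabolites": len(self.lumen_metabolites),
            "n_reactions": len(self.model.reactions),
            "n_metabolites": len(self.model.metabolites),
            "biomass_reactions": self.biomass_reactions,
            "diet": self.diet_name,
        }


def _base_name(met_id: str, compartment_suffix: str) -> str:
    suffix = f"_{compartment_suffix}"
    return met_id[: -len(suffix)] if met_id.endswith(suffix) else met_id


def _tag_model(model: cobra.Model, tag: str) -> cobra.Model:
    tagged = model.copy()
    for met in tagged.metabolites:
        met.id = f"{met.id}_{tag}"
    for rxn in tagged.reactions:
        rxn.id = f"{rxn.id}_{tag}"
    tagged.repair()
    return tagged


def _objective_reaction(model: cobra.Model, tag: str) -> str:
    objs = [
        r.id
        for r in model.reactions
        if r.objective_coefficient not in (0, 0.0)
    ]
    if len(objs) != 1:
        raise ValueError(
            f"model for {tag!r} must carry exactly one objective (biomass or "
            f"maintenance) reaction; found {objs!r}"
        )
    return objs[0]


def build_community(
    member_models: Mapping[str, cobra.Model],
    host_model: cobra.Model,
    host_tag: str = "host",
    extracellular: str = "e",
) -> CommunityModel:
    """Merge member models and a host into one gut community model.

    ``member_models`` maps the unique member tag to its model.  Each model
    must have exactly one objective (biomass/maintenance) reaction.  For
    every extracellular metabolite of every member (and the host, which is
    linked to the lumen exactly like a member) a reversible luminal
    transport reaction is added, and each distinct lumen metabolite gains a
    diet and a fecal exchange.  Original member boundary (exchange)
    reactions are removed — the lumen boundary replaces them.
    """
    tags = list(member_models) + [host_tag]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate tags in {tags!r}")

    community = cobra.Model("gut_community")
    lumen_mets: dict[str, Metabolite] = {}
    biomass: dict[str, str] = {}
    transports: dict[str, list[str]] = {}
    n_transport = 0

    all_models = dict(member_models)
    all_models[host_tag] = host_model

    for tag, source in all_models.items():
        biomass[tag] = f"{_objective_reaction(source, tag)}_{tag}"
        tagged = _tag_model(source, tag)
        # collect the boundary-crossing metabolites before pruning, then
        # drop the member's own extracellular exchanges; the lumen boundary
        # replaces them (internal sinks/demands are kept)
        ex_mets = [m for m in tagged.metabolites if m.compartment == extracellular]
        tagged.remove_reactions(
            [
                r
                for r in tagged.reactions
                if r.boundary
                and len(r.metabolites) == 1
                and next(iter(r.metabolites)).compartment == extracellular
            ]
        )
        community.add_reactions(list(tagged.reactions))
        if not ex_mets and tag != host_tag:
            logger.warning("member %r has no extracellular metabolites", tag)
        transports[tag] = []
        for met in ex_mets:
            base = _base_name(met.id[: -len(tag) - 1], extracellular)
            lu_id = f"{base}_{LUMEN}"
            if lu_id not in lumen_mets:
                lu_met = Metabolite(lu_id, name=base, compartment=LUMEN)
                lumen_mets[lu_id] = lu_met
            rxn = Reaction(f"IEX_{base}_{LUMEN}_{tag}", lower_bound=-_WIDE, upper_bound=_WIDE)
            rxn.add_metabolites({met: -1.0, lumen_mets[lu_id]: 1.0})
            rxn.subsystem = "Luminal transport"
            community.add_reactions([rxn])
            transports[tag].append(rxn.id)
            n_transport += 1

    diet_ex: dict[str, str] = {}
    fecal_ex: dict[str, str] = {}
    for lu_id, met in sorted(lumen_mets.items()):
        base = _base_name(lu_id, LUMEN)
        diet = Reaction(f"EX_{base}_{LUMEN}_diet", lower_bound=0.0, upper_bound=0.0)
        diet.add_metabolites({met: -1.0})
        diet.subsystem = "Diet exchange"
        fecal = Reaction(f"EX_{base}_{LUMEN}_fecal", lower_bound=0.0, upper_bound=_WIDE)
        fecal.add_metabolites({met: -1.0})
        fecal.subsystem = "Fecal exchange"
        community.add_reactions([diet, fecal])
        diet_ex[base] = diet.id
        fecal_ex[base] = fecal.id

    community.objective = {
        community.reactions.get_by_id(rid): 1.0 for rid in biomass.values()
    }
    logger.info("community built: %d luminal transport reactions added", n_transport)
    return CommunityModel(
        model=community,
        member_tags=list(member_models),
        host_tag=host_tag,
        biomass_reactions=biomass,
        transport_reactions=transports,
        lumen_metabolites=sorted(lumen_mets),
        diet_exchanges=diet_ex,
        fecal_exchanges=fecal_ex,
        n_transport_added=n_transport,
    )


def apply_diet(community: CommunityModel, diet: DietSpec) -> CommunityModel:
    """Constrain the community with a diet by only opening listed uptakes.

    The diet exchange lower bound of each listed lumen metabolite is set to
    minus its allowance; every other diet exchange is closed (lb = 0).
    Fecal (secretion) bounds are untouched.  Diet entries that do not match
    any lumen metabolite are skipped with a warning.
    """
    model = community.model
    for base, rid in community.diet_exchanges.items():
        rxn = model.reactions.get_by_id(rid)
        allowance = diet.entries.get(base, 0.0)
        rxn.bounds = (-float(allowance), 0.0)
    unknown = set(diet.entries) - set(community.diet_exchanges)
    for met in sorted(unknown):
        logger.warning("diet %r entry %r matches no lumen metabolite; skipped", diet.name, met)
    community.diet_name = diet.name
    return community


def set_oxygen_condition(
    community: CommunityModel,
    lb_value: float = -1.0,
    oxygen_id: str = "o2",
) -> CommunityModel:
    """Set the member oxygen exchange lower bound (default -1 mmol/gDW/hr).

    Only bacterial members are constrained: the oxygen bound models the
    microaerobic small-intestinal lumen each bacterium experiences.  The
    member's luminal oxygen transport carries its uptake (negative flux), so
    ``lb_value`` caps per-member oxygen uptake at ``-lb_value``.
    """
    found = False
    for tag in community.member_tags:
        rid = f"IEX_{oxygen_id}_{LUMEN}_{tag}"
        if rid in community.model.reactions:
            rxn = community.model.reactions.get_by_id(rid)
            rxn.lower_bound = lb_value
            found = True
    if not found:
        logger.warning("no member oxygen exchange (%r) found", oxygen_id)
    return community


def split_reversible_exchange(
    model: cobra.Model, reaction_id: str
) -> tuple[str, str]:
    """Replace an exchange reaction by an irreversible input/output pair.

    The input reaction (``<id>_in``) carries the uptake direction with upper
    bound equal to the original uptake allowance (``max(0, -lb)``); the
    output reaction (``<id>_out``) carries secretion with the original upper
    bound.  The net flux space is unchanged.  Returns the new (input_id,
    output_id) pair.
    """
    rxn = model.reactions.get_by_id(reaction_id)
    if not rxn.boundary or len(rxn.metabolites) != 1:
        raise ValueError(f"{reaction_id!r} is not an exchange reaction")
    (met, coeff), = rxn.metabolites.items()
    if coeff >= 0:
        raise ValueError(f"{reaction_id!r}: exchange must consume its metabolite")
    lb, ub = rxn.bounds
    rxn_in = Reaction(f"{reaction_id}_in", lower_bound=0.0, upper_bound=max(0.0, -lb))
    rxn_in.add_metabolites({met: 1.0})
    rxn_in.subsystem = rxn.subsystem
    rxn_out = Reaction(f"{reaction_id}_out", lower_bound=0.0, upper_bound=max(0.0, ub))
    rxn_out.add_metabolites({met: -1.0})
    rxn_out.subsystem = rxn.subsystem
    model.remove_reactions([rxn])
    model.add_reactions([rxn_in, rxn_out])
    return rxn_in.id, rxn_out.id


def load_diet(path: str | Path) -> DietSpec:
    """Load a diet from JSON ({"name": ..., "entries": {...}}) or TSV
    (columns ``metabolite``, ``max_uptake``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return DietSpec(name=payload.get("name", path.stem), entries=dict(payload["entries"]))
    frame = pd.read_csv(path, sep="\t")
    entries = dict(zip(frame["metabolite"], frame["max_uptake"].astype(float)))
    return DietSpec(name=path.stem, entries=entries)


def save_diet(diet: DietSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"name": diet.name, "entries": diet.entries}, indent=2))
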