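"""Deterministic toy fixtures: bacteria, host, brain, diets, PBPK parameters.

These hand-designed minimal networks stand in for genome-scale
reconstructions (AGORA-style gut bacteria, a small-intestinal enterocyte,
and combined neuron/astrocyte brain models) so the whole framework can be
built and exercised with no external downloads.  Every network is small
enough that its FBA optima are hand-checkable.

Design of the toy metabolism (shared metabolite bases: ``fiber``, ``glc``,
``ac``, ``o2``, ``h``, ``h2o2``, ``o2s``):

* **beneficial** members ferment fiber efficiently (2 carbon units per
  fiber, 1 per glucose) and secrete no toxins;
* **harmful** members prefer glucose (2 carbon units per glucose, 1 per
  fiber) and co-secrete hydrogen peroxide and superoxide stoichiometrically
  with biomass;
* the **host** enterocyte grows on glucose, detoxifies a bounded amount of
  H2O2, and (optionally) carries superoxide dismutase catalyzing
  ``2 H+ + 2 O2s- -> O2 + H2O2``;
* the **brain** carries an ATP maintenance demand, glutamate -> GABA
  synthesis that consumes reducing power (NADPH), demand reactions for both
  neurotransmitters, and NADPH-consuming toxin detoxification — so forced
  toxin influx diverts reducing power and lowers the attainable GABA demand
  flux.

Fixture generation is pure: identical spec + seed give identical models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import numpy as np
from cobra import Metabolite, Reaction

from .community import CommunityModel, DietSpec, apply_diet, build_community, save_diet, set_oxygen_condition
from .core import write_sbml
from .pbpk import PBPKParameters, TissueParameters

__all__ = [
    "FixtureSpec",
    "make_toy_member",
    "make_toy_host",
    "make_toy_brain",
    "make_toy_diets",
    "make_toy_pbpk_params",
    "make_toy_community",
    "write_fixtures",
]

_WIDE = 1000.0


@dataclass(frozen=True)
class FixtureSpec:
    """Layout and stoichiometric knobs of the fixture community.

    The default five-member layout (2 beneficial, 3 harmful) mirrors a
    five-microbe gut community; ``ten_member_layout`` doubles it.
    """

    n_beneficial: int = 2
    n_harmful: int = 3
    h2o2_yield: float = 0.3    # mol toxin per unit harmful biomass
    o2s_yield: float = 0.3
    o2_per_biomass: float = 0.02
    host_detox_capacity: float = 0.1  # mmol/gDW/hr of H2O2 the host can degrade
    include_sod: bool = True
    fiber_sources: tuple[str, ...] = ("fiber",)
    western_sources: tuple[str, ...] = ("glc",)
    seed: int = 0
    jitter: float = 0.0        # optional relative jitter on catabolic yields

    @classmethod
    def ten_member_layout(cls, **kwargs) -> "FixtureSpec":
        return cls(n_beneficial=4, n_harmful=6, **kwargs)

    @property
    def beneficial_tags(self) -> list[str]:
        return [f"ben{i + 1}" for i in range(self.n_beneficial)]

    @property
    def harmful_tags(self) -> list[str]:
        return [f"harm{i + 1}" for i in range(self.n_harmful)]


def _met(mid: str, compartment: str) -> Metabolite:
    return Metabolite(mid, name=mid.rsplit("_", 1)[0], compartment=compartment)


def _rxn(rid, stoich, lb=0.0, ub=_WIDE, subsystem="unassigned"):
    rxn = Reaction(rid, lower_bound=lb, upper_bound=ub)
    rxn.add_metabolites(stoich)
    rxn.subsystem = subsystem
    return rxn


def _yield_jitter(spec: FixtureSpec, key: str) -> float:
    if spec.jitter <= 0:
        return 1.0
    rng = np.random.default_rng([spec.seed, hash(key) % (2**31)])
    return 1.0 + spec.jitter * float(rng.uniform(-1.0, 1.0))


def make_toy_member(
    member_class: str, spec: FixtureSpec | None = None, name: str = "member"
) -> cobra.Model:
    """A ~12-reaction toy gut bacterium of class 'beneficial' or 'harmful'."""
    spec = spec or FixtureSpec()
    if member_class not in ("beneficial", "harmful"):
        raise ValueError("member_class must be 'beneficial' or 'harmful'")
    harmful = member_class == "harmful"
    m = cobra.Model(name)
    fiber_e, fiber_c = _met("fiber_e", "e"), _met("fiber_c", "c")
    glc_e, glc_c = _met("glc_e", "e"), _met("glc_c", "c")
    ac_e, ac_c = _met("ac_e", "e"), _met("ac_c", "c")
    o2_e, o2_c = _met("o2_e", "e"), _met("o2_c", "c")
    carbon = _met("carbon_c", "c")

    fiber_yield = (1.0 if harmful else 2.0) * _yield_jitter(spec, f"{name}:fiber")
    glc_yield = (2.0 if harmful else 1.0) * _yield_jitter(spec, f"{name}:glc")

    biomass_stoich = {carbon: -1.0, o2_c: -spec.o2_per_biomass, ac_c: 0.2}
    reactions = [
        _rxn("EX_fiber_e", {fiber_e: -1}, lb=-_WIDE),
        _rxn("EX_glc_e", {glc_e: -1}, lb=-_WIDE),
        _rxn("EX_ac_e", {ac_e: -1}, lb=-_WIDE),
        _rxn("EX_o2_e", {o2_e: -1}, lb=-_WIDE),
        _rxn("T_fiber", {fiber_e: -1, fiber_c: 1}, subsystem="Transport"),
        _rxn("T_glc", {glc_e: -1, glc_c: 1}, subsystem="Transport"),
        _rxn("T_ac", {ac_c: -1, ac_e: 1}, subsystem="Transport"),
        _rxn("T_o2", {o2_e: -1, o2_c: 1}, subsystem="Transport"),
        _rxn("CAT_fiber", {fiber_c: -1, carbon: fiber_yield}, subsystem="Fiber fermentation"),
        _rxn("CAT_glc", {glc_c: -1, carbon: glc_yield}, subsystem="Glycolysis"),
    ]
    if harmful:
        h2o2_e, h2o2_c = _met("h2o2_e", "e"), _met("h2o2_c", "c")
        o2s_e, o2s_c = _met("o2s_e", "e"), _met("o2s_c", "c")
        biomass_stoich[h2o2_c] = spec.h2o2_yield
        biomass_stoich[o2s_c] = spec.o2s_yield
        reactions += [
            _rxn("T_h2o2", {h2o2_c: -1, h2o2_e: 1}, subsystem="ROS secretion"),
            _rxn("T_o2s", {o2s_c: -1, o2s_e: 1}, subsystem="ROS secretion"),
            _rxn("EX_h2o2_e", {h2o2_e: -1}),
            _rxn("EX_o2s_e", {o2s_e: -1}),
        ]
    reactions.append(_rxn("BIOMASS", biomass_stoich, subsystem="Biomass"))
    m.add_reactions(reactions)
    m.objective = "BIOMASS"
    return m


def make_toy_host(include_sod: bool = True, spec: FixtureSpec | None = None) -> cobra.Model:
    """A toy enterocyte: glucose growth, bounded H2O2 detox, optional SOD."""
    spec = spec or FixtureSpec(include_sod=include_sod)
    m = cobra.Model("host")
    glc_e, glc_c = _met("glc_e", "e"), _met("glc_c", "c")
    o2_e, o2_c = _met("o2_e", "e"), _met("o2_c", "c")
    h_e, h_c = _met("h_e", "e"), _met("h_c", "c")
    h2o2_e, h2o2_c = _met("h2o2_e", "e"), _met("h2o2_c", "c")
    o2s_e, o2s_c = _met("o2s_e", "e"), _met("o2s_c", "c")
    carbon = _met("carbon_c", "c")
    reactions = [
        _rxn("EX_glc_e", {glc_e: -1}, lb=-_WIDE),
        _rxn("EX_o2_e", {o2_e: -1}, lb=-_WIDE),
        _rxn("EX_h_e", {h_e: -1}, lb=-_WIDE),
        _rxn("EX_h2o2_e", {h2o2_e: -1}, lb=-_WIDE),
        _rxn("EX_o2s_e", {o2s_e: -1}, lb=-_WIDE),
        _rxn("T_glc", {glc_e: -1, glc_c: 1}, subsystem="Transport"),
        _rxn("T_o2", {o2_e: -1, o2_c: 1}, subsystem="Transport"),
        _rxn("T_h", {h_e: -1, h_c: 1}, lb=-_WIDE, subsystem="Transport"),
        _rxn("T_h2o2", {h2o2_e: -1, h2o2_c: 1}, lb=-_WIDE, subsystem="Transport"),
        _rxn("T_o2s", {o2s_e: -1, o2s_c: 1}, lb=-_WIDE, subsystem="Transport"),
        _rxn("CAT_glc", {glc_c: -1, carbon: 1.0}, subsystem="Glycolysis"),
        _rxn(
            "DETOX_h2o2",
            {h2o2_c: -1},
            ub=spec.host_detox_capacity,
            subsystem="ROS detoxification",
        ),
        _rxn(
            "BIOMASS",
            {carbon: -1.0, o2_c: -spec.o2_per_biomass},
            subsystem="Biomass",
        ),
    ]
    if include_sod:
        # superoxide dismutase: 2 H+ + 2 O2s- -> O2 + H2O2
        reactions.append(
            _rxn(
                "SOD",
                {h_c: -2, o2s_c: -2, o2_c: 1, h2o2_c: 1},
                subsystem="ROS detoxification",
            )
        )
    m.add_reactions(reactions)
    m.objective = "BIOMASS"
    return m


def make_toy_brain(glc_uptake: float = 10.0, atp_maintenance: float = 5.0) -> cobra.Model:
    """A toy brain: ATP maintenance, glutamate->GABA synthesis, toxin detox.

    Glucose feeds two competing routes — energy (ATP + NADPH) and carbon
    (glutamate).  GABA synthesis and toxin detoxification both consume
    NADPH, so toxin influx lowers the attainable GABA demand flux while ATP
    maintenance stays feasible.
    """
    m = cobra.Model("brain")
    glc_e, glc_c = _met("glc_e", "e"), _met("glc_c", "c")
    atp = _met("atp_c", "c")
    nadph = _met("nadph_c", "c")
    glu = _met("glu_c", "c")
    gaba = _met("gaba_c", "c")
    h2o2_e, h2o2_c = _met("h2o2_e", "e"), _met("h2o2_c", "c")
    o2s_e, o2s_c = _met("o2s_e", "e"), _met("o2s_c", "c")
    m.add_reactions(
        [
            _rxn("EX_glc_e", {glc_e: -1}, lb=-glc_uptake),
            _rxn("EX_h2o2_e", {h2o2_e: -1}, lb=-_WIDE),
            _rxn("EX_o2s_e", {o2s_e: -1}, lb=-_WIDE),
            _rxn("T_glc", {glc_e: -1, glc_c: 1}, subsystem="Transport"),
            _rxn("T_h2o2", {h2o2_e: -1, h2o2_c: 1}, lb=-_WIDE, subsystem="Transport"),
            _rxn("T_o2s", {o2s_e: -1, o2s_c: 1}, lb=-_WIDE, subsystem="Transport"),
            _rxn(
                "ENERGY", {glc_c: -1, atp: 2, nadph: 2},
                subsystem="Oxidative phosphorylation",
            ),
            _rxn("GLUSYN", {glc_c: -1, glu: 2}, subsystem="Glutamate metabolism"),
            _rxn(
                "GAD", {glu: -1, nadph: -0.5, gaba: 1},
                subsystem="Glutamate metabolism",
            ),
            _rxn("ATPM", {atp: -1}, ub=atp_maintenance, subsystem="Energy maintenance"),
            _rxn("DM_gaba", {gaba: -1}, subsystem="Neurotransmitter demand"),
            _rxn("DM_glu", {glu: -1}, subsystem="Neurotransmitter demand"),
            _rxn(
                "DETOX_h2o2", {h2o2_c: -1, nadph: -1},
                subsystem="ROS detoxification",
            ),
            _rxn(
                "DETOX_o2s", {o2s_c: -1, nadph: -1},
                subsystem="ROS detoxification",
            ),
        ]
    )
    m.objective = "ATPM"
    return m


def make_toy_diets(spec: FixtureSpec | None = None) -> tuple[DietSpec, DietSpec]:
    """High-fiber and Western diets over the fixture lumen metabolites.

    Both carry the same total carbon allowance but weight fiber vs glucose
    oppositely, so the high-fiber diet favors beneficial (fiber-fermenting)
    growth and the Western diet favors harmful (glucose-preferring) growth.
    """
    spec = spec or FixtureSpec()
    common = {"o2": 10.0, "h": 10.0}
    high_fiber = DietSpec(
        name="high_fiber", entries={"fiber": 10.0, "glc": 2.0, **common}
    )
    western = DietSpec(name="western", entries={"fiber": 2.0, "glc": 10.0, **common})
    return high_fiber, western


def make_toy_pbpk_params(renal_clearance: float = 5.0) -> PBPKParameters:
    """Six-tissue toy PBPK parameter set (order-1 values, rat gram weights).

    Gut gram weight 7.26 g and brain 2 g; partition coefficients default to
    1 so the no-source equilibrium is a uniform concentration.
    """
    tissues = {
        "brain": TissueParameters(0.8, 1.2, 0.6, 1.0, 1.0, 1.0, 2.0),
        "heart": TissueParameters(0.3, 0.3, 0.15, 1.0, 1.0, 1.0, 1.0),
        "adipose": TissueParameters(0.4, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0),
        "liver": TissueParameters(1.5, 1.5, 0.75, 1.0, 1.0, 1.0, 2.0),
        "gut": TissueParameters(1.0, 1.0, 0.5, 1.0, 1.0, 1.0, 7.26),
        "kidney": TissueParameters(1.2, 0.4, 0.2, 1.0, 1.0, 1.0, 1.0),
    }
    return PBPKParameters(tissues=tissues, blood_volume=1.0, renal_clearance=renal_clearance)


def make_toy_community(
    spec: FixtureSpec | None = None,
    diet: DietSpec | None = None,
    include_beneficial: bool = True,
    include_harmful: bool = True,
    oxygen_lb: float = -1.0,
) -> CommunityModel:
    """Assemble the fixture gut community (members + host, diet applied)."""
    spec = spec or FixtureSpec()
    members: dict[str, cobra.Model] = {}
    if include_beneficial:
        for tag in spec.beneficial_tags:
            members[tag] = make_toy_member("beneficial", spec, name=tag)
    if include_harmful:
        for tag in spec.harmful_tags:
            members[tag] = make_toy_member("harmful", spec, name=tag)
    if not members:
        raise ValueError("community needs at least one member")
    host = make_toy_host(include_sod=spec.include_sod, spec=spec)
    community = build_community(members, host)
    if diet is not None:
        apply_diet(community, diet)
    set_oxygen_condition(community, oxygen_lb)
    return community


def write_fixtures(directory: str | Path, spec: FixtureSpec | None = None) -> dict:
    """Write the full fixture set (SBML + diet JSON + PBPK YAML) to disk."""
    spec = spec or FixtureSpec()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for tag in spec.beneficial_tags:
        path = directory / f"{tag}.xml"
        write_sbml(make_toy_member("beneficial", spec, name=tag), path)
        written[tag] = str(path)
    for tag in spec.harmful_tags:
        path = directory / f"{tag}.xml"
        write_sbml(make_toy_member("harmful", spec, name=tag), path)
        written[tag] = str(path)
    host_path = directory / "host.xml"
    write_sbml(make_toy_host(spec.include_sod, spec), host_path)
    written["host"] = str(host_path)
    brain_path = directory / "brain.xml"
    write_sbml(make_toy_brain(), brain_path)
    written["brain"] = str(brain_path)
    high_fiber, western = make_toy_diets(spec)
    for diet in (high_fiber, western):
        diet_path = directory / f"diet_{diet.name}.json"
        save_diet(diet, diet_path)
        written[f"diet_{diet.name}"] = str(diet_path)
    pbpk_path = directory / "pbpk.yaml"
    make_toy_pbpk_params().to_yaml(pbpk_path)
    written["pbpk"] = str(pbpk_path)
    manifest = directory / "fixtures.json"
    manifest.write_text(json.dumps(written, indent=2))
    return written
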