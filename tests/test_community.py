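"""Community assembly, diet application, and exchange splitting."""

import numpy as np
import pytest
from cobra.util.array import create_stoichiometric_matrix

import gutbrain as gb
from conftest import build_model


def _tiny_member(name, ex_mets):
    """Member with the given extracellular metabolites, growing on the first."""
    carbon = ex_mets[0]
    mets = [f"{m}_e" for m in ex_mets] + [f"{carbon}_c"]
    reactions = [(f"EX_{m}_e", {f"{m}_e": -1}, -1000, 1000) for m in ex_mets]
    reactions += [
        (f"T_{carbon}", {f"{carbon}_e": -1, f"{carbon}_c": 1}, 0, 1000),
        ("BIOMASS", {f"{carbon}_c": -1}, 0, 1000),
    ]
    model = build_model(name, mets, reactions)
    model.objective = "BIOMASS"
    return model


class TestBuildCommunity:
    def test_transport_and_lumen_counts(self):
        # 4 + 3 extracellular metabolites (1 shared) + host with 2 -> 9
        # transports, 6 distinct lumen metabolites
        m1 = _tiny_member("m1", ["a", "b", "c", "d"])
        m2 = _tiny_member("m2", ["a", "e", "f"])
        host = _tiny_member("hostm", ["a", "b"])
        community = gb.build_community({"m1": m1, "m2": m2}, host)
        assert community.n_transport_added == 9
        assert len(community.lumen_metabolites) == 6

    def test_rebuild_is_deterministic(self):
        def make():
            return gb.build_community(
                {"m1": _tiny_member("m1", ["a", "b"])}, _tiny_member("h", ["a"])
            )

        ids1 = [r.id for r in make().model.reactions]
        ids2 = [r.id for r in make().model.reactions]
        assert ids1 == ids2

    def test_duplicate_tags_rejected(self):
        member = _tiny_member("m1", ["a"])
        with pytest.raises(ValueError, match="duplicate"):
            gb.build_community({"host": member}, _tiny_member("h", ["a"]))

    def test_member_without_extracellular_mets(self, caplog):
        bare = build_model("bare", ["x_c"], [("SRC", {"x_c": 1}, 0, 5), ("BIOMASS", {"x_c": -1}, 0, 1000)])
        bare.objective = "BIOMASS"
        community = gb.build_community({"bare": bare}, _tiny_member("h", ["a"]))
        assert community.transport_reactions["bare"] == []

    def test_block_diagonal_except_lumen(self):
        community = gb.build_community(
            {"m1": _tiny_member("m1", ["a"]), "m2": _tiny_member("m2", ["b"])},
            _tiny_member("h", ["a"]),
        )
        model = community.model
        S = create_stoichiometric_matrix(model, array_type="dense")
        met_tags = [m.id.rsplit("_", 1)[-1] for m in model.metabolites]
        for j, rxn in enumerate(model.reactions):
            if rxn.id.startswith(("IEX_", "EX_")):
                continue  # lumen-coupling / boundary columns
            touched = {met_tags[i] for i in np.nonzero(S[:, j])[0]}
            assert len(touched) == 1  # internal columns touch one member only


class TestApplyDiet:
    def test_listed_open_others_closed(self):
        community = gb.build_community(
            {"m1": _tiny_member("m1", ["a", "b", "c"])}, _tiny_member("h", ["a"])
        )
        gb.apply_diet(community, gb.DietSpec("d", {"a": 10.0}))
        model = community.model
        assert model.reactions.get_by_id("EX_a_lu_diet").lower_bound == -10.0
        for met in ("b", "c"):
            assert model.reactions.get_by_id(f"EX_{met}_lu_diet").lower_bound == 0.0

    def test_empty_diet_starves(self):
        community = gb.build_community(
            {"m1": _tiny_member("m1", ["a"])}, _tiny_member("h", ["a"])
        )
        gb.apply_diet(community, gb.DietSpec("empty", {}))
        sol = gb.solve_fba(community.model, community.biomass_reactions["m1"])
        assert sol.status != "optimal" or sol.objective_value == pytest.approx(0.0, abs=1e-8)

    def test_unknown_entry_skipped_with_warning(self, caplog):
        community = gb.build_community(
            {"m1": _tiny_member("m1", ["a"])}, _tiny_member("h", ["a"])
        )
        with caplog.at_level("WARNING"):
            gb.apply_diet(community, gb.DietSpec("d", {"a": 1.0, "unobtainium": 5.0}))
        assert "unobtainium" in caplog.text

    def test_negative_allowance_rejected(self):
        with pytest.raises(ValueError):
            gb.DietSpec("bad", {"a": -1.0})

    def test_carbon_availability_shifts_growth(self, fixture_spec, diets):
        ben_hf = gb.make_toy_community(diet=diets["high_fiber"], include_harmful=False)
        ben_wd = gb.make_toy_community(diet=diets["western"], include_harmful=False)
        growth = {}
        for label, com in (("hf", ben_hf), ("wd", ben_wd)):
            sol = gb.pareto_linear_search(
                gb.ParetoProblem(com.model, list(com.biomass_reactions.values()))
            )
            growth[label] = sum(sol.objective_fluxes)
        assert growth["hf"] > growth["wd"]


class TestOxygenCondition:
    def test_default_lb(self, diets):
        community = gb.make_toy_community(diet=diets["high_fiber"])
        for tag in community.member_tags:
            rxn = community.model.reactions.get_by_id(f"IEX_o2_lu_{tag}")
            assert rxn.lower_bound == -1.0

    def test_anaerobic_stops_obligate_aerobe(self, diets):
        community = gb.make_toy_community(diet=diets["western"], include_beneficial=False)
        gb.set_oxygen_condition(community, 0.0)
        # host o2 uptake unrestricted, members cut off: member growth -> 0
        for tag in community.member_tags:
            sol = gb.solve_fba(community.model, community.biomass_reactions[tag])
            assert sol.objective_value == pytest.approx(0.0, abs=1e-8)

    def test_idempotent(self, diets):
        community = gb.make_toy_community(diet=diets["high_fiber"])
        bounds1 = {r.id: r.bounds for r in community.model.reactions}
        gb.set_oxygen_condition(community, -1.0)
        bounds2 = {r.id: r.bounds for r in community.model.reactions}
        assert bounds1 == bounds2


class TestSplitReversibleExchange:
    def test_sign_split(self):
        model = build_model("t", ["a_e"], [("EX_a_e", {"a_e": -1}, -5, 8)])
        rxn_in, rxn_out = gb.split_reversible_exchange(model, "EX_a_e")
        assert model.reactions.get_by_id(rxn_in).bounds == (0, 5)
        assert model.reactions.get_by_id(rxn_out).bounds == (0, 8)

    def test_already_irreversible(self):
        model = build_model("t", ["a_e"], [("EX_a_e", {"a_e": -1}, 0, 8)])
        rxn_in, rxn_out = gb.split_reversible_exchange(model, "EX_a_e")
        assert model.reactions.get_by_id(rxn_in).bounds == (0, 0)
        assert model.reactions.get_by_id(rxn_out).bounds == (0, 8)

    def test_non_exchange_rejected(self, chain_model):
        with pytest.raises(ValueError):
            gb.split_reversible_exchange(chain_model, "R_ab")

    def test_fba_optimum_preserved(self, chain_model):
        before = gb.solve_fba(chain_model, "EX_c").objective_value
        gb.split_reversible_exchange(chain_model, "EX_a")
        after = gb.solve_fba(chain_model, "EX_c").objective_value
        assert after == pytest.approx(before, abs=1e-9)

    def test_all_exchanges_split_preserves_objectives(self, diets):
        community = gb.make_toy_community(diet=diets["western"], include_beneficial=False)
        rid = community.biomass_reactions["harm1"]
        before = gb.solve_fba(community.model, rid).objective_value
        for ex_id in list(community.diet_exchanges.values()):
            gb.split_reversible_exchange(community.model, ex_id)
        after = gb.solve_fba(community.model, rid).objective_value
        assert after == pytest.approx(before, abs=1e-8)


def test_diet_json_round_trip(tmp_path):
    from gutbrain.community import save_diet

    diet = gb.DietSpec("custom", {"a": 1.5, "b": 2.0})
    path = tmp_path / "diet.json"
    save_diet(diet, path)
    back = gb.load_diet(path)
    assert back.name == "custom"
    assert back.entries == diet.entries


def test_diet_tsv_loading(tmp_path):
    path = tmp_path / "diet.tsv"
    path.write_text("metabolite\tmax_uptake\nglc\t10\nfiber\t2.5\n")
    diet = gb.load_diet(path)
    assert diet.entries == {"glc": 10.0, "fiber": 2.5}
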