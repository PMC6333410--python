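"""FBA correctness against brute-force vertex enumeration, constraint
application (knockouts, overexpression, aeration), and the four yield
features."""

import numpy as np
import pytest
import cobra
from cobra import Metabolite, Reaction

from cellfactory.flux import (ModificationSpec, apply_modifications,
                              compute_flux_features, fba, load_model,
                              spec_from_record, wrap_model, ConfigurationError)
from cellfactory.synth import (CARBON_EXCHANGES, make_toy_model,
                               toy_analytic_yields)

GLC10 = {"EX_glc": 10.0}


def _mini_model(reactions, biomass="EX_b", product="EX_b", carbon=("EX_a",)):
    """Assemble a cobra model from (id, stoich, lb, ub) tuples."""
    model = cobra.Model("mini")
    mets = {}
    rxns = []
    for rid, stoich, lb, ub in reactions:
        r = Reaction(rid)
        for mid, coef in stoich.items():
            mets.setdefault(mid, Metabolite(mid, compartment="c"))
            r.add_metabolites({mets[mid]: coef})
        r.bounds = (lb, ub)
        rxns.append(r)
    model.add_reactions(rxns)
    return wrap_model(model, biomass_id=biomass, product_id=product,
                      carbon_ids=carbon)


@pytest.fixture
def linear_chain():
    # A -> B -> out, uptake capped at 10
    return _mini_model([
        ("EX_a", {"a": -1}, -10, 1000),
        ("AB", {"a": -1, "b": 1}, 0, 1000),
        ("EX_b", {"b": -1}, 0, 1000),
    ])


@pytest.fixture
def branched():
    # A -> B (1:1) and A -> 2 C; separate sinks with distinct caps
    return _mini_model([
        ("EX_a", {"a": -1}, -10, 1000),
        ("AB", {"a": -1, "b": 1}, 0, 1000),
        ("AC", {"a": -1, "c": 2}, 0, 6),
        ("EX_b", {"b": -1}, 0, 4),
        ("EX_c", {"c": -1}, 0, 1000),
    ], product="EX_c")


class TestFBAAgainstEnumeration:
    def _oracle_inputs(self, m):
        model = m.cobra_model
        S = cobra.util.array.create_stoichiometric_matrix(model)
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
        ids = [r.id for r in model.reactions]
        return S, lb, ub, ids

    @pytest.mark.parametrize("objective", ["EX_b", "AB"])
    def test_linear_chain_optimum(self, linear_chain, lp_oracle, objective):
        S, lb, ub, ids = self._oracle_inputs(linear_chain)
        c = np.array([1.0 if i == objective else 0.0 for i in ids])
        expected = lp_oracle(S, lb, ub, c)
        res = fba(linear_chain, objective)
        assert res.optimal
        assert res.objective_value == pytest.approx(expected, abs=1e-6)
        assert res.objective_value == pytest.approx(10.0, abs=1e-6)

    @pytest.mark.parametrize("objective,expected", [
        ("EX_b", 4.0),     # capped sink
        ("EX_c", 12.0),    # 2:1 branch capped at AC flux 6
    ])
    def test_branched_optima(self, branched, lp_oracle, objective, expected):
        S, lb, ub, ids = self._oracle_inputs(branched)
        c = np.array([1.0 if i == objective else 0.0 for i in ids])
        assert lp_oracle(S, lb, ub, c) == pytest.approx(expected, abs=1e-9)
        res = fba(branched, objective)
        assert res.objective_value == pytest.approx(expected, abs=1e-6)

    def test_all_exchanges_closed_forces_zero(self, linear_chain):
        m = apply_modifications(linear_chain, ModificationSpec())  # no uptake
        res = fba(m, "EX_b")
        assert res.optimal and res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_contradictory_constraint_is_infeasible(self, linear_chain):
        res = fba(linear_chain, "EX_b",
                  extra_constraints=[({"EX_b": 1.0}, "ge", 50.0)])
        assert res.status == "infeasible"

    def test_unbounded_objective_reported(self):
        m = _mini_model([
            ("EX_a", {"a": -1}, -np.inf, np.inf),
            ("EX_b", {"a": -1}, -np.inf, np.inf),
        ], biomass="EX_b", product="EX_b")
        assert fba(m, "EX_b").status == "unbounded"

    def test_fixed_settings_are_deterministic(self, branched):
        r1 = fba(branched, "EX_c")
        r2 = fba(branched, "EX_c")
        assert np.array_equal(r1.fluxes.values, r2.fluxes.values)


class TestModifications:
    def test_empty_spec_is_identity_on_bounds(self, toy_model):
        before = toy_model.bounds
        spec = ModificationSpec(carbon_uptake={"EX_glc": toy_model.cobra_model
                                               .reactions.EX_glc.lower_bound * -1})
        after = apply_modifications(toy_model, spec).bounds
        assert before == after
        assert toy_model.bounds == before  # original untouched

    def test_sole_catalyst_knockout_zeroes_reaction(self, toy_model):
        out = apply_modifications(toy_model, ModificationSpec(
            knockouts=("gSPL",), carbon_uptake=GLC10))
        assert out.cobra_model.reactions.SPLIT.bounds == (0.0, 0.0)

    def test_isozyme_or_rule_survives_single_knockout(self, toy_model):
        out = apply_modifications(toy_model, ModificationSpec(
            knockouts=("gP2",), carbon_uptake=GLC10))
        assert out.cobra_model.reactions.PRODSYN.upper_bound > 0

    def test_and_rule_dies_with_either_subunit(self, toy_model):
        out = apply_modifications(toy_model, ModificationSpec(
            knockouts=("gPTS2",), carbon_uptake=GLC10))
        assert out.cobra_model.reactions.PTS.bounds == (0.0, 0.0)

    def test_overexpression_sets_lb_to_tenth_of_max(self, toy_model):
        # theoretical max product flux is 20 at uptake 10 -> lower bound 2.0
        out = apply_modifications(toy_model, ModificationSpec(
            overexpress=("PRODSYN",), carbon_uptake=GLC10, oxygen="aerobic"))
        assert out.cobra_model.reactions.PRODSYN.lower_bound == pytest.approx(2.0, abs=1e-6)

    def test_blocked_overexpression_target_left_untouched(self, toy_model):
        # no glycerol available -> GLYCUP theoretical max 0 -> bound unchanged
        out = apply_modifications(toy_model, ModificationSpec(
            overexpress=("GLYCUP",), carbon_uptake=GLC10))
        assert out.cobra_model.reactions.GLYCUP.lower_bound == 0.0

    def test_aeration_regimes_scale_oxygen_uptake(self, toy_model):
        for regime, expected in [("anaerobic", 0.0), ("microaerobic", -4.0),
                                 ("aerobic", -20.0)]:
            out = apply_modifications(toy_model, ModificationSpec(
                carbon_uptake=GLC10, oxygen=regime))
            assert out.cobra_model.reactions.EX_o2.lower_bound == pytest.approx(expected)

    def test_knockout_and_overexpression_must_be_disjoint(self):
        with pytest.raises(ValueError, match="knocked out and overexpressed"):
            ModificationSpec(knockouts=("gX",), overexpress=("gX",))

    def test_tightening_a_bound_never_raises_the_optimum(self, toy_model):
        base = compute_flux_features(toy_model, ModificationSpec(
            carbon_uptake=GLC10, oxygen="aerobic"))
        tight = compute_flux_features(toy_model, ModificationSpec(
            carbon_uptake={"EX_glc": 6.0}, oxygen="aerobic"))
        assert tight.vb_star <= base.vb_star + 1e-9
        assert tight.vp_star <= base.vp_star + 1e-9


class TestFluxFeatures:
    def test_toy_network_matches_closed_forms(self, toy_model):
        ana = toy_analytic_yields()
        fx = compute_flux_features(toy_model, ModificationSpec(
            carbon_uptake=GLC10, oxygen="aerobic"))
        assert fx.feasible
        assert fx.vb_star == pytest.approx(ana["vb_max_aerobic"], abs=1e-6)
        assert fx.vp_star == pytest.approx(ana["vp_max"], abs=1e-6)
        assert fx.yp_max == pytest.approx(ana["yp_max"], abs=1e-6)
        assert fx.yb_max == pytest.approx(ana["yb_max_aerobic"], abs=1e-6)
        assert fx.yb50p == pytest.approx(ana["yb50p"], abs=1e-6)
        assert fx.yp50b == pytest.approx(ana["yp50b"], abs=1e-6)

    def test_anaerobic_growth_pays_fermentation_overhead(self, toy_model):
        ana = toy_analytic_yields()
        fx = compute_flux_features(toy_model, ModificationSpec(
            carbon_uptake=GLC10, oxygen="anaerobic"))
        assert fx.vb_star == pytest.approx(ana["vb_max_anaerobic"], abs=1e-6)
        assert fx.yb_max == pytest.approx(ana["yb_max_anaerobic"], abs=1e-6)

    def test_product_branch_knockout_zeroes_product_yield_only(self, toy_model):
        fx = compute_flux_features(toy_model, ModificationSpec(
            knockouts=("gP1", "gP2"), carbon_uptake=GLC10, oxygen="aerobic"))
        assert fx.feasible
        assert fx.vp_star == pytest.approx(0.0, abs=1e-9)
        assert fx.yp_max == pytest.approx(0.0, abs=1e-9)
        assert fx.vb_star > 0

    def test_half_constraint_yields_bounded_by_maxima(self, toy_model):
        rng = np.random.default_rng(11)
        regimes = ["anaerobic", "microaerobic", "aerobic", "extra-aerobic"]
        genes = list("x")  # placeholder; real pool below
        pool = ["gF", "gR", "gP2", "gGLY", "gSPL"]
        for _ in range(25):
            kos = tuple(g for g in pool if rng.random() < 0.3)
            spec = ModificationSpec(
                knockouts=kos,
                overexpress=("PRODSYN",) if (rng.random() < 0.4 and "gP1" not in kos) else (),
                carbon_uptake={"EX_glc": float(rng.uniform(2, 10))},
                oxygen=regimes[rng.integers(0, 4)])
            fx = compute_flux_features(toy_model, spec)
            if fx.feasible:
                assert -1e-6 <= fx.yb50p <= fx.yb_max + 1e-6
                assert -1e-6 <= fx.yp50b <= fx.yp_max + 1e-6

    def test_measured_growth_floor_restricts_product_side(self, toy_model):
        free = compute_flux_features(toy_model, ModificationSpec(
            carbon_uptake=GLC10, oxygen="aerobic"))
        floored = compute_flux_features(toy_model, ModificationSpec(
            carbon_uptake=GLC10, oxygen="aerobic", growth_rate=2.0))
        assert floored.vp_star < free.vp_star
        assert floored.vb_star == pytest.approx(free.vb_star, abs=1e-6)


class TestModelIO:
    def test_json_round_trip_preserves_optima(self, toy_model, tmp_path):
        make_toy_model(out_dir=tmp_path)
        loaded = load_model(tmp_path / "toy_model.json",
                            biomass_id="BIOMASS", product_id="EX_prod",
                            carbon_ids=("EX_glc", "EX_glyc"), oxygen_id="EX_o2")
        fx = compute_flux_features(loaded, ModificationSpec(
            carbon_uptake=GLC10, oxygen="aerobic"))
        assert fx.yp_max == pytest.approx(2.0, abs=1e-6)

    def test_sbml_round_trip_preserves_gene_rules(self, tmp_path):
        make_toy_model(out_dir=tmp_path)
        loaded = load_model(tmp_path / "toy_model.xml",
                            biomass_id="BIOMASS", product_id="EX_prod",
                            carbon_ids=("EX_glc", "EX_glyc"), oxygen_id="EX_o2")
        out = apply_modifications(loaded, ModificationSpec(
            knockouts=("gSPL",), carbon_uptake=GLC10))
        assert out.cobra_model.reactions.SPLIT.bounds == (0.0, 0.0)

    def test_unresolved_designation_is_configuration_error(self, tmp_path):
        make_toy_model(out_dir=tmp_path)
        with pytest.raises(ConfigurationError, match="biomass"):
            load_model(tmp_path / "toy_model.json", biomass_id="NOPE",
                       product_id="EX_prod", carbon_ids=("EX_glc",))

    def test_malformed_sbml_names_the_standard(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<notsbml/>")
        with pytest.raises(ConfigurationError, match="SBML"):
            load_model(bad, biomass_id="BIOMASS", product_id="EX_prod",
                       carbon_ids=("EX_glc",))


class TestSpecFromRecord:
    def test_record_genes_and_environment_map_to_model(self, toy_model):
        from cellfactory.synth import fixture_record
        import dataclasses
        rec = dataclasses.replace(
            fixture_record(),
            gene_mod=("gF", "gP1", "alsS"), gene_del=(1, 0, 0),
            gene_ovr=(0, 1, 1), het_gene=(0, 0, 1), rep_origin=(0.0, 5.0, 5.0),
            codon_opt=(0, 0, 0), sen_reg=(0, 0, 0), enz_design=(0, 0, 0),
            protein_scaffold=(0, 0, 0), oxygen="anaerobic")
        spec = spec_from_record(rec, toy_model, CARBON_EXCHANGES)
        assert spec.knockouts == ("gF",)
        assert spec.overexpress == ("PRODSYN",)   # via gP1's reactions
        assert spec.carbon_uptake == {"EX_glc": 10.0}
        assert spec.oxygen == "anaerobic"
        assert spec.growth_rate == rec.bio_grw_rate
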