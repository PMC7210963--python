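"""FBA/FVA core, gene deletion, knock-ins, screens, biomass variants."""

from fractions import Fraction

import numpy as np
import pytest

from zmgem import (
    Metabolite,
    Model,
    Reaction,
    biomass_variant,
    delete_genes,
    fba,
    fva,
    knock_in,
    substrate_screen,
)
from zmgem.flux import BalanceError, knockout_bounds
from zmgem.lp import STEADY_STATE_TOL
from zmgem.synth import ToySpec, make_toy_ed_model, pathway_preset, toy_media

from conftest import brute_force_lp_max


class TestFBA:
    def test_toy_ethanol_yield_is_two_per_glucose(self, toy_model, toy_truth, media):
        res = fba(toy_model, media["RM"], objective="EX_etoh_e")
        assert res.optimal
        assert res.objective_value == pytest.approx(toy_truth["ethanol_max"])

    def test_growth_matches_analytic_optimum(self, toy_model, toy_truth, media):
        res = fba(toy_model, media["RM"])
        assert res.objective_value == pytest.approx(toy_truth["growth_anaerobic"])
        aer = fba(toy_model, media["RM_aerobic"])
        assert aer.objective_value == pytest.approx(toy_truth["growth_aerobic"])

    def test_all_exchanges_closed_means_no_growth(self, toy_model, media):
        closed = media["RM"].with_(carbon_exchanges=[], name="closed")
        res = fba(toy_model, closed)
        assert res.optimal and res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_optimal_solution_satisfies_steady_state_and_bounds(
        self, toy_model, media
    ):
        res = fba(toy_model, media["RM"])
        S = toy_model.stoichiometric_matrix()
        v = np.array([res.fluxes[r] for r in toy_model.reactions])
        assert np.abs(S @ v).max() <= STEADY_STATE_TOL
        medium_bounds = media["RM"].apply(toy_model)
        for j, rid in enumerate(toy_model.reactions):
            lo, hi = medium_bounds.get(
                rid,
                (toy_model.reactions[rid].lower_bound,
                 toy_model.reactions[rid].upper_bound),
            )
            assert lo - 1e-7 <= v[j] <= hi + 1e-7

    def test_unknown_objective_raises(self, toy_model):
        with pytest.raises(KeyError):
            fba(toy_model, objective="NOPE")

    def test_lp_matches_vertex_enumeration_oracle(self, tiny_lp_model):
        """On <=8-reaction models the LP optimum equals the brute-force
        polytope-vertex enumeration optimum."""
        res = fba(tiny_lp_model)
        oracle = brute_force_lp_max(tiny_lp_model, tiny_lp_model.objective_id)
        assert res.objective_value == pytest.approx(oracle, abs=1e-6)

    def test_relaxing_a_bound_never_decreases_the_optimum(self, tiny_lp_model):
        base = fba(tiny_lp_model).objective_value
        for rid, rxn in tiny_lp_model.reactions.items():
            relaxed = fba(
                tiny_lp_model,
                extra_bounds={rid: (rxn.lower_bound - 1.0, rxn.upper_bound + 1.0)},
            )
            assert relaxed.objective_value >= base - 1e-9


class TestFVA:
    def test_single_reaction_fva_equals_fba_extremes(self, toy_model, media):
        rng = np.random.default_rng(0)
        rids = list(rng.choice(list(toy_model.reactions), size=8, replace=False))
        res = fva(toy_model, media["RM"], rids)
        for rid in rids:
            lo = fba(toy_model, media["RM"], objective=rid, direction="min")
            hi = fba(toy_model, media["RM"], objective=rid, direction="max")
            assert res[rid][0] == pytest.approx(lo.objective_value, abs=1e-6)
            assert res[rid][1] == pytest.approx(hi.objective_value, abs=1e-6)

    def test_irreversible_with_zero_upper_bound_is_pinned(self):
        m = Model()
        m.add_metabolite(Metabolite("a_e", compartment="e"))
        m.add_reaction(Reaction("EX", {"a_e": Fraction(-1)}, -5, 1000))
        m.add_reaction(Reaction("DEAD", {"a_e": Fraction(-1)}, 0, 0))
        res = fva(m)
        assert res["DEAD"] == (0.0, 0.0)

    def test_min_le_max_and_within_bounds(self, toy_model, media):
        res = fva(toy_model, media["RM"])
        for rid, (lo, hi) in res.ranges.items():
            assert lo <= hi + 1e-9


class TestKnockouts:
    def test_empty_deletion_is_identity(self, toy_model, media):
        plain = fba(toy_model, media["RM"])
        deleted, disabled = delete_genes(toy_model, set(), media["RM"])
        assert disabled == []
        assert deleted.objective_value == pytest.approx(plain.objective_value)

    def test_pdc_ldh_deletion_disables_both_reactions(
        self, toy_model, toy_truth, media
    ):
        res, disabled = delete_genes(
            toy_model, toy_truth["pdc_ldh_genes"], media["RM"]
        )
        assert set(disabled) == {"PDC", "LDH"}
        assert res.objective_value == pytest.approx(toy_truth["growth_pdc_ldh_ko"])

    def test_succinate_strictly_increases_after_pdc_ldh_knockout(
        self, toy_model, toy_truth, media
    ):
        """Removing the ethanol/lactate routes redirects flux to succinate."""
        wt = fva(toy_model, media["RM"], ["EX_succ_e"], fraction_of_optimum=1.0)
        ko_bounds, _ = knockout_bounds(toy_model, toy_truth["pdc_ldh_genes"])
        ko = fva(toy_model, media["RM"], ["EX_succ_e"], fraction_of_optimum=1.0,
                 extra_bounds=ko_bounds)
        assert wt["EX_succ_e"][1] == pytest.approx(
            toy_truth["succinate_at_optimum"], rel=1e-6)
        assert ko["EX_succ_e"][1] == pytest.approx(
            toy_truth["succinate_at_ko_optimum"], rel=1e-6)
        assert ko["EX_succ_e"][1] > wt["EX_succ_e"][1] + 1.0

    def test_essential_gene_kills_growth(self, toy_model, media):
        # ED lump is the only route to pyruvate and ATP
        res, _ = delete_genes(toy_model, {"ZMS0367"}, media["RM"])
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unknown_gene_raises(self, toy_model, media):
        from zmgem.model import UnknownGeneError

        with pytest.raises(UnknownGeneError):
            delete_genes(toy_model, {"NOPE"}, media["RM"])


class TestKnockIns:
    def test_xylose_pathway_enables_growth_and_orders_ethanol(
        self, toy_model, media
    ):
        xk = knock_in(toy_model, pathway_preset("xylose"))
        glc = media["RM"]
        xyl = glc.with_(name="xylose", carbon_exchanges=["EX_xyl_e"])
        mix = glc.with_(name="mixed", carbon_exchanges=["EX_glc_e", "EX_xyl_e"])
        e_glc = fba(xk, glc, "EX_etoh_e").objective_value
        e_xyl = fba(xk, xyl, "EX_etoh_e").objective_value
        e_mix = fba(xk, mix, "EX_etoh_e").objective_value
        assert e_glc == pytest.approx(20.0)
        assert e_xyl == pytest.approx(50.0 / 3.0)
        assert e_mix == pytest.approx(110.0 / 3.0)
        assert e_mix > e_glc > e_xyl
        assert fba(xk, xyl).objective_value > 0.5  # growth on xylose alone

    def test_arabinose_pathway_restores_growth(self, toy_model, media):
        ak = knock_in(toy_model, pathway_preset("arabinose"))
        ara = media["RM"].with_(name="ara", carbon_exchanges=["EX_arab_e"])
        assert fba(toy_model, media["RM"].with_(
            carbon_exchanges=[], name="none")).objective_value == pytest.approx(0, abs=1e-9)
        assert fba(ak, ara).objective_value > 0.5

    def test_beta_carotene_pathway_carries_flux(self, toy_model, media):
        ck = knock_in(toy_model, pathway_preset("beta_carotene"))
        res = fba(ck, media["RM"], "EX_caro_e")
        assert res.objective_value == pytest.approx(5.0 / 7.0)

    def test_alanine_production_trades_off_ethanol(self, toy_model, media):
        alk = knock_in(toy_model, pathway_preset("alanine"))
        base = fba(alk, media["RM"], "EX_etoh_e").objective_value
        # force alanine secretion (ammonia uptake open) and re-maximize ethanol
        forced = fba(alk, media["RM"], "EX_etoh_e",
                     extra_bounds={"EX_ala_e": (2.0, 1000.0),
                                   "EX_nh3_e": (-1000.0, 1000.0)}).objective_value
        assert base == pytest.approx(20.0)
        assert forced < base

    def test_butanediol_on_mixed_carbon_exceeds_single(self, toy_model, media):
        bk = knock_in(knock_in(toy_model, pathway_preset("butanediol")),
                      pathway_preset("xylose"))
        glc = media["RM"]
        mix = glc.with_(name="mixed", carbon_exchanges=["EX_glc_e", "EX_xyl_e"])
        b_glc = fba(bk, glc, "EX_btd_e").objective_value
        b_mix = fba(bk, mix, "EX_btd_e").objective_value
        assert b_mix > b_glc > 0

    def test_duplicate_knock_in_is_noticed_and_skipped(self, toy_model):
        once = knock_in(toy_model, pathway_preset("xylose"))
        with pytest.warns(UserWarning, match="duplicates"):
            twice = knock_in(once, pathway_preset("xylose"))
        assert len(twice.reactions) == len(once.reactions)

    def test_unbalanced_addition_rejected(self, toy_model):
        from zmgem.flux import KnockInPathway

        bad = KnockInPathway(
            name="bad",
            metabolites=[],
            reactions=[Reaction("BAD", {"pyr_c": Fraction(-1),
                                        "etoh_c": Fraction(1)}, 0, 1000)],
        )
        with pytest.raises(BalanceError):
            knock_in(toy_model, bad)
        permitted = knock_in(toy_model, bad, check_mass_balance=False)
        assert "BAD" in permitted.reactions


class TestSubstrateScreen:
    def test_carbon_sources_called_correctly(self, toy_model, media):
        observed = {
            "EX_glc_e": True, "EX_fru_e": True, "EX_sucr_e": True,
            "EX_glcn_e": False, "EX_lev_e": False,
        }
        calls = substrate_screen(
            toy_model,
            [("EX_glc_e", "C"), ("EX_fru_e", "C"), ("EX_sucr_e", "C"),
             ("EX_glcn_e", "C"), ("EX_lev_e", "C"), ("EX_xyl_e", "C")],
            media["RM"],
            observed=observed,
        )
        by_substrate = {c.substrate: c for c in calls}
        assert by_substrate["EX_glc_e"].category == "Growth/True"
        assert by_substrate["EX_fru_e"].category == "Growth/True"
        assert by_substrate["EX_sucr_e"].category == "Growth/True"
        # gluconate: model predicts growth, phenotype says no (false positive)
        assert by_substrate["EX_glcn_e"].category == "Growth/False"
        assert by_substrate["EX_lev_e"].category == "No-Growth/True"
        assert by_substrate["EX_xyl_e"].category == "non-tested"

    def test_other_sources_of_class_are_closed(self, toy_model, media):
        # levan alone cannot support growth even though glucose could
        calls = substrate_screen(toy_model, [("EX_lev_e", "C")], media["RM"])
        assert calls[0].predicted is False


class TestBiomassVariant:
    def test_cellulose_requirement_makes_synthase_essential(
        self, toy_model, media
    ):
        cellmodel = biomass_variant(toy_model, {"cel_c": -0.05})
        grows = fba(cellmodel, media["minimal_aerobic"])
        assert grows.objective_value > 0.1
        res, disabled = delete_genes(
            cellmodel, {"ZMS1083"}, media["minimal_aerobic"]
        )
        assert "CELS" in disabled
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_empty_additions_is_identity(self, toy_model, media):
        same = biomass_variant(toy_model, {})
        assert fba(same, media["RM"]).objective_value == pytest.approx(
            fba(toy_model, media["RM"]).objective_value
        )

    def test_positive_coefficient_rejected(self, toy_model):
        with pytest.raises(ValueError):
            biomass_variant(toy_model, {"cel_c": 0.05})

    def test_unproducible_precursor_blocks_growth(self, toy_model, media):
        # xylose is not in the wild-type toy: an unproducible precursor
        model = toy_model.copy()
        model.add_metabolite(Metabolite("orphan_c", compartment="c"))
        model.add_reaction(Reaction("ORPHAN_SINK",
                                    {"orphan_c": Fraction(-1)}, 0, 0))
        variant = biomass_variant(model, {"orphan_c": -0.1})
        res = fba(variant, media["RM"])
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)


class TestAminoAcidCap:
    def test_growth_scales_linearly_with_amino_acid_allowance(self):
        model, _ = make_toy_ed_model(ToySpec(biomass_requires_aa=True))
        media_aa = toy_media(model)
        growths = []
        for cap in (0.05, 0.1, 0.2):
            medium = media_aa["RM"].with_(amino_acid_uptake=cap)
            growths.append(fba(model, medium).objective_value)
        assert growths[0] == pytest.approx(0.05)
        assert growths[1] == pytest.approx(0.1)
        assert growths[2] == pytest.approx(0.2)


@pytest.fixture(scope="module")
def cobra_pair(toy_model, media, tmp_path_factory):
    cobra = pytest.importorskip("cobra")
    path = tmp_path_factory.mktemp("cobra") / "toy.xml"
    from zmgem import write_model

    write_model(toy_model, path)
    cmodel = cobra.io.read_sbml_model(str(path))
    bounds = media["RM"].apply(toy_model)
    for rid, (lo, hi) in bounds.items():
        rxn = cmodel.reactions.get_by_id(rid)
        rxn.lower_bound, rxn.upper_bound = lo, hi
    return cmodel


class TestCobraCrossCheck:
    """Independent oracle: the same SBML solved by the cobra toolbox."""

    def test_fba_objective_agrees(self, cobra_pair, toy_model, media, toy_truth):
        sol = cobra_pair.optimize()
        ours = fba(toy_model, media["RM"])
        assert sol.objective_value == pytest.approx(ours.objective_value, rel=1e-6)

    def test_fva_ranges_agree(self, cobra_pair, toy_model, media):
        from cobra.flux_analysis import flux_variability_analysis

        rids = ["EX_etoh_e", "EX_succ_e", "ED", "PDC", "BIOMASS"]
        theirs = flux_variability_analysis(
            cobra_pair, reaction_list=rids, fraction_of_optimum=0.0
        )
        ours = fva(toy_model, media["RM"], rids)
        for rid in rids:
            assert ours[rid][0] == pytest.approx(theirs.loc[rid, "minimum"], abs=1e-5)
            assert ours[rid][1] == pytest.approx(theirs.loc[rid, "maximum"], abs=1e-5)
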