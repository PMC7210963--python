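"""Dead-end detection, blocked reactions, and MILP gap filling."""

import itertools
from fractions import Fraction

import pytest

from zmgem import (
    Metabolite,
    Model,
    Reaction,
    fba,
    find_blocked,
    find_dead_ends,
    find_gaps,
    gap_fill,
)
from zmgem.synth import ToySpec, make_toy_ed_model, toy_media


def chain_model(break_bc: bool = False):
    """a_e -> a -> b -> c (drainable); optionally delete the b->c step."""
    m = Model(id="chain")
    m.add_metabolite(Metabolite("a_e", compartment="e"))
    for mid in ("a_c", "b_c", "c_c"):
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("EX_a", {"a_e": Fraction(-1)}, -10, 1000))
    m.add_reaction(Reaction("T_a", {"a_e": Fraction(-1), "a_c": Fraction(1)}, 0, 1000))
    m.add_reaction(Reaction("AB", {"a_c": Fraction(-1), "b_c": Fraction(1)}, 0, 1000))
    if not break_bc:
        m.add_reaction(Reaction("BC", {"b_c": Fraction(-1), "c_c": Fraction(1)}, 0, 1000))
    m.add_reaction(Reaction("C_SINK", {"c_c": Fraction(-1)}, 0, 1000))
    return m


class TestDeadEnds:
    def test_intact_chain_has_no_dead_ends(self):
        report = find_dead_ends(chain_model())
        assert not report.dead_ends

    def test_broken_chain_c_unproducible_b_unconsumable(self):
        report = find_dead_ends(chain_model(break_bc=True))
        assert "c_c" in report.no_production
        assert "b_c" in report.no_consumption

    def test_product_only_metabolite_is_no_consumption(self):
        m = Model()
        m.add_metabolite(Metabolite("a_e", compartment="e"))
        m.add_metabolite(Metabolite("waste_c", compartment="c"))
        m.add_reaction(Reaction("EX_a", {"a_e": Fraction(-1)}, -10, 1000))
        m.add_reaction(Reaction("MK", {"a_e": Fraction(-1), "waste_c": Fraction(1)},
                                0, 1000))
        report = find_dead_ends(m)
        assert "waste_c" in report.no_consumption
        assert "waste_c" not in report.no_production

    def test_planted_branch_gap_recovered_exactly(self, toy_model):
        baseline = find_gaps(toy_model)
        planted, truth = make_toy_ed_model(ToySpec(planted_gaps=("BR2_ISO",)))
        report = find_gaps(planted)
        expected = truth["dead_ends"]["BR2_ISO"]
        assert report.no_production - baseline.no_production == set(
            expected["no_production"])
        assert report.no_consumption - baseline.no_consumption == set(
            expected["no_consumption"])
        assert report.blocked_reactions - baseline.blocked_reactions == set(
            expected["blocked"])

    def test_dead_end_probes_match_brute_force_per_metabolite_lp(self, toy_model):
        """Cross-check the probe against an independently assembled LP."""
        import numpy as np
        from scipy.optimize import linprog

        planted, _ = make_toy_ed_model(ToySpec(planted_gaps=("BR1_ISO",)))
        report = find_dead_ends(planted)
        S = planted.stoichiometric_matrix().toarray()
        lb, ub = planted.bounds_arrays()
        for j, rxn in enumerate(planted.reactions.values()):
            if rxn.is_exchange:
                lb[j], ub[j] = -1000, 1000
        for i, met in enumerate(planted.metabolites):
            col = np.zeros((S.shape[0], 1))
            col[i, 0] = -1.0
            res = linprog(
                np.concatenate([np.zeros(S.shape[1]), [-1.0]]),
                A_eq=np.hstack([S, col]), b_eq=np.zeros(S.shape[0]),
                bounds=list(zip(np.append(lb, 0), np.append(ub, 1000))),
                method="highs",
            )
            producible = res.status == 0 and -res.fun >= 1e-6
            assert (met not in report.no_production) == producible, met


class TestBlocked:
    def test_fully_connected_toy_has_no_blocked_reactions(self, toy_model):
        assert not find_blocked(toy_model).blocked_reactions

    def test_reaction_behind_dead_end_is_blocked(self):
        report = find_blocked(chain_model(break_bc=True))
        assert "C_SINK" in report.blocked_reactions

    def test_isolated_reversible_cycle_is_not_blocked(self):
        """A <-> B two-reaction loop with no exchange: an internal loop can
        still carry circulating flux, so loopless-agnostic FVA reports both
        reactions unblocked (documented behavior)."""
        m = Model()
        m.add_metabolite(Metabolite("a_c", compartment="c"))
        m.add_metabolite(Metabolite("b_c", compartment="c"))
        m.add_reaction(Reaction("F", {"a_c": Fraction(-1), "b_c": Fraction(1)},
                                -1000, 1000))
        m.add_reaction(Reaction("G", {"b_c": Fraction(-1), "a_c": Fraction(1)},
                                -1000, 1000))
        report = find_blocked(m)
        assert not report.blocked_reactions


def universal_with(reactions, mets=("br1a_c", "br1b_c", "br2a_c", "br2b_c")):
    uni = Model(id="universal")
    for mid in mets:
        uni.add_metabolite(Metabolite(mid, formula="C6H12O6", charge=0,
                                      compartment="c"))
    for rxn in reactions:
        uni.add_reaction(rxn)
    return uni


class TestGapFill:
    @pytest.fixture()
    def gapped(self):
        model, truth = make_toy_ed_model(ToySpec(planted_gaps=("BR1_ISO",)))
        return model, toy_media(model)["RM"]

    def test_single_planted_deletion_repaired_by_exactly_that_reaction(
        self, gapped
    ):
        model, medium = gapped
        uni = universal_with([
            Reaction("BR1_ISO", {"br1a_c": Fraction(-1), "br1b_c": Fraction(1)},
                     0, 1000),
            Reaction("DISTRACT", {"br2a_c": Fraction(-1), "br2b_c": Fraction(1)},
                     0, 1000),
        ])
        sol = gap_fill(model, uni, "EX_br1b_e", medium)
        assert sol.status == "optimal"
        assert sol.added_reaction_ids == ["BR1_ISO"]
        assert sol.cardinality == 1
        assert sol.objective_flux_after >= 1e-6

    def test_already_feasible_target_needs_nothing(self, toy_model, media):
        uni = universal_with([])
        sol = gap_fill(toy_model, uni, "EX_etoh_e", media["RM"])
        assert sol.status == "optimal" and sol.cardinality == 0

    def test_empty_universal_is_unfillable(self, gapped):
        model, medium = gapped
        sol = gap_fill(model, universal_with([]), "EX_br1b_e", medium)
        assert sol.status == "unfillable"

    def test_nonpositive_eps_rejected(self, gapped):
        model, medium = gapped
        with pytest.raises(ValueError):
            gap_fill(model, universal_with([]), "EX_br1b_e", medium, eps=0.0)

    def test_weighted_choice_prefers_light_repair(self, gapped):
        model, medium = gapped
        uni = universal_with([
            Reaction("HEAVY", {"br1a_c": Fraction(-1), "br1b_c": Fraction(1)},
                     0, 1000),
            Reaction("LIGHT", {"br1a_c": Fraction(-2), "br1b_c": Fraction(2)},
                     0, 1000),
        ])
        sol = gap_fill(model, uni, "EX_br1b_e", medium,
                       weights={"HEAVY": 2.0, "LIGHT": 1.0})
        assert sol.added_reaction_ids == ["LIGHT"]

    def test_equal_weight_tie_breaks_lexicographically(self, gapped):
        model, medium = gapped
        uni = universal_with([
            Reaction("ZREPAIR", {"br1a_c": Fraction(-1), "br1b_c": Fraction(1)},
                     0, 1000),
            Reaction("AREPAIR", {"br1a_c": Fraction(-1), "br1b_c": Fraction(1)},
                     0, 500),
        ])
        sol = gap_fill(model, uni, "EX_br1b_e", medium)
        assert sol.added_reaction_ids == ["AREPAIR"]

    def test_two_step_repair_is_minimal_by_exhaustive_subsets(self):
        model, truth = make_toy_ed_model(
            ToySpec(planted_gaps=("BR1_ISO", "BR2_ISO")))
        medium = toy_media(model)["RM"]
        # the only repair routes through an intermediate known solely to the
        # universal database: a genuine two-reaction fill
        uni = universal_with(
            [
                Reaction("STEP1", {"br1a_c": Fraction(-1), "uint_c": Fraction(1)},
                         0, 1000),
                Reaction("STEP2", {"uint_c": Fraction(-1), "br1b_c": Fraction(1)},
                         0, 1000),
                Reaction("NOISE", {"br2b_c": Fraction(-1), "uint_c": Fraction(1)},
                         0, 1000),
            ],
            mets=("br1a_c", "br1b_c", "br2a_c", "br2b_c", "uint_c"),
        )
        sol = gap_fill(model, uni, "EX_br1b_e", medium)
        assert sol.status == "optimal"
        assert set(sol.added_reaction_ids) == {"STEP1", "STEP2"}
        # exhaustive subset oracle: no proper subset restores the target
        for k in range(len(sol.added_reaction_ids)):
            for subset in itertools.combinations(sol.added_reaction_ids, k):
                test_model = model.copy()
                for rid in subset:
                    src = uni.reactions[rid]
                    for mid in src.stoichiometry:
                        if mid not in test_model.metabolites:
                            met = uni.metabolites[mid]
                            test_model.add_metabolite(
                                Metabolite(mid, formula=met.formula,
                                           charge=met.charge,
                                           compartment=met.compartment))
                    test_model.add_reaction(
                        Reaction(rid, dict(src.stoichiometry),
                                 src.lower_bound, src.upper_bound))
                res = fba(test_model, medium, "EX_br1b_e")
                assert not (res.optimal and res.objective_value >= 1e-6), subset

    def test_solutions_are_deterministic_across_runs(self, gapped):
        model, medium = gapped
        uni = universal_with([
            Reaction("R1", {"br1a_c": Fraction(-1), "br1b_c": Fraction(1)}, 0, 1000),
            Reaction("R2", {"br1a_c": Fraction(-1), "br1b_c": Fraction(1)}, 0, 900),
            Reaction("R3", {"br1a_c": Fraction(-1), "br1b_c": Fraction(1)}, 0, 800),
        ])
        results = [gap_fill(model, uni, "EX_br1b_e", medium).added_reaction_ids
                   for _ in range(3)]
        assert results[0] == results[1] == results[2] == ["R1"]
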