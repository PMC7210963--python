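"""Identifier normalization, duplicate detection and model merging."""

from fractions import Fraction

import numpy as np
import pytest

from zmgem import (
    IdMap,
    Metabolite,
    Model,
    Reaction,
    apply_id_map,
    canonical_key,
    merge_models,
)
from zmgem.synth import ToySpec, make_legacy_pair, make_toy_ed_model


def rxn(rid, stoich, lb=0.0, ub=1000.0):
    return Reaction(rid, {m: Fraction(c) for m, c in stoich.items()}, lb, ub)


class TestCanonicalKey:
    def test_sign_flip_identity(self):
        fwd = rxn("F", {"a": -1, "b": -1, "c": 1})
        rev = rxn("R", {"c": -1, "a": 1, "b": 1})
        assert canonical_key(fwd) == canonical_key(rev)

    def test_positive_rescaling(self):
        assert canonical_key(rxn("A", {"a": -2, "b": 2})) == canonical_key(
            rxn("B", {"a": -1, "b": 1})
        )

    def test_distinct_products_differ(self):
        assert canonical_key(rxn("A", {"a": -1, "b": -1, "c": 1})) != canonical_key(
            rxn("B", {"a": -1, "b": -1, "d": 1})
        )

    def test_no_collisions_on_randomized_reactions(self):
        """Hash quality: 10^3 random distinct stoichiometries, keys collide
        only when a brute-force pairwise comparison says they should."""
        rng = np.random.default_rng(7)
        mets = [f"m{i}" for i in range(12)]
        reactions = []
        for i in range(1000):
            k = rng.integers(2, 5)
            chosen = rng.choice(mets, size=k, replace=False)
            coefs = rng.integers(1, 4, size=k)
            signs = np.concatenate([[-1], rng.choice([-1, 1], size=k - 1)])
            stoich = {m: int(s * c) for m, s, c in zip(chosen, signs, coefs)}
            reactions.append(rxn(f"r{i}", stoich))

        def equivalent(r1, r2):
            s1 = {m: Fraction(c) for m, c in r1.stoichiometry.items()}
            s2 = {m: Fraction(c) for m, c in r2.stoichiometry.items()}
            if set(s1) != set(s2):
                return False
            ratios = {s2[m] / s1[m] for m in s1}
            return len(ratios) == 1

        keys = [canonical_key(r) for r in reactions]
        by_key = {}
        for r, k in zip(reactions, keys):
            by_key.setdefault(k, []).append(r)
        for group in by_key.values():
            for other in group[1:]:
                assert equivalent(group[0], other)
        # and soundness the other way on a spot sample
        idx = rng.choice(len(reactions), size=200, replace=False)
        for i in idx[:100]:
            for j in idx[100:]:
                if equivalent(reactions[i], reactions[j]):
                    assert keys[i] == keys[j]


class TestApplyIdMap:
    def _one_reaction_model(self):
        m = Model(id="m1")
        m.add_metabolite(Metabolite("glc_D", compartment="e"))
        m.add_reaction(rxn("EX", {"glc_D": -1}))
        return m

    def test_simple_rename(self):
        model = self._one_reaction_model()
        out, report = apply_id_map(model, IdMap(metabolites={"glc_D": "C00031_e"}))
        assert "C00031_e" in out.metabolites
        assert out.reactions["EX"].stoichiometry == {"C00031_e": Fraction(-1)}
        assert not report.collisions

    def test_synonym_collision_sums_coefficients(self):
        m = Model(id="m2")
        for mid in ("nad_1", "nad_2", "x_c"):
            m.add_metabolite(Metabolite(mid, compartment="c"))
        m.add_reaction(rxn("R", {"nad_1": -1, "nad_2": -1, "x_c": 1}))
        out, report = apply_id_map(
            m, IdMap(metabolites={"nad_1": "nad_c", "nad_2": "nad_c"})
        )
        assert out.reactions["R"].stoichiometry == {
            "nad_c": Fraction(-2), "x_c": Fraction(1)
        }
        assert report.collisions == [("nad_c", ["nad_1", "nad_2"])]

    def test_self_cancellation_warns_and_drops_term(self):
        m = Model(id="m3")
        for mid in ("a1", "a2", "b_c"):
            m.add_metabolite(Metabolite(mid, compartment="c"))
        m.add_reaction(rxn("R", {"a1": -1, "a2": 1, "b_c": 1}))
        with pytest.warns(UserWarning, match="self-cancellation"):
            out, report = apply_id_map(
                m, IdMap(metabolites={"a1": "a_c", "a2": "a_c"})
            )
        assert "a_c" not in out.reactions["R"].stoichiometry
        assert report.self_cancellations == ["R"]

    def test_empty_map_is_identity_with_passthrough_flags(self, toy_model):
        out, report = apply_id_map(toy_model, IdMap())
        assert list(out.metabolites) == list(toy_model.metabolites)
        assert set(report.passed_through) == set(toy_model.metabolites)


class TestMerge:
    def test_merging_a_model_with_itself_is_idempotent(self, toy_model):
        a = toy_model.copy()
        b = toy_model.copy()
        b.id = "copy"
        merged, report = merge_models([a, b])
        assert len(merged.reactions) == len(toy_model.reactions)
        assert report.n_shared == len(toy_model.reactions)
        assert report.n_unique(a.id) == 0 and report.n_unique("copy") == 0
        assert not report.conflicts

    def test_legacy_pair_counts_match_planted_truth(self, toy_model):
        spec = ToySpec()
        a, b, truth = make_legacy_pair(toy_model, spec)
        am, _ = apply_id_map(a, IdMap(metabolites=truth.idmap_a))
        bm, _ = apply_id_map(b, IdMap(metabolites=truth.idmap_b))
        merged, report = merge_models([am, bm])
        assert report.n_shared == truth.shared
        assert (report.n_unique(am.id), report.n_unique(bm.id)) == truth.unique
        # sum invariant: shared + unique = per-source reaction count after dedup
        for m in (am, bm):
            assert report.n_shared + report.n_unique(m.id) == report.dedup_counts[m.id]

    def test_merge_counts_are_order_insensitive(self, toy_model):
        spec = ToySpec(seed=3)
        a, b, truth = make_legacy_pair(toy_model, spec)
        am, _ = apply_id_map(a, IdMap(metabolites=truth.idmap_a))
        bm, _ = apply_id_map(b, IdMap(metabolites=truth.idmap_b))
        _, r1 = merge_models([am, bm])
        _, r2 = merge_models([bm, am])
        assert r1.n_shared == r2.n_shared
        assert r1.n_unique(am.id) == r2.n_unique(am.id)
        assert r1.n_unique(bm.id) == r2.n_unique(bm.id)

    def test_direction_flips_still_match(self, toy_model):
        spec = ToySpec(n_renames=0, n_private=(0, 0), n_flips=3)
        a, b, truth = make_legacy_pair(toy_model, spec)
        merged, report = merge_models([a, b])
        assert report.n_shared == len(toy_model.reactions)

    def test_reversibility_conflict_policies(self):
        def source(sid, lb, ub):
            m = Model(id=sid)
            m.add_metabolite(Metabolite("a_c", compartment="c"))
            m.add_metabolite(Metabolite("b_c", compartment="c"))
            m.add_reaction(rxn("R", {"a_c": -1, "b_c": 1}, lb, ub))
            return m

        widest, rep = merge_models(
            [source("s1", 0, 1000), source("s2", -1000, 1000)],
            policy="widest-bounds",
        )
        assert (widest.reactions["R"].lower_bound,
                widest.reactions["R"].upper_bound) == (-1000, 1000)
        assert rep.conflicts and rep.conflicts[0].field == "bounds"

        first, _ = merge_models(
            [source("s1", 0, 1000), source("s2", -1000, 1000)],
            policy="first-source",
        )
        assert first.reactions["R"].lower_bound == 0

        refdb, _ = merge_models(
            [source("s1", 0, 1000), source("s2", -1000, 1000)],
            policy="reference-db",
            reversibility={"R": "reverse"},
        )
        assert (refdb.reactions["R"].lower_bound,
                refdb.reactions["R"].upper_bound) == (-1000, 0)

    def test_gpr_disagreement_is_or_combined_and_logged(self):
        def source(sid, gpr):
            m = Model(id=sid)
            m.add_metabolite(Metabolite("a_c", compartment="c"))
            m.add_metabolite(Metabolite("b_c", compartment="c"))
            r = rxn("R", {"a_c": -1, "b_c": 1})
            r.gpr = r.gpr.from_string(gpr)
            m.add_reaction(r)
            return m

        merged, report = merge_models([source("s1", "g1"), source("s2", "g2")])
        assert merged.reactions["R"].gpr.to_dnf() == frozenset(
            {frozenset({"g1"}), frozenset({"g2"})}
        )
        assert any(c.field == "gpr" for c in report.conflicts)

    def test_incompatible_compartments_rejected(self, toy_model):
        other = Model(id="weird", compartments={"c": "cytoplasm", "p": "peri"})
        other.add_metabolite(Metabolite("a_c", compartment="c"))
        other.add_reaction(rxn("R", {"a_c": -1}))
        from zmgem.model import ModelIntegrityError

        with pytest.raises(ModelIntegrityError):
            merge_models([toy_model, other])
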