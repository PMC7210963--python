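"""Shared fixtures: synthetic models, media and small LP oracles."""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pytest

from zmgem import Metabolite, Model, Reaction
from zmgem.synth import ToySpec, make_toy_ed_model, toy_media


@pytest.fixture(scope="session")
def toy():
    """Default synthetic ED model and its ground truth."""
    model, truth = make_toy_ed_model(ToySpec())
    return model, truth


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def media(toy_model):
    return toy_media(toy_model)


@pytest.fixture()
def box_model():
    """One metabolite, two exchanges: feasible flux is a segment [0, 10]."""
    m = Model(id="box")
    m.add_metabolite(Metabolite("a_e", compartment="e"))
    m.add_reaction(Reaction("IN", {"a_e": Fraction(1)}, 0.0, 10.0))
    m.add_reaction(Reaction("OUT", {"a_e": Fraction(-1)}, 0.0, 10.0))
    m.objective_id = "OUT"
    return m


def small_chain_model():
    """a -> b -> c with exchanges; 5 reactions, known optimum 5."""
    m = Model(id="chain")
    for mid, comp in (("a_e", "e"), ("a_c", "c"), ("b_c", "c"), ("c_e", "e")):
        m.add_metabolite(Metabolite(mid, compartment=comp))
    m.add_reaction(Reaction("EX_a", {"a_e": Fraction(-1)}, -5.0, 1000.0))
    m.add_reaction(Reaction("T_a", {"a_e": Fraction(-1), "a_c": Fraction(1)}, 0, 1000))
    m.add_reaction(Reaction("AB", {"a_c": Fraction(-1), "b_c": Fraction(1)}, 0, 1000))
    m.add_reaction(Reaction("BC", {"b_c": Fraction(-1), "c_e": Fraction(1)}, 0, 1000))
    m.add_reaction(Reaction("EX_c", {"c_e": Fraction(-1)}, 0.0, 1000.0))
    m.objective_id = "EX_c"
    return m


def branched_model():
    """8-reaction branched network with a reversible shunt."""
    m = Model(id="branched")
    for mid, comp in (("s_e", "e"), ("s_c", "c"), ("x_c", "c"), ("y_c", "c"),
                      ("p_e", "e"), ("q_e", "e")):
        m.add_metabolite(Metabolite(mid, compartment=comp))
    m.add_reaction(Reaction("EX_s", {"s_e": Fraction(-1)}, -4.0, 0.0))
    m.add_reaction(Reaction("T_s", {"s_e": Fraction(-1), "s_c": Fraction(1)}, 0, 1000))
    m.add_reaction(Reaction("SX", {"s_c": Fraction(-1), "x_c": Fraction(2)}, 0, 1000))
    m.add_reaction(Reaction("XY", {"x_c": Fraction(-1), "y_c": Fraction(1)}, -1000, 1000))
    m.add_reaction(Reaction("XP", {"x_c": Fraction(-1), "p_e": Fraction(1)}, 0, 3.0))
    m.add_reaction(Reaction("YQ", {"y_c": Fraction(-1), "q_e": Fraction(1)}, 0, 1000))
    m.add_reaction(Reaction("EX_p", {"p_e": Fraction(-1)}, 0, 1000))
    m.add_reaction(Reaction("EX_q", {"q_e": Fraction(-1)}, 0, 1000))
    m.objective_id = "EX_q"
    return m


@pytest.fixture(params=["chain", "branched"])
def tiny_lp_model(request):
    return {"chain": small_chain_model, "branched": branched_model}[request.param]()


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-8):
    """Brute-force vertex enumeration of {v: Sv=0, lb<=v<=ub} (tiny n only).

    A vertex has at least n - rank(S) coordinates at a bound; enumerate all
    such supports, solve the remaining square-ish system, keep consistent,
    in-bound solutions.  Independent of the LP solver by construction.
    """
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    n_fix = n - r
    vertices = []
    for fixed_idx in itertools.combinations(range(n), n_fix):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        for pattern in itertools.product(*[(lb[j], ub[j]) for j in fixed_idx]):
            rhs = -S[:, fixed_idx] @ np.array(pattern)
            A = S[:, free_idx]
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.linalg.norm(A @ sol - rhs) > tol:
                continue
            v = np.empty(n)
            v[list(fixed_idx)] = pattern
            v[free_idx] = sol
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                vertices.append(np.clip(v, lb, ub))
    return vertices


def brute_force_lp_max(model: Model, objective: str,
                       bounds_override=None) -> float:
    """LP optimum via vertex enumeration (oracle for <=8-reaction models)."""
    S = model.stoichiometric_matrix().toarray()
    lb, ub = model.bounds_arrays()
    if bounds_override:
        idx = {rid: j for j, rid in enumerate(model.reactions)}
        for rid, (lo, hi) in bounds_override.items():
            lb[idx[rid]], ub[idx[rid]] = lo, hi
    verts = enumerate_vertices(S, lb, ub)
    assert verts, "vertex enumeration found no feasible vertex"
    j = list(model.reactions).index(objective)
    return max(v[j] for v in verts)
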