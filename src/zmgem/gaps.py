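"""Gap analysis: dead-end metabolites, blocked reactions, MILP gap filling.

A *no-production* metabolite cannot carry any drain flux at steady state
under the medium bounds; a *no-consumption* metabolite cannot absorb any
supply flux; a *blocked* reaction has a flux span of exactly zero.  Such
entities usually mark knowledge gaps.  Gap filling selects a provably
minimal-weight set of candidate reactions from a universal database whose
addition restores a stated target flux, as a mixed-integer program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import lp
from .flux import _assemble, fba, fva
from .media import Medium
from .model import Model, Reaction

EPS_FLUX = 1e-6      # mmol gDCW^-1 h^-1; feasibility / blocking threshold
MILP_TOL = 1e-9      # solver feasibility tolerance


@dataclass
class GapReport:
    no_production: Set[str] = field(default_factory=set)
    no_consumption: Set[str] = field(default_factory=set)
    blocked_reactions: Set[str] = field(default_factory=set)

    @property
    def dead_ends(self) -> Set[str]:
        return self.no_production | self.no_consumption


@dataclass
class GapFillSolution:
    status: str                       # "optimal" | "unfillable"
    added_reaction_ids: List[str] = field(default_factory=list)
    objective_flux_after: Optional[float] = None
    total_weight: Optional[float] = None

    @property
    def cardinality(self) -> int:
        return len(self.added_reaction_ids)


def _check_feasible(S, lb, ub) -> None:
    sol = lp.solve_flux_lp(S, lb, ub, np.zeros(S.shape[1]), maximize=False)
    if sol.status != lp.STATUS_OPTIMAL:
        raise lp.SolverError(f"base model is {sol.status} under this medium")


def _gap_problem(model, medium, extra_bounds, open_exchanges):
    """Assemble bounds for gap analysis.

    Without an explicit medium the structural question is asked: every
    exchange is opened in both directions, so only true connectivity gaps
    (not medium choices) surface.  Note that conserved internal pools
    (e.g. NAD+/NADH) can never carry net drain flux and therefore always
    appear as no-production/no-consumption under the probe definition;
    planted-gap recovery is measured against the intact-model baseline.
    """
    if open_exchanges is None:
        open_exchanges = medium is None
    extra = dict(extra_bounds or {})
    if open_exchanges:
        for rxn in model.exchanges():
            extra.setdefault(rxn.id, (-1000.0, 1000.0))
    return _assemble(model, medium, extra)


def find_dead_ends(
    model: Model,
    medium: Optional[Medium] = None,
    eps: float = EPS_FLUX,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    open_exchanges: Optional[bool] = None,
) -> GapReport:
    """No-production / no-consumption metabolites by per-metabolite probe LPs.

    For each metabolite a temporary drain (resp. supply) column is appended
    and its maximum flux computed; below ``eps`` means the network cannot
    produce (resp. consume) the metabolite under the effective bounds.
    """
    S, lb, ub, _ = _gap_problem(model, medium, extra_bounds, open_exchanges)
    _check_feasible(S, lb, ub)
    report = GapReport()
    n = S.shape[1]
    met_ids = list(model.metabolites)
    S = sparse.csc_matrix(S)
    for i, met in enumerate(met_ids):
        for sign, bucket in ((-1.0, report.no_production), (1.0, report.no_consumption)):
            col = sparse.csc_matrix(([sign], ([i], [0])), shape=(S.shape[0], 1))
            S_aug = sparse.hstack([S, col], format="csc")
            lb_aug = np.append(lb, 0.0)
            ub_aug = np.append(ub, 1000.0)
            c = np.zeros(n + 1)
            c[n] = 1.0
            sol = lp.solve_flux_lp(S_aug, lb_aug, ub_aug, c, maximize=True)
            if sol.status != lp.STATUS_OPTIMAL or sol.objective < eps:
                bucket.add(met)
    return report


def find_blocked(
    model: Model,
    medium: Optional[Medium] = None,
    eps: float = EPS_FLUX,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    open_exchanges: Optional[bool] = None,
) -> GapReport:
    """Reactions with FVA min = max = 0 under the effective bounds."""
    if open_exchanges is None:
        open_exchanges = medium is None
    extra = dict(extra_bounds or {})
    if open_exchanges:
        for rxn in model.exchanges():
            extra.setdefault(rxn.id, (-1000.0, 1000.0))
    S, lb, ub, _ = _assemble(model, medium, extra)
    _check_feasible(S, lb, ub)
    result = fva(model, medium=medium, fraction_of_optimum=0.0,
                 extra_bounds=extra)
    report = GapReport()
    for rid, (lo, hi) in result.ranges.items():
        if abs(lo) < eps and abs(hi) < eps:
            report.blocked_reactions.add(rid)
    return report


def find_gaps(
    model: Model,
    medium: Optional[Medium] = None,
    eps: float = EPS_FLUX,
    open_exchanges: Optional[bool] = None,
) -> GapReport:
    """Dead ends and blocked reactions in one report."""
    dead = find_dead_ends(model, medium, eps, open_exchanges=open_exchanges)
    blocked = find_blocked(model, medium, eps, open_exchanges=open_exchanges)
    dead.blocked_reactions = blocked.blocked_reactions
    return dead


# ---------------------------------------------------------------------------
# MILP gap filling


def _solve_fill_milp(
    S_all: sparse.csc_matrix,
    lb_all: np.ndarray,
    ub_all: np.ndarray,
    n_model: int,
    weights: np.ndarray,
    target_idx: int,
    eps: float,
    fixed_in: Set[int],
    fixed_out: Set[int],
) -> tuple[Optional[float], Optional[np.ndarray]]:
    """Min sum(w_j y_j) s.t. steady state, target >= eps, lb_j y_j <= v_j <= ub_j y_j."""
    n_cand = S_all.shape[1] - n_model
    n_var = n_model + 2 * n_cand  # v_model, v_cand, y
    # clamp candidate big-M bounds so tolerance leakage stays << the target
    lb_all = lb_all.copy()
    ub_all = ub_all.copy()
    lb_all[n_model:] = np.maximum(lb_all[n_model:], -100.0)
    ub_all[n_model:] = np.minimum(ub_all[n_model:], 100.0)
    c = np.concatenate([np.zeros(n_model + n_cand), weights])
    A_eq = sparse.hstack(
        [S_all, sparse.csc_matrix((S_all.shape[0], n_cand))], format="csc"
    )
    constraints = [LinearConstraint(A_eq, 0.0, 0.0)]
    rows_up, rows_lo = [], []
    for j in range(n_cand):
        row = np.zeros(n_var)
        row[n_model + j] = 1.0
        row[n_model + n_cand + j] = -ub_all[n_model + j]
        rows_up.append(row)
        row = np.zeros(n_var)
        row[n_model + j] = 1.0
        row[n_model + n_cand + j] = -lb_all[n_model + j]
        rows_lo.append(row)
    if n_cand:
        constraints.append(
            LinearConstraint(sparse.csc_matrix(np.array(rows_up)), -np.inf, 0.0)
        )
        constraints.append(
            LinearConstraint(sparse.csc_matrix(np.array(rows_lo)), 0.0, np.inf)
        )
    v_lb = lb_all.copy()
    v_ub = ub_all.copy()
    # target requirement: enforced at >= max(eps, 1e-3) inside the MILP so
    # that big-M leakage (candidate bound x feasibility tolerance, at most
    # ~1e-4 with the clamped candidate bounds) cannot fake a repair; the
    # selected set is re-verified by LP at the true eps afterwards
    t_row = np.zeros(n_var)
    t_row[target_idx] = 1.0
    constraints.append(
        LinearConstraint(sparse.csc_matrix(t_row.reshape(1, -1)),
                         max(eps, 1e-3), np.inf)
    )
    y_lb = np.zeros(n_cand)
    y_ub = np.ones(n_cand)
    for j in fixed_in:
        y_lb[j] = 1.0
    for j in fixed_out:
        y_ub[j] = 0.0
    bounds_lo = np.concatenate([v_lb, y_lb])
    bounds_hi = np.concatenate([v_ub, y_ub])
    integrality = np.concatenate([np.zeros(n_model + n_cand), np.ones(n_cand)])
    res = milp(
        c,
        constraints=constraints,
        bounds=Bounds(bounds_lo, bounds_hi),
        integrality=integrality,
        options={"presolve": True, "mip_rel_gap": 0.0},
    )
    if res.status != 0:
        return None, None
    return float(res.fun), np.asarray(res.x)


def gap_fill(
    model: Model,
    universal: Model,
    target: str,
    medium: Optional[Medium] = None,
    eps: float = EPS_FLUX,
    weights: Optional[Mapping[str, float]] = None,
) -> GapFillSolution:
    """Minimal-weight candidate set restoring ``target`` flux >= eps.

    Ties between equal-weight optima are broken deterministically toward the
    lexicographically smallest set of reaction ids (greedy inclusion of the
    smallest id compatible with the optimal weight).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if target not in model.reactions:
        raise KeyError(f"target reaction {target!r} not in model")
    candidates = [
        r for rid, r in universal.reactions.items() if rid not in model.reactions
    ]
    missing_mets = {
        m
        for r in candidates
        for m in r.stoichiometry
        if m not in model.metabolites and m in universal.metabolites
    }
    # quick exit: already feasible
    base = fba(model, medium=medium, objective=target, direction="max")
    if base.optimal and base.objective_value >= eps:
        return GapFillSolution("optimal", [], base.objective_value, 0.0)
    if not candidates:
        return GapFillSolution("unfillable")

    work = model.copy()
    for mid in missing_mets:
        work.add_metabolite(universal.metabolites[mid].__class__(
            **vars(universal.metabolites[mid])))
    n_model = len(work.reactions)
    cand_ids = [r.id for r in candidates]
    for r in candidates:
        work.add_reaction(
            Reaction(id=r.id, name=r.name, stoichiometry=dict(r.stoichiometry),
                     lower_bound=r.lower_bound, upper_bound=r.upper_bound,
                     gpr=r.gpr, subsystem=r.subsystem),
            register_genes=True,
        )
    S_all, lb_all, ub_all, index = _assemble(work, medium)
    w = np.array([(weights or {}).get(rid, 1.0) for rid in cand_ids])
    target_idx = index[target]
    opt, x = _solve_fill_milp(
        sparse.csc_matrix(S_all), lb_all, ub_all, n_model, w, target_idx, eps,
        set(), set())
    if opt is None:
        return GapFillSolution("unfillable")
    # deterministic lexicographic tie-break at fixed optimal weight
    fixed_in: Set[int] = set()
    fixed_out: Set[int] = set()
    order = sorted(range(len(cand_ids)), key=lambda j: cand_ids[j])
    for j in order:
        trial, _ = _solve_fill_milp(
            sparse.csc_matrix(S_all), lb_all, ub_all, n_model, w, target_idx,
            eps, fixed_in | {j}, fixed_out)
        if trial is not None and trial <= opt + MILP_TOL:
            fixed_in.add(j)
        else:
            fixed_out.add(j)
    added = sorted(cand_ids[j] for j in fixed_in)
    # verify and report the restored target flux
    overrides = {cand_ids[j]: (0.0, 0.0) for j in fixed_out}
    after = fba(work, medium=medium, objective=target, direction="max",
                extra_bounds=overrides)
    if not after.optimal or after.objective_value < eps - MILP_TOL:
        return GapFillSolution("unfillable")
    return GapFillSolution("optimal", added, after.objective_value,
                           float(sum(w[j] for j in fixed_in)))
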