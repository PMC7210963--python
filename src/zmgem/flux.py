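"""Constraint-based simulation: FBA, FVA, knockouts, knock-ins, screens.

This is the engine behind every simulation number downstream: flux balance
analysis (LP over steady-state flux vectors), flux variability analysis
(per-reaction min/max, optionally at a fraction of the growth optimum),
GPR-based gene deletion, heterologous pathway addition, substrate-
utilization screening against observed phenotypes, and biomass-composition
variants for essentiality tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from . import lp
from .media import Medium
from .model import Metabolite, Model, Reaction, check_balance, evaluate_gpr

GROWTH_THRESHOLD = 1e-3  # h^-1; phenotype call cutoff


@dataclass
class FluxResult:
    status: str
    objective_value: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == lp.STATUS_OPTIMAL


@dataclass
class FVAResult:
    ranges: Dict[str, Tuple[float, float]]
    fraction_of_optimum: float = 0.0

    def __getitem__(self, rid: str) -> Tuple[float, float]:
        return self.ranges[rid]


@dataclass
class KnockInPathway:
    """A heterologous pathway: reactions (with placeholder GPRs for the
    foreign genes) plus any new metabolites and boundary reactions."""

    name: str
    reactions: List[Reaction]
    metabolites: List[Metabolite] = field(default_factory=list)


@dataclass
class PhenotypeCall:
    substrate: str
    element: str
    predicted: Optional[bool]  # None = exchange absent -> non-tested
    observed: Optional[bool] = None

    @property
    def category(self) -> str:
        if self.predicted is None:
            return "non-tested"
        growth = "Growth" if self.predicted else "No-Growth"
        if self.observed is None:
            return growth
        return f"{growth}/{'True' if self.predicted == self.observed else 'False'}"


# ---------------------------------------------------------------------------
# problem assembly


def _assemble(
    model: Model,
    medium: Optional[Medium],
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray, Dict[str, int]]:
    S = model.stoichiometric_matrix()
    lb_arr, ub_arr = model.bounds_arrays()
    index = {rid: j for j, rid in enumerate(model.reactions)}
    overrides: Dict[str, Tuple[float, float]] = {}
    if medium is not None:
        overrides.update(medium.apply(model))
    if extra_bounds:
        overrides.update(extra_bounds)
    for rid, (lo, hi) in overrides.items():
        j = index[rid]
        lb_arr[j], ub_arr[j] = lo, hi
    return S, lb_arr, ub_arr, index


def fba(
    model: Model,
    medium: Optional[Medium] = None,
    objective: Optional[str] = None,
    direction: str = "max",
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> FluxResult:
    """Flux balance analysis: optimize one reaction's flux at steady state."""
    objective = objective or model.objective_id
    if objective is None or objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    S, lb_arr, ub_arr, index = _assemble(model, medium, extra_bounds)
    c = np.zeros(len(index))
    c[index[objective]] = 1.0
    sol = lp.solve_flux_lp(S, lb_arr, ub_arr, c, maximize=(direction == "max"))
    if not sol.status == lp.STATUS_OPTIMAL:
        return FluxResult(sol.status, None)
    fluxes = dict(zip(model.reactions, map(float, sol.x)))
    return FluxResult(sol.status, sol.objective, fluxes)


def fva(
    model: Model,
    medium: Optional[Medium] = None,
    reactions: Optional[Sequence[str]] = None,
    fraction_of_optimum: float = 0.0,
    objective: Optional[str] = None,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> FVAResult:
    """Per-reaction [min, max] flux, optionally at >= fraction of optimum."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    S, lb_arr, ub_arr, index = _assemble(model, medium, extra_bounds)
    targets = list(reactions) if reactions is not None else list(model.reactions)
    missing = [r for r in targets if r not in index]
    if missing:
        raise KeyError(f"unknown reactions in FVA request: {missing}")
    A_extra = None
    b_extra = None
    if fraction_of_optimum > 0.0:
        objective = objective or model.objective_id
        if objective is None:
            raise KeyError("fraction_of_optimum requires an objective reaction")
        c = np.zeros(len(index))
        c[index[objective]] = 1.0
        opt = lp.solve_flux_lp(S, lb_arr, ub_arr, c, maximize=True)
        if opt.status != lp.STATUS_OPTIMAL:
            raise lp.SolverError(
                f"FVA base problem is {opt.status}; cannot constrain to optimum"
            )
        A_extra = sparse.csr_matrix(c)
        # small relative slack keeps the constrained problem numerically feasible
        b_extra = np.array([fraction_of_optimum * opt.objective - 1e-9])
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        c = np.zeros(len(index))
        c[index[rid]] = 1.0
        lo = lp.solve_flux_lp(
            S, lb_arr, ub_arr, c, maximize=False, A_extra=A_extra, b_extra_lower=b_extra
        )
        hi = lp.solve_flux_lp(
            S, lb_arr, ub_arr, c, maximize=True, A_extra=A_extra, b_extra_lower=b_extra
        )
        if lo.status != lp.STATUS_OPTIMAL or hi.status != lp.STATUS_OPTIMAL:
            raise lp.SolverError(f"FVA subproblem for {rid} is {lo.status}/{hi.status}")
        ranges[rid] = (lo.objective, hi.objective)
    return FVAResult(ranges, fraction_of_optimum)


# ---------------------------------------------------------------------------
# gene deletion


def knockout_bounds(
    model: Model, genes: Iterable[str]
) -> tuple[Dict[str, Tuple[float, float]], List[str]]:
    """Bound overrides (lb=ub=0) for reactions disabled by deleting genes."""
    genes = set(genes)
    disabled: List[str] = []
    overrides: Dict[str, Tuple[float, float]] = {}
    for rxn in model.reactions.values():
        if not evaluate_gpr(model, rxn.gpr, genes):
            overrides[rxn.id] = (0.0, 0.0)
            disabled.append(rxn.id)
    return overrides, disabled


def delete_genes(
    model: Model,
    genes: Iterable[str],
    medium: Optional[Medium] = None,
    objective: Optional[str] = None,
) -> tuple[FluxResult, List[str]]:
    """FBA of the deletion strain; returns the result and disabled reactions."""
    overrides, disabled = knockout_bounds(model, genes)
    result = fba(model, medium=medium, objective=objective, extra_bounds=overrides)
    return result, disabled


# ---------------------------------------------------------------------------
# heterologous knock-in


class BalanceError(ValueError):
    """An added pathway reaction is elementally unbalanced."""


def knock_in(
    model: Model,
    pathway: KnockInPathway,
    check_mass_balance: bool = True,
) -> Model:
    """Augment a model with a heterologous pathway.

    Reactions whose canonical stoichiometric key duplicates an existing
    reaction are skipped with a warning (the pathway is already present).
    Unbalanced non-boundary reactions raise unless checking is disabled.
    """
    from .reconcile import canonical_key  # local import avoids cycle

    new = model.copy()
    for met in pathway.metabolites:
        if met.id not in new.metabolites:
            new.add_metabolite(met)
    existing_keys = {canonical_key(r) for r in new.reactions.values()}
    staged: List[Reaction] = []
    for rxn in pathway.reactions:
        if rxn.id in new.reactions or canonical_key(rxn) in existing_keys:
            warnings.warn(
                f"knock-in {pathway.name}: reaction {rxn.id} duplicates an "
                "existing reaction; skipped",
                stacklevel=2,
            )
            continue
        staged.append(rxn)
    for rxn in staged:
        new.add_reaction(rxn)
    if check_mass_balance and staged:
        report = check_balance(new)
        bad = {r.id for r in staged} & report.unbalanced
        if bad:
            raise BalanceError(
                f"knock-in {pathway.name}: unbalanced reactions {sorted(bad)}: "
                f"{ {r: report.imbalances[r] for r in sorted(bad)} }"
            )
    return new


# ---------------------------------------------------------------------------
# substrate-utilization screening


def substrate_screen(
    model: Model,
    substrates: Sequence[Tuple[str, str]],
    base_medium: Medium,
    growth_threshold: float = GROWTH_THRESHOLD,
    observed: Optional[Mapping[str, bool]] = None,
    uptake: float = 10.0,
) -> List[PhenotypeCall]:
    """Growth calls per sole substrate of an element class (C, N or S).

    For each (exchange id, element class): every other source of that class
    in the base medium *and* in the substrate list is closed, the tested
    exchange opened at ``-uptake``, and growth called against the threshold.
    An absent exchange yields a non-tested call, not an error.
    """
    class_sources = {
        "C": list(base_medium.carbon_exchanges),
        "N": list(base_medium.nitrogen_exchanges),
        "S": list(base_medium.sulfur_exchanges),
    }
    for exch, element in substrates:
        if element not in class_sources:
            raise ValueError(f"element class must be C/N/S, got {element!r}")
        class_sources[element].append(exch)
    calls: List[PhenotypeCall] = []
    for exch, element in substrates:
        obs = observed.get(exch) if observed else None
        if exch not in model.reactions:
            calls.append(PhenotypeCall(exch, element, None, obs))
            continue
        overrides = dict(base_medium.exchange_overrides)
        for other in class_sources[element]:
            if other in model.reactions:
                overrides[other] = (0.0, model.reactions[other].upper_bound)
        overrides[exch] = (-abs(uptake), model.reactions[exch].upper_bound)
        medium = base_medium.with_(
            name=f"{base_medium.name}+{exch}", exchange_overrides=overrides
        )
        result = fba(model, medium=medium)
        grows = result.optimal and (result.objective_value or 0.0) > growth_threshold
        calls.append(PhenotypeCall(exch, element, grows, obs))
    return calls


# ---------------------------------------------------------------------------
# biomass variants


def biomass_variant(
    model: Model,
    additions: Mapping[str, float],
    biomass_id: Optional[str] = None,
    variant_id: Optional[str] = None,
) -> Model:
    """Clone the biomass reaction with extra precursor terms.

    Coefficients must be negative (precursors are consumed); the variant
    becomes the model objective so essentiality of producers is testable
    with :func:`delete_genes`.
    """
    biomass_id = biomass_id or model.objective_id
    if biomass_id is None or biomass_id not in model.reactions:
        raise KeyError(f"biomass reaction {biomass_id!r} not in model")
    bad = {m: c for m, c in additions.items() if c >= 0}
    if bad:
        raise ValueError(f"precursor coefficients must be negative: {bad}")
    missing = [m for m in additions if m not in model.metabolites]
    if missing:
        raise KeyError(f"unknown metabolites in biomass additions: {missing}")
    new = model.copy()
    if not additions:
        return new
    base = new.reactions[biomass_id]
    stoich = dict(base.stoichiometry)
    for met, coef in additions.items():
        stoich[met] = stoich.get(met, 0) + coef
    vid = variant_id or f"{biomass_id}_variant"
    new.add_reaction(
        Reaction(
            id=vid,
            name=f"{base.name or biomass_id} (variant)",
            stoichiometry=stoich,
            lower_bound=base.lower_bound,
            upper_bound=base.upper_bound,
            gpr=base.gpr,
            subsystem=base.subsystem,
        )
    )
    # the original biomass is retired so the variant is the sole growth route
    new.reactions[biomass_id].lower_bound = 0.0
    new.reactions[biomass_id].upper_bound = 0.0
    new.objective_id = vid
    return new
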