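"""Domain types for genome-scale metabolic models (GEMs).

A model is the stoichiometric object of constraint-based analysis: the
sparse matrix S (metabolites x reactions), flux bounds lb/ub in
mmol gDCW^-1 h^-1, an objective reaction (biomass by default), and
gene-protein-reaction rules linking gene presence to reaction activity.
Exactly two compartments are supported, cytoplasm ("c") and extracellular
space ("e"), which covers Gram-negative single-cell reconstructions.

Metabolite formulas are element->count maps; a missing formula or charge
is "undetermined", never silently zero, so that balance checking degrades
explicitly on legacy models that ignored mass and charge balance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Set

import numpy as np
from scipy import sparse

from .gpr import GPR

CYTOPLASM = "c"
EXTRACELLULAR = "e"
DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelIntegrityError(ValueError):
    """A model violates a structural invariant (dangling references etc.)."""


class UnknownGeneError(KeyError):
    """A locus tag was referenced that is not in the model's gene set."""


def parse_formula(formula: str | None) -> Optional[Dict[str, int]]:
    """Parse ``"C6H12O6"`` into ``{"C": 6, "H": 12, "O": 6}``.

    Returns None for empty/unknown formulas.  Zero-count entries are dropped.
    The single uppercase pseudo-element ``X`` is allowed for abstract
    metabolites in synthetic fixtures.
    """
    if formula is None or not formula.strip():
        return None
    out: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        n = int(m.group(2) or 1)
        if n:
            out[m.group(1)] = out.get(m.group(1), 0) + n
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


def formula_to_string(formula: Optional[Mapping[str, int]]) -> str:
    if not formula:
        return ""
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(formula.items())
    )


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: Optional[Dict[str, int]] = None
    charge: Optional[int] = None
    compartment: str = CYTOPLASM

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.formula:
            self.formula = {el: n for el, n in self.formula.items() if n}


@dataclass
class Gene:
    locus_tag: str
    name: str = ""


@dataclass
class Reaction:
    """One column of S.

    Stoichiometric coefficients are signed (negative = substrate) and may be
    ``Fraction`` or float; exact rationals are preserved where given so that
    duplicate detection under rescaling stays stable.
    """

    id: str
    stoichiometry: Dict[str, Fraction | float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPR = field(default_factory=GPR)
    name: str = ""
    subsystem: str = ""
    ec_numbers: List[str] = field(default_factory=list)
    is_exchange: Optional[bool] = None
    is_transport: Optional[bool] = None

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = GPR.from_string(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def infer_flags(self, metabolites: Mapping[str, Metabolite]) -> None:
        """Fill is_exchange / is_transport from stoichiometry when unset.

        Exchange: touches exactly one metabolite, which is extracellular.
        Transport: moves species between both compartments.
        """
        comps = {
            metabolites[m].compartment
            for m in self.stoichiometry
            if m in metabolites
        }
        if self.is_exchange is None:
            self.is_exchange = (
                len(self.stoichiometry) == 1 and comps == {EXTRACELLULAR}
            )
        if self.is_transport is None:
            self.is_transport = len(comps) > 1

    def equation(self, arrow: str | None = None) -> str:
        """Human-readable equation string, ``a A + b B <=> c C`` style."""
        if arrow is None:
            arrow = "<=>" if self.lower_bound < 0 else "-->"
        subs, prods = [], []
        for met, coef in self.stoichiometry.items():
            c = Fraction(coef).limit_denominator(10**9)
            mag = -c if c < 0 else c
            term = met if mag == 1 else f"{_fmt_coef(mag)} {met}"
            (subs if c < 0 else prods).append(term)
        return f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()


def _fmt_coef(c: Fraction) -> str:
    return str(c.numerator) if c.denominator == 1 else f"{c.numerator}/{c.denominator}"


@dataclass
class Model:
    """A genome-scale metabolic model: S, v-bounds, objective, GPRs."""

    id: str = "model"
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    genes: Dict[str, Gene] = field(default_factory=dict)
    objective_id: Optional[str] = None
    compartments: Dict[str, str] = field(
        default_factory=lambda: {CYTOPLASM: "cytoplasm", EXTRACELLULAR: "extracellular"}
    )

    # -- construction ------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelIntegrityError(f"duplicate metabolite id {met.id}")
        if met.compartment not in self.compartments:
            raise ModelIntegrityError(
                f"metabolite {met.id}: undeclared compartment {met.compartment!r}"
            )
        self.metabolites[met.id] = met
        return met

    def add_gene(self, gene: Gene) -> Gene:
        self.genes.setdefault(gene.locus_tag, gene)
        return self.genes[gene.locus_tag]

    def add_reaction(self, rxn: Reaction, register_genes: bool = True) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelIntegrityError(
                f"reaction {rxn.id} references unknown metabolites: {missing}"
            )
        if not rxn.stoichiometry:
            raise ModelIntegrityError(f"reaction {rxn.id} has empty stoichiometry")
        if register_genes:
            for tag in rxn.gpr.genes():
                self.add_gene(Gene(tag))
        rxn.infer_flags(self.metabolites)
        self.reactions[rxn.id] = rxn
        return rxn

    # -- views -------------------------------------------------------------

    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> List[str]:
        return list(self.metabolites)

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S as |metabolites| x |reactions| sparse matrix (float)."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions.values()):
            for met, coef in rxn.stoichiometry.items():
                rows.append(met_index[met])
                cols.append(j)
                vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions.values()])
        ub = np.array([r.upper_bound for r in self.reactions.values()])
        return lb, ub

    def copy(self) -> "Model":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- integrity & stats -------------------------------------------------

    def validate(self) -> None:
        """Raise ModelIntegrityError on any violated structural invariant."""
        if not self.reactions:
            raise ModelIntegrityError(f"model {self.id}: no reactions (no objective resolvable)")
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelIntegrityError(
                        f"reaction {rxn.id} references unknown metabolite {met}"
                    )
            unknown = rxn.gpr.genes() - set(self.genes)
            if unknown:
                raise ModelIntegrityError(
                    f"reaction {rxn.id} GPR references unknown genes {sorted(unknown)}"
                )
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ModelIntegrityError(
                f"objective reaction {self.objective_id!r} not in model"
            )
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelIntegrityError(
                    f"metabolite {met.id}: undeclared compartment {met.compartment!r}"
                )

    def stats(self, genome_gene_count: Optional[int] = None) -> Dict[str, object]:
        """Summary counts in the style of a model-characteristics table."""
        transport = sum(1 for r in self.reactions.values() if r.is_transport and not r.is_exchange)
        exchange = sum(1 for r in self.reactions.values() if r.is_exchange)
        metabolic = len(self.reactions) - transport - exchange
        non_transport = [
            r for r in self.reactions.values() if not r.is_transport and not r.is_exchange
        ]
        gene_assoc = sum(1 for r in non_transport if not r.gpr.is_empty)
        cyto = sum(1 for m in self.metabolites.values() if m.compartment == CYTOPLASM)
        extra = len(self.metabolites) - cyto
        out: Dict[str, object] = {
            "model": self.id,
            "genes": len(self.genes),
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
            "metabolic_reactions": metabolic,
            "transport_reactions": transport,
            "exchange_reactions": exchange,
            "cytoplasmic_metabolites": cyto,
            "extracellular_metabolites": extra,
            "gene_associated_nontransport": gene_assoc,
            "gene_associated_share": (
                gene_assoc / len(non_transport) if non_transport else float("nan")
            ),
        }
        if genome_gene_count:
            out["gene_coverage"] = len(self.genes) / genome_gene_count
        return out


# ---------------------------------------------------------------------------
# GPR evaluation against a model


def evaluate_gpr(model: Model, gpr: GPR, deleted: Iterable[str]) -> bool:
    """Evaluate a GPR with ``deleted`` genes knocked out.

    Unknown locus tags raise :class:`UnknownGeneError`; an empty GPR is
    always active (orphan reactions cannot be disabled by deletion).
    """
    dele = set(deleted)
    unknown = dele - set(model.genes)
    if unknown:
        raise UnknownGeneError(f"unknown locus tags: {sorted(unknown)}")
    return gpr.evaluate(dele)


# ---------------------------------------------------------------------------
# Elemental / charge balance checking


@dataclass
class BalanceReport:
    """Per-reaction mass and charge imbalances.

    ``imbalances`` maps reaction id -> element->net map (products minus
    substrates) plus a net charge under key ``"charge"`` when determinable.
    Exchange, biomass and sink/demand reactions are exempt by convention
    (they are deliberately unbalanced boundary drains).  Reactions touching
    a metabolite without formula are "undetermined", never failures.
    """

    imbalances: Dict[str, Dict[str, float]] = field(default_factory=dict)
    undetermined: Set[str] = field(default_factory=set)
    exempt: Set[str] = field(default_factory=set)

    @property
    def unbalanced(self) -> Set[str]:
        return set(self.imbalances)

    @property
    def n_failures(self) -> int:
        return len(self.imbalances)


def check_balance(model: Model, extra_exempt: Iterable[str] = ()) -> BalanceReport:
    """Check elemental and charge balance of every non-exempt reaction."""
    report = BalanceReport()
    exempt_ids = set(extra_exempt)
    if model.objective_id:
        exempt_ids.add(model.objective_id)
    for rxn in model.reactions.values():
        if (
            rxn.id in exempt_ids
            or rxn.is_exchange
            or rxn.id.startswith(("SK_", "DM_", "sink_"))
        ):
            report.exempt.add(rxn.id)
            continue
        net: Dict[str, Fraction] = {}
        charge_net = Fraction(0)
        charge_known = True
        undetermined = False
        for met_id, coef in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            if met.formula is None:
                undetermined = True
                break
            c = Fraction(coef).limit_denominator(10**9)
            for el, n in met.formula.items():
                net[el] = net.get(el, Fraction(0)) + c * n
            if met.charge is None:
                charge_known = False
            else:
                charge_net += c * met.charge
        if undetermined:
            report.undetermined.add(rxn.id)
            continue
        bad = {el: float(v) for el, v in net.items() if v != 0}
        if charge_known and charge_net != 0:
            bad["charge"] = float(charge_net)
        if bad:
            report.imbalances[rxn.id] = bad
    return report
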