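"""SBML Level 3 reader/writer with FBC flux bounds and gene associations.

Writing always emits L3V1 + fbc-v2 (bounds as global parameters, GPRs as
gene-product associations, formulas/charges as fbc species attributes).
Reading is more liberal, to cope with legacy exports:

* bounds: fbc flux-bound parameters first, then legacy kinetic-law
  ``LOWER_BOUND``/``UPPER_BOUND`` local parameters, then the defaults
  (+-1000 reversible, 0..1000 irreversible);
* GPRs: fbc gene-product associations take precedence; a
  ``GENE_ASSOCIATION:`` line in the reaction notes is the fallback.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import libsbml

from .gpr import GPR
from .model import (
    DEFAULT_BOUND,
    Gene,
    Metabolite,
    Model,
    ModelIntegrityError,
    Reaction,
    formula_to_string,
)


class SBMLFormatError(ValueError):
    """Raised when an SBML file cannot be parsed or fails validation."""


_GA_NOTE = re.compile(r"GENE[_ ]ASSOCIATION:\s*([^<\n]+)", re.IGNORECASE)


def _check(ret: int, what: str) -> None:
    if ret not in (libsbml.LIBSBML_OPERATION_SUCCESS, None):
        raise SBMLFormatError(f"libsbml call failed ({ret}) while setting {what}")


def write_sbml(model: Model, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    _check(sm.setId(model.id), "model id")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for cid, cname in model.compartments.items():
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        _check(sp.setId(met.id), f"species {met.id}")
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(formula_to_string(met.formula))
        if met.charge is not None:
            splug.setCharge(met.charge)

    for gene in model.genes.values():
        gp = mplug.createGeneProduct()
        _check(gp.setId(gene.locus_tag), f"gene {gene.locus_tag}")
        gp.setLabel(gene.locus_tag)
        if gene.name:
            gp.setName(gene.name)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        _check(sr.setId(rxn.id), f"reaction {rxn.id}")
        sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        if rxn.subsystem or rxn.ec_numbers:
            notes = []
            if rxn.subsystem:
                notes.append(f"<p>SUBSYSTEM: {rxn.subsystem}</p>")
            if rxn.ec_numbers:
                notes.append(f"<p>EC Number: {';'.join(rxn.ec_numbers)}</p>")
            sr.setNotes(
                "<body xmlns=\"http://www.w3.org/1999/xhtml\">"
                + "".join(notes)
                + "</body>"
            )
        for met, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(float(rxn.lower_bound)))
        rplug.setUpperFluxBound(bound_param(float(rxn.upper_bound)))
        if not rxn.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            _check(gpa.setAssociation(rxn.gpr.to_string()), f"GPR of {rxn.id}")

    if model.objective_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _species_formula(sp: libsbml.Species) -> tuple[Optional[str], Optional[int]]:
    splug = sp.getPlugin("fbc")
    formula = None
    charge = None
    if splug is not None:
        if splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula() or None
        if splug.isSetCharge():
            charge = splug.getCharge()
    if sp.isSetCharge() and charge is None:  # L2 legacy attribute
        charge = sp.getCharge()
    return formula, charge


def _reaction_bounds(
    sr: libsbml.Reaction, sm: libsbml.Model
) -> tuple[float, float]:
    rplug = sr.getPlugin("fbc")
    lb = ub = None
    if rplug is not None:
        if rplug.isSetLowerFluxBound():
            par = sm.getParameter(rplug.getLowerFluxBound())
            if par is not None:
                lb = par.getValue()
        if rplug.isSetUpperFluxBound():
            par = sm.getParameter(rplug.getUpperFluxBound())
            if par is not None:
                ub = par.getValue()
    if (lb is None or ub is None) and sr.isSetKineticLaw():
        kl = sr.getKineticLaw()
        plo = kl.getParameter("LOWER_BOUND")
        pup = kl.getParameter("UPPER_BOUND")
        if lb is None and plo is not None:
            lb = plo.getValue()
        if ub is None and pup is not None:
            ub = pup.getValue()
    if lb is None:
        lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
    if ub is None:
        ub = DEFAULT_BOUND
    return lb, ub


def _reaction_gpr(sr: libsbml.Reaction) -> GPR:
    rplug = sr.getPlugin("fbc")
    if rplug is not None:
        gpa = rplug.getGeneProductAssociation()
        if gpa is not None and gpa.getAssociation() is not None:
            return GPR.from_string(gpa.getAssociation().toInfix())
    if sr.isSetNotes():
        m = _GA_NOTE.search(sr.getNotesString())
        if m:
            rule = m.group(1).strip()
            if rule and rule.lower() not in ("none", "n/a", "-"):
                return GPR.from_string(rule)
    return GPR(None)


def read_sbml(path: str | Path) -> Model:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLFormatError(
            f"{path}: line {err.getLine()}: {err.getMessage().strip()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise SBMLFormatError(f"{path}: no <model> element")

    model = Model(id=sm.getId() or path.stem, compartments={})
    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()
    if not model.compartments:
        model.compartments = {"c": "cytoplasm", "e": "extracellular"}

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        formula, charge = _species_formula(sp)
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment(),
            )
        )

    mplug = sm.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            model.add_gene(Gene(gp.getId(), gp.getName()))

    if sm.getNumReactions() == 0:
        raise ModelIntegrityError(
            f"{path}: model has no reactions (no objective resolvable)"
        )

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = (
                stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
            )
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = (
                stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
            )
        stoich = {m: c for m, c in stoich.items() if c != 0}
        missing = [m for m in stoich if m not in model.metabolites]
        if missing:
            raise ModelIntegrityError(
                f"{path}: reaction {sr.getId()} references unknown species {missing}"
            )
        lb, ub = _reaction_bounds(sr, sm)
        subsystem = ""
        ec: list[str] = []
        if sr.isSetNotes():
            notes = sr.getNotesString()
            msub = re.search(r"SUBSYSTEM:\s*([^<\n]+)", notes)
            if msub:
                subsystem = msub.group(1).strip()
            mec = re.search(r"EC Number:\s*([^<\n]+)", notes, re.IGNORECASE)
            if mec:
                ec = [e for e in mec.group(1).strip().split(";") if e]
        model.add_reaction(
            Reaction(
                id=sr.getId(),
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=_reaction_gpr(sr),
                subsystem=subsystem,
                ec_numbers=ec,
            )
        )

    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_id = obj.getFluxObjective(0).getReaction()
    model.validate()
    return model
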