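"""Tabular model dialect: a sectioned TSV mirroring supplementary-file layouts.

One file with three blocks, each introduced by a ``# <section>`` line:

    # model  <tab> <model id> <tab> <objective id>
    # metabolites
    id  name  formula  charge  compartment
    ...
    # genes
    locus_tag  name
    ...
    # reactions
    id  name  equation  gpr  subsystem  lower_bound  upper_bound  ec_numbers

The reaction ``equation`` column carries the stoichiometry as a string,
`` + ``-separated terms with leading rational coefficients, ``<=>`` for
reversible and ``-->`` for irreversible reactions; parsing is
whitespace-insensitive.  This keeps the file human-auditable and diffable,
which is the point of the dialect.
"""

from __future__ import annotations

import io
import re
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Tuple

from .gpr import GPR
from .model import (
    DEFAULT_BOUND,
    Gene,
    Metabolite,
    Model,
    Reaction,
    formula_to_string,
)


class TableFormatError(ValueError):
    """Raised when a tabular model file cannot be parsed."""


_ARROWS = ("<=>", "-->", "<--", "->", "<->")


def parse_equation(eq: str) -> Tuple[Dict[str, Fraction], bool]:
    """Parse ``"a A + b B <=> c C"`` into (stoichiometry, reversible).

    Coefficients are leading rationals (``2``, ``1/2``, ``0.5``); a missing
    coefficient means 1.  A one-sided equation (``A --> ``) is allowed for
    boundary/drain reactions.
    """
    eq = eq.strip()
    arrow = None
    for a in _ARROWS:
        if a in eq:
            arrow = a
            break
    if arrow is None:
        raise TableFormatError(f"no reaction arrow in equation {eq!r}")
    left, right = eq.split(arrow, 1)
    reversible = arrow in ("<=>", "<->")
    if arrow == "<--":  # right-to-left irreversible: normalize
        left, right = right, left
    stoich: Dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coef, met = Fraction(1), parts[0]
            elif len(parts) == 2:
                try:
                    coef = (
                        Fraction(parts[0])
                        if "/" in parts[0] or "." not in parts[0]
                        else Fraction(str(parts[0])).limit_denominator(10**9)
                    )
                except ValueError as exc:
                    raise TableFormatError(
                        f"bad coefficient {parts[0]!r} in equation {eq!r}"
                    ) from exc
                met = parts[1]
            else:
                raise TableFormatError(f"cannot parse term {term!r} in {eq!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coef
    add_side(left, -1)
    add_side(right, +1)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise TableFormatError(f"equation {eq!r} has empty net stoichiometry")
    return stoich, reversible


def write_table(model: Model, path: str | Path) -> None:
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# model\t{model.id}\t{model.objective_id or ''}\n")
    buf.write("# metabolites\n")
    buf.write("id\tname\tformula\tcharge\tcompartment\n")
    for met in model.metabolites.values():
        charge = "" if met.charge is None else str(met.charge)
        buf.write(
            f"{met.id}\t{met.name}\t{formula_to_string(met.formula)}\t"
            f"{charge}\t{met.compartment}\n"
        )
    buf.write("# genes\n")
    buf.write("locus_tag\tname\n")
    for gene in model.genes.values():
        buf.write(f"{gene.locus_tag}\t{gene.name}\n")
    buf.write("# reactions\n")
    buf.write(
        "id\tname\tequation\tgpr\tsubsystem\tlower_bound\tupper_bound\tec_numbers\n"
    )
    for rxn in model.reactions.values():
        buf.write(
            "\t".join(
                [
                    rxn.id,
                    rxn.name,
                    rxn.equation(),
                    rxn.gpr.to_string(),
                    rxn.subsystem,
                    repr(rxn.lower_bound),
                    repr(rxn.upper_bound),
                    ";".join(rxn.ec_numbers),
                ]
            )
            + "\n"
        )
    path.write_text(buf.getvalue())


def read_table(path: str | Path) -> Model:
    path = Path(path)
    lines = path.read_text().splitlines()
    model = Model(id=path.stem)
    objective = None
    section = None
    header: List[str] = []
    pending_reactions: List[dict] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = [f.strip() for f in line.lstrip("#").split("\t")]
            section = fields[0]
            header = []
            if section == "model" and len(fields) >= 2:
                model.id = fields[1]
                if len(fields) >= 3 and fields[2]:
                    objective = fields[2]
            continue
        cols = line.split("\t")
        if not header:
            header = cols
            continue
        row = dict(zip(header, cols))
        try:
            if section == "metabolites":
                model.add_metabolite(
                    Metabolite(
                        id=row["id"],
                        name=row.get("name", ""),
                        formula=row.get("formula") or None,
                        charge=int(row["charge"]) if row.get("charge") else None,
                        compartment=row.get("compartment", "c"),
                    )
                )
            elif section == "genes":
                model.add_gene(Gene(row["locus_tag"], row.get("name", "")))
            elif section == "reactions":
                pending_reactions.append(row)
        except (KeyError, ValueError) as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    for row in pending_reactions:
        stoich, reversible = parse_equation(row["equation"])
        lb = float(row["lower_bound"]) if row.get("lower_bound") else (
            -DEFAULT_BOUND if reversible else 0.0
        )
        ub = float(row["upper_bound"]) if row.get("upper_bound") else DEFAULT_BOUND
        missing = [m for m in stoich if m not in model.metabolites]
        if missing:
            raise TableFormatError(
                f"{path}: reaction {row['id']} references unknown metabolites {missing}"
            )
        model.add_reaction(
            Reaction(
                id=row["id"],
                name=row.get("name", ""),
                stoichiometry=dict(stoich),
                lower_bound=lb,
                upper_bound=ub,
                gpr=GPR.from_string(row.get("gpr", "")),
                subsystem=row.get("subsystem", ""),
                ec_numbers=[e for e in row.get("ec_numbers", "").split(";") if e],
            )
        )
    model.objective_id = objective
    model.validate()
    return model
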