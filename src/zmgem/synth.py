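"""Synthetic model and data generators with known ground truth.

Every input class the pipeline consumes can be generated here, so all
stages are testable without any external file:

* a small mass-balanced Entner-Doudoroff (ED) style network — glucose to
  pyruvate to ethanol plus biomass — with analytically known optima,
  optional planted dead-ends and elemental imbalances;
* a pair of "legacy" variants of that model with divergent identifiers,
  flipped reaction directions and private reactions, for merge testing;
* gene-level p-value tables with a planted reporter-metabolite signal.

The ED backbone is deliberately Zymomonas-like: one ATP per hexose, ethanol
as the redox-neutral carbon sink, acetoin as a redox-neutral pyruvate
overflow, an ATP-costly reductive succinate branch, extracellular
levansucrase splitting sucrose, and a cellulose-synthase route feeding an
alternative biomass.  With glucose uptake bounded at 10 mmol gDCW^-1 h^-1
the analytic optima are (derivable by hand from the four balances on
hexose, pyruvate, NADH and ATP):

* max ethanol = 2 x uptake = 20,
* anaerobic growth 200/117 ~ 1.7094 h^-1 with succinate pinned at
  140/117 ~ 1.1966 at the optimum,
* pdc+ldh knockout: growth 50/53 ~ 0.9434 h^-1 with succinate pinned at
  510/53 ~ 9.6226 (fluxes redirected to succinate),
* aerobic growth 20/11 ~ 1.8182 h^-1 (NADH surplus vented to O2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import FORMULAS
from .gpr import GPR
from .media import Medium
from .model import Gene, Metabolite, Model, Reaction, parse_formula
from .flux import KnockInPathway
from .transcriptome import ExpressionTable


class ConstructionError(ValueError):
    """A synthetic-model spec is internally inconsistent."""


@dataclass
class ToySpec:
    """Parameters of the synthetic ED model family."""

    n_linear_chain: int = 2          # glucose->hexose-pool steps
    branch_count: int = 2            # abstract C6 side branches
    planted_gaps: Tuple[str, ...] = ()     # branch isomerase reaction ids to remove
    planted_imbalances: int = 0      # number of branch entries given an H error
    n_renames: int = 3               # legacy-pair: metabolites renamed per variant
    n_flips: int = 2                 # legacy-pair: reaction directions flipped
    n_private: Tuple[int, int] = (4, 4)    # legacy-pair: private reactions
    glucose_uptake: float = 10.0
    biomass_requires_aa: bool = False      # cap growth by amino-acid import
    seed: int = 0


# gene roles of the synthetic ZM-like strain (ZMS = synthetic locus tags)
TOY_GENES: Dict[str, str] = {
    "GLF": "ZMS0366",
    "CHAIN_1": "ZMS0369",
    "ED": "ZMS0367 and ZMS0997 and ZMS0998",
    "PDC": "ZMS1360",
    "ADH": "ZMS1596 or ZMS1236",
    "LDH": "ZMS0256",
    "SUC_SYN": "ZMS1655 and ZMS0149",
    "ACTD": "ZMS1139",
    "NOX": "ZMS1113",
    "CELS": "ZMS1083 and ZMS1084",
    "LEVANS": "ZMS0375",
    "FRK": "ZMS1719",
    "GNT_RED": "ZMS1649",
    "FRUt": "ZMS0293",
    "GNTt": "ZMS0294",
}

PDC_LDH_GENES = ("ZMS1360", "ZMS0256")


def _met(model: Model, tag: str, comp: str, name: str = "") -> str:
    mid = f"{tag}_{comp}"
    if mid not in model.metabolites:
        model.add_metabolite(
            Metabolite(mid, name or tag, FORMULAS.get(tag), charge=0, compartment=comp)
        )
    return mid


def _balanced(model: Model, stoich: Dict[str, Fraction | float]) -> Dict[str, Fraction]:
    """Complete a C/N/P-balanced draft with water and protons (cytoplasmic)."""
    net: Dict[str, Fraction] = {}
    for mid, coef in stoich.items():
        formula = model.metabolites[mid].formula or {}
        for el, n in formula.items():
            net[el] = net.get(el, Fraction(0)) + Fraction(coef) * n
    for el in net:
        if el not in ("H", "O") and net[el] != 0:
            raise ConstructionError(f"cannot water-balance {el} imbalance {net[el]}")
    a = -net.get("O", Fraction(0))          # h2o coefficient
    b = -net.get("H", Fraction(0)) - 2 * a  # h coefficient
    out = {m: Fraction(c) for m, c in stoich.items()}
    if a:
        h2o = _met(model, "h2o", "c", "water")
        out[h2o] = out.get(h2o, Fraction(0)) + a
    if b:
        h = _met(model, "h", "c", "proton")
        out[h] = out.get(h, Fraction(0)) + b
    return {m: c for m, c in out.items() if c != 0}


def _rxn(
    model: Model,
    rid: str,
    stoich: Dict[str, Fraction | float],
    lb: float = 0.0,
    ub: float = 1000.0,
    gpr: str = "",
    name: str = "",
    subsystem: str = "",
    balance: bool = True,
) -> Reaction:
    if balance:
        stoich = _balanced(model, stoich)
    return model.add_reaction(
        Reaction(
            id=rid,
            name=name or rid,
            stoichiometry=dict(stoich),
            lower_bound=lb,
            upper_bound=ub,
            gpr=GPR.from_string(gpr),
            subsystem=subsystem,
        )
    )


def _exchange(model: Model, tag: str, lb: float = 0.0, ub: float = 1000.0) -> str:
    mid = _met(model, tag, "e")
    rid = f"EX_{mid}"
    _rxn(model, rid, {mid: Fraction(-1)}, lb, ub, balance=False,
         subsystem="Exchange")
    return rid


def make_toy_ed_model(spec: ToySpec = ToySpec()) -> tuple[Model, dict]:
    """Build the synthetic ED model and its ground-truth record."""
    if spec.n_linear_chain < 1:
        raise ConstructionError("n_linear_chain must be >= 1 (zero-length backbone)")
    if spec.planted_imbalances > spec.branch_count:
        raise ConstructionError("more planted imbalances than branches")
    model = Model(id=f"toy_ed_{spec.seed}")
    F = Fraction
    u = spec.glucose_uptake

    # boundary species and exchanges
    _exchange(model, "glc", -u, 1000)
    _exchange(model, "fru")
    _exchange(model, "glcn")
    _exchange(model, "sucr")
    _exchange(model, "lev")
    _exchange(model, "etoh")
    _exchange(model, "lac")
    _exchange(model, "succ")
    _exchange(model, "actn")
    _exchange(model, "cel")
    _exchange(model, "co2", -1000, 1000)
    _exchange(model, "o2", 0, 1000)     # anaerobic unless a medium opens it
    _exchange(model, "h2o", -1000, 1000)
    _exchange(model, "h", -1000, 1000)

    # cytoplasmic cofactor pool
    for tag in ("nad", "nadh", "atp", "adp", "pi", "h2o", "h"):
        _met(model, tag, "c")

    # uptake and backbone: glucose -> (chain) -> hexose pool -> ED -> pyruvate
    _met(model, "glc", "c", "D-glucose")
    _rxn(model, "GLF", {"glc_e": F(-1), "glc_c": F(1)}, gpr=TOY_GENES["GLF"],
         name="glucose facilitated diffusion", subsystem="Transport")
    prev = "glc_c"
    for i in range(1, spec.n_linear_chain + 1):
        nxt = "hex_c" if i == spec.n_linear_chain else f"c6i{i}_c"
        if nxt != "hex_c":
            model.add_metabolite(
                Metabolite(nxt, f"hexose intermediate {i}", FORMULAS["hex"], 0, "c")
            )
        else:
            _met(model, "hex", "c", "hexose pool")
        _rxn(model, f"CHAIN_{i}", {prev: F(-1), nxt: F(1)},
             gpr=TOY_GENES.get(f"CHAIN_{i}", f"ZMS02{i:02d}"),
             subsystem="Glycolysis (ED)")
        prev = nxt
    for tag in ("pyr", "acald", "etoh", "lac", "succ", "actn", "co2", "o2", "cel"):
        _met(model, tag, "c")
    _rxn(model, "ED",
         {"hex_c": F(-1), "nad_c": F(-2), "adp_c": F(-1), "pi_c": F(-1),
          "pyr_c": F(2), "nadh_c": F(2), "atp_c": F(1)},
         gpr=TOY_GENES["ED"], name="Entner-Doudoroff lump",
         subsystem="Glycolysis (ED)")
    _rxn(model, "PDC", {"pyr_c": F(-1), "acald_c": F(1), "co2_c": F(1)},
         gpr=TOY_GENES["PDC"], name="pyruvate decarboxylase",
         subsystem="Fermentation")
    _rxn(model, "ADH", {"acald_c": F(-1), "nadh_c": F(-1), "etoh_c": F(1),
                        "nad_c": F(1)},
         gpr=TOY_GENES["ADH"], name="alcohol dehydrogenase",
         subsystem="Fermentation")
    _rxn(model, "LDH", {"pyr_c": F(-1), "nadh_c": F(-1), "lac_c": F(1),
                        "nad_c": F(1)},
         gpr=TOY_GENES["LDH"], name="lactate dehydrogenase",
         subsystem="Fermentation")
    _rxn(model, "SUC_SYN",
         {"pyr_c": F(-1), "co2_c": F(-1), "nadh_c": F(-2),
          "atp_c": F(-1, 2), "succ_c": F(1), "nad_c": F(2),
          "adp_c": F(1, 2), "pi_c": F(1, 2)},
         gpr=TOY_GENES["SUC_SYN"], name="reductive succinate lump",
         subsystem="TCA / anaplerosis")
    _rxn(model, "ACTD", {"pyr_c": F(-2), "actn_c": F(1), "co2_c": F(2)},
         gpr=TOY_GENES["ACTD"], name="acetolactate to acetoin lump",
         subsystem="Fermentation")
    _rxn(model, "NOX", {"nadh_c": F(-2), "o2_c": F(-1), "nad_c": F(2)},
         gpr=TOY_GENES["NOX"], name="NADH oxidase", subsystem="Respiration")
    _rxn(model, "ATPM", {"atp_c": F(-1), "h2o_c": F(-1), "adp_c": F(1),
                         "pi_c": F(1)},
         lb=0.0, ub=50.0, name="ATP maintenance", subsystem="Energy",
         balance=True)
    _rxn(model, "CELS", {"hex_c": F(-1), "cel_c": F(1)},
         gpr=TOY_GENES["CELS"], name="cellulose synthase lump",
         subsystem="Cell envelope")

    # alternative carbon routes
    _met(model, "fru", "c"); _met(model, "glcn", "c")
    _rxn(model, "FRUt", {"fru_e": F(-1), "fru_c": F(1)}, gpr=TOY_GENES["FRUt"],
         subsystem="Transport")
    _rxn(model, "FRK", {"fru_c": F(-1), "hex_c": F(1)}, gpr=TOY_GENES["FRK"],
         name="fructokinase lump", subsystem="Glycolysis (ED)")
    _rxn(model, "GNTt", {"glcn_e": F(-1), "glcn_c": F(1)}, gpr=TOY_GENES["GNTt"],
         subsystem="Transport")
    _rxn(model, "GNT_RED", {"glcn_c": F(-1), "nadh_c": F(-1), "glc_c": F(1),
                            "nad_c": F(1)},
         gpr=TOY_GENES["GNT_RED"], name="gluconate reduction lump",
         subsystem="Glycolysis (ED)")
    _rxn(model, "LEVANS", {"sucr_e": F(-1), "lev_e": F(1), "glc_e": F(1)},
         gpr=TOY_GENES["LEVANS"], name="levansucrase (extracellular)",
         subsystem="Cell envelope")

    # secretion / gas / water transport
    for tag in ("etoh", "lac", "succ", "actn", "cel"):
        _rxn(model, f"T_{tag}", {f"{tag}_c": F(-1), f"{tag}_e": F(1)},
             subsystem="Transport")
    for tag in ("co2", "o2", "h2o", "h"):
        _rxn(model, f"T_{tag}", {f"{tag}_c": F(-1), f"{tag}_e": F(1)},
             lb=-1000.0, subsystem="Transport")

    # biomass: hexose + pyruvate carbon, 5 ATP, small net NADH release
    biomass = {
        "hex_c": F(-1, 2), "pyr_c": F(-1, 2),
        "atp_c": F(-5), "h2o_c": F(-5), "adp_c": F(5), "pi_c": F(5),
        "nad_c": F(-1, 5), "nadh_c": F(1, 5),
    }
    if spec.biomass_requires_aa:
        _exchange(model, "glu")
        _met(model, "glu", "c", "amino-acid pool (glutamate)")
        _rxn(model, "AAt", {"glu_e": F(-1), "glu_c": F(1)}, subsystem="Transport")
        biomass["glu_c"] = F(-1)
    _rxn(model, "BIOMASS", biomass, name="biomass", subsystem="Biomass",
         balance=False)
    model.objective_id = "BIOMASS"

    # abstract C6 side branches off glucose, for gap/imbalance planting
    truth_dead: dict[str, dict[str, list[str]]] = {}
    imbalanced: list[str] = []
    for k in range(1, spec.branch_count + 1):
        for part in ("a", "b"):
            model.add_metabolite(
                Metabolite(f"br{k}{part}_c", f"branch {k} metabolite {part}",
                           FORMULAS["hex"], 0, "c")
            )
        model.add_metabolite(
            Metabolite(f"br{k}b_e", f"branch {k} product", FORMULAS["hex"], 0, "e")
        )
        syn = _rxn(model, f"BR{k}_SYN", {"glc_c": F(-1), f"br{k}a_c": F(1)},
                   gpr=f"ZMS6{k}01", subsystem="Branches")
        iso_id = f"BR{k}_ISO"
        if iso_id not in spec.planted_gaps:
            _rxn(model, iso_id, {f"br{k}a_c": F(-1), f"br{k}b_c": F(1)},
                 gpr=f"ZMS6{k}02", subsystem="Branches")
        else:
            # truth under the structural probe (all exchanges open): the
            # extracellular product stays producible via its own exchange
            truth_dead[iso_id] = {
                "no_production": [f"br{k}b_c"],
                "no_consumption": [f"br{k}a_c"],
                "blocked": [f"BR{k}_SYN", f"BR{k}_T", f"EX_br{k}b_e"],
            }
        _rxn(model, f"BR{k}_T", {f"br{k}b_c": F(-1), f"br{k}b_e": F(1)},
             subsystem="Transport")
        _rxn(model, f"EX_br{k}b_e", {f"br{k}b_e": F(-1)}, 0.0, 1000.0,
             balance=False, subsystem="Exchange")
        if len(imbalanced) < spec.planted_imbalances:
            # one spare hydrogen on the branch entry: an H: +1 error
            h = _met(model, "h", "c")
            syn.stoichiometry[h] = syn.stoichiometry.get(h, F(0)) + 1
            imbalanced.append(syn.id)

    unknown = [g for g in spec.planted_gaps if g not in truth_dead]
    if unknown:
        raise ConstructionError(
            f"planted_gaps must name branch isomerases BRk_ISO; got {unknown}"
        )
    model.validate()

    mu_wt = Fraction(200, 117) * F(u) / 10
    truth = {
        "spec": spec,
        "ethanol_max": 2 * u,
        "growth_anaerobic": float(mu_wt),
        "succinate_at_optimum": float(Fraction(140, 117) * F(u) / 10),
        "growth_pdc_ldh_ko": float(Fraction(50, 53) * F(u) / 10),
        "succinate_at_ko_optimum": float(Fraction(510, 53) * F(u) / 10),
        "growth_aerobic": float(Fraction(20, 11) * F(u) / 10),
        "pdc_ldh_genes": list(PDC_LDH_GENES),
        "gene_roles": dict(TOY_GENES),
        "dead_ends": truth_dead,
        "imbalanced_reactions": imbalanced,
    }
    return model, truth


# ---------------------------------------------------------------------------
# media presets for the toy namespace


def toy_media(model: Model) -> Dict[str, Medium]:
    """RM-style presets phrased as exchange-bound patterns on the toy model."""
    aa = ["EX_glu_e"] if "EX_glu_e" in model.reactions else []
    free = ["EX_co2_e", "EX_h2o_e", "EX_h_e"]
    common = dict(
        free_exchanges=free,
        oxygen_exchange="EX_o2_e",
        amino_acid_exchanges=aa,
        atp_maintenance="ATPM",
    )
    return {
        "RM": Medium(name="RM", aerobic=False,
                     carbon_exchanges=["EX_glc_e"], **common),
        "RM_aerobic": Medium(name="RM_aerobic", aerobic=True,
                             carbon_exchanges=["EX_glc_e"], **common),
        "SRM": Medium(name="SRM", aerobic=True, carbon_exchanges=[],
                      exchange_overrides={"EX_sucr_e": (-5.0, 1000.0)},
                      **common),
        "minimal": Medium(name="minimal", aerobic=False,
                          carbon_exchanges=["EX_glc_e"],
                          amino_acid_exchanges=[],
                          free_exchanges=free,
                          oxygen_exchange="EX_o2_e",
                          atp_maintenance="ATPM"),
        "minimal_aerobic": Medium(name="minimal_aerobic", aerobic=True,
                                  carbon_exchanges=["EX_glc_e"],
                                  amino_acid_exchanges=[],
                                  free_exchanges=free,
                                  oxygen_exchange="EX_o2_e",
                                  atp_maintenance="ATPM"),
    }


# ---------------------------------------------------------------------------
# heterologous pathway presets (toy namespace)


def _pathway_model_scaffold() -> Model:
    """Private scaffold so preset reactions can be water/proton-balanced."""
    m = Model(id="scaffold")
    for tag in ("xyl", "xlu", "arab", "rbl", "hex", "pyr", "nad", "nadh",
                "adp", "atp", "pi", "h2o", "h", "co2", "nh3", "ala", "actn",
                "btd", "caro"):
        _met(m, tag, "c")
    for tag in ("xyl", "arab", "nh3", "ala", "btd", "caro"):
        _met(m, tag, "e")
    return m


def pathway_preset(name: str) -> KnockInPathway:
    """Shipped heterologous pathways, lumped but mass-balanced.

    ``xylose``: isomerase + a xylulokinase/transketolase/transaldolase lump
    feeding the hexose pool and pyruvate (3 pentoses -> 2 hexoses + 1 triose,
    the classic non-oxidative pentose-phosphate stoichiometry).
    ``arabinose``: isomerase + the same pentose lump via L-ribulose.
    ``alanine``: alanine dehydrogenase (pyruvate amination).
    ``butanediol``: butanediol dehydrogenase on native acetoin.
    ``beta_carotene``: a terpenoid lump from pyruvate (16 C3 -> C40 + 8 CO2).
    """
    F = Fraction
    scaffold = _pathway_model_scaffold()
    mets = {mid: met for mid, met in scaffold.metabolites.items()}

    def reaction(rid, stoich, lb=0.0, ub=1000.0, gpr="", name_=""):
        stoich = _balanced(scaffold, stoich)
        return Reaction(id=rid, name=name_ or rid, stoichiometry=dict(stoich),
                        lower_bound=lb, upper_bound=ub,
                        gpr=GPR.from_string(gpr), subsystem="Heterologous")

    def pick(*mids):
        return [mets[m] for m in mids]

    pentose_lump = lambda pid, src: reaction(
        pid,
        {src: F(-3), "nad_c": F(-1), "adp_c": F(-1), "pi_c": F(-1),
         "hex_c": F(2), "pyr_c": F(1), "nadh_c": F(1), "atp_c": F(1)},
        gpr="XKS1 and TKT1 and TAL1",
        name_="pentose assimilation lump (kinase/transketolase/transaldolase)",
    )

    if name == "xylose":
        return KnockInPathway(
            name="xylose",
            metabolites=pick("xyl_c", "xlu_c") + [mets["xyl_e"]],
            reactions=[
                Reaction("EX_xyl_e", stoichiometry={"xyl_e": F(-1)},
                         lower_bound=0.0, upper_bound=1000.0,
                         subsystem="Exchange"),
                reaction("XYLt", {"xyl_e": F(-1), "xyl_c": F(1)}),
                reaction("XI", {"xyl_c": F(-1), "xlu_c": F(1)}, gpr="XYLA",
                         name_="xylose isomerase"),
                pentose_lump("XPK", "xlu_c"),
            ],
        )
    if name == "arabinose":
        lump = pentose_lump("APK", "rbl_c")
        lump.gpr = GPR.from_string("ARAB and RPE1 and TAL1")
        return KnockInPathway(
            name="arabinose",
            metabolites=pick("arab_c", "rbl_c") + [mets["arab_e"]],
            reactions=[
                Reaction("EX_arab_e", stoichiometry={"arab_e": F(-1)},
                         lower_bound=0.0, upper_bound=1000.0,
                         subsystem="Exchange"),
                reaction("ARAt", {"arab_e": F(-1), "arab_c": F(1)}),
                reaction("AI", {"arab_c": F(-1), "rbl_c": F(1)}, gpr="ARAA",
                         name_="arabinose isomerase"),
                lump,
            ],
        )
    if name == "alanine":
        return KnockInPathway(
            name="alanine",
            metabolites=pick("nh3_c", "ala_c") + pick("nh3_e", "ala_e"),
            reactions=[
                Reaction("EX_nh3_e", stoichiometry={"nh3_e": F(-1)},
                         lower_bound=-1000.0, upper_bound=1000.0,
                         subsystem="Exchange"),
                Reaction("EX_ala_e", stoichiometry={"ala_e": F(-1)},
                         lower_bound=0.0, upper_bound=1000.0,
                         subsystem="Exchange"),
                reaction("NH3t", {"nh3_e": F(-1), "nh3_c": F(1)}, lb=-1000.0),
                reaction("ALAt", {"ala_c": F(-1), "ala_e": F(1)}),
                reaction("ALADH",
                         {"pyr_c": F(-1), "nh3_c": F(-1), "nadh_c": F(-1),
                          "ala_c": F(1), "nad_c": F(1)},
                         gpr="ALD", name_="alanine dehydrogenase"),
            ],
        )
    if name == "butanediol":
        return KnockInPathway(
            name="butanediol",
            metabolites=pick("btd_c") + [mets["btd_e"]],
            reactions=[
                Reaction("EX_btd_e", stoichiometry={"btd_e": F(-1)},
                         lower_bound=0.0, upper_bound=1000.0,
                         subsystem="Exchange"),
                reaction("BTDt", {"btd_c": F(-1), "btd_e": F(1)}),
                reaction("BDH",
                         {"actn_c": F(-1), "nadh_c": F(-1), "btd_c": F(1),
                          "nad_c": F(1)},
                         gpr="BDH1", name_="butanediol dehydrogenase"),
            ],
        )
    if name == "beta_carotene":
        return KnockInPathway(
            name="beta_carotene",
            metabolites=pick("caro_c") + [mets["caro_e"]],
            reactions=[
                Reaction("EX_caro_e", stoichiometry={"caro_e": F(-1)},
                         lower_bound=0.0, upper_bound=1000.0,
                         subsystem="Exchange"),
                reaction("CAROt", {"caro_c": F(-1), "caro_e": F(1)}),
                reaction("CRT_LUMP",
                         {"pyr_c": F(-16), "nadh_c": F(-28),
                          "caro_c": F(1), "co2_c": F(8), "nad_c": F(28)},
                         gpr="CRTE and CRTB and CRTI and CRTY",
                         name_="carotenoid biosynthesis lump"),
            ],
        )
    raise KeyError(
        f"unknown pathway preset {name!r}; available: xylose, arabinose, "
        "alanine, butanediol, beta_carotene"
    )


PATHWAY_PRESETS = ("xylose", "arabinose", "alanine", "butanediol", "beta_carotene")


# ---------------------------------------------------------------------------
# legacy-variant pair for reconciliation testing


@dataclass
class LegacyPairTruth:
    shared: int
    unique: Tuple[int, int]
    idmap_a: Dict[str, str]      # legacy local id -> canonical id
    idmap_b: Dict[str, str]
    flipped_a: List[str]
    flipped_b: List[str]
    private_a: List[str]
    private_b: List[str]


def _legacy_variant(
    model: Model,
    rng: np.random.Generator,
    label: str,
    n_renames: int,
    n_flips: int,
    n_private: int,
) -> tuple[Model, Dict[str, str], List[str], List[str]]:
    variant = model.copy()
    variant.id = f"{model.id}_{label}"
    candidates = sorted(
        m for m in variant.metabolites
        if m.endswith("_c") and not m.startswith(("nad", "atp", "adp", "pi", "h"))
    )
    renamed = list(rng.choice(candidates, size=min(n_renames, len(candidates)),
                              replace=False))
    idmap: Dict[str, str] = {}
    for mid in renamed:
        legacy = f"{label.upper()}_{mid[:-2].upper()}"
        idmap[legacy] = mid
        met = variant.metabolites.pop(mid)
        met.id = legacy
        variant.metabolites[legacy] = met
        for rxn in variant.reactions.values():
            if mid in rxn.stoichiometry:
                rxn.stoichiometry[legacy] = rxn.stoichiometry.pop(mid)
    internal = sorted(
        r.id for r in variant.reactions.values()
        if not r.is_exchange and r.lower_bound == 0 and r.id != "BIOMASS"
    )
    flipped = list(rng.choice(internal, size=min(n_flips, len(internal)),
                              replace=False))
    for rid in flipped:
        rxn = variant.reactions[rid]
        rxn.stoichiometry = {m: -c for m, c in rxn.stoichiometry.items()}
        rxn.lower_bound, rxn.upper_bound = -rxn.upper_bound, -rxn.lower_bound
    private: List[str] = []
    for i in range(n_private):
        m1 = variant.add_metabolite(
            Metabolite(f"{label}_priv{i}a_c", formula={"X": 1}, charge=0,
                       compartment="c")
        )
        m2 = variant.add_metabolite(
            Metabolite(f"{label}_priv{i}b_c", formula={"X": 1}, charge=0,
                       compartment="c")
        )
        rid = f"PRIV_{label.upper()}_{i}"
        variant.add_reaction(
            Reaction(rid, {m1.id: Fraction(-1), m2.id: Fraction(1)},
                     lower_bound=0.0, upper_bound=1000.0,
                     subsystem="Private"))
        private.append(rid)
    return variant, idmap, flipped, private


def make_legacy_pair(
    model: Model, spec: ToySpec = ToySpec()
) -> tuple[Model, Model, LegacyPairTruth]:
    """Two divergent legacy encodings of one model, with merge ground truth."""
    rng_a = np.random.default_rng(spec.seed * 2 + 1)
    rng_b = np.random.default_rng(spec.seed * 2 + 2)
    n_core = len(model.reactions)
    a, idmap_a, flips_a, priv_a = _legacy_variant(
        model, rng_a, "va", spec.n_renames, spec.n_flips, spec.n_private[0])
    b, idmap_b, flips_b, priv_b = _legacy_variant(
        model, rng_b, "vb", spec.n_renames, spec.n_flips, spec.n_private[1])
    truth = LegacyPairTruth(
        shared=n_core,
        unique=(spec.n_private[0], spec.n_private[1]),
        idmap_a=idmap_a, idmap_b=idmap_b,
        flipped_a=flips_a, flipped_b=flips_b,
        private_a=priv_a, private_b=priv_b,
    )
    return a, b, truth


# ---------------------------------------------------------------------------
# synthetic expression tables with planted reporter signal


def make_expression(
    model: Model,
    hot_metabolite: str,
    p_hot: float = 1e-4,
    seed: int = 0,
) -> tuple[ExpressionTable, dict]:
    """Gene p-values with a planted coordinated signal around one metabolite.

    Neighbor genes (genes of reactions touching the hot metabolite) receive
    ``p_hot``; every other model gene draws p ~ Uniform(0, 1].
    """
    if hot_metabolite not in model.metabolites:
        raise KeyError(f"unknown metabolite {hot_metabolite!r}")
    neighbors: set[str] = set()
    for rxn in model.reactions.values():
        if hot_metabolite in rxn.stoichiometry:
            neighbors |= rxn.gpr.genes()
    if not neighbors:
        raise ConstructionError(
            f"metabolite {hot_metabolite!r} has no neighbor genes (k=0)"
        )
    rng = np.random.default_rng(seed)
    entries: Dict[str, Tuple[float, str]] = {}
    for tag in model.genes:  # insertion order: deterministic
        if tag in neighbors:
            entries[tag] = (p_hot, "up")
        else:
            p = float(1.0 - rng.random())  # uniform on (0, 1]
            entries[tag] = (p, "none")
    truth = {"hot_metabolite": hot_metabolite,
             "neighbor_genes": sorted(neighbors)}
    return ExpressionTable(entries), truth
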