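"""Generate every synthetic input the downstream analyses consume.

Outputs under results/models/: the Zymomonas-like toy ED model (SBML and
tabular dialects), a variant with a planted dead-end, a legacy model pair
with divergent identifiers plus their curation id-maps, a universal repair
table, and a gene-expression table with a planted reporter signal.
"""

from pathlib import Path

from zmgem import IdMap, Metabolite, Model, Reaction, write_model
from zmgem.media import save_medium
from zmgem.synth import ToySpec, make_expression, make_legacy_pair, make_toy_ed_model, toy_media

OUT = Path(__file__).resolve().parent.parent / "results" / "models"
OUT.mkdir(parents=True, exist_ok=True)

spec = ToySpec(seed=0)
model, truth = make_toy_ed_model(spec)
write_model(model, OUT / "toy_ed.xml")
write_model(model, OUT / "toy_ed.tsv")
print(f"toy ED model: {len(model.genes)} genes, {len(model.reactions)} "
      f"reactions, {len(model.metabolites)} metabolites")
print(f"  analytic optima: ethanol {truth['ethanol_max']}, growth "
      f"{truth['growth_anaerobic']:.4f} h^-1 (anaerobic)")

gapped, gap_truth = make_toy_ed_model(ToySpec(seed=0, planted_gaps=("BR1_ISO",)))
write_model(gapped, OUT / "toy_ed_gapped.xml")
print(f"gapped variant: removed BR1_ISO; expected dead ends "
      f"{gap_truth['dead_ends']['BR1_ISO']}")

# universal repair table: the removed isomerase plus decoys
universal = Model(id="universal", compartments=dict(model.compartments))
for mid in ("br1a_c", "br1b_c", "br2a_c"):
    met = gapped.metabolites[mid]
    universal.add_metabolite(Metabolite(mid, formula=met.formula, charge=0,
                                        compartment="c"))
from fractions import Fraction
universal.add_reaction(Reaction("BR1_ISO", {"br1a_c": Fraction(-1),
                                            "br1b_c": Fraction(1)}, 0, 1000))
universal.add_reaction(Reaction("DECOY", {"br2a_c": Fraction(-1),
                                          "br1b_c": Fraction(1)}, 0, 1000))
write_model(universal, OUT / "universal.tsv")

a, b, pair_truth = make_legacy_pair(model, spec)
write_model(a, OUT / "legacy_a.xml")
write_model(b, OUT / "legacy_b.xml")
IdMap(source=a.id, metabolites=pair_truth.idmap_a).to_tsv(OUT / "idmap_a.tsv")
IdMap(source=b.id, metabolites=pair_truth.idmap_b).to_tsv(OUT / "idmap_b.tsv")
print(f"legacy pair: shared={pair_truth.shared} unique={pair_truth.unique}; "
      f"{len(pair_truth.idmap_a)} renames and {len(pair_truth.flipped_a)} "
      "direction flips per variant")

expr, expr_truth = make_expression(model, "succ_c", p_hot=1e-4, seed=0)
expr.to_tsv(OUT / "expression_planted.tsv")
print(f"expression table: planted signal on {expr_truth['hot_metabolite']} "
      f"({len(expr_truth['neighbor_genes'])} neighbor genes)")

media_dir = OUT / "media"
media_dir.mkdir(exist_ok=True)
for name, medium in toy_media(model).items():
    save_medium(medium, media_dir / f"{name}.yaml")
print(f"media presets written to {media_dir}")
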