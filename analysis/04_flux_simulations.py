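"""The constraint-based simulation battery on the toy ED network.

Reproduces, at toy scale, the simulation repertoire used to validate a
Zymomonas GEM: growth on rich/aerobic/sucrose media, ethanol yields with
pentose knock-ins, product knock-ins (alanine, butanediol, beta-carotene),
the pdc+ldh succinate redirection under flux variability at optimal growth,
the levansucrase flux pin on sucrose, the sole-carbon substrate screen, and
a cellulose-containing biomass essentiality check.
"""

import json
from pathlib import Path

from zmgem import (
    biomass_variant,
    delete_genes,
    fba,
    fva,
    knock_in,
    read_model,
    substrate_screen,
)
from zmgem.flux import knockout_bounds
from zmgem.media import load_medium
from zmgem.synth import PDC_LDH_GENES, pathway_preset

BASE = Path(__file__).resolve().parent.parent / "results"
MODELS = BASE / "models"

model = read_model(MODELS / "toy_ed.xml")
media = {name: load_medium(MODELS / "media" / f"{name}.yaml")
         for name in ("RM", "RM_aerobic", "SRM", "minimal", "minimal_aerobic")}
out = {}

# growth and ethanol
out["growth_RM_anaerobic"] = fba(model, media["RM"]).objective_value
out["growth_RM_aerobic"] = fba(model, media["RM_aerobic"]).objective_value
out["growth_SRM_sucrose"] = fba(model, media["SRM"]).objective_value
out["ethanol_glucose"] = fba(model, media["RM"], "EX_etoh_e").objective_value
print(f"growth: {out['growth_RM_anaerobic']:.4f} h^-1 anaerobic, "
      f"{out['growth_RM_aerobic']:.4f} aerobic, "
      f"{out['growth_SRM_sucrose']:.4f} on sucrose")
print(f"ethanol on glucose: {out['ethanol_glucose']:.2f} mmol gDCW^-1 h^-1 "
      "(2 per glucose, the ED signature)")

# pentose knock-ins
xk = knock_in(model, pathway_preset("xylose"))
xyl = media["RM"].with_(name="xyl", carbon_exchanges=["EX_xyl_e"])
mix = media["RM"].with_(name="mix", carbon_exchanges=["EX_glc_e", "EX_xyl_e"])
out["ethanol_xylose"] = fba(xk, xyl, "EX_etoh_e").objective_value
out["ethanol_mixed"] = fba(xk, mix, "EX_etoh_e").objective_value
out["growth_xylose"] = fba(xk, xyl).objective_value
ak = knock_in(model, pathway_preset("arabinose"))
ara = media["RM"].with_(name="ara", carbon_exchanges=["EX_arab_e"])
out["ethanol_arabinose"] = fba(ak, ara, "EX_etoh_e").objective_value
print(f"ethanol: xylose {out['ethanol_xylose']:.2f} < glucose "
      f"{out['ethanol_glucose']:.2f} < mixed {out['ethanol_mixed']:.2f}")

# product knock-ins
caro = knock_in(model, pathway_preset("beta_carotene"))
out["beta_carotene_flux"] = fba(caro, media["RM"], "EX_caro_e").objective_value
btd = knock_in(knock_in(model, pathway_preset("butanediol")),
               pathway_preset("xylose"))
out["butanediol_glucose"] = fba(btd, media["RM"], "EX_btd_e").objective_value
out["butanediol_mixed"] = fba(btd, mix, "EX_btd_e").objective_value
ala = knock_in(model, pathway_preset("alanine"))
out["ethanol_with_forced_alanine"] = fba(
    ala, media["RM"], "EX_etoh_e",
    extra_bounds={"EX_ala_e": (2.0, 1000.0), "EX_nh3_e": (-1000.0, 1000.0)},
).objective_value
print(f"beta-carotene {out['beta_carotene_flux']:.3f}; butanediol glucose "
      f"{out['butanediol_glucose']:.2f} -> mixed {out['butanediol_mixed']:.2f}; "
      f"ethanol drops to {out['ethanol_with_forced_alanine']:.2f} when alanine "
      "is co-produced")

# pdc+ldh knockout: succinate redirection under FVA at optimal growth
wt = fva(model, media["RM"], ["EX_succ_e"], fraction_of_optimum=1.0)
ko_bounds, disabled = knockout_bounds(model, PDC_LDH_GENES)
ko = fva(model, media["RM"], ["EX_succ_e"], fraction_of_optimum=1.0,
         extra_bounds=ko_bounds)
ko_growth, _ = delete_genes(model, PDC_LDH_GENES, media["RM"])
out["succinate_max_wild_type"] = wt["EX_succ_e"][1]
out["succinate_max_pdc_ldh_ko"] = ko["EX_succ_e"][1]
out["growth_pdc_ldh_ko"] = ko_growth.objective_value
print(f"pdc+ldh knockout (disables {disabled}): succinate max "
      f"{out['succinate_max_wild_type']:.2f} -> "
      f"{out['succinate_max_pdc_ldh_ko']:.2f} at the respective growth optima")

# levansucrase pinned on sucrose medium
lev = fva(model, media["SRM"], ["LEVANS"], fraction_of_optimum=1.0)
out["levansucrase_min"], out["levansucrase_max"] = lev["LEVANS"]
print(f"levansucrase flux on SRM pinned to "
      f"[{out['levansucrase_min']:.3f}, {out['levansucrase_max']:.3f}]")

# substrate screen against the observed phenotype table
observed = {"EX_glc_e": True, "EX_fru_e": True, "EX_sucr_e": True,
            "EX_glcn_e": False, "EX_lev_e": False}
calls = substrate_screen(
    model,
    [(s, "C") for s in ("EX_glc_e", "EX_fru_e", "EX_sucr_e", "EX_glcn_e",
                        "EX_lev_e", "EX_xyl_e")],
    media["RM"], observed=observed,
)
out["substrate_screen"] = {c.substrate: c.category for c in calls}
print("substrate screen:", out["substrate_screen"])

# cellulose-containing biomass: synthase essentiality in minimal aerobic medium
cellulose = biomass_variant(model, {"cel_c": -0.05})
grown = fba(cellulose, media["minimal_aerobic"]).objective_value
lost, _ = delete_genes(cellulose, {"ZMS1083"}, media["minimal_aerobic"])
out["growth_cellulose_biomass"] = grown
out["growth_cellulose_biomass_synthase_ko"] = lost.objective_value
print(f"cellulose biomass: growth {grown:.3f}; cellulose-synthase knockout "
      f"{lost.objective_value:.3f} (essential)")

(BASE / "flux_simulations.json").write_text(json.dumps(out, indent=2))
print(f"wrote {BASE / 'flux_simulations.json'}")
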