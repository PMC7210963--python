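"""Transcriptome integration: reporter metabolites and sampling consistency.

Scores the planted expression table against the toy network (the succinate
neighborhood must rank first), then compares aerobic vs anaerobic flux
samples and scores the significant calls against a synthetic regulated-gene
list through the GPR mapping, reporting the confusion matrix with accuracy
and F1.
"""

import json
from pathlib import Path

from zmgem import (
    ExpressionTable,
    compare_conditions,
    read_model,
    reporter_metabolites,
    sample_fluxes,
    score_against_genes,
)
from zmgem.media import load_medium

BASE = Path(__file__).resolve().parent.parent / "results"
MODELS = BASE / "models"

model = read_model(MODELS / "toy_ed.xml")
rm = load_medium(MODELS / "media" / "RM.yaml")
rm_aerobic = load_medium(MODELS / "media" / "RM_aerobic.yaml")

# reporter metabolites on the planted table
expr = ExpressionTable.from_tsv(MODELS / "expression_planted.tsv")
scores = reporter_metabolites(model, expr, n_background=10_000, seed=0)
frame = scores.as_frame()
frame.to_csv(BASE / "reporter_scores.tsv", sep="\t", index=False)
top = frame.iloc[0]
print(f"top reporter metabolite: {top.metabolite} "
      f"(k={top.k}, corrected Z={top.z_corrected:.2f}, p={top.p_reporter:.2e})")

# aerobic vs anaerobic flux-space sampling
anaerobic = sample_fluxes(model, rm, n=300, seed=1)
aerobic = sample_fluxes(model, rm_aerobic, n=300, seed=2)
report = compare_conditions(anaerobic, aerobic)
pdc_call = report.decisions["PDC"]
adh_call = report.decisions["ADH"]
print(f"aerobic vs anaerobic: PDC {pdc_call[0]} (p={pdc_call[1]:.2e}), "
      f"ADH {adh_call[0]} (p={adh_call[1]:.2e}); "
      f"{len(report.significant())} of {len(report.decisions)} reactions "
      "significantly changed")

# score the calls against a regulated-gene list: oxygen-responsive genes up
regulated_up = {"ZMS1113"}          # NADH oxidase benefits from oxygen
regulated_down = set(model.reactions["PDC"].gpr.genes()) | set(
    model.reactions["ADH"].gpr.genes())
entries = {}
for g in model.genes:
    if g in regulated_up:
        entries[g] = (0.01, "up")
    elif g in regulated_down:
        entries[g] = (0.01, "down")
    else:
        entries[g] = (0.5, "none")
scored = score_against_genes(report, ExpressionTable(entries), model)
print(f"consistency vs regulated genes: TP={scored.tp} FP={scored.fp} "
      f"TN={scored.tn} FN={scored.fn}; accuracy={scored.accuracy:.2f}, "
      f"F1={scored.f1:.2f}" if scored.f1 is not None else "F1 not applicable")

(BASE / "transcriptome_report.json").write_text(json.dumps({
    "top_reporter": top.metabolite,
    "top_reporter_z": float(top.z_corrected),
    "pdc_call": pdc_call[0],
    "adh_call": adh_call[0],
    "n_significant": len(report.significant()),
    "confusion": {"tp": scored.tp, "fp": scored.fp, "tn": scored.tn,
                  "fn": scored.fn},
    "accuracy": scored.accuracy,
    "f1": scored.f1,
    "up_consistency": scored.up_consistency,
    "down_consistency": scored.down_consistency,
}, indent=2))
print(f"wrote {BASE / 'transcriptome_report.json'}")
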