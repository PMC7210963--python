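"""Elemental compositions of the small molecules used by the synthetic models.

Real neutral-species formulas, so that elemental balance checking on the
synthetic networks is meaningful; the single pseudo-element ``X`` is the
escape hatch for abstract branch metabolites.
"""

FORMULAS: dict[str, str] = {
    "glc": "C6H12O6",       # D-glucose
    "fru": "C6H12O6",       # D-fructose
    "hex": "C6H12O6",       # hexose-phosphate pool surrogate (isomer lump)
    "glcn": "C6H12O7",      # D-gluconate (acid form)
    "sorb": "C6H14O6",      # D-sorbitol
    "sucr": "C12H22O11",    # sucrose
    "lev": "C6H10O5",       # levan, per anhydrofructose unit
    "cel": "C6H10O5",       # cellulose, per anhydroglucose unit
    "xyl": "C5H10O5",       # D-xylose
    "xlu": "C5H10O5",       # D-xylulose
    "arab": "C5H10O5",      # L-arabinose
    "rbl": "C5H10O5",       # L-ribulose
    "pyr": "C3H4O3",        # pyruvate (acid form)
    "acald": "C2H4O",       # acetaldehyde
    "etoh": "C2H6O",        # ethanol
    "lac": "C3H6O3",        # lactate (acid form)
    "succ": "C4H6O4",       # succinate (acid form)
    "actn": "C4H8O2",       # acetoin
    "btd": "C4H10O2",       # 2,3-butanediol
    "ala": "C3H7NO2",       # L-alanine
    "glu": "C5H9NO4",       # L-glutamate (yeast-extract amino-acid surrogate)
    "caro": "C40H56",       # beta-carotene
    "nh3": "H3N",
    "co2": "CO2",
    "o2": "O2",
    "h2o": "H2O",
    "h": "H",
    "pi": "H3O4P",          # phosphate (acid form)
    "nad": "C21H27N7O14P2",
    "nadh": "C21H28N7O14P2",
    "atp": "C10H16N5O13P3",
    "adp": "C10H15N5O10P2",
    "x": "X",
}
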