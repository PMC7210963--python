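# Methods

`zmgem` implements the computational pipeline used to build and validate a
genome-scale metabolic model (GEM) of *Zymomonas mobilis* ZM4: legacy-model
reconciliation, gap analysis with mixed-integer gap filling, the full
constraint-based simulation repertoire (FBA, FVA, gene knockout,
heterologous knock-in, substrate screening, biomass variants), and two
routes of transcriptome integration (reporter metabolites and flux-space
sampling consistency).  Because the deposited curated model is consumed as
data rather than regenerated, every stage is exercised end to end on a
synthetic *Z. mobilis*-like network with analytically known optima.

## The constraint-based core

All simulations solve linear programs over steady-state flux vectors
`v` (mmol gDCW⁻¹ h⁻¹):

    optimize c·v   s.t.   S·v = 0,   lb ≤ v ≤ ub

with HiGHS (via `scipy.optimize.linprog`).  Solutions are audited after
every solve — `|S·v| ≤ 1e-6` componentwise and box bounds within `1e-7` —
so solver output is never trusted silently.  FVA re-solves min and max per
reaction, optionally with `c·v ≥ f·optimum` added as a row (with a `1e-9`
absolute slack so the constrained problem stays numerically feasible at
`f = 1`).

Conventions: exactly two compartments (cytoplasm `_c`, extracellular
`_e`); exchange reactions touch one extracellular metabolite and negative
flux is uptake; flux bounds default to ±1000 (reversible) or 0..1000
(irreversible); the biomass reaction's flux is the specific growth rate in
h⁻¹.

Media are exchange-bound patterns, not g/L recipes.  Applying a medium
closes every exchange's uptake, then opens carbon sources at
`-carbon_uptake` (default 10), amino-acid exchanges at `-0.1` (a
yeast-extract allowance, read as an uptake bound — a literal positive
lower bound would force secretion), oxygen at −1000/0 for
aerobic/anaerobic, and freely diffusing species (CO₂, water, protons) in
both directions; explicit overrides win.  ATP maintenance is a model
reaction (`ATPM`) whose bounds a medium may re-set via `atp_settings`.

## GPR rules, knockouts and knock-ins

GPRs are boolean trees (AND = complex, OR = isozymes); an empty rule marks
an orphan reaction that no deletion can disable.  Gene deletion evaluates
each rule with the deleted set false and pins disabled reactions to zero
before solving.  Knock-in adds pathway reactions after two checks:
duplicate detection against the canonical stoichiometric key of every
existing reaction, and elemental balance of the additions (overridable).

Shipped knock-in presets target the synthetic namespace and use lumped but
mass-balanced stoichiometry: xylose and arabinose isomerases feed a
pentose-assimilation lump with the classic non-oxidative
pentose-phosphate yield (3 pentoses → 2 hexoses + 1 pyruvate equivalent,
1 ATP), alanine dehydrogenase aminates pyruvate, butanediol dehydrogenase
reduces native acetoin, and a carotenoid lump condenses 16 pyruvate into
β-carotene (C40) at a cost of 28 NADH.

## Reconciliation

Legacy reconstructions are unified in three steps.  (1) Curated id maps
rename each source into one canonical namespace; metabolites that collide
onto one canonical id have their stoichiometric rows merged, and net-zero
self-cancellations are dropped with a warning.  (2) Duplicates are
detected by a canonical stoichiometric key: coefficients (exact rationals)
are divided by the magnitude of the lexicographically smallest metabolite's
coefficient and sign-flipped so that metabolite is a substrate — two
reactions share a key iff they differ only by positive rescaling or
direction reversal.  (3) The merge keeps one reaction per key (first
source's id and orientation), OR-combines GPRs with syntactic
simplification only (idempotence and absorption on the DNF; no semantic
proof), and resolves reversibility conflicts by policy: a user-supplied
reversibility table (the default, mirroring curation against reaction
databases), widest bounds (also the table's fallback), or first source.
Every conflict is logged with its resolution; shared/unique counts satisfy
`shared + unique = per-source count after within-source dedup` and are
order-insensitive.

## Gap analysis

A metabolite is *no-production* (resp. *no-consumption*) if a temporary
drain (supply) on it supports maximal flux < 1e-6 at steady state; a
reaction is *blocked* if its FVA span is exactly zero.  Without an
explicit medium the structural question is asked with every exchange open
in both directions.  Two consequences of the probe definition are worth
stating: conserved internal pools (NAD⁺/NADH, ATP/ADP, phosphate) can
never carry net drain flux and therefore always appear as dead ends, so
planted-gap recovery is always measured against the intact-model
baseline; and thermodynamically infeasible internal loops are *not*
excluded (no loopless constraint), so an isolated reversible cycle counts
as unblocked.

Gap filling is a MILP: one binary indicator per candidate from the
universal set, minimizing total weight (default 1 per reaction; a weight
column can encode biological preference) subject to steady state, medium
bounds and a target flux ≥ ε (default 1e-6).  Numerics: inside the MILP
the candidate big-M bounds are clamped to ±100 and the target is enforced
at ≥ 1e-3, because the solver's feasibility tolerance (1e-6) times a
±1000 big-M could otherwise let a candidate "leak" enough flux to fake a
repair; the selected set is then re-verified by a plain LP at the true ε.
Ties among equal-weight optima are broken deterministically toward the
lexicographically smallest reaction-id set by greedy inclusion in
ascending id order (force a candidate in; keep it iff the optimal weight
is unchanged).  Minimality is verified in the tests by exhaustive subset
enumeration for all planted repairs of cardinality ≤ 3.

## Transcriptome integration

**Reporter metabolites.**  Gene p-values are inverse-normal transformed,
`Z_g = Φ⁻¹(1 − p)` (p clamped to [1e-300, 1 − 1e-16]; p = 0 warns).  A
metabolite with k neighbor genes — the union of genes over the GPRs of
reactions touching it — scores `Z_raw = Σ Z_g / √k`, standardized against
the mean and standard deviation of the same statistic over 10⁴ random
size-k gene draws (with replacement, seeded), so hubs are not rewarded
for degree.  Metabolites with no scored neighbor gene are omitted;
expression entries for genes absent from the model are counted and
ignored.

**Flux sampling.**  The feasible set is sampled by hit-and-run.  A
preparatory all-reaction FVA yields (a) an interior-leaning start point
(mean of the vertex solutions) and (b) the set of numerically fixed
coordinates (span < 1e-9), whose unit rows are appended to S before the
null-space computation — the walk then lives in the polytope's affine
hull, so no step is wasted on blocked directions.  Directions are
isotropic in null-space coordinates: axis-aligned basis directions mixed
too slowly on realistic media (the null-calibration rate left the
expected α band), and the isotropic variant restored calibration without
touching the walk's other parameters.  Defaults: warm-up 1000 steps,
thinning 100; every stored sample is audited against `S·v = 0` (1e-6) and
the bounds; a (seed, n) pair is bit-reproducible.

**Condition comparison and scoring.**  Per reaction, a two-sided
Mann-Whitney U test (normal approximation) compares the two sample sets;
the direction is the sign of the median difference, a minimum
median-shift filter (1e-6) suppresses numerically identical
"significant" calls, and raw p < 0.05 is called significant (no
multiple-testing correction by default; Benjamini-Hochberg behind a
flag).  Gene-level confusion scoring assigns each expressed model gene
the majority direction of the significant calls among its GPR-associated
reactions (tie → unchanged): match = TP, regulated-but-missed = FN,
unregulated-but-called = FP, quiet = TN; accuracy = (TP+TN)/total and
F1 = 2TP/(2TP+FP+FN), reported as not-applicable (never 0) when the
denominator vanishes.  Both gene-level (default) and the per-call
consistency fractions for up- and down-lists are computed.  Because
finite chains are autocorrelated and reactions share flux modes, the
null significant-call rate fluctuates around α across seed pairs rather
than sitting exactly on it; the test suite asserts the
`α ± 3·√(α(1−α)/R)` band.

## The synthetic study system

The generator builds a small mass-balanced network with the metabolic
signature of *Z. mobilis*: glucose enters by facilitated diffusion, an
Entner-Doudoroff lump yields 2 pyruvate + 2 NADH + **1 ATP** per hexose
(the organism's famously low energy yield), pyruvate decarboxylase and
alcohol dehydrogenase form the redox-neutral ethanol sink (2 ethanol per
glucose), lactate dehydrogenase and a redox-neutral acetoin lump are
overflow routes, a reductive succinate lump consumes 2 NADH + ½ ATP and
fixes CO₂, an NADH oxidase vents surplus redox aerobically, extracellular
levansucrase splits sucrose into levan units plus glucose, and a
cellulose-synthase route supports a cellulose-containing biomass variant.
Biomass drains ½ hexose + ½ pyruvate + 5 ATP and releases 0.2 NADH per
unit flux — the small anabolic redox surplus that, anaerobically, only
the succinate branch can absorb.  Metabolite formulas are real neutral
species (glucose C₆H₁₂O₆ …, one abstract `X` element for branch
metabolites), and every reaction is auto-completed with water/protons so
the whole network passes elemental balance with exactly the planted
number of failures.

These stoichiometric choices make the validation arithmetic exact.  With
glucose uptake 10: max ethanol = 20; anaerobic growth = 200/117 ≈ 1.709
h⁻¹ with succinate export pinned at 140/117 ≈ 1.197 at the optimum;
deleting *pdc* + *ldh* removes the ethanol/lactate routes, drops growth
to 50/53 ≈ 0.943 h⁻¹ and forces succinate to 510/53 ≈ 9.623 — the strict
flux redirection to succinate that the knockout analysis must show.
Xylose (after knock-in) yields 5/3 ethanol per pentose, so
ethanol(mixed) > ethanol(glucose) > ethanol(xylose).  On the sucrose
medium all growth carbon passes through levansucrase, whose FVA range at
the growth optimum collapses to the point {5} (the sucrose uptake bound).

Planted defects carry exact ground truth: removing a branch isomerase
creates one no-production and one no-consumption metabolite and blocks
the rest of that branch; an extra proton on a branch entry is a single-H
elemental error; the legacy pair renames three metabolites, flips two
reaction directions and adds four private reactions per variant, with the
id maps and merge counts recorded.  Expression tables plant p = 1e-4 on
one metabolite's neighbor genes against a Uniform(0, 1] background.

What the toy does **not** emulate: genome-scale size (≈50 reactions vs
hundreds), realistic GPR complexity, charged metabolite species, membrane
energetics/proton-motive force, kinetic regulation, or the noisy
incomplete annotations of real reconstructions.  Passing tests therefore
demonstrate algorithmic correctness on exactly specified inputs, not
curation quality on real data.

## Problem sizes and numerical defaults

The shipped analyses and the acceptance script use the toy network
(~49 reactions), 20-seed recovery batteries, 50-seed reporter batteries
(background 2000), and 200-sample chains; the full test suite adds
100-seed batteries and a 5000-sample uniformity check on a
one-dimensional polytope.  Key tolerances: steady-state audit 1e-6;
blocking/feasibility ε 1e-6; MILP feasibility 1e-9 (relative gap 0);
FVA-fixed coordinate detection 1e-9; reporter background 10⁴ draws;
growth-call threshold 1e-3 h⁻¹ for substrate screens.

## Known limitations

* FVA and blocking ignore thermodynamic loop constraints.
* Degenerate LP optima mean flux *vectors* are not reproducible across
  solver versions; objective values and FVA ranges are.
* The gap-fill MILP's internal target floor (1e-3) means a repair that can
  only ever carry between 1e-6 and 1e-3 flux units would be missed; no
  such regime occurs in the shipped fixtures.
* Gene-level confusion counting treats a direction mismatch (up gene,
  decreased flux) as a miss (FN), not a double error.
* The tabular dialect stores bounds in full float repr; third-party table
  exports with lossy rounding will not round-trip bit-identically.
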