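"""Reconciliation of legacy models: id normalization, dedup, merging.

Legacy reconstructions of the same organism disagree on identifiers,
reaction direction and gene associations.  Unification proceeds in three
steps: (1) rename every entity into one canonical namespace via curated id
maps; (2) detect duplicate reactions by a canonical stoichiometric key that
is invariant to positive rescaling and direction reversal; (3) merge, with
explicit per-field conflict resolution and a full audit trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .gpr import GPR, gpr_or
from .model import Model, ModelIntegrityError, Reaction


def canonical_key(reaction: Reaction) -> tuple:
    """Stoichiometric key, equal iff stoichiometries match up to a positive
    scale factor and/or an overall direction flip.

    Normalization: divide by |coefficient| of the lexicographically smallest
    metabolite id, then flip signs so that this metabolite is a substrate.
    Rational arithmetic keeps keys exact under rescaling.
    """
    items = sorted(
        (m, Fraction(c).limit_denominator(10**9))
        for m, c in reaction.stoichiometry.items()
        if c != 0
    )
    if not items:
        raise ValueError(f"reaction {reaction.id}: empty stoichiometry")
    anchor = items[0][1]
    scale = abs(anchor)
    sign = -1 if anchor > 0 else 1
    return tuple((m, c / scale * sign) for m, c in items)


def _relative_orientation(base: Reaction, other: Reaction) -> Fraction:
    """Factor s with stoich(other) = s * stoich(base); sign tracks direction."""
    anchor = min(base.stoichiometry)
    return Fraction(other.stoichiometry[anchor]).limit_denominator(10**9) / Fraction(
        base.stoichiometry[anchor]
    ).limit_denominator(10**9)


# ---------------------------------------------------------------------------
# id maps


@dataclass
class IdMap:
    """Local-to-canonical renaming for one source model."""

    source: str = ""
    metabolites: Dict[str, str] = field(default_factory=dict)
    reactions: Dict[str, str] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path, source: str = "") -> "IdMap":
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns)
        if len(cols) < 2:
            raise ValueError(f"{path}: id map needs (local_id, canonical_id)")
        mets = dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))
        return cls(source=source or Path(path).stem, metabolites=mets)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"local_id": list(self.metabolites),
             "canonical_id": list(self.metabolites.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class IdMapReport:
    collisions: List[Tuple[str, List[str]]] = field(default_factory=list)
    passed_through: List[str] = field(default_factory=list)
    self_cancellations: List[str] = field(default_factory=list)


def apply_id_map(model: Model, idmap: IdMap) -> tuple[Model, IdMapReport]:
    """Rename into the canonical namespace; merge metabolites that collide.

    Ids absent from the map pass through unchanged and are flagged.  When
    two local metabolites map onto one canonical id, their stoichiometric
    rows merge (coefficients summed); a resulting net-zero coefficient is a
    self-cancellation, logged with a warning.
    """
    report = IdMapReport()
    new = model.copy()
    target_of: Dict[str, str] = {}
    for mid in list(new.metabolites):
        target_of[mid] = idmap.metabolites.get(mid, mid)
        if mid not in idmap.metabolites:
            report.passed_through.append(mid)
    by_target: Dict[str, List[str]] = {}
    for local, target in target_of.items():
        by_target.setdefault(target, []).append(local)
    merged_mets = {}
    for target, locals_ in by_target.items():
        if len(locals_) > 1:
            report.collisions.append((target, sorted(locals_)))
        keep = new.metabolites[locals_[0]]
        keep.id = target
        merged_mets[target] = keep
    new.metabolites = merged_mets
    for rxn in new.reactions.values():
        stoich: Dict[str, Fraction] = {}
        for mid, coef in rxn.stoichiometry.items():
            tgt = target_of[mid]
            stoich[tgt] = stoich.get(tgt, Fraction(0)) + Fraction(coef).limit_denominator(10**9)
        zeros = [m for m, c in stoich.items() if c == 0]
        for m in zeros:
            warnings.warn(
                f"reaction {rxn.id}: substrate/product merged to {m} with net "
                "zero coefficient (self-cancellation); term dropped",
                stacklevel=2,
            )
            report.self_cancellations.append(rxn.id)
            del stoich[m]
        rxn.stoichiometry = stoich
    for old_id, new_id in idmap.reactions.items():
        if old_id in new.reactions:
            rxn = new.reactions.pop(old_id)
            rxn.id = new_id
            new.reactions[new_id] = rxn
            if new.objective_id == old_id:
                new.objective_id = new_id
    new.validate()
    return new, report


# ---------------------------------------------------------------------------
# merging


@dataclass
class Conflict:
    reaction: str
    field: str
    values: Dict[str, object]  # source id -> value
    resolution: object


@dataclass
class MergeReport:
    shared_reactions: List[str] = field(default_factory=list)
    unique_reactions: Dict[str, List[str]] = field(default_factory=dict)
    shared_genes: List[str] = field(default_factory=list)
    unique_genes: Dict[str, List[str]] = field(default_factory=dict)
    shared_ecs: List[str] = field(default_factory=list)
    unique_ecs: Dict[str, List[str]] = field(default_factory=dict)
    conflicts: List[Conflict] = field(default_factory=list)
    dedup_counts: Dict[str, int] = field(default_factory=dict)  # per-source, post-dedup

    @property
    def n_shared(self) -> int:
        return len(self.shared_reactions)

    def n_unique(self, source: str) -> int:
        return len(self.unique_reactions.get(source, []))


POLICIES = ("widest-bounds", "reference-db", "first-source")


def _resolve_bounds(
    rid: str,
    per_source: Dict[str, Tuple[float, float]],
    policy: str,
    reversibility: Optional[Dict[str, str]],
) -> tuple[Tuple[float, float], Optional[Conflict]]:
    values = list(per_source.values())
    if all(v == values[0] for v in values[1:]):
        return values[0], None
    if policy == "first-source":
        resolved = values[0]
    elif policy == "reference-db" and reversibility and rid in reversibility:
        kind = reversibility[rid]
        resolved = {
            "reversible": (-1000.0, 1000.0),
            "forward": (0.0, 1000.0),
            "reverse": (-1000.0, 0.0),
        }[kind]
    else:  # widest-bounds, also the reference-db fallback
        resolved = (min(v[0] for v in values), max(v[1] for v in values))
    conflict = Conflict(rid, "bounds", dict(per_source), resolved)
    return resolved, conflict


def merge_models(
    models: Sequence[Model],
    policy: str = "reference-db",
    reversibility: Optional[Dict[str, str]] = None,
    merged_id: str = "merged",
) -> tuple[Model, MergeReport]:
    """Union of canonical-id models with one reaction per stoichiometric key.

    Duplicates across sources keep the first source's id and orientation;
    their GPRs are OR-combined and syntactically simplified; reversibility
    disagreements are resolved per ``policy``.  Within-source duplicates are
    deduplicated first so the shared/unique counts add up per source.
    """
    if len(models) < 2:
        raise ValueError("merge requires at least two models")
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    comps = None
    for m in models:
        if comps is None:
            comps = set(m.compartments)
        elif set(m.compartments) != comps:
            raise ModelIntegrityError(
                "models declare different compartment sets; cannot merge"
            )
    report = MergeReport()
    # per-source dedup by canonical key
    deduped: Dict[str, Dict[tuple, Reaction]] = {}
    for m in models:
        keyed: Dict[tuple, Reaction] = {}
        for rxn in m.reactions.values():
            key = canonical_key(rxn)
            if key in keyed:
                warnings.warn(
                    f"model {m.id}: reactions {keyed[key].id} and {rxn.id} are "
                    "stoichiometric duplicates; second dropped",
                    stacklevel=2,
                )
                continue
            keyed[key] = rxn
        deduped[m.id] = keyed
        report.dedup_counts[m.id] = len(keyed)

    merged = Model(id=merged_id, compartments=dict(models[0].compartments))
    for m in models:
        for met in m.metabolites.values():
            if met.id not in merged.metabolites:
                merged.add_metabolite(met.__class__(**vars(met)))
    all_keys: Dict[tuple, List[str]] = {}
    for m in models:
        for key in deduped[m.id]:
            all_keys.setdefault(key, []).append(m.id)

    for key, sources in all_keys.items():
        base = deduped[sources[0]][key]
        duplicates = [(src, deduped[src][key]) for src in sources]
        per_source_bounds: Dict[str, Tuple[float, float]] = {}
        gprs: List[GPR] = []
        ecs: List[str] = []
        for src, rxn in duplicates:
            s = _relative_orientation(base, rxn)
            lo, hi = sorted((float(rxn.lower_bound / s), float(rxn.upper_bound / s)))
            per_source_bounds[src] = (lo, hi)
            gprs.append(rxn.gpr)
            ecs.extend(rxn.ec_numbers)
        bounds, conflict = _resolve_bounds(
            base.id, per_source_bounds, policy, reversibility
        )
        if conflict:
            report.conflicts.append(conflict)
        combined_gpr = gpr_or(gprs)
        distinct = {g.to_dnf() for g in gprs if not g.is_empty}
        if len(distinct) > 1:
            report.conflicts.append(
                Conflict(base.id, "gpr",
                         {src: r.gpr.to_string() for src, r in duplicates},
                         combined_gpr.to_string())
            )
        merged.add_reaction(
            Reaction(
                id=base.id,
                name=base.name,
                stoichiometry=dict(base.stoichiometry),
                lower_bound=bounds[0],
                upper_bound=bounds[1],
                gpr=combined_gpr,
                subsystem=base.subsystem,
                ec_numbers=sorted(set(ecs)),
            )
        )
        if len(sources) == len(models):
            report.shared_reactions.append(base.id)
        else:
            for src in sources:
                report.unique_reactions.setdefault(src, []).append(
                    deduped[src][key].id
                )
    for m in models:
        report.unique_reactions.setdefault(m.id, [])

    # genes and enzymes (EC numbers)
    gene_sets = {m.id: set(m.genes) for m in models}
    ec_sets = {
        m.id: {e for r in m.reactions.values() for e in r.ec_numbers}
        for m in models
    }
    report.shared_genes = sorted(set.intersection(*gene_sets.values()))
    report.unique_genes = {
        mid: sorted(genes - set.union(*(g for k, g in gene_sets.items() if k != mid)))
        for mid, genes in gene_sets.items()
    }
    report.shared_ecs = sorted(set.intersection(*ec_sets.values()))
    report.unique_ecs = {
        mid: sorted(ecs - set.union(*(e for k, e in ec_sets.items() if k != mid)))
        for mid, ecs in ec_sets.items()
    }
    objective = next((m.objective_id for m in models if m.objective_id), None)
    if objective and objective in merged.reactions:
        merged.objective_id = objective
    merged.validate()
    return merged, report
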