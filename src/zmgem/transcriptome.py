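"""Transcriptome integration: reporter metabolites and flux-sample scoring.

Two complementary routes link gene-level differential expression to a
metabolic network:

* *Reporter metabolites* — each metabolite is scored by the aggregated
  significance of its neighboring enzymes' transcripts.  Gene p-values are
  inverse-normal transformed (Z_g = Phi^-1(1 - p)); a metabolite with k
  neighbor genes gets Z_raw = sum(Z_g)/sqrt(k), corrected against the mean
  and standard deviation of size-k random gene sets, so a hub metabolite is
  not rewarded for degree alone.

* *Flux-space sampling consistency* — per-reaction flux distributions under
  two conditions are compared with a rank test, and the significant
  increased/decreased calls are scored against the up-/down-regulated gene
  lists through the GPR mapping, yielding a confusion matrix with accuracy
  and F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import Model

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass
class ExpressionTable:
    """Gene-level differential-expression input: locus_tag -> (p, direction)."""

    entries: Dict[str, Tuple[float, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tag, (p, direction) in self.entries.items():
            if not 0.0 < p <= 1.0:
                if p == 0.0:
                    warnings.warn(
                        f"gene {tag}: p=0 clamped to {_P_FLOOR} "
                        "(inverse-normal transform diverges)",
                        stacklevel=2,
                    )
                    self.entries[tag] = (_P_FLOOR, direction)
                else:
                    raise ValueError(f"gene {tag}: p-value {p} outside (0, 1]")
            if direction not in ("up", "down", "none"):
                raise ValueError(f"gene {tag}: direction {direction!r}")

    def p_values(self) -> Dict[str, float]:
        return {g: p for g, (p, _) in self.entries.items()}

    def regulated(self, direction: str) -> List[str]:
        return [g for g, (_, d) in self.entries.items() if d == direction]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        required = {"locus_tag", "p_value"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        direction = df["direction"] if "direction" in df.columns else "none"
        entries = {
            str(row.locus_tag): (
                float(row.p_value),
                str(getattr(row, "direction", "none") or "none"),
            )
            for row in df.itertuples()
        }
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"locus_tag": g, "p_value": p, "direction": d}
            for g, (p, d) in self.entries.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reporter metabolites


@dataclass
class ReporterScore:
    """Per-metabolite aggregated transcriptional-change scores."""

    scores: Dict[str, Tuple[int, float, float, float]]  # k, Z_raw, Z_corr, p
    n_ignored_genes: int = 0

    def ranked(self) -> List[str]:
        """Metabolite ids by decreasing corrected Z."""
        return sorted(self.scores, key=lambda m: -self.scores[m][2])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"metabolite": m, "k": k, "z_raw": zr, "z_corrected": zc,
                 "p_reporter": p}
                for m, (k, zr, zc, p) in self.scores.items()
            ]
        ).sort_values("z_corrected", ascending=False, ignore_index=True)


def metabolite_neighbor_genes(model: Model) -> Dict[str, frozenset]:
    """Neighbor genes of each metabolite: union over GPRs of touching reactions."""
    out: Dict[str, set] = {m: set() for m in model.metabolites}
    for rxn in model.reactions.values():
        genes = rxn.gpr.genes()
        if not genes:
            continue
        for met in rxn.stoichiometry:
            out[met] |= genes
    return {m: frozenset(g) for m, g in out.items()}


def reporter_metabolites(
    model: Model,
    expr: ExpressionTable,
    n_background: int = 10_000,
    seed: int = 0,
) -> ReporterScore:
    """Score metabolites by coordinated transcriptional change of neighbors.

    Background correction: for every occurring neighborhood size k, the mean
    and standard deviation of sum(Z)/sqrt(k) over ``n_background`` random
    size-k gene draws (with replacement, fixed seed) standardize the raw
    score.  Metabolites with no scored neighbor gene are omitted.
    """
    pvals = expr.p_values()
    scored_genes = [g for g in model.genes if g in pvals]
    n_ignored = len([g for g in pvals if g not in model.genes])
    if not scored_genes:
        raise ValueError("no model gene has a p-value")
    z_by_gene = {
        g: float(stats.norm.ppf(1.0 - min(max(pvals[g], _P_FLOOR), _P_CEIL)))
        for g in scored_genes
    }
    z_pool = np.array([z_by_gene[g] for g in scored_genes])
    neighbors = metabolite_neighbor_genes(model)
    raw: Dict[str, Tuple[int, float]] = {}
    for met, genes in neighbors.items():
        used = [g for g in genes if g in z_by_gene]
        if not used:
            continue
        k = len(used)
        raw[met] = (k, float(sum(z_by_gene[g] for g in used) / np.sqrt(k)))
    rng = np.random.default_rng(seed)
    background: Dict[int, Tuple[float, float]] = {}
    for k in sorted({k for k, _ in raw.values()}):
        draws = rng.choice(z_pool, size=(n_background, k), replace=True)
        agg = draws.sum(axis=1) / np.sqrt(k)
        background[k] = (float(agg.mean()), float(agg.std(ddof=0)) or 1.0)
    scores: Dict[str, Tuple[int, float, float, float]] = {}
    for met, (k, z_raw) in raw.items():
        mu_k, sigma_k = background[k]
        z_corr = (z_raw - mu_k) / sigma_k
        scores[met] = (k, z_raw, z_corr, float(stats.norm.sf(z_corr)))
    return ReporterScore(scores, n_ignored)


# ---------------------------------------------------------------------------
# condition comparison and confusion scoring


@dataclass
class ConsistencyReport:
    """Per-reaction differential-flux decisions plus gene-list confusion."""

    decisions: Dict[str, Tuple[str, float]]  # id -> (increased/decreased/unchanged, p)
    alpha: float = 0.05
    tp: Optional[int] = None
    fp: Optional[int] = None
    tn: Optional[int] = None
    fn: Optional[int] = None
    accuracy: Optional[float] = None
    f1: Optional[float] = None
    up_consistency: Optional[float] = None
    down_consistency: Optional[float] = None
    n_unmapped_genes: int = 0

    def significant(self, direction: Optional[str] = None) -> List[str]:
        return [
            r
            for r, (d, _) in self.decisions.items()
            if d != "unchanged" and (direction is None or d == direction)
        ]


def confusion_metrics(
    tp: int, fp: int, tn: int, fn: int
) -> Tuple[Optional[float], Optional[float]]:
    """(accuracy, F1) from confusion counts; None where undefined."""
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else None
    denom = 2 * tp + fp + fn
    f1 = (2 * tp) / denom if denom else None
    return accuracy, f1


def compare_conditions(
    a: "SampleSet",
    b: "SampleSet",
    alpha: float = 0.05,
    min_effect: float = 1e-6,
    correction: Optional[str] = None,
) -> ConsistencyReport:
    """Per-reaction two-sample rank test between two flux sample sets.

    Direction comes from the median difference (b relative to a); calls with
    a median shift below ``min_effect`` are "unchanged" regardless of the
    p-value, suppressing numerically identical distributions.  Optional
    ``correction="bh"`` applies Benjamini-Hochberg to the p-values.
    """
    from .sampling import SampleSet  # noqa: F401  (typing only)

    if list(a.reaction_ids) != list(b.reaction_ids):
        raise ValueError("sample sets cover different reaction universes")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    raw: Dict[str, Tuple[float, float]] = {}
    for j, rid in enumerate(a.reaction_ids):
        xa = a.samples[:, j]
        xb = b.samples[:, j]
        shift = float(np.median(xb) - np.median(xa))
        if np.ptp(xa) < 1e-12 and np.ptp(xb) < 1e-12:
            p = 1.0  # degenerate constant distributions
        else:
            p = float(
                stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                   method="asymptotic").pvalue
            )
        raw[rid] = (shift, p)
    pvals = np.array([p for _, p in raw.values()])
    if correction == "bh":
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.empty_like(pvals)
        adjusted[order] = np.minimum(adj, 1.0)
        pvals = adjusted
    decisions: Dict[str, Tuple[str, float]] = {}
    for (rid, (shift, _)), p in zip(raw.items(), pvals):
        if p < alpha and abs(shift) >= min_effect:
            decisions[rid] = ("increased" if shift > 0 else "decreased", float(p))
        else:
            decisions[rid] = ("unchanged", float(p))
    return ConsistencyReport(decisions, alpha=alpha)


def score_against_genes(
    report: ConsistencyReport,
    expr: ExpressionTable,
    model: Model,
) -> ConsistencyReport:
    """Fill the confusion part: sampled flux calls vs regulated gene lists.

    Gene-level counting: each expressed model gene is assigned the majority
    direction of the significant calls among its GPR-associated reactions
    (tie or none -> unchanged), then scored against its annotated direction:
    match = TP, regulated-but-missed = FN, unregulated-but-called = FP,
    unregulated-and-quiet = TN.
    """
    gene_to_rxns: Dict[str, List[str]] = {}
    for rxn in model.reactions.values():
        for g in rxn.gpr.genes():
            gene_to_rxns.setdefault(g, []).append(rxn.id)
    tp = fp = tn = fn = 0
    unmapped = 0
    pred_up_genes: List[bool] = []
    pred_down_genes: List[bool] = []
    for gene, (_, direction) in expr.entries.items():
        rxns = [r for r in gene_to_rxns.get(gene, []) if r in report.decisions]
        if not rxns:
            unmapped += 1
            continue
        n_inc = sum(1 for r in rxns if report.decisions[r][0] == "increased")
        n_dec = sum(1 for r in rxns if report.decisions[r][0] == "decreased")
        if n_inc > n_dec:
            predicted = "up"
        elif n_dec > n_inc:
            predicted = "down"
        else:
            predicted = "none"
        if direction in ("up", "down"):
            if predicted == direction:
                tp += 1
            else:
                fn += 1
        else:
            if predicted == "none":
                tn += 1
            else:
                fp += 1
        if predicted == "up":
            pred_up_genes.append(direction == "up")
        elif predicted == "down":
            pred_down_genes.append(direction == "down")
    accuracy, f1 = confusion_metrics(tp, fp, tn, fn)
    report.tp, report.fp, report.tn, report.fn = tp, fp, tn, fn
    report.accuracy, report.f1 = accuracy, f1
    report.up_consistency = (
        sum(pred_up_genes) / len(pred_up_genes) if pred_up_genes else None
    )
    report.down_consistency = (
        sum(pred_down_genes) / len(pred_down_genes) if pred_down_genes else None
    )
    report.n_unmapped_genes = unmapped
    return report
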