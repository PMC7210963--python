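"""Gene-protein-reaction (GPR) boolean rules.

A GPR links gene presence to reaction activity: AND nodes model enzyme
complexes (every subunit required), OR nodes model isozymes (any one
suffices).  An empty rule marks an orphan (non-gene-associated) reaction,
which is never disabled by gene deletion.

Rules are parsed from the conventional string syntax, e.g.::

    ZMO1360
    (ZMO1596 or ZMO1236)
    (ZMO0152 and ZMO0369) or ZMO1719

Internally a rule is a tree of ``("and", children)`` / ``("or", children)``
tuples with gene locus tags at the leaves.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Tuple, Union

Node = Union[str, Tuple[str, tuple]]  # leaf locus tag, or (op, children)

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class GPRParseError(ValueError):
    """Raised when a GPR rule string is malformed."""


def _parse(tokens: list[str]) -> Node:
    def parse_or(pos: int) -> tuple[Node, int]:
        node, pos = parse_and(pos)
        parts = [node]
        while pos < len(tokens) and tokens[pos].lower() == "or":
            nxt, pos = parse_and(pos + 1)
            parts.append(nxt)
        if len(parts) == 1:
            return parts[0], pos
        return ("or", tuple(parts)), pos

    def parse_and(pos: int) -> tuple[Node, int]:
        node, pos = parse_atom(pos)
        parts = [node]
        while pos < len(tokens) and tokens[pos].lower() == "and":
            nxt, pos = parse_atom(pos + 1)
            parts.append(nxt)
        if len(parts) == 1:
            return parts[0], pos
        return ("and", tuple(parts)), pos

    def parse_atom(pos: int) -> tuple[Node, int]:
        if pos >= len(tokens):
            raise GPRParseError("unexpected end of GPR rule")
        tok = tokens[pos]
        if tok == "(":
            node, pos = parse_or(pos + 1)
            if pos >= len(tokens) or tokens[pos] != ")":
                raise GPRParseError("unbalanced parenthesis in GPR rule")
            return node, pos + 1
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR rule")
        return tok, pos + 1

    node, pos = parse_or(0)
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR rule: {tokens[pos:]}")
    return node


@dataclass(frozen=True)
class GPR:
    """A boolean gene requirement for one reaction; ``root is None`` = orphan."""

    root: Optional[Node] = None

    @classmethod
    def from_string(cls, rule: str | None) -> "GPR":
        if rule is None or not rule.strip():
            return cls(None)
        tokens = _TOKEN.findall(rule)
        return cls(_parse(tokens))

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> FrozenSet[str]:
        """All locus tags referenced by the rule."""
        out: set[str] = set()

        def walk(node: Node) -> None:
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        if self.root is not None:
            walk(self.root)
        return frozenset(out)

    def evaluate(self, deleted: Iterable[str]) -> bool:
        """True iff the reaction stays active with ``deleted`` genes removed.

        Orphan rules always evaluate active: a reaction with no known gene
        cannot be switched off by a gene deletion.
        """
        if self.root is None:
            return True
        dele = set(deleted)

        def walk(node: Node) -> bool:
            if isinstance(node, str):
                return node not in dele
            op, children = node
            if op == "and":
                return all(walk(c) for c in children)
            return any(walk(c) for c in children)

        return walk(self.root)

    def to_string(self) -> str:
        if self.root is None:
            return ""

        def walk(node: Node, parent_op: str | None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            inner = f" {op} ".join(walk(c, op) for c in children)
            if parent_op is not None and op != parent_op:
                return f"({inner})"
            return inner

        return walk(self.root, None)

    # --- normal form used by the merge simplifier -------------------------

    def to_dnf(self) -> FrozenSet[FrozenSet[str]]:
        """Disjunctive normal form: a set of minimal AND-clauses (gene sets)."""
        if self.root is None:
            return frozenset()

        def walk(node: Node) -> set[frozenset[str]]:
            if isinstance(node, str):
                return {frozenset([node])}
            op, children = node
            parts = [walk(c) for c in children]
            if op == "or":
                out: set[frozenset[str]] = set()
                for p in parts:
                    out |= p
                return out
            # and: cartesian product of clauses
            acc = parts[0]
            for p in parts[1:]:
                acc = {a | b for a in acc for b in p}
            return acc

        clauses = walk(self.root)
        # absorption: drop any clause that is a superset of another
        minimal = {c for c in clauses if not any(o < c for o in clauses)}
        return frozenset(minimal)

    @classmethod
    def from_dnf(cls, clauses: FrozenSet[FrozenSet[str]]) -> "GPR":
        if not clauses:
            return cls(None)
        ands: list[Node] = []
        for clause in sorted(clauses, key=lambda c: sorted(c)):
            genes = sorted(clause)
            ands.append(genes[0] if len(genes) == 1 else ("and", tuple(genes)))
        if len(ands) == 1:
            return cls(ands[0])
        return cls(("or", tuple(ands)))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def gpr_or(rules: Iterable[GPR]) -> GPR:
    """OR-combine rules and simplify syntactically (idempotence, absorption).

    Used when duplicate reactions from different source models are merged:
    either source's gene requirement suffices.  Simplification is purely
    syntactic on the DNF; no semantic equivalence proof is attempted.
    """
    clauses: set[frozenset[str]] = set()
    nonempty = False
    for rule in rules:
        if rule.is_empty:
            continue
        nonempty = True
        clauses |= rule.to_dnf()
    if not nonempty:
        return GPR(None)
    minimal = frozenset(c for c in clauses if not any(o < c for o in clauses))
    return GPR.from_dnf(minimal)
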