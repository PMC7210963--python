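"""Unified model reader/writer over the SBML and tabular dialects."""

from __future__ import annotations

from pathlib import Path

from .model import Model
from .sbml_io import read_sbml, write_sbml
from .table_io import read_table, write_table

DIALECTS = ("sbml", "table")


def _guess_dialect(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix in (".tsv", ".txt", ".tab"):
        return "table"
    raise ValueError(f"cannot guess model dialect from suffix {suffix!r}")


def read_model(path: str | Path, dialect: str | None = None) -> Model:
    dialect = dialect or _guess_dialect(path)
    if dialect == "sbml":
        return read_sbml(path)
    if dialect == "table":
        return read_table(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_model(model: Model, path: str | Path, dialect: str | None = None) -> None:
    dialect = dialect or _guess_dialect(path)
    if dialect == "sbml":
        write_sbml(model, path)
    elif dialect == "table":
        write_table(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
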