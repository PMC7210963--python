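"""Growth media as exchange-bound patterns.

A medium is not a g/L recipe: in constraint-based analysis it is the set of
boundary fluxes the cell may use.  Applying a medium first closes the uptake
direction (lower bound 0) of every exchange reaction, then re-opens:

* listed carbon sources at ``-carbon_uptake`` (default 10 mmol gDCW^-1 h^-1,
  the conventional carbon bound);
* amino-acid exchanges at ``-amino_acid_uptake`` (default 0.1, the yeast-
  extract allowance; interpreted as an uptake allowance, i.e. lb = -0.1);
* the oxygen exchange at -1000 (aerobic) or 0 (anaerobic);
* freely diffusing species (water, protons, CO2) in both directions;
* explicit per-exchange overrides last, so they always win.

Secretion (upper) bounds are left at the model's values unless overridden.
If the model has an ATP-maintenance reaction, ``atp_settings`` optionally
rebounds it (hydrolysis lb / synthesis ub pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .model import Model

DEFAULT_CARBON_UPTAKE = 10.0
DEFAULT_AA_UPTAKE = 0.1


class MediumError(ValueError):
    """A medium references exchanges absent from the model, or is inconsistent."""


@dataclass
class Medium:
    name: str = "medium"
    aerobic: bool = False
    carbon_uptake: float = DEFAULT_CARBON_UPTAKE
    amino_acid_uptake: float = DEFAULT_AA_UPTAKE
    carbon_exchanges: List[str] = field(default_factory=list)
    nitrogen_exchanges: List[str] = field(default_factory=list)
    sulfur_exchanges: List[str] = field(default_factory=list)
    amino_acid_exchanges: List[str] = field(default_factory=list)
    free_exchanges: List[str] = field(default_factory=list)
    oxygen_exchange: Optional[str] = None
    exchange_overrides: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    atp_maintenance: Optional[str] = None
    atp_settings: Optional[Tuple[float, float]] = None

    def with_(self, **kwargs) -> "Medium":
        """A modified copy (media are treated as immutable presets)."""
        new = replace(self)
        for key, val in kwargs.items():
            setattr(new, key, val)
        return new

    def apply(self, model: Model) -> Dict[str, Tuple[float, float]]:
        """Bound overrides (reaction id -> (lb, ub)) realizing this medium."""
        referenced = (
            set(self.carbon_exchanges)
            | set(self.nitrogen_exchanges)
            | set(self.sulfur_exchanges)
            | set(self.amino_acid_exchanges)
            | set(self.free_exchanges)
            | set(self.exchange_overrides)
            | ({self.oxygen_exchange} if self.oxygen_exchange else set())
        )
        missing = [r for r in referenced if r not in model.reactions]
        if missing:
            raise MediumError(
                f"medium {self.name!r} references absent exchanges: {sorted(missing)}"
            )
        bounds: Dict[str, Tuple[float, float]] = {}
        for rxn in model.exchanges():
            bounds[rxn.id] = (0.0, rxn.upper_bound)
        for rid in self.carbon_exchanges:
            bounds[rid] = (-abs(self.carbon_uptake), bounds.get(rid, (0, 1000))[1])
        for rid in self.nitrogen_exchanges + self.sulfur_exchanges:
            bounds[rid] = (-abs(self.carbon_uptake), bounds.get(rid, (0, 1000))[1])
        for rid in self.amino_acid_exchanges:
            bounds[rid] = (-abs(self.amino_acid_uptake), bounds.get(rid, (0, 1000))[1])
        for rid in self.free_exchanges:
            bounds[rid] = (-1000.0, 1000.0)
        if self.oxygen_exchange:
            ub = bounds.get(self.oxygen_exchange, (0, 1000))[1]
            bounds[self.oxygen_exchange] = (-1000.0 if self.aerobic else 0.0, ub)
        for rid, (lo, hi) in self.exchange_overrides.items():
            bounds[rid] = (float(lo), float(hi))
        if not self.aerobic and self.oxygen_exchange:
            lo, hi = bounds[self.oxygen_exchange]
            if lo < 0:
                raise MediumError(
                    f"medium {self.name!r}: anaerobic but O2 lower bound is {lo}"
                )
        if self.atp_maintenance and self.atp_settings:
            if self.atp_maintenance not in model.reactions:
                raise MediumError(
                    f"medium {self.name!r}: no reaction {self.atp_maintenance!r}"
                )
            hyd, syn = self.atp_settings
            bounds[self.atp_maintenance] = (float(hyd), float(syn))
        return bounds


def load_medium(path: str | Path) -> Medium:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise MediumError(f"{path}: medium YAML must be a mapping")
    overrides = {
        k: (float(v[0]), float(v[1]))
        for k, v in (data.get("exchange_overrides") or {}).items()
    }
    atp = data.get("atp_settings")
    return Medium(
        name=data.get("name", Path(path).stem),
        aerobic=bool(data.get("aerobic", False)),
        carbon_uptake=float(data.get("carbon_uptake", DEFAULT_CARBON_UPTAKE)),
        amino_acid_uptake=float(data.get("amino_acid_uptake", DEFAULT_AA_UPTAKE)),
        carbon_exchanges=list(data.get("carbon_exchanges") or []),
        nitrogen_exchanges=list(data.get("nitrogen_exchanges") or []),
        sulfur_exchanges=list(data.get("sulfur_exchanges") or []),
        amino_acid_exchanges=list(data.get("amino_acid_exchanges") or []),
        free_exchanges=list(data.get("free_exchanges") or []),
        oxygen_exchange=data.get("oxygen_exchange"),
        exchange_overrides=overrides,
        atp_maintenance=data.get("atp_maintenance"),
        atp_settings=tuple(atp) if atp else None,
    )


def save_medium(medium: Medium, path: str | Path) -> None:
    data = {
        "name": medium.name,
        "aerobic": medium.aerobic,
        "carbon_uptake": medium.carbon_uptake,
        "amino_acid_uptake": medium.amino_acid_uptake,
        "carbon_exchanges": list(medium.carbon_exchanges),
        "nitrogen_exchanges": list(medium.nitrogen_exchanges),
        "sulfur_exchanges": list(medium.sulfur_exchanges),
        "amino_acid_exchanges": list(medium.amino_acid_exchanges),
        "free_exchanges": list(medium.free_exchanges),
        "oxygen_exchange": medium.oxygen_exchange,
        "exchange_overrides": {
            k: [v[0], v[1]] for k, v in medium.exchange_overrides.items()
        },
        "atp_maintenance": medium.atp_maintenance,
        "atp_settings": list(medium.atp_settings) if medium.atp_settings else None,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
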