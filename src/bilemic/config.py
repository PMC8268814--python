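"""Declarative analysis configuration (YAML/JSON serializable)."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .counterion import PKA2_CARBONATE
from .exceptions import ValidationError
from .mass_action import WATER_MOLARITY_MM

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Unit conventions, solver policies and seeds for a full analysis run.

    The defaults reproduce the packaged reference analysis.
    """

    water_molarity_mm: float = WATER_MOLARITY_MM
    pKa2: float = PKA2_CARBONATE
    cmc_convention: str = "inflection"
    drop_first_injection: bool = False
    refine_itc_fit: bool = True
    breakpoint_alpha: float = 0.05
    seed: int = 0
    thermo_table: str | None = None    # None -> packaged fixture
    logp_table: str | None = None
    output_path: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
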