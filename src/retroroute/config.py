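"""Configuration schema and loading (YAML or JSON).

One schema covers the whole pipeline: tagging strategies, loop beams, route
scoring, search budgets, and the global seed governing every stochastic
component (the search itself is deterministic).  Unknown keys are rejected
so typos fail loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from retroroute.loop import LoopConfig
from retroroute.scoring import ScoreConfig, heuristic_complexity
from retroroute.search import SearchConfig
from retroroute.sites import TaggingConfig

__all__ = ["AppConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TaggingSection(_Strict):
    systematic: bool = True
    template: bool = True
    template_radius: int = Field(default=2, ge=1, le=3)
    model: bool = True
    model_beam: int = Field(default=50, ge=1)

    def build(self) -> TaggingConfig:
        return TaggingConfig(**self.model_dump())


class LoopSection(_Strict):
    retro_beam: int = Field(default=3, ge=1)
    reagent_beam: int = Field(default=3, ge=1)
    min_confidence: float = Field(default=0.0, ge=0.0, le=1.0)

    def build(self, tagging: TaggingConfig) -> LoopConfig:
        return LoopConfig(tagging=tagging, **self.model_dump())


class ScoringSection(_Strict):
    step_penalty: float = 0.8
    count_duplicates: bool = False
    complexity: str = "heuristic"

    @field_validator("step_penalty")
    @classmethod
    def _sp_range(cls, v: float) -> float:
        if not 0.0 < v <= 1.0:
            raise ValueError(f"step_penalty must be in (0, 1], got {v}")
        return v

    @field_validator("complexity")
    @classmethod
    def _known_scorer(cls, v: str) -> str:
        if v not in ("heuristic",):
            raise ValueError(f"unknown complexity scorer {v!r}")
        return v

    def build(self) -> ScoreConfig:
        return ScoreConfig(
            step_penalty=self.step_penalty, count_duplicates=self.count_duplicates
        )

    def build_scorer(self):
        return heuristic_complexity


class SearchSection(_Strict):
    expansion_width: int = Field(default=20, ge=1)
    min_solved: int = Field(default=10, ge=1)
    max_iterations: int = Field(default=10, ge=0)
    route_cap: int = Field(default=10000, ge=1)
    per_molecule_cap: int = Field(default=50, ge=1)

    def build(self) -> SearchConfig:
        return SearchConfig(**self.model_dump())


class AppConfig(_Strict):
    """Validated top-level configuration with all defaults filled in."""

    seed: int = 0
    tagging: TaggingSection = Field(default_factory=TaggingSection)
    loop: LoopSection = Field(default_factory=LoopSection)
    scoring: ScoringSection = Field(default_factory=ScoringSection)
    search: SearchSection = Field(default_factory=SearchSection)


def load_config(path: str | Path | None = None) -> AppConfig:
    """Load and validate a YAML or JSON config file; ``None`` or an empty
    file yields the full default configuration."""
    if path is None:
        return AppConfig()
    text = Path(path).read_text()
    if not text.strip():
        return AppConfig()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return AppConfig()
    return AppConfig.model_validate(data)
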