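"""Run configuration: every tunable the pipeline exposes, in one object.

Serialises to/from YAML losslessly; all values are validated against
documented ranges.  A single master seed feeds named substreams per
module, so results do not depend on the order modules run in.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

__all__ = ["RunConfig", "ContinuityConfig", "ComoveConfig", "ReleaseConfig"]


class ContinuityConfig(BaseModel):
    # a vacated-then-reoccupied dwelling starts a new household unless the
    # vacancy is at most this many days
    allow_gap_days: int = Field(0, ge=0)


class ComoveConfig(BaseModel):
    window_days: int = Field(28, ge=0)
    min_movers: int = Field(2, ge=1)


class ReleaseConfig(BaseModel):
    suppress_threshold: int = Field(5, ge=2)
    exclude_communal: bool = False
    alpha: float = Field(0.05, gt=0, lt=1)
    level: str = "LSOA"


class RunConfig(BaseModel):
    censor_date: str = "2016-12-31"
    adult_age: int = Field(18, ge=16, le=21)
    continuity: ContinuityConfig = Field(default_factory=ContinuityConfig)
    comove: ComoveConfig = Field(default_factory=ComoveConfig)
    family_min_comoves: int = Field(2, ge=1)
    release: ReleaseConfig = Field(default_factory=ReleaseConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as f:
            data = yaml.safe_load(f) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as f:
            yaml.safe_dump(self.model_dump(), f, sort_keys=True)
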