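"""Pipeline configuration.

Defaults encode the study parameterization: 365-day episode gap, 240-day
persistence horizon with rule day 210, index dates 2008-2013, age cap 88,
small-cell suppression below 5 users, 95% Wilson intervals.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator


class PipelineConfig(BaseModel):
    registry_dir: Optional[Path] = None
    output_dir: Optional[Path] = None

    drug_groups: dict[str, list[str]] = Field(
        default_factory=lambda: {
            "haloperidol": ["N05AD01"],
            "citalopram_escitalopram": ["N06AB10", "N06AB04"],
            "verapamil": ["C08DA01"],
            "betablockers": ["C07"],
            "digitalis": ["C01A"],
        }
    )
    combinations: list[tuple[str, str]] = Field(
        default_factory=lambda: [
            ("betablockers", "citalopram_escitalopram"),
            ("verapamil", "citalopram_escitalopram"),
        ]
    )
    daily_rates: dict[str, float] = Field(default_factory=lambda: {"N06DA03": 2.0})

    gap_days: int = Field(default=365, ge=1)
    horizon_days: int = Field(default=240, ge=1)
    rule_day: int = Field(default=210, ge=1)
    index_window_start: dt.date = dt.date(2008, 1, 1)
    index_window_end: dt.date = dt.date(2013, 12, 31)
    earliest_index_date: dt.date = dt.date(2005, 1, 1)
    age_cap: int = Field(default=88, ge=0)
    registry_presence_window: tuple[int, int] = (365, 729)
    suppression_threshold: int = Field(default=5, ge=0)
    confidence: float = Field(default=0.95, gt=0.0, lt=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.index_window_start > self.index_window_end:
            raise ValueError("index window must be non-empty")
        if len(set(self.drug_groups)) != len(self.drug_groups):
            raise ValueError("drug-group names must be unique")
        for a, b in self.combinations:
            for g in (a, b):
                if g not in self.drug_groups:
                    raise ValueError(f"combination references unknown drug group {g!r}")
        return self

    @property
    def initiation_years(self) -> tuple[int, ...]:
        return tuple(range(self.index_window_start.year, self.index_window_end.year + 1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
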