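"""Validated configuration files for simulations.

A YAML/JSON config describes a cohort simulation: the experiment variant,
the between-subject condition, the agent policy (a preset name plus field
overrides), cohort size, and the root seed.  ``SimulationSpec`` is the
pydantic schema; ``load_config`` parses and validates a file, and
``json_schema`` exports the machine-readable schema document.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import agents
from .environment import TrialConfig

__all__ = ["PolicySpec", "SimulationSpec", "load_config", "json_schema",
           "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"


class PolicySpec(BaseModel):
    """Agent policy: a preset name plus optional field overrides."""

    preset: str = "random_switcher"
    overrides: dict = Field(default_factory=dict)

    @field_validator("preset")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in agents.PRESET_NAMES:
            raise ValueError(
                f"unknown preset {v!r}; choose from {agents.PRESET_NAMES}"
            )
        return v

    def build(self) -> agents.AgentPolicy:
        return agents.preset(self.preset).with_(**self.overrides)


class SimulationSpec(BaseModel):
    """One simulated cohort: variant x role x policy x size."""

    schema_version: str = SCHEMA_VERSION
    experiment: Literal["E1_avoid", "E2_freeze", "E3_reward"] = "E1_avoid"
    role: Literal["hunted", "distracted", "baseline"] = "hunted"
    wolf_behavior: Literal["pack", "lone"] = "pack"
    n_participants: int = Field(default=1, ge=1)
    n_correct: Optional[int] = Field(
        default=None,
        description="correct trials per cell; defaults to the variant's "
        "standard block size (E1: 3 per velocity cell, E2: 10, E3: 20)",
    )
    speeds: Optional[list[float]] = None  # E1 velocity conditions
    policy: PolicySpec = Field(default_factory=PolicySpec)
    trial_overrides: dict = Field(default_factory=dict)
    seed: int = 0

    def grid(self) -> list[tuple[TrialConfig, int]]:
        kw = dict(self.trial_overrides)
        if self.experiment == "E1_avoid":
            g = agents.e1_grid(
                role=self.role,
                wolf_behavior=self.wolf_behavior,
                speeds=self.speeds or (30, 42, 54, 66, 78),
                **kw,
            )
            if self.n_correct is not None:
                g = [(c, self.n_correct) for c, _ in g]
            return g
        if self.experiment == "E2_freeze":
            return agents.e2_grid(
                role=self.role, n_correct=self.n_correct or 10, **kw
            )
        return agents.e3_grid(
            role=self.role, n_correct=self.n_correct or 20, **kw
        )


def load_config(path) -> SimulationSpec:
    """Parse and validate a YAML or JSON simulation config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return SimulationSpec.model_validate(data)


def json_schema() -> str:
    """The versioned JSON-schema document for simulation configs."""
    return json.dumps(SimulationSpec.model_json_schema(), indent=2)
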