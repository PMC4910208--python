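"""Simulation configuration with validated study-condition defaults.

Defaults encode the subpopulation structure of the birthing population the
generator emulates: prisoner mothers are rare (<1 %), serious mental health
morbidity (MHM) affects about 7 % of mothers overall but about 68 % of
prisoner mothers, prisoners average about 2.9 incarceration episodes each,
and the unlinked remainder of the population is retained as a 10 % random
sample.
"""

from __future__ import annotations

from typing import Dict

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: Error types the generator can inject, mirroring the censoring audit's
#: reason taxonomy plus linkage-level identity merges.
ERROR_TYPES = (
    "duplicate_birth",
    "merged_identity",
    "overlapping_episodes",
    "inverted_episode",
    "duplicated_episode",
    "missing_episode_bound",
    "excess_maternities",
    "non_chronological_age",
    "concurrent_pregnancy",
    "prison_conception",
)


class SimulationConfig(BaseModel):
    """Parameters of the synthetic linked-cohort generator.

    All proportions are in [0, 1].  ``error_rates`` maps an error type from
    :data:`ERROR_TYPES` to the proportion of eligible units (women, episodes
    or births, depending on the type) that receive an injected error;
    omitted types default to zero, i.e. clean data.
    """

    model_config = ConfigDict(extra="forbid")

    n_women: int = Field(gt=0)
    prisoner_prevalence: float = Field(default=0.008, ge=0.0, le=1.0)
    mhm_prevalence: float = Field(default=0.07, ge=0.0, le=1.0)
    mhm_given_prisoner: float = Field(default=0.68, ge=0.0, le=1.0)
    maternity_rate: float = Field(default=1.4, ge=1.0)
    gestation_mean_weeks: float = 39.0
    gestation_sd_weeks: float = Field(default=2.0, gt=0.0)
    gestation_min_weeks: int = Field(default=20, ge=20)
    gestation_max_weeks: int = 43
    episodes_per_prisoner_mean: float = Field(default=2.9, ge=1.0)
    max_episodes: int = Field(default=30, ge=1)
    prison_pregnancy_rate: float = Field(default=0.20, ge=0.0, le=1.0)
    birth_in_prison_given_exposed: float = Field(default=0.21, ge=0.0, le=1.0)
    twin_rate: float = Field(default=0.015, ge=0.0, le=1.0)
    error_rates: Dict[str, float] = Field(default_factory=dict)
    sampling_fraction: float = Field(default=0.10, gt=0.0, le=1.0)
    conception_guard_days: int = Field(default=30, ge=0)
    seed: int = 0

    @field_validator("error_rates")
    @classmethod
    def _check_error_rates(cls, v: Dict[str, float]) -> Dict[str, float]:
        for key, rate in v.items():
            if key not in ERROR_TYPES:
                raise ValueError(
                    f"error_rates: unknown error type {key!r}; "
                    f"expected one of {ERROR_TYPES}"
                )
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"error_rates[{key!r}] must be in [0, 1], got {rate}")
        return v

    @model_validator(mode="after")
    def _check_gestation(self) -> "SimulationConfig":
        if self.gestation_max_weeks < self.gestation_min_weeks:
            raise ValueError(
                "gestation_max_weeks must be >= gestation_min_weeks"
            )
        return self

    def rate(self, error_type: str) -> float:
        return float(self.error_rates.get(error_type, 0.0))
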