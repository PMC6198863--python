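"""YAML run-configuration schema for the command-line interface.

Defaults mirror the demonstration calibration protocol: estimation
bounds 1e-7..1e4, genetic algorithm with population 300 over 500
generations and 300 repeat runs, chaser Hooke & Jeeves refinement of
the best three sets (tolerance 1e-10, iteration limit 1000), profile
likelihoods with Hooke & Jeeves (tolerance 1e-6, iteration limit 50)
scanned 3 orders of magnitude either side of the best value at the 95%
confidence level, and top-10% truncation for exploratory plots.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .estimation import DEFAULT_LOWER_BOUND, DEFAULT_UPPER_BOUND, OptimizerConfig


class FreeParameterSpec(BaseModel):
    name: str
    lower: float = DEFAULT_LOWER_BOUND
    upper: float = DEFAULT_UPPER_BOUND

    @model_validator(mode="after")
    def _check_bounds(self):
        if not (0 < self.lower < self.upper):
            raise ValueError("bounds must satisfy 0 < lower < upper")
        return self


class ObservableSpec(BaseModel):
    species: str
    scale_factor: float = 100.0

    @field_validator("scale_factor")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("scale_factor must be > 0")
        return v


class EstimationSpec(BaseModel):
    algorithm: Literal["genetic", "hooke_jeeves"] = "genetic"
    population_size: int = 300
    generations: int = 500
    n_runs: int = 300
    tolerance: float = 1e-6
    iteration_limit: int = 50

    def optimizer_config(self, seed: int | None = None) -> OptimizerConfig:
        return OptimizerConfig(
            algorithm=self.algorithm,
            population_size=self.population_size,
            generations=self.generations,
            tolerance=self.tolerance,
            iteration_limit=self.iteration_limit,
            seed=seed,
        )


class ChaserSpec(BaseModel):
    top_k: int = 3
    tolerance: float = 1e-10
    iteration_limit: int = 1000

    def optimizer_config(self) -> OptimizerConfig:
        return OptimizerConfig(
            algorithm="hooke_jeeves",
            tolerance=self.tolerance,
            iteration_limit=self.iteration_limit,
        )


class ProfileSpec(BaseModel):
    tolerance: float = 1e-6
    iteration_limit: int = 50
    span_orders: float = 3.0
    n_points: int = 20
    alpha: float = 0.95
    mode: Literal["chi2_pointwise", "f_based"] = "chi2_pointwise"

    def optimizer_config(self) -> OptimizerConfig:
        return OptimizerConfig(
            algorithm="hooke_jeeves",
            tolerance=self.tolerance,
            iteration_limit=self.iteration_limit,
        )


class SelectionSpec(BaseModel):
    criteria: list[Literal["aic", "aicc", "bic"]] = Field(
        default_factory=lambda: ["aicc", "bic"]
    )


class TruncationSpec(BaseModel):
    mode: Literal["fraction", "count", "rss_cutoff"] = "fraction"
    value: float = 0.1


class GenerateSpec(BaseModel):
    times: list[float] = Field(default_factory=lambda: [0, 1, 2, 4, 8, 12])
    replicates: int = 6
    noise: Literal["none", "gaussian_cv", "lognormal"] = "gaussian_cv"
    cv: float = 0.1
    protein_lag_h: float = 0.5
    protein_magnitude: float = 100.0


class RunConfig(BaseModel):
    """Schema of a kincal YAML configuration file."""

    models: list[str] = Field(default_factory=list)  # model file paths
    data: str | None = None  # experiment CSV path
    observation_map: dict[str, ObservableSpec] = Field(default_factory=dict)
    free_parameters: list[FreeParameterSpec] = Field(default_factory=list)
    weighting: Literal["sd", "none"] = "sd"
    estimation: EstimationSpec = Field(default_factory=EstimationSpec)
    chaser: ChaserSpec = Field(default_factory=ChaserSpec)
    profile: ProfileSpec = Field(default_factory=ProfileSpec)
    selection: SelectionSpec = Field(default_factory=SelectionSpec)
    truncation: TruncationSpec = Field(default_factory=TruncationSpec)
    generate: GenerateSpec = Field(default_factory=GenerateSpec)
    output_dir: str = "kincal_runs"
    seed: int = 0
    max_workers: int = 1


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
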