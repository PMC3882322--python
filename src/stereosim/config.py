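"""Study configuration: schema, validation, defaults.

A study config describes cohorts, the stereological sampling design, the
size-bin layout, the kinetics scenario and the power analysis in one YAML
(or JSON) document.  Validation is strict — unknown keys are rejected so
typos fail loudly — and every diagnostic names the offending field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import cohort as _cohort
from .errors import ConfigurationError
from .estimators import SamplingDesign
from .kinetics import KineticsParams, PowerSpec
from .population import BinSpec

__all__ = [
    "SizeMixtureConfig",
    "DiseaseEffectConfig",
    "CohortConfig",
    "SamplingConfig",
    "BinConfig",
    "KineticsConfig",
    "PowerConfig",
    "StudyConfig",
    "load_config",
    "validate_config",
    "default_study_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SizeMixtureConfig(_Strict):
    weights: list[float]
    medians_um3: list[float]
    log_sigmas: list[float]

    def to_mixture(self) -> _cohort.LognormalMixture:
        return _cohort.LognormalMixture(
            tuple(self.weights), tuple(self.medians_um3), tuple(self.log_sigmas)
        )


class DiseaseEffectConfig(_Strict):
    kind: Literal["none", "uniform", "banded"] = "none"
    loss: float = Field(default=0.0, ge=0.0, le=1.0)
    atrophy: float = Field(default=1.0, gt=0.0, le=1.0)
    band_um3: tuple[float, float] = _cohort.DEFAULT_LOSS_BAND_UM3

    def to_effect(self) -> Optional[_cohort.DiseaseEffect]:
        if self.kind == "none":
            return None
        if self.kind == "uniform":
            return _cohort.DiseaseEffect.uniform(loss=self.loss, atrophy=self.atrophy)
        return _cohort.DiseaseEffect.banded(
            loss=self.loss, atrophy=self.atrophy, band=self.band_um3
        )


class CohortConfig(_Strict):
    genotype: str
    age_weeks: float = Field(gt=0)
    n_animals: int = Field(ge=1)
    mean_true_count: float = Field(gt=0)
    between_animal_cv: float = Field(default=_cohort.DEFAULT_BETWEEN_ANIMAL_CV, ge=0)
    size_distribution: Optional[SizeMixtureConfig] = None
    disease_effect: Optional[DiseaseEffectConfig] = None

    def to_spec(self, extent: tuple[float, float, float], seed: int) -> _cohort.CohortSpec:
        mixture = (
            self.size_distribution.to_mixture()
            if self.size_distribution is not None
            else _cohort.DEFAULT_SIZE_DISTRIBUTION
        )
        effect = self.disease_effect.to_effect() if self.disease_effect else None
        return _cohort.CohortSpec(
            genotype=self.genotype,
            age_weeks=self.age_weeks,
            n_animals=self.n_animals,
            mean_true_count=self.mean_true_count,
            between_animal_cv=self.between_animal_cv,
            size_distribution=mixture,
            disease_effect=effect,
            extent=extent,
            seed=seed,
        )


class SamplingConfig(_Strict):
    section_thickness_um: float = Field(default=40.0, gt=0)
    period: int = Field(default=12, ge=1)
    frame_side_um: float = Field(default=40.0, gt=0)
    grid_step_um: float = Field(default=500.0, gt=0)
    dissector_height_um: float = Field(default=20.0, gt=0)
    guard_zone_um: float = Field(default=2.0, ge=0)

    @model_validator(mode="after")
    def _geometry(self) -> "SamplingConfig":
        if self.frame_side_um > self.grid_step_um:
            raise ValueError("frame_side_um must not exceed grid_step_um")
        if self.dissector_height_um + 2 * self.guard_zone_um > self.section_thickness_um:
            raise ValueError(
                "dissector_height_um plus guard zones must fit within section_thickness_um"
            )
        return self

    def to_design(self) -> SamplingDesign:
        return SamplingDesign.from_geometry(
            section_thickness=self.section_thickness_um,
            period=self.period,
            frame_side=self.frame_side_um,
            grid_step=self.grid_step_um,
            dissector_height=self.dissector_height_um,
            guard_zone=self.guard_zone_um,
        )


class BinConfig(_Strict):
    bin_width_um3: float = Field(default=50.0, gt=0)
    origin_um3: float = Field(default=0.0, ge=0)

    def to_spec(self) -> BinSpec:
        return BinSpec(bin_width=self.bin_width_um3, origin=self.origin_um3)


class KineticsConfig(_Strict):
    onset_age_days: float = 60.0
    sacrifice_age_days: float = 84.0
    removal_window_hours: float = Field(default=8.0, gt=0)
    section_thickness_um: float = Field(default=20.0, ge=0)
    striatal_z_extent_um: float = Field(default=2400.0, gt=0)

    @model_validator(mode="after")
    def _ages(self) -> "KineticsConfig":
        if self.sacrifice_age_days <= self.onset_age_days:
            raise ValueError("sacrifice_age_days must exceed onset_age_days")
        return self

    def to_params(self) -> KineticsParams:
        return KineticsParams(
            onset_age_days=self.onset_age_days,
            sacrifice_age_days=self.sacrifice_age_days,
            removal_window_hours=self.removal_window_hours,
            section_thickness_um=self.section_thickness_um,
            striatal_z_extent_um=self.striatal_z_extent_um,
        )


class PowerConfig(_Strict):
    power: float = Field(default=0.80, gt=0, lt=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    tails: Literal["one", "two"] = "one"
    cv: float = Field(default=_cohort.DEFAULT_BETWEEN_ANIMAL_CV, ge=0)
    rescue_fractions: list[float] = Field(default_factory=lambda: [0.5, 1.0])

    def to_spec(self, rescue_fraction: float) -> PowerSpec:
        return PowerSpec(
            power=self.power, alpha=self.alpha, tails=self.tails,
            cv=self.cv, rescue_fraction=rescue_fraction,
        )


class StudyConfig(_Strict):
    """Top-level study description; ``seed`` fixes every random choice."""

    seed: int = 0
    extent_um: tuple[float, float, float] = _cohort.DEFAULT_EXTENT_UM
    reference_genotype: str = "wild-type"
    cohorts: list[CohortConfig] = Field(min_length=1)
    sampling: SamplingConfig = Field(default_factory=SamplingConfig)
    bins: BinConfig = Field(default_factory=BinConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    power: PowerConfig = Field(default_factory=PowerConfig)

    def echo(self) -> dict:
        """Resolved configuration (defaults filled), JSON-serializable."""
        return self.model_dump(mode="json")


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"{loc}: {e['msg']}")
    return "invalid study configuration:\n  " + "\n  ".join(lines)


def validate_config(data: dict) -> StudyConfig:
    """Validate a raw mapping into a :class:`StudyConfig` (strict schema)."""
    try:
        return StudyConfig.model_validate(data)
    except ValidationError as err:
        raise ConfigurationError(_format_validation_error(err)) from err


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML/JSON study configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigurationError("config file must contain a mapping at top level")
    return validate_config(data)


def default_study_config(seed: int = 0) -> StudyConfig:
    """The four-group study layout with the published group sizes.

    Five-week cohorts and the 12-week wild-type share a healthy baseline;
    the 12-week HD cohort applies the default banded loss/atrophy effect
    (≈12.7% whole-striatum loss concentrated in 550–1050 µm³).
    """
    baseline = 993891.0
    return StudyConfig(
        seed=seed,
        cohorts=[
            CohortConfig(genotype="wild-type", age_weeks=5, n_animals=15,
                         mean_true_count=baseline),
            CohortConfig(genotype="HD", age_weeks=5, n_animals=13,
                         mean_true_count=baseline),
            CohortConfig(genotype="wild-type", age_weeks=12, n_animals=9,
                         mean_true_count=baseline),
            CohortConfig(
                genotype="HD", age_weeks=12, n_animals=10,
                mean_true_count=baseline,
                disease_effect=DiseaseEffectConfig(kind="banded", loss=0.26, atrophy=0.85),
            ),
        ],
    )
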