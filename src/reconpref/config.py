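"""Configuration for the synthetic respondent cohort.

The defaults emulate the published study population: a 40-woman breast
reconstruction cohort with the reported covariate distributions (age
51.65 +/- 11.66 clipped to 27-68, BMI 30/40/30% normal/overweight/obese,
40/60% unilateral/bilateral, ASI-R and BREAST-Q score moments), default
base utilities close to the reported median standard-gamble utilities,
and generating covariate effects taken from the reported multivariable
regressions (VAS points per unit covariate, divided by 100 to act on the
latent 0-1 utility scale).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .states import RECON_QUALITIES, reconstruction_states

#: option-group keys an effect may target, besides an explicit state_id
EFFECT_GROUPS = ("any", "implant", "tissue", "none")

#: VAS rounding grids supported by the rating instrument (0 disables snapping)
VAS_GRIDS = (0.0, 0.5, 1.0, 2.5, 5.0)


@dataclass
class ContinuousSpec:
    """Clipped-normal marginal for one continuous covariate.

    ``calibrate_mean`` shifts the pre-clip mean so the clipped draw has
    expectation ``mean`` (clipping at the observed min/max otherwise biases
    the mean toward the nearer bound).
    """

    mean: float
    sd: float
    lo: float
    hi: float
    calibrate_mean: bool = True

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ValueError(f"{name}: sd must be nonnegative, got {self.sd}")
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError(
                f"{name}: mean {self.mean} outside clip range [{self.lo}, {self.hi}]"
            )
        if self.lo > self.hi:
            raise ValueError(f"{name}: empty clip range [{self.lo}, {self.hi}]")


@dataclass
class Effect:
    """Additive covariate effect on the latent utilities of one option group.

    ``per_point`` is expressed in VAS points (0-100 scale) per covariate
    unit, matching how the study reports regression coefficients; the
    generator divides by 100.  Continuous covariates are centred at their
    configured mean; categorical covariates need a ``level`` and act as an
    indicator.
    """

    covariate: str
    group: str
    per_point: float
    level: Optional[str] = None


def _study_continuous_defaults() -> dict[str, ContinuousSpec]:
    return {
        "age": ContinuousSpec(51.65, 11.66, 27.0, 68.0),
        "asir_total": ContinuousSpec(3.28, 0.59, 1.95, 4.45),
        "asir_behavior": ContinuousSpec(3.76, 0.63, 2.14, 5.00),
        "asir_self_evaluation": ContinuousSpec(2.97, 0.77, 1.25, 4.50),
        "asir_control": ContinuousSpec(3.09, 0.65, 1.80, 4.40),
        "breastq_breast": ContinuousSpec(54.11, 9.90, 35.75, 74.00),
        "breastq_outcome": ContinuousSpec(57.99, 13.68, 32.00, 80.00),
    }


def _study_categorical_defaults() -> dict[str, dict[str, float]]:
    return {
        "race": {"white": 0.925, "asian": 0.025, "black": 0.025, "other": 0.025},
        "ethnicity": {"hispanic": 0.225, "non_hispanic": 0.775},
        "married": {"married": 0.775, "not_married": 0.225},
        "education": {
            "high_school_or_some_college": 0.325,
            "college_graduate_or_higher": 0.675,
        },
        "indication": {
            "cancer_one_breast": 0.75,
            "cancer_both": 0.125,
            "prophylactic": 0.125,
        },
        "laterality": {"unilateral": 0.40, "bilateral": 0.60},
        "bmi_category": {"normal": 0.30, "overweight": 0.40, "obese": 0.30},
        "timing": {"pre_mastectomy": 0.50, "post_mastectomy": 0.50},
    }


def default_base_utilities() -> dict[str, float]:
    """Default latent base utilities per state.

    Close to the study's median standard-gamble utilities, with two values
    nudged (implant_poor 0.93, tissue_fair 0.935) so the noiseless ordering
    excellent > good > fair > poor is strict and no two cards tie exactly.
    """
    return {
        "implant_excellent": 0.99,
        "implant_good": 0.96,
        "implant_fair": 0.94,
        "implant_poor": 0.93,
        "tissue_excellent": 0.97,
        "tissue_good": 0.95,
        "tissue_fair": 0.935,
        "tissue_poor": 0.92,
        "none": 0.86,
    }


def default_effects() -> list[Effect]:
    """Generating covariate effects (study's VAS-without-death panel)."""
    return [
        Effect("breastq_breast", "any", 0.29),
        Effect("breastq_breast", "implant", 0.46),
        Effect("breastq_outcome", "none", -0.25),
        Effect("asir_behavior", "any", 4.20),
        Effect("asir_self_evaluation", "any", -6.96),
        Effect("asir_self_evaluation", "tissue", -6.04),
        Effect("bmi_category", "implant", -16.15, level="obese"),
        Effect("bmi_category", "tissue", 10.59, level="obese"),
    ]


@dataclass
class GeneratorConfig:
    """Everything needed to simulate a cohort and its interview responses."""

    n_participants: int = 40
    rng_seed: int = 0
    continuous: dict[str, ContinuousSpec] = field(default_factory=_study_continuous_defaults)
    categorical: dict[str, dict[str, float]] = field(default_factory=_study_categorical_defaults)
    base_utilities: dict[str, float] = field(default_factory=default_base_utilities)
    effects: list[Effect] = field(default_factory=default_effects)
    # respondent behaviour
    latent_noise_sd: float = 0.03
    choice_noise: float = 0.02
    weighting_gamma: float = 1.0
    vas_noise_sd: float = 5.0
    unexpected_rank_fraction: float = 0.45
    equipoise_fraction: float = 0.25
    equipoise_strength: float = 0.9
    # instrument settings
    sg_step: float = 0.05
    vas_rounding: float = 2.5

    # ------------------------------------------------------------------ #
    def validate(self) -> "GeneratorConfig":
        if self.n_participants < 1:
            raise ValueError(f"n_participants must be >= 1, got {self.n_participants}")
        for name, spec in self.continuous.items():
            spec.validate(name)
        for name, probs in self.categorical.items():
            if not probs:
                raise ValueError(f"{name}: empty category map")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name}: negative category probability")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"{name}: category probabilities sum to {total}, not 1")
        valid_states = {s.state_id for s in reconstruction_states()} | {"none"}
        missing = valid_states - set(self.base_utilities)
        if missing:
            raise ValueError(f"base_utilities missing states: {sorted(missing)}")
        for sid, u in self.base_utilities.items():
            if sid not in valid_states:
                raise ValueError(f"base_utilities: unknown state {sid!r}")
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"base_utilities[{sid!r}]={u} outside [0, 1]")
        known_covs = set(self.continuous) | set(self.categorical)
        for eff in self.effects:
            if eff.covariate not in known_covs:
                raise ValueError(
                    f"effect references unknown covariate {eff.covariate!r}"
                )
            if eff.group not in EFFECT_GROUPS and eff.group not in valid_states:
                raise ValueError(f"effect targets unknown group {eff.group!r}")
            if eff.covariate in self.categorical:
                if eff.level is None:
                    raise ValueError(
                        f"effect on categorical covariate {eff.covariate!r} needs a level"
                    )
                if eff.level not in self.categorical[eff.covariate]:
                    raise ValueError(
                        f"effect level {eff.level!r} not a category of {eff.covariate!r}"
                    )
            elif eff.level is not None:
                raise ValueError(
                    f"effect on continuous covariate {eff.covariate!r} cannot have a level"
                )
        for frac_name in ("unexpected_rank_fraction", "equipoise_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name}={v} outside [0, 1]")
        if not 0.0 <= self.equipoise_strength <= 1.0:
            raise ValueError(f"equipoise_strength={self.equipoise_strength} outside [0, 1]")
        for noise_name in ("latent_noise_sd", "choice_noise", "vas_noise_sd"):
            if getattr(self, noise_name) < 0:
                raise ValueError(f"{noise_name} must be nonnegative")
        if self.weighting_gamma <= 0:
            raise ValueError("weighting_gamma must be positive")
        if not 0.0 < self.sg_step <= 0.25:
            raise ValueError(f"sg_step={self.sg_step} outside (0, 0.25]")
        if self.vas_rounding not in VAS_GRIDS:
            raise ValueError(
                f"vas_rounding={self.vas_rounding} not one of {VAS_GRIDS}"
            )
        return self

    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        if "continuous" in data:
            data["continuous"] = {
                k: ContinuousSpec(**v) if isinstance(v, dict) else v
                for k, v in data["continuous"].items()
            }
        if "effects" in data:
            data["effects"] = [
                Effect(**e) if isinstance(e, dict) else e for e in data["effects"]
            ]
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw).validate()
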