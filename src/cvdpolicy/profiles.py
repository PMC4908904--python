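"""Risk profiles, SIMD fifths and the run configuration.

An individual is described by the nine ASSIGN risk factors: age, sex, SIMD
deprivation score, family history of CVD, diabetes, systolic blood pressure,
total cholesterol, HDL cholesterol and cigarettes smoked per day.  Family
history and diabetes are stored as proportions in [0, 1] so that cohort-level
"expected" profiles (e.g. family history 0.26) can enter linear predictors as
expectations; ordinary individuals use 0.0 / 1.0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

SEXES = ("male", "female")

#: reference SIMD-score quintile boundaries (configurable; the population
#: boundaries are an input, not something the model derives).
DEFAULT_SIMD_CUTPOINTS = (8.0, 14.0, 21.0, 34.0)

AGE_MIN, AGE_MAX = 20, 120


def simd_fifth(simd_score: float, cutpoints=DEFAULT_SIMD_CUTPOINTS) -> int:
    """Map a SIMD deprivation score to a population fifth in {1..5}.

    1 = least deprived, 5 = most deprived.  Bins are half-open [low, high)
    with ties to the upper bin.
    """
    if simd_score < 0:
        raise ValidationError(f"SIMD score must be non-negative, got {simd_score}")
    cutpoints = np.asarray(cutpoints, dtype=float)
    if cutpoints.size != 4 or np.any(np.diff(cutpoints) <= 0):
        raise ValidationError("SIMD cutpoints must be 4 ascending reals")
    return int(np.searchsorted(cutpoints, simd_score, side="right")) + 1


@dataclass(frozen=True)
class RiskProfile:
    """One individual's nine ASSIGN risk-factor values."""

    age: int
    sex: str
    simd: float
    family_history: float
    diabetes: float
    sbp: float
    total_chol: float
    hdl_chol: float
    cigarettes_per_day: float
    simd_cutpoints: tuple = field(default=DEFAULT_SIMD_CUTPOINTS, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "age", int(self.age))
        for name in ("simd", "family_history", "diabetes", "sbp",
                     "total_chol", "hdl_chol", "cigarettes_per_day"):
            object.__setattr__(self, name, float(getattr(self, name)))

    @property
    def fifth(self) -> int:
        """Derived SIMD fifth in {1..5}."""
        return simd_fifth(self.simd, self.simd_cutpoints)

    @property
    def chol_ratio(self) -> float:
        """Total / HDL cholesterol ratio."""
        return self.total_chol / self.hdl_chol

    def replace(self, **changes) -> "RiskProfile":
        return dataclasses.replace(self, **changes)


def validate_profile(profile: RiskProfile) -> list[str]:
    """Return a list of invariant violations (empty iff the profile is valid)."""
    v: list[str] = []
    if not (AGE_MIN <= profile.age <= AGE_MAX):
        v.append(f"age={profile.age} outside [{AGE_MIN}, {AGE_MAX}]")
    if profile.sex not in SEXES:
        v.append(f"sex={profile.sex!r} not in {SEXES}")
    if profile.simd < 0:
        v.append(f"simd={profile.simd} must be >= 0")
    if not (0.0 <= profile.family_history <= 1.0):
        v.append(f"family_history={profile.family_history} outside [0, 1]")
    if not (0.0 <= profile.diabetes <= 1.0):
        v.append(f"diabetes={profile.diabetes} outside [0, 1]")
    if not profile.sbp > 0:
        v.append(f"sbp={profile.sbp} must be > 0")
    if not profile.hdl_chol > 0:
        v.append(f"hdl_chol={profile.hdl_chol} must be > 0")
    elif profile.total_chol < profile.hdl_chol:
        v.append(
            f"total_chol={profile.total_chol} < hdl_chol={profile.hdl_chol}"
            " (ratio below 1)"
        )
    if profile.cigarettes_per_day < 0:
        v.append(f"cigarettes_per_day={profile.cigarettes_per_day} must be >= 0")
    return v


#: risk-factor terms an equation may reference by name
def term_value(profile: RiskProfile, term: str, age: float | None = None) -> float:
    """Value of a named linear-predictor term for a profile.

    ``age`` overrides the profile's entry age (the model advances age one
    year per cycle).
    """
    if age is None:
        age = profile.age
    if term == "age":
        return float(age)
    if term == "sbp":
        return profile.sbp
    if term == "total_chol":
        return profile.total_chol
    if term == "hdl_chol":
        return profile.hdl_chol
    if term == "chol_ratio":
        return profile.chol_ratio
    if term == "cigarettes_per_day":
        return profile.cigarettes_per_day
    if term == "family_history":
        return profile.family_history
    if term == "diabetes":
        return profile.diabetes
    if term == "simd":
        return profile.simd
    if term == "simd_fifth":
        return float(profile.fifth)
    raise ValidationError(f"equation references unknown risk-factor term {term!r}")


class ProfilePath:
    """A possibly time-varying risk profile over model cycles.

    ``at(k)`` returns the profile in force during cycle ``k`` (age in the
    returned profile is still the entry age: the engine advances age itself).
    A constant path wraps a single profile.
    """

    def __init__(self, profiles, warnings=()):
        if isinstance(profiles, RiskProfile):
            profiles = [profiles]
        if not profiles:
            raise ValidationError("ProfilePath needs at least one profile")
        self.profiles = list(profiles)
        self.warnings = list(warnings)

    @classmethod
    def constant(cls, profile: RiskProfile) -> "ProfilePath":
        return cls([profile])

    @property
    def base(self) -> RiskProfile:
        return self.profiles[0]

    @property
    def is_constant(self) -> bool:
        return len(self.profiles) == 1

    def at(self, cycle: int) -> RiskProfile:
        return self.profiles[min(cycle, len(self.profiles) - 1)]


def as_path(profile_or_path) -> ProfilePath:
    if isinstance(profile_or_path, ProfilePath):
        return profile_or_path
    return ProfilePath.constant(profile_or_path)


_MODE_RATES = {"health_technology": 0.035, "public_health": 0.015}


@dataclass(frozen=True)
class RunConfig:
    """Structured run configuration.

    Discount-rate defaults follow the evaluation mode: 3.5%/year for health
    technology appraisal and 1.5%/year for public health interventions,
    applied to life expectancy, QALE and costs alike.
    """

    horizon: int = 100
    evaluation_mode: str = "health_technology"
    discount_rate_outcomes: float | None = None
    discount_rate_costs: float | None = None
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.evaluation_mode not in _MODE_RATES:
            raise ValidationError(
                f"evaluation_mode must be one of {tuple(_MODE_RATES)}, "
                f"got {self.evaluation_mode!r}"
            )
        if not (1 <= self.horizon <= 100):
            raise ValidationError(f"horizon={self.horizon} outside [1, 100]")
        for r in (self.discount_rate_outcomes, self.discount_rate_costs):
            if r is not None and not (0.0 <= r < 1.0):
                raise ValidationError(f"discount rate {r} outside [0, 1)")

    @property
    def outcome_rate(self) -> float:
        if self.discount_rate_outcomes is not None:
            return self.discount_rate_outcomes
        return _MODE_RATES[self.evaluation_mode]

    @property
    def cost_rate(self) -> float:
        if self.discount_rate_costs is not None:
            return self.discount_rate_costs
        return _MODE_RATES[self.evaluation_mode]

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)
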