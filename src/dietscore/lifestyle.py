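"""Non-FFQ covariate derivation.

GPAQ MET-minutes and WHO activity tertiles, BMI, triplicate blood-pressure
averaging, 3-day-diary water fraction, and estimated energy requirements
(Schofield BMR x physical-activity factor) with assignment to the nearest
DASH eating-plan calorie level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

KCAL_TO_KJ = 4.184

#: DASH eating-plan calorie levels (kcal/day).
DASH_LEVELS_KCAL: tuple[int, ...] = (1600, 2000, 2600, 3100)

#: Physical-activity factors by GPAQ category (low, moderate, high).
DEFAULT_PA_FACTORS: tuple[float, float, float] = (1.4, 1.6, 1.8)

#: MET weights per GPAQ analysis guide: vigorous work/recreation 8,
#: moderate work/recreation and travel 4.
GPAQ_MET_WEIGHTS = {
    "vigorous_work": 8.0,
    "moderate_work": 4.0,
    "travel": 4.0,
    "vigorous_recreation": 8.0,
    "moderate_recreation": 4.0,
}


class LifestyleError(ValueError):
    """Validation error for lifestyle-covariate inputs."""


@dataclass(frozen=True)
class ActivityProfile:
    met_min_week: float
    category: int  # 0 low, 1 moderate, 2 high

    def __post_init__(self) -> None:
        if self.met_min_week < 0:
            raise LifestyleError("MET-minutes must be non-negative")
        if classify_activity(self.met_min_week) != self.category:
            raise LifestyleError("activity category inconsistent with MET minutes")


@dataclass(frozen=True)
class EnergyAssignment:
    """BMR, estimated energy requirement and assigned DASH calorie level."""

    bmr_kj: float
    pa_factor: float
    eer_kj: float
    dash_level_kcal: int

    def __post_init__(self) -> None:
        if abs(self.eer_kj - self.bmr_kj * self.pa_factor) > 1e-6 * max(1.0, self.eer_kj):
            raise LifestyleError("eer_kj must equal bmr_kj * pa_factor")
        if self.dash_level_kcal not in DASH_LEVELS_KCAL:
            raise LifestyleError(f"dash_level_kcal must be one of {DASH_LEVELS_KCAL}")


@dataclass(frozen=True)
class DiaryBeverages:
    """Per-day water and total-beverage volumes (mL) from a 3-day diary."""

    water_ml: tuple[float, ...]
    total_ml: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.water_ml) == 0 or len(self.water_ml) != len(self.total_ml):
            raise LifestyleError("diary needs >=1 day with matching water/total entries")
        for w, t in zip(self.water_ml, self.total_ml):
            if w < 0 or t < 0 or w > t:
                raise LifestyleError("each day needs 0 <= water <= total beverages")


def gpaq_met_minutes(
    vigorous_work_days: float = 0, vigorous_work_min: float = 0,
    moderate_work_days: float = 0, moderate_work_min: float = 0,
    travel_days: float = 0, travel_min: float = 0,
    vigorous_recreation_days: float = 0, vigorous_recreation_min: float = 0,
    moderate_recreation_days: float = 0, moderate_recreation_min: float = 0,
) -> float:
    """MET-minutes/week = sum over domains of days x minutes x MET weight."""
    domains = {
        "vigorous_work": (vigorous_work_days, vigorous_work_min),
        "moderate_work": (moderate_work_days, moderate_work_min),
        "travel": (travel_days, travel_min),
        "vigorous_recreation": (vigorous_recreation_days, vigorous_recreation_min),
        "moderate_recreation": (moderate_recreation_days, moderate_recreation_min),
    }
    total = 0.0
    for name, (days, minutes) in domains.items():
        if not 0 <= days <= 7:
            raise LifestyleError(f"{name}: days/week {days} outside 0..7")
        if not 0 <= minutes <= 960:
            raise LifestyleError(f"{name}: minutes/day {minutes} outside 0..960")
        total += days * minutes * GPAQ_MET_WEIGHTS[name]
    return total


def classify_activity(met_min_week: float) -> int:
    """WHO tertile: 0 if MET < 600; 1 if 600 <= MET < 1500; 2 if MET >= 1500."""
    if met_min_week < 0:
        raise LifestyleError("MET-minutes must be non-negative")
    if met_min_week < 600:
        return 0
    if met_min_week < 1500:
        return 1
    return 2


def activity_profile(met_min_week: float) -> ActivityProfile:
    return ActivityProfile(met_min_week, classify_activity(met_min_week))


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight (kg) / height (m) squared."""
    if weight_kg <= 0 or height_m <= 0:
        raise LifestyleError("weight and height must be positive")
    return weight_kg / height_m**2


def mean_blood_pressure(
    readings: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Average systolic/diastolic of readings 2 and 3; the first is discarded."""
    if len(readings) != 3:
        raise LifestyleError(f"exactly 3 readings required, got {len(readings)}")
    (_, _), (s2, d2), (s3, d3) = readings
    return (s2 + s3) / 2.0, (d2 + d3) / 2.0


# Schofield BMR equations (kcal/day), by sex and age band: kcal = a*weight + b.
_SCHOFIELD = {
    "male": [
        (10, 18, 17.686, 658.2),
        (18, 30, 15.057, 692.2),
        (30, 60, 11.472, 873.1),
        (60, 200, 11.711, 587.7),
    ],
    "female": [
        (10, 18, 13.384, 692.6),
        (18, 30, 14.818, 486.6),
        (30, 60, 8.126, 845.6),
        (60, 200, 9.082, 658.5),
    ],
}


def schofield_bmr_kj(age: float, sex: str, weight_kg: float) -> float:
    """Basal metabolic rate (kJ/day) from the Schofield weight equations."""
    sex = sex.lower()
    if sex not in _SCHOFIELD:
        raise LifestyleError(f"sex must be 'male' or 'female', got {sex!r}")
    if weight_kg <= 0:
        raise LifestyleError("weight must be positive")
    for lo, hi, a, b in _SCHOFIELD[sex]:
        if lo <= age < hi:
            return (a * weight_kg + b) * KCAL_TO_KJ
    raise LifestyleError(f"age {age} outside supported range (10..200)")


def estimate_energy(
    age: float,
    sex: str,
    weight_kg: float,
    activity_category: int,
    pa_factors: tuple[float, float, float] = DEFAULT_PA_FACTORS,
    levels_kcal: Sequence[int] = DASH_LEVELS_KCAL,
) -> EnergyAssignment:
    """Estimated energy requirement and nearest DASH calorie level.

    EER = Schofield BMR x activity factor.  The assigned level minimises the
    absolute distance in kJ; an exact midpoint resolves to the lower level.
    """
    if activity_category not in (0, 1, 2):
        raise LifestyleError(f"activity category must be 0/1/2, got {activity_category}")
    bmr = schofield_bmr_kj(age, sex, weight_kg)
    pa = pa_factors[activity_category]
    eer = bmr * pa
    level = nearest_dash_level(eer, levels_kcal)
    return EnergyAssignment(bmr_kj=bmr, pa_factor=pa, eer_kj=eer, dash_level_kcal=level)


def nearest_dash_level(
    eer_kj: float, levels_kcal: Sequence[int] = DASH_LEVELS_KCAL
) -> int:
    """Admissible calorie level minimising |EER - level| in kJ; ties go lower."""
    if eer_kj <= 0:
        raise LifestyleError("EER must be positive")
    levels = sorted(int(lv) for lv in levels_kcal)
    dists = {lv: abs(eer_kj - lv * KCAL_TO_KJ) for lv in levels}
    dmin = min(dists.values())
    # exact midpoints tie to the lower level; tolerance absorbs kcal->kJ rounding
    return min(lv for lv, d in dists.items() if d <= dmin + 1e-6)


def water_fraction(diary: DiaryBeverages) -> float:
    """Mean daily water / mean daily total beverages over the diary days."""
    mean_total = sum(diary.total_ml) / len(diary.total_ml)
    if mean_total <= 0:
        raise LifestyleError("total beverages are zero on every diary day")
    mean_water = sum(diary.water_ml) / len(diary.water_ml)
    return mean_water / mean_total
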