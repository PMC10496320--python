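"""Diet-quality composite scores.

Implements six adherence indices on quantified daily intakes:

* DASH index (Gunther scheme): ten components, 0-80, with component targets
  specific to the assigned DASH eating-plan calorie level.  Forward
  components score proportionally up to a target; reverse components (meat,
  fats/oils, sweets) give full points at or below the target and decay as
  target/intake above it.
* Dairy-adjusted DASH: the same score with the "75% of dairy low fat"
  component granted in full, retaining the 0-80 scale.
* Vegetarian Lifestyle Index: eleven diet components standardised to
  2000 kcal plus three lifestyle components (exercise, water, sunlight),
  each scored 0 / 0.5 / 1, composite 0-14.
* HEIFA: eleven components against the Australian Guide to Healthy Eating,
  nine scored 0-10 and water/alcohol 0-5, composite 0-100.
* MEDAS (14 items) and erMedDiet (17 items): binary adherence screeners.

All numeric cut-points live in a YAML config (``data/score_defaults.yaml``)
so unverifiable constants stay auditable and overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .ffq_engine import (
    ENERGY_KJ_PER_G,
    DailyIntake,
    FoodCompositionTable,
    percent_energy,
)
from .lifestyle import EnergyAssignment

logger = logging.getLogger(__name__)

SCORE_NAMES = ("dash", "dash_dairy_adj", "vegetarian", "heifa", "medas", "ermeddiet")

SCALE_MAX = {
    "dash": 80.0,
    "dash_dairy_adj": 80.0,
    "vegetarian": 14.0,
    "heifa": 100.0,
    "medas": 14.0,
    "ermeddiet": 17.0,
}


class ScoreError(ValueError):
    """Raised for invalid scoring inputs or malformed configs."""


@dataclass
class ScoreResult:
    """Per-component points and composite for one index."""

    index_name: str
    component_points: dict[str, float]
    scale_max: float

    def __post_init__(self) -> None:
        for name, pts in self.component_points.items():
            if pts < -1e-9:
                raise ScoreError(f"{self.index_name}: negative points for {name}")
        if self.composite > self.scale_max + 1e-9:
            raise ScoreError(
                f"{self.index_name}: composite {self.composite} exceeds "
                f"scale max {self.scale_max}"
            )

    @property
    def composite(self) -> float:
        return float(sum(self.component_points.values()))


@dataclass
class ScreenerResponse:
    """Quantitative/boolean answers to screener criteria, keyed by name."""

    participant_id: str
    answers: dict[str, float | bool] = field(default_factory=dict)


def load_default_config() -> dict:
    """Load the packaged default score configuration."""
    with resources.files("dietscore.data").joinpath("score_defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path | None = None) -> dict:
    """Load and validate a score config (the packaged defaults if no path)."""
    if path is None:
        cfg = load_default_config()
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping) -> None:
    for index in ("dash", "vegetarian", "heifa", "medas", "ermeddiet"):
        if index not in cfg:
            raise ScoreError(f"score config missing block {index!r}")
    for name, block in (("medas", cfg["medas"]), ("ermeddiet", cfg["ermeddiet"])):
        n = int(block["scale_max"])
        if len(block["criteria"]) != n:
            raise ScoreError(
                f"{name}: {len(block['criteria'])} criteria but scale max {n}"
            )
        for c in block["criteria"]:
            if c["kind"] not in ("bool", "ge", "lt"):
                raise ScoreError(f"{name}: unknown criterion kind {c['kind']!r}")
            if c["kind"] != "bool" and "threshold" not in c:
                raise ScoreError(f"{name}: criterion {c['name']} missing threshold")
    for cname, comp in cfg["dash"]["components"].items():
        if comp["direction"] not in ("forward", "reverse", "share"):
            raise ScoreError(f"dash component {cname}: bad direction")
        if comp["max_points"] <= 0:
            raise ScoreError(f"dash component {cname}: max_points must be > 0")


def _tag_serves(intake: DailyIntake, tags: list[str]) -> float:
    return float(sum(intake.servings_per_day.get(t, 0.0) for t in tags))


def proportional_points(
    intake: float, target: float, max_points: float, direction: str
) -> float:
    """Proportional component scoring.

    forward: ``max_points * min(intake/target, 1)`` — lower intakes score
    proportionally less.  reverse: full points at or below the target,
    ``max_points * target/intake`` above it (bounded, continuous decay).
    """
    if target <= 0:
        raise ScoreError("target must be positive")
    if intake < 0:
        raise ScoreError("intake must be non-negative")
    if direction == "forward":
        return max_points * min(intake / target, 1.0)
    if direction == "reverse":
        return max_points if intake <= target else max_points * target / intake
    raise ScoreError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# DASH


def score_dash(
    intake: DailyIntake,
    energy: EnergyAssignment,
    config: Mapping | None = None,
    dairy_adjusted: bool = False,
) -> ScoreResult:
    """DASH adherence, 0-80, at the participant's assigned calorie level.

    Six 10-point components (fruits; vegetables; meat/poultry/fish/eggs
    reverse; nuts/seeds/legumes; fats & oils reverse; sweets reverse) and
    four 5-point components (total dairy; low-fat dairy share; whole grains;
    high-fibre grains).  With ``dairy_adjusted`` the low-fat-share component
    is granted in full, removing the requirement that 75% of dairy be low
    fat while keeping the 0-80 scale.
    """
    if energy is None:
        raise ScoreError("DASH scoring requires an energy assignment")
    cfg = (config or load_default_config())["dash"]
    level = energy.dash_level_kcal
    share_target = float(cfg.get("lowfat_share_target", 0.75))
    points: dict[str, float] = {}
    for cname, comp in cfg["components"].items():
        maxp = float(comp["max_points"])
        if comp["direction"] == "share":
            if dairy_adjusted:
                points[cname] = maxp
                continue
            total_dairy = intake.servings_per_day.get("dairy", 0.0)
            lowfat = _tag_serves(intake, comp["tags"])
            if total_dairy <= 0:
                points[cname] = 0.0
            else:
                points[cname] = maxp * min(lowfat / (share_target * total_dairy), 1.0)
            continue
        target = float(comp["targets"][level])
        serves = _tag_serves(intake, comp["tags"])
        points[cname] = proportional_points(serves, target, maxp, comp["direction"])
    name = "dash_dairy_adj" if dairy_adjusted else "dash"
    return ScoreResult(name, points, float(cfg["scale_max"]))


# ---------------------------------------------------------------------------
# Vegetarian Lifestyle Index


def _step_points(value: float, full: float, half: float, direction: str) -> float:
    if direction == "forward":
        if value >= full:
            return 1.0
        if value >= half:
            return 0.5
        return 0.0
    if direction == "reverse":
        if value <= full:
            return 1.0
        if value <= half:
            return 0.5
        return 0.0
    raise ScoreError(f"unknown direction {direction!r}")


def score_vegetarian(
    intake: DailyIntake,
    eer_kj: float,
    activity_category: int,
    water_frac: float,
    b12_source: bool,
    sunlight: bool = True,
    config: Mapping | None = None,
) -> ScoreResult:
    """Vegetarian Lifestyle Index, 0-14, per the Loma Linda pyramid.

    Dietary serves are standardised to 2000 kcal (8368 kJ) by the factor
    ``8368 / estimated energy requirement`` before threshold comparison.
    Eleven diet components and three lifestyle components (exercise, water,
    sunlight) each score 0, 0.5 or 1; sunlight defaults to full marks.
    """
    if eer_kj <= 0:
        raise ScoreError("estimated energy requirement must be positive")
    if activity_category not in (0, 1, 2):
        raise ScoreError("activity category must be 0/1/2")
    if not 0 <= water_frac <= 1:
        raise ScoreError("water fraction must lie in [0, 1]")
    cfg = (config or load_default_config())["vegetarian"]
    factor = float(cfg["reference_energy_kj"]) / eer_kj
    points: dict[str, float] = {}
    for cname, comp in cfg["diet_components"].items():
        serves = _tag_serves(intake, comp["tags"]) * factor
        points[cname] = _step_points(
            serves, float(comp["full"]), float(comp["half"]), comp["direction"]
        )
    points["b12_source"] = 1.0 if b12_source else 0.0
    points["exercise"] = {0: 0.0, 1: 0.5, 2: 1.0}[activity_category]
    full_w = float(cfg["water_full_fraction"])
    half_w = float(cfg["water_half_fraction"])
    points["water"] = 1.0 if water_frac >= full_w else (0.5 if water_frac >= half_w else 0.0)
    points["sunlight"] = 1.0 if sunlight else 0.0
    return ScoreResult("vegetarian", points, float(cfg["scale_max"]))


# ---------------------------------------------------------------------------
# HEIFA


def _linear_reverse(value: float, full_below: float, zero_at: float, maxp: float) -> float:
    """Full points below ``full_below``, zero at/above ``zero_at``, linear between."""
    if value <= full_below:
        return maxp
    if value >= zero_at:
        return 0.0
    return maxp * (zero_at - value) / (zero_at - full_below)


def _variety_count(
    intake: DailyIntake, table: FoodCompositionTable, tags: list[str]
) -> int:
    tagset = set(tags)
    n = 0
    for item_id, g in intake.grams_per_day.items():
        if g > 0 and item_id in table and table[item_id].group_tags & tagset:
            n += 1
    return n


def score_heifa(
    intake: DailyIntake,
    table: FoodCompositionTable,
    water_frac: float,
    config: Mapping | None = None,
) -> ScoreResult:
    """HEIFA composite, 0-100, against the Australian dietary guidelines.

    Nine components scored 0-10 — vegetables and fruit with variety
    sub-scores, grains with a >=50%-wholegrain sub-rule, dairy,
    meat/alternatives, discretionary foods (reverse), saturated fat as a
    percent of energy (full <10%E, zero >=15%E, linear between), added sugar
    %E and sodium — plus water and alcohol scored 0-5.  Requires a positive
    energy intake for the %-energy components.
    """
    if intake.energy_kj_per_day <= 0:
        raise ScoreError("HEIFA requires positive energy intake")
    if not 0 <= water_frac <= 1:
        raise ScoreError("water fraction must lie in [0, 1]")
    cfg = (config or load_default_config())["heifa"]
    comps = cfg["components"]
    points: dict[str, float] = {}

    for cname in ("vegetables", "fruit"):
        c = comps[cname]
        serves = _tag_serves(intake, c["tags"])
        quantity = float(c["quantity_max"]) * min(serves / float(c["quantity_target"]), 1.0)
        variety = float(c["variety_max"]) * min(
            _variety_count(intake, table, c["tags"]) / float(c["variety_target"]), 1.0
        )
        points[cname] = quantity + variety

    g = comps["grains"]
    grain_serves = _tag_serves(intake, g["tags"])
    quantity = float(g["quantity_max"]) * min(grain_serves / float(g["quantity_target"]), 1.0)
    whole = _tag_serves(intake, g["wholegrain_tags"])
    if grain_serves > 0:
        share = whole / grain_serves
        wg = float(g["wholegrain_max"]) * min(share / float(g["wholegrain_share_target"]), 1.0)
    else:
        wg = 0.0
    points["grains"] = quantity + wg

    for cname in ("dairy", "meat_alternatives"):
        c = comps[cname]
        serves = _tag_serves(intake, c["tags"])
        points[cname] = float(c["max_points"]) * min(serves / float(c["target"]), 1.0)

    d = comps["discretionary"]
    points["discretionary"] = _linear_reverse(
        _tag_serves(intake, d["tags"]), float(d["full_below"]), float(d["zero_at"]),
        float(d["max_points"]),
    )

    sat = comps["saturated_fat"]
    sat_pct = percent_energy(
        intake.nutrients_per_day.get("satfat_g", 0.0),
        intake.energy_kj_per_day,
        ENERGY_KJ_PER_G["satfat_g"],
    )
    points["saturated_fat"] = _linear_reverse(
        sat_pct, float(sat["full_below_pct_energy"]), float(sat["zero_at_pct_energy"]),
        float(sat["max_points"]),
    )

    sug = comps["added_sugar"]
    sug_pct = percent_energy(
        intake.nutrients_per_day.get("added_sugar_g", 0.0),
        intake.energy_kj_per_day,
        ENERGY_KJ_PER_G["added_sugar_g"],
    )
    points["added_sugar"] = _linear_reverse(
        sug_pct, float(sug["full_below_pct_energy"]), float(sug["zero_at_pct_energy"]),
        float(sug["max_points"]),
    )

    sod = comps["sodium"]
    points["sodium"] = _linear_reverse(
        intake.nutrients_per_day.get("sodium_mg", 0.0),
        float(sod["full_below_mg"]), float(sod["zero_at_mg"]), float(sod["max_points"]),
    )

    w = comps["water"]
    points["water"] = float(w["max_points"]) * min(water_frac / float(w["full_fraction"]), 1.0)

    a = comps["alcohol"]
    alc_serves = _tag_serves(intake, a["tags"])
    points["alcohol"] = float(a["max_points"]) if alc_serves <= float(a["max_serves_day"]) else 0.0

    return ScoreResult("heifa", points, float(cfg["scale_max"]))


# ---------------------------------------------------------------------------
# Mediterranean screeners


def _score_screener(
    resp: ScreenerResponse, block: Mapping, index_name: str, strict: bool
) -> ScoreResult:
    points: dict[str, float] = {}
    for crit in block["criteria"]:
        name = crit["name"]
        if name not in resp.answers:
            if strict:
                raise ScoreError(
                    f"{index_name}: participant {resp.participant_id!r} missing "
                    f"criterion {name!r}"
                )
            logger.warning(
                "%s: participant %s missing criterion %s, scored 0",
                index_name, resp.participant_id, name,
            )
            points[name] = 0.0
            continue
        value = resp.answers[name]
        kind = crit["kind"]
        if kind == "bool":
            met = bool(value)
        elif kind == "ge":
            met = float(value) >= float(crit["threshold"])
        else:  # lt
            met = float(value) < float(crit["threshold"])
        points[name] = 1.0 if met else 0.0
    return ScoreResult(index_name, points, float(block["scale_max"]))


def score_medas(
    resp: ScreenerResponse, config: Mapping | None = None, strict: bool = True
) -> ScoreResult:
    """14-item MEDAS: one point per adherence criterion met, composite 0-14."""
    cfg = (config or load_default_config())["medas"]
    return _score_screener(resp, cfg, "medas", strict)


def score_ermeddiet(
    resp: ScreenerResponse, config: Mapping | None = None, strict: bool = True
) -> ScoreResult:
    """17-item energy-restricted Mediterranean screener, composite 0-17."""
    cfg = (config or load_default_config())["ermeddiet"]
    return _score_screener(resp, cfg, "ermeddiet", strict)


# ---------------------------------------------------------------------------
# Screener derivation from FFQ intakes


def derive_screener(
    intake: DailyIntake,
    qualifiers: Mapping[str, str] | None = None,
) -> ScreenerResponse:
    """Build screener answers from quantified FFQ intake plus open-section flags.

    Weekly criteria use day-rate x 7.  Habit questions that the FFQ cannot
    quantify come from open-section qualifiers: ``cooking_fat`` (olive oil as
    main fat), ``sofrito_per_week``, ``sugar_in_tea_coffee``.  White-meat
    preference is derived as poultry serves exceeding red + processed meat.
    """
    quals = dict(qualifiers or {})
    s = intake.servings_per_day

    def serves(*tags: str) -> float:
        return float(sum(s.get(t, 0.0) for t in tags))

    answers: dict[str, float | bool] = {
        "olive_oil_main_fat": quals.get("cooking_fat", "") == "olive_oil",
        "olive_oil_tbsp_day": serves("oil_olive"),
        "vegetables_serves_day": serves("vegetable"),
        "fruit_serves_day": serves("fruit"),
        "red_processed_meat_serves_day": serves("red_meat", "processed_meat"),
        "butter_cream_serves_day": serves("butter"),
        "ssb_serves_day": serves("ssb"),
        "wine_glasses_week": serves("wine") * 7.0,
        "legumes_serves_week": serves("legume", "soy") * 7.0,
        "fish_serves_week": serves("fish") * 7.0,
        "commercial_sweets_week": serves("sweets") * 7.0,
        "nuts_serves_week": serves("nut_seed") * 7.0,
        "prefers_white_meat": serves("poultry") > serves("red_meat", "processed_meat"),
        "sofrito_week": float(quals.get("sofrito_per_week", 0.0)),
        "wholegrain_serves_day": serves("wholegrain"),
        "white_bread_serves_day": serves("white_bread"),
        "refined_rice_pasta_week": serves("refined_rice_pasta") * 7.0,
        "no_sugar_in_tea_coffee": quals.get("sugar_in_tea_coffee", "yes") == "no",
    }
    return ScreenerResponse(intake.participant_id, answers)
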