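"""Quantification of food-frequency-questionnaire (FFQ) responses.

Converts ordinal consumption frequencies into daily gram, serving, nutrient
and energy intakes using a food-composition table, in the style of the
EPIC-Norfolk FETA computation: for every item,

    grams/day = occasions/day x portion fraction x serving size (g)

Servings per food group divide grams by the item's standard serve; nutrients
accumulate from per-100 g densities.  The 9-point frequency scale runs from
"never or less than once a month" to "6+ per day"; the default multipliers
follow the EPIC convention and are configurable because instruments differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Occasions/day for frequency categories 1..9 (EPIC convention):
#: never/<1 per month, 1-3 per month, once a week, 2-4 per week, 5-6 per week,
#: once a day, 2-3 per day, 4-5 per day, 6+ per day.
DEFAULT_FREQUENCY_SCALE: dict[int, float] = {
    1: 0.0,
    2: 2.0 / 30.44,
    3: 1.0 / 7.0,
    4: 3.0 / 7.0,
    5: 5.5 / 7.0,
    6: 1.0,
    7: 2.5,
    8: 4.5,
    9: 6.0,
}

FREQUENCY_LABELS: dict[int, str] = {
    1: "never or less than once a month",
    2: "1-3 per month",
    3: "once a week",
    4: "2-4 per week",
    5: "5-6 per week",
    6: "once a day",
    7: "2-3 per day",
    8: "4-5 per day",
    9: "6+ per day",
}

#: Energy conversion factors, kJ per gram (Atwater-style).
ENERGY_KJ_PER_G: dict[str, float] = {
    "carbohydrate_g": 17.0,
    "protein_g": 17.0,
    "fat_g": 37.0,
    "satfat_g": 37.0,
    "mufa_g": 37.0,
    "pufa_g": 37.0,
    "added_sugar_g": 17.0,
    "alcohol_g": 29.0,
}

#: Canonical nutrient keys used throughout the package.
NUTRIENT_KEYS: tuple[str, ...] = (
    "energy_kj",
    "fat_g",
    "satfat_g",
    "mufa_g",
    "pufa_g",
    "carbohydrate_g",
    "added_sugar_g",
    "protein_g",
    "sodium_mg",
    "potassium_mg",
    "phosphorus_mg",
    "alcohol_g",
)


class FFQError(ValueError):
    """Domain error raised for invalid FFQ inputs or failed lookups."""


@dataclass(frozen=True)
class FoodItem:
    """One line item of the questionnaire with its composition data.

    Parameters
    ----------
    item_id
        Opaque unique identifier.
    name
        Human-readable name.
    group_tags
        Food-group memberships (an item may carry several, e.g. cheese is
        both ``dairy`` and ``discretionary``).
    serving_size_g
        Grams per standard serve; must be positive.
    nutrient_density
        Nutrient amounts per 100 g, keyed by :data:`NUTRIENT_KEYS`.
    portion_fractions
        Optional per-frequency-category portion multiplier (defaults to 1
        for categories not listed).
    """

    item_id: str
    name: str
    group_tags: frozenset[str]
    serving_size_g: float
    nutrient_density: Mapping[str, float] = field(default_factory=dict)
    portion_fractions: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.serving_size_g <= 0:
            raise FFQError(f"item {self.item_id!r}: serving_size_g must be > 0")
        if not self.group_tags:
            raise FFQError(f"item {self.item_id!r}: needs at least one group tag")
        for k, v in self.nutrient_density.items():
            if v < 0:
                raise FFQError(f"item {self.item_id!r}: negative density for {k}")
        object.__setattr__(self, "group_tags", frozenset(self.group_tags))

    def portion_fraction(self, category: int) -> float:
        return float(self.portion_fractions.get(category, 1.0))


class FoodCompositionTable:
    """Collection of :class:`FoodItem` keyed by item id.

    Unknown-id lookups raise :class:`FFQError` naming the item, never return
    a silent default.
    """

    def __init__(self, items: Iterable[FoodItem], provenance: str = "unspecified"):
        self.items: dict[str, FoodItem] = {}
        for it in items:
            if it.item_id in self.items:
                raise FFQError(f"duplicate item_id {it.item_id!r}")
            self.items[it.item_id] = it
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.items

    def __getitem__(self, item_id: str) -> FoodItem:
        try:
            return self.items[item_id]
        except KeyError:
            raise FFQError(
                f"item {item_id!r} not present in composition table "
                f"({self.provenance})"
            ) from None

    def items_with_tag(self, tag: str) -> list[FoodItem]:
        return [it for it in self.items.values() if tag in it.group_tags]

    # -- serialisation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items.values():
            row: dict[str, object] = {
                "item_id": it.item_id,
                "name": it.name,
                "tags": "|".join(sorted(it.group_tags)),
                "serving_size_g": it.serving_size_g,
            }
            for k in NUTRIENT_KEYS:
                row[f"{k}_100g"] = it.nutrient_density.get(k, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "FoodCompositionTable":
        df = pd.read_csv(path)
        required = {"item_id", "name", "tags", "serving_size_g"}
        missing = required - set(df.columns)
        if missing:
            raise FFQError(f"composition table missing columns: {sorted(missing)}")
        items = []
        for _, r in df.iterrows():
            density = {
                k: float(r[f"{k}_100g"])
                for k in NUTRIENT_KEYS
                if f"{k}_100g" in df.columns and pd.notna(r[f"{k}_100g"])
            }
            items.append(
                FoodItem(
                    item_id=str(r["item_id"]),
                    name=str(r["name"]),
                    group_tags=frozenset(str(r["tags"]).split("|")),
                    serving_size_g=float(r["serving_size_g"]),
                    nutrient_density=density,
                )
            )
        return cls(items, provenance=provenance or str(path))


@dataclass(frozen=True)
class FFQResponse:
    """One participant's frequency answer for one item."""

    participant_id: str
    item_id: str
    frequency_category: int

    def __post_init__(self) -> None:
        if not 1 <= int(self.frequency_category) <= 9:
            raise FFQError(
                f"participant {self.participant_id!r}, item {self.item_id!r}: "
                f"frequency category {self.frequency_category} outside 1..9"
            )


@dataclass
class DailyIntake:
    """Quantified per-day intake for one participant."""

    participant_id: str
    grams_per_day: dict[str, float] = field(default_factory=dict)
    servings_per_day: dict[str, float] = field(default_factory=dict)
    nutrients_per_day: dict[str, float] = field(default_factory=dict)
    energy_kj_per_day: float = 0.0


def validate_frequency_scale(scale: Mapping[int, float]) -> None:
    if set(scale) != set(range(1, 10)):
        raise FFQError("frequency scale must map exactly categories 1..9")
    prev = -1.0
    for cat in range(1, 10):
        v = float(scale[cat])
        if v < 0:
            raise FFQError(f"frequency multiplier for category {cat} is negative")
        if v < prev:
            raise FFQError("frequency multipliers must be non-decreasing in category")
        prev = v


def frequency_to_daily(category: int, scale: Mapping[int, float] | None = None) -> float:
    """Map an ordinal frequency category (1..9) to occasions per day."""
    scale = DEFAULT_FREQUENCY_SCALE if scale is None else scale
    validate_frequency_scale(scale)
    category = int(category)
    if category not in scale:
        raise FFQError(f"unknown frequency category {category}")
    return float(scale[category])


def apply_open_section(
    responses: Iterable[FFQResponse],
    qualifiers: Mapping[str, Mapping[str, str]],
    substitutions: Mapping[tuple[str, str], Mapping[str, str]],
    table: FoodCompositionTable,
) -> list[FFQResponse]:
    """Resolve open-section qualifiers by substituting item variants.

    ``qualifiers`` maps participant_id -> {qualifier: value} (e.g.
    ``{"p1": {"milk_type": "skim"}}``); ``substitutions`` maps
    (qualifier, value) -> {original item_id: replacement item_id}.  A matched
    qualifier swaps the responded item for its variant (e.g. generic milk for
    skim milk, changing the nutrient densities used downstream).  Unmatched
    qualifiers are logged and ignored.
    """
    responses = list(responses)
    answered: dict[str, set[str]] = {}
    for r in responses:
        answered.setdefault(r.participant_id, set()).add(r.item_id)
    known_qualifiers = {qual for qual, _ in substitutions}
    logged: set[tuple[str, str]] = set()
    out: list[FFQResponse] = []
    for resp in responses:
        quals = qualifiers.get(resp.participant_id, {})
        item_id = resp.item_id
        for qual, value in quals.items():
            mapping = substitutions.get((qual, str(value)))
            if mapping is None:
                # qualifiers outside the substitution vocabulary are consumed
                # elsewhere (screener derivation) and only logged at debug level
                key = (resp.participant_id, qual)
                if key not in logged:
                    logged.add(key)
                    level = logging.INFO if qual in known_qualifiers else logging.DEBUG
                    logger.log(
                        level,
                        "participant %s: unmatched open-section qualifier %s=%s (ignored)",
                        resp.participant_id, qual, value,
                    )
                continue
            if item_id in mapping:
                replacement = mapping[item_id]
                if replacement not in table:
                    logger.warning(
                        "participant %s: substitution %s -> %s not in table, kept original",
                        resp.participant_id, item_id, replacement,
                    )
                    continue
                if replacement in answered[resp.participant_id]:
                    logger.warning(
                        "participant %s: variant %s already answered, kept %s",
                        resp.participant_id, replacement, item_id,
                    )
                    continue
                item_id = replacement
        if item_id == resp.item_id:
            out.append(resp)
        else:
            out.append(
                FFQResponse(resp.participant_id, item_id, resp.frequency_category)
            )
    return out


def compute_gram_intake(
    responses: Iterable[FFQResponse],
    table: FoodCompositionTable,
    scale: Mapping[int, float] | None = None,
) -> DailyIntake:
    """Quantify grams/day per item from FFQ responses.

    Items never responded to contribute zero (missing response = zero intake).
    At most one response per (participant, item) is allowed, and all responses
    must belong to a single participant.
    """
    responses = list(responses)
    if not responses:
        raise FFQError("no responses supplied")
    pids = {r.participant_id for r in responses}
    if len(pids) > 1:
        raise FFQError(f"responses span multiple participants: {sorted(pids)}")
    seen: set[str] = set()
    grams: dict[str, float] = {}
    for resp in responses:
        if resp.item_id in seen:
            raise FFQError(
                f"participant {resp.participant_id!r}: duplicate response for "
                f"item {resp.item_id!r}"
            )
        seen.add(resp.item_id)
        item = table[resp.item_id]
        occ = frequency_to_daily(resp.frequency_category, scale)
        grams[resp.item_id] = (
            occ * item.portion_fraction(resp.frequency_category) * item.serving_size_g
        )
    return DailyIntake(participant_id=responses[0].participant_id, grams_per_day=grams)


def compute_servings(intake: DailyIntake, table: FoodCompositionTable) -> dict[str, float]:
    """Serves/day per food-group tag: sum of grams/serving over tagged items.

    Items carrying several tags contribute to every tag they bear.
    """
    serves: dict[str, float] = {}
    for item_id, g in intake.grams_per_day.items():
        item = table[item_id]
        s = g / item.serving_size_g
        for tag in item.group_tags:
            serves[tag] = serves.get(tag, 0.0) + s
    return serves


def compute_nutrients(
    intake: DailyIntake, table: FoodCompositionTable
) -> tuple[dict[str, float], float]:
    """Nutrients/day (per-100 g densities x grams/day) and energy kJ/day."""
    nutrients: dict[str, float] = {}
    for item_id, g in intake.grams_per_day.items():
        item = table[item_id]
        for k, dens in item.nutrient_density.items():
            nutrients[k] = nutrients.get(k, 0.0) + g * dens / 100.0
    energy = nutrients.get("energy_kj", 0.0)
    return nutrients, energy


def quantify(
    responses: Iterable[FFQResponse],
    table: FoodCompositionTable,
    scale: Mapping[int, float] | None = None,
) -> DailyIntake:
    """Full quantification: grams, servings, nutrients, energy in one pass."""
    intake = compute_gram_intake(responses, table, scale)
    intake.servings_per_day = compute_servings(intake, table)
    nutrients, energy = compute_nutrients(intake, table)
    intake.nutrients_per_day = nutrients
    intake.energy_kj_per_day = energy
    return intake


def percent_energy(
    grams_per_day: float, energy_kj_per_day: float, kj_per_g: float
) -> float:
    """Percent of total energy contributed by an energy-yielding nutrient."""
    if grams_per_day < 0:
        raise FFQError("nutrient intake must be non-negative")
    if energy_kj_per_day <= 0:
        raise FFQError("total energy must be positive to express %energy")
    return 100.0 * grams_per_day * kj_per_g / energy_kj_per_day


def read_ffq_csv(path: str | Path) -> dict[str, list[FFQResponse]]:
    """Read a long-format FFQ CSV (participant_id,item_id,frequency_category)."""
    df = pd.read_csv(path)
    required = {"participant_id", "item_id", "frequency_category"}
    missing = required - set(df.columns)
    if missing:
        raise FFQError(f"FFQ file missing columns: {sorted(missing)}")
    out: dict[str, list[FFQResponse]] = {}
    for _, r in df.iterrows():
        resp = FFQResponse(
            str(r["participant_id"]), str(r["item_id"]), int(r["frequency_category"])
        )
        out.setdefault(resp.participant_id, []).append(resp)
    return out


def read_open_section_csv(path: str | Path) -> dict[str, dict[str, str]]:
    """Read the open-section CSV (participant_id,qualifier,value)."""
    df = pd.read_csv(path)
    required = {"participant_id", "qualifier", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FFQError(f"open-section file missing columns: {sorted(missing)}")
    out: dict[str, dict[str, str]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["participant_id"]), {})[str(r["qualifier"])] = str(r["value"])
    return out
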