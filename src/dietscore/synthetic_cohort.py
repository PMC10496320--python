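"""Synthetic cohort generation.

Emulates the structure of a cross-sectional diet/inflammation study: ~100
adults at mixed cardiovascular risk recruited over two calendar years, each
with FFQ responses on a 9-point frequency scale, open-section qualifiers,
GPAQ activity answers, a 3-day beverage diary, anthropometry, triplicate
blood pressure and three inflammation biomarkers (hsCRP and PAF log-normal,
Lp-PLA2 Gaussian — matching the study's reporting of median/IQR for the
former and mean +- SD for the latter).

A latent diet-quality factor ``z`` per participant drives both the FFQ
response tendencies (higher z -> more fruit/vegetable/wholegrain/legume
occasions, fewer sweets/processed-meat occasions, via ordered-threshold
sampling) and the biomarkers, with configurable standardised effect sizes
(default -0.35 on log hsCRP, 0 on log PAF and Lp-PLA2).  Because the
biomarker equations are written on the standardised scale with unit total
variance, the configured effect is exactly the population standardised
regression coefficient of the latent factor, which parameter-recovery
checks can target directly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ffq_engine import DailyIntake, FoodCompositionTable, FoodItem
from .lifestyle import EnergyAssignment
from .scores import ScreenerResponse


class CohortError(ValueError):
    """Raised for invalid cohort configurations."""


# ---------------------------------------------------------------------------
# Synthetic food-composition fixture
#
# item_id, name, tags, serve g, per-100 g: energy kJ, fat, satfat, mufa, pufa,
# carb, added sugar, protein (g), sodium, potassium, phosphorus (mg), alcohol g
_ITEMS: list[tuple] = [
    ("apple", "Apple", "fruit", 150, 220, 0.2, 0, 0, 0.1, 12, 0, 0.3, 1, 110, 11, 0),
    ("banana", "Banana", "fruit", 120, 380, 0.3, 0.1, 0, 0.1, 21, 0, 1.1, 1, 360, 22, 0),
    ("orange", "Orange", "fruit", 130, 200, 0.1, 0, 0, 0, 9, 0, 0.9, 2, 180, 14, 0),
    ("orange_juice", "Orange juice", "fruit_juice", 250, 180, 0.1, 0, 0, 0, 9, 0, 0.6, 2, 180, 15, 0),
    ("broccoli", "Broccoli", "vegetable", 75, 140, 0.4, 0.1, 0, 0.1, 2, 0, 3.5, 20, 320, 70, 0),
    ("carrot", "Carrot", "vegetable", 75, 150, 0.2, 0, 0, 0.1, 7, 0, 0.8, 60, 240, 30, 0),
    ("spinach", "Spinach", "vegetable", 75, 100, 0.4, 0.1, 0, 0.2, 1, 0, 2.9, 70, 560, 50, 0),
    ("tomato", "Tomato", "vegetable", 75, 80, 0.2, 0, 0, 0.1, 3, 0, 0.9, 5, 240, 25, 0),
    ("capsicum", "Capsicum", "vegetable", 75, 110, 0.3, 0.1, 0, 0.1, 5, 0, 1.0, 3, 210, 25, 0),
    ("potato", "Potato, boiled", "potato", 150, 320, 0.1, 0, 0, 0, 17, 0, 2.0, 5, 380, 45, 0),
    ("lentils", "Lentils, cooked", "legume", 75, 420, 0.4, 0.1, 0.1, 0.2, 14, 0, 7.5, 2, 280, 120, 0),
    ("chickpeas", "Chickpeas, cooked", "legume", 75, 550, 2.6, 0.3, 0.6, 1.2, 17, 0, 7.2, 6, 230, 110, 0),
    ("tofu", "Tofu", "soy|legume", 100, 320, 4.5, 0.7, 1.0, 2.5, 1.5, 0, 8.0, 7, 120, 100, 0),
    ("almonds", "Almonds", "nut_seed", 30, 2500, 53, 4.0, 33, 13, 5, 0, 20, 1, 730, 480, 0),
    ("walnuts", "Walnuts", "nut_seed", 30, 2900, 65, 6.0, 9, 47, 3, 0, 14, 2, 440, 350, 0),
    ("milk_full", "Milk, full cream", "dairy", 250, 280, 3.8, 2.4, 1.0, 0.2, 5, 0, 3.3, 45, 150, 95, 0),
    ("milk_skim", "Milk, skim", "dairy|dairy_lowfat", 250, 150, 0.1, 0.1, 0, 0, 5, 0, 3.5, 45, 160, 100, 0),
    ("yoghurt_lowfat", "Yoghurt, low fat", "dairy|dairy_lowfat", 200, 240, 0.2, 0.1, 0, 0, 7, 0, 5.5, 60, 240, 150, 0),
    ("cheese", "Cheddar cheese", "dairy|discretionary", 40, 1700, 34, 22, 9, 1, 0.2, 0, 25, 650, 80, 520, 0),
    ("beef", "Beef, lean", "red_meat", 100, 800, 8, 3.3, 3.5, 0.4, 0, 0, 27, 55, 350, 210, 0),
    ("lamb", "Lamb", "red_meat", 100, 950, 13, 6.0, 5.2, 0.7, 0, 0, 25, 70, 310, 190, 0),
    ("bacon", "Bacon", "processed_meat|discretionary", 50, 1100, 19, 7.0, 8.5, 2.5, 0.5, 0, 22, 1500, 280, 200, 0),
    ("sausage", "Sausage", "processed_meat|discretionary", 70, 1200, 23, 9.5, 10, 2.8, 4, 0, 14, 800, 220, 140, 0),
    ("chicken", "Chicken breast", "poultry", 100, 650, 3.5, 1.0, 1.4, 0.8, 0, 0, 31, 60, 330, 220, 0),
    ("salmon", "Salmon", "fish", 100, 880, 13, 2.7, 5.0, 4.0, 0, 0, 22, 50, 380, 240, 0),
    ("white_fish", "White fish", "fish", 100, 420, 1.5, 0.4, 0.4, 0.5, 0, 0, 22, 80, 340, 200, 0),
    ("eggs", "Egg, boiled", "egg", 50, 580, 10, 3.2, 4.0, 1.5, 0.5, 0, 13, 135, 130, 180, 0),
    ("wholemeal_bread", "Wholemeal bread", "wholegrain|high_fibre_grain", 40, 1000, 3, 0.6, 0.7, 1.2, 40, 1, 10, 400, 230, 180, 0),
    ("oats", "Rolled oats", "wholegrain|high_fibre_grain", 40, 1600, 8, 1.4, 2.8, 3.0, 60, 0, 13, 3, 360, 420, 0),
    ("brown_rice", "Brown rice, cooked", "wholegrain", 75, 600, 1.1, 0.2, 0.4, 0.4, 30, 0, 3.0, 3, 90, 100, 0),
    ("white_bread", "White bread", "refined_grain|white_bread", 40, 1050, 2.5, 0.5, 0.5, 1.0, 46, 2, 9, 450, 120, 100, 0),
    ("white_rice", "White rice, cooked", "refined_grain|refined_rice_pasta", 75, 540, 0.3, 0.1, 0.1, 0.1, 28, 0, 2.7, 2, 35, 45, 0),
    ("pasta", "Pasta, cooked", "refined_grain|refined_rice_pasta", 75, 640, 0.9, 0.2, 0.1, 0.4, 29, 0, 5.5, 2, 60, 60, 0),
    ("chocolate", "Milk chocolate", "sweets|discretionary", 25, 2200, 30, 18, 9, 1, 57, 51, 7.5, 80, 420, 210, 0),
    ("cake", "Cake", "sweets|discretionary", 60, 1550, 17, 7.5, 6.5, 2.5, 50, 30, 5, 350, 110, 120, 0),
    ("biscuits", "Sweet biscuits", "sweets|discretionary", 25, 2000, 20, 10, 7, 2, 65, 28, 6, 400, 140, 110, 0),
    ("olive_oil", "Olive oil", "oil_olive", 14, 3700, 100, 14, 73, 10, 0, 0, 0, 0, 0, 0, 0),
    ("vegetable_oil", "Vegetable oil", "oil_vegetable", 14, 3700, 100, 12, 35, 48, 0, 0, 0, 0, 0, 0, 0),
    ("butter", "Butter", "butter|discretionary", 10, 3000, 81, 52, 21, 3, 0.6, 0, 0.7, 580, 25, 24, 0),
    ("soft_drink", "Soft drink", "ssb|discretionary", 375, 180, 0, 0, 0, 0, 11, 11, 0, 10, 1, 0, 0),
    ("wine", "Wine, red", "wine|alcohol", 150, 290, 0, 0, 0, 0, 0.3, 0, 0.1, 4, 110, 15, 10),
    ("beer", "Beer", "alcohol|discretionary", 375, 150, 0, 0, 0, 0, 1.5, 0, 0.4, 4, 35, 15, 3.8),
    ("water", "Water", "water_beverage", 250, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0),
]

_NUTRIENT_ORDER = (
    "energy_kj", "fat_g", "satfat_g", "mufa_g", "pufa_g", "carbohydrate_g",
    "added_sugar_g", "protein_g", "sodium_mg", "potassium_mg",
    "phosphorus_mg", "alcohol_g",
)

#: Latent-factor loading per item: +1 healthy, -1 unhealthy, 0 neutral.
HEALTH_WEIGHTS: dict[str, float] = {
    **{k: 1.0 for k in (
        "apple", "banana", "orange", "broccoli", "carrot", "spinach", "tomato",
        "capsicum", "lentils", "chickpeas", "tofu", "almonds", "walnuts",
        "wholemeal_bread", "oats", "brown_rice", "salmon", "white_fish",
        "olive_oil", "yoghurt_lowfat",
    )},
    **{k: -1.0 for k in (
        "bacon", "sausage", "chocolate", "cake", "biscuits", "soft_drink",
        "butter", "white_bread", "white_rice", "beef", "lamb", "beer",
    )},
}

#: Baseline frequency offsets (shift the typical response category).
_BASE_OFFSETS: dict[str, float] = {
    "milk_full": 1.0, "milk_skim": 1.0, "wholemeal_bread": 0.8,
    "white_bread": 0.8, "water": 1.5, "wine": -0.5, "beer": -0.5,
    "lamb": -0.5, "cake": -0.5, "tofu": -0.8, "orange_juice": -0.3,
}

#: Thresholds mapping the latent item propensity to frequency categories 1..9.
_CATEGORY_THRESHOLDS = np.array([-2.0, -1.2, -0.5, 0.2, 0.9, 1.5, 2.1, 2.7])

#: Item variants resolved only via the open section, never asked directly.
VARIANT_ONLY_ITEMS = frozenset({"milk_skim"})


def build_composition_table() -> FoodCompositionTable:
    """Synthetic food-composition fixture (AUSNUT-style schema, invented values)."""
    items = []
    for row in _ITEMS:
        item_id, name, tags, serve = row[0], row[1], row[2], row[3]
        density = dict(zip(_NUTRIENT_ORDER, (float(v) for v in row[4:])))
        items.append(
            FoodItem(
                item_id=item_id,
                name=name,
                group_tags=frozenset(tags.split("|")),
                serving_size_g=float(serve),
                nutrient_density=density,
            )
        )
    return FoodCompositionTable(items, provenance="dietscore synthetic fixture")


# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Generator settings; defaults mirror the emulated study conditions."""

    n: int = 100
    p_high_risk: float = 0.68
    p_year_2022: float = 0.54
    p_female: float = 0.69
    #: standardised effect of the latent diet factor on each biomarker
    effect_crp: float = -0.35
    effect_paf: float = 0.0
    effect_lppla2: float = 0.0
    #: standardised effect of female gender on Lp-PLA2 (males run higher)
    gender_effect_lppla2: float = -0.32
    #: standardised effect of 2022 collection on log PAF (off by default)
    year_effect_paf: float = 0.0
    #: nuisance structure on log hsCRP (age and risk-class effects)
    age_effect_crp: float = 0.15
    risk_effect_crp: float = 0.25
    risk_effect_paf: float = -0.30
    #: biomarker location/spread (log-normal for hsCRP/PAF, normal Lp-PLA2)
    hscrp_log_mean: float = math.log(0.96)
    hscrp_log_sd: float = 1.33
    paf_log_mean: float = math.log(7.96)
    paf_log_sd: float = 1.08
    lppla2_mean: float = 14.91
    lppla2_sd: float = 4.29
    #: strength of the latent-factor link into FFQ frequencies
    ffq_link: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n < 10:
            raise CohortError("n must be >= 10")
        for name in ("p_high_risk", "p_year_2022", "p_female"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise CohortError(f"{name} must lie in [0, 1]")
        for name in ("hscrp_log_sd", "paf_log_sd", "lppla2_sd", "ffq_link"):
            if getattr(self, name) <= 0:
                raise CohortError(f"{name} must be positive")
        for outcome, loads in self._loadings().items():
            total = sum(v * v for v in loads.values())
            if total >= 1:
                raise CohortError(
                    f"{outcome}: squared standardised effects sum to {total:.3f} >= 1"
                )

    def _loadings(self) -> dict[str, dict[str, float]]:
        return {
            "hscrp": {"diet": self.effect_crp, "age": self.age_effect_crp,
                      "risk": self.risk_effect_crp},
            "paf": {"diet": self.effect_paf, "risk": self.risk_effect_paf,
                    "year": self.year_effect_paf},
            "lppla2": {"diet": self.effect_lppla2,
                       "gender": self.gender_effect_lppla2},
        }

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class FlowLedger:
    """Participant flow: recruited minus ineligible minus declined."""

    recruited: int
    ineligible: int
    declined: int

    def __post_init__(self) -> None:
        if min(self.recruited, self.ineligible, self.declined) < 0:
            raise CohortError("flow counts must be non-negative")
        if self.ineligible + self.declined > self.recruited:
            raise CohortError(
                f"ineligible ({self.ineligible}) + declined ({self.declined}) "
                f"exceed recruited ({self.recruited})"
            )

    @property
    def analysed(self) -> int:
        return self.recruited - self.ineligible - self.declined


def generate_flow_ledger(recruited: int, ineligible: int, declined: int) -> FlowLedger:
    return FlowLedger(recruited, ineligible, declined)


# ---------------------------------------------------------------------------


def _standardise_binary(x: np.ndarray, p: float) -> np.ndarray:
    var = p * (1 - p)
    if var == 0:
        return np.zeros_like(x, dtype=float)
    return (x - p) / math.sqrt(var)


def generate_analysis_frame(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics, covariates and biomarkers for ``n`` participants.

    Biomarkers are built on the standardised scale with unit total variance,
    so each configured effect equals the population standardised regression
    coefficient of its predictor.  The latent diet factor is returned as
    ``diet_z`` so effect-recovery checks can regress on it directly.
    """
    config.validate()
    n = config.n
    pid = np.array([f"p{i+1:04d}" for i in range(n)])
    z = rng.standard_normal(n)
    female = (rng.random(n) < config.p_female).astype(int)
    year2022 = (rng.random(n) < config.p_year_2022).astype(int)
    high_risk = (rng.random(n) < config.p_high_risk).astype(int)
    age = rng.uniform(20, 69, n)

    age_z = (age - age.mean()) / age.std(ddof=1)
    risk_std = _standardise_binary(high_risk, config.p_high_risk)
    year_std = _standardise_binary(year2022, config.p_year_2022)
    female_std = _standardise_binary(female, config.p_female)

    def _residual_sd(loads: dict[str, float]) -> float:
        return math.sqrt(1.0 - sum(v * v for v in loads.values()))

    loads = config._loadings()
    crp_star = (
        loads["hscrp"]["diet"] * z
        + loads["hscrp"]["age"] * age_z
        + loads["hscrp"]["risk"] * risk_std
        + _residual_sd(loads["hscrp"]) * rng.standard_normal(n)
    )
    paf_star = (
        loads["paf"]["diet"] * z
        + loads["paf"]["risk"] * risk_std
        + loads["paf"]["year"] * year_std
        + _residual_sd(loads["paf"]) * rng.standard_normal(n)
    )
    lppla2_star = (
        loads["lppla2"]["diet"] * z
        + loads["lppla2"]["gender"] * female_std
        + _residual_sd(loads["lppla2"]) * rng.standard_normal(n)
    )

    hscrp = np.exp(config.hscrp_log_mean + config.hscrp_log_sd * crp_star)
    paf = np.exp(config.paf_log_mean + config.paf_log_sd * paf_star)
    lppla2 = config.lppla2_mean + config.lppla2_sd * lppla2_star

    height = np.where(
        female == 1, rng.normal(1.62, 0.07, n), rng.normal(1.76, 0.08, n)
    ).round(2)
    bmi_draw = np.clip(rng.normal(28.3, 6.5, n), 18.0, 55.0)
    weight = (bmi_draw * height**2).round(1)
    waist = np.clip(
        rng.normal(88.0, 11.0, n) + 11.0 * high_risk, 55.0, 160.0
    ).round(1)

    # triplicate BP; the first reading runs high (familiarisation effect)
    sbp_true = rng.normal(125, 14, n)
    dbp_true = rng.normal(78, 9, n)
    sbp = {f"sbp{i}": (sbp_true + (8.0 if i == 1 else 0.0)
                       + rng.normal(0, 4, n)).round(0) for i in (1, 2, 3)}
    dbp = {f"dbp{i}": (dbp_true + (4.0 if i == 1 else 0.0)
                       + rng.normal(0, 3, n)).round(0) for i in (1, 2, 3)}

    # GPAQ: draw a target tertile (low/moderate/high ~ 20/19/61%) and place
    # the MET minutes in moderate recreation
    tertile = rng.choice([0, 1, 2], size=n, p=[0.20, 0.19, 0.61])
    met = np.where(
        tertile == 0, rng.uniform(0, 599, n),
        np.where(tertile == 1, rng.uniform(600, 1499, n), rng.uniform(1500, 4200, n)),
    )
    mod_rec_days = np.full(n, 5.0)
    mod_rec_min = np.round(met / (mod_rec_days * 4.0), 0)
    mod_rec_min = np.clip(mod_rec_min, 0, 960)

    total_bev = np.clip(rng.normal(2000, 350, (n, 3)), 600, None).round(0)
    frac = np.clip(0.5 + 0.08 * z[:, None] + rng.normal(0, 0.12, (n, 3)), 0.02, 0.98)
    water = (frac * total_bev).round(0)

    df = pd.DataFrame({
        "participant_id": pid,
        "age": age.round(0).astype(int),
        "sex": np.where(female == 1, "female", "male"),
        "height_m": height,
        "weight_kg": weight,
        "waist_cm": waist,
        **sbp, **dbp,
        "gpaq_vig_work_days": 0.0, "gpaq_vig_work_min": 0.0,
        "gpaq_mod_work_days": 0.0, "gpaq_mod_work_min": 0.0,
        "gpaq_travel_days": 0.0, "gpaq_travel_min": 0.0,
        "gpaq_vig_rec_days": 0.0, "gpaq_vig_rec_min": 0.0,
        "gpaq_mod_rec_days": mod_rec_days, "gpaq_mod_rec_min": mod_rec_min,
        "water_d1": water[:, 0], "water_d2": water[:, 1], "water_d3": water[:, 2],
        "total_d1": total_bev[:, 0], "total_d2": total_bev[:, 1], "total_d3": total_bev[:, 2],
        "hscrp": hscrp.round(4),
        "paf": paf.round(4),
        "lppla2": lppla2.round(4),
        "cvd_risk": np.where(high_risk == 1, "high", "low"),
        "year": np.where(year2022 == 1, 2022, 2021),
        "diet_z": z.round(6),
    })
    return df


def _generate_ffq(
    config: CohortConfig,
    rng: np.random.Generator,
    pids: np.ndarray,
    z: np.ndarray,
    table: FoodCompositionTable,
) -> pd.DataFrame:
    """Ordered-threshold sampling of frequency categories from the latent factor."""
    item_ids = [i for i in table.items if i not in VARIANT_ONLY_ITEMS]
    weights = np.array([HEALTH_WEIGHTS.get(i, 0.0) for i in item_ids])
    offsets = np.array([_BASE_OFFSETS.get(i, 0.0) for i in item_ids])
    n, k = len(pids), len(item_ids)
    propensity = (
        config.ffq_link * np.outer(z, weights)
        + offsets[None, :]
        + rng.standard_normal((n, k))
    )
    cats = np.searchsorted(_CATEGORY_THRESHOLDS, propensity) + 1
    return pd.DataFrame({
        "participant_id": np.repeat(pids, k),
        "item_id": np.tile(item_ids, n),
        "frequency_category": cats.ravel().astype(int),
    })


def _generate_open_section(
    rng: np.random.Generator, pids: np.ndarray, z: np.ndarray
) -> pd.DataFrame:
    n = len(pids)
    olive = (z + rng.standard_normal(n) * 0.8) > 0
    skim = (z + rng.standard_normal(n) * 0.8) > 0
    no_sugar = (z + rng.standard_normal(n) * 0.8) > 0
    sofrito = np.clip(np.round(1.0 + z + rng.standard_normal(n)), 0, 7)
    b12 = rng.random(n) < 0.9
    rows = []
    for i, pid in enumerate(pids):
        rows.extend([
            (pid, "cooking_fat", "olive_oil" if olive[i] else "vegetable_oil"),
            (pid, "milk_type", "skim" if skim[i] else "full"),
            (pid, "sugar_in_tea_coffee", "no" if no_sugar[i] else "yes"),
            (pid, "sofrito_per_week", str(int(sofrito[i]))),
            (pid, "b12_source", "yes" if b12[i] else "no"),
        ])
    return pd.DataFrame(rows, columns=["participant_id", "qualifier", "value"])


@dataclass
class Cohort:
    """One generated cohort: input tables plus the composition fixture."""

    config: CohortConfig
    covariates: pd.DataFrame
    ffq: pd.DataFrame
    open_section: pd.DataFrame
    table: FoodCompositionTable

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the full input file set plus a manifest; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "covariates": out / "covariates.csv",
            "ffq": out / "ffq.csv",
            "open_section": out / "open_section.csv",
            "composition": out / "composition.csv",
            "manifest": out / "manifest.json",
        }
        self.covariates.to_csv(paths["covariates"], index=False, float_format="%.6g")
        self.ffq.to_csv(paths["ffq"], index=False)
        self.open_section.to_csv(paths["open_section"], index=False)
        self.table.to_csv(paths["composition"])
        manifest = {
            "seed": self.config.seed,
            "n": self.config.n,
            "config_hash": self.config.config_hash(),
            "config": asdict(self.config),
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return paths


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a complete synthetic input set; reproducible given the seed."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    covariates = generate_analysis_frame(config, rng)
    table = build_composition_table()
    pids = covariates["participant_id"].to_numpy()
    z = covariates["diet_z"].to_numpy(float)
    ffq = _generate_ffq(config, rng, pids, z, table)
    open_section = _generate_open_section(rng, pids, z)
    return Cohort(config, covariates, ffq, open_section, table)


# ---------------------------------------------------------------------------
# Full-adherence profiles (harness for the printed scale maxima)


def generate_full_adherence_profile(index_name: str) -> dict:
    """Inputs that reach exactly the index's scale maximum under defaults."""
    table = build_composition_table()
    if index_name in ("dash", "dash_dairy_adj"):
        energy = EnergyAssignment(
            bmr_kj=8368.0 / 1.6, pa_factor=1.6, eer_kj=8368.0, dash_level_kcal=2000
        )
        intake = DailyIntake(
            participant_id="full_dash",
            servings_per_day={
                "fruit": 4.5, "vegetable": 4.5,
                "red_meat": 1.0, "fish": 0.5, "poultry": 0.5,
                "nut_seed": 0.5, "legume": 0.5,
                "oil_olive": 2.0, "sweets": 0.0,
                "dairy": 2.0, "dairy_lowfat": 1.6,
                "wholegrain": 4.0, "high_fibre_grain": 2.0,
            },
        )
        return {"intake": intake, "energy": energy,
                "dairy_adjusted": index_name == "dash_dairy_adj"}
    if index_name == "vegetarian":
        intake = DailyIntake(
            participant_id="full_veg",
            servings_per_day={
                "wholegrain": 3.0, "legume": 1.0, "soy": 0.5,
                "vegetable": 3.0, "fruit": 2.0, "nut_seed": 1.0,
                "oil_olive": 1.0, "dairy": 0.0, "egg": 0.0, "sweets": 0.0,
            },
        )
        return {"intake": intake, "eer_kj": 8368.0, "activity_category": 2,
                "water_fraction": 0.6, "b12_source": True, "sunlight": True}
    if index_name == "heifa":
        serves = {
            "broccoli": 1.0, "carrot": 1.0, "spinach": 1.0, "tomato": 1.0,
            "capsicum": 1.0,                     # 5 veg serves, 5 distinct
            "apple": 1.0, "banana": 1.0,          # 2 fruit serves, 2 distinct
            "wholemeal_bread": 2.0, "oats": 2.0, "brown_rice": 2.0,  # 6 grain, all whole
            "milk_skim": 1.5, "yoghurt_lowfat": 1.0,                 # 2.5 dairy
            "salmon": 1.5, "lentils": 1.0,                           # 2.5 meat/alt
        }
        grams = {k: v * table[k].serving_size_g for k, v in serves.items()}
        intake = DailyIntake(participant_id="full_heifa", grams_per_day=grams)
        from .ffq_engine import compute_servings
        intake.servings_per_day = compute_servings(intake, table)
        # nutrient totals set directly, below every cut-off at 8000 kJ
        intake.nutrients_per_day = {
            "satfat_g": 10.0, "added_sugar_g": 20.0, "sodium_mg": 800.0,
            "energy_kj": 8000.0,
        }
        intake.energy_kj_per_day = 8000.0
        return {"intake": intake, "table": table, "water_fraction": 0.6}
    if index_name in ("medas", "ermeddiet"):
        answers: dict[str, float | bool] = {
            "olive_oil_main_fat": True, "olive_oil_tbsp_day": 4.0,
            "vegetables_serves_day": 2.0, "fruit_serves_day": 3.0,
            "red_processed_meat_serves_day": 0.0, "butter_cream_serves_day": 0.0,
            "ssb_serves_day": 0.0, "wine_glasses_week": 7.0,
            "legumes_serves_week": 3.0, "fish_serves_week": 3.0,
            "commercial_sweets_week": 0.0, "nuts_serves_week": 3.0,
            "prefers_white_meat": True, "sofrito_week": 2.0,
            "wholegrain_serves_day": 2.0, "white_bread_serves_day": 0.0,
            "refined_rice_pasta_week": 0.0, "no_sugar_in_tea_coffee": True,
        }
        return {"response": ScreenerResponse("full_med", answers)}
    raise CohortError(f"unknown index {index_name!r}")
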