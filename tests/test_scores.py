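"""Diet-quality index scoring: component rules, bounds, monotonicity."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dietscore import scores
from dietscore.ffq_engine import DailyIntake
from dietscore.lifestyle import EnergyAssignment
from dietscore.scores import ScoreError, ScreenerResponse
from dietscore.synthetic_cohort import generate_full_adherence_profile

ENERGY_2000 = EnergyAssignment(
    bmr_kj=8368.0 / 1.6, pa_factor=1.6, eer_kj=8368.0, dash_level_kcal=2000
)

DASH_TAGS = [
    "fruit", "fruit_juice", "vegetable", "potato", "red_meat", "processed_meat",
    "poultry", "fish", "egg", "nut_seed", "legume", "soy", "oil_olive",
    "oil_vegetable", "butter", "sweets", "dairy", "wholegrain",
    "high_fibre_grain", "refined_grain", "ssb", "wine", "alcohol",
]

serving_maps = st.fixed_dictionaries(
    {tag: st.floats(0.0, 8.0, allow_nan=False) for tag in DASH_TAGS}
)


def random_intake(serves: dict) -> DailyIntake:
    serves = dict(serves)
    # keep the low-fat dairy sub-group within total dairy
    serves["dairy_lowfat"] = 0.5 * serves.get("dairy", 0.0)
    return DailyIntake("px", servings_per_day=serves)


class TestProportionalPoints:
    def test_forward_zero_intake(self):
        assert scores.proportional_points(0.0, 4.0, 10, "forward") == 0.0

    def test_forward_at_target_is_max(self):
        assert scores.proportional_points(4.0, 4.0, 10, "forward") == 10.0

    def test_forward_caps_above_target(self):
        assert scores.proportional_points(9.0, 4.0, 10, "forward") == 10.0

    def test_reverse_double_target_halves_points(self):
        assert scores.proportional_points(4.0, 2.0, 10, "reverse") == pytest.approx(5.0)

    def test_reverse_at_or_below_target_is_max(self):
        assert scores.proportional_points(1.0, 2.0, 10, "reverse") == 10.0

    def test_invalid_inputs(self):
        with pytest.raises(ScoreError):
            scores.proportional_points(1.0, 0.0, 10, "forward")
        with pytest.raises(ScoreError):
            scores.proportional_points(-1.0, 2.0, 10, "forward")


class TestDash:
    def test_full_adherence_reaches_80(self, score_config):
        prof = generate_full_adherence_profile("dash")
        res = scores.score_dash(prof["intake"], prof["energy"], score_config)
        assert res.composite == pytest.approx(80.0)

    def test_empty_diet_scores_reverse_maxima(self, score_config):
        """With nothing eaten only the three reverse components score: 30."""
        res = scores.score_dash(DailyIntake("p0"), ENERGY_2000, score_config)
        assert res.composite == pytest.approx(30.0)
        assert res.component_points["meat_poultry_fish_eggs"] == 10.0
        assert res.component_points["fats_oils"] == 10.0
        assert res.component_points["sweets"] == 10.0
        assert res.component_points["lowfat_dairy_share"] == 0.0

    def test_missing_energy_assignment_rejected(self, score_config):
        with pytest.raises(ScoreError):
            scores.score_dash(DailyIntake("p0"), None, score_config)

    def test_lowfat_share_rule(self, score_config):
        base = {"dairy": 2.0, "dairy_lowfat": 1.5}
        res = scores.score_dash(
            DailyIntake("p", servings_per_day=base), ENERGY_2000, score_config
        )
        assert res.component_points["lowfat_dairy_share"] == pytest.approx(5.0)
        half = {"dairy": 2.0, "dairy_lowfat": 0.75}
        res2 = scores.score_dash(
            DailyIntake("p", servings_per_day=half), ENERGY_2000, score_config
        )
        assert res2.component_points["lowfat_dairy_share"] == pytest.approx(2.5)

    @given(serves=serving_maps)
    def test_dairy_adjusted_dominates(self, score_config, serves):
        intake = random_intake(serves)
        plain = scores.score_dash(intake, ENERGY_2000, score_config)
        adj = scores.score_dash(intake, ENERGY_2000, score_config, dairy_adjusted=True)
        assert adj.composite >= plain.composite - 1e-9
        met = plain.component_points["lowfat_dairy_share"] == pytest.approx(5.0)
        if met:
            assert adj.composite == pytest.approx(plain.composite)
        else:
            assert adj.composite > plain.composite

    @given(serves=serving_maps, delta=st.floats(0.0, 5.0))
    def test_monotone_components(self, score_config, serves, delta):
        """More of a forward food never lowers DASH; more sweets never raises it."""
        intake = random_intake(serves)
        base = scores.score_dash(intake, ENERGY_2000, score_config).composite
        up_fruit = dict(serves)
        up_fruit["fruit"] = up_fruit["fruit"] + delta
        more_fruit = scores.score_dash(
            random_intake(up_fruit), ENERGY_2000, score_config
        ).composite
        assert more_fruit >= base - 1e-9
        up_sweets = dict(serves)
        up_sweets["sweets"] = up_sweets["sweets"] + delta
        more_sweets = scores.score_dash(
            random_intake(up_sweets), ENERGY_2000, score_config
        ).composite
        assert more_sweets <= base + 1e-9

    @given(serves=serving_maps)
    def test_bounds(self, score_config, serves):
        res = scores.score_dash(random_intake(serves), ENERGY_2000, score_config)
        assert 0.0 <= res.composite <= 80.0
        for name, pts in res.component_points.items():
            assert pts >= 0.0


class TestVegetarian:
    def test_full_adherence_reaches_14(self, score_config):
        prof = generate_full_adherence_profile("vegetarian")
        res = scores.score_vegetarian(
            prof["intake"], prof["eer_kj"], prof["activity_category"],
            prof["water_fraction"], prof["b12_source"], prof["sunlight"],
            score_config,
        )
        assert res.composite == pytest.approx(14.0)

    @given(serves=serving_maps, eer=st.floats(6000, 14000),
           cat=st.integers(0, 2), wf=st.floats(0, 1), b12=st.booleans())
    def test_codomain_and_bounds(self, score_config, serves, eer, cat, wf, b12):
        res = scores.score_vegetarian(
            random_intake(serves), eer, cat, wf, b12, config=score_config
        )
        assert 0.0 <= res.composite <= 14.0
        for name, pts in res.component_points.items():
            assert pts in (0.0, 0.5, 1.0)
        # sunlight gets full marks under the default rule
        assert res.component_points["sunlight"] == 1.0

    @given(serves=serving_maps, eer=st.floats(6000, 12000))
    def test_energy_scale_invariance(self, score_config, serves, eer):
        """Doubling intake and energy requirement together leaves the score fixed."""
        intake = random_intake(serves)
        doubled = DailyIntake(
            "px", servings_per_day={k: 2 * v for k, v in intake.servings_per_day.items()}
        )
        a = scores.score_vegetarian(intake, eer, 1, 0.4, True, config=score_config)
        b = scores.score_vegetarian(doubled, 2 * eer, 1, 0.4, True, config=score_config)
        assert a.composite == pytest.approx(b.composite)

    def test_invalid_inputs(self, score_config):
        with pytest.raises(ScoreError):
            scores.score_vegetarian(DailyIntake("p"), 0.0, 1, 0.5, True)
        with pytest.raises(ScoreError):
            scores.score_vegetarian(DailyIntake("p"), 8368.0, 7, 0.5, True)
        with pytest.raises(ScoreError):
            scores.score_vegetarian(DailyIntake("p"), 8368.0, 1, 1.5, True)


class TestHeifa:
    def test_full_adherence_reaches_100(self, score_config):
        prof = generate_full_adherence_profile("heifa")
        res = scores.score_heifa(
            prof["intake"], prof["table"], prof["water_fraction"], score_config
        )
        assert res.composite == pytest.approx(100.0)

    @pytest.mark.parametrize("satfat_pct,expected", [
        (9.9, 10.0),    # below 10 %E: full score
        (15.0, 0.0),    # at 15 %E: zero
        (12.5, 5.0),    # midway: linear interpolation
    ])
    def test_saturated_fat_percent_energy_rule(
        self, score_config, synthetic_table, satfat_pct, expected
    ):
        energy = 8000.0
        satfat_g = satfat_pct * energy / (100 * 37.0)
        intake = DailyIntake(
            "p", nutrients_per_day={"satfat_g": satfat_g, "energy_kj": energy},
            energy_kj_per_day=energy,
        )
        res = scores.score_heifa(intake, synthetic_table, 0.5, score_config)
        assert res.component_points["saturated_fat"] == pytest.approx(expected)

    def test_water_rule(self, score_config, synthetic_table):
        intake = DailyIntake("p", nutrients_per_day={"energy_kj": 8000.0},
                             energy_kj_per_day=8000.0)
        full = scores.score_heifa(intake, synthetic_table, 0.5, score_config)
        assert full.component_points["water"] == pytest.approx(5.0)
        half = scores.score_heifa(intake, synthetic_table, 0.25, score_config)
        assert half.component_points["water"] == pytest.approx(2.5)

    def test_zero_energy_rejected(self, score_config, synthetic_table):
        with pytest.raises(ScoreError):
            scores.score_heifa(DailyIntake("p"), synthetic_table, 0.5, score_config)

    @given(serves=serving_maps, wf=st.floats(0, 1),
           satfat=st.floats(0, 80), sugar=st.floats(0, 150),
           sodium=st.floats(0, 5000))
    def test_bounds(self, score_config, synthetic_table, serves, wf, satfat,
                    sugar, sodium):
        intake = random_intake(serves)
        intake.nutrients_per_day = {
            "satfat_g": satfat, "added_sugar_g": sugar, "sodium_mg": sodium,
            "energy_kj": 9000.0,
        }
        intake.energy_kj_per_day = 9000.0
        res = scores.score_heifa(intake, synthetic_table, wf, score_config)
        assert 0.0 <= res.composite <= 100.0


def _answers_for_pattern(criteria, pattern):
    """Construct answers meeting exactly the criteria flagged in pattern."""
    answers = {}
    for crit, met in zip(criteria, pattern):
        kind = crit["kind"]
        if kind == "bool":
            answers[crit["name"]] = bool(met)
        elif kind == "ge":
            thr = float(crit["threshold"])
            answers[crit["name"]] = thr if met else max(thr - 1.0, 0.0)
        else:  # lt
            thr = float(crit["threshold"])
            answers[crit["name"]] = max(thr - 1.0, 0.0) if met else thr
    return answers


class TestScreeners:
    def test_medas_full_and_zero(self, score_config):
        criteria = score_config["medas"]["criteria"]
        full = ScreenerResponse("p", _answers_for_pattern(criteria, [1] * 14))
        assert scores.score_medas(full, score_config).composite == 14.0
        none = ScreenerResponse("p", _answers_for_pattern(criteria, [0] * 14))
        assert scores.score_medas(none, score_config).composite == 0.0

    def test_ermeddiet_full_and_zero(self, score_config):
        criteria = score_config["ermeddiet"]["criteria"]
        full = ScreenerResponse("p", _answers_for_pattern(criteria, [1] * 17))
        assert scores.score_ermeddiet(full, score_config).composite == 17.0
        none = ScreenerResponse("p", _answers_for_pattern(criteria, [0] * 17))
        assert scores.score_ermeddiet(none, score_config).composite == 0.0

    def test_medas_counts_met_criteria_exactly(self, score_config, rng):
        """Composite equals the bit count for sampled adherence patterns."""
        criteria = score_config["medas"]["criteria"]
        patterns = [rng.integers(0, 2, size=14) for _ in range(200)]
        patterns += list(itertools.islice(itertools.product([0, 1], repeat=14), 40))
        for pattern in patterns:
            resp = ScreenerResponse("p", _answers_for_pattern(criteria, pattern))
            assert scores.score_medas(resp, score_config).composite == sum(pattern)

    def test_shared_criteria_agree_between_screeners(self, score_config, rng):
        """MEDAS and erMedDiet award identical points on their shared items."""
        med_names = {c["name"] for c in score_config["medas"]["criteria"]}
        er_names = {c["name"] for c in score_config["ermeddiet"]["criteria"]}
        shared = med_names & er_names
        assert len(shared) == 13
        er_criteria = score_config["ermeddiet"]["criteria"]
        for _ in range(50):
            pattern = rng.integers(0, 2, size=17)
            answers = _answers_for_pattern(er_criteria, pattern)
            # give MEDAS its extra (olive-oil quantity) answer too
            answers.setdefault("olive_oil_tbsp_day", 4.0)
            resp = ScreenerResponse("p", answers)
            med = scores.score_medas(resp, score_config)
            er = scores.score_ermeddiet(resp, score_config)
            for name in shared:
                assert med.component_points[name] == er.component_points[name]

    def test_missing_criterion_strict_vs_lenient(self, score_config):
        resp = ScreenerResponse("p", {"olive_oil_main_fat": True})
        with pytest.raises(ScoreError, match="missing"):
            scores.score_medas(resp, score_config, strict=True)
        lenient = scores.score_medas(resp, score_config, strict=False)
        assert lenient.composite == 1.0


class TestDeriveScreener:
    def test_weekly_rates_and_habit_flags(self, synthetic_table):
        from dietscore.ffq_engine import DailyIntake
        intake = DailyIntake(
            "p",
            servings_per_day={
                "fish": 0.5, "legume": 0.6, "vegetable": 2.5, "fruit": 3.0,
                "poultry": 1.0, "red_meat": 0.2, "processed_meat": 0.1,
                "oil_olive": 4.0, "wine": 1.0, "nut_seed": 0.5, "sweets": 0.2,
            },
        )
        resp = scores.derive_screener(
            intake, {"cooking_fat": "olive_oil", "sofrito_per_week": "3"}
        )
        assert resp.answers["fish_serves_week"] == pytest.approx(3.5)
        assert resp.answers["legumes_serves_week"] == pytest.approx(4.2)
        assert resp.answers["olive_oil_main_fat"] is True
        assert resp.answers["prefers_white_meat"] is True
        assert resp.answers["sofrito_week"] == pytest.approx(3.0)
        assert resp.answers["wine_glasses_week"] == pytest.approx(7.0)


class TestConfigValidation:
    def test_criteria_count_must_match_scale(self, score_config):
        import copy
        bad = copy.deepcopy(score_config)
        bad["medas"]["criteria"] = bad["medas"]["criteria"][:-1]
        with pytest.raises(ScoreError):
            scores.validate_config(bad)

    def test_score_result_rejects_overflow(self):
        with pytest.raises(ScoreError):
            scores.ScoreResult("dash", {"a": 90.0}, 80.0)
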