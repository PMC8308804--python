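"""FFQ conversion, nutrient totals and the derived clinical formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from upfharmony import (
    DomainError,
    FoodCompositionTable,
    FrequencyScale,
    ValidationError,
    bmi,
    friedewald_ldl,
    glycemic_index,
    grams_per_day,
    nutrient_intake,
    percent_energy,
)
from upfharmony.errors import MissingItemError
from upfharmony.ffq import NUTRIENT_COLUMNS, finalize_profile


def make_comp(rows):
    frame = pd.DataFrame(rows, columns=["item_id", *NUTRIENT_COLUMNS])
    return FoodCompositionTable(frame.set_index("item_id"))


@pytest.fixture()
def two_item_comp():
    # item, energy, protein, fat, sfa, mufa, pufa, carb, fiber, sugars,
    # sodium, omega3, gl
    return make_comp([
        ("a", 100.0, 5.0, 2.0, 0.5, 1.0, 0.5, 15.0, 2.0, 5.0, 50.0, 0.1, 6.0),
        ("b", 300.0, 10.0, 20.0, 8.0, 9.0, 3.0, 20.0, 1.0, 10.0, 400.0, 0.0,
         12.0),
    ])


class TestFrequencyScale:
    def test_default_is_valid_and_anchored_at_zero(self):
        scale = FrequencyScale()
        assert scale.multipliers[0] == 0.0
        assert all(b > a for a, b in zip(scale.multipliers,
                                         scale.multipliers[1:]))

    def test_rejects_nonzero_never_category(self):
        with pytest.raises(ValidationError):
            FrequencyScale(multipliers=(0.1, 0.2, 0.3, 0.4, 0.5, 1, 2, 3, 4))

    def test_rejects_non_increasing(self):
        with pytest.raises(ValidationError):
            FrequencyScale(multipliers=(0, 0.5, 0.4, 0.6, 0.7, 1, 2, 3, 4))

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        scale = FrequencyScale()
        path = tmp_path / "scale.yaml"
        path.write_text(yaml.safe_dump({
            "labels": list(scale.labels),
            "multipliers": [float(m) for m in scale.multipliers]}))
        assert FrequencyScale.from_yaml(path) == scale


class TestGramsPerDay:
    @pytest.mark.parametrize("category, portion, expected", [
        (1, 500.0, 0.0),            # never -> zero regardless of portion
        (6, 200.0, 200.0),          # once per day
        (4, 70.0, 30.0),            # 2-4/week midpoint: 70 x 3/7
    ])
    def test_hand_products(self, category, portion, expected):
        assert grams_per_day(category, portion) == pytest.approx(
            expected, abs=1e-12)

    def test_monotone_in_category(self):
        values = grams_per_day(np.arange(1, 10), np.full(9, 80.0))
        assert np.all(np.diff(values) > 0)

    def test_unknown_category_rejected(self):
        with pytest.raises(DomainError):
            grams_per_day(np.array([3, 10]), np.array([50.0, 50.0]))


class TestNutrientIntake:
    def test_zero_intake_gives_zero_totals(self, two_item_comp):
        intake = pd.DataFrame(0.0, index=["p1"], columns=["a", "b"])
        totals = nutrient_intake(intake, two_item_comp)
        assert (totals.loc["p1"] == 0).all()

    def test_identity_at_100g(self, two_item_comp):
        intake = pd.DataFrame([[100.0, 0.0]], index=["p1"],
                              columns=["a", "b"])
        totals = nutrient_intake(intake, two_item_comp)
        expected = two_item_comp.frame.loc["a"]
        for col in NUTRIENT_COLUMNS:
            assert totals.loc["p1", col] == pytest.approx(expected[col])
        assert totals.loc["p1", "total_g"] == 100.0

    def test_two_items_at_50g_each_average_the_rows(self, two_item_comp):
        intake = pd.DataFrame([[50.0, 50.0]], index=["p1"],
                              columns=["a", "b"])
        totals = nutrient_intake(intake, two_item_comp)
        mean_row = two_item_comp.frame.loc[["a", "b"]].mean()
        for col in NUTRIENT_COLUMNS:
            assert totals.loc["p1", col] == pytest.approx(mean_row[col])

    def test_missing_item_listed(self, two_item_comp):
        intake = pd.DataFrame([[10.0, 10.0]], index=["p1"],
                              columns=["a", "zz"])
        with pytest.raises(MissingItemError, match="zz"):
            nutrient_intake(intake, two_item_comp)

    def test_fatty_acid_consistency_enforced(self):
        with pytest.raises(ValidationError, match="fat"):
            make_comp([("a", 100.0, 5.0, 2.0, 1.5, 1.0, 0.5, 15.0, 2.0,
                        5.0, 50.0, 0.1, 6.0)])


class TestDerivedQuantities:
    def test_percent_energy_hand_value(self):
        profile = pd.DataFrame({"energy_kcal": [2000.0],
                                "protein_g": [100.0], "fat_g": [0.0],
                                "sfa_g": [0.0], "mufa_g": [0.0],
                                "pufa_g": [0.0], "carb_g": [0.0]})
        out = percent_energy(profile)
        assert out["pct_protein"].iloc[0] == pytest.approx(20.0, abs=1e-9)
        assert out["pct_fat"].iloc[0] == 0.0

    def test_pure_carbohydrate_diet_is_100_percent_energy(self):
        profile = pd.DataFrame({"energy_kcal": [800.0], "protein_g": [0.0],
                                "fat_g": [0.0], "sfa_g": [0.0],
                                "mufa_g": [0.0], "pufa_g": [0.0],
                                "carb_g": [200.0]})
        out = percent_energy(profile)
        assert out["pct_carb"].iloc[0] == pytest.approx(100.0, abs=1e-9)

    def test_percent_energy_requires_positive_energy(self):
        profile = pd.DataFrame({"energy_kcal": [0.0], "protein_g": [1.0],
                                "fat_g": [0.0], "sfa_g": [0.0],
                                "mufa_g": [0.0], "pufa_g": [0.0],
                                "carb_g": [0.0]})
        with pytest.raises(DomainError):
            percent_energy(profile)

    @pytest.mark.parametrize("gl, carbs, expected", [
        (120.0, 240.0, 50.0), (0.0, 200.0, 0.0),
    ])
    def test_glycemic_index_formula(self, gl, carbs, expected):
        assert glycemic_index(gl, carbs) == pytest.approx(expected,
                                                          abs=1e-9)

    def test_glycemic_index_requires_carbohydrate(self):
        with pytest.raises(DomainError):
            glycemic_index(50.0, 0.0)

    @pytest.mark.parametrize("tc, hdl, tg, expected", [
        (200.0, 50.0, 150.0, 120.0),
        (200.0, 50.0, 0.0, 150.0),
    ])
    def test_friedewald_hand_values(self, tc, hdl, tg, expected):
        assert friedewald_ldl(tc, hdl, tg) == pytest.approx(expected,
                                                            abs=1e-9)

    def test_friedewald_undefined_above_400_triglycerides(self):
        assert np.isnan(friedewald_ldl(200.0, 50.0, 450.0))

    def test_friedewald_rejects_negative_inputs(self):
        with pytest.raises(DomainError):
            friedewald_ldl(200.0, -1.0, 100.0)

    @pytest.mark.parametrize("w, h, expected", [(80.0, 1.60, 31.25),
                                                (1.0, 1.0, 1.0)])
    def test_bmi_hand_values(self, w, h, expected):
        assert bmi(w, h) == pytest.approx(expected, abs=1e-9)

    def test_bmi_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            bmi(0.0, 1.7)


class TestLinearity:
    """Doubling intake doubles totals but leaves ratios unchanged."""

    @settings(max_examples=25, deadline=None)
    @given(st_h.floats(min_value=0.1, max_value=9.5),
           st_h.floats(min_value=0.1, max_value=9.5))
    def test_scaling_invariance(self, ga, gb):
        comp = make_comp([
            ("a", 100.0, 5.0, 2.0, 0.5, 1.0, 0.5, 15.0, 2.0, 5.0, 50.0,
             0.1, 6.0),
            ("b", 300.0, 10.0, 20.0, 8.0, 9.0, 3.0, 20.0, 1.0, 10.0, 400.0,
             0.0, 12.0)])
        intake = pd.DataFrame([[ga, gb]], index=["p"], columns=["a", "b"])
        base = finalize_profile(nutrient_intake(intake, comp))
        double = finalize_profile(nutrient_intake(2.0 * intake, comp))
        for col in (*NUTRIENT_COLUMNS, "total_g"):
            assert double[col].iloc[0] == pytest.approx(
                2.0 * base[col].iloc[0], rel=1e-12)
        for col in ("pct_protein", "pct_fat", "pct_carb", "gi"):
            assert double[col].iloc[0] == pytest.approx(base[col].iloc[0],
                                                        rel=1e-12)

    def test_macronutrient_percent_energy_bounded(self, small_cohort):
        """On Atwater-consistent items, protein+fat+carb %E is <= 100
        (strictly below only where alcohol contributes energy)."""
        intake = small_cohort.intake()
        prof = finalize_profile(nutrient_intake(intake,
                                                small_cohort.composition))
        total_pct = prof["pct_protein"] + prof["pct_fat"] + prof["pct_carb"]
        assert (total_pct <= 100.0 + 1e-9).all()
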