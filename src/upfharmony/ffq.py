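"""FFQ unit conversion, nutrient totals and derived clinical quantities.

A semi-quantitative food-frequency questionnaire records, for each food
item, a usual-consumption frequency on a nine-category ordinal scale and a
commonly used portion size.  Daily intake in grams is portion size times
the times-per-day multiplier of the reported category; nutrient intakes
follow by weighting a per-100 g composition table.

Also implemented here: percent-of-energy macronutrients using Atwater
factors (protein 4, carbohydrate 4, fat 9 kcal/g), the diet-level glycemic
index GI = GL * 100 / carbohydrate grams, the Friedewald LDL formula
(undefined above 400 mg/dL triglycerides), and body mass index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, FormatError, MissingItemError, ValidationError

__all__ = [
    "ATWATER",
    "FrequencyScale",
    "FoodCompositionTable",
    "grams_per_day",
    "intake_from_ffq",
    "nutrient_intake",
    "percent_energy",
    "glycemic_index",
    "friedewald_ldl",
    "bmi",
]

ATWATER = {"protein": 4.0, "carb": 4.0, "fat": 9.0}

FRIEDEWALD_TG_LIMIT = 400.0  # mg/dL; accepted applicability bound

#: times-per-day midpoints for the nine frequency categories, from
#: "never or hardly ever" up to "more than six times a day"
DEFAULT_MULTIPLIERS = (
    0.0,           # never or hardly ever
    2.0 / 30.44,   # 1-3 per month (midpoint 2/month)
    1.0 / 7.0,     # once per week
    3.0 / 7.0,     # 2-4 per week (midpoint 3/week)
    5.5 / 7.0,     # 5-6 per week
    1.0,           # once per day
    2.5,           # 2-3 per day
    5.0,           # 4-6 per day
    6.0,           # more than 6 per day
)

DEFAULT_LABELS = (
    "never or hardly ever", "1-3 per month", "once per week", "2-4 per week",
    "5-6 per week", "once per day", "2-3 per day", "4-6 per day",
    "more than 6 per day",
)

NUTRIENT_COLUMNS = (
    "energy_kcal", "protein_g", "fat_g", "sfa_g", "mufa_g", "pufa_g",
    "carb_g", "fiber_g", "sugars_g", "sodium_mg", "omega3_g", "gl",
)

PCT_ENERGY_MAP = {
    "protein_g": ("pct_protein", ATWATER["protein"]),
    "fat_g": ("pct_fat", ATWATER["fat"]),
    "sfa_g": ("pct_sfa", ATWATER["fat"]),
    "mufa_g": ("pct_mufa", ATWATER["fat"]),
    "pufa_g": ("pct_pufa", ATWATER["fat"]),
    "carb_g": ("pct_carb", ATWATER["carb"]),
}


@dataclass(frozen=True)
class FrequencyScale:
    """Nine ordered consumption-frequency categories with day multipliers."""

    labels: tuple[str, ...] = DEFAULT_LABELS
    multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS

    def __post_init__(self) -> None:
        if len(self.labels) != 9 or len(self.multipliers) != 9:
            raise ValidationError("a frequency scale has nine categories")
        mult = np.asarray(self.multipliers, dtype=float)
        if mult[0] != 0.0:
            raise ValidationError(
                'category 1 ("never or hardly ever") must map to 0'
            )
        if np.any(mult < 0) or np.any(np.diff(mult) <= 0):
            raise ValidationError(
                "multipliers must be non-negative and strictly increasing"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FrequencyScale":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        try:
            return cls(labels=tuple(spec["labels"]),
                       multipliers=tuple(float(m)
                                         for m in spec["multipliers"]))
        except (KeyError, TypeError) as exc:
            raise FormatError(
                f"frequency-scale YAML needs 'labels' and 'multipliers' "
                f"lists of length 9 ({exc})"
            ) from exc


def grams_per_day(categories, portions_g, scale: FrequencyScale | None = None):
    """Daily grams per item: portion size x frequency multiplier.

    ``categories`` are integers in 1..9; shapes broadcast like numpy arrays.
    """
    scale = scale or FrequencyScale()
    cats = np.asarray(categories)
    if cats.size and (cats.min() < 1 or cats.max() > 9):
        bad = sorted(set(np.unique(cats)) - set(range(1, 10)))
        raise DomainError(f"frequency categories must be 1..9, got {bad}")
    mult = np.asarray(scale.multipliers, dtype=float)
    out = np.asarray(portions_g, dtype=float) * mult[cats.astype(int) - 1]
    return out


def intake_from_ffq(categories: pd.DataFrame, portions: pd.DataFrame,
                    scale: FrequencyScale | None = None) -> pd.DataFrame:
    """Participant x item grams/day from wide FFQ category/portion tables."""
    if not categories.columns.equals(portions.columns) or \
            not categories.index.equals(portions.index):
        raise ValidationError(
            "FFQ category and portion tables must be aligned"
        )
    values = grams_per_day(categories.to_numpy(), portions.to_numpy(), scale)
    return pd.DataFrame(values, index=categories.index,
                        columns=categories.columns)


@dataclass(frozen=True)
class FoodCompositionTable:
    """Per-100 g nutrient densities for FFQ items.

    Wraps a DataFrame indexed by ``item_id`` with the columns in
    ``NUTRIENT_COLUMNS``.  Energy may exceed the Atwater reconstruction from
    macronutrients (alcohol calories), but fatty-acid classes may not exceed
    total fat.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in NUTRIENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(
                f"composition table missing column(s): {', '.join(missing)}"
            )
        data = self.frame[list(NUTRIENT_COLUMNS)]
        if (data.to_numpy() < 0).any():
            raise ValidationError("composition values must be non-negative")
        fa_sum = data[["sfa_g", "mufa_g", "pufa_g"]].sum(axis=1)
        bad = data.index[fa_sum > data["fat_g"] + 1e-6]
        if len(bad):
            raise ValidationError(
                f"SFA+MUFA+PUFA exceeds total fat for: "
                f"{', '.join(map(str, bad[:5]))}"
            )

    @classmethod
    def load(cls, path: str | Path) -> "FoodCompositionTable":
        frame = pd.read_csv(path, sep="\t", index_col="item_id")
        return cls(frame)

    @classmethod
    def default(cls) -> "FoodCompositionTable":
        """Packaged synthetic composition table (matches the synthetic FFQ)."""
        from importlib import resources

        with resources.as_file(
            resources.files("upfharmony.data") / "composition_synthetic.tsv"
        ) as path:
            return cls.load(path)

    @property
    def item_ids(self) -> pd.Index:
        return self.frame.index


def nutrient_intake(intake: pd.DataFrame,
                    comp: FoodCompositionTable) -> pd.DataFrame:
    """Daily nutrient totals per participant.

    Each nutrient total is sum over items of g/day x density/100; also
    returns ``total_g``, the total daily grams over all items supplied.
    """
    values = intake.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValidationError("intake entries must be finite and >= 0")
    missing = [c for c in intake.columns if c not in comp.frame.index]
    if missing:
        raise MissingItemError(
            f"items absent from composition table: {', '.join(missing)}"
        )
    dens = comp.frame.loc[intake.columns, list(NUTRIENT_COLUMNS)]
    totals = intake.to_numpy() @ (dens.to_numpy() / 100.0)
    out = pd.DataFrame(totals, index=intake.index,
                       columns=list(NUTRIENT_COLUMNS))
    out["total_g"] = intake.sum(axis=1)
    return out


def percent_energy(profile: pd.DataFrame) -> pd.DataFrame:
    """Add percent-of-energy columns for the macronutrient intakes.

    %E = 100 x grams x Atwater factor / energy; requires positive energy.
    """
    energy = profile["energy_kcal"]
    if (energy <= 0).any():
        raise DomainError("percent-energy requires energy_kcal > 0")
    out = profile.copy()
    for grams_col, (pct_col, factor) in PCT_ENERGY_MAP.items():
        out[pct_col] = 100.0 * profile[grams_col] * factor / energy
    return out


def glycemic_index(gl, carbs):
    """Diet-level glycemic index: GL x 100 / grams of carbohydrate."""
    gl_arr = np.asarray(gl, dtype=float)
    carb_arr = np.asarray(carbs, dtype=float)
    if (carb_arr <= 0).any():
        raise DomainError("glycemic index requires carbohydrate intake > 0")
    out = gl_arr * 100.0 / carb_arr
    return float(out) if out.ndim == 0 else out


def friedewald_ldl(total_chol, hdl, triglycerides):
    """LDL cholesterol (mg/dL) via Friedewald: TC - HDL - TG/5.

    Returns NaN where triglycerides exceed 400 mg/dL, the formula's
    accepted validity bound.
    """
    tc = np.asarray(total_chol, dtype=float)
    hdl_ = np.asarray(hdl, dtype=float)
    tg = np.asarray(triglycerides, dtype=float)
    if (tc < 0).any() or (hdl_ < 0).any() or (tg < 0).any():
        raise DomainError("lipid concentrations must be non-negative")
    ldl = tc - hdl_ - tg / 5.0
    ldl = np.where(tg > FRIEDEWALD_TG_LIMIT, np.nan, ldl)
    return float(ldl) if ldl.ndim == 0 else ldl


def bmi(weight_kg, height_m):
    """Body mass index: weight (kg) / height (m) squared."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if (w <= 0).any() or (h <= 0).any():
        raise DomainError("weight and height must be positive")
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def finalize_profile(profile: pd.DataFrame) -> pd.DataFrame:
    """Percent-energy columns plus the diet glycemic index, in one pass."""
    out = percent_energy(profile)
    out["gi"] = glycemic_index(out["gl"], out["carb_g"])
    return out
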