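"""Cohort inclusion rules, UPF exposure variants and quintile assignment.

The primary exposure per classification system is the percentage of daily
intake, in grams, coming from that system's UPF group, with the denominator
restricted to items the system allocates.  Two sensitivity exposures are
computed alongside: UPF grams/day per kilogram of body weight, and
calorie-adjusted UPF grams/day by the residual method (residual from the
regression of UPF grams on total energy, re-centred at the cohort mean).
The regression predictor used downstream is UPF% divided by five, i.e. a
five-percentage-point increment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
    ValidationError,
)
from .taxonomy import TaxonomyTable, get_system

__all__ = [
    "OUTCOME_COLUMNS",
    "ENERGY_BOUNDS",
    "apply_inclusion",
    "upf_grams",
    "upf_percentage",
    "upf_g_per_kg",
    "calorie_adjusted_upf",
    "assign_quintiles",
    "compute_exposures",
]

#: cardiometabolic outcome variables required for inclusion
OUTCOME_COLUMNS = (
    "weight", "bmi", "waist", "glucose", "hba1c", "triglycerides",
    "total_chol", "ldl_chol", "hdl_chol", "creatinine", "sbp", "dbp",
)

#: plausible daily energy (kcal) by sex: outside is excluded
ENERGY_BOUNDS = {"female": (500.0, 3500.0), "male": (800.0, 4000.0)}


def apply_inclusion(participants: pd.DataFrame, profiles: pd.DataFrame,
                    outcome_columns=OUTCOME_COLUMNS):
    """Apply the cohort inclusion rules; return (included ids, exclusion log).

    Participants with any missing cardiometabolic outcome are dropped first,
    then those with sex-specific implausible energy intake (<500 or >3500
    kcal for females; <800 or >4000 kcal for males).  The log records one
    row per dropped participant with the reason.
    """
    if "sex" not in participants.columns:
        raise ValidationError("participants table needs a 'sex' column")
    if "energy_kcal" not in profiles.columns:
        raise ValidationError("profiles table needs an 'energy_kcal' column")
    ids = participants.index
    if not ids.isin(profiles.index).all():
        raise ValidationError("every participant needs a nutrient profile")
    sex = participants["sex"]
    if sex.isna().any() or not sex.isin(list(ENERGY_BOUNDS)).all():
        raise ValidationError("sex must be 'female' or 'male' for everyone")
    energy = profiles.loc[ids, "energy_kcal"]
    if energy.isna().any():
        raise ValidationError("energy intake missing for some participants")

    missing_cols = [c for c in outcome_columns
                    if c not in participants.columns]
    if missing_cols:
        raise ValidationError(
            f"participants table missing outcome column(s): "
            f"{', '.join(missing_cols)}"
        )
    log_rows = []
    outcome_na = participants[list(outcome_columns)].isna()
    for pid in ids[outcome_na.any(axis=1)]:
        cols = outcome_na.columns[outcome_na.loc[pid]].tolist()
        log_rows.append((pid, f"missing cardiometabolic variable: "
                              f"{', '.join(cols)}"))
    keep = ids[~outcome_na.any(axis=1)]

    lo = sex.loc[keep].map({s: b[0] for s, b in ENERGY_BOUNDS.items()})
    hi = sex.loc[keep].map({s: b[1] for s, b in ENERGY_BOUNDS.items()})
    e = energy.loc[keep]
    for pid in keep[e < lo]:
        log_rows.append((pid, f"energy below {sex[pid]} bound"))
    for pid in keep[e > hi]:
        log_rows.append((pid, f"energy above {sex[pid]} bound"))
    keep = keep[(e >= lo) & (e <= hi)]

    log = pd.DataFrame(log_rows, columns=["participant_id", "reason"])
    return keep, log


def _classified_columns(intake: pd.DataFrame, taxonomy: TaxonomyTable,
                        system) -> tuple[list, list]:
    allocated = set(taxonomy.allocated_ids(system))
    upf = set(taxonomy.upf_ids(system))
    cols = [c for c in intake.columns if c in allocated]
    upf_cols = [c for c in cols if c in upf]
    return cols, upf_cols


def upf_grams(intake: pd.DataFrame, taxonomy: TaxonomyTable,
              system) -> pd.Series:
    """Daily grams from the system's UPF group, per participant."""
    _, upf_cols = _classified_columns(intake, taxonomy, system)
    return intake[upf_cols].sum(axis=1)


def upf_percentage(intake: pd.DataFrame, taxonomy: TaxonomyTable,
                   system) -> pd.Series:
    """UPF share of daily intake: 100 x UPF grams / classified grams."""
    cols, upf_cols = _classified_columns(intake, taxonomy, system)
    total = intake[cols].sum(axis=1)
    if (total <= 0).any():
        bad = total.index[total <= 0].tolist()
        raise DomainError(
            f"zero classified intake for participant(s): {bad[:5]}"
        )
    return 100.0 * intake[upf_cols].sum(axis=1) / total


def upf_g_per_kg(intake: pd.DataFrame, taxonomy: TaxonomyTable, system,
                 weight_kg: pd.Series) -> pd.Series:
    """UPF grams/day per kilogram of body weight."""
    w = weight_kg.loc[intake.index]
    if (w <= 0).any():
        raise DomainError("body weight must be positive")
    return upf_grams(intake, taxonomy, system) / w


def calorie_adjusted_upf(upf_g, energy_kcal):
    """Residual-method energy adjustment of UPF grams/day.

    Residuals from the least-squares regression of UPF grams on total
    energy, plus the cohort mean, so the output keeps the input's units and
    mean but is uncorrelated with energy.
    """
    y = np.asarray(upf_g, dtype=float)
    x = np.asarray(energy_kcal, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or y.size < 3:
        raise ValidationError(
            "need aligned 1-D vectors of length >= 3"
        )
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise DegenerateDataError(
            "energy is constant; residual regression is degenerate"
        )
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    out = resid + y.mean()
    if isinstance(upf_g, pd.Series):
        return pd.Series(out, index=upf_g.index)
    return out


def assign_quintiles(values) -> np.ndarray:
    """Quintile labels 1-5 from the 20/40/60/80 empirical percentiles.

    Percentiles use linear interpolation; a value equal to a cut point
    falls into the lower quintile.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 5:
        raise InsufficientDataError("need at least five values")
    if np.isnan(v).any():
        raise ValidationError("quintile input contains NaN")
    if np.ptp(v) == 0:
        raise DegenerateDataError(
            "all values identical; quintiles are undefined"
        )
    cuts = np.percentile(v, [20, 40, 60, 80], method="linear")
    return (np.searchsorted(cuts, v, side="left") + 1).astype(int)


def compute_exposures(intake: pd.DataFrame, taxonomy: TaxonomyTable,
                      weight_kg: pd.Series, energy_kcal: pd.Series,
                      systems=("NOVA", "IARC", "IFIC", "UNC")) -> pd.DataFrame:
    """Per participant x system exposure records, long format.

    Columns: ``participant_id, system, upf_pct, upf_g_per_kg, upf_kcal_adj,
    quintile, increment`` with ``increment = upf_pct / 5``.
    """
    frames = []
    for system in systems:
        name = get_system(system).name
        pct = upf_percentage(intake, taxonomy, name)
        grams = upf_grams(intake, taxonomy, name)
        frames.append(pd.DataFrame({
            "participant_id": intake.index,
            "system": name,
            "upf_pct": pct.to_numpy(),
            "upf_g_per_kg": upf_g_per_kg(intake, taxonomy, name,
                                         weight_kg).to_numpy(),
            "upf_kcal_adj": np.asarray(calorie_adjusted_upf(
                grams, energy_kcal.loc[intake.index])),
            "quintile": assign_quintiles(pct.to_numpy()),
            "increment": pct.to_numpy() / 5.0,
        }))
    return pd.concat(frames, ignore_index=True)
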