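"""Inferential layer: quintile profiles, Tukey contrasts, association models
and cross-system concordance.

Quintile profiles summarise a variable as mean (SD) per UPF-consumption
quintile with a classical one-way ANOVA; pairwise quintile differences use
Tukey's honestly-significant-difference test (Tukey-Kramer for unequal
group sizes).  Associations between a cardiometabolic outcome and a
five-percentage-point UPF increment are ordinary least squares with three
nested covariate sets.  Concordance between classification systems combines
an intraclass correlation coefficient from the two-way ANOVA mean squares
(single rating; absolute agreement by default, consistency as an option)
with the percentage of subjects assigned the same quintile.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "MODEL_COVARIATES",
    "QuintileProfile",
    "RegressionResult",
    "ICCResult",
    "AgreementResult",
    "quintile_profile",
    "tukey_hsd",
    "fit_association_model",
    "icc_agreement",
    "quintile_agreement",
    "pairwise_concordance",
]

QUINTILES = (1, 2, 3, 4, 5)

#: covariate sets of the three nested linear models; ``C(...)`` columns are
#: expanded to dummies with the first level as reference
MODEL_COVARIATES = {
    1: ("age", "sex", "C(center)"),
    2: ("age", "sex", "C(center)", "energy_kcal", "C(activity)",
        "C(education)"),
    3: ("age", "sex", "C(center)", "energy_kcal", "C(activity)",
        "C(education)", "med_hypertension", "med_cholesterol",
        "med_diabetes"),
}


def _check_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if not np.isin(lab, QUINTILES).all():
        raise ValidationError("quintile labels must be integers 1..5")
    return lab.astype(int)


@dataclass(frozen=True)
class QuintileProfile:
    """Per-quintile summary of one variable, with the one-way ANOVA."""

    variable: str
    kind: str                     # "continuous" | "categorical"
    summary: pd.DataFrame         # per-quintile mean/sd or category %
    anova_f: float | None = None
    anova_p: float | None = None
    tukey: pd.DataFrame | None = None


def quintile_profile(values, quintile_labels, kind: str = "continuous",
                     variable: str = "value",
                     with_tukey: bool = False) -> QuintileProfile:
    """Summarise a variable across UPF quintiles.

    Continuous variables get mean and SD per quintile plus one-way ANOVA F
    and p (and optionally the Tukey contrasts); categorical variables get
    the within-quintile category percentages, which sum to 100 per quintile.
    """
    lab = _check_labels(quintile_labels)
    if kind == "continuous":
        v = np.asarray(values, dtype=float)
        groups = []
        rows = []
        for q in QUINTILES:
            g = v[lab == q]
            if g.size < 2:
                raise InsufficientDataError(
                    f"quintile {q} has fewer than two observations"
                )
            groups.append(g)
            rows.append((q, g.size, g.mean(), g.std(ddof=1)))
        summary = pd.DataFrame(rows, columns=["quintile", "n", "mean", "sd"])
        if all(np.ptp(g) == 0 for g in groups) and \
                np.ptp([g.mean() for g in groups]) == 0:
            f_stat, p = 0.0, 1.0    # constant input: no variation to test
        else:
            f_stat, p = sps.f_oneway(*groups)
            if np.isnan(f_stat):
                f_stat, p = 0.0, 1.0
        tuk = tukey_hsd(v, lab) if with_tukey else None
        return QuintileProfile(variable, kind, summary, float(f_stat),
                               float(p), tuk)
    if kind == "categorical":
        ser = pd.Series(np.asarray(values), name=variable)
        tab = pd.crosstab(pd.Series(lab, name="quintile"), ser,
                          normalize="index") * 100.0
        return QuintileProfile(variable, kind, tab)
    raise ValidationError(f"kind must be continuous or categorical: {kind!r}")


def tukey_hsd(values, quintile_labels) -> pd.DataFrame:
    """All pairwise Tukey(-Kramer) contrasts between quintiles.

    The estimate for pair (i, j) is mean(Qi) - mean(Qj); the SE uses the
    pooled within-group variance; adjusted p-values come from the
    studentized-range distribution with k groups and N-k error df.
    """
    lab = _check_labels(quintile_labels)
    v = np.asarray(values, dtype=float)
    groups = {q: v[lab == q] for q in sorted(set(lab))}
    if len(groups) < 2:
        raise ValidationError("Tukey contrasts need at least two groups")
    k = len(groups)
    n_total = sum(g.size for g in groups.values())
    df_err = n_total - k
    if df_err <= 0 or any(g.size < 2 for g in groups.values()):
        raise InsufficientDataError("each group needs >= 2 observations")
    mse = sum((g.size - 1) * g.var(ddof=1) for g in groups.values()) / df_err
    rows = []
    for qi, qj in combinations(sorted(groups), 2):
        gi, gj = groups[qi], groups[qj]
        est = gi.mean() - gj.mean()
        se = np.sqrt(mse * (1.0 / gi.size + 1.0 / gj.size))
        if mse == 0:
            p_adj = 1.0 if est == 0 else 0.0
        else:
            q_stat = abs(est) / np.sqrt(mse / 2.0 *
                                        (1.0 / gi.size + 1.0 / gj.size))
            p_adj = float(sps.studentized_range.sf(q_stat, k, df_err))
        rows.append((qi, qj, est, se, min(max(p_adj, 0.0), 1.0)))
    return pd.DataFrame(rows, columns=["q_i", "q_j", "estimate", "se",
                                       "p_adj"])


@dataclass(frozen=True)
class RegressionResult:
    """Exposure coefficient of one covariate-adjusted linear model."""

    outcome: str
    system: str
    model_id: int
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    exposure: str = "increment"


def _build_design(data: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov.startswith("C(") and cov.endswith(")"):
            name = cov[2:-1]
            if name not in data.columns:
                raise ValidationError(f"missing covariate column: {name}")
            series = data[name].astype("category")
            if series.nunique() < 2:
                raise ValidationError(
                    f"categorical covariate {name!r} needs >= 2 levels"
                )
            dummies = pd.get_dummies(series, prefix=name, drop_first=True,
                                     dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c]
        else:
            if cov not in data.columns:
                raise ValidationError(f"missing covariate column: {cov}")
            series = data[cov]
            if series.dtype == object or str(series.dtype) == "category":
                if cov == "sex":
                    series = series.map({"female": 0.0, "male": 1.0})
                    if series.isna().any():
                        raise ValidationError(
                            "sex must be 'female' or 'male'"
                        )
                else:
                    raise ValidationError(
                        f"covariate {cov!r} is non-numeric"
                    )
            cols[cov] = series.astype(float)
    return pd.DataFrame(cols, index=data.index)


def fit_association_model(data: pd.DataFrame, outcome: str,
                          model_id: int = 3, exposure: str = "increment",
                          system: str = "") -> RegressionResult:
    """OLS of an outcome on the UPF exposure plus a nested covariate set.

    Model 1 adjusts for age, sex and recruitment center; model 2 adds total
    energy, physical activity and education; model 3 adds medication for
    hypertension, cholesterol and diabetes.  Rows with missing values in
    the outcome, exposure or covariates are dropped (complete case).
    Returns the exposure term's coefficient with its t-based 95% CI and
    two-sided p-value.
    """
    if model_id not in MODEL_COVARIATES:
        raise ValidationError(f"model_id must be 1, 2 or 3: {model_id}")
    for col in (outcome, exposure):
        if col not in data.columns:
            raise ValidationError(f"missing column: {col}")
    design = _build_design(data, MODEL_COVARIATES[model_id])
    design.insert(0, exposure, data[exposure].astype(float))
    frame = pd.concat([data[outcome].astype(float).rename("__y"), design],
                      axis=1).dropna()
    y = frame["__y"]
    x = sm.add_constant(frame.drop(columns="__y"))
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise DegenerateDataError("singular design matrix")
    fit = sm.OLS(y, x).fit()
    ci_low, ci_high = fit.conf_int(alpha=0.05).loc[exposure]
    return RegressionResult(
        outcome=outcome, system=system, model_id=model_id,
        beta=float(fit.params[exposure]), ci_low=float(ci_low),
        ci_high=float(ci_high), p=float(fit.pvalues[exposure]),
        n=int(fit.nobs), exposure=exposure,
    )


@dataclass(frozen=True)
class ICCResult:
    """Single-rating intraclass correlation with its ANOVA mean squares."""

    icc: float
    msr: float     # between-subject (rows) mean square
    msc: float     # between-rater (columns) mean square
    mse: float     # residual mean square
    n_subjects: int
    k_raters: int
    form: str      # "absolute" | "consistency"


def icc_agreement(ratings, form: str = "absolute") -> ICCResult:
    """ICC of an n-subjects x k-raters matrix from two-way ANOVA.

    Absolute agreement (default), single rating:
    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))``;
    the consistency form drops the rater-variance term:
    ``(MSR - MSE) / (MSR + (k-1) MSE)``.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ratings must be a 2-D matrix")
    n, k = x.shape
    if np.isnan(x).any():
        raise ValidationError("missing cells are not supported")
    if n < 3:
        raise InsufficientDataError("need at least three subjects")
    if k < 2:
        raise InsufficientDataError("need at least two raters")
    if form not in ("absolute", "consistency"):
        raise ValidationError(f"unknown ICC form: {form!r}")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    if form == "absolute":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    else:
        denom = msr + (k - 1) * mse
    if denom == 0:
        raise DegenerateDataError("no variance in ratings; ICC undefined")
    return ICCResult(float((msr - mse) / denom), float(msr), float(msc),
                     float(mse), n, k, form)


class AgreementResult(NamedTuple):
    overall: float
    q1: float
    q5: float


def quintile_agreement(q_a, q_b) -> AgreementResult:
    """Percentage of subjects placed in the same quintile by two systems.

    ``overall`` counts any matching quintile; ``q1``/``q5`` count matches in
    that specific quintile, still over the total number of subjects.
    """
    a = _check_labels(q_a)
    b = _check_labels(q_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValidationError("label vectors must be equal-length, non-empty")
    same = a == b
    n = a.size
    return AgreementResult(
        overall=100.0 * same.sum() / n,
        q1=100.0 * (same & (a == 1)).sum() / n,
        q5=100.0 * (same & (a == 5)).sum() / n,
    )


def pairwise_concordance(labels: pd.DataFrame,
                         form: str = "absolute") -> pd.DataFrame:
    """ICC and quintile agreement for every pair of systems.

    ``labels`` is a participants x systems table of quintile numbers.
    Returns one row per unordered pair with columns ``system_a, system_b,
    icc3, overall, q1, q5``.
    """
    rows = []
    for a, b in combinations(labels.columns, 2):
        icc = icc_agreement(labels[[a, b]].to_numpy(), form=form)
        agree = quintile_agreement(labels[a], labels[b])
        rows.append((a, b, icc.icc, agree.overall, agree.q1, agree.q5))
    return pd.DataFrame(rows, columns=["system_a", "system_b", "icc3",
                                       "overall", "q1", "q5"])
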