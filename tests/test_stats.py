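"""ANOVA profiles, Tukey contrasts, association models and concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from upfharmony import (
    fit_association_model,
    icc_agreement,
    quintile_agreement,
    quintile_profile,
    tukey_hsd,
)
from upfharmony.errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from upfharmony.stats import pairwise_concordance


def icc_oracle(x, form="absolute"):
    """ICC from raw sums of squares, straight from the definitions."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    sst = ((x - grand) ** 2).sum()
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sst - ssr - ssc
    msr, msc = ssr / (n - 1), ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "absolute":
        return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return (msr - mse) / (msr + (k - 1) * mse)


def _grouped(rng, means, n_per=30, sd=1.0):
    values = np.concatenate([rng.normal(m, sd, n_per) for m in means])
    labels = np.repeat(np.arange(1, len(means) + 1), n_per)
    return values, labels


class TestQuintileProfile:
    def test_constant_input_gives_zero_f(self):
        values = np.full(50, 7.0)
        labels = np.repeat([1, 2, 3, 4, 5], 10)
        qp = quintile_profile(values, labels)
        assert qp.anova_f == 0.0 and qp.anova_p == 1.0
        assert (qp.summary["mean"] == 7.0).all()

    def test_hand_two_values_per_quintile(self):
        values = np.array([1.0, 3.0, 2.0, 4.0, 10.0, 14.0, 5.0, 5.0,
                           0.0, 8.0])
        labels = np.repeat([1, 2, 3, 4, 5], 2)
        qp = quintile_profile(values, labels)
        assert qp.summary["mean"].tolist() == [2.0, 3.0, 12.0, 5.0, 4.0]
        # SD with ddof=1 of two points a,b is |a-b|/sqrt(2)
        expected_sd = [2.0 / np.sqrt(2), 2.0 / np.sqrt(2),
                       4.0 / np.sqrt(2), 0.0, 8.0 / np.sqrt(2)]
        assert qp.summary["sd"].to_numpy() == pytest.approx(expected_sd)

    def test_anova_matches_scipy(self, rng):
        values, labels = _grouped(rng, [0.0, 0.1, 0.0, -0.2, 0.3])
        qp = quintile_profile(values, labels)
        groups = [values[labels == q] for q in range(1, 6)]
        f_ref, p_ref = sps.f_oneway(*groups)
        assert qp.anova_f == pytest.approx(f_ref, rel=1e-12)
        assert qp.anova_p == pytest.approx(p_ref, rel=1e-12)

    def test_anova_location_and_scale_invariance(self, rng):
        values, labels = _grouped(rng, [0.0, 0.5, 0.2, -0.1, 0.4])
        f0 = quintile_profile(values, labels).anova_f
        f_shift = quintile_profile(values + 100.0, labels).anova_f
        f_scale = quintile_profile(values * 7.0, labels).anova_f
        assert f_shift == pytest.approx(f0, rel=1e-9)
        assert f_scale == pytest.approx(f0, rel=1e-9)

    def test_power_for_half_sd_shift(self, rng):
        """One group shifted by 0.5 SD at n=200/group: ANOVA should reject
        at alpha=0.05 in at least 95% of 200 replicates."""
        hits = 0
        for _ in range(200):
            values, labels = _grouped(rng, [0, 0, 0, 0, 0.5], n_per=200)
            if quintile_profile(values, labels).anova_p < 0.05:
                hits += 1
        assert hits >= 190

    def test_categorical_percentages_sum_to_100(self, rng):
        cats = rng.choice(["never", "former", "current"], size=300)
        labels = rng.integers(1, 6, size=300)
        qp = quintile_profile(cats, labels, kind="categorical",
                              variable="smoking")
        assert qp.summary.sum(axis=1).to_numpy() == pytest.approx(
            np.full(qp.summary.shape[0], 100.0))

    def test_empty_quintile_rejected(self):
        with pytest.raises(InsufficientDataError):
            quintile_profile(np.arange(8.0), np.array([1, 1, 2, 2, 3, 3,
                                                       4, 4]))


class TestTukey:
    def test_null_simulation_estimates_near_zero(self, rng):
        values, labels = _grouped(rng, [5.0] * 5, n_per=200)
        out = tukey_hsd(values, labels)
        assert (out["p_adj"] > 0.2).all()
        assert out["estimate"].abs().max() < 0.5

    def test_exact_shift_with_zero_within_variance(self):
        values = np.concatenate([np.full(10, 1.0), np.full(10, 3.5)])
        labels = np.repeat([1, 2], 10)
        out = tukey_hsd(values, labels)
        assert out["estimate"].iloc[0] == pytest.approx(1.0 - 3.5)
        assert out["p_adj"].iloc[0] == 0.0

    def test_matches_scipy_tukey_oracle(self, rng):
        values, labels = _grouped(rng, [0.0, 0.3, 0.1, -0.4, 0.2])
        ours = tukey_hsd(values, labels)
        ref = sps.tukey_hsd(*[values[labels == q] for q in range(1, 6)])
        for _, row in ours.iterrows():
            i, j = int(row["q_i"]) - 1, int(row["q_j"]) - 1
            assert row["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-6)
            assert row["estimate"] == pytest.approx(
                ref.statistic[i, j], rel=1e-12)

    def test_q1_q5_contrast_is_difference_of_means(self, rng):
        values, labels = _grouped(rng, [1.0, 2.0, 3.0, 4.0, 5.0])
        out = tukey_hsd(values, labels).set_index(["q_i", "q_j"])
        est = out.loc[(1, 5), "estimate"]
        assert est == values[labels == 1].mean() - values[labels == 5].mean()


class TestAssociationModel:
    @staticmethod
    def _frame(rng, n=400, beta=0.5, noise=0.0):
        centers = rng.choice(["C1", "C2", "C3"], size=n)
        age = rng.uniform(55, 75, n)
        sex = rng.choice(["female", "male"], size=n)
        increment = rng.gamma(3.0, 1.0, n)
        y = (2.0 + beta * increment + 0.1 * age
             + 0.5 * (sex == "male") + 0.3 * (centers == "C2")
             + noise * rng.normal(size=n))
        return pd.DataFrame({
            "increment": increment, "age": age, "sex": sex,
            "center": centers, "energy_kcal": rng.normal(2400, 300, n),
            "activity": rng.choice(["low", "medium", "high"], size=n),
            "education": rng.choice(["primary", "secondary", "university"],
                                    size=n),
            "med_hypertension": rng.integers(0, 2, n),
            "med_cholesterol": rng.integers(0, 2, n),
            "med_diabetes": rng.integers(0, 2, n),
            "y": y})

    def test_zero_noise_exact_recovery(self, rng):
        frame = self._frame(rng, beta=0.5, noise=0.0)
        for model_id in (1, 2, 3):
            res = fit_association_model(frame, "y", model_id=model_id)
            assert res.beta == pytest.approx(0.5, abs=1e-10)
            assert res.ci_low <= res.beta <= res.ci_high

    def test_beta_matches_simple_slope_when_covariates_are_noise(self, rng):
        frame = self._frame(rng, n=4000, beta=0.0, noise=1.0)
        frame["y"] = 1.0 + 0.4 * frame["increment"] + rng.normal(
            0, 1.0, len(frame))
        res = fit_association_model(frame, "y", model_id=3)
        simple = np.polyfit(frame["increment"], frame["y"], 1)[0]
        se = (res.ci_high - res.ci_low) / (2 * 1.96)
        assert res.beta == pytest.approx(simple, abs=4 * se)

    def test_missing_covariate_column_named(self, rng):
        frame = self._frame(rng).drop(columns="education")
        with pytest.raises(ValidationError, match="education"):
            fit_association_model(frame, "y", model_id=2)

    def test_single_center_rejected(self, rng):
        frame = self._frame(rng)
        frame["center"] = "C1"
        with pytest.raises(ValidationError, match="center"):
            fit_association_model(frame, "y", model_id=1)

    def test_collinear_design_rejected(self, rng):
        frame = self._frame(rng)
        frame["age"] = 2.0 * frame["increment"]
        with pytest.raises(DegenerateDataError):
            fit_association_model(frame, "y", model_id=1)

    def test_complete_case_drops_missing_rows(self, rng):
        frame = self._frame(rng, noise=0.0)
        frame.loc[frame.index[:25], "y"] = np.nan
        res = fit_association_model(frame, "y", model_id=1)
        assert res.n == len(frame) - 25


class TestICC:
    def test_identical_columns_give_one(self, rng):
        col = rng.normal(size=40)
        res = icc_agreement(np.column_stack([col, col, col]))
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_six_by_two_toy_matches_oracle(self):
        x = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [7, 6], [8, 1]],
                     float)
        res = icc_agreement(x)
        assert res.icc == pytest.approx(icc_oracle(x), abs=1e-12)

    def test_oracle_equivalence_on_random_matrices(self, rng):
        for _ in range(500):
            x = rng.integers(0, 10, size=(5, 3)).astype(float)
            if np.ptp(x) == 0:
                continue
            for form in ("absolute", "consistency"):
                assert icc_agreement(x, form=form).icc == pytest.approx(
                    icc_oracle(x, form=form), abs=1e-12)

    def test_independent_columns_near_zero(self, rng):
        x = rng.normal(size=(10_000, 2))
        assert abs(icc_agreement(x).icc) < 0.03

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=(30, 4)) + rng.normal(size=(30, 1))
        frame = pd.DataFrame(x).stack().rename("score").reset_index()
        frame.columns = ["subject", "rater", "score"]
        table = pg.intraclass_corr(frame, targets="subject",
                                   raters="rater", ratings="score")
        table = table.set_index("Type")["ICC"]
        assert icc_agreement(x, "absolute").icc == pytest.approx(
            table["ICC(A,1)"], abs=1e-9)
        assert icc_agreement(x, "consistency").icc == pytest.approx(
            table["ICC(C,1)"], abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(InsufficientDataError):
            icc_agreement(np.ones((2, 3)))
        with pytest.raises(ValidationError):
            icc_agreement(np.array([[1.0, np.nan], [2, 3], [4, 5]]))


class TestQuintileAgreement:
    def test_identical_balanced_vectors(self):
        q = np.repeat([1, 2, 3, 4, 5], 4)
        res = quintile_agreement(q, q)
        assert res == (100.0, 20.0, 20.0)

    def test_cyclic_shift_disagrees_everywhere(self):
        q = np.repeat([1, 2, 3, 4, 5], 4)
        shifted = q % 5 + 1
        assert quintile_agreement(q, shifted).overall == 0.0

    def test_hand_counted_example(self):
        a = np.array([1, 1, 2, 3, 4, 5, 5, 2, 3, 4])
        b = np.array([1, 2, 2, 3, 5, 4, 5, 3, 2, 3])
        # matches at positions 0, 2, 3, 6 -> overall 40%; one is in Q1
        res = quintile_agreement(a, b)
        assert res.overall == 40.0
        assert res.q1 == 10.0
        assert res.q5 == 10.0

    def test_self_agreement_dominates(self, rng):
        a = rng.integers(1, 6, 60)
        b = rng.integers(1, 6, 60)
        assert quintile_agreement(a, a).overall >= \
            quintile_agreement(a, b).overall

    def test_bounds_and_validation(self):
        with pytest.raises(ValidationError):
            quintile_agreement(np.array([1, 2]), np.array([1]))
        with pytest.raises(ValidationError):
            quintile_agreement(np.array([0, 2]), np.array([1, 2]))

    def test_pairwise_table_shape(self, rng):
        labels = pd.DataFrame(rng.integers(1, 6, size=(50, 3)),
                              columns=["NOVA", "IARC", "IFIC"])
        out = pairwise_concordance(labels)
        assert len(out) == 3
        assert ((out["q1"] <= out["overall"]) &
                (out["q5"] <= out["overall"])).all()
        assert out["icc3"].between(-1, 1).all()
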