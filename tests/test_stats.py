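"""Group statistics: worked examples from printed counts, oracles, null calibration."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cartt2.config import SimConfig
from cartt2.exceptions import DegenerateDataError, InputError
from cartt2.stats import (adjusted_group_difference, chi_square_2x2,
                          logistic_prevalence_or, partial_correlation,
                          standardized_difference)
from cartt2.synthetic import true_t2_cohort_table


def make_table(rng, n_inc=92, n_ctl=53, effect=0.0, sd=2.0):
    n = n_inc + n_ctl
    group = np.array(["incidence"] * n_inc + ["control"] * n_ctl)
    return pd.DataFrame({
        "group": group,
        "age": rng.normal(50, 3, n),
        "sex": rng.choice(["F", "M"], n),
        "bmi": rng.normal(24, 2, n),
        "y": rng.normal(0, sd, n) + np.where(group == "incidence", effect, 0.0),
    })


class TestAdjustedGroupDifference:
    def test_constant_covariates_reduce_to_mean_difference(self):
        rng = np.random.default_rng(0)
        t = make_table(rng, effect=1.0)
        t["age"], t["bmi"], t["sex"] = 50.0, 24.0, "F"
        with pytest.raises(DegenerateDataError):
            adjusted_group_difference(t, "y")  # constant columns are singular
        res = adjusted_group_difference(t, "y", covariates=())
        raw = t.loc[t.group == "control", "y"].mean() - t.loc[t.group == "incidence", "y"].mean()
        assert res.coefficient == pytest.approx(raw, rel=1e-10)

    def test_sign_convention_incidence_elevated_gives_negative(self):
        rng = np.random.default_rng(1)
        res = adjusted_group_difference(make_table(rng, effect=2.0, sd=0.5), "y")
        assert res.coefficient < 0
        assert res.ci_low <= res.coefficient <= res.ci_high

    def test_recovers_configured_mf_contrast_over_replicates(self):
        # True MF means differ by 0.83 ms between groups; the control-minus-
        # incidence coefficient should average -0.83 over generator replicates.
        coefs = []
        for i in range(120):
            cfg = replace(SimConfig(), seed=3000 + i)
            df = true_t2_cohort_table(cfg, with_worms=False)
            res = adjusted_group_difference(df, "mean_t2_medial_femur")
            coefs.append(res.coefficient)
        assert np.mean(coefs) == pytest.approx(-(37.68 - 36.85), abs=0.12)

    def test_effect_sign_detected_in_most_replicates(self):
        hits = 0
        for i in range(100):
            cfg = replace(SimConfig(), seed=5000 + i)
            df = true_t2_cohort_table(cfg, with_worms=False)
            res = adjusted_group_difference(df, "mean_t2_medial_femur")
            hits += res.coefficient < 0
        assert hits > 90

    def test_null_label_permutation_centers_at_zero(self):
        rng = np.random.default_rng(2)
        coefs = []
        for _ in range(200):
            t = make_table(rng, effect=0.0)
            coefs.append(adjusted_group_difference(t, "y").coefficient)
        assert abs(np.mean(coefs)) < 3 * np.std(coefs) / np.sqrt(len(coefs))


class TestLogisticOR:
    def test_reduces_to_cross_product_without_covariates(self):
        # printed counts: incidence 59/88 lesioned, control 33/45
        y = np.r_[np.ones(59), np.zeros(29), np.ones(33), np.zeros(12)]
        g = np.r_[["incidence"] * 88, ["control"] * 45]
        t = pd.DataFrame({"group": g, "lesion": y})
        res = logistic_prevalence_or(t, "lesion", covariates=())
        assert res.odds_ratio == pytest.approx((59 * 12) / (29 * 33), abs=1e-6)

    def test_equal_prevalence_gives_unit_or(self):
        y = np.r_[np.ones(40), np.zeros(40), np.ones(25), np.zeros(25)]
        g = np.r_[["incidence"] * 80, ["control"] * 50]
        res = logistic_prevalence_or(pd.DataFrame({"group": g, "lesion": y}),
                                     "lesion", covariates=())
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_single_class_signaled(self):
        t = pd.DataFrame({"group": ["incidence"] * 5 + ["control"] * 5,
                          "lesion": np.ones(10)})
        with pytest.raises(DegenerateDataError):
            logistic_prevalence_or(t, "lesion", covariates=())

    def test_adjusted_or_on_generated_marginals_near_printed(self):
        # Cohort simulated at the printed prevalences: adjusted OR should sit
        # inside the printed interval around 0.83 (stochastic check).
        ors = []
        for i in range(40):
            cfg = replace(SimConfig(), seed=7000 + i)
            df = true_t2_cohort_table(cfg)
            d = df[df.worms_readable == True]  # noqa: E712
            res = logistic_prevalence_or(d, "cartilage_lesion",
                                         covariates=("age", "sex", "bmi"))
            ors.append(res.odds_ratio)
        assert 0.36 < np.mean(ors) < 1.88


class TestPartialCorrelation:
    def test_reduces_to_pearson_when_controls_uninformative(self):
        rng = np.random.default_rng(3)
        n = 4000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        t = pd.DataFrame({"x": x, "y": y, "age": rng.normal(50, 3, n),
                          "sex": rng.choice(["F", "M"], n),
                          "bmi": rng.normal(24, 2, n)})
        r, p = partial_correlation(t, "x", "y", group_col=None)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.02)

    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(4)
        n = 50
        x = rng.normal(size=n)
        t = pd.DataFrame({"x": x, "y": x, "age": rng.normal(50, 3, n),
                          "sex": rng.choice(["F", "M"], n),
                          "bmi": rng.normal(24, 2, n)})
        r, _ = partial_correlation(t, "x", "y", group_col=None)
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_pingouin_agreement(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n = 200
        t = pd.DataFrame({"x": rng.normal(size=n), "age": rng.normal(50, 3, n),
                          "bmi": rng.normal(24, 2, n)})
        t["y"] = 0.4 * t.x + 0.1 * t.age + rng.normal(size=n)
        r, p = partial_correlation(t, "x", "y", covariates=("age", "bmi"),
                                   group_col=None)
        ref = pg.partial_corr(t, x="x", y="y", covar=["age", "bmi"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_worms_t2_coupling_recovers_configured_association(self):
        # Paper-scale cohort: pooled partial correlation between the cartilage
        # WORMS maximum and MF mean T2 lands near the coupling calibration
        # target of 0.31.
        cfg = replace(SimConfig(), seed=77)
        df = true_t2_cohort_table(cfg)
        d = df[df.worms_readable == True]  # noqa: E712
        r, _ = partial_correlation(d, "worms_max_cartilage",
                                   "mean_t2_medial_femur")
        assert r == pytest.approx(0.31, abs=0.15)


class TestStandardizedDifference:
    def test_printed_all_compartment_values(self):
        assert standardized_difference(32.65, 32.07, 1.55, 1.38) == pytest.approx(
            0.396, abs=5e-4)

    def test_equal_means_zero(self):
        assert standardized_difference(5, 5, 1, 2) == 0

    def test_unit_case(self):
        assert standardized_difference(1, 0, 1, 1) == 1

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(InputError):
            standardized_difference(1, 0, 0, 1)


class TestChiSquare:
    def test_printed_sex_table(self):
        stat, p = chi_square_2x2([[50, 42], [36, 17]])
        assert round(stat, 2) == 2.57
        assert p == pytest.approx(0.10, abs=0.015)

    def test_proportional_table_is_null(self):
        stat, p = chi_square_2x2([[20, 10], [40, 20]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            t = rng.integers(1, 60, (2, 2)).astype(float)
            stat, _ = chi_square_2x2(t)
            n = t.sum()
            a, b, c, d = t.ravel()
            hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert stat == pytest.approx(hand, rel=1e-12)

    def test_zero_margin_signaled(self):
        with pytest.raises(DegenerateDataError):
            chi_square_2x2([[0, 0], [5, 3]])
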