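"""Tests for hit rates, Bayes factors, F tests and the accuracy regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tmsdda.io import MISSING
from tmsdda.stats import (
    DEFAULT_PRIOR_WIDTH,
    accuracy_regression,
    bf_paired_onesided,
    bf_robustness,
    bf_two_sided,
    f_pvalue,
    hit_rates,
    relative_accuracy,
)


def behavior_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["participant", "site", "tms", "order", "true_label",
                 "response_label", "correct", "rt"],
    )


class TestHitRates:
    def test_all_correct(self):
        rows = [("P1", "LipM1", t, "CV", "b+A", "b+A", True, 0.5)
                for t in (True, False)]
        rates = hit_rates(behavior_frame(rows))
        assert (rates["hit_rate"] == 1.0).all()

    def test_missing_excluded_from_denominator(self):
        rows = [
            ("P1", "LipM1", True, "CV", "b+A", "b+A", True, 0.5),
            ("P1", "LipM1", True, "CV", "b+i", "b+i", True, 0.5),
            ("P1", "LipM1", True, "CV", "b+u", "b+u", True, 0.5),
            ("P1", "LipM1", True, "CV", "p+A", "b+A", False, 0.5),
            ("P1", "LipM1", True, "CV", "p+i", MISSING, False, np.nan),
        ]
        rates = hit_rates(behavior_frame(rows))
        cell = rates[rates["unit"] == "bilabial"]
        assert cell["n_responded"].iloc[0] == 4
        assert cell["hit_rate"].iloc[0] == 0.75

    def test_category_rate_is_weighted_phoneme_mean(self, rng):
        # consistency identity on a random table
        from tmsdda.synth import SessionConfig, generate_behavioral_cohort

        beh = generate_behavioral_cohort(SessionConfig(), 3, seed=17)
        cat = hit_rates(beh, unit="category")
        pho = hit_rates(beh, unit="phoneme")
        pho["category"] = pho["unit"].map(
            {"b": "bilabial", "p": "bilabial", "d": "alveolar", "t": "alveolar"}
        )
        merged = (
            pho.groupby(["participant", "site", "tms", "category"])
            .apply(
                lambda g: np.average(g["hit_rate"], weights=g["n_responded"]),
                include_groups=False,
            )
            .rename("weighted")
            .reset_index()
        )
        joined = cat.merge(
            merged,
            left_on=["participant", "site", "tms", "unit"],
            right_on=["participant", "site", "tms", "category"],
        )
        assert np.allclose(joined["hit_rate"], joined["weighted"])

    def test_order_filter(self):
        rows = [
            ("P1", "LipM1", True, "CV", "b+A", "b+A", True, 0.5),
            ("P1", "LipM1", True, "VC", "A+b", "A+p", False, 0.5),
        ]
        rates = hit_rates(behavior_frame(rows), order="CV")
        assert rates["hit_rate"].iloc[0] == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            hit_rates(behavior_frame([]))


class TestRelativeAccuracy:
    def rates(self, tms_rate, sham_rate):
        rows = []
        for tms, rate in ((True, tms_rate), (False, sham_rate)):
            rows.append({"participant": "P1", "site": "LipM1", "tms": tms,
                         "unit": "bilabial", "n_responded": 10, "hit_rate": rate})
        return pd.DataFrame(rows)

    def test_equal_rates_give_zero(self):
        rel = relative_accuracy(self.rates(0.8, 0.8))
        assert rel["relative_accuracy"].iloc[0] == 0.0

    def test_sham_can_exceed_tms(self):
        rel = relative_accuracy(self.rates(0.8, 0.9))
        assert np.isclose(rel["relative_accuracy"].iloc[0], -0.1)

    def test_missing_sham_partner_named(self):
        r = self.rates(0.8, 0.9)
        r = r[r["tms"]]
        with pytest.raises(ValueError, match="LipM1"):
            relative_accuracy(r)


class TestBayesFactor:
    def diffs(self, seed=0, mean=0.08, sd=0.1, n=8):
        rng = np.random.default_rng(seed)
        return rng.standard_normal(n) * sd + mean

    def test_one_sided_equals_two_sided_at_t_zero(self):
        # symmetric data: t = 0, the posterior is symmetric about zero
        x = np.array([-0.2, -0.1, -0.05, 0.05, 0.1, 0.2])
        plus = bf_paired_onesided(x).bf_plus0
        both = bf_two_sided(x)
        assert abs(plus - both) < 1e-8

    def test_prior_decomposition_identity(self):
        for seed in range(5):
            x = self.diffs(seed)
            plus = bf_paired_onesided(x, alternative="greater").bf_plus0
            minus = bf_paired_onesided(x, alternative="less").bf_plus0
            both = bf_two_sided(x)
            assert abs(plus + minus - 2 * both) < 1e-8

    def test_quadrature_matches_dense_grid(self):
        # brute-force trapezoid on a dense delta grid as integration oracle
        x = self.diffs(3)
        n = len(x)
        t = x.mean() / (x.std(ddof=1) / np.sqrt(n))
        r = DEFAULT_PRIOR_WIDTH
        grid = np.linspace(0.0, 40.0, 400_001)
        dens = sps.nct.pdf(t, n - 1, grid * np.sqrt(n)) * 2 * sps.cauchy.pdf(grid, 0, r)
        oracle = np.trapezoid(dens, grid) / sps.t.pdf(t, n - 1)
        ours = bf_paired_onesided(x, r).bf_plus0
        assert abs(ours - oracle) / oracle < 1e-6

    def test_matches_pingouin_two_sided(self):
        import pingouin as pg

        for seed in range(3):
            x = self.diffs(seed)
            t = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
            ref = float(pg.bayesfactor_ttest(t, len(x), paired=True,
                                             r=DEFAULT_PRIOR_WIDTH))
            assert abs(bf_two_sided(x) - ref) / ref < 1e-6

    def test_monotone_in_t(self):
        bfs = []
        for mean in (0.0, 0.05, 0.1, 0.2):
            x = np.array([-0.1, -0.05, 0.0, 0.05, 0.1, 0.15, -0.15, 0.02]) + mean
            bfs.append(bf_paired_onesided(x).bf_plus0)
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_vanishing_prior_limit(self):
        x = self.diffs(1)
        assert abs(bf_paired_onesided(x, r=1e-4).bf_plus0 - 1.0) < 1e-2

    def test_error_percent_reported(self):
        res = bf_paired_onesided(self.diffs(2))
        assert res.error_pct >= 0.0
        assert res.error_pct < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            bf_paired_onesided([0.1, 0.1, 0.1])

    def test_robustness_curve(self):
        x = self.diffs(4, mean=0.25, sd=0.1)  # strong effect, t ~ 6
        curve = bf_robustness(x)
        assert (curve.bf_plus0 > 3.0).all()
        # BF varies smoothly along the grid
        ratios = curve.bf_plus0[1:] / curve.bf_plus0[:-1]
        assert np.all(ratios > 0.5) and np.all(ratios < 2.0)


class TestFPvalue:
    def test_f_zero_gives_one(self):
        assert f_pvalue(0.0, 3, 100) == 1.0

    def test_monotone_decreasing_in_f(self):
        ps = [f_pvalue(F, 3, 100) for F in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_matches_incomplete_beta(self):
        for F, d1, d2 in [(2.5, 3, 100), (11.51, 1, 135), (0.7, 9, 119)]:
            ib = sps.beta.sf(d1 * F / (d1 * F + d2), d1 / 2, d2 / 2)
            assert abs(f_pvalue(F, d1, d2) - ib) < 1e-10

    def test_negative_f_rejected(self):
        with pytest.raises(ValueError):
            f_pvalue(-1.0, 1, 10)


class TestAccuracyRegression:
    def cells(self, rng, n_per=20, slope=0.6, noise=0.01):
        n = 8 * n_per
        df = pd.DataFrame(
            {
                "participant": np.repeat([f"S{i}" for i in range(8)], n_per),
                "target": np.tile(
                    np.repeat(["Lip_tms", "Lip_sham", "Tong_tms", "Tong_sham"],
                              n_per // 4), 8
                ),
                "category": np.tile(["bilabial", "alveolar"], n // 2),
                "task_accuracy": rng.uniform(0.5, 1.0, n),
            }
        )
        df["decoding_accuracy"] = (
            0.2 + slope * df["task_accuracy"] + rng.normal(0, noise, n)
        )
        return df

    def test_planted_signal_detected(self, rng):
        tests, _ = accuracy_regression(self.cells(rng))
        ta = next(t for t in tests if t.effect == "task_accuracy")
        assert ta.p < 1e-6

    def test_random_intercept_variance_near_zero(self, rng):
        _, re_var = accuracy_regression(self.cells(rng))
        assert re_var < 1e-4

    def test_type_three_equals_type_one_for_balanced_design(self, rng):
        # factors-only balanced design: sequential and partial sums of
        # squares coincide (a continuous covariate would break exact
        # orthogonality in finite samples)
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = pd.DataFrame(
            {
                "category": np.tile(["bilabial", "alveolar"], 48),
                "target": np.repeat(["Lt", "Ls", "Tt", "Ts"], 24),
                "decoding_accuracy": rng.normal(0.7, 0.05, 96),
            }
        )
        fit = smf.ols(
            "decoding_accuracy ~ C(category, Sum) * C(target, Sum)", df
        ).fit()
        t1 = anova_lm(fit, typ=1)
        t3 = anova_lm(fit, typ=3)
        for eff in ["C(category, Sum)", "C(target, Sum)"]:
            assert np.isclose(t1.loc[eff, "F"], t3.loc[eff, "F"], rtol=1e-8)

    def test_factor_reordering_invariance(self, rng):
        df = self.cells(rng)
        tests_a, _ = accuracy_regression(df)
        remap = {"bilabial": "x_bilabial", "alveolar": "a_alveolar"}
        df2 = df.assign(category=df["category"].map(remap))
        tests_b, _ = accuracy_regression(df2)
        fa = {t.effect: t.F for t in tests_a}
        fb = {t.effect: t.F for t in tests_b}
        for eff in fa:
            assert np.isclose(fa[eff], fb[eff], rtol=1e-8), eff

    def test_null_calibration(self, rng):
        # no dependence at all: p-values should be roughly uniform
        pvals = []
        for _ in range(20):
            df = self.cells(rng, slope=0.0, noise=0.05)
            df["decoding_accuracy"] = rng.normal(0.7, 0.05, len(df))
            tests, _ = accuracy_regression(df, include_interactions=False)
            pvals.extend(t.p for t in tests)
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.0 <= frac <= 0.15

    def test_missing_column_rejected(self, rng):
        with pytest.raises(ValueError, match="missing"):
            accuracy_regression(self.cells(rng).drop(columns="task_accuracy"))
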