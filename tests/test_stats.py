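"""Regression, studentised residuals, outlier flags, concentration, aggregates."""

import numpy as np
import pandas as pd
import pytest

from pacarbon.stats import (classify_outliers, concentration, fit_loglog,
                            studentised_residuals, summarise_categories)


class TestFitLogLog:
    def test_exact_power_law(self):
        """Points on emissions = 10 * area^2 give slope 2, intercept 1, r^2=1."""
        areas = np.array([1.0, 3.0, 10.0, 42.0, 180.0])
        emissions = 10.0 * areas ** 2
        fit = fit_loglog(areas, emissions)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_matches_normal_equations(self):
        """Five hand-chosen points against the closed-form OLS solution."""
        areas = np.array([12.0, 55.0, 130.0, 700.0, 2100.0])
        emissions = np.array([3e3, 9e3, 1.1e5, 2.5e5, 4e6])
        x, y = np.log10(areas), np.log10(emissions)
        n = len(x)
        slope_oracle = (n * (x * y).sum() - x.sum() * y.sum()) / \
                       (n * (x * x).sum() - x.sum() ** 2)
        intercept_oracle = (y.sum() - slope_oracle * x.sum()) / n
        fit = fit_loglog(areas, emissions)
        assert fit.slope == pytest.approx(slope_oracle)
        assert fit.intercept == pytest.approx(intercept_oracle)
        assert np.isclose(fit.residuals.sum(), 0.0, atol=1e-12)

    def test_permutation_invariance(self, rng):
        areas = rng.uniform(10, 1e4, 40)
        emissions = rng.uniform(1e2, 1e6, 40)
        fit = fit_loglog(areas, emissions)
        perm = rng.permutation(40)
        fit_p = fit_loglog(areas[perm], emissions[perm])
        assert fit_p.slope == pytest.approx(fit.slope)
        assert fit_p.r_squared == pytest.approx(fit.r_squared)
        np.testing.assert_allclose(fit_p.residuals, fit.residuals[perm])

    def test_scale_equivariance(self, rng):
        """x10 on emissions shifts the intercept by exactly 1 and nothing else."""
        areas = rng.uniform(10, 1e4, 30)
        emissions = rng.uniform(1e2, 1e6, 30)
        f1 = fit_loglog(areas, emissions)
        f2 = fit_loglog(areas, emissions * 10.0)
        assert f2.slope == pytest.approx(f1.slope)
        assert f2.intercept == pytest.approx(f1.intercept + 1.0)
        assert f2.r_squared == pytest.approx(f1.r_squared)
        np.testing.assert_allclose(f2.residuals, f1.residuals, atol=1e-12)
        np.testing.assert_allclose(studentised_residuals(f2),
                                   studentised_residuals(f1), atol=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_loglog([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            fit_loglog([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="positive"):
            fit_loglog([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestStudentisedResiduals:
    def test_textbook_formula_n6(self):
        """Six points against the step-by-step textbook computation:
        r_i = e_i / (s * sqrt(1 - h_i)), s^2 = SSE/(n-2), h_i = 1/n + dx^2/Sxx."""
        areas = np.array([10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0])
        emissions = np.array([200.0, 900.0, 1800.0, 12_000.0, 21_000.0, 150_000.0])
        fit = fit_loglog(areas, emissions)
        x = np.log10(areas)
        y = np.log10(emissions)
        xbar = x.mean()
        sxx = ((x - xbar) ** 2).sum()
        slope = ((x - xbar) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * xbar
        e = y - intercept - slope * x
        s = np.sqrt((e ** 2).sum() / (6 - 2))
        h = 1 / 6 + (x - xbar) ** 2 / sxx
        oracle = e / (s * np.sqrt(1 - h))
        np.testing.assert_allclose(studentised_residuals(fit), oracle, rtol=1e-12)

    def test_matches_statsmodels_influence(self, rng):
        """Independent cross-check against statsmodels' internal studentisation."""
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.stats.outliers_influence import OLSInfluence
        areas = rng.uniform(10, 5e3, 25)
        emissions = 10 ** (0.8 * np.log10(areas) + rng.normal(0, 0.4, 25) + 1.0)
        fit = fit_loglog(areas, emissions)
        X = sm.add_constant(np.log10(areas))
        res = sm.OLS(np.log10(emissions), X).fit()
        np.testing.assert_allclose(studentised_residuals(fit),
                                   OLSInfluence(res).resid_studentized_internal,
                                   rtol=1e-8)
        np.testing.assert_allclose(studentised_residuals(fit, kind="external"),
                                   OLSInfluence(res).resid_studentized_external,
                                   rtol=1e-8)

    def test_perfect_fit_studentises_to_zero(self):
        areas = np.array([1.0, 10.0, 100.0, 1000.0])
        fit = fit_loglog(areas, 2.0 * areas)
        np.testing.assert_array_equal(studentised_residuals(fit), 0.0)

    def test_symmetric_data_gives_paired_residuals(self):
        """Responses mirrored about the fitted line studentise to +/- pairs."""
        areas = np.array([10.0, 10.0, 100.0, 100.0, 1000.0, 1000.0])
        emissions = np.array([1e3 * 2, 1e3 / 2, 1e4 * 2, 1e4 / 2, 1e5 * 2, 1e5 / 2])
        stud = studentised_residuals(fit_loglog(areas, emissions))
        np.testing.assert_allclose(np.sort(stud[::2]), np.sort(-stud[1::2]))


class TestClassifyOutliers:
    def test_quiet_cohort_has_no_outliers(self, rng):
        resids = rng.uniform(-1, 1, 50)
        rep = classify_outliers(resids, np.ones(50), np.ones(50))
        assert rep.high_idx.size == 0 and rep.low_idx.size == 0

    def test_threshold_is_strict(self):
        resids = np.array([2.0, -2.0, 2.0001, -2.0001, 0.0])
        rep = classify_outliers(resids, np.ones(5), np.ones(5))
        assert rep.high_idx.tolist() == [2]
        assert rep.low_idx.tolist() == [3]

    def test_shares_partition_to_one(self, rng):
        resids = rng.normal(0, 1.5, 200)
        emissions = rng.uniform(0, 100, 200)
        areas = rng.uniform(1, 50, 200)
        rep = classify_outliers(resids, emissions, areas)
        inlier = 1.0 - rep.high_share_of_emissions - rep.low_share_of_emissions
        mask = np.ones(200, dtype=bool)
        mask[rep.high_idx] = mask[rep.low_idx] = False
        assert inlier == pytest.approx(emissions[mask].sum() / emissions.sum())
        assert set(rep.high_idx).isdisjoint(rep.low_idx)


class TestConcentration:
    def test_single_dominant_emitter(self):
        res = concentration(np.array([80.0, 10.0, 5.0, 5.0]), 0.8)
        assert res.n_pas == 1
        assert res.fraction_of_cohort == 0.25
        assert res.subset_emissions == 80.0

    def test_uniform_emissions(self):
        n = 17
        res = concentration(np.full(n, 3.0), 0.8)
        assert res.n_pas == int(np.ceil(0.8 * n))

    def test_matches_exhaustive_prefix_scan(self, rng):
        for _ in range(20):
            e = rng.uniform(0, 10, int(rng.integers(3, 30)))
            res = concentration(e, 0.8)
            order = np.argsort(-e, kind="stable")
            total = e.sum()
            k_oracle = next(k for k in range(1, e.size + 1)
                            if e[order[:k]].sum() / total >= 0.8 - 1e-12)
            assert res.n_pas == k_oracle

    def test_full_share_needs_all_nonzero(self):
        e = np.array([5.0, 0.0, 3.0, 2.0, 0.0])
        res = concentration(e, 1.0)
        assert res.n_pas == 3  # every PA with any emissions, none of the zeros
        assert res.cumulative_shares[-1] == pytest.approx(1.0)

    def test_monotone_cumulative_shares(self, rng):
        res = concentration(rng.uniform(0, 5, 40), 0.5)
        assert np.all(np.diff(res.cumulative_shares) >= -1e-15)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            concentration(np.zeros(4))


class TestSummariseCategories:
    @staticmethod
    def cohort(rng, n=60):
        cats = rng.choice(["Ia", "II", "IV", "VI"], n)
        countries = rng.choice(["Brazil", "Indonesia", "Cambodia"], n)
        stock = rng.uniform(1e5, 1e7, n)
        loss = stock * rng.uniform(0, 0.3, n)
        return pd.DataFrame({
            "iucn_cat": cats, "country": countries,
            "carbon_stock_mg": stock, "carbon_loss_mg": loss,
            "annual_carbon_loss_mg_yr": loss / 12.0,
            "annual_loss_rate_pct_yr": rng.uniform(0, 2.5, n),
            "carbon_density_mg_ha": rng.uniform(50, 200, n),
        })

    def test_single_category_equals_cohort_mean(self, rng):
        df = self.cohort(rng)
        df["iucn_cat"] = "II"
        summary = summarise_categories(df)
        assert len(summary.by_category) == 1
        row = summary.by_category.iloc[0]
        assert row["mean_loss_rate_pct_yr"] == pytest.approx(
            df["annual_loss_rate_pct_yr"].mean())

    def test_matches_groupby_oracle(self, rng):
        df = self.cohort(rng)
        summary = summarise_categories(df)
        for _, row in summary.by_category.iterrows():
            grp = df[df["iucn_cat"] == row["iucn_cat"]]
            rates = grp["annual_loss_rate_pct_yr"].to_numpy()
            assert row["n_pas"] == len(grp)
            assert row["mean_carbon_density_mg_ha"] == pytest.approx(
                grp["carbon_density_mg_ha"].mean())
            assert row["median_loss_rate_pct_yr"] == pytest.approx(np.median(rates))
            assert row["q1_loss_rate_pct_yr"] == pytest.approx(np.percentile(rates, 25))
        for _, row in summary.by_country.iterrows():
            grp = df[df["country"] == row["country"]]
            assert row["proportional_carbon_loss"] == pytest.approx(
                grp["carbon_loss_mg"].sum() / grp["carbon_stock_mg"].sum())

    def test_zero_loss_country(self, rng):
        df = self.cohort(rng, n=10)
        df.loc[df["country"] == "Cambodia", ["carbon_loss_mg",
                                             "annual_carbon_loss_mg_yr"]] = 0.0
        summary = summarise_categories(df)
        row = summary.by_country.set_index("country").loc["Cambodia"]
        assert row["proportional_carbon_loss"] == 0.0

    def test_whiskers_bounded_by_1p5_iqr(self, rng):
        df = self.cohort(rng, n=200)
        summary = summarise_categories(df)
        for _, row in summary.by_category.iterrows():
            iqr = row["q3_loss_rate_pct_yr"] - row["q1_loss_rate_pct_yr"]
            assert row["whisker_low_pct_yr"] >= row["q1_loss_rate_pct_yr"] - 1.5 * iqr - 1e-12
            assert row["whisker_high_pct_yr"] <= row["q3_loss_rate_pct_yr"] + 1.5 * iqr + 1e-12

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarise_categories(pd.DataFrame())
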