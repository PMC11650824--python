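"""OLS regression, stratum comparison, and quarter contrasts."""

import datetime

import numpy as np
import pytest

from rhizopipe import compare, synthetic
from rhizopipe.geometry import DepthProfile, QuarterSummary
from rhizopipe.io import CoreRecord, RhizopipeError


class TestFitLinear:
    def test_exact_line_recovers_published_coefficients(self):
        x = np.linspace(5, 150, 20)
        y = 0.10 + 0.0104 * x
        res = compare.fit_linear(x, y)
        assert res.slope == pytest.approx(0.0104, abs=1e-12)
        assert res.intercept == pytest.approx(0.10, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_y_zero_slope_zero_r2(self):
        x = np.arange(10.0)
        y = np.full(10, 3.0)
        res = compare.fit_linear(x, y)
        assert res.slope == 0.0
        assert res.r_squared == 0.0

    def test_matches_statsmodels_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.uniform(0, 100, n)
            y = rng.normal(1 + 0.5 * x, 5.0)
            res = compare.fit_linear(x, y)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            assert res.intercept == pytest.approx(fit.params[0], abs=1e-8)
            assert res.slope == pytest.approx(fit.params[1], abs=1e-8)
            assert res.r_squared == pytest.approx(fit.rsquared, abs=1e-8)
            assert res.slope_p == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        """Closed-form fit equals an independent normal-equations solve."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 50))
            x = rng.uniform(-10, 10, n)
            if np.var(x) == 0:
                continue
            y = rng.normal(0, 3, n)
            res = compare.fit_linear(x, y)
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert res.intercept == pytest.approx(beta[0], abs=1e-8)
            assert res.slope == pytest.approx(beta[1], abs=1e-8)

    def test_r2_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 30)
        y = rng.normal(2 * x, 1.0)
        base = compare.fit_linear(x, y).r_squared
        scaled = compare.fit_linear(100 * x - 7, 0.01 * y + 3).r_squared
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_too_few_points_fatal(self):
        with pytest.raises(RhizopipeError):
            compare.fit_linear(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_zero_variance_fatal(self):
        with pytest.raises(RhizopipeError):
            compare.fit_linear(np.ones(5), np.arange(5.0))

    def test_slope_in_ci_at_nominal_rate(self):
        """95% CI covers the generator slope at close to the nominal rate."""
        from scipy import stats

        hits = 0
        reps = 200
        for rep in range(reps):
            x, y = synthetic.generate_paired_method_data(
                slope=0.0104, intercept=0.10, sigma=0.35, n=36, seed=900 + rep
            )
            res = compare.fit_linear(x, y)
            resid = y - (res.intercept + res.slope * x)
            se = np.sqrt(
                (resid**2).sum() / (res.n - 2) / ((x - x.mean()) ** 2).sum()
            )
            tcrit = stats.t.ppf(0.975, res.n - 2)
            if abs(res.slope - 0.0104) <= tcrit * se:
                hits += 1
        assert 0.95 - 0.03 <= hits / reps <= 1.0


def _profile(plot, date, bins):
    return DepthProfile(
        tube_id=plot, plot_id=plot, scan_date=date,
        bins={lab: bins.get(lab, 0.0) for lab in ("0-30", "30-60", "60-90", "90-120")},
    )


class TestCompareMethods:
    def _make_paired(self, n_plots=12, seed=0):
        """Profiles + cores generated with stratum-specific linear links."""
        rng = np.random.default_rng(seed)
        date = datetime.date(2022, 5, 20)
        slopes = {"0-30": 0.002, "30-60": 0.010, "60-90": 0.012, "90-120": 0.014}
        profiles, cores = [], []
        for i in range(n_plots):
            bins = {}
            for lab, slope in slopes.items():
                length = rng.uniform(20, 150)
                bins[lab] = length
                rld = 0.1 + slope * length + rng.normal(0, 0.02)
                cores.append(CoreRecord(f"P{i}", lab, max(rld, 0.0), date))
            profiles.append(_profile(f"P{i}", date, bins))
        return profiles, cores

    def test_two_strata_two_results(self):
        profiles, cores = self._make_paired()
        res = compare.compare_methods(
            profiles, cores, strata=(("0-30", ("0-30",)), ("30-120", ("30-60", "60-90", "90-120")))
        )
        assert [r.stratum for r in res] == ["0-30", "30-120"]
        assert all(r.fit_ok for r in res)

    def test_default_strata_cover_topsoil_subsoil_and_bins(self):
        profiles, cores = self._make_paired()
        res = compare.compare_methods(profiles, cores)
        assert [r.stratum for r in res] == ["0-30", "30-120", "30-60", "60-90", "90-120"]

    def test_no_matching_plots_all_unfit(self):
        profiles, _ = self._make_paired()
        other_cores = [
            CoreRecord("Z9", "30-60", 0.5, datetime.date(2022, 5, 20))
        ]
        res = compare.compare_methods(profiles, other_cores)
        assert all(not r.fit_ok for r in res)

    def test_date_window_excludes_distant_samplings(self):
        profiles, cores = self._make_paired()
        far = [
            CoreRecord(r.plot_id, r.depth_bin, r.rld, datetime.date(2022, 9, 1))
            for r in cores
        ]
        res = compare.compare_methods(profiles, far, date_window_days=21)
        assert all(not r.fit_ok for r in res)


def _summary(vals, tube="T01", date=datetime.date(2022, 5, 20)):
    return QuarterSummary(
        tube_id=tube, scan_date=date,
        lengths=dict(zip(("above", "right", "below", "left"), vals)),
    )


class TestQuarterContrast:
    def test_single_summary_means_equal_inputs_sd_missing(self):
        df = compare.quarter_contrast([_summary((10.0, 20.0, 30.0, 40.0))])
        by = df.set_index("quarter")
        assert by.loc["above", "mean_cm"] == 10.0
        assert by.loc["left", "mean_cm"] == 40.0
        assert df["sd_cm"].isna().all()

    def test_identical_summaries_sd_zero(self):
        df = compare.quarter_contrast([_summary((10, 20, 30, 40))] * 2)
        assert (df["sd_cm"] == 0.0).all()

    def test_empty_input_fatal(self):
        with pytest.raises(RhizopipeError):
            compare.quarter_contrast([])

    def test_below_shift_detected_in_most_replicates(self):
        """A +40 cm shift below the tube shows as the highest quarter mean."""
        wins = 0
        reps = 50
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            summaries = [
                _summary(
                    (
                        rng.normal(85, 30),
                        rng.normal(85, 30),
                        rng.normal(125, 30),  # below shifted up
                        rng.normal(85, 30),
                    ),
                    tube=f"T{i}",
                )
                for i in range(12)
            ]
            df = compare.quarter_contrast(summaries).set_index("quarter")
            if df["mean_cm"].idxmax() == "below":
                wins += 1
        assert wins >= int(0.9 * reps)

    def test_long_table_one_row_per_tube_quarter(self):
        df = compare.quarter_long_table([_summary((1, 2, 3, 4)), _summary((5, 6, 7, 8), "T02")])
        assert len(df) == 8
        assert set(df.columns) >= {"tube_id", "quarter", "root_length_cm"}


class TestPairedGenerator:
    def test_zero_noise_exact_recovery(self):
        x, y = synthetic.generate_paired_method_data(0.0104, 0.10, 0.0, 20, seed=1)
        res = compare.fit_linear(x, y)
        assert res.slope == pytest.approx(0.0104, abs=1e-12)
        assert res.intercept == pytest.approx(0.10, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_identical(self):
        a = synthetic.generate_paired_method_data(0.01, 0.1, 0.3, 36, seed=5)
        b = synthetic.generate_paired_method_data(0.01, 0.1, 0.3, 36, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_mean_fitted_slope_unbiased(self):
        slopes = []
        for rep in range(200):
            x, y = synthetic.generate_paired_method_data(
                0.0104, 0.10, 0.35, 36, seed=2000 + rep
            )
            slopes.append(compare.fit_linear(x, y).slope)
        assert np.mean(slopes) == pytest.approx(0.0104, rel=0.05)
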