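"""Runs test, Hodges–Lehmann, Theil regression, Jarque–Bera, Smirnov."""

import itertools
import math

import numpy as np
import pytest

from censuswalk import (
    hl_median_ci,
    jarque_bera,
    runs_test,
    smirnov_two_sample,
    theil_regression,
)
from censuswalk.nonparam import runs_pmf
from censuswalk.synthgen import NoiseSpec, gen_cauchy, gen_gaussian


def enumerate_runs_pmf(n_above, n_below):
    """Brute-force null pmf of the run count by exhausting all arrangements."""
    n = n_above + n_below
    counts = {}
    total = 0
    for positions in itertools.combinations(range(n), n_above):
        signs = np.zeros(n, dtype=bool)
        signs[list(positions)] = True
        r = 1 + int(np.count_nonzero(signs[1:] != signs[:-1]))
        counts[r] = counts.get(r, 0) + 1
        total += 1
    pmf = np.zeros(n + 1)
    for r, c in counts.items():
        pmf[r] = c / total
    return pmf


class TestRunsTest:
    def test_alternating_sequence_upper_tail(self):
        # 10 points, 5 above / 5 below, perfectly alternating: 10 runs,
        # P(R >= 10) = 2/C(10,5) = 2/252
        ys = np.array([1, 10, 2, 11, 3, 12, 4, 13, 5, 14], dtype=float)
        result = runs_test(ys)
        assert result.n_runs == 10
        assert result.n_above == result.n_below == 5
        pmf = runs_pmf(5, 5)
        assert pmf[10:].sum() == pytest.approx(2 / 252)
        assert result.p_two_sided == pytest.approx(2 * 2 / 252)

    def test_lower_tail_combinatorial_value(self):
        # 11 above, 11 below, 5 runs: P(R <= 5) = 1122/705432
        pmf = runs_pmf(11, 11)
        assert pmf[:6].sum() * math.comb(22, 11) == pytest.approx(1122)
        assert pmf[:6].sum() == pytest.approx(1122 / 705432)

    @pytest.mark.parametrize(
        "n_above,n_below",
        [(2, 2), (3, 4), (5, 5), (6, 3), (6, 6), (5, 7), (2, 10)],
    )
    def test_exact_pmf_equals_enumeration(self, n_above, n_below):
        """The combinatorial run-count distribution matches exhaustive
        enumeration for every split with n_used <= 12."""
        assert np.allclose(
            runs_pmf(n_above, n_below), enumerate_runs_pmf(n_above, n_below)
        )

    def test_constant_sequence_rejected(self):
        with pytest.raises(ValueError):
            runs_test(np.full(10, 3.0))

    def test_one_sided_sequence_rejected(self):
        with pytest.raises(ValueError):
            runs_test(np.array([1.0, 1.0, 5.0]))  # median ties drop the rest

    def test_exact_and_normal_approx_agree_mid_sample(self):
        """On white noise with 20–40 usable points the exact tail and the
        continuity-corrected normal approximation differ by < 0.02."""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 25:
            n = int(rng.integers(20, 41))
            ys = rng.normal(size=n)
            result = runs_test(ys)
            if result.method != "exact":
                continue
            m, k = result.n_above, result.n_below
            mean = 1 + 2 * m * k / (m + k)
            var = 2 * m * k * (2 * m * k - m - k) / ((m + k) ** 2 * (m + k - 1))
            from scipy.stats import norm

            approx = norm.cdf((result.n_runs + 0.5 - mean) / math.sqrt(var))
            assert abs(approx - result.p_lower) < 0.02
            checked += 1

    def test_mean_run_count_on_white_noise(self):
        """i.i.d. sequences produce about n/2 + 1 runs."""
        totals = []
        for seed in range(500):
            ys = gen_gaussian(NoiseSpec("gaussian", 100, seed=seed))
            totals.append(runs_test(ys).n_runs)
        n_used = 100  # continuous draws: no median ties
        assert abs(np.mean(totals) - (n_used / 2 + 1)) < 0.05 * (n_used / 2 + 1)

    def test_matches_statsmodels_normal_approximation(self):
        statsmodels = pytest.importorskip("statsmodels.sandbox.stats.runs")
        rng = np.random.default_rng(8)
        ys = rng.normal(size=200)
        result = runs_test(ys)
        med = np.median(ys)
        _, p_sm = statsmodels.runstest_1samp(ys, cutoff=med, correction=True)
        assert result.method == "normal_approx"
        # statsmodels drops the continuity correction for n >= 50; the two
        # conventions agree only to ~the correction's width
        assert abs(result.p_two_sided - p_sm) < 0.05


class TestHodgesLehmann:
    def test_small_sample_walsh_enumeration(self):
        estimate, lo, hi = hl_median_ci([1.0, 2.0, 3.0])
        # Walsh averages {1, 1.5, 2, 2, 2.5, 3}
        assert estimate == 2.0
        assert lo == 1.0 and hi == 3.0

    def test_single_observation_degenerate(self):
        assert hl_median_ci([4.2]) == (4.2, 4.2, 4.2)

    def test_symmetric_sample_centers_at_zero(self):
        ys = np.arange(-5.0, 6.0)
        estimate, lo, hi = hl_median_ci(ys)
        assert estimate == 0.0
        assert lo == -hi

    def test_gaussian_coverage(self):
        """95% interval covers the true median in 93–97% of samples (n=30)."""
        rng = np.random.default_rng(17)
        covered = 0
        reps = 500
        for _ in range(reps):
            ys = rng.normal(10.0, 2.0, size=30)
            _, lo, hi = hl_median_ci(ys)
            covered += lo <= 10.0 <= hi
        assert 0.93 * reps <= covered <= 0.97 * reps

    def test_large_sample_normal_approximation_path(self):
        rng = np.random.default_rng(4)
        ys = rng.normal(100.0, 5.0, size=400)
        estimate, lo, hi = hl_median_ci(ys)
        assert lo < estimate < hi
        assert hi - lo < 2.5  # roughly 2 * 1.96 * sigma * sqrt(pi/3) / sqrt(n)


class TestTheilRegression:
    def test_exact_line_recovered(self):
        xs = np.arange(10.0)
        fit = theil_regression(xs, 2.0 * xs + 1.0)
        assert fit.beta == pytest.approx(2.0)
        assert fit.alpha == pytest.approx(1.0)
        assert fit.rho_s == pytest.approx(1.0)

    def test_single_outlier_cannot_move_slope(self):
        xs = np.arange(11.0)
        ys = 2.0 * xs + 1.0
        ys[5] = 500.0
        fit = theil_regression(xs, ys)
        assert fit.beta == pytest.approx(2.0)

    def test_antitone_relation_gives_rho_minus_one(self):
        xs = np.arange(8.0)
        fit = theil_regression(xs, -3.0 * xs + 2.0)
        assert fit.rho_s == pytest.approx(-1.0)

    def test_identical_abscissae_rejected(self):
        with pytest.raises(ValueError):
            theil_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_slope_recovery_under_cauchy_noise(self):
        """The median-of-pairwise-slopes estimator survives noise with no
        moments: over seeds the median slope estimate stays within 5%."""
        beta = 3.0
        xs = np.arange(40.0)
        estimates = []
        for seed in range(200):
            noise = gen_cauchy(NoiseSpec("cauchy", 40, seed=seed))
            fit = theil_regression(xs, beta * xs + noise)
            estimates.append(fit.beta)
        assert abs(np.median(estimates) - beta) < 0.05 * beta


class TestJarqueBera:
    def test_hand_computed_moments(self):
        # {-1,1,-1,1}: skewness 0, kurtosis 1, JB = 4/6 * (0 + 4/4) = 2/3
        statistic, p = jarque_bera([-1.0, 1.0, -1.0, 1.0])
        assert statistic == pytest.approx(2.0 / 3.0)

    def test_matches_scipy_on_large_sample(self):
        from scipy import stats

        ys = gen_gaussian(NoiseSpec("gaussian", 2000, seed=1))
        ours, p_ours = jarque_bera(ys)
        ref = stats.jarque_bera(ys)
        assert ours == pytest.approx(ref.statistic, rel=1e-10)
        assert p_ours == pytest.approx(ref.pvalue, rel=1e-8)

    def test_type_one_error_calibrated(self):
        """On Gaussian samples the rejection rate at alpha=0.05 stays in the
        [0.02, 0.09] band over 200 seeds (the chi2 reference is asymptotic)."""
        rejections = 0
        for seed in range(200):
            ys = gen_gaussian(NoiseSpec("gaussian", 10_000, seed=1000 + seed))
            _, p = jarque_bera(ys)
            rejections += p < 0.05
        assert 0.02 * 200 <= rejections <= 0.09 * 200

    def test_power_against_heavy_tails(self):
        rejections = 0
        for seed in range(100):
            ys = gen_cauchy(NoiseSpec("cauchy", 1000, seed=seed))
            _, p = jarque_bera(ys)
            rejections += p < 0.05
        assert rejections >= 95

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            jarque_bera(np.full(20, 1.0))


class TestSmirnov:
    def test_identical_samples(self):
        a = np.arange(10.0)
        d, p = smirnov_two_sample(a, a)
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = smirnov_two_sample([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert d == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            smirnov_two_sample([], [1.0])

    def test_panel_difference_series_indistinguishable(self, clean_panel):
        """On artifact-free panels the census daily variation and the
        admissions-minus-discharges difference share a distribution, while
        admissions and discharges with asymmetric zero-inflation do not."""
        from censuswalk import daily_diff, ddiad

        dinp = daily_diff(clean_panel.inp).values[1:]
        dd = ddiad(clean_panel).values[1:]
        _, p_same = smirnov_two_sample(dinp, dd)
        assert p_same > 0.5

        rng = np.random.default_rng(0)
        adm = clean_panel.adm.copy()
        zeroed = rng.random(len(adm)) < 0.3  # extra no-admission days
        adm[zeroed] = 0.0
        _, p_diff = smirnov_two_sample(adm, clean_panel.dis)
        assert p_diff < 1e-4
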