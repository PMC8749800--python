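"""Method-comparison statistics: gates, bias tests, LoA, coefficients."""

import numpy as np
import pytest
from scipy import stats

import imugait as ig
from imugait import GaitSpec, PairedMeasurements


class TestNormalityGate:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(11)
        ok, p = ig.normality_test(rng.normal(0, 1, 1000))
        assert ok and p >= 0.05

    def test_uniform_sample_fails(self):
        rng = np.random.default_rng(11)
        ok, _ = ig.normality_test(rng.uniform(0, 1, 1000))
        assert not ok

    def test_rejection_rate_close_to_alpha(self):
        """The KS gate with estimated parameters is conservative: its
        false-rejection rate on truly normal data stays below alpha."""
        rng = np.random.default_rng(21)
        rejected = sum(not ig.normality_test(rng.normal(5, 2, 300))[0]
                       for _ in range(300))
        assert rejected / 300 <= 0.05

    def test_constant_sample_degenerate(self):
        ok, p = ig.normality_test([3.0, 3.0, 3.0])
        assert not ok and np.isnan(p)

    def test_lilliefors_variant_available(self):
        rng = np.random.default_rng(2)
        ok, _ = ig.normality_test(rng.normal(0, 1, 200), method="lilliefors")
        assert ok


class TestFixedBiasTest:
    def test_all_zero_differences(self):
        assert ig.fixed_bias_test(np.zeros(50), normal=False) == 1.0

    def test_shifted_normal_detected(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.5, 1.0, 342)
        assert ig.fixed_bias_test(d, normal=True) < 0.001
        assert ig.fixed_bias_test(d, normal=False) < 0.001

    def test_symmetric_differences_rarely_flagged(self):
        rng = np.random.default_rng(4)
        n_pass = sum(ig.fixed_bias_test(rng.normal(0, 1, 342), normal=False) >= 0.05
                     for _ in range(200))
        assert n_pass >= 180  # >= 90% of simulations

    def test_zero_inclusive_rank_treatment(self):
        # grid-snapped differences contain many exact zeros; Pratt keeps them
        d = np.array([0.0] * 30 + [10.0] * 6 + [-10.0] * 4)
        p = ig.fixed_bias_test(d, normal=False)
        assert 0.0 < p < 1.0


class TestProportionalBiasTest:
    def test_independent_series(self):
        rng = np.random.default_rng(5)
        a, d = rng.normal(50, 5, 500), rng.normal(0, 1, 500)
        r, p = ig.proportional_bias_test(d, a, normal_both=True)
        assert abs(r) < 0.15

    def test_proportional_relation_detected(self):
        rng = np.random.default_rng(6)
        a = rng.normal(50, 5, 500)
        d = 0.3 * a + rng.normal(0, 1, 500)
        for normal_both in (True, False):
            r, p = ig.proportional_bias_test(d, a, normal_both)
            assert p < 0.05 and r > 0.5

    def test_constant_differences_convention(self):
        r, p = ig.proportional_bias_test(np.full(20, 2.0), np.arange(20.0), True)
        assert r == 0.0 and p == 1.0


class TestClassicLoa:
    def test_normal_large_sample(self):
        rng = np.random.default_rng(5)
        lo, hi = ig.loa_classic(rng.normal(0, 1, 100_000), normal=True)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_constant_differences(self):
        assert ig.loa_classic(np.full(10, 3.0), normal=True) == (3.0, 3.0)

    def test_uniform_percentiles(self):
        rng = np.random.default_rng(5)
        lo, hi = ig.loa_classic(rng.uniform(0, 1, 100_000), normal=False)
        assert lo == pytest.approx(0.025, abs=0.005)
        assert hi == pytest.approx(0.975, abs=0.005)


class TestParametricCorrectedLoa:
    def test_zero_slope_recovers_classic_width(self):
        # E|R| = sigma*sqrt(2/pi) makes 1.96*sqrt(pi/2)*E|R| = 1.96*sigma
        rng = np.random.default_rng(8)
        a = rng.normal(100, 10, 100_000)
        d = 2.0 + rng.normal(0, 1.5, 100_000)
        pa, (lo, hi) = ig.loa_parametric_corrected(d, a)
        at_mean = pa[0] + pa[1] * a.mean()
        assert at_mean == pytest.approx(2.0, abs=0.02)
        assert pa[1] == pytest.approx(0.0, abs=0.002)
        half = hi[0] - pa[0]
        assert half == pytest.approx(1.96 * 1.5, rel=0.02)
        c_lo, c_hi = ig.loa_classic(d, normal=True)
        assert hi[0] + hi[1] * a.mean() == pytest.approx(c_hi, rel=0.02)
        assert lo[0] + lo[1] * a.mean() == pytest.approx(c_lo, rel=0.02)

    def test_noise_free_linear_bias_collapses_the_band(self):
        a = np.linspace(0, 10, 200)
        d = 1.5 + 0.4 * a
        pa, (lo, hi) = ig.loa_parametric_corrected(d, a)
        assert pa == pytest.approx((1.5, 0.4))
        assert lo == pytest.approx(pa) and hi == pytest.approx(pa)

    def test_matches_independent_least_squares(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 3, 200)
        d = 0.7 * a + rng.normal(0, 1, 200)
        pa, _ = ig.loa_parametric_corrected(d, a)
        slope, intercept = np.polyfit(a, d, 1)  # independent oracle
        assert pa == pytest.approx((intercept, slope))

    def test_constant_averages_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ig.loa_parametric_corrected(np.arange(5.0), np.ones(5))


def pinball_grid_oracle(d, a, tau, b0s, b1s):
    """Exhaustive pinball-loss minimisation over a coefficient grid."""
    best, best_loss = None, np.inf
    for b0 in b0s:
        for b1 in b1s:
            r = d - (b0 + b1 * a)
            loss = np.sum(np.where(r >= 0, tau * r, (tau - 1) * r))
            if loss < best_loss:
                best, best_loss = (b0, b1), loss
    return best


class TestQuantileCorrectedLoa:
    def test_median_line_matches_grid_search_oracle(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(0, 10, 50)
        d = 1.0 + 0.5 * a + rng.laplace(0, 0.5, 50)
        pa, _ = ig.loa_quantile_corrected(d, a)
        b0s = np.arange(0.0, 2.01, 0.05)
        b1s = np.arange(0.0, 1.01, 0.02)
        o0, o1 = pinball_grid_oracle(d, a, 0.50, b0s, b1s)
        assert pa[0] == pytest.approx(o0, abs=0.1)
        assert pa[1] == pytest.approx(o1, abs=0.04)

    def test_constant_differences_give_constant_lines(self):
        pa, (lo, hi) = ig.loa_quantile_corrected(np.full(30, 2.5), np.arange(30.0))
        assert pa == (2.5, 0.0) and lo == (2.5, 0.0) and hi == (2.5, 0.0)

    def test_uniform_noise_closed_form(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(0, 20, 100_000)
        d = a + rng.uniform(-1, 1, 100_000)
        pa, (lo, hi) = ig.loa_quantile_corrected(d, a)
        assert hi[0] == pytest.approx(0.95, abs=0.02)
        assert lo[0] == pytest.approx(-0.95, abs=0.02)
        assert pa[1] == pytest.approx(1.0, abs=0.01)
        assert lo[1] == pytest.approx(1.0, abs=0.01)

    def test_outer_lines_bracket_95_percent(self):
        rng = np.random.default_rng(14)
        a = rng.normal(50, 10, 100_000)
        d = 0.2 * a + rng.normal(0, 2, 100_000)
        _, (lo, hi) = ig.loa_quantile_corrected(d, a)
        inside = np.mean((d >= lo[0] + lo[1] * a) & (d <= hi[0] + hi[1] * a))
        assert 0.94 <= inside <= 0.96

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            ig.loa_quantile_corrected(np.arange(5.0), np.arange(5.0) * 2)


class TestIcc:
    def test_identity_is_one(self):
        x = np.arange(30.0)
        assert ig.icc(x, x, "2,1") == pytest.approx(1.0)
        assert ig.icc(x, x, "2,k") == pytest.approx(1.0)

    def test_variance_component_closed_form(self):
        # between-target variance 9*sigma^2 -> ICC(2,1) ~ 9/10
        rng = np.random.default_rng(9)
        truth = rng.normal(0, 3.0, 500)
        x1 = truth + rng.normal(0, 1.0, 500)
        x2 = truth + rng.normal(0, 1.0, 500)
        assert ig.icc(x1, x2, "2,1") == pytest.approx(0.9, abs=0.03)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(15)
        val = ig.icc(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000), "2,1")
        assert abs(val) < 0.1

    def test_average_measure_at_least_single_measure(self):
        rng = np.random.default_rng(16)
        for _ in range(25):
            t = rng.normal(0, rng.uniform(0.5, 3), 40)
            x1 = t + rng.normal(0, 1, 40)
            x2 = t + rng.normal(0, 1, 40) + rng.uniform(-1, 1)
            assert ig.icc(x1, x2, "2,k") >= ig.icc(x1, x2, "2,1") - 1e-12

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(17)
        t = rng.normal(10, 2, 60)
        x1 = t + rng.normal(0, 1, 60)
        x2 = 0.5 + t + rng.normal(0, 1, 60)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(60), 2),
            "raters": np.repeat(["a", "b"], 60),
            "scores": np.concatenate([x1, x2]),
        })
        res = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores").set_index("Type")
        # two-way random, absolute agreement = pingouin's ICC(A,1)/(A,k)
        assert ig.icc(x1, x2, "2,1") == pytest.approx(res.loc["ICC(A,1)", "ICC"],
                                                      abs=1e-6)
        assert ig.icc(x1, x2, "2,k") == pytest.approx(res.loc["ICC(A,k)", "ICC"],
                                                      abs=1e-6)


class TestKendallsW:
    def test_identical_rankings_with_ties(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 5.0])
        assert ig.kendalls_w(x, x) == pytest.approx(1.0)

    def test_reversed_untied_rankings(self):
        x = np.arange(10.0)
        assert ig.kendalls_w(x, x[::-1]) == pytest.approx(0.0)

    def test_random_rankings_average_one_half(self):
        # for two raters W = (rho_s + 1)/2, so E[W] ~ 0.5 on independent data
        rng = np.random.default_rng(18)
        ws = [ig.kendalls_w(rng.permutation(342).astype(float),
                            rng.permutation(342).astype(float))
              for _ in range(60)]
        assert np.mean(ws) == pytest.approx(0.5, abs=0.02)

    def test_relation_to_spearman_for_two_raters(self):
        rng = np.random.default_rng(19)
        x = np.round(rng.normal(50, 10, 100), 0)  # discrete -> ties
        y = np.round(x + rng.normal(0, 5, 100), 0)
        rho = stats.spearmanr(x, y).statistic  # independent oracle
        assert ig.kendalls_w(x, y) == pytest.approx((rho + 1) / 2, abs=1e-6)

    def test_invariant_under_common_monotone_transform(self):
        rng = np.random.default_rng(20)
        x = rng.normal(10, 2, 80)
        y = x + rng.normal(0, 1, 80)
        w0 = ig.kendalls_w(x, y)
        assert ig.kendalls_w(np.exp(x / 5), np.exp(y / 5)) == pytest.approx(w0)


class TestInterpretationBands:
    @pytest.mark.parametrize("value,band", [
        (0.9, "excellent"), (0.70, "good"), (0.45, "fair"), (0.2, "poor")])
    def test_icc_bands(self, value, band):
        assert ig.interpret_icc(value) == band

    @pytest.mark.parametrize("value,band", [
        (0.8, "strong"), (0.45, "moderate"), (0.2, "weak"), (0.05, "almost none")])
    def test_w_bands(self, value, band):
        assert ig.interpret_w(value) == band


class TestPipeline:
    def test_equal_pairs_give_perfect_agreement(self):
        x = np.arange(100.0)
        rep = ig.run_agreement_pipeline(PairedMeasurements(x, x.copy()))
        assert rep.accuracy == 0.0 and rep.precision == 0.0
        assert rep.coefficient == pytest.approx(1.0)

    def test_normal_with_proportional_bias_takes_parametric_branch(self):
        rng = np.random.default_rng(22)
        ref = rng.normal(100, 10, 400)
        test = ref + 0.2 * (ref - 100) + rng.normal(0, 1, 400)
        rep = ig.run_agreement_pipeline(PairedMeasurements(ref, test))
        assert rep.normal_d and rep.prop_bias_p < 0.05
        assert rep.loa_method == "parametric"
        assert isinstance(rep.loa_upper, tuple)
        assert rep.coefficient_type == "ICC(2,1)"

    def test_non_normal_proportional_bias_takes_quantile_branch(self):
        rng = np.random.default_rng(23)
        ref = rng.lognormal(4.0, 0.5, 400)  # clearly skewed measurements
        test = ref + 0.2 * (ref - ref.mean()) + rng.exponential(3.0, 400)
        rep = ig.run_agreement_pipeline(PairedMeasurements(ref, test))
        assert not rep.normal_both
        assert rep.loa_method == "quantile"
        assert rep.coefficient_type == "KendallW"

    def test_grid_snapped_jitter_behaves_like_discrete_comparison(self):
        pairs = ig.generate_paired_measurements(
            GaitSpec(seed=5, n_strides=342, gc_sd_ms=40.0, gc_ms=1100),
            jitter_sd_ms=15.0)
        rep = ig.run_agreement_pipeline(pairs)
        # QD of N(0, 15 ms) differences is ~10 ms after 10 ms grid snapping
        assert not rep.normal_d or rep.precision <= 16
        assert 6.0 <= (rep.precision if not rep.normal_d else 0.6745 * rep.precision) <= 14.0

    def test_multi_stride_switches_to_average_measure_icc(self):
        rng = np.random.default_rng(24)
        ref = rng.normal(200, 20, 300)
        test = ref + rng.normal(0, 5, 300)
        r1 = ig.run_agreement_pipeline(PairedMeasurements(ref, test))
        rk = ig.run_agreement_pipeline(PairedMeasurements(ref, test),
                                       multi_stride=True)
        if r1.coefficient_type.startswith("ICC"):
            assert rk.coefficient >= r1.coefficient

    def test_report_serialises_to_json_friendly_dict(self):
        x = np.arange(50.0)
        rep = ig.run_agreement_pipeline(PairedMeasurements(x, x + 1.0))
        d = rep.to_dict()
        assert isinstance(d["pa_line"], dict)
        assert set(d) >= {"accuracy", "precision", "loa_lower", "loa_upper",
                          "coefficient", "interpretation"}
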