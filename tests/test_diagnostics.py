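"""QQ diagnostics, model selection, confidence intervals, chi-squared."""

import math

import numpy as np
import pytest
from scipy import stats

import nanomix as nm
from nanomix.errors import ValidationError


def make_model(weights, means, sigmas):
    return nm.MixtureModel.from_arrays(weights, means, sigmas)


SYMMETRIC_PAIR = make_model([0.5, 0.5], [-3.0, 3.0], [1.0, 1.0])


class TestMixtureCdf:
    def test_limits(self):
        assert nm.mixture_cdf(-1e6, SYMMETRIC_PAIR) == pytest.approx(0.0, abs=1e-12)
        assert nm.mixture_cdf(1e6, SYMMETRIC_PAIR) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_center_is_half(self):
        assert nm.mixture_cdf(0.0, SYMMETRIC_PAIR) == pytest.approx(0.5)

    def test_single_component_matches_normal_cdf(self):
        model = make_model([1.0], [1500.0], [120.0])
        for x in (1200.0, 1500.0, 1777.0):
            assert nm.mixture_cdf(x, model) == pytest.approx(
                stats.norm.cdf(x, 1500.0, 120.0)
            )

    def test_monotone_on_grid(self):
        model = make_model([0.3, 0.7], [0.0, 5.0], [1.0, 2.0])
        grid = np.linspace(-10, 20, 200)
        assert np.all(np.diff(nm.mixture_cdf(grid, model)) >= 0)


class TestMixtureQuantile:
    def test_median_of_symmetric_mixture(self):
        assert nm.mixture_quantile(0.5, SYMMETRIC_PAIR) == pytest.approx(0.0, abs=1e-6)

    def test_roundtrip_is_identity(self):
        model = make_model([0.2, 0.8], [1000.0, 1600.0], [50.0, 150.0])
        probs = np.linspace(0.01, 0.99, 25)
        assert np.allclose(
            nm.mixture_cdf(nm.mixture_quantile(probs, model), model), probs, atol=1e-8
        )

    def test_single_component_normal_quantile(self):
        model = make_model([1.0], [10.0], [2.0])
        assert nm.mixture_quantile(0.975, model) == pytest.approx(
            10.0 + 1.959964 * 2.0, abs=1e-4
        )

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_range_probability_rejected(self, p):
        with pytest.raises(ValidationError):
            nm.mixture_quantile(p, SYMMETRIC_PAIR)


class TestQQDiagnostic:
    def test_self_consistent_data_lies_on_identity(self):
        model = make_model([0.4, 0.6], [0.0, 8.0], [1.0, 2.0])
        positions = (np.arange(1, 101) - 0.5) / 100
        data = nm.MeasurementSet(nm.mixture_quantile(positions, model), unit="width_nm")
        qq = nm.qq_diagnostic(data, model)
        assert qq.slope == pytest.approx(1.0, abs=1e-6)
        assert qq.intercept == pytest.approx(0.0, abs=1e-6)
        assert qq.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_correctly_specified_model_is_linear(self):
        spec = nm.preset_spec("area_2h")
        model = make_model(*[[c.weight for c in spec], [c.mean for c in spec],
                             [c.sigma for c in spec]])
        data, _ = nm.sample_mixture(spec, 500, seed=17)
        assert nm.qq_diagnostic(data, model).r_squared > 0.99

    def test_constant_data_rejected(self):
        model = make_model([1.0], [5.0], [1.0])
        with pytest.raises(ValidationError):
            nm.qq_diagnostic(nm.MeasurementSet([5.0, 5.0, 5.0], unit="width_nm"), model)


class TestSelectModel:
    def test_singleton_range_returned_unconditionally(self):
        data, _ = nm.sample_mixture([(1.0, 50.0, 5.0)], 300, seed=0, unit="width_nm")
        report = nm.select_model(data, [3], seed=0)
        assert report.selected_K == 3

    def test_monotone_in_gain_threshold(self):
        spec = nm.preset_spec("width_singlepass_all")
        data, _ = nm.sample_mixture(spec, 400, seed=5, unit="width_nm")
        selected = [
            nm.select_model(data, range(1, 4), gain_threshold=g, seed=1).selected_K
            for g in (0.5, 2.0, 10.0, 1e4)
        ]
        assert selected == sorted(selected, reverse=True)

    def test_force_K_override_is_recorded(self):
        data, _ = nm.sample_mixture([(1.0, 50.0, 5.0)], 200, seed=2, unit="width_nm")
        report = nm.select_model(data, range(1, 4), seed=0, force_K=3)
        assert report.selected_K == 3
        assert report.forced

    def test_K_above_half_N_rejected(self):
        data, _ = nm.sample_mixture([(1.0, 0.0, 1.0)], 8, seed=0, unit="width_nm")
        with pytest.raises(ValidationError):
            nm.select_model(data, range(1, 6), seed=0)


class TestComponentCi:
    @pytest.mark.parametrize("N,K,expected", [(36, 2, 18), (33, 3, 11), (23, 4, 6), (19, 2, 10)])
    def test_effective_n_rounds_half_up(self, N, K, expected):
        assert nm.effective_n(N, K) == expected

    def test_large_n_limit_is_normal(self):
        model = make_model([1.0], [0.0], [1.0])
        ci = nm.component_ci(model, 10**6, confidence=0.95)[0]
        assert ci.half_width == pytest.approx(1.959964e-3, rel=1e-4)

    def test_half_width_formula(self):
        model = make_model([0.5, 0.5], [0.0, 10.0], [2.0, 4.0])
        cis = nm.component_ci(model, 40, confidence=0.95)
        t = stats.t.ppf(0.975, df=19)
        assert cis[0].half_width == pytest.approx(t * 2.0 / math.sqrt(20))
        assert cis[1].half_width == pytest.approx(t * 4.0 / math.sqrt(20))

    def test_tiny_n_rejected(self):
        model = make_model([1.0], [0.0], [1.0])
        with pytest.raises(ValidationError):
            nm.component_ci(model, 1)


class TestHardAssign:
    def test_single_component_takes_all(self):
        model = make_model([1.0], [5.0], [1.0])
        assert nm.hard_assign([1.0, 2.0, 3.0], model).tolist() == [3]

    def test_tie_goes_to_smaller_mean(self):
        counts = nm.hard_assign([0.0], SYMMETRIC_PAIR)
        assert counts.tolist() == [1, 0]

    def test_counts_fluctuate_binomially(self, well_separated_pair):
        data, _ = nm.sample_mixture(well_separated_pair, 1000, seed=3, unit="width_nm")
        model = make_model([0.5, 0.5], [0.0, 10.0], [1.0, 1.0])
        counts = nm.hard_assign(data, model)
        bound = 3 * math.sqrt(1000 * 0.25)
        assert abs(counts[0] - 500) <= bound


class TestPearsonChiSquared:
    def test_identical_rows_give_zero(self):
        res = nm.pearson_chi_squared([[10, 20, 30], [10, 20, 30]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        res = nm.pearson_chi_squared([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(6.6667, abs=1e-3)
        assert res.df == 1

    def test_scaling_property(self):
        a = nm.pearson_chi_squared([[10, 20], [20, 10]])
        b = nm.pearson_chi_squared([[20, 40], [40, 20]])
        assert b.statistic == pytest.approx(2 * a.statistic)
        assert b.df == a.df

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            nm.pearson_chi_squared([[0, 10], [0, 20]])

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 1000
        probs = np.array([0.3, 0.5, 0.2])
        for _ in range(n_sim):
            table = np.vstack(
                [rng.multinomial(200, probs), rng.multinomial(200, probs)]
            )
            if (table.sum(axis=0) == 0).any():
                continue
            rejections += nm.pearson_chi_squared(table).p_value < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_distinct_populations_detected(self):
        d1, _ = nm.sample_mixture(
            nm.preset_spec("width_singlepass_all"), 500, seed=0,
            unit="width_nm", condition="single",
        )
        d2, _ = nm.sample_mixture(
            nm.preset_spec("width_doublepass_all"), 500, seed=1,
            unit="width_nm", condition="double",
        )
        m1, _ = nm.fit_em(d1, 2, seed=0)
        m2, _ = nm.fit_em(d2, 4, seed=0)
        table = nm.condition_count_table([d1, d2], [m1, m2])
        assert nm.pearson_chi_squared(table).p_value < 0.01


class TestConditionCountTable:
    def test_row_sums_equal_sample_sizes(self):
        d1, _ = nm.sample_mixture([(1.0, 60.0, 3.0)], 80, seed=0, unit="width_nm", condition="a")
        d2, _ = nm.sample_mixture([(1.0, 80.0, 3.0)], 120, seed=1, unit="width_nm", condition="b")
        m1, _ = nm.fit_em(d1, 1, seed=0)
        m2, _ = nm.fit_em(d2, 1, seed=0)
        table = nm.condition_count_table([d1, d2], [m1, m2])
        assert table.sum(axis=1).tolist() == [80, 120]

    def test_bins_mode_needs_no_models(self):
        d1, _ = nm.sample_mixture([(1.0, 60.0, 3.0)], 100, seed=0, unit="width_nm", condition="a")
        d2, _ = nm.sample_mixture([(1.0, 80.0, 3.0)], 100, seed=1, unit="width_nm", condition="b")
        table = nm.condition_count_table([d1, d2], mode="bins", n_bins=6)
        assert table.to_numpy().sum() == 200
        assert nm.pearson_chi_squared(table).p_value < 0.01

    def test_single_condition_rejected(self):
        d1, _ = nm.sample_mixture([(1.0, 60.0, 3.0)], 50, seed=0, unit="width_nm")
        with pytest.raises(ValidationError):
            nm.condition_count_table([d1], mode="bins")


class TestDescribe:
    def test_simple_example(self):
        res = nm.describe([1.0, 2.0, 3.0])
        assert res == (2.0, 1.0, 3)

    def test_constant_data_has_zero_sd(self):
        assert nm.describe([4.0, 4.0, 4.0]).sd == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            nm.describe([1.0])

    def test_matches_generator_moments(self):
        data, _ = nm.sample_mixture([(1.0, 74.1, 8.47)], 20000, seed=8, unit="width_nm")
        res = nm.describe(data)
        assert abs(res.mean - 74.1) < 3 * 8.47 / math.sqrt(20000)
        assert abs(res.sd - 8.47) < 3 * 8.47 / math.sqrt(2 * 20000)
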