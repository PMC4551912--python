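"""Transfer points, confidence intervals, and fold-induction error propagation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import biosensorkit as bk
from biosensorkit.dose_response import fold_induction_from_stats
from biosensorkit.errors import EstimationError, UndefinedFoldError


class TestTInterval:
    def test_identical_values_zero_width(self):
        lo, hi = bk.t_interval([5.0, 5.0, 5.0])
        assert lo == hi == 5.0

    def test_123_half_width(self):
        lo, hi = bk.t_interval([1.0, 2.0, 3.0])
        assert lo == pytest.approx(-0.4841, abs=1e-3)
        assert hi == pytest.approx(4.4841, abs=1e-3)

    def test_requires_two_values(self):
        with pytest.raises(EstimationError):
            bk.t_interval([1.0])

    def test_coverage_on_normal_triples(self):
        """About 95% of t-intervals from normal triples cover the true mean."""
        rng = np.random.default_rng(0)
        n, hits = 4000, 0
        for _ in range(n):
            x = rng.normal(10.0, 2.0, size=3)
            lo, hi = bk.t_interval(x)
            hits += lo <= 10.0 <= hi
        assert hits / n == pytest.approx(0.95, abs=0.01)


class TestBootstrapCI:
    def test_identical_values_zero_width(self):
        lo, hi = bk.bootstrap_sem_ci([2.0, 2.0, 2.0, 2.0], seed=1)
        assert lo == hi == 2.0

    def test_reproducible(self):
        x = [1.0, 4.0, 2.5, 3.0]
        assert bk.bootstrap_sem_ci(x, seed=42) == bk.bootstrap_sem_ci(x, seed=42)

    def test_bracketed_by_t_interval_on_normal_samples(self):
        """The n=3 bootstrap CI for the mean is narrower than the t-interval
        (it cannot see beyond the sample) but both center on the mean."""
        rng = np.random.default_rng(3)
        x = rng.normal(100.0, 10.0, size=30)
        t_lo, t_hi = bk.t_interval(x)
        b_lo, b_hi = bk.bootstrap_sem_ci(x, n_boot=4000, seed=0)
        assert b_lo == pytest.approx(t_lo, abs=0.2 * (t_hi - t_lo))
        assert b_hi == pytest.approx(t_hi, abs=0.2 * (t_hi - t_lo))


class TestTransferFunction:
    def test_zero_width_ci_for_identical_replicates(self, well_factory):
        wells = [
            well_factory([0, 900], [0.5, 1.0], [100.0, 1000.0], replicate=r)
            for r in (1, 2, 3)
        ]
        tf = bk.transfer_function(bk.PlateExperiment(wells=wells), endpoint_min=900)
        (point,) = tf["S"]
        assert point.mean == point.ci_low == point.ci_high == 1000.0

    def test_monotone_means_on_zero_noise_titration(self, zero_noise_arac):
        _, exp = zero_noise_arac
        points = bk.transfer_function(exp)["AraC"]
        means = [p.mean for p in points]
        assert means == sorted(means)

    def test_missing_endpoint_names_wells(self, well_factory):
        wells = [well_factory([0, 10], [0.5, 1.0], [1.0, 2.0])]
        with pytest.raises(EstimationError, match="W0"):
            bk.transfer_function(bk.PlateExperiment(wells=wells), endpoint_min=900)


class TestFoldInduction:
    def test_equal_signals_give_unity_fold(self):
        fi = fold_induction_from_stats(150.0, 0.0, 150.0, 0.0, 50.0, 0.0)
        assert fi.value == 1.0 and fi.se == 0.0 and not fi.is_lower_bound

    def test_worked_example(self):
        """I=1000+/-10, U=100+/-5, C=50+/-2 -> F=19, sigma ~ 2.06."""
        fi = fold_induction_from_stats(1000.0, 10.0, 100.0, 5.0, 50.0, 2.0)
        assert fi.value == pytest.approx(19.0)
        assert fi.se == pytest.approx(2.06, abs=0.01)
        assert not fi.is_lower_bound

    def test_replicate_arrays_reproduce_worked_example(self):
        d = np.array([-1.0, 0.0, 1.0]) * np.sqrt(3)
        fi = bk.fold_induction(1000 + 10 * d, 100 + 5 * d, 50 + 2 * d)
        assert fi.value == pytest.approx(19.0)
        assert fi.se == pytest.approx(2.06, abs=0.01)

    def test_monte_carlo_agreement(self):
        """The propagated sigma matches brute-force Monte-Carlo propagation
        within 5% away from the background regime."""
        rng = np.random.default_rng(1)
        cases = [(1000.0, 10.0, 100.0, 5.0, 50.0, 2.0)]
        for _ in range(5):
            c, s_c = 50.0, rng.uniform(0.5, 3.0)
            u_b = rng.uniform(40.0, 400.0)
            s_u = rng.uniform(0.2, u_b / 8.0)  # clear of the lower-bound rule
            i_b = u_b * rng.uniform(5.0, 50.0)
            s_i = rng.uniform(0.01, 0.05) * i_b
            cases.append((i_b + c, s_i, u_b + c, s_u, c, s_c))
        n = 1_000_000
        for i_m, s_i, u_m, s_u, c_m, s_c in cases:
            fi = fold_induction_from_stats(i_m, s_i, u_m, s_u, c_m, s_c)
            draws_i = rng.normal(i_m, s_i, n)
            draws_u = rng.normal(u_m, s_u, n)
            draws_c = rng.normal(c_m, s_c, n)
            mc = (draws_i - draws_c) / (draws_u - draws_c)
            assert fi.se == pytest.approx(float(mc.std()), rel=0.05)

    def test_lower_bound_rule(self):
        """Uninduced within background: report the ratio of doubled-SE bounds."""
        fi = fold_induction_from_stats(1000.0, 10.0, 52.0, 3.0, 50.0, 2.0)
        assert fi.is_lower_bound and fi.se is None
        s_ib = np.hypot(10.0, 2.0)
        s_ub = np.hypot(3.0, 2.0)
        expected = (950.0 - 2 * s_ib) / (2.0 + 2 * s_ub)
        assert fi.value == pytest.approx(expected)

    def test_lower_bound_below_point_estimate(self):
        """Whenever both are computable, the bound is the smaller number."""
        i_m, s_i, u_m, s_u, c_m, s_c = 1000.0, 10.0, 100.0, 5.0, 50.0, 2.0
        point = fold_induction_from_stats(i_m, s_i, u_m, s_u, c_m, s_c)
        s_ib, s_ub = np.hypot(s_i, s_c), np.hypot(s_u, s_c)
        bound = (point.components["I_B"] - 2 * s_ib) / (point.components["U_B"] + 2 * s_ub)
        assert bound <= point.value

    def test_undefined_fold(self):
        with pytest.raises(UndefinedFoldError):
            fold_induction_from_stats(1000.0, 1.0, 10.0, 0.0, 50.0, 0.0)

    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale):
        base = fold_induction_from_stats(1000.0, 10.0, 100.0, 5.0, 50.0, 2.0)
        scaled = fold_induction_from_stats(
            1000.0 * scale, 10.0 * scale, 100.0 * scale, 5.0 * scale,
            50.0 * scale, 2.0 * scale,
        )
        assert scaled.value == pytest.approx(base.value, rel=1e-9)
        assert scaled.se / scaled.value == pytest.approx(base.se / base.value, rel=1e-9)

    def test_requires_replicates(self):
        with pytest.raises(EstimationError):
            bk.fold_induction([1.0], [1.0, 2.0], [0.5, 0.6])


def test_fold_induction_from_experiment(default_noise_arac):
    _, exp = default_noise_arac
    fi = bk.fold_induction_from_experiment(exp, "AraC")
    # generator truth: v(top)/v(0) since signal scales with velocity
    preset = bk.TABLE1[("AraC", "high")].expression
    top = max(w.condition.concentration for w in exp.sample_wells)
    expected = bk.simulate.hill_rate(preset, top) / preset.v_min
    assert fi.value == pytest.approx(expected, rel=0.2)
    assert not fi.is_lower_bound
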