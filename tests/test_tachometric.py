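import numpy as np
import pytest

from oddsearch import (agresti_coull_ci, ceiling_accuracy, compute_tachometric,
                       difference_curve, floor_accuracy, mean_rt,
                       resample_compare)
from oddsearch.synthetic import GenerativeParams, generate_session

from conftest import make_session, random_session
from oracles import agresti_coull_closed_form, brute_tachometric_counts


class TestAgrestiCoull:

    def test_frozen_example(self):
        lo, hi = agresti_coull_ci(50, 100, 0.95)
        assert lo == pytest.approx(0.4038, abs=5e-5)
        assert hi == pytest.approx(0.5962, abs=5e-5)

    @pytest.mark.parametrize("k, n", [(0, 20), (20, 20), (3, 7), (99, 200)])
    def test_matches_closed_form(self, k, n):
        got = agresti_coull_ci(k, n)
        exp = agresti_coull_closed_form(k, n)
        assert got == pytest.approx(exp, abs=1e-12)

    def test_boundary_clipping(self):
        lo, _ = agresti_coull_ci(0, 20)
        _, hi = agresti_coull_ci(20, 20)
        assert lo == 0.0 and hi == 1.0

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            agresti_coull_ci(0, 0)

    def test_width_shrinks_as_inverse_sqrt_n(self):
        def width(n):
            lo, hi = agresti_coull_ci(n // 2, n)
            return hi - lo
        ratio = width(2_000) / width(4_000)
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.05)


class TestComputeTachometric:

    def test_alternating_outcomes_in_one_bin(self):
        # 10 trials, PTs 91..100 ms, alternating correct/error -> bin at 100
        # (covering [75, 125)) holds all ten with fraction 0.5
        pts = [91.0 + i for i in range(10)]
        outcomes = [i % 2 == 0 for i in range(10)]
        trials = make_session(outcomes=outcomes, pts=pts)
        curve = compute_tachometric(trials, pt_range=(80.0, 110.0))
        j = int(np.where(curve.pt_grid == 100.0)[0][0])
        assert curve.n_trials[j] == 10
        assert curve.fraction_correct[j] == 0.5

    def test_all_correct(self):
        trials = make_session(outcomes=[True] * 20,
                              pts=list(np.linspace(0, 300, 20)))
        curve = compute_tachometric(trials)
        defined = curve.defined
        assert defined.any()
        np.testing.assert_allclose(curve.fraction_correct[defined], 1.0)

    def test_empty_input_all_bins_undefined(self):
        trials = make_session(outcomes=[True]).iloc[:0]
        curve = compute_tachometric(trials, pt_range=(0.0, 100.0))
        assert not curve.defined.any()
        assert np.isnan(curve.fraction_correct).all()

    def test_bad_bin_params_rejected(self):
        trials = make_session(outcomes=[True])
        with pytest.raises(ValueError):
            compute_tachometric(trials, bin_width_ms=0.0)
        with pytest.raises(ValueError):
            compute_tachometric(trials, step_ms=-1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(21)
        trials = random_session(rng, 500)
        curve = compute_tachometric(trials, bin_width_ms=50.0, step_ms=7.0,
                                    pt_range=(-40.0, 390.0))
        n, k = brute_tachometric_counts(trials["pt_ms"], trials["correct"],
                                        curve.pt_grid, 50.0)
        np.testing.assert_array_equal(curve.n_trials, n)
        np.testing.assert_array_equal(curve.n_correct, k)

    def test_counts_add_over_disjoint_sets(self):
        rng = np.random.default_rng(22)
        a = random_session(rng, 300, session="a")
        b = random_session(rng, 200, session="b")
        import pandas as pd
        both = pd.concat([a, b], ignore_index=True)
        rngspec = dict(pt_range=(-50.0, 400.0))
        ca = compute_tachometric(a, **rngspec)
        cb = compute_tachometric(b, **rngspec)
        cab = compute_tachometric(both, **rngspec)
        np.testing.assert_array_equal(cab.n_trials, ca.n_trials + cb.n_trials)
        np.testing.assert_array_equal(cab.n_correct,
                                      ca.n_correct + cb.n_correct)


class TestFloorCeiling:

    def test_strict_boundaries(self):
        # PT exactly 100 and 150 fall in the excluded transition band
        trials = make_session(outcomes=[True] * 4,
                              pts=[99.9, 100.0, 150.0, 150.1])
        assert floor_accuracy(trials).n == 1
        assert ceiling_accuracy(trials).n == 1

    def test_floor_arithmetic(self):
        trials = make_session(outcomes=[True] * 3 + [False] * 9,
                              pts=[50.0] * 12)
        est = floor_accuracy(trials)
        assert (est.k, est.n, est.proportion) == (3, 12, 0.25)

    def test_empty_region_flagged_undefined(self):
        trials = make_session(outcomes=[True] * 3, pts=[120.0] * 3)
        est = floor_accuracy(trials)
        assert not est.defined and np.isnan(est.proportion)

    def test_ceiling_recovers_generator_parameter(self, history_free_trials):
        est = ceiling_accuracy(history_free_trials)
        # informed asymptote 0.70; PT>150 includes a thin partially-informed
        # fringe, hence the generous margin
        assert est.proportion == pytest.approx(0.70, abs=0.01)


class TestDifferenceCurve:

    def _curve(self, frac, n=100):
        trials = make_session(outcomes=[True] * 10,
                              pts=list(np.linspace(0, 300, 10)))
        c = compute_tachometric(trials, pt_range=(0.0, 300.0))
        c.fraction_correct = np.full_like(c.fraction_correct, frac)
        c.n_trials = np.full_like(c.n_trials, n)
        return c

    def test_self_difference_is_zero(self):
        c = self._curve(0.7)
        d = difference_curve(c, c)
        np.testing.assert_allclose(d.difference, 0.0)
        assert np.isfinite(d.se).all()

    def test_constant_offset(self):
        d = difference_curve(self._curve(0.7), self._curve(0.4))
        np.testing.assert_allclose(d.difference, 0.3)

    def test_grid_mismatch_rejected(self):
        trials = make_session(outcomes=[True] * 5, pts=[10, 50, 90, 130, 170])
        a = compute_tachometric(trials, pt_range=(0.0, 200.0))
        b = compute_tachometric(trials, pt_range=(0.0, 100.0))
        with pytest.raises(ValueError):
            difference_curve(a, b)

    def test_ceiling_only_modulation_sign_pattern(self):
        # color-modulated ceiling, no location bias: S-D color difference
        # flat at floor, nonzero in the informed region
        params = GenerativeParams(n_trials=150_000, seed=31,
                                  location_bias_kappa=0.0)
        trials, _ = generate_session(params)
        from oddsearch.analysis import region_contrast
        floor_c = region_contrast(trials, "color", 1, "floor")
        ceil_c = region_contrast(trials, "color", 1, "ceiling")
        assert abs(ceil_c.z) > 2.5
        assert abs(floor_c.z) < 2.5


class TestMeanRt:

    def test_two_trials(self):
        trials = make_session(outcomes=[True, True], pts=[150.0, 250.0])
        m, sem, n = mean_rt(trials)
        assert (m, sem, n) == (250.0, 50.0, 2)

    def test_single_trial_sem_undefined(self):
        trials = make_session(outcomes=[True], pts=[100.0])
        m, sem, n = mean_rt(trials)
        assert n == 1 and np.isnan(sem)

    def test_reorder_invariance(self):
        rng = np.random.default_rng(23)
        trials = random_session(rng, 50)
        m1, s1, _ = mean_rt(trials)
        m2, s2, _ = mean_rt(trials.sample(frac=1.0, random_state=1))
        assert m1 == pytest.approx(m2) and s1 == pytest.approx(s2)


class TestResampleCompare:

    def test_null_case_not_significant(self, history_free_trials):
        half = len(history_free_trials) // 8
        a = history_free_trials.iloc[:half]
        b = history_free_trials.iloc[half:2 * half]
        res = resample_compare(a, b, "ceiling", n_boot=2_000, seed=99)
        assert res.p_value > 0.01

    def test_distinct_ceilings_detected(self):
        pa = GenerativeParams(n_trials=2_000, seed=41,
                              ceiling_base=0.9).history_free()
        pb = GenerativeParams(n_trials=2_000, seed=42,
                              ceiling_base=0.5).history_free()
        a, _ = generate_session(pa)
        b, _ = generate_session(pb)
        res = resample_compare(a, b, "ceiling", n_boot=2_000, seed=5)
        assert res.p_value < 0.001
        assert res.observed_diff > 0.3

    def test_seed_reproducibility(self, history_free_trials):
        a = history_free_trials.iloc[:2_000]
        b = history_free_trials.iloc[2_000:4_000]
        r1 = resample_compare(a, b, "floor", n_boot=500, seed=7)
        r2 = resample_compare(a, b, "floor", n_boot=500, seed=7)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.distribution, r2.distribution)

    def test_requires_seed_and_nonempty(self, history_free_trials):
        a = history_free_trials.iloc[:100]
        with pytest.raises(ValueError):
            resample_compare(a, a, "floor", seed=None)
        with pytest.raises(ValueError):
            resample_compare(a, a.iloc[:0], "floor", seed=1)
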