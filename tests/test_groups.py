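"""Group-inference tests: weighted means, bootstraps, break points, verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microtherm as mt
from microtherm.models import BOLTZMANN_EV


class TestWeightedMean:
    def test_equal_weights_reduce_to_arithmetic_mean(self):
        E = [0.5, 0.7, 1.2]
        for w in (1.0, 0.37):
            assert mt.weighted_mean_ES(E, [w] * 3) == pytest.approx(np.mean(E))

    def test_hand_computed_example(self):
        assert mt.weighted_mean_ES([0.6, 0.9], [1.0, 0.5]) == pytest.approx(0.70)

    def test_single_fit_identity(self):
        assert mt.weighted_mean_ES([0.83], [0.4]) == 0.83

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mt.weighted_mean_ES([], [])


class TestBootstrapWeightedMean:
    def test_identical_values_give_zero_width(self):
        lo, hi = mt.bootstrap_weighted_mean([0.9] * 10, [1.0] * 10, seed=0)
        assert lo == hi == pytest.approx(0.9)

    def test_width_matches_normal_theory(self):
        """Percentile CI width near 2*1.96*sd/sqrt(n) for normal samples."""
        rng = np.random.default_rng(42)
        E = rng.normal(0.9, 0.1, 200)
        lo, hi = mt.bootstrap_weighted_mean(E, np.ones(200), n_boot=2000, seed=1)
        expected = 2 * 1.96 * 0.1 / np.sqrt(200)
        assert (hi - lo) == pytest.approx(expected, rel=0.15)

    def test_seed_determinism(self):
        E = np.linspace(0.5, 1.3, 30)
        w = np.linspace(0.3, 1.0, 30)
        assert mt.bootstrap_weighted_mean(E, w, seed=7) == mt.bootstrap_weighted_mean(E, w, seed=7)

    def test_single_value_degenerates_to_point(self):
        assert mt.bootstrap_weighted_mean([0.8], [1.0], seed=0) == (0.8, 0.8)

    def test_ci_width_shrinks_with_sample_size(self):
        """CI at n=400 narrower than at n=100 on identically distributed data."""
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            big = rng.normal(0.9, 0.2, 400)
            lo4, hi4 = mt.bootstrap_weighted_mean(big, np.ones(400), n_boot=400, seed=s)
            lo1, hi1 = mt.bootstrap_weighted_mean(big[:100], np.ones(100), n_boot=400, seed=s)
            wins += (hi4 - lo4) < (hi1 - lo1)
        assert wins >= 19


class TestInterspecificBA:
    def _cloud(self, E, n=20, lo=278.0, hi=318.0, B0=5.0):
        T = np.linspace(lo, hi, n)
        P = B0 * np.exp(-E / (BOLTZMANN_EV * T))
        return np.column_stack([T, P, np.ones(n)])

    def test_exact_recovery_from_model_data(self):
        params, stats = mt.fit_interspecific_BA(self._cloud(0.98))
        assert params.E == pytest.approx(0.98, rel=1e-6)
        assert stats["rss"] == pytest.approx(0.0, abs=1e-12)

    def test_recovery_independent_of_weights(self):
        cloud = self._cloud(0.98)
        cloud[:, 2] = np.linspace(0.2, 1.0, cloud.shape[0])
        params, _ = mt.fit_interspecific_BA(cloud)
        assert params.E == pytest.approx(0.98, rel=1e-6)

    def test_flat_cloud_gives_zero_energy(self):
        T = np.linspace(278.0, 318.0, 20)
        cloud = np.column_stack([T, np.full_like(T, 0.73), np.ones_like(T)])
        params, _ = mt.fit_interspecific_BA(cloud)
        assert params.E == pytest.approx(0.0, abs=1e-8)

    def test_three_collinear_points_invert_the_arrhenius_example(self):
        B0 = np.exp(0.65 / (BOLTZMANN_EV * 293.15))  # rate(293.15 K) = 1
        T = np.array([293.15, 298.15, 303.15])
        P = B0 * np.exp(-0.65 / (BOLTZMANN_EV * T))
        assert P[0] == pytest.approx(1.0) and P[2] == pytest.approx(2.3368612, rel=1e-6)
        params, _ = mt.fit_interspecific_BA(np.column_stack([T, P, np.ones(3)]))
        assert params.E == pytest.approx(0.65, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            mt.fit_interspecific_BA(self._cloud(0.9, n=2))


class TestBootstrapEL:
    def test_noiseless_ci_collapses_onto_truth(self):
        T = np.linspace(278.0, 318.0, 25)
        P = 5.0 * np.exp(-0.9 / (BOLTZMANN_EV * T))
        cloud = np.column_stack([T, P, np.ones(25)])
        lo, hi = mt.bootstrap_EL(cloud, n_boot=100, seed=0)
        assert hi - lo < 1e-6
        assert lo == pytest.approx(0.9, abs=1e-6)

    def test_seed_determinism(self):
        cloud = mt.generate_peak_cloud(mt.SynthConfig(n_strains=40, seed=5))
        assert mt.bootstrap_EL(cloud, n_boot=200, seed=3) == mt.bootstrap_EL(
            cloud, n_boot=200, seed=3
        )


class TestBreakpoint:
    def test_recovers_simulated_break(self):
        """Slope -0.9 below 40 degC, flat above: break found within 2 degC."""
        cloud = mt.generate_mixture_ensemble(
            n_mesophiles=35, n_thermophiles=25, break_c=40.0, seed=8
        )
        bp = mt.breakpoint_analysis(cloud[:, :2])
        assert bp.significant
        assert bp.break_temperature_c == pytest.approx(40.0, abs=2.0)
        assert bp.left_segment.slope == pytest.approx(-0.9, abs=0.15)
        assert bp.right_segment.slope == pytest.approx(0.0, abs=0.15)

    def test_collinear_data_has_no_break(self):
        T = np.linspace(278.0, 330.0, 20)
        P = 4.0 * np.exp(-0.8 / (BOLTZMANN_EV * T))
        bp = mt.breakpoint_analysis(np.column_stack([T, P]))
        assert not bp.significant
        assert bp.break_temperature_c is None

    def test_too_few_points_rejected(self):
        T = np.linspace(278.0, 318.0, 5)
        P = np.exp(-0.8 / (BOLTZMANN_EV * T))
        with pytest.raises(ValueError):
            mt.breakpoint_analysis(np.column_stack([T, P]))

    def test_narrow_span_rejected(self):
        T = np.linspace(300.0, 310.0, 12)
        P = np.exp(-0.8 / (BOLTZMANN_EV * T))
        with pytest.raises(ValueError):
            mt.breakpoint_analysis(np.column_stack([T, P]))


class TestNicheClassification:
    @pytest.mark.parametrize(
        "t_pk,break_t,expected",
        [
            (30.0, 40.48, "mesophile"),
            (55.0, 40.48, "thermophile"),
            (40.48, 40.48, "mesophile"),  # tie goes to mesophile
            (-2.0, 40.48, "mesophile"),  # no lower bound: psychrophiles included
        ],
    )
    def test_cutoff(self, t_pk, break_t, expected):
        assert mt.classify_niche(t_pk, break_t) == expected


class TestOverlapFraction:
    def test_identical_intervals(self):
        assert mt.ci_overlap_fraction((0.1, 0.5), (0.1, 0.5)) == 1.0

    def test_disjoint_intervals(self):
        assert mt.ci_overlap_fraction((0.1, 0.2), (0.3, 0.4)) == 0.0

    def test_small_overlap_hand_example(self):
        assert mt.ci_overlap_fraction((0.50, 0.70), (0.69, 2.26)) == pytest.approx(0.05)

    def test_degenerate_interval_inside_other(self):
        assert mt.ci_overlap_fraction((0.3, 0.3), (0.1, 0.5)) == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.tuples(st.floats(-5, 5), st.floats(0.01, 5)),
        b=st.tuples(st.floats(-5, 5), st.floats(0.01, 5)),
        shift=st.floats(-3, 3),
        scale=st.floats(0.1, 4),
    )
    def test_symmetry_and_affine_invariance(self, a, b, shift, scale):
        ia = (a[0], a[0] + a[1])
        ib = (b[0], b[0] + b[1])
        f = mt.ci_overlap_fraction(ia, ib)
        assert f == mt.ci_overlap_fraction(ib, ia)
        ja = (ia[0] * scale + shift, ia[1] * scale + shift)
        jb = (ib[0] * scale + shift, ib[1] * scale + shift)
        assert mt.ci_overlap_fraction(ja, jb) == pytest.approx(f, abs=1e-9)


class TestHibVerdict:
    def test_overlapping_positive_intervals_support_hib(self):
        v, frac, _ = mt.hib_test((0.82, 0.93), (0.75, 1.25))
        assert v == "hotter_is_better" and frac == 1.0

    def test_interval_containing_zero_means_equalisation(self):
        v, _, _ = mt.hib_test((0.78, 0.92), (-0.26, 0.12))
        assert v == "equalisation"

    def test_sliver_of_overlap_is_ambiguous(self):
        v, frac, _ = mt.hib_test((0.50, 0.70), (0.69, 2.26))
        assert v == "ambiguous" and 0 < frac < 0.5

    def test_disjoint_with_lower_el_is_partial_constraint(self):
        v, frac, note = mt.hib_test((0.80, 0.95), (0.20, 0.40),
                                    ES_point=0.88, EL_point=0.30)
        assert v == "partial_constraint" and frac == 0.0 and note is None

    def test_disjoint_with_higher_el_is_flagged_super_arrhenius(self):
        v, _, note = mt.hib_test((0.40, 0.55), (0.90, 1.20),
                                 ES_point=0.47, EL_point=1.05)
        assert v == "partial_constraint" and note == "super_arrhenius"

    def test_missing_interval_not_testable(self):
        v, _, _ = mt.hib_test(None, (0.1, 0.5))
        assert v == "not_testable"


class TestTpkTlabRegression:
    def test_identity_map(self):
        t = np.linspace(5.0, 45.0, 12)
        r = mt.tpk_tlab_regression(t, t)
        assert r.slope == pytest.approx(1.0) and r.intercept == pytest.approx(0.0, abs=1e-10)
        assert r.r_squared == pytest.approx(1.0)

    def test_sub_unit_slope_detected(self):
        """T_pk = 8 + 0.9 T_lab with tiny noise: CI excludes slope 1."""
        rng = np.random.default_rng(3)
        t_lab = np.linspace(5.0, 60.0, 40)
        t_pk = 8.0 + 0.9 * t_lab + rng.normal(0, 0.1, 40)
        r = mt.tpk_tlab_regression(t_lab, t_pk)
        assert r.slope == pytest.approx(0.9, abs=0.02)
        assert r.ci_excludes_unity

    def test_two_points_not_testable(self):
        r = mt.tpk_tlab_regression([10.0, 20.0], [12.0, 25.0])
        assert not r.testable


class TestSummariseGroup:
    def test_small_groups_omitted_but_counted(self):
        entries = [("big", 0.9, 1.0)] * 6 + [("small", 0.7, 1.0)] * 4
        out = mt.summarise_group(entries, seed=0)
        labels = [g.label for g in out]
        assert "big" in labels and "small" not in labels
        remainder = [g for g in out if g.label == "_remainder"][0]
        assert remainder.n == 4

    def test_identical_fits_give_zero_width(self):
        out = mt.summarise_group([("g", 0.9, 1.0)] * 5, seed=0)
        g = out[0]
        assert g.E_S_bar == pytest.approx(0.9)
        assert g.E_S_ci[0] == g.E_S_ci[1] == pytest.approx(0.9)

    def test_right_skew_puts_median_below_mean(self):
        rng = np.random.default_rng(1)
        E = rng.lognormal(np.log(0.8), 0.5, 50)
        out = mt.summarise_group([("g", e, 1.0) for e in E], seed=0)
        assert out[0].E_S_median < out[0].E_S_bar
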