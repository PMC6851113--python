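"""Curve-fitting tests: recovery, exclusions, uncertainty, replicates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import microtherm as mt
from microtherm.fitting import RateObservation, TPCRecord, replace_record
from microtherm.interface import fits_to_dataframe


def _record_from_model(params, temps_k, curve_id="c1", **meta):
    rates = mt.ss_evaluate(params, np.asarray(temps_k))
    obs = [RateObservation(t - 273.15, float(r)) for t, r in zip(temps_k, rates)]
    return TPCRecord(curve_id=curve_id, observations=obs, **meta)


class TestFitSharpeSchoolfield:
    def test_noiseless_recovery(self):
        """Data generated from the model give back its parameters."""
        truth = mt.SharpeSchoolfieldParams(B0=0.05, E=0.9, E_D=3.0, T_pk=308.15)
        temps = np.linspace(308.15 - 15, 308.15 + 15, 8)
        rec = _record_from_model(truth, temps)
        fit = mt.fit_sharpe_schoolfield(rec, mt.FitConfig(n_multistart=5, seed=1))
        assert fit.converged and fit.excluded_reason is None
        assert fit.params.E == pytest.approx(0.9, rel=1e-3)
        assert fit.params.T_pk == pytest.approx(308.15, abs=0.01)
        assert fit.P_pk == pytest.approx(mt.ss_peak_performance(truth), rel=1e-3)

    def test_too_few_points_excluded(self):
        obs = [RateObservation(t, 0.001 * (i + 1)) for i, t in enumerate([10, 20, 30])]
        fit = mt.fit_sharpe_schoolfield(TPCRecord("c", obs))
        assert not fit.converged
        assert fit.excluded_reason == "insufficient_points"

    def test_all_zero_rates_excluded(self):
        obs = [RateObservation(t, 0.0) for t in [5, 10, 15, 20, 25, 30]]
        fit = mt.fit_sharpe_schoolfield(TPCRecord("c", obs))
        assert fit.excluded_reason == "no_signal"

    def test_seeded_determinism(self):
        """Identical inputs and seeds give bitwise-identical fit tables."""
        cfg = mt.SynthConfig(n_strains=4, seed=3)
        records, _ = mt.generate_strain_ensemble(cfg)
        fit_cfg = mt.FitConfig(n_multistart=4, seed=9)
        a = fits_to_dataframe(mt.fit_dataset(records, fit_cfg))
        b = fits_to_dataframe(mt.fit_dataset(records, fit_cfg))
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_every_curve_accounted_for(self):
        """Each input appears exactly once: as a fit or with a reason."""
        cfg = mt.SynthConfig(n_strains=5, seed=4)
        records, _ = mt.generate_strain_ensemble(cfg)
        records.append(TPCRecord("tiny", [RateObservation(20.0, 1e-4)]))
        fits = mt.fit_dataset(records, mt.FitConfig(n_multistart=2, seed=0))
        assert [f.curve_id for f in fits] == [r.curve_id for r in records]
        for f in fits:
            assert f.converged or f.excluded_reason

    def test_noisy_parameter_recovery(self):
        """Median error over noisy curves: E within 0.05 eV, T_pk within 0.5 K."""
        cfg = mt.SynthConfig(n_strains=25, seed=21)
        records, truth = mt.generate_strain_ensemble(cfg)
        fits = mt.fit_dataset(records, mt.FitConfig(n_multistart=3, seed=2))
        e_err, t_err = [], []
        for f, (_, row) in zip(fits, truth.iterrows()):
            if f.converged:
                e_err.append(abs(f.params.E - row.true_E))
                t_err.append(abs(f.params.T_pk - 273.15 - row.true_T_pk_c))
        assert np.median(e_err) <= 0.05
        assert np.median(t_err) <= 0.5


class TestDetectPeak:
    def test_interior_peak_detected(self, noiseless_ensemble):
        records, _ = noiseless_ensemble
        fit = mt.fit_sharpe_schoolfield(records[0], mt.FitConfig(n_multistart=2))
        assert fit.has_peak

    def test_monotonically_rising_curve_has_no_peak(self):
        truth = mt.SharpeSchoolfieldParams(B0=0.05, E=0.8, E_D=3.0, T_pk=320.15)
        temps = np.linspace(280.0, 310.0, 7)  # entirely below the optimum
        rec = _record_from_model(truth, temps)
        fit = mt.fit_sharpe_schoolfield(rec, mt.FitConfig(n_multistart=5, seed=1))
        assert fit.converged
        assert not fit.has_peak

    def test_fitted_peak_outside_range_rejected(self):
        truth = mt.SharpeSchoolfieldParams(B0=0.05, E=0.8, E_D=3.0, T_pk=320.15)
        temps = np.linspace(280.0, 310.0, 7)
        rec = _record_from_model(truth, temps)
        fit = mt.fit_sharpe_schoolfield(rec, mt.FitConfig(n_multistart=5, seed=1))
        fake = mt.SSFit(curve_id="x", params=mt.SharpeSchoolfieldParams(
            B0=0.05, E=0.8, E_D=3.0, T_pk=330.0))
        assert not mt.detect_peak(fake, rec)


class TestPropagateUncertainty:
    def _fit_with_cov(self, cov):
        p = mt.SharpeSchoolfieldParams(B0=0.05, E=0.9, E_D=3.0, T_pk=308.15)
        return mt.SSFit(curve_id="c", params=p, P_pk=mt.ss_peak_performance(p),
                        covariance=np.asarray(cov, dtype=float), converged=True)

    def test_zero_covariance_gives_zero_sd_and_unit_weight(self):
        fit = self._fit_with_cov(np.zeros((4, 4)))
        sd_e, sd_ppk = mt.propagate_uncertainty(fit, n_draws=500, seed=0)
        assert sd_e == pytest.approx(0.0, abs=1e-12)
        assert sd_ppk == pytest.approx(0.0, abs=1e-12)
        assert mt.compute_weight(sd_e) == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_covariance_recovers_marginal_sd(self):
        """var(E)=0.01 alone propagates to SD_E near 0.1."""
        cov = np.zeros((4, 4))
        cov[1, 1] = 0.01
        fit = self._fit_with_cov(cov)
        sd_e, _ = mt.propagate_uncertainty(fit, n_draws=1000, seed=1)
        # MC standard error of an SD estimate at n=1000 is ~ sd/sqrt(2n)
        assert sd_e == pytest.approx(0.1, abs=3 * 0.1 / np.sqrt(2 * 1000))

    def test_missing_covariance_is_an_exclusion_error(self):
        p = mt.SharpeSchoolfieldParams(B0=0.05, E=0.9, E_D=3.0, T_pk=308.15)
        fit = mt.SSFit(curve_id="c", params=p, converged=True)
        with pytest.raises(mt.fitting.MissingCovarianceError):
            mt.propagate_uncertainty(fit)


class TestWeights:
    @pytest.mark.parametrize("sd,expected", [(0.0, 1.0), (1.0, 0.5), (3.0, 0.25)])
    def test_known_values(self, sd, expected):
        assert mt.compute_weight(sd) == expected

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            mt.compute_weight(-0.1)

    @settings(max_examples=100, derandomize=True)
    @given(sd=st.floats(0.0, 1e6))
    def test_weight_bounds_and_monotonicity(self, sd):
        w = mt.compute_weight(sd)
        assert 0.0 < w <= 1.0
        if sd == 0.0:
            assert w == 1.0
        elif sd > 1e-12:
            assert w < 1.0
        assert mt.compute_weight(sd + 1.0) < w


class TestDeduplicateReplicates:
    def _rec(self, cid, n, strain="s1", study="st1", **meta):
        obs = [RateObservation(10.0 + 3 * i, 1e-4 * (i + 1)) for i in range(n)]
        return TPCRecord(cid, obs, strain_id=strain, study_id=study, **meta)

    def test_pseudoreplicates_pooled_into_one_curve(self):
        a, b = self._rec("a", 6), self._rec("b", 6)
        out = mt.deduplicate_replicates([a, b], "pool_pseudoreplicates")
        assert len(out) == 1
        assert len(out[0].observations) == 12

    def test_single_record_unchanged(self):
        a = self._rec("a", 6)
        assert mt.deduplicate_replicates([a], "pool_pseudoreplicates") == [a]

    def test_different_strains_not_pooled(self):
        a = self._rec("a", 6, strain="s1")
        b = self._rec("b", 6, strain="s2")
        assert len(mt.deduplicate_replicates([a, b], "pool_pseudoreplicates")) == 2

    def test_conflicting_trait_kinds_error(self):
        a = self._rec("a", 6, trait_kind="growth")
        b = self._rec("b", 6, trait_kind="flux")
        with pytest.raises(ValueError):
            mt.deduplicate_replicates([a, b], "pool_pseudoreplicates")

    def test_best_fit_keeps_lower_rss_replicate(self):
        truth = mt.SharpeSchoolfieldParams(B0=0.05, E=0.9, E_D=3.0, T_pk=308.15)
        temps = np.linspace(293.15, 318.15, 7)
        clean = _record_from_model(truth, temps, curve_id="clean", species="Algaspora x")
        rng = np.random.default_rng(5)
        noisy_obs = [
            RateObservation(o.temperature_c, o.rate * rng.lognormal(0, 0.5))
            for o in clean.observations
        ]
        noisy = replace_record(clean, curve_id="noisy", observations=noisy_obs)
        out = mt.deduplicate_replicates(
            [noisy, clean], "best_fit", mt.FitConfig(n_multistart=3, seed=1)
        )
        assert [r.curve_id for r in out] == ["clean"]
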