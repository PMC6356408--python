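"""Fold averaging, sample filtering, nonlinear fitting and aggregation."""

import numpy as np
import pytest

from vfret import (
    AcousticDrive,
    DonorParticle,
    EstimationProtocol,
    FluidMedium,
    NoiseModel,
    aggregate,
    estimate_measurements,
    estimate_series,
    fit_measurement,
    fold_average,
    sample_positions,
    select_samples,
    simulate_series,
    vibration_state,
)
from vfret.estimator import MeasurementFit, SampleSelection


def _series(fluid, drive, particle, d0, n_periods, **kw):
    return simulate_series(fluid, drive, particle, d0, n_periods, **kw)


class TestFoldAverage:
    def test_single_period_identity(self, water, drive50, particle500):
        s = _series(water, drive50, particle500, 20e-9, 3, snr_db=20.0, seed=1)
        tau, w = fold_average(s, 1)
        np.testing.assert_array_equal(w, s.counts[: s.samples_per_period])
        np.testing.assert_array_equal(tau, s.t[: s.samples_per_period])

    def test_constant_input(self, water, particle500):
        s = _series(water, AcousticDrive(0.0, 50.0), particle500, 20e-9, 4)
        _, w = fold_average(s, 4)
        np.testing.assert_allclose(w, s.counts[0], rtol=1e-14)

    def test_noiseless_periodic_input(self, water, drive50, particle500):
        s = _series(water, drive50, particle500, 20e-9, 5)
        _, w = fold_average(s, 5)
        np.testing.assert_allclose(w, s.counts[: s.samples_per_period], rtol=1e-12)

    def test_too_short_series_rejected(self, water, drive50, particle500):
        s = _series(water, drive50, particle500, 20e-9, 2)
        with pytest.raises(ValueError, match="NT"):
            fold_average(s, 3)

    def test_noise_suppression(self, water, drive50, particle500):
        """Folded-mean noise variance shrinks as sigma_n^2 / NT."""
        NT, snr_db = 64, 10.0
        s = _series(water, drive50, particle500, 25e-9, NT,
                    noise=NoiseModel(snr_db=snr_db, seed=11))
        clean = _series(water, drive50, particle500, 25e-9, 1)
        _, w = fold_average(s, NT)
        resid = w - clean.counts
        sigma2 = 10 ** (-snr_db / 10)
        # 1000 folded bins: relative sd of the variance estimate ~ 4.5%
        assert np.var(resid) == pytest.approx(sigma2 / NT, rel=0.15)


class TestSelectSamples:
    def test_all_below_threshold_rejected(self):
        proto = EstimationProtocol()
        sel = select_samples(np.full(48, 1e-4), 1.0, proto)
        assert not sel.accepted and sel.reason == "too_few_samples"

    def test_saturated_waveform_rejected_as_touching(self):
        proto = EstimationProtocol()
        w = np.linspace(0.0, 1.0, 48)
        sel = select_samples(w, 1.0, proto)
        assert not sel.accepted and sel.reason == "touching"

    def test_boundary_count_inclusive(self):
        # S = 48 at Nmin_fraction = 1/12 -> exactly 4 qualifying samples accept
        proto = EstimationProtocol()
        w = np.full(48, 1e-4)
        w[:4] = 0.5
        sel = select_samples(w, 1.0, proto)
        assert sel.accepted and len(sel.kept) == 4
        w[3] = 1e-4
        assert not select_samples(w, 1.0, proto).accepted

    def test_threshold_on_measured_scale(self):
        # filter applies to counts / alpha, not raw counts
        proto = EstimationProtocol(E_min=0.01)
        w = np.full(48, 0.5)  # efficiency 0.005 at alpha=100
        sel = select_samples(w, 100.0, proto)
        assert not sel.accepted


class TestSamplePositions:
    def test_all_above_amplitude(self):
        proto = EstimationProtocol()
        pos = sample_positions(200, 50e-9, proto, rng=0)
        assert np.all(pos > 50e-9)
        assert np.all(pos <= 50e-9 + proto.d0_max)

    def test_uniform_mean(self):
        proto = EstimationProtocol()
        n = 100_000
        pos = sample_positions(n, 50e-9, proto, rng=1)
        expected = 50e-9 + 0.5 * (proto.d0_min + proto.d0_max)
        se = (proto.d0_max - proto.d0_min) / np.sqrt(12 * n)
        assert abs(pos.mean() - expected) < 3 * se

    def test_seed_reproducibility(self):
        proto = EstimationProtocol()
        np.testing.assert_array_equal(
            sample_positions(10, 50e-9, proto, rng=7),
            sample_positions(10, 50e-9, proto, rng=7),
        )


class TestFitMeasurement:
    def _fit_noiseless(self, fluid, drive, particle, d0, protocol=None):
        protocol = protocol or EstimationProtocol(NT=1)
        s = _series(fluid, drive, particle, d0, 1)
        tau, w = fold_average(s, 1)
        sel = select_samples(w, 1.0, protocol)
        assert sel.accepted
        return fit_measurement(tau, w, sel.kept, fluid, drive, particle, 1.0, protocol)

    @pytest.mark.parametrize("mu_true", [0.89e-3, 2.0e-3, 3.5e-3])
    def test_noiseless_recovery(self, drive50, particle500, mu_true):
        fluid = FluidMedium(1000.0, 1543.0, mu_true)
        vib = vibration_state(drive50, fluid, particle500)
        d0 = vib.Up_max + 12e-9
        fit = self._fit_noiseless(fluid, drive50, particle500, d0)
        assert fit.converged
        assert fit.mu_hat == pytest.approx(mu_true, rel=1e-6)
        assert fit.d0_hat == pytest.approx(d0, rel=1e-6)

    def test_static_donor_ill_conditioned(self, water, particle500):
        """Without vibration the waveform carries no viscosity information."""
        drive = AcousticDrive(0.0, 50.0)
        proto = EstimationProtocol(NT=1)
        s = _series(water, drive, particle500, 18e-9, 1)
        tau, w = fold_average(s, 1)
        kept = np.arange(len(w))
        fit = fit_measurement(tau, w, kept, water, drive, particle500, 1.0, proto)
        assert fit.jacobian_cond > 1e8 or not fit.converged

    def test_estimates_respect_bounds(self, water, drive50, particle500):
        proto = EstimationProtocol(NT=1)
        vib = vibration_state(drive50, water, particle500)
        fit = self._fit_noiseless(water, drive50, particle500, vib.Up_max + 5e-9, proto)
        assert proto.d0_bounds[0] <= fit.d0_hat <= proto.d0_bounds[1]
        assert proto.mu_bounds[0] <= fit.mu_hat <= proto.mu_bounds[1]

    def test_empty_kept_set_rejected(self, water, drive50, particle500):
        proto = EstimationProtocol(NT=1)
        with pytest.raises(ValueError, match="kept"):
            fit_measurement(
                np.arange(10.0), np.ones(10), np.array([], dtype=int),
                water, drive50, particle500, 1.0, proto,
            )


class TestPipeline:
    def test_touching_series_refused(self, water, particle500):
        drive = AcousticDrive(20.0, 10.0)
        s = _series(water, drive, particle500, 5e-9, 5)
        assert s.touching
        sel, fit = estimate_series(s, water, drive, particle500,
                                   EstimationProtocol(NT=5))
        assert not sel.accepted and sel.reason == "touching" and fit is None

    def test_fold_of_many_periods_equals_single_period_fit(
        self, blood, drive50, particle500
    ):
        """Noiseless: fitting the NT-fold equals fitting one period."""
        vib = vibration_state(drive50, blood, particle500)
        d0 = vib.Up_max + 9e-9
        fits = []
        for NT in (1, 4):
            proto = EstimationProtocol(NT=NT)
            s = _series(blood, drive50, particle500, d0, NT)
            _, fit = estimate_series(s, blood, drive50, particle500, proto)
            assert fit is not None and fit.converged
            fits.append(fit)
        assert fits[0].mu_hat == pytest.approx(fits[1].mu_hat, rel=1e-8)
        assert fits[0].d0_hat == pytest.approx(fits[1].d0_hat, rel=1e-8)

    def test_noiseless_end_to_end_recovery(self, drive50, particle500):
        for mu_true in (0.89e-3, 3.5e-3):
            fluid = FluidMedium(1000.0, 1543.0, mu_true)
            proto = EstimationProtocol(NT=2, Nm=6)
            vib = vibration_state(drive50, fluid, particle500)
            pos = sample_positions(proto.Nm, vib.Up_max, proto, rng=5)
            series = [_series(fluid, drive50, particle500, d0, proto.NT) for d0 in pos]
            report = estimate_measurements(series, fluid, drive50, particle500, proto)
            assert abs(report.mu_hat_final - mu_true) / mu_true <= 1e-4


class TestAggregate:
    def _fit(self, d0, mu, converged=True):
        return MeasurementFit(d0_hat=d0, mu_hat=mu, converged=converged,
                              residual_norm=0.0, n_samples_used=100)

    def _accept(self):
        return SampleSelection(kept=np.arange(5), accepted=True)

    def _reject(self, reason):
        return SampleSelection(kept=np.array([], dtype=int), accepted=False,
                               reason=reason)

    def test_identical_estimates(self):
        results = [(self._accept(), self._fit(20e-9, 2e-3))] * 3
        rep = aggregate(results)
        assert rep.mu_hat_final == pytest.approx(2e-3, rel=1e-15)
        assert rep.d0_hat_final == pytest.approx(20e-9, rel=1e-15)
        assert rep.n_used == 3 and rep.n_rejected == 0

    def test_arithmetic_mean(self):
        results = [
            (self._accept(), self._fit(10e-9, mu))
            for mu in (1e-3, 2e-3, 3e-3)
        ]
        assert aggregate(results).mu_hat_final == pytest.approx(2e-3, rel=1e-14)

    def test_rejections_ledgered(self):
        results = [
            (self._accept(), self._fit(15e-9, 1.5e-3)),
            (self._reject("touching"), None),
        ]
        rep = aggregate(results)
        assert rep.mu_hat_final == 1.5e-3
        assert rep.n_rejected == 1
        assert rep.rejection_reasons == {"touching": 1}

    def test_nonconverged_excluded(self):
        results = [
            (self._accept(), self._fit(15e-9, 1.5e-3)),
            (self._accept(), self._fit(99e-9, 9e-3, converged=False)),
        ]
        rep = aggregate(results)
        assert rep.mu_hat_final == 1.5e-3
        assert rep.rejection_reasons == {"not_converged": 1}

    def test_permutation_invariance(self):
        results = [
            (self._accept(), self._fit(d0, mu))
            for d0, mu in [(10e-9, 1e-3), (20e-9, 2e-3), (30e-9, 4e-3)]
        ]
        a = aggregate(results)
        b = aggregate(results[::-1])
        assert a.mu_hat_final == pytest.approx(b.mu_hat_final, rel=1e-14)
        assert a.d0_hat_final == pytest.approx(b.d0_hat_final, rel=1e-14)

    def test_no_usable_measurement_raises(self):
        with pytest.raises(RuntimeError, match="no usable"):
            aggregate([(self._reject("touching"), None)])

    def test_report_serialization(self, tmp_path):
        rep = aggregate([
            (self._accept(), self._fit(15e-9, 1.5e-3)),
            (self._reject("too_few_samples"), None),
        ])
        rep.to_json(tmp_path / "report.json")
        rep.to_csv(tmp_path / "report.csv")
        import json
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["mu_hat_final"] == rep.mu_hat_final
        assert payload["rejection_reasons"] == {"too_few_samples": 1}
        lines = (tmp_path / "report.csv").read_text().strip().splitlines()
        assert len(lines) == 1 + 2 + 1  # header, two measurements, summary
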