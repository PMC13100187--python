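"""TCSPC decay processing: timeline, reconvolution model, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc

from npqtau import parse_light_sequence
from npqtau.decay import (
    BiExpFit,
    DecayFitError,
    DecayHistogram,
    convolved_model,
    delta_irf,
    fit_decay,
    gaussian_irf,
    select_saturated_subwindow,
    snapshot_timeline,
)
from npqtau.synth import synth_decay_histograms


class TestSnapshotTimeline:
    @pytest.mark.parametrize("seq", ["20HL", "5HL-10D-5HL",
                                     "3HL-1D-1HL-3D-9HL-3D"])
    def test_any_20min_sequence_gives_83_snapshots(self, seq):
        light = parse_light_sequence(seq)
        times = snapshot_timeline(light)
        assert times.size == 83
        assert times[0] == -30.0 and times[2] == 0.0 and times[-1] == 1200.0

    def test_one_minute_no_dark(self):
        np.testing.assert_allclose(
            snapshot_timeline(60.0, interval=15.0, n_dark=0),
            [0.0, 15.0, 30.0, 45.0, 60.0])

    def test_zero_length_sequence(self):
        np.testing.assert_allclose(
            snapshot_timeline(0.0, interval=15.0, n_dark=0), [0.0])

    def test_dark_snapshots_end_at_zero(self):
        times = snapshot_timeline(30.0, interval=10.0, n_dark=2)
        np.testing.assert_allclose(times, [-10.0, 0.0, 10.0, 20.0, 30.0])


class TestConvolvedModel:
    def test_delta_irf_reproduces_pure_biexponential(self):
        bins = np.arange(0.0, 8000.0, 4.0)
        irf = delta_irf(bins)
        fit = BiExpFit(A1=100.0, A2=40.0, tau1=0.3, tau2=1.5)
        model = convolved_model(fit, irf, bins)
        expected = (100.0 * np.exp(-bins / 300.0)
                    + 40.0 * np.exp(-bins / 1500.0))
        np.testing.assert_allclose(model, expected, rtol=1e-12)

    def test_single_component_when_A2_zero(self):
        bins = np.arange(0.0, 8000.0, 4.0)
        irf = gaussian_irf(bins, fwhm=37.0, t0=200.0)
        one = convolved_model(BiExpFit(A1=50.0, A2=0.0, tau1=0.5, tau2=2.0),
                              irf, bins)
        same = convolved_model(BiExpFit(A1=50.0, A2=1e-30, tau1=0.5,
                                        tau2=2.0), irf, bins)
        np.testing.assert_allclose(one, same, rtol=1e-6)

    def test_matches_closed_form_gaussian_convolution(self):
        """Discrete reconvolution agrees with the exact exponentially
        modified Gaussian on a fine grid."""
        dt = 0.5  # ps
        bins = np.arange(0.0, 6000.0, dt)
        fwhm = 37.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        t0 = 300.0
        tau = 500.0  # ps
        irf = gaussian_irf(bins, fwhm=fwhm, t0=t0)
        model = convolved_model(BiExpFit(A1=1.0, A2=0.0, tau1=tau / 1e3,
                                         tau2=tau / 1e3), irf, bins)
        # the left-endpoint discrete kernel corresponds to the continuous
        # convolution shifted by half a bin (absorbed by t0 in real fits)
        t = bins - t0 + dt / 2
        exact = 0.5 * np.exp(sigma**2 / (2 * tau**2) - t / tau) * erfc(
            (sigma**2 / tau - t) / (np.sqrt(2) * sigma))
        sel = exact > 1e-3 * exact.max()
        np.testing.assert_allclose(model[sel], exact[sel], rtol=1e-3)
        peak = np.argmax(exact)
        assert abs(model[peak] - exact[peak]) / exact[peak] < 1e-3


class TestFitDecay:
    def test_noiseless_decay_recovers_parameters(self):
        bins = np.arange(0.0, 12000.0, 4.0)
        irf = delta_irf(bins)
        true = BiExpFit(A1=600.0, A2=400.0, tau1=0.3, tau2=1.5)
        counts = convolved_model(true, irf, bins)  # exact, no shot noise
        h = DecayHistogram(bin_times=bins, counts=counts)
        fit = fit_decay(h, irf, fit_t0=False)
        assert fit.tau1 == pytest.approx(0.3, rel=1e-4)
        assert fit.tau2 == pytest.approx(1.5, rel=1e-4)
        assert fit.tau_avg == pytest.approx(true.tau_avg, rel=1e-4)

    def test_amplitude_weighted_average(self):
        fit = BiExpFit(A1=1.0, A2=1.0, tau1=1.0, tau2=3.0)
        assert fit.tau_avg == pytest.approx(2.0)

    def test_canonical_ordering_enforced(self):
        fit = BiExpFit(A1=2.0, A2=1.0, tau1=3.0, tau2=1.0)
        assert fit.tau1 == 1.0 and fit.tau2 == 3.0
        assert fit.A1 == 1.0 and fit.A2 == 2.0

    def test_poisson_noise_recovery_within_2pct(self):
        h, info = synth_decay_histograms(
            ((0.6, 0.4), (0.4, 1.8)), counts_total=100_000, seed=42)
        irf = gaussian_irf(h.bin_times)
        fit = fit_decay(h, irf)
        assert fit.tau_avg == pytest.approx(info["tau_avg"], rel=0.02)

    def test_count_floor_enforced(self):
        bins = np.arange(0.0, 1000.0, 4.0)
        h = DecayHistogram(bin_times=bins,
                           counts=np.zeros(bins.size, dtype=int))
        with pytest.raises(DecayFitError):
            fit_decay(h, delta_irf(bins))


class TestTauAvgInvariance:
    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0.01, 100.0))
    def test_joint_amplitude_rescaling_preserves_tau_avg(self, scale):
        fit = BiExpFit(A1=10.0, A2=30.0, tau1=0.4, tau2=1.9)
        scaled = BiExpFit(A1=10.0 * scale, A2=30.0 * scale,
                          tau1=0.4, tau2=1.9)
        assert scaled.tau_avg == pytest.approx(fit.tau_avg, rel=1e-12)


class TestSubwindowSelection:
    def _histogram(self, tau_ns, seed):
        h, _ = synth_decay_histograms(((1.0, tau_ns),),
                                      counts_total=40_000, seed=seed)
        return h

    def test_rising_lifetime_selects_last_window(self):
        """As reaction centers close, tau rises; the saturated window is
        the longest-lifetime one."""
        subs = [self._histogram(tau, seed=i)
                for i, tau in enumerate([0.6, 0.9, 1.2, 1.5, 1.8])]
        irf = gaussian_irf(subs[0].bin_times)
        best = fit_decay(subs[-1], irf)
        chosen = select_saturated_subwindow(subs, irf)
        assert chosen.tau_avg == pytest.approx(best.tau_avg, rel=1e-9)

    def test_single_subwindow_returns_its_fit(self):
        sub = self._histogram(1.0, seed=7)
        irf = gaussian_irf(sub.bin_times)
        assert select_saturated_subwindow([sub], irf).tau_avg == \
            pytest.approx(fit_decay(sub, irf).tau_avg)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_saturated_subwindow([], None)
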