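"""Tests of the narrowband phase extraction and trial-wise synchrony metrics."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0, i1

from gammasync import (AnalysisWindows, BandSpec, CohortSpec, TrialSet,
                       baseline_zscore, ciplv_pair, itpc, itpc_map, make_mesh,
                       narrowband_phase, plv_pair, sample_thickness,
                       seed_connectivity_map, simulate_trialset,
                       steady_state_average)


def _sinusoid_trialset(fs=600.0, f0=40.0, phase=0.0, n_trials=2, extra=None):
    times = -1.5 + np.arange(int(3 * fs)) / fs
    sig = np.cos(2 * np.pi * f0 * times + phase)
    if extra is not None:
        sig = sig + extra(times)
    data = np.tile(sig, (n_trials, 1, 1))
    return TrialSet(data, fs, times)


class TestNarrowbandPhase:
    def test_pure_40hz_phase_advance(self):
        """Unwrapped analytic phase of a 40 Hz sinusoid advances 2*pi*40/s."""
        ts = _sinusoid_trialset()
        ph = narrowband_phase(ts)
        interior = slice(300, 1500)
        un = np.unwrap(ph[0, 0, interior])
        slope = np.polyfit(ts.times[interior], un, 1)[0]
        assert abs(slope - 2 * np.pi * 40) < 0.01 * 2 * np.pi * 40
        resid = un - np.polyval(np.polyfit(ts.times[interior], un, 1),
                                ts.times[interior])
        assert np.abs(resid).max() < 0.01

    def test_onset_phase_recovered(self):
        """cos with phase pi/3 at t=0 -> extracted phase pi/3 at t=0."""
        ts = _sinusoid_trialset(phase=np.pi / 3)
        ph = narrowband_phase(ts)
        i0_ = np.argmin(np.abs(ts.times))
        assert abs(ph[0, 0, i0_] - np.pi / 3) < 0.02

    def test_out_of_band_component_rejected(self):
        """A 10 Hz component of equal amplitude does not perturb the
        recovered 40 Hz phase beyond 0.05 rad (band-pass rejection)."""
        ts = _sinusoid_trialset(phase=0.7,
                                extra=lambda t: np.cos(2 * np.pi * 10 * t))
        ph = narrowband_phase(ts)
        interior = slice(300, 1500)
        err = np.angle(np.exp(1j * (ph[0, 0, interior]
                                    - (2 * np.pi * 40 * ts.times[interior] + 0.7))))
        assert np.abs(err).max() < 0.05

    def test_band_above_nyquist_rejected(self):
        ts = _sinusoid_trialset(fs=70.0)
        with pytest.raises(ValueError, match="Nyquist"):
            narrowband_phase(ts, BandSpec(low_hz=39, high_hz=41))

    def test_epoch_shorter_than_filter_rejected(self):
        fs = 600.0
        times = np.arange(100) / fs
        ts = TrialSet(np.zeros((2, 1, 100)), fs, times)
        with pytest.raises(ValueError, match="filter length"):
            narrowband_phase(ts, BandSpec(n_taps=241))


class TestITPC:
    def test_identical_phases_give_one(self):
        assert itpc(np.full((12, 3), 1.234)) == pytest.approx(1.0)

    def test_antipodal_phases_cancel(self):
        ph = np.array([0.0, np.pi] * 5)[:, None]
        assert itpc(ph)[0] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_floor_monte_carlo(self, rng):
        """E[ITPC] for N=180 uniform phases ~ sqrt(pi)/(2 sqrt(180))."""
        vals = itpc(rng.uniform(-np.pi, np.pi, size=(180, 10_000)))
        assert abs(vals.mean() - np.sqrt(np.pi) / (2 * np.sqrt(180))) < 0.002

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 2.0, 4.0])
    def test_large_n_converges_to_bessel_ratio(self, kappa, rng):
        draws = rng.vonmises(0.0, kappa, size=(10_000, 1)) if kappa else \
            rng.uniform(-np.pi, np.pi, size=(10_000, 1))
        expected = i1(kappa) / i0(kappa) if kappa else 0.0
        assert abs(itpc(draws)[0] - expected) < 0.01

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            itpc(np.zeros((1, 4)))


class TestPairMetrics:
    def test_plv_identical_and_constant_lag(self):
        ph = np.linspace(-np.pi, np.pi, 8)[:, None]
        assert plv_pair(ph, ph)[0] == pytest.approx(1.0)
        assert plv_pair(ph, ph - np.pi / 3)[0] == pytest.approx(1.0)

    def test_plv_mixed_lags_hand_value(self):
        """Half trials at lag 0, half at lag pi/2: |C| = |(1+i)/2| = sqrt2/2."""
        ph1 = np.zeros((4, 1))
        ph2 = np.array([0.0, 0.0, -np.pi / 2, -np.pi / 2])[:, None]
        assert plv_pair(ph1, ph2)[0] == pytest.approx(np.sqrt(2) / 2)

    def test_ciplv_zero_lag_suppressed(self):
        ph = np.linspace(-1, 1, 6)[:, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert ciplv_pair(ph, ph)[0] == 0.0

    def test_ciplv_quarter_cycle_lag_is_one(self):
        ph1 = np.linspace(-1, 1, 6)[:, None]
        assert ciplv_pair(ph1, ph1 - np.pi / 2)[0] == pytest.approx(1.0)

    def test_ciplv_mixed_lags_hand_value(self):
        """C = (1+i)/2 -> ciPLV = 0.5 / sqrt(1 - 0.25)."""
        ph1 = np.zeros((4, 1))
        ph2 = np.array([0.0, 0.0, -np.pi / 2, -np.pi / 2])[:, None]
        assert ciplv_pair(ph1, ph2)[0] == pytest.approx(0.5 / np.sqrt(0.75))

    def test_mismatched_trial_counts_rejected(self):
        with pytest.raises(ValueError, match="trial counts"):
            plv_pair(np.zeros((3, 1)), np.zeros((4, 1)))

    @given(st.floats(-np.pi, np.pi), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_common_rotation_invariance(self, rotation, seed):
        """ITPC/PLV/ciPLV are invariant under a common phase rotation."""
        r = np.random.default_rng(seed)
        ph1 = r.uniform(-np.pi, np.pi, size=(8, 2))
        ph2 = r.uniform(-np.pi, np.pi, size=(8, 2))
        np.testing.assert_allclose(itpc(ph1 + rotation), itpc(ph1), atol=1e-9)
        np.testing.assert_allclose(plv_pair(ph1 + rotation, ph2 + rotation),
                                   plv_pair(ph1, ph2), atol=1e-9)
        np.testing.assert_allclose(ciplv_pair(ph1 + rotation, ph2 + rotation),
                                   ciplv_pair(ph1, ph2), atol=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_ciplv_plv_inequalities(self, seed):
        """PLV >= |Im C|; ciPLV <= 1; ciPLV = PLV when Re C = 0."""
        r = np.random.default_rng(seed)
        ph1 = r.uniform(-np.pi, np.pi, size=(10, 3))
        ph2 = r.uniform(-np.pi, np.pi, size=(10, 3))
        c = np.mean(np.exp(1j * (ph1 - ph2)), axis=0)
        assert np.all(plv_pair(ph1, ph2) >= np.abs(c.imag) - 1e-12)
        assert np.all(ciplv_pair(ph1, ph2) <= 1 + 1e-12)


class TestSeedConnectivityMap:
    @pytest.fixture(scope="class")
    def coupled_trialset(self):
        mesh = make_mesh(15, rng_seed=1)
        spec = CohortSpec(n_subjects=1, n_trials=60, kappa_base=5.0,
                          coupling_lag_rad=np.pi / 2, noise_snr=8.0, rng_seed=2)
        thickness = sample_thickness(mesh, rng_seed=3)
        return mesh, simulate_trialset(mesh, spec, thickness, rng_seed=4)

    def test_identical_signals_give_unit_plv(self):
        mesh = make_mesh(12, rng_seed=0)
        fs = 600.0
        times = -1.5 + np.arange(1800) / fs
        sig = np.cos(2 * np.pi * 40 * times)
        data = np.tile(sig, (4, mesh.n_vertices, 1))
        ts = TrialSet(data, fs, times, mesh=mesh)
        m = seed_connectivity_map(ts, BandSpec(), "A1-left", "PLV")
        outside = np.setdiff1d(np.arange(mesh.n_vertices),
                               mesh.roi_labels["A1-left"])
        assert np.all(m[outside][:, 300:1500] > 0.999)

    def test_coupled_target_high_ciplv_uncoupled_at_floor(self, coupled_trialset):
        mesh, ts = coupled_trialset
        m = seed_connectivity_map(ts, BandSpec(), "A1-left", "ciPLV")
        steady = (ts.times >= 0.3) & (ts.times <= 0.7)
        coupled = mesh.roi_labels["A1-right"]
        labeled = np.concatenate(list(mesh.roi_labels.values()))
        uncoupled = np.setdiff1d(np.arange(mesh.n_vertices), labeled)
        assert m[coupled][:, steady].mean() > 0.9
        assert m[uncoupled][:, steady].mean() < 0.3

    def test_two_vertex_seed_is_mean_of_single_seed_maps(self, coupled_trialset):
        mesh, ts = coupled_trialset
        a1 = mesh.roi_labels["A1-left"]
        sub = {"s0": a1[:1], "s1": a1[1:2], "both": a1[:2]}
        mesh.roi_labels.update(sub)
        try:
            m0 = seed_connectivity_map(ts, BandSpec(), "s0", "PLV")
            m1 = seed_connectivity_map(ts, BandSpec(), "s1", "PLV")
            mb = seed_connectivity_map(ts, BandSpec(), "both", "PLV")
        finally:
            for k in sub:
                mesh.roi_labels.pop(k)
        outside = np.setdiff1d(np.arange(mesh.n_vertices), a1[:2])
        np.testing.assert_allclose(mb[outside], (m0 + m1)[outside] / 2, atol=1e-9)

    def test_empty_seed_rejected(self, coupled_trialset):
        mesh, ts = coupled_trialset
        with pytest.raises(ValueError, match="seed ROI"):
            seed_connectivity_map(ts, BandSpec(), "nonexistent", "PLV")


class TestZScoreAndAveraging:
    def test_hand_arithmetic_fixes_ddof(self):
        """Baseline {1,2,3}, stim value 5 -> z = (5-2)/1 with sample sd."""
        times = np.array([-0.5, -0.35, -0.2, 0.5])
        m = np.array([[1.0, 2.0, 3.0, 5.0]])
        z = baseline_zscore(m, times)
        assert z[0, -1] == pytest.approx(3.0)

    def test_baseline_window_standardized(self, rng):
        times = np.linspace(-1.5, 1.5, 1800)
        m = rng.standard_normal((5, 1800))
        z = baseline_zscore(m, times)
        w = (times >= -0.5) & (times <= -0.2)
        np.testing.assert_allclose(z[:, w].mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z[:, w].std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_metric_zeroed_with_warning(self):
        times = np.linspace(-1.5, 1.5, 100)
        with pytest.warns(UserWarning, match="zero baseline variance"):
            z = baseline_zscore(np.ones((2, 100)), times)
        assert np.all(z == 0)

    def test_steady_average_of_linear_ramp_is_midpoint(self):
        """Mean of a + b*t over [0.3, 0.7] is a + b*0.5."""
        times = np.linspace(-1.5, 1.5, 1801)
        a, b = 1.5, 2.0
        z = (a + b * times)[None, :]
        got = steady_state_average(z, times)[0]
        assert abs(got - (a + b * 0.5)) < b * (times[1] - times[0])

    def test_constant_in_window(self):
        times = np.linspace(-1.5, 1.5, 100)
        assert steady_state_average(np.full((1, 100), 3.3),
                                    times)[0] == pytest.approx(3.3, abs=1e-12)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            AnalysisWindows(baseline_s=(-0.2, -0.5))
        with pytest.raises(ValueError):
            AnalysisWindows(baseline_s=(0.4, 0.6), steady_s=(0.3, 0.7))


class TestFullMapPipeline:
    def test_strong_entrainment_raises_steady_z(self):
        """kappa -> large: steady-state z is positive at every entrained
        vertex and exceeds the baseline-window average."""
        mesh = make_mesh(12, rng_seed=5)
        spec = CohortSpec(n_subjects=1, n_trials=50, kappa_base=50.0,
                          noise_snr=10.0, rng_seed=6)
        th = sample_thickness(mesh, rng_seed=7)
        ts = simulate_trialset(mesh, spec, th, rng_seed=8)
        steady = itpc_map(ts)
        base = itpc_map(ts, window="baseline")
        assert np.all(steady.values > 0)
        assert np.all(steady.values > base.values)

    def test_pipeline_determinism(self):
        mesh = make_mesh(12, rng_seed=5)
        spec = CohortSpec(n_subjects=1, n_trials=20, rng_seed=6)
        th = sample_thickness(mesh, rng_seed=7)
        ts = simulate_trialset(mesh, spec, th, rng_seed=8)
        m1 = itpc_map(ts)
        m2 = itpc_map(ts)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_raw_map_bounded(self):
        mesh = make_mesh(12, rng_seed=5)
        spec = CohortSpec(n_subjects=1, n_trials=20, rng_seed=6)
        th = sample_thickness(mesh, rng_seed=7)
        ts = simulate_trialset(mesh, spec, th, rng_seed=8)
        raw = itpc_map(ts, zscored=False)
        assert raw.kind == "raw"
        assert raw.values.min() >= 0 and raw.values.max() <= 1
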