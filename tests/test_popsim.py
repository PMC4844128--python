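"""Forward model: modulation, thinning, calibration, rendering, noise."""
import numpy as np
import pytest
from scipy import stats

from muadecode.popsim import (ModulationSchedule, NoiseModel, SimulationError,
                              Window, add_noise, binned_rates, calibrate_depth,
                              default_schedule, modulated_rate,
                              modulation_factor, render_trace,
                              simulate_spike_trains, PEAK_RATE_TARGETS)
from muadecode.spectral import band_limited_power
from muadecode.waveforms import (CellType, Population, PopulationConfig,
                                 make_waveform, sample_population)

FS = 20_000.0


def single_cell_population(rate, library, index=0):
    return Population(np.array([library[index].cell_type is CellType.MSN]),
                      np.array([float(rate)]), np.array([index]), library)


class TestSchedule:
    def test_default_windows(self):
        sched = default_schedule()
        mods = [w.modulates for w in sched.windows]
        assert mods == [frozenset(), {"MSN"}, {"FSI"}, {"MSN", "FSI"},
                        {"MSN", "FSI"}]
        assert sched.windows[3].antiphase == "FSI"
        assert sched.duration == 50.0

    def test_negative_depth_rejected(self):
        with pytest.raises(SimulationError):
            default_schedule(depth_msn=-0.5)


class TestModulatedRate:
    def test_unresponsive_constant(self):
        sched = default_schedule(depth_msn=5.0)
        t = np.linspace(0.0, 49.99, 1000)
        np.testing.assert_array_equal(
            modulated_rate(2.4, t, sched, "MSN", responsive=False),
            np.full(1000, 2.4))

    def test_sine_peak_value(self):
        """At the sine peak (t_start + 0.5 s at 0.5 Hz) rate = mean*(1+d)."""
        sched = default_schedule(depth_msn=3.0)
        assert modulated_rate(2.0, 10.5, sched, "MSN") == pytest.approx(8.0)

    def test_clipping_at_zero(self):
        sched = default_schedule(depth_msn=10.0)
        t_trough = 11.5  # sine = -1 one half-period after the peak
        assert modulated_rate(2.0, t_trough, sched, "MSN") == 0.0

    def test_pointwise_oracle(self):
        """Direct evaluation of mean*(max(0, 1+d*sin)) per window."""
        sched = default_schedule(depth_msn=4.0, depth_fsi=2.0)
        rng = np.random.default_rng(0)
        t = rng.uniform(0.0, 50.0, 500)
        got = modulated_rate(3.0, t, sched, "FSI")
        expected = np.full(t.size, 3.0)
        for w in sched.windows:
            inside = (t >= w.t_start) & (t < w.t_end)
            if "FSI" in w.modulates:
                s = np.sin(2 * np.pi * 0.5 * (t[inside] - w.t_start))
                if w.antiphase == "FSI":
                    s = -s
                expected[inside] = 3.0 * np.maximum(0.0, 1.0 + 2.0 * s)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_antiphase_negates_fsi(self):
        sched = default_schedule(depth_msn=1.0, depth_fsi=1.0)
        w = sched.windows[3]
        t = np.array([30.5])  # MSN sine peak
        assert modulation_factor(t, w, "MSN", sched)[0] == pytest.approx(2.0)
        assert modulation_factor(t, w, "FSI", sched)[0] == pytest.approx(0.0)


class TestSimulate:
    def test_unmodulated_rates_recovered(self, small_population):
        """0% responsive: per-type mean rates match the population means
        within 3 standard errors (Poisson counting)."""
        sched = default_schedule(depth_msn=5.0, depth_fsi=5.0)
        sched = sched.with_fraction(0.0)
        trains = simulate_spike_trains(small_population, sched, seed=0)
        rates = binned_rates(trains)
        for name, arr, mask in (("MSN", rates.msn, small_population.is_msn),
                                ("FSI", rates.fsi, ~small_population.is_msn)):
            expect = small_population.mean_rate[mask].mean()
            n_spikes_expected = expect * mask.sum() * 50.0
            se = np.sqrt(n_spikes_expected) / (mask.sum() * 50.0)
            assert abs(arr.mean() - expect) < 3 * se

    def test_single_neuron_count(self, library):
        pop = single_cell_population(2.4, library)
        sched = default_schedule().with_fraction(0.0)
        trains = simulate_spike_trains(pop, sched, seed=1)
        assert abs(len(trains) - 120) < 3 * np.sqrt(120)

    def test_seed_determinism(self, small_population):
        sched = default_schedule(depth_msn=2.0).with_fraction(0.5)
        a = simulate_spike_trains(small_population, sched, seed=9)
        b = simulate_spike_trains(small_population, sched, seed=9)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.cell_index, b.cell_index)

    def test_times_sorted_within_duration(self, small_population):
        sched = default_schedule(depth_msn=2.0)
        trains = simulate_spike_trains(small_population, sched, seed=3)
        assert np.all(np.diff(trains.times) >= 0)
        assert trains.times[0] >= 0 and trains.times[-1] < 50.0

    def test_time_rescaling_oracle(self, library):
        """Rescaled inter-spike intervals of a modulated cell are Exp(1)
        (Kolmogorov-Smirnov at alpha = 0.01)."""
        pop = single_cell_population(60.0, library)  # high rate for power
        sched = default_schedule(depth_msn=1.0)
        trains = simulate_spike_trains(pop, sched, seed=4)
        t = trains.times
        # numeric integral of the rate over a fine grid
        grid = np.linspace(0.0, 50.0, 500_001)
        lam = modulated_rate(60.0, grid, sched, "MSN")
        cum = np.concatenate([[0.0], np.cumsum((lam[1:] + lam[:-1]) / 2
                                               * np.diff(grid))])
        rescaled = np.interp(t, grid, cum)
        intervals = np.diff(rescaled)
        res = stats.kstest(intervals, "expon")
        assert res.pvalue > 0.01

    def test_stationary_at_zero_fraction(self, small_population):
        """Unmodulated binned rates carry no trend (slope CI contains 0)."""
        sched = default_schedule(depth_msn=5.0).with_fraction(0.0)
        trains = simulate_spike_trains(small_population, sched, seed=5)
        rates = binned_rates(trains)
        res = stats.linregress(rates.t, rates.msn)
        ci = 2.58 * res.stderr
        assert abs(res.slope) < ci


class TestCalibration:
    def test_self_consistent_peak(self, library):
        """Re-simulating with calibrated depths reproduces the target peak
        rates within 2 Hz."""
        pop = sample_population(PopulationConfig(n_cells=20_000, seed=1),
                                library)
        sched = default_schedule()
        dm, df = calibrate_depth(pop, sched)
        full = sched.with_depths(dm, df).with_fraction(1.0)
        trains = simulate_spike_trains(pop, full, seed=0)
        rates = binned_rates(trains)
        assert rates.msn.max() == pytest.approx(PEAK_RATE_TARGETS["MSN"], abs=2.0)
        assert rates.fsi.max() == pytest.approx(PEAK_RATE_TARGETS["FSI"], abs=2.0)

    def test_depth_monotone_in_target(self, small_population):
        sched = default_schedule()
        d_lo, _ = calibrate_depth(small_population, sched,
                                  targets={"MSN": 40.0, "FSI": 60.0})
        d_hi, _ = calibrate_depth(small_population, sched,
                                  targets={"MSN": 80.0, "FSI": 60.0})
        assert d_hi > d_lo

    def test_zero_depth_peak_near_mean(self, small_population):
        """depth 0 leaves the peak at the mean plus Poisson fluctuation."""
        sched = default_schedule().with_fraction(1.0)
        trains = simulate_spike_trains(small_population, sched, seed=6)
        rates = binned_rates(trains)
        mean = small_population.mean_rate[small_population.is_msn].mean()
        n_msn = small_population.n_msn
        bin_sd = np.sqrt(mean * n_msn * 0.01) / (n_msn * 0.01)
        assert rates.msn.max() < mean + 6 * bin_sd


class TestRender:
    def test_single_spike_is_template(self, library):
        pop = single_cell_population(1.0, library, index=0)
        w = library[0]
        trains = simulate_spike_trains(pop, default_schedule().with_fraction(0.0),
                                       seed=0)
        trains.times = np.array([0.5])
        trains.cell_index = np.array([0])
        trace = render_trace(trains)
        i = int(round(0.5 * FS))
        seg = trace.msn[i - w.peak_index:i - w.peak_index + w.samples.size]
        np.testing.assert_allclose(seg, w.samples)
        outside = np.concatenate([trace.msn[:i - w.peak_index],
                                  trace.msn[i - w.peak_index + w.samples.size:]])
        assert np.all(outside == 0)

    def test_coincident_spikes_sum(self, library):
        pop = single_cell_population(1.0, library, index=0)
        trains = simulate_spike_trains(pop, default_schedule().with_fraction(0.0),
                                       seed=0)
        trains.times = np.array([0.5, 0.5])
        trains.cell_index = np.array([0, 0])
        doubled = render_trace(trains)
        assert doubled.msn.max() == pytest.approx(2 * library[0].samples.max())

    def test_energy_additivity(self, library):
        """Sparse train: trace energy equals n_spikes x template energy."""
        w = library[0]
        pop = single_cell_population(1.0, library, index=0)
        trains = simulate_spike_trains(pop, default_schedule().with_fraction(0.0),
                                       seed=0)
        times = np.arange(0.1, 49.0, 1.0)
        trains.times = times
        trains.cell_index = np.zeros(times.size, dtype=np.int64)
        trace = render_trace(trains)
        assert (trace.msn ** 2).sum() == pytest.approx(
            times.size * (w.samples ** 2).sum(), rel=1e-9)


class TestNoise:
    def _trace(self, library, seed=0):
        pop = sample_population(PopulationConfig(n_cells=500, seed=2), library)
        sched = default_schedule(depth_msn=2.0, depth_fsi=2.0)
        trains = simulate_spike_trains(pop, sched, seed=seed)
        return render_trace(trains)

    def test_zero_amplitude_identity(self, library):
        trace = self._trace(library)
        out = add_noise(trace, NoiseModel(rms_ratio=0.0), seed=0)
        assert np.all(out.noise == 0)
        np.testing.assert_array_equal(out.total, trace.msn + trace.fsi)

    def test_line_only_band_separation(self, library):
        """Pure 60 Hz noise: BLP near 60 Hz carries A^2/2, nothing >300 Hz."""
        trace = self._trace(library)
        out = add_noise(trace, NoiseModel(rms_ratio=0.5, line_fraction=1.0),
                        seed=1)
        line_amp = np.sqrt(2.0) * out.noise.std()
        blp_line = band_limited_power(out.noise, (55.0, 65.0), FS)
        blp_high = band_limited_power(out.noise, (300.0, 1000.0), FS)
        interior = slice(int(0.5 * FS), -int(0.5 * FS))
        assert blp_line.values[interior].mean() == pytest.approx(
            line_amp ** 2 / 2, rel=0.05)
        assert blp_high.values[interior].mean() < 1e-6 * line_amp ** 2

    def test_default_noise_leaves_mua_band_intact(self, library):
        """>300 Hz BLP of the default noisy trace is within 5% of the
        noiseless value."""
        trace = self._trace(library)
        noisy = add_noise(trace, NoiseModel(), seed=2)
        clean = band_limited_power(trace.msn + trace.fsi, (300.0, 9999.0), FS)
        dirty = band_limited_power(noisy.total, (300.0, 9999.0), FS)
        assert dirty.values.mean() == pytest.approx(clean.values.mean(),
                                                    rel=0.05)

    def test_component_decomposition_exact(self, library):
        """With zero noise, BLP(total) equals BLP(msn+fsi) exactly."""
        trace = self._trace(library)
        a = band_limited_power(trace.total, (300.0, 2000.0), FS).values
        b = band_limited_power(trace.msn + trace.fsi, (300.0, 2000.0), FS).values
        np.testing.assert_array_equal(a, b)
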