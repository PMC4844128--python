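"""Forward model of striatal multiunit activity.

A population of Poisson-spiking neurons (by default 20,000 cells,
95:5 MSN:FSI) is driven through a five-condition schedule of 10-s
windows: rest (no modulation), MSN-only modulation, FSI-only
modulation, anti-phase modulation of both types, and in-phase
modulation of both types.  Within a modulated window, the firing rate
of each *responsive* cell is multiplied by ``max(0, 1 + depth*sin)``
with a 0.5 Hz sine restarting at phase zero at the window start
(negated for FSIs in the anti-phase window), so modulation both drives
and silences cells.  The modulation depth is not free: it is
calibrated by bisection so that at 100 % responsiveness the maximum
per-neuron population rate in 10-ms bins reaches the study's printed
peaks (78.2 Hz for MSNs, 141.5 Hz for FSIs).

Spike trains are drawn by thinning an aggregate homogeneous Poisson
process per (type, window) and assigning accepted events to cells in
proportion to their mean rates - exactly equivalent in distribution to
independent per-cell inhomogeneous Poisson processes.  Each spike then
deposits its neuron's waveform template into a 20 kHz trace
(peak-aligned, nearest sample), per cell type, and parametric
non-neuronal noise (a dominant 60 Hz line plus weak broadband
Gaussian) is added last.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .waveforms import Population, SpikeWaveform

__all__ = [
    "Window",
    "ModulationSchedule",
    "SpikeTrainSet",
    "BinnedRates",
    "Trace",
    "NoiseModel",
    "SimulationError",
    "default_schedule",
    "modulation_factor",
    "modulated_rate",
    "simulate_spike_trains",
    "binned_rates",
    "render_trace",
    "add_noise",
    "calibrate_depth",
    "PEAK_RATE_TARGETS",
]

#: printed 100%-responsiveness peak per-neuron population rates, Hz
PEAK_RATE_TARGETS = {"MSN": 78.2, "FSI": 141.5}
#: width of a rate bin, seconds
BIN_S = 0.01


class SimulationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Window:
    """One schedule condition: which types the sine drives in [t_start, t_end)."""

    t_start: float
    t_end: float
    modulates: frozenset[str]  # subset of {"MSN", "FSI"}
    antiphase: str | None = None  # type whose sine is negated

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclasses.dataclass(frozen=True)
class ModulationSchedule:
    """The five-condition schedule with per-type depth and responsiveness."""

    sine_freq: float = 0.5
    responsive_fraction: float = 1.0
    depth_msn: float = 0.0
    depth_fsi: float = 0.0
    windows: tuple[Window, ...] = ()

    def __post_init__(self):
        if self.depth_msn < 0 or self.depth_fsi < 0:
            raise SimulationError("modulation depth must be >= 0")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise SimulationError("responsive_fraction must lie in [0, 1]")
        if not self.windows:
            object.__setattr__(self, "windows", _default_windows())

    @property
    def duration(self) -> float:
        return max(w.t_end for w in self.windows)

    def depth(self, cell_type: str) -> float:
        return self.depth_msn if cell_type == "MSN" else self.depth_fsi

    def rest_window(self) -> Window:
        for w in self.windows:
            if not w.modulates:
                return w
        raise SimulationError("schedule has no rest window")

    def with_depths(self, depth_msn: float, depth_fsi: float) -> "ModulationSchedule":
        return dataclasses.replace(self, depth_msn=depth_msn, depth_fsi=depth_fsi)

    def with_fraction(self, fraction: float) -> "ModulationSchedule":
        return dataclasses.replace(self, responsive_fraction=fraction)


def _default_windows() -> tuple[Window, ...]:
    none: frozenset[str] = frozenset()
    return (
        Window(0.0, 10.0, none),
        Window(10.0, 20.0, frozenset({"MSN"})),
        Window(20.0, 30.0, frozenset({"FSI"})),
        Window(30.0, 40.0, frozenset({"MSN", "FSI"}), antiphase="FSI"),
        Window(40.0, 50.0, frozenset({"MSN", "FSI"})),
    )


def default_schedule(responsive_fraction: float = 1.0, depth_msn: float = 0.0,
                     depth_fsi: float = 0.0) -> ModulationSchedule:
    return ModulationSchedule(responsive_fraction=responsive_fraction,
                              depth_msn=depth_msn, depth_fsi=depth_fsi)


def modulation_factor(t: np.ndarray, window: Window, cell_type: str,
                      sched: ModulationSchedule) -> np.ndarray:
    """Multiplicative rate factor max(0, 1 + depth*sin) for responsive cells
    of ``cell_type`` at times ``t`` inside ``window``; 1 when unmodulated."""
    t = np.asarray(t, dtype=float)
    if cell_type not in window.modulates:
        return np.ones_like(t)
    s = np.sin(2.0 * np.pi * sched.sine_freq * (t - window.t_start))
    if window.antiphase == cell_type:
        s = -s
    return np.maximum(0.0, 1.0 + sched.depth(cell_type) * s)


def modulated_rate(mean_rate: float, t: np.ndarray | float, sched: ModulationSchedule,
                   cell_type: str, responsive: bool = True) -> np.ndarray:
    """Instantaneous firing rate of one cell at times ``t`` under the schedule."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.full(t_arr.shape, float(mean_rate))
    if responsive:
        for w in sched.windows:
            mask = (t_arr >= w.t_start) & (t_arr < w.t_end)
            if np.any(mask) and cell_type in w.modulates:
                out[mask] = mean_rate * modulation_factor(t_arr[mask], w,
                                                          cell_type, sched)
    return out if np.ndim(t) else float(out[0])


@dataclasses.dataclass
class SpikeTrainSet:
    """All spikes of one simulation: parallel time / cell-index arrays,
    time-sorted, with the population they came from."""

    times: np.ndarray
    cell_index: np.ndarray
    population: Population
    duration: float
    responsive: np.ndarray  # bool per cell

    def spike_train(self, neuron_id: int) -> np.ndarray:
        return self.times[self.cell_index == neuron_id]

    def by_type(self, cell_type: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.population.is_msn[self.cell_index]
        if cell_type == "FSI":
            mask = ~mask
        return self.times[mask], self.cell_index[mask]

    def __len__(self) -> int:
        return self.times.size


@dataclasses.dataclass(frozen=True)
class BinnedRates:
    """Per-type instantaneous population rate: mean spikes/s per neuron
    in half-open 10-ms bins."""

    msn: np.ndarray
    fsi: np.ndarray
    bin_s: float = BIN_S

    @property
    def n_bins(self) -> int:
        return self.msn.size

    @property
    def t(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_s


def _aggregate_window_spikes(rng: np.random.Generator, rates: np.ndarray,
                             window: Window, factor_fn) -> tuple[np.ndarray, np.ndarray]:
    """Thinning sampler for one (sub)population over one window.

    ``factor_fn(t)`` is the shared modulation factor (1 for homogeneous
    segments).  Returns accepted times and indices into ``rates``.
    """
    total = float(rates.sum())
    if total <= 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    # upper bound of the shared factor on this window
    probe = np.linspace(window.t_start, window.t_end, 2001)
    fmax = float(np.max(factor_fn(probe)))
    if fmax <= 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    lam = total * fmax * window.duration
    n_cand = rng.poisson(lam)
    t_cand = rng.uniform(window.t_start, window.t_end, n_cand)
    accept = rng.random(n_cand) * fmax < factor_fn(t_cand)
    t_acc = t_cand[accept]
    # mark each accepted spike with a cell, proportional to mean rate
    cum = np.cumsum(rates)
    idx = np.searchsorted(cum, rng.random(t_acc.size) * total, side="right")
    return t_acc, idx.astype(np.int64)


def simulate_spike_trains(population: Population, sched: ModulationSchedule,
                          seed: int | np.random.Generator) -> SpikeTrainSet:
    """Inhomogeneous-Poisson spike trains for every cell under the schedule.

    The responsive subset (``sched.responsive_fraction`` of each type) is
    drawn first; within each window, responsive cells of a modulated type
    share the sinusoidal factor and are sampled by thinning, all other
    cells are homogeneous at their mean rate.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    n = len(population)
    responsive = np.zeros(n, dtype=bool)
    for type_mask in (population.is_msn, ~population.is_msn):
        ids = np.nonzero(type_mask)[0]
        k = int(round(sched.responsive_fraction * ids.size))
        if k > 0:
            responsive[rng.choice(ids, size=k, replace=False)] = True

    all_t, all_i = [], []
    for w in sched.windows:
        for cell_type, type_mask in (("MSN", population.is_msn),
                                     ("FSI", ~population.is_msn)):
            ids = np.nonzero(type_mask)[0]
            if ids.size == 0:
                continue
            modulated = cell_type in w.modulates
            resp_ids = ids[responsive[ids]] if modulated else np.empty(0, dtype=np.int64)
            flat_ids = np.setdiff1d(ids, resp_ids, assume_unique=True)
            if modulated and resp_ids.size:
                t, j = _aggregate_window_spikes(
                    rng, population.mean_rate[resp_ids], w,
                    lambda t: modulation_factor(t, w, cell_type, sched))
                all_t.append(t)
                all_i.append(resp_ids[j])
            if flat_ids.size:
                t, j = _aggregate_window_spikes(
                    rng, population.mean_rate[flat_ids], w,
                    lambda t: np.ones_like(np.asarray(t, dtype=float)))
                all_t.append(t)
                all_i.append(flat_ids[j])

    times = np.concatenate(all_t) if all_t else np.empty(0)
    cells = np.concatenate(all_i) if all_i else np.empty(0, dtype=np.int64)
    order = np.argsort(times, kind="stable")
    return SpikeTrainSet(times[order], cells[order], population,
                         sched.duration, responsive)


def binned_rates(trains: SpikeTrainSet, bin_s: float = BIN_S) -> BinnedRates:
    """Per-type per-neuron population rate in half-open [t, t+bin) bins, Hz."""
    n_bins = int(round(trains.duration / bin_s))
    pop = trains.population
    out = {}
    for cell_type in ("MSN", "FSI"):
        t, _ = trains.by_type(cell_type)
        idx = np.floor(t / bin_s).astype(np.int64)
        idx = idx[idx < n_bins]
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        n_cells = pop.n_msn if cell_type == "MSN" else pop.n_fsi
        out[cell_type] = counts / max(n_cells, 1) / bin_s
    return BinnedRates(out["MSN"], out["FSI"], bin_s)


@dataclasses.dataclass
class Trace:
    """A 20 kHz extracellular trace decomposed into components.

    ``total = msn + fsi + noise`` sample-wise by construction.
    """

    fs: float
    msn: np.ndarray
    fsi: np.ndarray
    noise: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.msn + self.fsi + self.noise

    @property
    def n_samples(self) -> int:
        return self.msn.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def render_trace(trains: SpikeTrainSet, fs: float = 20_000.0,
                 duration: float | None = None) -> Trace:
    """Superpose waveform templates at spike times (peak at nearest sample).

    Spikes whose template would overrun the trace end are truncated.
    Implemented per template: the spike times using a template form an
    impulse train that is convolved with the template once.
    """
    pop = trains.population
    if duration is None:
        duration = trains.duration
    n = int(round(duration * fs))
    components = {"MSN": np.zeros(n), "FSI": np.zeros(n)}
    widx_per_spike = pop.waveform_index[trains.cell_index]
    sample_idx = np.rint(trains.times * fs).astype(np.int64)
    keep = (sample_idx >= 0) & (sample_idx < n)
    sample_idx = sample_idx[keep]
    widx_per_spike = widx_per_spike[keep]
    is_msn_spike = pop.is_msn[trains.cell_index[keep]]

    for wi in np.unique(widx_per_spike):
        w: SpikeWaveform = pop.library[int(wi)]
        mask = widx_per_spike == wi
        impulses = np.bincount(sample_idx[mask], minlength=n).astype(float)
        conv = np.convolve(impulses, w.samples)
        # align template peak to the spike sample
        seg = conv[w.peak_index:w.peak_index + n]
        target = "MSN" if is_msn_spike[mask][0] else "FSI"
        components[target] += seg
    return Trace(fs, components["MSN"], components["FSI"], np.zeros(n))


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Parametric non-neuronal noise: a 60 Hz line plus broadband Gaussian.

    ``rms_ratio`` sets total noise RMS relative to the neural signal RMS;
    ``line_fraction`` is the share of noise *power* carried by the line.
    The default noise is almost entirely line hum: the broadband
    remainder is kept small enough that power in the multiunit bands
    (including 8-10 kHz) stays spike-dominated, i.e. noise does not
    materially affect any accuracy measurement.
    """

    rms_ratio: float = 0.5
    line_fraction: float = 0.998
    line_freq: float = 60.0
    #: window over which the reference signal RMS is taken, seconds.
    #: The rig's noise floor is a property of the recording, so it is
    #: matched against *spontaneous* (rest-window) wideband activity
    #: rather than evoked bursts.
    ref_window: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self):
        if self.rms_ratio < 0 or not 0.0 <= self.line_fraction <= 1.0:
            raise SimulationError("invalid noise model amplitudes")


def add_noise(trace: Trace, noise_model: NoiseModel,
              seed: int | np.random.Generator) -> Trace:
    """Return a new Trace with the noise component filled in."""
    rng = np.random.default_rng(seed)
    n = trace.n_samples
    signal = trace.msn + trace.fsi
    lo = min(n, int(round(noise_model.ref_window[0] * trace.fs)))
    hi = min(n, int(round(noise_model.ref_window[1] * trace.fs)))
    ref = signal[lo:hi] if hi > lo else signal
    signal_rms = float(np.sqrt(np.mean(ref ** 2)))
    noise_rms = noise_model.rms_ratio * signal_rms
    if noise_rms == 0:
        return Trace(trace.fs, trace.msn, trace.fsi, np.zeros(n))
    line_rms = noise_rms * np.sqrt(noise_model.line_fraction)
    white_sd = noise_rms * np.sqrt(1.0 - noise_model.line_fraction)
    t = np.arange(n) / trace.fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    noise = line_rms * np.sqrt(2.0) * np.sin(
        2.0 * np.pi * noise_model.line_freq * t + phase)
    if white_sd > 0:
        noise = noise + rng.normal(0.0, white_sd, n)
    return Trace(trace.fs, trace.msn, trace.fsi, noise)


def _peak_binned_rate(rng: np.random.Generator, rates: np.ndarray, depth: float,
                      window: Window, sine_freq: float, bin_s: float = BIN_S
                      ) -> float:
    """Max per-neuron 10-ms-bin rate of a fully responsive subpopulation,
    simulated exactly at the bin level (binned inhomogeneous Poisson)."""
    total = float(rates.sum())
    n_bins = int(round(window.duration / bin_s))
    edges = window.t_start + np.arange(n_bins + 1) * bin_s
    # mean of max(0, 1 + d sin) over each bin, by fine sub-sampling
    fine = np.linspace(0, 1, 9)[None, :] * bin_s + edges[:-1, None]
    m = np.maximum(0.0, 1.0 + depth * np.sin(
        2.0 * np.pi * sine_freq * (fine - window.t_start)))
    lam = total * m.mean(axis=1) * bin_s
    counts = rng.poisson(lam)
    return float(counts.max() / rates.size / bin_s)


def calibrate_depth(population: Population, sched: ModulationSchedule,
                    targets: dict[str, float] | None = None,
                    seeds: Sequence[int] = (0, 1, 2, 3, 4),
                    tol_hz: float = 0.5, max_depth: float = 200.0
                    ) -> tuple[float, float]:
    """Bisection of per-type modulation depths against the printed peaks.

    For each type, the depth is chosen so that with 100 % of that type
    responsive, the maximum per-neuron population rate in 10-ms bins
    (averaged over ``seeds``) matches the target (78.2 Hz MSN,
    141.5 Hz FSI) within ``tol_hz``.
    """
    if targets is None:
        targets = PEAK_RATE_TARGETS
    depths = {}
    for cell_type, type_mask in (("MSN", population.is_msn),
                                 ("FSI", ~population.is_msn)):
        rates = population.mean_rate[type_mask]
        if rates.size == 0:
            depths[cell_type] = 0.0
            continue
        window = next(w for w in sched.windows
                      if w.modulates == frozenset({cell_type}))
        target = targets[cell_type]

        def peak(depth: float) -> float:
            vals = [_peak_binned_rate(np.random.default_rng(s), rates, depth,
                                      window, sched.sine_freq) for s in seeds]
            return float(np.mean(vals))

        lo, hi = 0.0, 1.0
        while peak(hi) < target:
            hi *= 2.0
            if hi > max_depth:
                raise SimulationError(
                    f"cannot bracket depth for {cell_type}: target {target} Hz "
                    f"unreachable below depth {max_depth}")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            p = peak(mid)
            if abs(p - target) < tol_hz:
                lo = hi = mid
                break
            if p < target:
                lo = mid
            else:
                hi = mid
        depths[cell_type] = 0.5 * (lo + hi)
    return depths["MSN"], depths["FSI"]
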