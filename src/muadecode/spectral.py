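"""Frequency decomposition of spike snippets and band-limited power of traces.

Two complementary spectral views are used throughout the package:

* short snippets (a spike and its surroundings) are Fourier-transformed
  onto a fixed fine grid (2048 positive-frequency bands up to 10 kHz),
  a noise band at 4500-5000 Hz is excised, and the result is normalised
  to unit area so templates of different amplitude are comparable;
* long traces are summarised by band-limited power (BLP): the pointwise
  square of a zero-phase 5-pole Butterworth band-pass, i.e. an
  instantaneous power envelope in a named frequency band.

The default band grid is the conventional EEG set below 100 Hz (theta
4-8, alpha 8-12, beta 12-25, gamma 30-100 Hz) followed by contiguous
100-Hz-wide bands up to 10 kHz.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .waveforms import SpikeWaveform, make_waveform

__all__ = [
    "SpectralDecomposition",
    "BandPower",
    "CorrelationResult",
    "SpectralError",
    "default_bands",
    "spectrum_of_snippet",
    "normalized_power_spectrum",
    "band_mass",
    "band_limited_power",
    "correlate_attribute_power",
    "attribute_modulation_experiment",
]

#: snippet length for spike spectra: 10 ms before and after the spike
SNIPPET_WINDOW_S = 20e-3
#: number of positive-frequency bands retained
N_BANDS = 2048
#: FFT length achieving that band count for a 20 kHz snippet
NFFT = 2 * N_BANDS
#: excised environmental-noise band, Hz
EXCISE_HZ = (4500.0, 5000.0)
#: Butterworth design order (applied forward and backward: zero phase)
FILTER_ORDER = 5


class SpectralError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SpectralDecomposition:
    """Power on a fixed frequency grid; NaN marks excised bands.

    When ``normalized``, sum(power * df) over retained bands equals 1.
    """

    freqs: np.ndarray
    power: np.ndarray
    normalized: bool

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclasses.dataclass(frozen=True)
class BandPower:
    """Squared band-passed trace: a nonnegative power envelope at fs."""

    band: tuple[float, float]
    values: np.ndarray
    fs: float
    trace_id: str | None = None

    @property
    def duration(self) -> float:
        return self.values.size / self.fs


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with the t-statistic t = r*sqrt(n-2)/sqrt(1-r^2)."""

    r: float
    n: int
    t_stat: float
    p_value: float

    @property
    def df(self) -> int:
        return self.n - 2


def default_bands(f_max: float = 10_000.0) -> list[tuple[float, float]]:
    """EEG bands below 100 Hz, then contiguous 100-Hz bands up to ``f_max``."""
    bands = [(4.0, 8.0), (8.0, 12.0), (12.0, 25.0), (30.0, 100.0)]
    lo = 100.0
    while lo < f_max:
        bands.append((lo, min(lo + 100.0, f_max)))
        lo += 100.0
    return bands


def normalized_power_spectrum(x: np.ndarray, fs: float, nfft: int = NFFT,
                              excise_hz: tuple[float, float] | None = EXCISE_HZ
                              ) -> SpectralDecomposition:
    """Discrete Fourier power of a segment on the fine band grid.

    The segment is zero-padded (or the FFT length grown to the next
    power of two for longer segments), the DC bin dropped, the excised
    band replaced by NaN, and the result scaled to unit area over the
    retained bands.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x != 0):
        raise SpectralError("all-zero segment: normalization undefined")
    n = x.size
    if n > nfft:
        nfft = 1 << (n - 1).bit_length()
    spec = np.fft.rfft(x, nfft)
    power = np.abs(spec[1:]) ** 2  # drop DC; keep up to Nyquist
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)[1:]
    if excise_hz is not None:
        lo, hi = excise_hz
        power = power.copy()
        power[(freqs >= lo) & (freqs <= hi)] = np.nan
    df = freqs[1] - freqs[0]
    area = np.nansum(power) * df
    if area == 0:
        raise SpectralError("zero spectral mass after excision")
    return SpectralDecomposition(freqs, power / area, normalized=True)


def spectrum_of_snippet(snippet: np.ndarray, fs: float) -> SpectralDecomposition:
    """Normalised power spectrum of a 20-ms spike snippet.

    The snippet is symmetrically zero-padded or centre-truncated to
    20 ms (400 samples at 20 kHz) before transforming, so spectra of
    snippets cut with different margins share a grid.
    """
    x = np.asarray(snippet, dtype=float)
    n_target = int(round(SNIPPET_WINDOW_S * fs))
    if x.size < n_target:
        pad = n_target - x.size
        x = np.pad(x, (pad // 2, pad - pad // 2))
    elif x.size > n_target:
        start = (x.size - n_target) // 2
        x = x[start:start + n_target]
    return normalized_power_spectrum(x, fs)


def band_mass(decomp: SpectralDecomposition, lo: float, hi: float) -> float:
    """Integrated (normalised) power in [lo, hi) Hz, NaN bands skipped."""
    mask = (decomp.freqs >= lo) & (decomp.freqs < hi)
    return float(np.nansum(decomp.power[mask]) * decomp.df)


def design_bandpass(band: tuple[float, float], fs: float):
    """Second-order sections of the 5-pole Butterworth for ``band``.

    A band reaching the Nyquist frequency degenerates to a high-pass.
    """
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < nyq:
        raise SpectralError(f"band low edge {lo} Hz outside (0, Nyquist)")
    if hi <= lo:
        raise SpectralError("band high edge must exceed low edge")
    if hi >= nyq:
        return signal.butter(FILTER_ORDER, lo, btype="highpass", fs=fs, output="sos")
    return signal.butter(FILTER_ORDER, [lo, hi], btype="bandpass", fs=fs, output="sos")


def band_limited_power(trace: np.ndarray, band: tuple[float, float], fs: float,
                       trace_id: str | None = None) -> BandPower:
    """Band-limited power: zero-phase Butterworth band-pass, then square.

    The 5-pole filter is applied forward and backward (``sosfiltfilt``),
    doubling the effective order and cancelling phase, with reflective
    padding of one impulse-response scale at the edges.
    """
    x = np.asarray(trace, dtype=float)
    sos = design_bandpass(band, fs)
    # reflect-pad by roughly one impulse-response length of the low edge
    padlen = min(x.size - 1, max(3 * FILTER_ORDER, int(3 * fs / band[0])))
    y = signal.sosfiltfilt(sos, x, padlen=padlen)
    return BandPower(tuple(band), y * y, fs, trace_id)


def correlate_attribute_power(values: np.ndarray, powers: np.ndarray
                              ) -> CorrelationResult:
    """Pearson correlation between a per-unit attribute and per-unit power,
    with significance from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df."""
    v = np.asarray(values, dtype=float)
    p = np.asarray(powers, dtype=float)
    if v.size != p.size or v.size < 3:
        raise SpectralError("need >= 3 paired observations")
    if np.std(v) == 0 or np.std(p) == 0:
        raise SpectralError("zero variance: correlation undefined")
    r = float(np.corrcoef(v, p)[0, 1])
    n = v.size
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * math.sqrt(n - 2) / math.sqrt(1.0 - r_clip ** 2)
    p_value = 2.0 * stats.t.sf(abs(t), n - 2)
    return CorrelationResult(r, n, t, p_value)


def _regular_train_trace(w: SpikeWaveform, rate: float, duration: float,
                         fs: float) -> np.ndarray:
    """Trace of regularly spaced copies of a template (peak-aligned)."""
    n = int(round(duration * fs))
    out = np.zeros(n + w.samples.size)
    period = 1.0 / rate
    t = period / 2.0
    while t < duration:
        i = int(round(t * fs))
        start = i - w.peak_index
        if start >= 0 and start + w.samples.size <= out.size:
            out[start:start + w.samples.size] += w.samples
        t += period
    return out[:n]


def attribute_modulation_experiment(base: SpikeWaveform, attribute: str,
                                    grid: Sequence[float], duration: float = 10.0,
                                    rate: float = 5.0,
                                    bands: Iterable[tuple[float, float]] | None = None,
                                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Effect of one spike attribute on band power, others held fixed.

    For each value on the grid, a spike train of the modified waveform is
    synthesised (regular spacing, so power is attributable to the
    attribute rather than timing noise), total BLP per band is integrated
    over the duration, and the attribute-vs-power correlation is computed
    per band.

    ``attribute`` is one of ``width`` (FWHM, seconds), ``amplitude``
    (peak-peak scale factor) or ``rate`` (Hz).

    Returns ``(table, correlations)``: the long-format power table
    (attribute_value, band_lo_hz, band_hi_hz, total_blp) and one
    correlation row per band.
    """
    if attribute not in ("width", "amplitude", "rate"):
        raise SpectralError(f"unknown attribute {attribute!r}")
    grid = list(grid)
    if len(grid) < 2 or any(b <= a for a, b in zip(grid, grid[1:])):
        raise SpectralError("grid must be monotone increasing with >= 2 values")
    if bands is None:
        bands = default_bands(base.fs / 2.0)
    bands = list(bands)

    rows = []
    for value in grid:
        if attribute == "width":
            w = make_waveform(base.cell_type, value, base.peak_peak, base.fs)
            r = rate
        elif attribute == "amplitude":
            w = base.scaled(value)
            r = rate
        else:
            w = base
            r = value
        trace = _regular_train_trace(w, r, duration, base.fs)
        for band in bands:
            blp = band_limited_power(trace, band, base.fs)
            rows.append({"attribute": attribute, "attribute_value": value,
                         "band_lo_hz": band[0], "band_hi_hz": band[1],
                         "total_blp": float(blp.values.sum() / base.fs)})
    table = pd.DataFrame(rows)

    corr_rows = []
    for band in bands:
        sub = table[(table.band_lo_hz == band[0]) & (table.band_hi_hz == band[1])]
        res = correlate_attribute_power(sub.attribute_value.to_numpy(),
                                        sub.total_blp.to_numpy())
        corr_rows.append({"band_lo_hz": band[0], "band_hi_hz": band[1],
                          "r": res.r, "n": res.n, "t_stat": res.t_stat,
                          "p_value": res.p_value})
    return table, pd.DataFrame(corr_rows)
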