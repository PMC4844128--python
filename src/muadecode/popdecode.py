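"""Decoding population firing from multiunit band-limited power.

The decoders all compare the current 10-ms bin against *rest*
statistics (mean and SD over the unmodulated 0-10 s window):

* pattern decoding - each bin's z-scored low-MUA (0.3-2 kHz) and
  high-MUA (8-10 kHz) BLP is thresholded at +/-2 SD to a joint
  (MSN state, FSI state) pattern with states {down, none, up}; the
  ground truth applies the same +/-2 SD rule to the actual binned
  rates.  Scoring is 8-way (both states jointly; the none/none
  pattern is excluded, chance 1/8) or 2-way (direction of one type
  wherever its actual rate deviates, chance 1/2);
* continuous prediction - the z-scored BLP trace is mapped to a rate
  via pred = rest_rate_mean + z * rest_rate_SD, evaluated by
  correlation against actual rates and by percent error as a function
  of actual rate and responsive fraction.

Low MUA predicts MSNs and high MUA predicts FSIs: broad MSN spikes
dominate 0.3-2 kHz, while narrow FSI spikes retain proportionally
more power at 8-10 kHz.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .popsim import BIN_S, BinnedRates, ModulationSchedule, Window
from .spectral import BandPower, correlate_attribute_power

__all__ = [
    "LOW_MUA_BAND",
    "HIGH_MUA_BAND",
    "RestStatistics",
    "PatternReport",
    "DecodeError",
    "bin_blp",
    "rest_statistics",
    "actual_pattern",
    "classify_pattern",
    "pattern_accuracy",
    "PatternDecoder",
    "MuaRatePredictor",
    "band_rate_correlations",
    "binned_prediction_summary",
    "percent_error",
    "error_surface",
    "modulation_bin_mask",
    "direction_prediction",
]

LOW_MUA_BAND = (300.0, 2000.0)
HIGH_MUA_BAND = (8000.0, 10_000.0)
#: codes for down / none / up
DOWN, NONE, UP = -1, 0, 1


class DecodeError(ValueError):
    pass


def bin_blp(blp: BandPower, bin_s: float = BIN_S) -> np.ndarray:
    """Mean BLP in half-open 10-ms bins."""
    n_bins = int(blp.values.size / (bin_s * blp.fs))
    per_bin = int(round(bin_s * blp.fs))
    return blp.values[:n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)


@dataclasses.dataclass(frozen=True)
class RestStatistics:
    """Rest-window (0-10 s) means and SDs of rates and binned BLP."""

    rate_mean: dict[str, float]
    rate_sd: dict[str, float]
    blp_mean: dict[str, float]
    blp_sd: dict[str, float]


def rest_statistics(rates: BinnedRates, blp_bins: dict[str, np.ndarray],
                    rest_window: Window | tuple[float, float] = (0.0, 10.0)
                    ) -> RestStatistics:
    """Compute rest statistics over the unmodulated window only."""
    if isinstance(rest_window, Window):
        t0, t1 = rest_window.t_start, rest_window.t_end
    else:
        t0, t1 = rest_window
    lo = int(round(t0 / rates.bin_s))
    hi = int(round(t1 / rates.bin_s))
    rate_mean, rate_sd = {}, {}
    for name, arr in (("MSN", rates.msn), ("FSI", rates.fsi)):
        seg = arr[lo:hi]
        rate_mean[name] = float(seg.mean())
        rate_sd[name] = float(seg.std(ddof=1))
    blp_mean, blp_sd = {}, {}
    for name, arr in blp_bins.items():
        seg = arr[lo:hi]
        blp_mean[name] = float(seg.mean())
        sd = float(seg.std(ddof=1))
        if sd == 0:
            raise DecodeError(f"zero rest BLP variance in band {name!r}")
        blp_mean[name], blp_sd[name] = float(seg.mean()), sd
    return RestStatistics(rate_mean, rate_sd, blp_mean, blp_sd)


def _states(values: np.ndarray, mean: float, sd: float, threshold: float
            ) -> np.ndarray:
    z = (np.asarray(values, dtype=float) - mean) / sd
    return np.where(z > threshold, UP, np.where(z < -threshold, DOWN, NONE))


def actual_pattern(rates: BinnedRates, rest: RestStatistics,
                   threshold: float = 2.0) -> np.ndarray:
    """Ground-truth (MSN, FSI) state per bin from the +/-2 SD rate rule.

    Returns an (n_bins, 2) array with entries in {-1, 0, +1}.
    """
    msn = _states(rates.msn, rest.rate_mean["MSN"], rest.rate_sd["MSN"], threshold)
    fsi = _states(rates.fsi, rest.rate_mean["FSI"], rest.rate_sd["FSI"], threshold)
    return np.stack([msn, fsi], axis=1)


def classify_pattern(low_blp_bins: np.ndarray, high_blp_bins: np.ndarray,
                     rest: RestStatistics, threshold: float = 2.0) -> np.ndarray:
    """Predicted (MSN, FSI) state per bin: MSN from low-MUA z, FSI from
    high-MUA z, thresholded at +/-2 rest SD."""
    msn = _states(low_blp_bins, rest.blp_mean["low"], rest.blp_sd["low"], threshold)
    fsi = _states(high_blp_bins, rest.blp_mean["high"], rest.blp_sd["high"], threshold)
    return np.stack([msn, fsi], axis=1)


class PatternDecoder(BaseEstimator):
    """Rest-referenced +/-2 SD pattern decoder as a fit/predict estimator.

    ``fit`` consumes the rest-window bins of the two MUA bands
    (X_rest of shape (n_bins, 2): columns low, high) and stores their
    means and SDs; ``predict`` maps band bins to (MSN, FSI) state codes.
    """

    def __init__(self, threshold: float = 2.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_bins, 2): low and high MUA bins")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            raise DecodeError("zero rest BLP variance")
        return self

    def predict(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        z = (X - self.mean_) / self.scale_
        return np.where(z > self.threshold, UP,
                        np.where(z < -self.threshold, DOWN, NONE))


class MuaRatePredictor(RegressorMixin, BaseEstimator):
    """Continuous rate prediction from one MUA band, rest-scaled.

    ``fit`` takes the rest-window BLP bins (X, 1-D or (n, 1)) and the
    rest-window actual rates (y); ``predict`` returns
    rate_mean + z(blp) * rate_SD with z relative to the rest BLP
    statistics.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size or x.size < 3:
            raise ValueError("need matching rest BLP and rate bins")
        self.blp_mean_ = float(x.mean())
        self.blp_sd_ = float(x.std(ddof=1))
        if self.blp_sd_ == 0:
            raise DecodeError("zero rest BLP variance")
        self.rate_mean_ = float(y.mean())
        self.rate_sd_ = float(y.std(ddof=1))
        return self

    def predict(self, X):
        check_is_fitted(self, "blp_mean_")
        x = np.asarray(X, dtype=float).ravel()
        z = (x - self.blp_mean_) / self.blp_sd_
        return self.rate_mean_ + z * self.rate_sd_


@dataclasses.dataclass
class PatternReport:
    """Accuracy of pattern decoding over the scored bins."""

    mode: str  # "8-way", "2-way-MSN" or "2-way-FSI"
    overall: float  # micro-averaged over scored bins
    per_class: dict[tuple[int, int] | int, float]
    n_per_class: dict[tuple[int, int] | int, int]
    n_scored: int

    @property
    def chance(self) -> float:
        return 0.125 if self.mode == "8-way" else 0.5


def pattern_accuracy(predicted: np.ndarray, actual: np.ndarray, mode: str = "8-way",
                     scorable: np.ndarray | None = None) -> PatternReport:
    """Score predicted against actual patterns.

    8-way: bins whose actual pattern deviates in at least one type are
    scored on the exact joint pattern (8 classes; chance 1/8).
    2-way-MSN / 2-way-FSI: bins where the scored type's actual state is
    up or down are scored on that direction only (chance 1/2), with the
    other type free to co-modulate.

    ``scorable`` optionally restricts scoring to a boolean bin subset
    (e.g. the modulation windows).
    """
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape or predicted.ndim != 2:
        raise DecodeError("predicted/actual must both be (n_bins, 2)")
    base = np.ones(actual.shape[0], dtype=bool) if scorable is None else np.asarray(scorable, dtype=bool)

    if mode == "8-way":
        mask = base & ~((actual[:, 0] == NONE) & (actual[:, 1] == NONE))
        if not mask.any():
            raise DecodeError("no scorable bins")
        hit = (predicted[mask] == actual[mask]).all(axis=1)
        per_class, n_per_class = {}, {}
        for cls in map(tuple, np.unique(actual[mask], axis=0)):
            sel = (actual[mask] == cls).all(axis=1)
            per_class[cls] = float(hit[sel].mean())
            n_per_class[cls] = int(sel.sum())
        return PatternReport(mode, float(hit.mean()), per_class, n_per_class,
                             int(mask.sum()))

    if mode in ("2-way-MSN", "2-way-FSI"):
        col = 0 if mode.endswith("MSN") else 1
        mask = base & (actual[:, col] != NONE)
        if not mask.any():
            raise DecodeError("no scorable bins")
        # direction only: the sign of the predicted state/z deviation
        hit = np.sign(predicted[mask, col]) == np.sign(actual[mask, col])
        per_class, n_per_class = {}, {}
        for cls in (DOWN, UP):
            sel = actual[mask, col] == cls
            if sel.any():
                per_class[cls] = float(hit[sel].mean())
                n_per_class[cls] = int(sel.sum())
        return PatternReport(mode, float(hit.mean()), per_class, n_per_class,
                             int(mask.sum()))
    raise DecodeError(f"unknown mode {mode!r}")


def modulation_bin_mask(sched: ModulationSchedule, n_bins: int,
                        bin_s: float = BIN_S) -> np.ndarray:
    """Boolean mask of bins lying in modulated (non-rest) windows."""
    t = (np.arange(n_bins) + 0.5) * bin_s
    mask = np.zeros(n_bins, dtype=bool)
    for w in sched.windows:
        if w.modulates:
            mask |= (t >= w.t_start) & (t < w.t_end)
    return mask


def direction_prediction(blp_bins: np.ndarray, rest_mean: float) -> np.ndarray:
    """Direction (+/-1) of a band's deviation from its rest mean, per bin."""
    return np.where(np.asarray(blp_bins, dtype=float) >= rest_mean, UP, DOWN)


def band_rate_correlations(blp_bins_by_band: dict[tuple[float, float], np.ndarray],
                           rates: BinnedRates, sched: ModulationSchedule
                           ) -> pd.DataFrame:
    """Pearson r between binned BLP and per-type rates, per modulation cycle.

    Every 10-s condition window is split into full cycles of the
    modulating sine (2 s at 0.5 Hz) and r is computed within each cycle,
    for each band and each cell type.  Windows with constant rate yield
    NaN r (recorded, not an error).
    """
    cycle_s = 1.0 / sched.sine_freq
    rows = []
    for w in sched.windows:
        condition = "+".join(sorted(w.modulates)) if w.modulates else "rest"
        if w.antiphase:
            condition += "(anti)"
        n_cycles = max(1, int(round(w.duration / cycle_s)))
        for cyc in range(n_cycles):
            t0 = w.t_start + cyc * cycle_s
            lo = int(round(t0 / rates.bin_s))
            hi = int(round(min(t0 + cycle_s, w.t_end) / rates.bin_s))
            for band, bins in blp_bins_by_band.items():
                for cell_type, rate in (("MSN", rates.msn), ("FSI", rates.fsi)):
                    seg_b = bins[lo:hi]
                    seg_r = rate[lo:hi]
                    if np.std(seg_r) == 0 or np.std(seg_b) == 0:
                        r = np.nan
                    else:
                        r = float(np.corrcoef(seg_b, seg_r)[0, 1])
                    rows.append({"band_lo_hz": band[0], "band_hi_hz": band[1],
                                 "cell_type": cell_type, "condition": condition,
                                 "cycle": cyc, "r": r, "n": hi - lo})
    return pd.DataFrame(rows)


def binned_prediction_summary(predicted: np.ndarray, actual: np.ndarray,
                              n_rate_bins: int = 30):
    """Mean predicted rate per actual-rate bin, and the correlation over
    those bin means (the scatter-summary convention of rate-prediction
    plots; its df is n_occupied_bins - 2).

    Returns ``(summary_frame, CorrelationResult)``.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    edges = np.linspace(actual.min(), actual.max() + 1e-12, n_rate_bins + 1)
    idx = np.clip(np.digitize(actual, edges) - 1, 0, n_rate_bins - 1)
    rows = []
    for b in range(n_rate_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append({"rate_bin_center": 0.5 * (edges[b] + edges[b + 1]),
                     "actual_mean": float(actual[sel].mean()),
                     "predicted_mean": float(predicted[sel].mean()),
                     "predicted_sd": float(predicted[sel].std(ddof=0)),
                     "n": int(sel.sum())})
    frame = pd.DataFrame(rows)
    res = correlate_attribute_power(frame["actual_mean"].to_numpy(),
                                    frame["predicted_mean"].to_numpy())
    return frame, res


def percent_error(predicted: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """100*|pred - actual| / actual per bin; NaN where actual is zero."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    out = np.full(actual.shape, np.nan)
    nz = actual != 0
    out[nz] = 100.0 * np.abs(predicted[nz] - actual[nz]) / actual[nz]
    return out


def error_surface(runs: Sequence[tuple[float, np.ndarray, np.ndarray]],
                  cell_type: str, rate_edges: np.ndarray | None = None
                  ) -> pd.DataFrame:
    """Percent prediction error by (actual-rate bin, responsive fraction).

    ``runs`` is a sequence of (fraction, predicted, actual) bin arrays.
    Zero-rate bins are excluded; their count is reported per row.
    """
    if len(runs) < 2:
        raise DecodeError("need >= 2 responsive fractions for a surface")
    if rate_edges is None:
        top = max(float(np.max(a)) for _, _, a in runs)
        rate_edges = np.linspace(0.0, top + 1e-12, 31)
    rows = []
    for fraction, pred, act in runs:
        pe = percent_error(pred, act)
        n_zero = int((np.asarray(act) == 0).sum())
        idx = np.clip(np.digitize(act, rate_edges) - 1, 0, len(rate_edges) - 2)
        for b in range(len(rate_edges) - 1):
            sel = (idx == b) & ~np.isnan(pe)
            if not sel.any():
                continue
            rows.append({"cell_type": cell_type, "fraction": fraction,
                         "rate_bin_lo": rate_edges[b], "rate_bin_hi": rate_edges[b + 1],
                         "percent_error": float(pe[sel].mean()),
                         "n": int(sel.sum()), "n_zero_rate_excluded": n_zero})
    return pd.DataFrame(rows)
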