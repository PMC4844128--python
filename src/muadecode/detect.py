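"""Threshold detection of spikes from z-scored band-limited power.

A spike is counted as detected (true positive) when the mean z-scored
BLP in a +/-1 ms window around its time exceeds the threshold
(2 SD by default); every sample outside all spike windows with z-BLP
at or below threshold is a true negative.  Sensitivity is the true
positive rate over spikes, specificity the true negative rate over
non-spike samples.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .spectral import BandPower, band_limited_power

__all__ = ["DetectionMetrics", "DetectError", "zscore", "detection_metrics",
           "detection_curve"]


class DetectError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class DetectionMetrics:
    band: tuple[float, float] | None
    sensitivity: float  # NaN when the spike train is empty
    specificity: float
    threshold_sd: float
    n_spikes: int
    n_nonspike_samples: int


def zscore(series: np.ndarray) -> np.ndarray:
    """Standardise to mean 0, SD 1 (sample SD, ddof=1).

    Affine-invariant: ``zscore(a*x + b) == zscore(x)`` for a > 0.
    """
    x = np.asarray(series, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0 or not math.isfinite(sd):
        raise DetectError("zero variance: z-score undefined")
    return (x - np.mean(x)) / sd


def detection_metrics(blp: BandPower, spike_times: np.ndarray,
                      threshold_sd: float = 2.0, window_s: float = 1e-3
                      ) -> DetectionMetrics:
    """Sensitivity/specificity of thresholded z-BLP for a spike train.

    The SD used for z-scoring is computed over the whole trace,
    spike epochs included.
    """
    z = zscore(blp.values)
    fs = blp.fs
    n = z.size
    times = np.sort(np.asarray(spike_times, dtype=float))
    half = int(round(window_s * fs))

    in_window = np.zeros(n, dtype=bool)
    hits = 0
    for t in times:
        c = int(round(t * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        in_window[lo:hi] = True
        if z[lo:hi].mean() > threshold_sd:
            hits += 1

    outside = ~in_window
    n_out = int(outside.sum())
    specificity = float((z[outside] <= threshold_sd).sum() / n_out) if n_out else float("nan")
    sensitivity = hits / times.size if times.size else float("nan")
    return DetectionMetrics(blp.band, sensitivity, specificity, threshold_sd,
                            times.size, n_out)


def detection_curve(trace: np.ndarray, fs: float, spike_times: np.ndarray,
                    bands, threshold_sd: float = 2.0) -> list[DetectionMetrics]:
    """Per-band sensitivity/specificity of BLP spike detection."""
    out = []
    for band in bands:
        blp = band_limited_power(trace, band, fs)
        out.append(detection_metrics(blp, spike_times, threshold_sd))
    return out
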