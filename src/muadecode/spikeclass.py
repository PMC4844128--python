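"""Single-trial classification of putative spikes as MSN vs FSI.

Candidate spikes are extracted wherever z-scored multiunit power
(> 300 Hz) peaks above 1 SD; a +/-25 ms snippet around each trigger is
Fourier-transformed, area-normalised, and summarised by two features:
integrated power in a low (500-600 Hz) and a high (3000-3500 Hz) band,
the bands with the largest MSN/FSI separation.  A linear soft-margin
SVM on those two features separates the types; held-out accuracy is
evaluated per *cell* (training cells and test cells never mix), with
missed spikes (no power trigger at a known spike time) counted as
errors.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .detect import zscore
from .spectral import band_limited_power, band_mass, normalized_power_spectrum

__all__ = [
    "PutativeSpike",
    "CellSnippets",
    "ClassifierReport",
    "SpectralSpikeClassifier",
    "extract_putative_spikes",
    "spike_features",
    "train_and_classify",
    "LOW_FEATURE_BAND",
    "HIGH_FEATURE_BAND",
]

LOW_FEATURE_BAND = (500.0, 600.0)
HIGH_FEATURE_BAND = (3000.0, 3500.0)
#: snippet half-width around a trigger, seconds
HALF_WINDOW_S = 25e-3
#: lower edge of the multiunit band used for triggering, Hz
MUA_LO_HZ = 300.0


@dataclasses.dataclass(frozen=True)
class PutativeSpike:
    """A +/-25 ms segment around a BLP trigger with its feature pair."""

    snippet: np.ndarray
    trigger_time: float
    fs: float
    features: tuple[float, float] | None = None
    true_label: str | None = None


@dataclasses.dataclass
class CellSnippets:
    """All labelled putative spikes of one cell plus its missed spikes."""

    cell_id: int
    label: str  # "MSN" or "FSI"
    features: np.ndarray  # (n_snippets, 2)
    n_misses: int = 0


@dataclasses.dataclass
class ClassifierReport:
    """Held-out single-trial accuracy, per cell and per class."""

    per_cell: pd.DataFrame  # cell_id, true_type, n_snippets, n_misses, accuracy
    class_accuracy: dict[str, float]  # per-cell-averaged, then per class
    snippet_accuracy: dict[str, float]  # pooled per-snippet (secondary)
    w: np.ndarray
    b: float


class SpectralSpikeClassifier(ClassifierMixin, BaseEstimator):
    """Linear soft-margin SVM on (low, high) spectral features.

    Features are standardised to the training set before fitting; the
    decision rule is sign(<w, x> + b) in the standardised space.

    Parameters
    ----------
    C : soft-margin constant of the linear SVM.

    Attributes
    ----------
    w_ : weight vector over the (standardised) features.
    b_ : offset of the separating hyperplane.
    support_vectors_ : training points on or inside the margin.
    classes_ : label vocabulary in sklearn order.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        if np.unique(y).size < 2:
            raise ValueError("training set must contain both classes")
        self._pipeline = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", C=self.C)),
        ])
        self._pipeline.fit(X, y)
        svm: SVC = self._pipeline.named_steps["svm"]
        self.classes_ = svm.classes_
        self.w_ = svm.coef_.ravel().copy()
        self.b_ = float(svm.intercept_[0])
        self.support_vectors_ = svm.support_vectors_.copy()
        return self

    def decision_function(self, X):
        check_is_fitted(self, "w_")
        return self._pipeline.decision_function(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "w_")
        return self._pipeline.predict(np.asarray(X, dtype=float))


def extract_putative_spikes(trace: np.ndarray, fs: float,
                            mua_lo_hz: float = MUA_LO_HZ,
                            threshold_sd: float = 1.0,
                            half_window_s: float = HALF_WINDOW_S
                            ) -> list[PutativeSpike]:
    """Trigger on local maxima of z-scored multiunit (>300 Hz) BLP.

    Triggers closer than one half-window are merged to the larger peak
    (``find_peaks`` distance constraint); snippets are zero-padded when
    a trigger sits within a half-window of the trace edge.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < int(0.1 * fs):
        raise ValueError("trace must be at least 100 ms long")
    blp = band_limited_power(x, (mua_lo_hz, fs / 2.0), fs)
    if np.std(blp.values) == 0:  # featureless trace: nothing to trigger on
        return []
    z = zscore(blp.values)
    half = int(round(half_window_s * fs))
    peaks, _ = _signal.find_peaks(z, height=threshold_sd, distance=half)
    out = []
    for p in peaks:
        lo, hi = p - half, p + half + 1
        snippet = np.zeros(2 * half + 1)
        src_lo, src_hi = max(0, lo), min(x.size, hi)
        snippet[src_lo - lo:src_hi - lo] = x[src_lo:src_hi]
        out.append(PutativeSpike(snippet, p / fs, fs))
    return out


def spike_features(p: PutativeSpike) -> tuple[float, float]:
    """(low 500-600 Hz, high 3000-3500 Hz) integrated normalised power.

    Invariant to amplitude scaling of the snippet (area normalisation).
    """
    decomp = normalized_power_spectrum(p.snippet, p.fs)
    return (band_mass(decomp, *LOW_FEATURE_BAND),
            band_mass(decomp, *HIGH_FEATURE_BAND))


def train_and_classify(cells: Sequence[CellSnippets], train_fraction: float = 0.25,
                       seed: int | np.random.Generator = 0, C: float = 1.0
                       ) -> ClassifierReport:
    """Cell-held-out evaluation of the spectral spike classifier.

    ``train_fraction`` of the cells of each class (at least one) is
    selected at random for training; snippets of the remaining cells are
    classified.  Accuracy is computed per cell - with misses counted as
    errors - then averaged within each class.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, c in enumerate(cells):
        by_class.setdefault(c.label, []).append(i)
    if len(by_class) < 2 or any(len(v) < 2 for v in by_class.values()):
        raise ValueError("need >= 2 cells per class")

    train_idx: list[int] = []
    for label, idxs in sorted(by_class.items()):
        k = max(1, int(round(train_fraction * len(idxs))))
        k = min(k, len(idxs) - 1)  # keep at least one test cell per class
        train_idx.extend(rng.choice(idxs, size=k, replace=False))
    train_set = set(train_idx)

    X_train = np.vstack([cells[i].features for i in train_idx])
    y_train = np.concatenate([[cells[i].label] * len(cells[i].features)
                              for i in train_idx])
    clf = SpectralSpikeClassifier(C=C).fit(X_train, y_train)

    rows = []
    pooled: dict[str, list[int]] = {}
    for i, c in enumerate(cells):
        if i in train_set:
            continue
        pred = clf.predict(c.features) if len(c.features) else np.array([])
        n_correct = int((pred == c.label).sum())
        n_total = len(c.features) + c.n_misses
        acc = n_correct / n_total if n_total else float("nan")
        rows.append({"cell_id": c.cell_id, "true_type": c.label,
                     "n_snippets": len(c.features), "n_misses": c.n_misses,
                     "accuracy": acc})
        pooled.setdefault(c.label, []).append((n_correct, n_total))
    per_cell = pd.DataFrame(rows)
    class_acc = per_cell.groupby("true_type")["accuracy"].mean().to_dict()
    snippet_acc = {lbl: sum(c for c, _ in v) / sum(t for _, t in v)
                   for lbl, v in pooled.items()}
    return ClassifierReport(per_cell, class_acc, snippet_acc, clf.w_, clf.b_)
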