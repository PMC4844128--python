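"""End-to-end experiment runner: configuration, staging, file I/O, manifest.

A run sweeps responsive fractions x seeds through the full chain

    waveform library -> population -> depth calibration ->
    spike trains -> trace rendering -> noise -> band-limited power ->
    pattern decoding + continuous prediction,

writing per-run and seed-averaged CSV tables plus a JSON manifest with
config hash, seeds, stage timings and a checksum of every output file.
All randomness flows from one root seed through named substreams
(library, population, calibration, and per-(fraction, seed) trains /
noise), so re-running an identical config reproduces identical tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import popdecode, popsim, spectral, waveforms
from .popdecode import (HIGH_MUA_BAND, LOW_MUA_BAND, MuaRatePredictor,
                        actual_pattern, bin_blp, classify_pattern,
                        modulation_bin_mask, pattern_accuracy, percent_error,
                        rest_statistics)
from .popsim import (ModulationSchedule, NoiseModel, add_noise, binned_rates,
                     calibrate_depth, default_schedule, render_trace,
                     simulate_spike_trains)
from .waveforms import PopulationConfig, default_waveform_library, sample_population

__all__ = ["ConfigError", "RunManifest", "validate_config", "run_experiment",
           "decode_run", "DEFAULTS", "save_trace", "load_trace"]

logger = logging.getLogger("muadecode")


class ConfigError(ValueError):
    pass


#: full study-condition defaults; an empty config runs the printed paradigm
DEFAULTS: dict[str, Any] = {
    "population": {
        "n_cells": 20_000,
        "msn_fraction": 0.95,
        "msn_rate_mean": 2.4,
        "msn_rate_sd": 3.6,
        "fsi_rate_mean": 16.1,
        "fsi_rate_sd": 10.2,
    },
    "waveforms": {"n_msn": 40, "n_fsi": 25},
    "fs": 20_000.0,
    "duration": 50.0,
    "sine_freq": 0.5,
    "responsive_fractions": [0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
    "depths": "calibrate",  # or {"msn": d, "fsi": d}
    "noise": {"rms_ratio": 0.5, "line_fraction": 0.998, "line_freq": 60.0},
    "bands": {"low": list(LOW_MUA_BAND), "high": list(HIGH_MUA_BAND)},
    "threshold_sd": 2.0,
    "n_seeds": 5,
}

_KNOWN_KEYS = set(DEFAULTS)


def validate_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    """Fill defaults, normalise units, reject unknown or out-of-range keys."""
    config = dict(config or {})
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    out = json.loads(json.dumps(DEFAULTS))  # deep copy
    for key, value in config.items():
        if isinstance(out.get(key), dict) and isinstance(value, Mapping):
            bad = set(value) - set(out[key])
            if bad:
                raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
            out[key].update(value)
        else:
            out[key] = value

    pop = out["population"]
    if not 0.0 <= pop["msn_fraction"] <= 1.0:
        raise ConfigError("population.msn_fraction must lie in [0, 1]")
    if pop["n_cells"] <= 0:
        raise ConfigError("population.n_cells must be positive")
    if out["duration"] <= 0:
        raise ConfigError("duration must be positive")
    for f in out["responsive_fractions"]:
        if not 0.0 <= f <= 1.0:
            raise ConfigError(f"responsive fraction {f} outside [0, 1]")
    if out["n_seeds"] < 1:
        raise ConfigError("n_seeds must be >= 1")
    for name in ("low", "high"):
        lo, hi = out["bands"][name]
        if not 0 < lo < hi <= out["fs"] / 2:
            raise ConfigError(f"band {name!r} outside (0, Nyquist]")
    return out


def config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Provenance of one experiment run."""

    config: dict[str, Any]
    config_hash: str
    root_seed: int
    depths: dict[str, float]
    timings_s: dict[str, float]
    outputs: dict[str, str]  # relative path -> sha256
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_trace(trace: popsim.Trace, path: str | Path) -> None:
    """Raw little-endian float32 components + JSON sidecar."""
    path = Path(path)
    data = np.stack([trace.msn, trace.fsi, trace.noise]).astype("<f4")
    data.tofile(path)
    sidecar = {"fs": trace.fs, "n_samples": trace.n_samples,
               "components": ["msn", "fsi", "noise"], "dtype": "<f4",
               "layout": "component-major"}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_trace(path: str | Path) -> popsim.Trace:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    raw = np.fromfile(path, dtype="<f4").reshape(3, meta["n_samples"])
    return popsim.Trace(meta["fs"], *(raw.astype(float)))


def seed_streams(root_seed: int) -> dict[str, np.random.SeedSequence]:
    """Named, independent substreams derived from one root seed."""
    names = ["library", "population", "calibration", "trains", "noise", "split"]
    children = np.random.SeedSequence(root_seed).spawn(len(names))
    return dict(zip(names, children))


def _sub_seed(ss: np.random.SeedSequence, *keys: int) -> int:
    # stable small integer seed for a keyed substream
    child = np.random.SeedSequence(entropy=ss.entropy,
                                   spawn_key=tuple(ss.spawn_key) + tuple(keys))
    return int(child.generate_state(1)[0] % (2 ** 31))


def decode_run(trace: popsim.Trace, rates: popsim.BinnedRates,
               sched: ModulationSchedule, bands: Mapping[str, Iterable[float]],
               threshold_sd: float = 2.0) -> dict[str, Any]:
    """All decoding analyses for one simulated run.

    Returns a dict with pattern reports (8-way and both 2-way modes,
    using the +/-2 SD state rule), continuous predictions, per-bin
    correlations, and the percent-error arrays needed for surfaces.
    """
    low_band = tuple(bands["low"])
    high_band = tuple(bands["high"])
    total = trace.total
    low = bin_blp(spectral.band_limited_power(total, low_band, trace.fs))
    high = bin_blp(spectral.band_limited_power(total, high_band, trace.fs))
    rest_win = sched.rest_window()
    rest = rest_statistics(rates, {"low": low, "high": high},
                           (rest_win.t_start, rest_win.t_end))
    actual = actual_pattern(rates, rest, threshold_sd)
    predicted = classify_pattern(low, high, rest, threshold_sd)
    mod = modulation_bin_mask(sched, rates.n_bins)

    report_8 = pattern_accuracy(predicted, actual, "8-way", mod)
    report_2m = pattern_accuracy(predicted, actual, "2-way-MSN", mod)
    report_2f = pattern_accuracy(predicted, actual, "2-way-FSI", mod)

    lo_bins = int(round(rest_win.t_start / rates.bin_s))
    hi_bins = int(round(rest_win.t_end / rates.bin_s))
    rest_sl = slice(lo_bins, hi_bins)
    pred_msn = MuaRatePredictor().fit(low[rest_sl], rates.msn[rest_sl]).predict(low)
    pred_fsi = MuaRatePredictor().fit(high[rest_sl], rates.fsi[rest_sl]).predict(high)

    def _r(pred, act):
        if np.std(act[mod]) == 0 or np.std(pred[mod]) == 0:
            return float("nan")
        return float(np.corrcoef(pred[mod], act[mod])[0, 1])

    return {
        "rest": rest,
        "rates": rates,
        "low_bins": low,
        "high_bins": high,
        "actual": actual,
        "predicted": predicted,
        "mod_mask": mod,
        "8-way": report_8,
        "2-way-MSN": report_2m,
        "2-way-FSI": report_2f,
        "pred_rate_msn": pred_msn,
        "pred_rate_fsi": pred_fsi,
        "r_msn": _r(pred_msn, rates.msn),
        "r_fsi": _r(pred_fsi, rates.fsi),
        "pct_err_msn": percent_error(pred_msn[mod], rates.msn[mod]),
        "pct_err_fsi": percent_error(pred_fsi[mod], rates.fsi[mod]),
        "rates_msn_mod": rates.msn[mod],
        "rates_fsi_mod": rates.fsi[mod],
    }


def simulate_one(population: waveforms.Population, sched: ModulationSchedule,
                 noise: NoiseModel, train_seed: int, noise_seed: int
                 ) -> tuple[popsim.Trace, popsim.BinnedRates]:
    """One forward simulation: trains -> rates -> rendered noisy trace."""
    trains = simulate_spike_trains(population, sched, train_seed)
    rates = binned_rates(trains)
    trace = render_trace(trains)
    trace = add_noise(trace, noise, noise_seed)
    return trace, rates


def run_experiment(config: Mapping[str, Any] | None, outdir: str | Path,
                   root_seed: int = 0, save_traces: bool = False) -> RunManifest:
    """Execute the full sweep and write all tables under ``outdir``.

    Writes per-(fraction, seed) accuracy/correlation rows
    (``accuracy.csv``), seed-averaged summaries with between-seed SD
    (``summary.csv``), error-surface tables (``error_surface.csv``),
    the waveform library, population and depths, and ``manifest.json``.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = seed_streams(root_seed)
    timings: dict[str, float] = {}
    t_start = time.time()

    t0 = time.time()
    lib = default_waveform_library(_sub_seed(streams["library"]),
                                   n_msn=cfg["waveforms"]["n_msn"],
                                   n_fsi=cfg["waveforms"]["n_fsi"],
                                   fs=cfg["fs"])
    pop_cfg = PopulationConfig(seed=_sub_seed(streams["population"]),
                               **cfg["population"])
    population = sample_population(pop_cfg, lib)
    waveforms.save_library(lib, outdir / "waveform_library.csv",
                           {"root_seed": root_seed, **cfg["waveforms"]})
    waveforms.save_population(population, outdir / "population.csv")
    timings["synthwave"] = time.time() - t0

    t0 = time.time()
    base_sched = default_schedule()
    base_sched = dataclasses.replace(base_sched, sine_freq=cfg["sine_freq"])
    if cfg["depths"] == "calibrate":
        cal_seeds = [_sub_seed(streams["calibration"], k)
                     for k in range(cfg["n_seeds"])]
        depth_msn, depth_fsi = calibrate_depth(population, base_sched,
                                               seeds=cal_seeds)
    else:
        depth_msn, depth_fsi = cfg["depths"]["msn"], cfg["depths"]["fsi"]
    sched0 = base_sched.with_depths(depth_msn, depth_fsi)
    timings["calibrate"] = time.time() - t0
    logger.info("calibrated depths: MSN %.2f FSI %.2f", depth_msn, depth_fsi)

    noise = NoiseModel(**cfg["noise"])
    acc_rows, surf_runs = [], {"MSN": [], "FSI": []}
    for fraction in cfg["responsive_fractions"]:
        sched = sched0.with_fraction(fraction)
        for k in range(cfg["n_seeds"]):
            t0 = time.time()
            trace, rates = simulate_one(
                population, sched, noise,
                _sub_seed(streams["trains"], int(fraction * 100), k),
                _sub_seed(streams["noise"], int(fraction * 100), k))
            if save_traces:
                save_trace(trace, outdir / f"trace_f{fraction:.1f}_s{k}.f32")
            dec = decode_run(trace, rates, sched, cfg["bands"],
                             cfg["threshold_sd"])
            row = {"fraction": fraction, "seed": k,
                   "acc_8way": dec["8-way"].overall,
                   "acc_2way_msn": dec["2-way-MSN"].overall,
                   "acc_2way_fsi": dec["2-way-FSI"].overall,
                   "acc_upup": dec["8-way"].per_class.get((1, 1), np.nan),
                   "r_msn": dec["r_msn"], "r_fsi": dec["r_fsi"]}
            acc_rows.append(row)
            surf_runs["MSN"].append((fraction, dec["pred_rate_msn"][dec["mod_mask"]],
                                     dec["rates_msn_mod"]))
            surf_runs["FSI"].append((fraction, dec["pred_rate_fsi"][dec["mod_mask"]],
                                     dec["rates_fsi_mod"]))
            logger.info("fraction %.1f seed %d done in %.1fs",
                        fraction, k, time.time() - t0)
    timings["simulate+decode"] = time.time() - t_start - sum(timings.values())

    accuracy = pd.DataFrame(acc_rows)
    accuracy.to_csv(outdir / "accuracy.csv", index=False)
    summary = accuracy.drop(columns="seed").groupby("fraction").agg(["mean", "std"])
    summary.columns = ["_".join(c) for c in summary.columns]
    summary.reset_index().to_csv(outdir / "summary.csv", index=False)

    if len(cfg["responsive_fractions"]) >= 2:
        surf = pd.concat([popdecode.error_surface(surf_runs[t], t)
                          for t in ("MSN", "FSI")])
        surf.to_csv(outdir / "error_surface.csv", index=False)

    pd.DataFrame([{"depth_msn": depth_msn, "depth_fsi": depth_fsi}]).to_csv(
        outdir / "depths.csv", index=False)

    outputs = {p.name: _checksum(p) for p in sorted(outdir.iterdir())
               if p.is_file() and p.name != "manifest.json"}
    manifest = RunManifest(cfg, config_hash(cfg), root_seed,
                           {"MSN": depth_msn, "FSI": depth_fsi},
                           {k: round(v, 2) for k, v in timings.items()}, outputs)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def load_config_file(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})
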