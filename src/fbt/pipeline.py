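"""End-to-end synthetic demo pipeline.

``run_pipeline`` wires the generators and analyses together into a
reproducible run: a simulated cohort is generated from the seed, each
analysis stage is executed in dependency order, and all outputs (CSV/JSON)
plus a manifest with a config echo, the seed, package version, per-stage
record counts and content checksums are written to the output directory.
A rerun with the same config and seed reproduces every file byte for byte.

The default cohort mirrors the shape of a chronic bilateral-implantation
study: sixteen ear-canal "animals" and three jacket-pocket measurements for
the cue stage, four animals' worth of ECAP sessions and impedance logs,
and head-versus-jacket orienting trials.
"""

from __future__ import annotations

import copy
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import __version__
from .acoustics import (
    BinauralRecording,
    CueCurve,
    ImpulseResponsePair,
    MicSite,
    align_zero_crossing,
    build_cue_curve,
    estimate_impulse_response,
    generate_golay_pair,
    rms_level_db,
    summarize_ranges,
)
from .ecap import (
    ThresholdSeries,
    fit_threshold,
    growth_function_from_frames,
    threshold_stability,
)
from .impedance import epoch_summary, functional_fraction, per_position_profile
from .io import cue_curve_to_table, sha256_of, write_json, write_table
from .orienting import analyze_trajectory, compare_conditions
from .synth import (
    EcapSimConfig,
    HeadModel,
    ImpedanceSimConfig,
    PlantedFailure,
    TrajectorySimConfig,
    simulate_ecap_session,
    simulate_head_ir,
    simulate_impedance_log,
    simulate_trajectory,
)

_WOODWORTH_MAX = 1.0 + math.pi / 2.0
_SPEED_OF_SOUND = 343.0

DEFAULT_CONFIG: dict[str, Any] = {
    "stages": ["cues", "ecap", "impedance", "orienting", "noise"],
    "cues": {
        "n_ear_canal": 16,
        "n_jacket": 3,
        "angles": list(range(-150, 151, 10)),
        "fs_hz": 80000.0,
        "n_taps": 512,
        "golay_order": 9,
        "measure_via_golay": True,
        # cohort calibration: [min, median, max] of per-animal cue
        # half-ranges; sampled from a triangular law matching the median
        "itd_half_range_us": [169.0, 190.0, 254.0],
        "jacket_itd_half_range_us": [163.0, 169.0, 174.0],
        "ild_low_db": [3.5, 4.3, 6.4],
        "ild_high_db": [9.0, 10.9, 15.9],
        "jacket_ild_low_db": [3.8, 4.2, 4.6],
        "jacket_ild_high_db": [9.2, 9.8, 10.4],
        "bands": [[750.0, 1500.0], [4000.0, 8000.0]],
    },
    "ecap": {
        "electrodes": ["AE1", "AE2", "AE3", "AE4", "AE5", "AE6", "AE7"],
        "ears": ["left", "right"],
        "days": list(range(0, 85, 7)),
        "base_threshold": 100.0,
        "electrode_threshold_offset": {"AE6": 8.0, "AE7": 12.0},
        "growth_slope": 20.0,
        "noise_sd_uv": 10.0,
        "levels_above_threshold": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0],
        "noise_floor_uv": 30.0,
    },
    "impedance": {
        "animals": ["F1", "F2", "F3", "F4"],
        "n_days": 90,
        "baseline_kohm": 1.9,
        "plateau_kohm": 8.5,
        "noise_sd_kohm": 0.25,
        "electrode_offset_kohm": {
            "AE1": 1.2, "AE2": 0.6, "AE3": 0.2, "AE4": -0.3,
            "AE5": -0.9, "AE6": -0.5, "AE7": 0.3, "EC": 0.0,
        },
        # six open-circuit failures from day 43 in the last two animals
        "open_failures": [
            ["F3", "left", "AE2", 43],
            ["F3", "right", "AE6", 43],
            ["F4", "left", "AE1", 43],
            ["F4", "left", "AE7", 43],
            ["F4", "right", "AE3", 43],
            ["F4", "right", "AE5", 43],
        ],
        "early_epoch_days": [0, 4],
        "late_epoch_days": [16, 20],
    },
    "orienting": {
        "n_trials": 20,
        "head_latency_ms": 180.0,
        "jacket_latency_ms": 297.0,
        "head_bearing_deg": 42.96,
        "jacket_bearing_deg": 41.69,
        "latency_jitter_ms": 20.0,
        "bearing_jitter_deg": 3.0,
        "tracker_noise_deg": 0.3,
        "move_threshold_deg": 1.0,
    },
    "noise": {
        "ambient_db_spl": 33.6,
        "ambient_jitter_db": 0.5,
        "animal_db_spl": 43.6,
        "animal_jitter_db": 3.9,
        "n_measurements": 10,
        "n_samples": 16000,
    },
}


def default_config() -> dict[str, Any]:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _sample_span(rng: np.random.Generator, span) -> float:
    """Draw from a triangular law over [min, max] whose median matches the
    configured value (real cohorts are skewed toward small heads)."""
    lo, med, hi = map(float, span)
    if not lo <= med <= hi:
        raise ValueError(f"span must be [min, median, max], got {span}")
    if lo == hi:
        return lo
    if med <= (lo + hi) / 2.0:
        mode = lo + 2.0 * (med - lo) ** 2 / (hi - lo)
    else:
        mode = hi - 2.0 * (hi - med) ** 2 / (hi - lo)
    return float(rng.triangular(lo, mode, hi))


def _radius_for_half_range(half_range_us: float) -> float:
    """Effective head radius whose Woodworth ITD peaks at the given half-range."""
    return half_range_us * 1e-6 * _SPEED_OF_SOUND / _WOODWORTH_MAX


def _measure_curve_via_golay(
    model: HeadModel, angles: list[float], fs: float, n_taps: int,
    order: int, bands: list[tuple[float, float]],
) -> CueCurve:
    """Full measurement chain: play both Golay codes through the simulated
    head, deconvolve, then extract cues from the recovered IRs."""
    pair = generate_golay_pair(order)
    irs = []
    for angle in angles:
        true_ir = simulate_head_ir(model, angle, fs=fs, n_taps=n_taps)
        rec = {}
        for code_name, code in (("a", pair.code_a), ("b", pair.code_b)):
            rec[code_name] = BinauralRecording(
                left=np.convolve(code, true_ir.left_ir),
                right=np.convolve(code, true_ir.right_ir),
                fs=fs,
                source_angle=angle,
                mic_site=model.mic_site,
            )
        irs.append(estimate_impulse_response(rec["a"], rec["b"], pair))
    return build_cue_curve(irs, bands=bands)


def _direct_curve(
    model: HeadModel, angles: list[float], fs: float, n_taps: int,
    bands: list[tuple[float, float]],
) -> CueCurve:
    irs = [simulate_head_ir(model, a, fs=fs, n_taps=n_taps) for a in angles]
    return build_cue_curve(irs, bands=bands)


def _stage_cues(cfg: dict, rng: np.random.Generator, out: Path) -> tuple[dict, list[Path]]:
    bands = [tuple(map(float, b)) for b in cfg["bands"]]
    angles = [float(a) for a in cfg["angles"]]
    low_band, high_band = bands[0], bands[1]

    def _cohort(n: int, hr_span, low_span, high_span, site: MicSite) -> list[CueCurve]:
        curves = []
        for _ in range(n):
            hr = _sample_span(rng, hr_span)
            model = HeadModel(
                effective_radius=_radius_for_half_range(hr),
                mic_site=site,
                shadow_strength={
                    low_band: _sample_span(rng, low_span),
                    high_band: _sample_span(rng, high_span),
                },
            )
            if cfg["measure_via_golay"]:
                curves.append(
                    _measure_curve_via_golay(
                        model, angles, cfg["fs_hz"], cfg["n_taps"],
                        cfg["golay_order"], bands,
                    )
                )
            else:
                curves.append(_direct_curve(model, angles, cfg["fs_hz"], cfg["n_taps"], bands))
        return curves

    ear_curves = _cohort(
        cfg["n_ear_canal"], cfg["itd_half_range_us"],
        cfg["ild_low_db"], cfg["ild_high_db"], MicSite.EAR_CANAL,
    )
    jacket_curves = _cohort(
        cfg["n_jacket"], cfg["jacket_itd_half_range_us"],
        cfg["jacket_ild_low_db"], cfg["jacket_ild_high_db"], MicSite.JACKET_POCKET,
    )

    files = []
    tables = []
    for label, curves in (("ear_canal", ear_curves), ("jacket", jacket_curves)):
        for i, c in enumerate(curves):
            t = cue_curve_to_table(c)
            t.insert(0, "curve", f"{label}_{i:02d}")
            tables.append(t)
    files.append(write_table(pd.concat(tables, ignore_index=True), out / "cue_curves.csv"))

    def _summary(curves: list[CueCurve]) -> dict:
        itd = summarize_ranges(curves, "itd")
        low = summarize_ranges(curves, "ild", low_band)
        high = summarize_ranges(curves, "ild", high_band)
        return {
            "itd_half_range_us": {"min": itd.min, "median": itd.median, "max": itd.max},
            "ild_low_half_range_db": {"min": low.min, "median": low.median, "max": low.max},
            "ild_high_half_range_db": {"min": high.min, "median": high.median, "max": high.max},
            "n_curves": len(curves),
        }

    aligned = [align_zero_crossing(c, "itd") for c in ear_curves]
    f0_abs = [float(np.interp(0.0, c.angles, c.itd_us, left=np.nan, right=np.nan)) for c in aligned]
    summary = {
        "ear_canal": _summary(ear_curves),
        "jacket": _summary(jacket_curves),
        "aligned_itd_at_zero_us": {
            "max_abs": float(np.nanmax(np.abs(f0_abs))),
        },
        "n_records": int(sum(len(c.angles) for c in ear_curves + jacket_curves)),
    }
    files.append(write_json(summary, out / "cues_summary.json"))
    return summary, files


def _stage_ecap(cfg: dict, rng: np.random.Generator, out: Path) -> tuple[dict, list[Path]]:
    series = ThresholdSeries()
    rows = []
    errors = []
    for electrode in cfg["electrodes"]:
        true_thr = cfg["base_threshold"] + cfg["electrode_threshold_offset"].get(electrode, 0.0)
        for ear in cfg["ears"]:
            for day in cfg["days"]:
                sim = EcapSimConfig(
                    threshold_level=true_thr,
                    growth_slope=cfg["growth_slope"],
                    noise_sd=cfg["noise_sd_uv"],
                    levels=tuple(true_thr + d for d in cfg["levels_above_threshold"]),
                    seed=int(rng.integers(2**31)),
                )
                frames = simulate_ecap_session(sim)
                for fr in frames:
                    fr.electrode, fr.ear, fr.day = electrode, ear, int(day)
                gf = growth_function_from_frames(frames)
                est = fit_threshold(gf, noise_floor_uv=cfg["noise_floor_uv"])
                series.add(electrode, ear, day, est.threshold)
                errors.append(abs(est.threshold - true_thr))
                rows.append(
                    (electrode, ear, int(day), est.threshold, est.slope,
                     est.n_used, est.excluded, true_thr)
                )
    thr_table = pd.DataFrame(
        rows,
        columns=["electrode", "ear", "day", "threshold", "slope",
                 "n_used", "excluded", "true_threshold"],
    )
    stab = threshold_stability(series)
    files = [write_table(thr_table, out / "ecap_thresholds.csv")]
    summary = {
        "median_abs_threshold_error": float(np.median(errors)),
        "mean_slope_per_day": stab.mean_slope,
        "slope_range_per_day": [min(stab.slopes.values()), max(stab.slopes.values())],
        "t_statistic": stab.t_statistic,
        "p_value": stab.p_value,
        "n_records": len(rows),
    }
    files.append(write_json(summary, out / "ecap_stability.json"))
    return summary, files


def _stage_impedance(cfg: dict, rng: np.random.Generator, out: Path) -> tuple[dict, list[Path]]:
    failures = tuple(
        PlantedFailure(electrode=e, day=int(d), kind="open", animal=a, ear=ear)
        for a, ear, e, d in cfg["open_failures"]
    )
    sim = ImpedanceSimConfig(
        baseline_kohm=cfg["baseline_kohm"],
        plateau_kohm=cfg["plateau_kohm"],
        noise_sd=cfg["noise_sd_kohm"],
        animals=tuple(cfg["animals"]),
        electrode_offset_kohm=dict(cfg["electrode_offset_kohm"]),
        planted_failures=failures,
        seed=int(rng.integers(2**31)),
    )
    log = simulate_impedance_log(sim, n_days=cfg["n_days"])
    files = [write_table(log, out / "impedance_log.csv")]

    early = epoch_summary(log, tuple(cfg["early_epoch_days"]), mode="CG")
    late = epoch_summary(log, tuple(cfg["late_epoch_days"]), mode="CG")
    frac = functional_fraction(log)
    profile = per_position_profile(log, mode="CG")
    files.append(write_table(profile.reset_index(), out / "impedance_profile.csv"))
    summary = {
        "early_epoch": {"mean_kohm": early.mean_kohm, "sd_kohm": early.sd_kohm, "n": early.n},
        "late_epoch": {"mean_kohm": late.mean_kohm, "sd_kohm": late.sd_kohm, "n": late.n},
        "functional": frac,
        "n_records": int(len(log)),
    }
    files.append(write_json(summary, out / "impedance_summary.json"))
    return summary, files


def _stage_orienting(cfg: dict, rng: np.random.Generator, out: Path) -> tuple[dict, list[Path]]:
    def _trials(latency_ms: float, bearing_deg: float) -> list:
        results = []
        for _ in range(cfg["n_trials"]):
            lat = max(latency_ms + rng.normal(0.0, cfg["latency_jitter_ms"]), 70.0)
            bearing = bearing_deg + rng.normal(0.0, cfg["bearing_jitter_deg"])
            sim = TrajectorySimConfig(
                latency_ms=float(lat),
                final_bearing_deg=float(bearing),
                tracker_noise_deg=cfg["tracker_noise_deg"],
                seed=int(rng.integers(2**31)),
            )
            traj = simulate_trajectory(sim)
            results.append(analyze_trajectory(traj, cfg["move_threshold_deg"]))
        return results

    head = _trials(cfg["head_latency_ms"], cfg["head_bearing_deg"])
    jacket = _trials(cfg["jacket_latency_ms"], cfg["jacket_bearing_deg"])
    lat_diff, bearing_diff = compare_conditions(head, jacket)

    rows = [
        (cond, i, r.latency_ms, r.final_bearing_deg, r.direction)
        for cond, results in (("head", head), ("jacket", jacket))
        for i, r in enumerate(results)
    ]
    table = pd.DataFrame(
        rows, columns=["condition", "trial", "latency_ms", "final_bearing_deg", "direction"]
    )
    files = [write_table(table, out / "orienting_results.csv")]

    def _mean_bearing(results: list) -> float:
        return float(np.mean([r.final_bearing_deg for r in results]))

    def _mean_latency(results: list) -> float:
        return float(np.mean([r.latency_ms for r in results if r.latency_ms is not None]))

    summary = {
        "head_mean_latency_ms": _mean_latency(head),
        "jacket_mean_latency_ms": _mean_latency(jacket),
        "latency_difference_ms": lat_diff,
        "head_mean_bearing_deg": _mean_bearing(head),
        "jacket_mean_bearing_deg": _mean_bearing(jacket),
        "bearing_difference_deg": bearing_diff,
        "n_records": len(rows),
    }
    files.append(write_json(summary, out / "orienting_summary.json"))
    return summary, files


def _stage_noise(cfg: dict, rng: np.random.Generator, out: Path) -> tuple[dict, list[Path]]:
    p_ref = 20e-6

    def _levels(target_db: float, jitter_db: float) -> list[float]:
        levels = []
        for _ in range(cfg["n_measurements"]):
            db = target_db + rng.normal(0.0, jitter_db)
            x = rng.normal(0.0, 1.0, cfg["n_samples"])
            x *= p_ref * 10.0 ** (db / 20.0) / np.sqrt(np.mean(x**2))
            levels.append(rms_level_db(x, reference=p_ref))
        return levels

    ambient = _levels(cfg["ambient_db_spl"], cfg["ambient_jitter_db"])
    animal = _levels(cfg["animal_db_spl"], cfg["animal_jitter_db"])
    summary = {
        "ambient_mean_db_spl": float(np.mean(ambient)),
        "ambient_sd_db": float(np.std(ambient, ddof=1)),
        "animal_mean_db_spl": float(np.mean(animal)),
        "animal_sd_db": float(np.std(animal, ddof=1)),
        "n_records": 2 * cfg["n_measurements"],
    }
    return summary, [write_json(summary, out / "noise_summary.json")]


_STAGES = {
    "cues": _stage_cues,
    "ecap": _stage_ecap,
    "impedance": _stage_impedance,
    "orienting": _stage_orienting,
    "noise": _stage_noise,
}


def run_pipeline(
    config: dict[str, Any] | None = None,
    seed: int = 0,
    out_dir: str | Path = "fbt_run",
) -> dict[str, Any]:
    """Execute the selected stages and write outputs plus a manifest.

    Each stage draws its randomness from a child generator spawned
    deterministically from ``seed``, so stages are independent of each
    other's record counts and a rerun is byte-identical.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {"seed": seed, "stages": {}}
    all_files: list[Path] = []
    for i, stage in enumerate(cfg["stages"]):
        if stage not in _STAGES:
            raise ValueError(f"unknown stage '{stage}'")
        stage_rng = np.random.default_rng([seed, i])
        try:
            summary, files = _STAGES[stage](cfg[stage], stage_rng, out)
        except (OSError, ValueError) as exc:
            raise type(exc)(f"stage '{stage}': {exc}") from exc
        report["stages"][stage] = summary
        all_files.extend(files)

    manifest = {
        "seed": seed,
        "version": __version__,
        "config": cfg,
        "stages": {s: {"n_records": report["stages"][s].get("n_records", 0)}
                   for s in cfg["stages"]},
        "files": {f.name: sha256_of(f) for f in sorted(all_files)},
    }
    write_json(manifest, out / "manifest.json")
    report["manifest"] = manifest
    return report
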