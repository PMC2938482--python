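"""Electrically evoked compound action potential (ECAP) analysis.

The ECAP is the synchronized auditory-nerve response to a biphasic current
pulse, recorded from an intracochlear electrode adjacent to the stimulating
one. The raw recording is dominated by stimulus artifact; the
forward-masking paradigm removes it by combining four frames recorded at
the same stimulus level:

* probe alone (artifact + neural response),
* masker + probe (the masker renders the nerve refractory, so the probe
  contributes artifact only),
* masker alone,
* no stimulus (amplifier baseline).

Under complete masking and additive artifacts the combination
``probe - (masker+probe - masker) - baseline`` cancels every artifact term
and leaves the probe-evoked neural response. Its P1-N1 amplitude grows
linearly with stimulus level above threshold; the ECAP threshold is the
zero crossing of a straight line fitted to the supra-noise-floor points of
that amplitude growth function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


class InsufficientDataError(ValueError):
    """Too few usable points for the requested fit."""


class NonGrowingFunctionError(ValueError):
    """The fitted amplitude growth function has non-positive slope."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EcapFrameSet:
    """The four forward-masking frames recorded at one stimulus level.

    All traces share a post-stimulus time base in microvolts sampled at
    ``fs``. ``stimulus_level`` is in abstract stimulus-level units (device
    current units or dB re an arbitrary reference - the analysis is
    agnostic; unit interpretation is metadata).
    """

    probe_alone: np.ndarray
    masker_probe: np.ndarray
    masker_alone: np.ndarray
    no_stimulus: np.ndarray
    fs: float
    stimulus_level: float
    electrode: str = "AE1"
    ear: str = "left"
    day: int = 0

    def __post_init__(self) -> None:
        traces = []
        for name in ("probe_alone", "masker_probe", "masker_alone", "no_stimulus"):
            t = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, t)
            traces.append(t)
        if len({t.shape for t in traces}) != 1:
            raise ValueError("the four frames must have equal length")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")


@dataclass
class EcapWaveform:
    """Artifact-free neural response, time origin at probe onset."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs * 1e3


@dataclass
class GrowthFunction:
    """P1-N1 amplitude versus stimulus level for one electrode/ear/day."""

    points: list[tuple[float, float]]  # (stimulus_level, p1n1_uv)
    electrode: str = "AE1"
    ear: str = "left"
    day: int = 0

    def __post_init__(self) -> None:
        levels = [p[0] for p in self.points]
        if len(set(levels)) != len(levels):
            raise ValueError("stimulus levels must be unique")
        if any(p[1] < 0 for p in self.points):
            raise ValueError("P1-N1 amplitudes must be non-negative")

    @property
    def levels(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass(frozen=True)
class ThresholdEstimate:
    """ECAP threshold from the extrapolated amplitude growth function."""

    threshold: float
    slope: float  # uV per stimulus-level unit
    intercept: float  # uV
    n_used: int
    excluded: int

    def __post_init__(self) -> None:
        if self.n_used < 2:
            raise ValueError("a valid estimate needs at least two points")
        if self.slope <= 0:
            raise ValueError("a valid estimate has positive slope")


@dataclass
class ThresholdSeries:
    """Longitudinal ECAP thresholds per (electrode, ear)."""

    series: dict[tuple[str, str], list[tuple[float, float]]] = field(default_factory=dict)
    # series[(electrode, ear)] = [(day, threshold), ...] sorted by day

    def add(self, electrode: str, ear: str, day: float, threshold: float) -> None:
        if day < 0:
            raise ValueError("post-operative day must be non-negative")
        key = (electrode, ear)
        self.series.setdefault(key, []).append((float(day), float(threshold)))
        self.series[key].sort(key=lambda p: p[0])


@dataclass(frozen=True)
class StabilityResult:
    """Per-electrode regression slopes and the slope-vs-zero t-test."""

    slopes: dict[tuple[str, str], float]
    mean_slope: float
    t_statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

#: Default extremum-search windows (ms post probe onset). The negative
#: trough N1 precedes the positive peak P1 in this recording convention;
#: both windows are configurable since latencies vary with electrode
#: geometry and level.
DEFAULT_N1_WINDOW_MS: tuple[float, float] = (0.1, 0.45)
DEFAULT_P1_WINDOW_MS: tuple[float, float] = (0.45, 1.0)

#: Amplitudes below this are treated as noise floor and excluded from
#: threshold fits.
DEFAULT_NOISE_FLOOR_UV: float = 30.0


def cancel_artifact(frames: EcapFrameSet) -> EcapWaveform:
    """Forward-masking artifact rejection.

    Returns ``probe_alone - (masker_probe - masker_alone) - no_stimulus``.
    Any artifact that is additive and identical across the frames in which
    the same stimulus appears cancels to machine precision, leaving the
    probe-evoked neural response.
    """
    response = (
        frames.probe_alone
        - (frames.masker_probe - frames.masker_alone)
        - frames.no_stimulus
    )
    return EcapWaveform(samples=response, fs=frames.fs)


def measure_p1n1(
    w: EcapWaveform,
    n1_window_ms: tuple[float, float] = DEFAULT_N1_WINDOW_MS,
    p1_window_ms: tuple[float, float] = DEFAULT_P1_WINDOW_MS,
) -> float:
    """P1-N1 amplitude in uV: max over the P1 window minus min over the N1
    window, clipped at zero (a flat trace measures 0, never negative)."""
    if n1_window_ms[0] >= p1_window_ms[0]:
        raise ValueError("the N1 window must precede the P1 window")
    t = w.t_ms

    def _slice(win: tuple[float, float]) -> np.ndarray:
        lo, hi = win
        if lo < 0 or hi > t[-1] or lo >= hi:
            raise ValueError(f"window {win} ms outside trace (0..{t[-1]:.3f} ms)")
        mask = (t >= lo) & (t <= hi)
        return w.samples[mask]

    n1 = np.min(_slice(n1_window_ms))
    p1 = np.max(_slice(p1_window_ms))
    return float(max(p1 - n1, 0.0))


def fit_threshold(
    gf: GrowthFunction,
    noise_floor_uv: float = DEFAULT_NOISE_FLOOR_UV,
) -> ThresholdEstimate:
    """ECAP threshold from the amplitude growth function.

    Points with P1-N1 amplitude strictly below ``noise_floor_uv`` are
    considered noise floor and excluded. An ordinary least-squares line is
    fitted to the retained points and the threshold is the stimulus level
    at its zero crossing, ``-intercept / slope``.
    """
    levels, amps = gf.levels, gf.amplitudes
    keep = amps >= noise_floor_uv
    excluded = int(np.sum(~keep))
    if np.sum(keep) < 2:
        raise InsufficientDataError(
            f"only {int(np.sum(keep))} point(s) at or above the "
            f"{noise_floor_uv} uV noise floor; need at least 2"
        )
    x, y = levels[keep], amps[keep]
    if np.ptp(x) == 0:
        raise InsufficientDataError("retained points share a single stimulus level")
    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise NonGrowingFunctionError(
            f"fitted growth slope {fit.slope:.3g} uV/unit is not positive"
        )
    return ThresholdEstimate(
        threshold=float(-fit.intercept / fit.slope),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_used=int(np.sum(keep)),
        excluded=excluded,
    )


def growth_function_from_frames(
    frame_sets: Sequence[EcapFrameSet],
    n1_window_ms: tuple[float, float] = DEFAULT_N1_WINDOW_MS,
    p1_window_ms: tuple[float, float] = DEFAULT_P1_WINDOW_MS,
) -> GrowthFunction:
    """Cancel artifacts and measure P1-N1 for a whole recording session."""
    if not frame_sets:
        raise ValueError("no frame sets given")
    points = []
    for fr in frame_sets:
        w = cancel_artifact(fr)
        points.append((fr.stimulus_level, measure_p1n1(w, n1_window_ms, p1_window_ms)))
    first = frame_sets[0]
    return GrowthFunction(
        points=points, electrode=first.electrode, ear=first.ear, day=first.day
    )


def threshold_stability(series: ThresholdSeries) -> StabilityResult:
    """Longitudinal stability of ECAP thresholds.

    Fits an OLS regression of threshold against post-operative day for each
    (electrode, ear) series and tests the collection of slopes against zero
    with a two-sided one-sample t-test. A non-significant result indicates
    thresholds remain constant over time.
    """
    slopes: dict[tuple[str, str], float] = {}
    for key, pts in series.series.items():
        if len(pts) < 2:
            raise InsufficientDataError(
                f"series {key} has {len(pts)} time point(s); need at least 2"
            )
        days = np.array([p[0] for p in pts])
        thr = np.array([p[1] for p in pts])
        if np.ptp(days) == 0:
            raise InsufficientDataError(f"series {key} has a single distinct day")
        slopes[key] = float(stats.linregress(days, thr).slope)
    vals = np.array(list(slopes.values()))
    if vals.size < 2:
        raise InsufficientDataError("need slopes from at least 2 series for the t-test")
    if np.allclose(vals, vals[0]):
        # identical slopes: zero variance; t undefined unless the mean is 0 too
        t_stat = 0.0 if np.isclose(vals[0], 0.0) else np.inf * np.sign(vals[0])
        p_val = 1.0 if np.isclose(vals[0], 0.0) else 0.0
    else:
        t_stat, p_val = stats.ttest_1samp(vals, 0.0)
    return StabilityResult(
        slopes=slopes,
        mean_slope=float(np.mean(vals)),
        t_statistic=float(t_stat),
        p_value=float(p_val),
    )
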