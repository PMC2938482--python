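"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure that the downstream
analyses assume, so the whole pipeline is testable without access to any
animal recordings:

* binaural impulse responses of a small-headed mammal, with a
  Woodworth-model ITD and a first-order per-band head-shadow ILD;
* ECAP forward-masking frame sets with a decaying stimulus artifact and a
  neural response whose P1-N1 amplitude grows linearly above threshold;
* longitudinal electrode-impedance logs that rise sigmoidally from a
  post-operative baseline to a plateau, with optional planted open/closed
  failures;
* sigmoidal head-orienting trajectories sampled at 60 frames/s.

Every generator is a pure function of its configuration and seed: the same
call reproduces bit-identical output. Head-model defaults are arbitrary
calibrations chosen to give cue ranges typical of a ferret-sized head, not
species constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .acoustics import ImpulseResponsePair, MicSite
from .ecap import EcapFrameSet
from .impedance import ELECTRODES, LOG_COLUMNS
from .orienting import Trajectory

import pandas as pd

__all__ = [
    "HeadModel",
    "EcapSimConfig",
    "ImpedanceSimConfig",
    "PlantedFailure",
    "TrajectorySimConfig",
    "woodworth_itd_us",
    "simulate_head_ir",
    "simulate_ecap_session",
    "simulate_impedance_log",
    "simulate_trajectory",
]


# ---------------------------------------------------------------------------
# binaural impulse responses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeadModel:
    """Spherical-head acoustic model for one microphone site.

    ``effective_radius`` sets the Woodworth ITD scale; ``shadow_strength``
    maps each frequency band to the peak ILD in dB reached at +-90 degrees
    (head shadow is stronger at high frequencies). The jacket-pocket site
    is modelled as a head with a slightly smaller effective radius and
    weaker shadow, constructed via :meth:`jacket`. ``head_orientation``
    rotates the head frame relative to the chamber frame, emulating an
    animal facing away from the 0 degree speaker.
    """

    effective_radius: float = 0.02535  # m; calibration, not a species constant
    speed_of_sound: float = 343.0  # m/s
    mic_site: MicSite = MicSite.EAR_CANAL
    shadow_strength: dict[tuple[float, float], float] = field(
        default_factory=lambda: {(750.0, 1500.0): 4.3, (4000.0, 8000.0): 10.9}
    )
    head_orientation: float = 0.0  # degrees

    def __post_init__(self) -> None:
        if self.effective_radius <= 0:
            raise ValueError("effective_radius must be positive")
        if self.speed_of_sound <= 0:
            raise ValueError("speed_of_sound must be positive")

    def jacket(
        self, radius_factor: float = 0.89, shadow_factor: float = 0.92
    ) -> "HeadModel":
        """Derived model for microphones in the jacket pockets.

        The pocket microphones sit slightly closer together than the ear
        canals and are less shadowed by the head, so both the effective
        radius and the per-band shadow strengths shrink by configurable
        factors.
        """
        return HeadModel(
            effective_radius=self.effective_radius * radius_factor,
            speed_of_sound=self.speed_of_sound,
            mic_site=MicSite.JACKET_POCKET,
            shadow_strength={
                b: s * shadow_factor for b, s in self.shadow_strength.items()
            },
            head_orientation=self.head_orientation,
        )


def _effective_angle_deg(angle_deg: float) -> float:
    """Fold an angle in (-180, 180] onto the frontal hemifield.

    Cues are maximal at +-90 degrees and fall back toward zero behind the
    head, mirroring the frontal dependence: angles beyond +-90 map to
    sign * (180 - |angle|).
    """
    a = float(-((-angle_deg + 180.0) % 360.0 - 180.0))  # wrap to (-180, 180]
    if abs(a) > 90.0:
        a = math.copysign(180.0 - abs(a), a)
    return a


def woodworth_itd_us(model: HeadModel, source_angle: float) -> float:
    """Woodworth spherical-head ITD in microseconds, positive to the right.

    ``(a/c) * (sin theta + theta)`` for the head-frame angle theta within
    +-90 degrees, mirrored beyond, which is frequency independent and peaks
    at ``(a/c)(1 + pi/2)`` for a source at +-90 degrees.
    """
    theta = math.radians(
        _effective_angle_deg(source_angle - model.head_orientation)
    )
    return model.effective_radius / model.speed_of_sound * (math.sin(theta) + theta) * 1e6


def _frac_delay_kernel(n_taps: int, delay: float) -> np.ndarray:
    """Band-limited (windowed-sinc) impulse at a fractional sample delay."""
    n = np.arange(n_taps)
    return np.sinc(n - delay) * np.blackman(n_taps)


def simulate_head_ir(
    model: HeadModel,
    source_angle: float,
    fs: float = 80000.0,
    n_taps: int = 512,
) -> ImpulseResponsePair:
    """Binaural impulse response for one source angle; deterministic.

    The left/right relative delay equals the Woodworth ITD of the
    head-frame angle; each shadow band contributes a band-passed impulse
    whose inter-channel gain is the band's ILD, ``shadow_strength *
    sin(theta)`` dB split symmetrically across the ears. Fractional-sample
    delays are realized by windowed-sinc interpolation so sub-sample ITDs
    are representable at 80 kHz.
    """
    if abs(source_angle) > 180.0:
        raise ValueError("|source_angle| must be <= 180 degrees")
    if fs <= 0:
        raise ValueError("sample rate must be positive")
    corners = [hi for (_, hi) in model.shadow_strength]
    if corners and fs <= 2.0 * max(corners):
        raise ValueError("fs must exceed twice the highest shadow-band corner")

    theta_deg = _effective_angle_deg(source_angle - model.head_orientation)
    itd_samples = (
        model.effective_radius
        / model.speed_of_sound
        * (math.sin(math.radians(theta_deg)) + math.radians(theta_deg))
        * fs
    )
    center = (n_taps - 1) / 2.0
    delay_left = center + itd_samples / 2.0  # positive ITD: left lags
    delay_right = center - itd_samples / 2.0
    margin = 16
    if not (margin <= min(delay_left, delay_right) and max(delay_left, delay_right) <= n_taps - 1 - margin):
        raise ValueError("n_taps too small to contain the maximum interaural delay")

    kernel_l = _frac_delay_kernel(n_taps, delay_left)
    kernel_r = _frac_delay_kernel(n_taps, delay_right)
    sin_t = math.sin(math.radians(theta_deg))
    left = np.zeros(n_taps)
    right = np.zeros(n_taps)
    for (lo, hi), strength in model.shadow_strength.items():
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        ild_db = strength * sin_t
        gain_r = 10.0 ** (+ild_db / 40.0)
        gain_l = 10.0 ** (-ild_db / 40.0)
        left += gain_l * signal.sosfiltfilt(sos, kernel_l)
        right += gain_r * signal.sosfiltfilt(sos, kernel_r)
    return ImpulseResponsePair(
        left_ir=left,
        right_ir=right,
        fs=fs,
        source_angle=source_angle,
        mic_site=model.mic_site,
    )


# ---------------------------------------------------------------------------
# ECAP sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EcapSimConfig:
    """Forward-masking ECAP session model.

    The injected P1-N1 amplitude is ``max(0, growth_slope * (level -
    threshold_level))`` - exactly piecewise linear with a hinge at
    threshold. The stimulus artifact decays exponentially from probe onset
    and is strictly additive and identical wherever the same stimulus
    appears, so the four-frame subtraction cancels it completely.
    """

    threshold_level: float = 100.0  # stimulus-level units
    growth_slope: float = 20.0  # uV per level unit
    artifact_amplitude: float = 500.0  # uV
    artifact_decay: float = 2.0  # 1/ms
    noise_sd: float = 0.0  # uV
    levels: tuple[float, ...] = (110.0, 120.0, 130.0, 140.0, 150.0, 160.0)
    n1_latency_ms: float = 0.3
    p1_latency_ms: float = 0.6
    peak_width_ms: float = 0.06
    fs: float = 20000.0
    n_samples: int = 36
    masker_artifact_scale: float = 1.6
    baseline_uv: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_slope < 0:
            raise ValueError("growth_slope must be non-negative")
        if len(self.levels) == 0:
            raise ValueError("levels must be non-empty")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if not self.n1_latency_ms < self.p1_latency_ms:
            raise ValueError("N1 latency must precede P1 latency")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _neural_shape(cfg: EcapSimConfig) -> np.ndarray:
    """Unit P1-N1 template: negative trough at N1, positive peak at P1.

    Normalized so that (max - min) over the sampled trace is exactly 1,
    which makes the measured P1-N1 of an injected response equal its
    configured amplitude.
    """
    t_ms = np.arange(cfg.n_samples) / cfg.fs * 1e3
    w = cfg.peak_width_ms
    raw = 0.45 * np.exp(-0.5 * ((t_ms - cfg.p1_latency_ms) / w) ** 2) - 0.55 * np.exp(
        -0.5 * ((t_ms - cfg.n1_latency_ms) / w) ** 2
    )
    return raw / (np.max(raw) - np.min(raw))


def simulate_ecap_session(cfg: EcapSimConfig) -> list[EcapFrameSet]:
    """One four-frame set per stimulus level; reproducible by seed."""
    rng = np.random.default_rng(cfg.seed)
    t_ms = np.arange(cfg.n_samples) / cfg.fs * 1e3
    probe_art = cfg.artifact_amplitude * np.exp(-cfg.artifact_decay * t_ms)
    masker_art = cfg.masker_artifact_scale * probe_art
    baseline = np.full(cfg.n_samples, cfg.baseline_uv)
    shape = _neural_shape(cfg)

    frame_sets = []
    for level in cfg.levels:
        amp = max(0.0, cfg.growth_slope * (level - cfg.threshold_level))
        neural = amp * shape

        def _noise() -> np.ndarray:
            if cfg.noise_sd == 0.0:
                return np.zeros(cfg.n_samples)
            return rng.normal(0.0, cfg.noise_sd, cfg.n_samples)

        frame_sets.append(
            EcapFrameSet(
                probe_alone=probe_art + baseline + neural + _noise(),
                masker_probe=masker_art + probe_art + baseline + _noise(),
                masker_alone=masker_art + baseline + _noise(),
                no_stimulus=baseline + _noise(),
                fs=cfg.fs,
                stimulus_level=float(level),
            )
        )
    return frame_sets


# ---------------------------------------------------------------------------
# impedance logs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedFailure:
    """A hardware failure injected from ``day`` onward.

    ``kind`` is ``"open"`` (values forced above 20 kOhm) or ``"closed"``
    (below 1 kOhm). ``animal``/``ear`` of ``None`` match every animal/ear.
    """

    electrode: str
    day: int
    kind: str  # "open" | "closed"
    animal: str | None = None
    ear: str | None = None

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("failure day must be non-negative")
        if self.kind not in ("open", "closed"):
            raise ValueError("failure kind must be 'open' or 'closed'")


@dataclass(frozen=True)
class ImpedanceSimConfig:
    """Post-operative impedance time-course model.

    Impedance rises sigmoidally from ``baseline_kohm`` at day 0 toward
    ``plateau_kohm`` (tissue response to the array completing within the
    first post-operative weeks) and stays there. Per-electrode plateau
    offsets let the apical-high / mid-array-low spatial profile be
    emulated; they default to zero.
    """

    baseline_kohm: float = 1.9
    plateau_kohm: float = 8.5
    rise_midpoint_day: float = 9.0
    rise_scale_days: float = 2.0
    noise_sd: float = 0.0  # kOhm
    animals: tuple[str, ...] = ("F1", "F2")
    ears: tuple[str, ...] = ("left", "right")
    electrodes: tuple[str, ...] = ELECTRODES + ("EC",)
    modes: tuple[str, ...] = ("CG", "MP")
    electrode_offset_kohm: dict[str, float] = field(default_factory=dict)
    planted_failures: tuple[PlantedFailure, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_kohm < self.plateau_kohm:
            raise ValueError("baseline must be below plateau")
        if self.rise_scale_days <= 0:
            raise ValueError("rise_scale_days must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _rise_fraction(day: np.ndarray, cfg: ImpedanceSimConfig) -> np.ndarray:
    """Logistic rise renormalized so it is exactly 0 at day 0 and tends to 1."""
    sig = 1.0 / (1.0 + np.exp(-(day - cfg.rise_midpoint_day) / cfg.rise_scale_days))
    sig0 = 1.0 / (1.0 + np.exp(cfg.rise_midpoint_day / cfg.rise_scale_days))
    return (sig - sig0) / (1.0 - sig0)


def simulate_impedance_log(cfg: ImpedanceSimConfig, n_days: int) -> pd.DataFrame:
    """Daily impedance log over days 0..n_days-1 for every position and mode."""
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    rng = np.random.default_rng(cfg.seed)
    days = np.arange(n_days)
    rise = _rise_fraction(days.astype(float), cfg)

    rows: list[tuple] = []
    for animal in cfg.animals:
        for ear in cfg.ears:
            for electrode in cfg.electrodes:
                offset = cfg.electrode_offset_kohm.get(electrode, 0.0)
                clean = cfg.baseline_kohm + (
                    cfg.plateau_kohm + offset - cfg.baseline_kohm
                ) * rise
                if cfg.noise_sd > 0:
                    # truncated at 3 sigma: healthy-electrode variability is
                    # bounded, so it cannot masquerade as a hardware failure
                    noise = np.clip(
                        rng.normal(0.0, cfg.noise_sd, n_days),
                        -3.0 * cfg.noise_sd,
                        3.0 * cfg.noise_sd,
                    )
                else:
                    noise = np.zeros(n_days)
                values = np.maximum(clean + noise, 0.05)
                fail_from: dict[int, str] = {}
                for f in cfg.planted_failures:
                    if f.electrode != electrode:
                        continue
                    if f.animal is not None and f.animal != animal:
                        continue
                    if f.ear is not None and f.ear != ear:
                        continue
                    for d in range(f.day, n_days):
                        fail_from[d] = f.kind
                for mode in cfg.modes:
                    for d in days:
                        kind = fail_from.get(int(d))
                        if kind == "open":
                            v = 25.0
                        elif kind == "closed":
                            v = 0.5
                        else:
                            v = float(values[d])
                        rows.append((animal, ear, electrode, int(d), mode, v))
    return pd.DataFrame(rows, columns=list(LOG_COLUMNS))


# ---------------------------------------------------------------------------
# orienting trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Sigmoidal head-orienting trajectory model.

    The marker is stationary at the start spout, then turns toward
    ``final_bearing_deg`` along a raised-cosine (sigmoid-shaped) angular
    path while translating at constant speed. ``latency_ms`` is the
    movement latency as operationally defined by the
    third-of-three-moving-frames rule; the kinematic onset is placed three
    frame intervals earlier so the rule lands on the configured value.
    """

    latency_ms: float = 200.0
    final_bearing_deg: float = 43.0
    fps: float = 60.0
    duration_s: float = 1.0
    tracker_noise_deg: float = 0.0
    rise_time_s: float = 0.15
    pre_onset_s: float = 0.25
    step_per_frame: float = 0.01  # arena units of marker travel per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not (0 <= self.latency_ms < self.duration_s * 1e3):
            raise ValueError("latency must lie within the post-onset second")
        if self.tracker_noise_deg < 0:
            raise ValueError("tracker_noise_deg must be non-negative")
        if self.rise_time_s <= 0:
            raise ValueError("rise_time_s must be positive")


def simulate_trajectory(cfg: TrajectorySimConfig) -> Trajectory:
    """x-y marker stream at ``fps`` with the stimulus onset index set.

    With ``tracker_noise_deg = 0`` the derived angle series is exactly zero
    until the kinematic onset and monotone up to the configured bearing.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pre = int(round(cfg.pre_onset_s * cfg.fps))
    n_post = int(round(cfg.duration_s * cfg.fps))
    n = n_pre + n_post + 1
    onset = n_pre

    lat_frames = int(round(cfg.latency_ms * cfg.fps / 1e3))
    onset_motion = max(lat_frames - 3, 0)  # frames after stimulus onset

    x = np.zeros(n)
    y = np.zeros(n)
    heading0 = 0.0  # arena frame: 0 degrees = +y
    for i in range(1, n):
        rel = i - onset
        if rel <= onset_motion:
            x[i], y[i] = x[i - 1], y[i - 1]
            continue
        tau = (rel - onset_motion) / cfg.fps
        frac = min(tau / cfg.rise_time_s, 1.0)
        bearing = cfg.final_bearing_deg * 0.5 * (1.0 - math.cos(math.pi * frac))
        if cfg.tracker_noise_deg > 0:
            bearing += rng.normal(0.0, cfg.tracker_noise_deg)
        rad = math.radians(heading0 + bearing)
        x[i] = x[i - 1] + cfg.step_per_frame * math.sin(rad)
        y[i] = y[i - 1] + cfg.step_per_frame * math.cos(rad)

    return Trajectory(
        t_s=np.arange(n) / cfg.fps,
        x=x,
        y=y,
        onset_index=onset,
        fps=cfg.fps,
    )
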