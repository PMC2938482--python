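"""Binaural-cue measurement from free-field recordings.

Impulse responses are measured with complementary Golay code pairs and
reduced to the two classical azimuth cues: the interaural time difference
(ITD), extracted by cross-correlating the unfiltered left and right impulse
responses, and the interaural level difference (ILD), the band-passed RMS
level difference between the ears. Cue-versus-angle curves from repeated
sessions can be re-registered on their zero crossing (F0 alignment) so that
curve-shape variability can be compared across microphone sites.

Sign conventions used throughout the package: negative source angles are to
the animal's left; a positive ITD means the right ear leads, and a positive
ILD means the right ear is louder. Cue curves are therefore increasing over
frontal angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import signal


class MicSite(str, Enum):
    """Where the measurement microphone sits."""

    EAR_CANAL = "ear_canal"
    JACKET_POCKET = "jacket_pocket"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GolayPair:
    """A complementary pair of binary (+1/-1) codes.

    The defining property is that the two autocorrelations sum to
    ``2 * length`` at lag 0 and exactly 0 at every other lag, which makes
    exact impulse-response deconvolution possible from two presentations.
    """

    code_a: np.ndarray
    code_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.code_a, dtype=float)
        b = np.asarray(self.code_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("Golay codes must be 1-D and of equal length")
        n = a.size
        if n == 0 or (n & (n - 1)) != 0:
            raise ValueError("Golay code length must be a power of two")
        object.__setattr__(self, "code_a", a)
        object.__setattr__(self, "code_b", b)

    @property
    def length(self) -> int:
        return int(self.code_a.size)


@dataclass
class BinauralRecording:
    """Left/right microphone signals for one stimulus presentation."""

    left: np.ndarray
    right: np.ndarray
    fs: float
    source_angle: float = 0.0
    mic_site: MicSite = MicSite.EAR_CANAL

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left/right channels must have equal length")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")


@dataclass
class ImpulseResponsePair:
    """Left/right impulse responses for one source angle and microphone site."""

    left_ir: np.ndarray
    right_ir: np.ndarray
    fs: float
    source_angle: float = 0.0
    mic_site: MicSite = MicSite.EAR_CANAL

    def __post_init__(self) -> None:
        self.left_ir = np.asarray(self.left_ir, dtype=float)
        self.right_ir = np.asarray(self.right_ir, dtype=float)
        if self.left_ir.shape != self.right_ir.shape:
            raise ValueError("left/right impulse responses must have equal length")
        if not (np.all(np.isfinite(self.left_ir)) and np.all(np.isfinite(self.right_ir))):
            raise ValueError("impulse responses must be finite")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")


@dataclass
class CueCurve:
    """ITD and per-band ILD as a function of lateral source angle.

    ``ild_db`` maps each ``(low_hz, high_hz)`` band to one ILD value per
    angle; ``itd_us`` holds one ITD per angle. Angles are strictly
    increasing.
    """

    angles: np.ndarray
    itd_us: np.ndarray
    ild_db: dict[tuple[float, float], np.ndarray] = field(default_factory=dict)
    mic_site: MicSite = MicSite.EAR_CANAL

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.itd_us = np.asarray(self.itd_us, dtype=float)
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.itd_us.shape != self.angles.shape:
            raise ValueError("one ITD value per angle required")
        for band, vals in self.ild_db.items():
            v = np.asarray(vals, dtype=float)
            if v.shape != self.angles.shape:
                raise ValueError(f"one ILD value per angle required for band {band}")
            self.ild_db[band] = v

    @property
    def bands(self) -> list[tuple[float, float]]:
        return list(self.ild_db.keys())


@dataclass(frozen=True)
class RangeSummary:
    """Min/median/max of per-curve half-ranges, in the cue's own units."""

    half_ranges: tuple[float, ...]
    min: float
    median: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ValueError("summary order statistics out of order")


#: Default analysis bands: a low band where ITD dominates and a high band
#: where head shadow makes the ILD large.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((750.0, 1500.0), (4000.0, 8000.0))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def generate_golay_pair(order: int) -> GolayPair:
    """Build the complementary Golay pair of length ``2**order``.

    Uses the standard doubling recursion ``a' = a ++ b``, ``b' = a ++ (-b)``
    starting from ``a = b = [+1]``. Order 9 gives the 512-point codes used
    for free-field transfer-function measurement.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    a = np.array([1.0])
    b = np.array([1.0])
    for _ in range(order):
        a, b = np.concatenate([a, b]), np.concatenate([a, -b])
    return GolayPair(a, b)


def _golay_deconvolve(resp_a: np.ndarray, resp_b: np.ndarray, pair: GolayPair) -> np.ndarray:
    n = pair.length
    # keep non-negative lags only: correlate(x, code)[n-1:] is lag 0, 1, ...
    ca = signal.correlate(resp_a, pair.code_a, mode="full")[n - 1 :]
    cb = signal.correlate(resp_b, pair.code_b, mode="full")[n - 1 :]
    return (ca + cb) / (2.0 * n)


def estimate_impulse_response(
    resp_a: BinauralRecording,
    resp_b: BinauralRecording,
    pair: GolayPair,
) -> ImpulseResponsePair:
    """Recover the binaural impulse response from the two Golay presentations.

    ``resp_a``/``resp_b`` are the recordings of code A and code B through the
    same acoustic system. Per channel the estimate is

        IR = (correlate(resp_a, code_a) + correlate(resp_b, code_b)) / (2 N)

    which, by the complementarity of the pair, equals the true impulse
    response exactly for a noiseless linear time-invariant system.
    """
    if resp_a.fs != resp_b.fs:
        raise ValueError("recordings must share a sample rate")
    if resp_a.source_angle != resp_b.source_angle or resp_a.mic_site != resp_b.mic_site:
        raise ValueError("recordings must share source angle and microphone site")
    if min(resp_a.left.size, resp_b.left.size) < pair.length:
        raise ValueError("recordings shorter than the Golay code")
    return ImpulseResponsePair(
        left_ir=_golay_deconvolve(resp_a.left, resp_b.left, pair),
        right_ir=_golay_deconvolve(resp_a.right, resp_b.right, pair),
        fs=resp_a.fs,
        source_angle=resp_a.source_angle,
        mic_site=resp_a.mic_site,
    )


def compute_itd(
    ir: ImpulseResponsePair,
    max_lag_us: float = 1000.0,
    interpolate: bool = True,
) -> float:
    """ITD in microseconds from cross-correlation of the unfiltered IRs.

    The integer-lag cross-correlation peak within ``+-max_lag_us`` is refined
    by 3-point parabolic interpolation, giving sub-sample resolution (the
    12.5 us sample period at 80 kHz would otherwise be coarse relative to
    the cue differences of interest); ``interpolate=False`` returns the raw
    integer-lag peak, which recovers whole-sample delays exactly. Positive
    ITD means the right ear leads, i.e. the source is on the right. Ties
    between equal integer peaks break toward the smaller absolute lag.
    """
    left, right, fs = ir.left_ir, ir.right_ir, ir.fs
    if not np.any(left) or not np.any(right):
        raise ValueError("silent channel: ITD undefined")
    max_lag = int(round(max_lag_us * 1e-6 * fs))
    if max_lag < 1:
        raise ValueError("max_lag_us must be at least one sample period")
    if max_lag >= left.size:
        raise ValueError("max_lag_us exceeds the impulse-response length")

    corr = signal.correlate(left, right, mode="full")
    lags = signal.correlation_lags(left.size, right.size, mode="full")
    keep = np.abs(lags) <= max_lag
    corr, lags = corr[keep], lags[keep]

    best = np.flatnonzero(corr == corr.max())
    i = best[np.argmin(np.abs(lags[best]))]  # tie-break toward small |lag|
    lag = float(lags[i])
    if interpolate and 0 < i < corr.size - 1:
        y0, y1, y2 = corr[i - 1], corr[i], corr[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0.0:
            lag += 0.5 * (y0 - y2) / denom
    # positive lag: left lags right -> right ear leads -> source on the right
    return lag / fs * 1e6


def compute_ild(
    ir: ImpulseResponsePair,
    band: tuple[float, float] | None = None,
    order: int = 4,
) -> float:
    """ILD in dB: ``20 log10(RMS_right / RMS_left)`` after band-pass filtering.

    Filtering is a zero-phase (forward-backward) Butterworth of the given
    order. ``band=None`` or a band spanning (0, fs/2) means the unfiltered
    broadband ILD.
    """
    left, right = ir.left_ir, ir.right_ir
    if band is not None and not (band[0] <= 0.0 and band[1] >= ir.fs / 2):
        lo, hi = band
        if not (0.0 < lo < hi < ir.fs / 2):
            raise ValueError(f"invalid band {band} for fs={ir.fs}")
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=ir.fs, output="sos")
        left = signal.sosfiltfilt(sos, left)
        right = signal.sosfiltfilt(sos, right)
    rms_l = np.sqrt(np.mean(left**2))
    rms_r = np.sqrt(np.mean(right**2))
    if rms_l == 0.0 or rms_r == 0.0:
        raise ValueError("zero RMS in a channel: ILD undefined")
    return float(20.0 * np.log10(rms_r / rms_l))


def build_cue_curve(
    irs: Sequence[ImpulseResponsePair],
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    max_lag_us: float = 1000.0,
) -> CueCurve:
    """Evaluate ITD and per-band ILD at every source angle, sorted by angle."""
    if not irs:
        raise ValueError("need at least one impulse response")
    angles = np.array([ir.source_angle for ir in irs], dtype=float)
    if np.unique(angles).size != angles.size:
        raise ValueError("duplicate source angles")
    order = np.argsort(angles)
    irs = [irs[i] for i in order]
    itd = np.array([compute_itd(ir, max_lag_us) for ir in irs])
    ild = {
        tuple(map(float, b)): np.array([compute_ild(ir, b) for ir in irs])
        for b in bands
    }
    return CueCurve(
        angles=angles[order],
        itd_us=itd,
        ild_db=ild,
        mic_site=irs[0].mic_site,
    )


def _select_cue(curve: CueCurve, quantity: str, band: tuple[float, float] | None) -> np.ndarray:
    if quantity == "itd":
        return curve.itd_us
    if quantity == "ild":
        if band is None:
            if len(curve.ild_db) != 1:
                raise ValueError("band must be given when the curve has several bands")
            return next(iter(curve.ild_db.values()))
        key = tuple(map(float, band))
        if key not in curve.ild_db:
            raise KeyError(f"band {band} not present in curve")
        return curve.ild_db[key]
    raise ValueError("quantity must be 'itd' or 'ild'")


def summarize_ranges(
    curves: Sequence[CueCurve],
    quantity: str = "itd",
    band: tuple[float, float] | None = None,
) -> RangeSummary:
    """Half-range per curve and min/median/max across curves.

    A curve's half-range is ``(max - min) / 2`` of the cue over its angle
    grid, matching the +-X reporting convention for cue ranges.
    """
    if not curves:
        raise ValueError("need at least one cue curve")
    hr = tuple(
        float((np.max(v) - np.min(v)) / 2.0)
        for v in (_select_cue(c, quantity, band) for c in curves)
    )
    return RangeSummary(
        half_ranges=hr,
        min=float(np.min(hr)),
        median=float(np.median(hr)),
        max=float(np.max(hr)),
    )


def align_zero_crossing(
    curve: CueCurve,
    quantity: str = "itd",
    band: tuple[float, float] | None = None,
) -> CueCurve:
    """Re-register the curve so the selected cue's zero crossing sits at 0°.

    F0, the lateral angle at which the cue equals zero, is found by linear
    interpolation between the bracketing grid angles; if the cue crosses
    zero more than once the crossing closest to 0° is used. All angles are
    relabeled as ``angle - F0``; cue values are unchanged.
    """
    vals = _select_cue(curve, quantity, band)
    f0 = None
    exact = np.flatnonzero(vals == 0.0)
    candidates: list[float] = [float(curve.angles[i]) for i in exact]
    s = np.sign(vals)
    crossings = np.flatnonzero(s[:-1] * s[1:] < 0)
    for i in crossings:
        a0, a1 = curve.angles[i], curve.angles[i + 1]
        v0, v1 = vals[i], vals[i + 1]
        candidates.append(float(a0 - v0 * (a1 - a0) / (v1 - v0)))
    if not candidates:
        raise ValueError("cue never crosses zero: no F0 exists")
    f0 = min(candidates, key=abs)
    return replace(curve, angles=curve.angles - f0)


def rms_level_db(samples: np.ndarray, reference: float = 20e-6) -> float:
    """RMS level of a calibrated single-channel signal in dB re ``reference``.

    With samples in pascals and the default reference of 20 uPa this is
    dB SPL.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    rms = np.sqrt(np.mean(x**2))
    if rms == 0.0:
        raise ValueError("all-zero signal: level undefined")
    if reference <= 0:
        raise ValueError("reference must be positive")
    return float(20.0 * np.log10(rms / reference))
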