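"""Golay deconvolution, ITD/ILD extraction and cue-curve handling."""

import numpy as np
import pytest
from scipy import signal

from fbt.acoustics import (
    BinauralRecording,
    CueCurve,
    ImpulseResponsePair,
    align_zero_crossing,
    build_cue_curve,
    compute_ild,
    compute_itd,
    estimate_impulse_response,
    generate_golay_pair,
    rms_level_db,
    summarize_ranges,
)
from fbt.synth import simulate_head_ir

FS = 80000.0
US_PER_SAMPLE = 1e6 / FS  # 12.5 us at 80 kHz


def _record(h_left, h_right, pair, fs=FS, angle=0.0):
    """Play both Golay codes through a two-channel system."""
    recs = []
    for code in (pair.code_a, pair.code_b):
        recs.append(
            BinauralRecording(
                left=np.convolve(code, h_left),
                right=np.convolve(code, h_right),
                fs=fs,
                source_angle=angle,
            )
        )
    return recs


class TestGolay:
    def test_recursion_base(self):
        pair = generate_golay_pair(1)
        assert pair.code_a.tolist() == [1, 1]
        assert pair.code_b.tolist() == [1, -1]

    def test_length_512_for_order_9(self):
        assert generate_golay_pair(9).length == 512

    @pytest.mark.parametrize("order", range(1, 13))
    def test_complementarity(self, order):
        """Autocorrelations sum to 2N at lag 0 and vanish at every other lag."""
        pair = generate_golay_pair(order)
        n = pair.length
        acf = signal.correlate(pair.code_a, pair.code_a) + signal.correlate(
            pair.code_b, pair.code_b
        )
        expected = np.zeros(2 * n - 1)
        expected[n - 1] = 2 * n
        np.testing.assert_allclose(acf, expected, atol=1e-9)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            generate_golay_pair(-1)


class TestDeconvolution:
    def test_identity_system(self):
        pair = generate_golay_pair(9)
        h = np.zeros(64)
        h[0] = 1.0
        ir = estimate_impulse_response(*_record(h, h, pair), pair)
        assert abs(ir.left_ir[0] - 1.0) < 1e-9
        assert np.max(np.abs(ir.left_ir[1:64])) < 1e-9

    def test_two_tap_system(self):
        """Oracle: the recording is the direct convolution, so the recovered
        IR must reproduce the constructed taps."""
        pair = generate_golay_pair(9)
        h = np.zeros(64)
        h[0], h[10] = 1.0, 0.5
        ir = estimate_impulse_response(*_record(h, h, pair), pair)
        np.testing.assert_allclose(ir.right_ir[:64], h, atol=1e-9)

    def test_random_sparse_systems(self, rng):
        """Noiseless sparse IRs (<=8 taps, length <=128) are recovered to
        1e-9 relative error."""
        pair = generate_golay_pair(9)
        for _ in range(20):
            length = int(rng.integers(16, 129))
            h = np.zeros(length)
            taps = rng.choice(length, size=int(rng.integers(1, 9)), replace=False)
            h[taps] = rng.normal(size=taps.size)
            ir = estimate_impulse_response(*_record(h, h, pair), pair)
            err = np.max(np.abs(ir.left_ir[:length] - h))
            assert err < 1e-9 * max(1.0, np.max(np.abs(h)))

    def test_sample_rate_mismatch_rejected(self):
        pair = generate_golay_pair(4)
        h = np.zeros(8)
        h[0] = 1.0
        rec_a, rec_b = _record(h, h, pair)
        rec_b.fs = 48000.0
        with pytest.raises(ValueError):
            estimate_impulse_response(rec_a, rec_b, pair)

    def test_recording_shorter_than_code_rejected(self):
        pair = generate_golay_pair(9)
        short = BinauralRecording(left=np.ones(10), right=np.ones(10), fs=FS)
        with pytest.raises(ValueError):
            estimate_impulse_response(short, short, pair)


def _bandlimited_click(n=1024, fs=FS, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    sos = signal.butter(6, 0.4, btype="lowpass", output="sos")
    return signal.sosfiltfilt(sos, x)


class TestItd:
    def test_identical_channels_give_zero(self):
        x = _bandlimited_click()
        ir = ImpulseResponsePair(left_ir=x, right_ir=x, fs=FS)
        assert compute_itd(ir) == pytest.approx(0.0, abs=1e-9)

    def test_integer_delay_sign_convention(self):
        """Left delayed by 8 samples at 80 kHz -> +100 us (right ear leads)."""
        x = np.zeros(1024)
        x[100:400] = _bandlimited_click(300)
        left = np.zeros(1024)
        left[8:] = x[:-8]  # pure shift, no wraparound
        ir = ImpulseResponsePair(left_ir=left, right_ir=x, fs=FS)
        assert compute_itd(ir) == pytest.approx(8 * US_PER_SAMPLE, abs=1e-6)

    def test_fractional_delay_against_upsampled_oracle(self):
        """3.4-sample delay -> 42.5 us; oracle is integer-lag
        cross-correlation on 64x upsampled signals."""
        delay = 3.4
        n = 1024
        x = _bandlimited_click(n)
        shift = np.exp(-2j * np.pi * np.fft.rfftfreq(n) * delay)
        left = np.fft.irfft(np.fft.rfft(x) * shift, n)
        ir = ImpulseResponsePair(left_ir=left, right_ir=x, fs=FS)

        up = 64
        lu = signal.resample(left, n * up)
        ru = signal.resample(x, n * up)
        corr = signal.correlate(lu, ru, mode="full")
        lag = signal.correlation_lags(lu.size, ru.size, mode="full")[np.argmax(corr)]
        oracle_us = lag / up * US_PER_SAMPLE

        measured = compute_itd(ir)
        assert measured == pytest.approx(3.4 * US_PER_SAMPLE, abs=2.0)
        assert measured == pytest.approx(oracle_us, abs=2.0)

    def test_silent_channel_rejected(self):
        ir = ImpulseResponsePair(left_ir=np.zeros(64), right_ir=np.ones(64), fs=FS)
        with pytest.raises(ValueError):
            compute_itd(ir)

    def test_excessive_max_lag_rejected(self):
        x = _bandlimited_click(64)
        ir = ImpulseResponsePair(left_ir=x, right_ir=x, fs=FS)
        with pytest.raises(ValueError):
            compute_itd(ir, max_lag_us=1e6)


class TestIld:
    def test_doubled_right_channel(self, rng):
        x = rng.normal(size=2048)
        ir = ImpulseResponsePair(left_ir=x, right_ir=2 * x, fs=FS)
        assert compute_ild(ir) == pytest.approx(20 * np.log10(2), abs=0.01)

    def test_equal_channels_give_zero(self, rng):
        x = rng.normal(size=2048)
        ir = ImpulseResponsePair(left_ir=x, right_ir=x, fs=FS)
        assert compute_ild(ir, (750, 1500)) == pytest.approx(0.0, abs=1e-9)

    def test_in_band_gain_against_parseval_oracle(self, rng):
        """+3 dB applied to the 4-8 kHz bins only, measured in that band;
        oracle is the Parseval band-energy ratio."""
        n = 1 << 17
        x = rng.normal(size=n)
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(n, 1 / FS)
        band = (f >= 4000) & (f <= 8000)
        boosted = spec.copy()
        boosted[band] *= 10 ** (3 / 20)
        y = np.fft.irfft(boosted, n)
        oracle = 10 * np.log10(
            np.sum(np.abs(boosted[band]) ** 2) / np.sum(np.abs(spec[band]) ** 2)
        )
        assert oracle == pytest.approx(3.0, abs=1e-9)
        ir = ImpulseResponsePair(left_ir=x, right_ir=y, fs=FS)
        assert compute_ild(ir, (4000, 8000)) == pytest.approx(3.0, abs=0.1)

    def test_zero_rms_rejected(self):
        ir = ImpulseResponsePair(left_ir=np.zeros(256), right_ir=np.ones(256), fs=FS)
        with pytest.raises(ValueError):
            compute_ild(ir)

    def test_invalid_band_rejected(self, rng):
        x = rng.normal(size=256)
        ir = ImpulseResponsePair(left_ir=x, right_ir=x, fs=FS)
        with pytest.raises(ValueError):
            compute_ild(ir, (8000, 4000))


class TestCueCurve:
    def test_symmetric_head_curve_is_odd(self, head_model):
        angles = list(range(-150, 151, 10))
        irs = [simulate_head_ir(head_model, a) for a in angles]
        curve = build_cue_curve(irs)
        itd = curve.itd_us
        np.testing.assert_allclose(itd, -itd[::-1], atol=US_PER_SAMPLE)
        for vals in curve.ild_db.values():
            np.testing.assert_allclose(vals, -vals[::-1], atol=0.1)

    def test_single_angle(self, head_model):
        curve = build_cue_curve([simulate_head_ir(head_model, 0.0)])
        assert curve.angles.tolist() == [0.0]
        assert curve.itd_us[0] == pytest.approx(0.0, abs=1e-6)

    def test_itd_monotone_over_frontal_angles(self, head_model):
        angles = list(range(-90, 91, 10))
        curve = build_cue_curve([simulate_head_ir(head_model, a) for a in angles])
        assert np.all(np.diff(curve.itd_us) >= 0)

    def test_duplicate_angles_rejected(self, head_model):
        ir = simulate_head_ir(head_model, 10.0)
        with pytest.raises(ValueError):
            build_cue_curve([ir, ir])


class TestRangesAndAlignment:
    def test_half_range_definition(self):
        angles = np.array([-90.0, 0.0, 90.0])
        c = CueCurve(angles=angles, itd_us=np.array([-169.0, 0.0, 169.0]))
        s = summarize_ranges([c], "itd")
        assert s.half_ranges == (169.0,)
        assert s.median == 169.0

    def test_median_across_curves(self):
        curves = [
            CueCurve(angles=np.array([-90.0, 90.0]), itd_us=np.array([-h, h]))
            for h in (163.0, 169.0, 174.0)
        ]
        assert summarize_ranges(curves, "itd").median == 169.0

    def test_ild_half_range(self):
        c = CueCurve(
            angles=np.array([-90.0, 90.0]),
            itd_us=np.array([-100.0, 100.0]),
            ild_db={(750.0, 1500.0): np.array([-3.5, 3.5])},
        )
        s = summarize_ranges([c], "ild", (750.0, 1500.0))
        assert s.median == 3.5

    def test_f0_by_linear_interpolation(self):
        c = CueCurve(angles=np.array([0.0, 10.0]), itd_us=np.array([-10.0, 10.0]))
        aligned = align_zero_crossing(c, "itd")
        np.testing.assert_allclose(aligned.angles, [-5.0, 5.0])
        np.testing.assert_allclose(aligned.itd_us, c.itd_us)  # values unchanged

    def test_curve_already_centered_is_unchanged(self):
        c = CueCurve(
            angles=np.array([-10.0, 0.0, 10.0]), itd_us=np.array([-10.0, 0.0, 10.0])
        )
        np.testing.assert_allclose(align_zero_crossing(c, "itd").angles, c.angles)

    def test_no_sign_change_rejected(self):
        c = CueCurve(angles=np.array([0.0, 10.0]), itd_us=np.array([5.0, 10.0]))
        with pytest.raises(ValueError):
            align_zero_crossing(c, "itd")


class TestRmsLevel:
    def test_rms_at_reference_is_zero_db(self):
        t = np.linspace(0, 1, 8000, endpoint=False)
        x = np.sqrt(2) * 0.02 * np.sin(2 * np.pi * 500 * t)  # RMS = 0.02
        assert rms_level_db(x, reference=0.02) == pytest.approx(0.0, abs=1e-6)

    def test_doubling_adds_six_db(self, rng):
        x = rng.normal(size=4096)
        assert rms_level_db(2 * x, 1.0) - rms_level_db(x, 1.0) == pytest.approx(
            20 * np.log10(2), abs=1e-9
        )

    def test_concatenation_invariance(self, rng):
        x = rng.normal(size=1024)
        assert rms_level_db(np.concatenate([x, x]), 1.0) == pytest.approx(
            rms_level_db(x, 1.0), abs=1e-12
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rms_level_db(np.zeros(100), 1.0)
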