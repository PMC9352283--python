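"""Optical-flow tracking: shift recovery, averaging, sound extraction."""

import numpy as np
import pytest
from scipy.signal import periodogram
from skimage.registration import phase_cross_correlation

from speckleheart.flow import (FlowField, FlowParams, LowTextureWarning,
                               dense_flow, extract_sound, mean_displacement)
from speckleheart.signals import Waveform
from speckleheart.speckle import (SpeckleVideoConfig, generate_static_speckle,
                                  render_video, translate_field)


def phase_correlation_shift(frame_a, frame_b):
    """Independent global-shift oracle: (dx, dy) displacement a -> b from
    upsampled phase correlation (periodic boundaries make it exact)."""
    shift, _, _ = phase_cross_correlation(frame_a.astype(float),
                                          frame_b.astype(float),
                                          upsample_factor=100,
                                          normalization=None)
    return np.array([-shift[1], -shift[0]])


@pytest.fixture(scope="module")
def speckle_frame():
    return generate_static_speckle(64, 64, 4.0, seed=0)


class TestDenseFlow:
    def test_identical_frames_give_zero_flow(self, speckle_frame):
        img = speckle_frame.intensity * 100
        flow = dense_flow(img, img)
        assert np.mean(np.hypot(flow.dx, flow.dy)) < 1e-3

    def test_integer_circular_shift_recovered(self, speckle_frame):
        img = speckle_frame.intensity * 100
        shifted = np.roll(img, 1, axis=1)  # +1 px along columns
        mean = mean_displacement(dense_flow(img, shifted))
        np.testing.assert_allclose(mean, [1.0, 0.0], atol=0.05)

    @pytest.mark.parametrize("shift", [(0.3, 0.0), (0.0, -0.3), (0.2, 0.25)])
    def test_subpixel_shift_recovered(self, speckle_frame, shift):
        img = speckle_frame.intensity * 100
        moved = translate_field(speckle_frame, shift).intensity * 100
        mean = mean_displacement(dense_flow(img, moved))
        np.testing.assert_allclose(mean, shift, atol=0.05)

    def test_agrees_with_phase_correlation_over_many_pairs(self):
        """Median disagreement with the phase-correlation oracle stays
        below 0.05 px for rigid sub-pixel shifts."""
        rng = np.random.default_rng(7)
        field = generate_static_speckle(64, 64, 4.0, seed=3)
        img = field.intensity * 100
        errors = []
        for _ in range(20):
            shift = rng.uniform(-0.8, 0.8, size=2)
            moved = translate_field(field, shift).intensity * 100
            est = mean_displacement(dense_flow(img, moved))
            oracle = phase_correlation_shift(img, moved)
            errors.append(np.hypot(*(est - oracle)))
        assert np.median(errors) < 0.05

    def test_pyramid_handles_larger_shift(self, speckle_frame):
        img = speckle_frame.intensity * 100
        moved = translate_field(speckle_frame, (3.0, 0.0)).intensity * 100
        params = FlowParams(levels=3, iterations=3)
        mean = mean_displacement(dense_flow(img, moved, params))
        np.testing.assert_allclose(mean, [3.0, 0.0], atol=0.1)

    def test_shape_mismatch_raises(self, speckle_frame):
        with pytest.raises(ValueError):
            dense_flow(speckle_frame.intensity,
                       speckle_frame.intensity[:32, :32])

    def test_low_texture_warns_and_returns_zero(self):
        flat = np.full((32, 32), 10.0)
        with pytest.warns(LowTextureWarning):
            flow = dense_flow(flat, flat + 0.01)
        assert np.all(flow.dx == 0)


class TestMeanDisplacement:
    def test_constant_field(self):
        c = FlowField(dx=np.full((8, 8), 1.5), dy=np.full((8, 8), -0.5))
        np.testing.assert_allclose(mean_displacement(c), [1.5, -0.5])

    def test_antisymmetric_field_cancels(self):
        dx = np.concatenate([np.full((4, 8), 2.0), np.full((4, 8), -2.0)])
        f = FlowField(dx=dx, dy=np.zeros_like(dx))
        np.testing.assert_allclose(mean_displacement(f), [0.0, 0.0],
                                   atol=1e-12)

    def test_matches_bruteforce_summation(self, rng):
        dx = rng.standard_normal((16, 17))
        dy = rng.standard_normal((16, 17))
        mean = mean_displacement(FlowField(dx=dx, dy=dy))
        brute = [sum(map(sum, dx.tolist())) / dx.size,
                 sum(map(sum, dy.tolist())) / dy.size]
        np.testing.assert_allclose(mean, brute, atol=1e-12)


class TestExtractSound:
    def test_static_video_gives_silent_trace(self):
        cfg = SpeckleVideoConfig(height=32, width=32, noise_sigma=0.0,
                                 drift_amp=0.0)
        video = render_video(Waveform(np.zeros(100), 1500.0), cfg, seed=0)
        trace = extract_sound(video)
        assert np.sqrt(np.mean(trace.scalar.samples ** 2)) < 1e-3

    def test_tone_recovered_at_injected_frequency(self):
        fs = 1500.0
        t = np.arange(3000) / fs
        sound = Waveform(np.sin(2 * np.pi * 100.0 * t), fs)
        cfg = SpeckleVideoConfig(height=32, width=32, gain=0.4,
                                 drift_amp=0.0)
        trace = extract_sound(render_video(sound, cfg, seed=1),
                              FlowParams(win_size=9))
        freqs, power = periodogram(trace.scalar.samples, fs)
        assert abs(freqs[np.argmax(power)] - 100.0) <= freqs[1]

    def test_trace_matches_ground_truth_shifts(self):
        fs = 1500.0
        t = np.arange(1500) / fs
        sound = Waveform(np.sin(2 * np.pi * 60.0 * t), fs)
        cfg = SpeckleVideoConfig(height=32, width=32, gain=0.5)
        video = render_video(sound, cfg, seed=2)
        trace = extract_sound(video, FlowParams(win_size=9))
        rmse = np.sqrt(np.mean(
            (trace.vectors - video.truth_pair_displacements()) ** 2))
        assert rmse < 0.05

    def test_amplitude_linearity_at_small_gain(self):
        """Doubling the simulator gain doubles the recovered amplitude
        within 5% (small-signal linearity of the tracker)."""
        fs = 1500.0
        t = np.arange(1500) / fs
        sound = Waveform(np.sin(2 * np.pi * 80.0 * t), fs)
        amps = []
        for gain in (0.2, 0.4):
            cfg = SpeckleVideoConfig(height=48, width=48, gain=gain,
                                     drift_amp=0.0, noise_sigma=0.0)
            trace = extract_sound(render_video(sound, cfg, seed=3),
                                  FlowParams(win_size=9))
            amps.append(np.sqrt(np.mean(trace.scalar.samples ** 2)))
        assert amps[1] / amps[0] == pytest.approx(2.0, rel=0.05)

    def test_too_few_frames_raises(self):
        cfg = SpeckleVideoConfig(height=32, width=32)
        video = render_video(Waveform(np.zeros(1), 1500.0), cfg, seed=0)
        with pytest.raises(ValueError):
            extract_sound(video)

    def test_low_texture_frames_flagged(self):
        cfg = SpeckleVideoConfig(height=32, width=32)
        video = render_video(Waveform(np.zeros(20), 1500.0), cfg, seed=0)
        video.frames[5:8] = 3  # blank out frames
        with pytest.warns(LowTextureWarning):
            trace = extract_sound(video)
        assert trace.low_texture.sum() >= 3
        assert np.all(trace.vectors[trace.low_texture] == 0)
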