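"""Dynamic laser-speckle simulation.

Coherent light scattered from a rough surface (skin) produces a fully
developed speckle pattern: the complex field amplitude is circular Gaussian,
so the intensity is negative-exponentially distributed with contrast
(std/mean) of 1. Under small tilts of the surface — here driven by heart-
sound pressure waves — the far-field pattern does not change shape but
translates proportionally to the tilt angle (the speckle memory effect).

The simulator renders videos by translating a single static speckle
realization along a shift trajectory composed of the heart-sound signal
(scaled by a gain in px per unit amplitude) plus a low-frequency sinusoidal
drift emulating macroscopic body motion (the 0-20 Hz component real
recordings contain), then adding Gaussian read noise and quantizing to the
camera bit depth. Translation is exact to sub-pixel precision via a Fourier
phase ramp on the retained complex amplitude (periodic boundaries), so every
frame comes with exact ground-truth shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.fft as sfft

from .signals import Waveform


class MemoryEffectError(ValueError):
    """Shift trajectory too large for the translation-only speckle model."""


@dataclass(frozen=True)
class SpeckleField:
    """A static speckle realization.

    The complex amplitude is retained so the field can be translated by an
    exact sub-pixel amount; ``intensity`` is its squared modulus, normalized
    to unit mean.
    """

    amplitude: np.ndarray  # complex, (rows, cols)
    grain_size: float

    @property
    def intensity(self) -> np.ndarray:
        a = self.amplitude
        return (a.real ** 2 + a.imag ** 2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape

    def contrast(self) -> float:
        """Speckle contrast std/mean (1 for fully developed speckle)."""
        i = self.intensity
        return float(np.std(i) / np.mean(i))


@dataclass(frozen=True)
class SpeckleVideoConfig:
    """Rendering configuration for a synthetic speckle video.

    The defaults mirror a high-frame-rate CMOS acquisition: 1.5 kHz frame
    rate at 200 x 208 px, 8-bit depth. ``gain`` converts sound amplitude to
    pattern shift in px; ``drift_freq``/``drift_amp`` specify the macroscopic
    motion sinusoid (frequency must stay below 20 Hz, the band removed by
    the phonocardiogram filter).
    """

    frame_rate: float = 1500.0
    height: int = 200
    width: int = 208
    bit_depth: int = 8
    grain_size: float = 4.0
    noise_sigma: float = 2.0
    gain: float = 0.3
    drift_freq: float = 1.2
    drift_amp: float = 2.0
    drift_phase: float = 0.0
    direction: tuple[float, float] = (1.0, 0.0)        # (dx, dy) unit vector
    drift_direction: tuple[float, float] = (1.0, 0.0)
    #: shifts beyond this fraction of the frame break the memory-effect model
    memory_fraction: float = 0.25
    #: intensity quantile mapped to the top quantization level
    saturation_quantile: float = 0.995

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.grain_size < 2:
            raise ValueError("grain_size < 2 px risks aliasing the speckle")
        if not (0 <= self.drift_freq < 20.0):
            raise ValueError("drift frequency must lie in [0, 20) Hz")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        for name in ("direction", "drift_direction"):
            v = np.asarray(getattr(self, name), dtype=float)
            norm = np.hypot(*v)
            if not norm > 0:
                raise ValueError(f"{name} must be a non-zero vector")
            object.__setattr__(self, name, tuple(float(x) for x in v / norm))

    @property
    def drift_spec(self) -> tuple[float, float]:
        return (self.drift_freq, self.drift_amp)


@dataclass(frozen=True)
class SpeckleVideo:
    """An ordered stack of quantized speckle frames.

    ``truth_shifts`` holds the exact (dx, dy) shift of each frame relative
    to the base field (present for synthetic videos, None for imported
    ones).
    """

    frames: np.ndarray  # (T, H, W) unsigned int
    config: SpeckleVideoConfig
    truth_shifts: Optional[np.ndarray] = None  # (T, 2) float, (dx, dy) px

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.truth_shifts is not None and len(self.truth_shifts) != len(self.frames):
            raise ValueError("truth_shifts length must equal the frame count")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_rate(self) -> float:
        return self.config.frame_rate

    def truth_pair_displacements(self) -> np.ndarray:
        """Exact frame-to-frame (dx, dy) displacements, shape (T-1, 2)."""
        if self.truth_shifts is None:
            raise ValueError("video carries no ground-truth shifts")
        return np.diff(self.truth_shifts, axis=0)


def generate_static_speckle(height: int, width: int, grain_size: float,
                            seed: int) -> SpeckleField:
    """Generate a fully developed speckle field.

    A circular complex Gaussian random field is band-limited by a circular
    pupil of cut-off 1/(2*grain_size) cycles/px, the discrete analogue of
    free-space speckle formation with an aperture setting the grain size.
    The intensity is normalized to unit mean.
    """
    if grain_size < 2:
        raise ValueError("grain_size < 2 px risks aliasing the speckle")
    rng = np.random.default_rng(seed)
    spectrum = rng.standard_normal((height, width)) + 1j * rng.standard_normal(
        (height, width))
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    pupil = (fy ** 2 + fx ** 2) <= (0.5 / grain_size) ** 2
    amplitude = sfft.ifft2(spectrum * pupil)
    power = np.mean(amplitude.real ** 2 + amplitude.imag ** 2)
    amplitude = amplitude / np.sqrt(power)
    return SpeckleField(amplitude=amplitude, grain_size=float(grain_size))


def translate_field(field: SpeckleField, shift: tuple[float, float]) -> SpeckleField:
    """Translate a speckle field by an exact sub-pixel (dx, dy) shift.

    Applies a Fourier phase ramp to the complex amplitude (periodic
    boundary); translating by a then b equals translating by a+b.
    """
    dx, dy = float(shift[0]), float(shift[1])
    h, w = field.shape
    spectrum = sfft.fft2(field.amplitude)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    spectrum = spectrum * np.exp(-2j * np.pi * (fx * dx + fy * dy))
    return SpeckleField(amplitude=sfft.ifft2(spectrum), grain_size=field.grain_size)


def _shift_trajectory(sound: Waveform, config: SpeckleVideoConfig) -> np.ndarray:
    """Exact per-frame (dx, dy) shifts: gain*sound along ``direction`` plus
    the drift sinusoid along ``drift_direction``."""
    t = np.arange(len(sound)) / config.frame_rate
    scalar_sound = config.gain * sound.samples
    scalar_drift = config.drift_amp * np.sin(
        2 * np.pi * config.drift_freq * t + config.drift_phase)
    d_sound = np.asarray(config.direction)
    d_drift = np.asarray(config.drift_direction)
    return scalar_sound[:, None] * d_sound[None, :] + \
        scalar_drift[:, None] * d_drift[None, :]


def render_video(sound: Waveform, config: SpeckleVideoConfig, seed: int,
                 chunk_frames: int = 4096) -> SpeckleVideo:
    """Render a dynamic speckle video driven by a sound waveform.

    Each frame is the base speckle field translated by that frame's exact
    shift (memory effect), plus Gaussian read noise, quantized to the camera
    bit depth. The intensity scale maps the ``saturation_quantile`` of the
    base field to the top level, so only the extreme exponential tail of the
    speckle statistics clips.

    Raises
    ------
    MemoryEffectError
        If the trajectory exceeds ``memory_fraction`` of the frame size,
        where the translation-only model stops being physical.
    """
    if abs(sound.fs - config.frame_rate) > 1e-9:
        raise ValueError(
            f"sound rate {sound.fs} Hz must equal the frame rate "
            f"{config.frame_rate} Hz (one frame per sample)")
    shifts = _shift_trajectory(sound, config)
    max_shift = float(np.max(np.abs(shifts))) if len(shifts) else 0.0
    limit = config.memory_fraction * min(config.height, config.width)
    if max_shift > limit:
        raise MemoryEffectError(
            f"peak shift {max_shift:.1f} px exceeds {limit:.1f} px "
            f"({config.memory_fraction:.0%} of the frame); the memory-effect "
            "model no longer holds")

    rng = np.random.default_rng(seed)
    base = generate_static_speckle(config.height, config.width,
                                   config.grain_size, seed=int(rng.integers(2 ** 31)))
    base_spectrum = sfft.fft2(base.amplitude).astype(np.complex64)
    levels = 2 ** config.bit_depth - 1
    ref = float(np.quantile(base.intensity, config.saturation_quantile))
    scale = levels / ref
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16

    h, w = config.height, config.width
    fy = np.fft.fftfreq(h).astype(np.float32)[None, :, None]
    fx = np.fft.fftfreq(w).astype(np.float32)[None, None, :]
    n = len(sound)
    frames = np.empty((n, h, w), dtype=dtype)
    for start in range(0, n, chunk_frames):
        stop = min(start + chunk_frames, n)
        dx = shifts[start:stop, 0].astype(np.float32)[:, None, None]
        dy = shifts[start:stop, 1].astype(np.float32)[:, None, None]
        ramp = np.exp(-2j * np.pi * (fy * dy)).astype(np.complex64) \
            * np.exp(-2j * np.pi * (fx * dx)).astype(np.complex64)
        amp = sfft.ifft2(base_spectrum[None, :, :] * ramp, axes=(1, 2))
        intensity = (amp.real ** 2 + amp.imag ** 2) * np.float32(scale)
        if config.noise_sigma > 0:
            intensity += rng.standard_normal(
                intensity.shape, dtype=np.float32) * np.float32(config.noise_sigma)
        np.clip(np.rint(intensity, out=intensity), 0, levels, out=intensity)
        frames[start:stop] = intensity.astype(dtype)
    return SpeckleVideo(frames=frames, config=config, truth_shifts=shifts)
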