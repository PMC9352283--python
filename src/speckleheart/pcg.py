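"""Phonocardiogram conditioning: band-pass, normalization, segmentation.

The raw displacement trace recovered from speckle video contains the heart
sound superposed on 0-20 Hz macroscopic body motion. A 20-700 Hz Butterworth
band-pass (order-10 design, applied forward-backward for zero phase) removes
the motion component and out-of-band noise; the result is rescaled to unit
peak amplitude and cut into fixed-length segments (2.5 s by default), the
examples consumed by feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import Waveform


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: 20-700 Hz Butterworth, order-10 design.

    ``order`` is the design order N passed to the Butterworth band-pass
    transformation (the common toolbox convention, yielding a transfer
    function with 2N poles). The filter is applied forward-backward, so the
    effective magnitude response is the squared Butterworth magnitude.
    """

    low_cut: float = 20.0
    high_cut: float = 700.0
    order: int = 10

    def validate(self, fs: float) -> None:
        if not (0 < self.low_cut < self.high_cut):
            raise ValueError("need 0 < low_cut < high_cut")
        if self.high_cut >= fs / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz must be below Nyquist {fs / 2} Hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.butter(self.order, [self.low_cut, self.high_cut],
                          btype="bandpass", fs=fs, output="sos")


@dataclass(frozen=True)
class SegmentationSpec:
    """Fixed-length windowing: 2.5 s segments, no overlap by default."""

    segment_length: float = 2.5
    overlap: float = 0.0

    def __post_init__(self) -> None:
        if not self.segment_length > 0:
            raise ValueError("segment_length must be positive")
        if not (0 <= self.overlap < self.segment_length):
            raise ValueError("overlap must be in [0, segment_length)")


def bandpass(wave: Waveform, spec: FilterSpec = FilterSpec()) -> Waveform:
    """Zero-phase Butterworth band-pass. Output length equals input length."""
    sos = spec.sos(wave.fs)
    filtered = sps.sosfiltfilt(sos, wave.samples)
    return wave.with_samples(filtered)


def butterworth_bandpass_gain(freqs, spec: FilterSpec, fs: float,
                              zero_phase: bool = True) -> np.ndarray:
    """Closed-form magnitude response of the designed digital band-pass.

    The digital filter is a bilinear transform (with frequency pre-warping)
    of the analog Butterworth band-pass prototype, so its magnitude at
    frequency f equals the analog prototype's magnitude at the pre-warped
    frequency: |H| = (1 + Omega^(2N))^(-1/2) with
    Omega = |w^2 - W1*W2| / (w * (W2 - W1)), w = 2*fs*tan(pi*f/fs).
    With ``zero_phase`` the forward-backward application squares this.
    """
    spec.validate(fs)
    f = np.asarray(freqs, dtype=np.float64)
    warp = lambda x: 2 * fs * np.tan(np.pi * x / fs)
    w1, w2 = warp(spec.low_cut), warp(spec.high_cut)
    w = warp(f)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.abs(w ** 2 - w1 * w2) / (w * (w2 - w1))
        gain = 1.0 / np.sqrt(1.0 + omega ** (2 * spec.order))
    gain = np.where(f == 0, 0.0, gain)
    return gain ** 2 if zero_phase else gain


def designed_bandpass_gain(freqs, spec: FilterSpec, fs: float,
                           zero_phase: bool = True) -> np.ndarray:
    """Magnitude response of the actually designed filter, for auditing."""
    sos = spec.sos(fs)
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs, float) / fs)
    mag = np.abs(h)
    return mag ** 2 if zero_phase else mag


def rescale_unit(wave: Waveform) -> Waveform:
    """Rescale to unit peak amplitude: output = x / max|x|."""
    peak = float(np.max(np.abs(wave.samples))) if len(wave) else 0.0
    if peak == 0:
        raise ValueError("cannot rescale an all-zero signal")
    return wave.with_samples(wave.samples / peak)


def segment(wave: Waveform, spec: SegmentationSpec = SegmentationSpec()
            ) -> list[Waveform]:
    """Cut a waveform into fixed-length windows; the remainder is dropped.

    With overlap, window starts advance by (segment_length - overlap). A
    4.5 min recording at 2.5 s windows yields 108 segments; 30 s yields 12.
    """
    seg_n = int(round(spec.segment_length * wave.fs))
    hop_n = int(round((spec.segment_length - spec.overlap) * wave.fs))
    if seg_n < 1 or hop_n < 1:
        raise ValueError("segment/hop shorter than one sample at this rate")
    out = []
    start = 0
    while start + seg_n <= len(wave):
        out.append(wave.with_samples(wave.samples[start:start + seg_n].copy()))
        start += hop_n
    return out


def preprocess(wave: Waveform, filter_spec: FilterSpec = FilterSpec(),
               seg_spec: SegmentationSpec = SegmentationSpec(),
               apply_filter: bool = True) -> list[Waveform]:
    """Filter -> rescale to unit amplitude -> segment.

    ``apply_filter=False`` supports already-conditioned sources such as
    digital-stethoscope corpora that ship pre-filtered, pre-scaled WAVs.
    """
    if apply_filter:
        wave = bandpass(wave, filter_spec)
    wave = rescale_unit(wave)
    return segment(wave, seg_spec)
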