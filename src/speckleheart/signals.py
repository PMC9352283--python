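"""Uniformly sampled 1-D signals.

A :class:`Waveform` is the common currency of the package: synthetic heart
sounds, displacement traces recovered from speckle video, and filtered
phonocardiograms are all waveforms with an attached sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray, shape (n,)
        Signal amplitudes. Stored as float64.
    fs : float
        Sampling rate in Hz. Must be positive.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Waveform":
        """Return a new waveform with the same rate and new samples."""
        return Waveform(samples=samples, fs=self.fs)
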