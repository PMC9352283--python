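"""Synthetic subject-specific heart sounds.

Normal heart sounds are short tonal bursts: S1 (mitral/tricuspid closure,
10-140 Hz) followed after the systolic interval by S2 (aortic/pulmonary
closure, 10-400 Hz); some subjects additionally present low-frequency S3/S4
sounds, and turbulent-flow murmurs occupy 20-1000 Hz. Each valve sound is
modelled as a Gabor atom — a Gaussian-windowed sinusoid — whose centre
frequency, damping (inverse Gaussian width) and amplitude are the
subject-specific parameters. A cohort of such profiles stands in for a panel
of real subjects and makes the downstream identification pipeline testable
without recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Optional, Sequence

import numpy as np

from .signals import Waveform

# Physiological frequency bands (Hz)
S1_BAND = (10.0, 140.0)
S2_BAND = (10.0, 400.0)
MURMUR_BAND_LIMITS = (20.0, 1000.0)

#: Minimum pairwise Euclidean separation of cohort members in the
#: (s1_freq, s2_freq) plane, in Hz. Guarantees identifiability at desk scale.
MIN_FREQ_SEPARATION_HZ = 5.0


class ProfileError(ValueError):
    """Raised when a subject profile violates its physiological invariants."""


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject heart-sound parameters.

    Attributes
    ----------
    subject_id : str
        Label used as the classification target.
    s1_freq, s2_freq : float
        Centre frequencies of the S1 and S2 tonal bursts, Hz.
    s1_amp, s2_amp : float
        Peak amplitudes (dimensionless; absolute scale is set downstream).
    s1_damping, s2_damping : float
        Envelope decay rates in 1/s; the Gaussian envelope of each burst has
        standard deviation ``1/damping`` seconds.
    s2_delay : float
        Systolic interval from S1 onset to S2 onset, seconds.
    heart_rate : float
        Beats per minute.
    hr_jitter : float
        Fractional standard deviation of the beat-to-beat interval.
    s3_amp, s4_amp : float
        Amplitudes of the optional diastolic sounds (0 disables).
    murmur_band : (float, float), optional
        Band of the optional systolic murmur noise, Hz.
    murmur_amp : float
        Murmur amplitude (0 disables).
    """

    subject_id: str
    s1_freq: float
    s2_freq: float
    s1_amp: float = 1.0
    s2_amp: float = 0.7
    s1_damping: float = 35.0
    s2_damping: float = 45.0
    s2_delay: float = 0.30
    heart_rate: float = 70.0
    hr_jitter: float = 0.0
    s3_amp: float = 0.0
    s4_amp: float = 0.0
    murmur_band: Optional[tuple[float, float]] = None
    murmur_amp: float = 0.0

    # low-frequency bands for the optional S3/S4 sounds
    s3_freq: float = 30.0
    s4_freq: float = 25.0
    s3_damping: float = 40.0
    s4_damping: float = 40.0

    def __post_init__(self) -> None:
        if not (S1_BAND[0] <= self.s1_freq <= S1_BAND[1]):
            raise ProfileError(f"s1_freq {self.s1_freq} outside {S1_BAND} Hz")
        if not (S2_BAND[0] <= self.s2_freq <= S2_BAND[1]):
            raise ProfileError(f"s2_freq {self.s2_freq} outside {S2_BAND} Hz")
        for name in ("s1_amp", "s2_amp", "s3_amp", "s4_amp", "murmur_amp"):
            if getattr(self, name) < 0:
                raise ProfileError(f"{name} must be >= 0")
        if not self.heart_rate > 0:
            raise ProfileError("heart_rate must be positive")
        if not (0 <= self.hr_jitter < 0.5):
            raise ProfileError("hr_jitter must be in [0, 0.5)")
        if not (0 < self.s2_delay < 60.0 / self.heart_rate):
            raise ProfileError("s2_delay must lie inside the cardiac cycle")
        if self.murmur_band is not None:
            lo, hi = self.murmur_band
            if not (MURMUR_BAND_LIMITS[0] <= lo < hi <= MURMUR_BAND_LIMITS[1]):
                raise ProfileError(
                    f"murmur_band {self.murmur_band} outside {MURMUR_BAND_LIMITS} Hz"
                )
        for name in ("s1_damping", "s2_damping", "s3_damping", "s4_damping"):
            if not getattr(self, name) > 0:
                raise ProfileError(f"{name} must be positive")

    @property
    def max_frequency(self) -> float:
        """Highest centre frequency present in the profile, Hz."""
        freqs = [self.s1_freq, self.s2_freq]
        if self.s3_amp > 0:
            freqs.append(self.s3_freq)
        if self.s4_amp > 0:
            freqs.append(self.s4_freq)
        if self.murmur_amp > 0 and self.murmur_band is not None:
            freqs.append(self.murmur_band[1])
        return max(freqs)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["murmur_band"] is not None:
            d["murmur_band"] = list(d["murmur_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectProfile":
        d = dict(d)
        if d.get("murmur_band") is not None:
            d["murmur_band"] = tuple(d["murmur_band"])
        return cls(**d)


def _gabor_atom(t: np.ndarray, t0: float, freq: float, amp: float,
                damping: float) -> np.ndarray:
    """Gaussian-windowed cosine burst centred at ``t0``.

    Envelope std is 1/damping s, so the burst's spectral footprint is a
    Gaussian of std damping/(2*pi) Hz around ``freq``.
    """
    tau = t - t0
    return amp * np.exp(-0.5 * (damping * tau) ** 2) * np.cos(2 * np.pi * freq * tau)


def beat_times(profile: SubjectProfile, duration: float,
               rng: np.random.Generator) -> np.ndarray:
    """S1 onset times over ``duration`` seconds.

    Beat intervals are (60/heart_rate)*(1 + jitter) with jitter drawn i.i.d.
    normal with std ``hr_jitter`` (clipped at 3 sigma so intervals stay
    positive for any admissible jitter).
    """
    mean_rr = 60.0 / profile.heart_rate
    times = []
    t = 0.5 * mean_rr * 0.5  # first beat shortly after the start
    while t < duration:
        times.append(t)
        jitter = 0.0
        if profile.hr_jitter > 0:
            jitter = float(np.clip(rng.normal(0.0, profile.hr_jitter), -0.45, 0.45))
        t += mean_rr * (1.0 + jitter)
    return np.asarray(times)


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS white noise restricted to ``band`` by FFT masking."""
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= min(band[1], fs / 2))
    spectrum[~mask] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def generate_heart_sound(profile: SubjectProfile, duration: float, fs: float,
                         seed: int) -> Waveform:
    """Synthesize a heart-sound waveform for one subject.

    Each cardiac cycle contains an S1 Gabor atom followed ``s2_delay``
    seconds later by an S2 atom; optional S4 (just before S1), S3 (early
    diastole, shortly after S2) and a systolic band-limited murmur are added
    when their amplitudes are non-zero. Identical inputs and seed give
    bit-identical output.

    Parameters
    ----------
    profile : SubjectProfile
    duration : float
        Length of the output in seconds (> 0).
    fs : float
        Sampling rate in Hz; must satisfy fs >= 2 * profile.max_frequency.
    seed : int
        Seed for the beat-interval jitter and murmur noise.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if fs < 2 * profile.max_frequency:
        raise ValueError(
            f"fs={fs} Hz cannot represent content at {profile.max_frequency} Hz"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    onsets = beat_times(profile, duration, rng)
    # Atoms have ~4/damping s support; add only where they overlap the window.
    for t1 in onsets:
        x += _gabor_atom(t, t1, profile.s1_freq, profile.s1_amp, profile.s1_damping)
        t2 = t1 + profile.s2_delay
        x += _gabor_atom(t, t2, profile.s2_freq, profile.s2_amp, profile.s2_damping)
        if profile.s4_amp > 0:
            x += _gabor_atom(t, t1 - 0.09, profile.s4_freq, profile.s4_amp,
                             profile.s4_damping)
        if profile.s3_amp > 0:
            x += _gabor_atom(t, t2 + 0.15, profile.s3_freq, profile.s3_amp,
                             profile.s3_damping)

    if profile.murmur_amp > 0 and profile.murmur_band is not None:
        noise = _bandlimited_noise(n, fs, profile.murmur_band, rng)
        gate = np.zeros(n)
        for t1 in onsets:
            # systolic gate between S1 and S2, smooth 10 ms edges
            lo, hi = t1 + 0.02, t1 + profile.s2_delay - 0.02
            gate += 0.5 * (np.tanh((t - lo) / 0.01) - np.tanh((t - hi) / 0.01))
        x += profile.murmur_amp * noise * np.clip(gate, 0.0, 1.0)

    return Waveform(samples=x, fs=fs)


def make_cohort(n_subjects: int, seed: int, *,
                s1_range: tuple[float, float] = (25.0, 90.0),
                s2_range: tuple[float, float] = (60.0, 220.0),
                hr_range: tuple[float, float] = (55.0, 95.0),
                hr_jitter: float = 0.03,
                min_separation: float = MIN_FREQ_SEPARATION_HZ,
                ) -> list[SubjectProfile]:
    """Draw a cohort of distinct subject profiles.

    Frequencies are drawn uniformly inside sub-ranges of the physiological
    S1/S2 bands (the defaults avoid the 20 Hz high-pass floor of the
    phonocardiogram band-pass), with rejection sampling enforcing a minimum
    pairwise Euclidean separation in the (s1_freq, s2_freq) plane.
    Reproducible from the seed.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if not (S1_BAND[0] <= s1_range[0] < s1_range[1] <= S1_BAND[1]):
        raise ValueError(f"s1_range must lie inside {S1_BAND}")
    if not (S2_BAND[0] <= s2_range[0] < s2_range[1] <= S2_BAND[1]):
        raise ValueError(f"s2_range must lie inside {S2_BAND}")
    rng = np.random.default_rng(seed)
    chosen: list[tuple[float, float]] = []
    profiles: list[SubjectProfile] = []
    attempts = 0
    while len(profiles) < n_subjects:
        attempts += 1
        if attempts > 10000 * n_subjects:
            raise RuntimeError("cohort sampling failed; ranges too tight for "
                               f"{n_subjects} subjects at {min_separation} Hz "
                               "separation")
        f1 = rng.uniform(*s1_range)
        f2 = rng.uniform(*s2_range)
        if any(np.hypot(f1 - a, f2 - b) < min_separation for a, b in chosen):
            continue
        chosen.append((f1, f2))
        profiles.append(SubjectProfile(
            subject_id=f"subject_{len(profiles):02d}",
            s1_freq=round(f1, 3),
            s2_freq=round(f2, 3),
            s1_amp=1.0,
            s2_amp=round(rng.uniform(0.5, 0.8), 3),
            s1_damping=round(rng.uniform(25.0, 45.0), 3),
            s2_damping=round(rng.uniform(35.0, 60.0), 3),
            s2_delay=round(rng.uniform(0.27, 0.35), 3),
            heart_rate=round(rng.uniform(*hr_range), 2),
            hr_jitter=hr_jitter,
        ))
    return profiles


def session_perturbation(profile: SubjectProfile, magnitude: float,
                         seed: int) -> SubjectProfile:
    """Jitter a profile to emulate re-recording on another day.

    Frequencies, amplitudes, dampings and heart rate are each multiplied by
    (1 + u) with u uniform in [-magnitude, magnitude], then clipped back to
    their physiological bands. Captures session-to-session variability when
    the laser spot is not repositioned identically. The subject identity is
    preserved.
    """
    if not (0 <= magnitude < 1):
        raise ValueError("magnitude must be in [0, 1)")
    if magnitude == 0:
        return profile
    rng = np.random.default_rng(seed)

    def jit(value: float, lo: float | None = None, hi: float | None = None) -> float:
        out = value * (1.0 + rng.uniform(-magnitude, magnitude))
        if lo is not None:
            out = max(out, lo)
        if hi is not None:
            out = min(out, hi)
        return out

    max_delay = 60.0 / profile.heart_rate  # clip after the new rate is known
    new_rate = jit(profile.heart_rate, 30.0, 180.0)
    return replace(
        profile,
        s1_freq=jit(profile.s1_freq, *S1_BAND),
        s2_freq=jit(profile.s2_freq, *S2_BAND),
        s1_amp=jit(profile.s1_amp),
        s2_amp=jit(profile.s2_amp),
        s1_damping=jit(profile.s1_damping),
        s2_damping=jit(profile.s2_damping),
        heart_rate=new_rate,
        s2_delay=min(jit(profile.s2_delay), 0.9 * 60.0 / new_rate, 0.9 * max_delay),
    )


def transient_bands(profile: SubjectProfile, width_sigmas: float = 3.0,
                    margin_hz: float = 2.0) -> list[tuple[float, float]]:
    """Frequency bands containing the profile's transient energy.

    Each Gabor atom at centre f with damping d has a Gaussian spectrum of std
    d/(2*pi) Hz; the band is f +/- (width_sigmas * std + margin).
    """
    bands = [
        (profile.s1_freq, profile.s1_damping, profile.s1_amp),
        (profile.s2_freq, profile.s2_damping, profile.s2_amp),
        (profile.s3_freq, profile.s3_damping, profile.s3_amp),
        (profile.s4_freq, profile.s4_damping, profile.s4_amp),
    ]
    out = []
    for f, d, a in bands:
        if a > 0:
            half = width_sigmas * d / (2 * np.pi) + margin_hz
            out.append((max(f - half, 0.0), f + half))
    if profile.murmur_amp > 0 and profile.murmur_band is not None:
        out.append(profile.murmur_band)
    return out
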