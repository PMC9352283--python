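"""Three-layer Gabor wavelet scattering transform.

The scattering transform cascades wavelet convolutions and modulus
nonlinearities: order-1 coefficients are time averages of |x * psi_l1|,
order-2 of ||x * psi_l1| * psi_l2|, and so on, with only
frequency-decreasing paths (l2 < l1, l3 < l2) retained. The result is a
fixed-length feature vector that is stable to translations and small
deformations while retaining the spectral envelope structure that
distinguishes heart sounds — the role the cochlea-like filter cascade plays
in the identification pipeline.

Filters are Gabor (Gaussian) band-passes defined directly in the frequency
domain with geometrically spaced centre frequencies and constant-Q
bandwidths, jointly normalized with a Gaussian low-pass so the
Littlewood-Paley sum stays below 1, which makes every layer — and hence the
whole transform — non-expansive.

Between layers the filtered envelopes are band-limited, so they are
resampled to the lowest rate that still supports the next layer's filters
(exact Fourier-domain subsampling); this multirate scheme is what makes the
default 56/30/9 filter-bank configuration affordable on long segments and
can be disabled with ``subsample=False`` for exact single-rate computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import scipy.fft as sfft
from sklearn.base import BaseEstimator, TransformerMixin

from .signals import Waveform

_LP_TARGET = 1.0 - 1e-3  # Littlewood-Paley headroom below the unit bound


@dataclass(frozen=True)
class FilterBank:
    """One layer of Gabor wavelets plus the shared Gaussian low-pass.

    ``scale`` is the common amplitude factor that enforces the
    Littlewood-Paley bound; it multiplies the wavelets and the low-pass
    alike.
    """

    fs: float
    center_freqs: tuple[float, ...]  # strictly decreasing, Hz
    sigmas: tuple[float, ...]        # spectral stds, Hz
    lowpass_T: float                 # invariance scale, s
    scale: float

    @property
    def n_filters(self) -> int:
        return len(self.center_freqs)

    @property
    def lowpass_sigma_hz(self) -> float:
        # time-domain Gaussian of std T/2 -> spectral std 1/(pi*T)
        return 1.0 / (np.pi * self.lowpass_T)

    def wavelet_gains(self, freqs: np.ndarray) -> np.ndarray:
        """|psi_hat| for every wavelet on a frequency grid, shape (M, len)."""
        f = np.asarray(freqs, dtype=np.float64)[None, :]
        fc = np.asarray(self.center_freqs)[:, None]
        sg = np.asarray(self.sigmas)[:, None]
        gains = np.exp(-0.5 * ((f - fc) / sg) ** 2)
        gains[np.broadcast_to(f < 0, gains.shape)] = 0.0  # analytic wavelets
        return self.scale * gains

    def lowpass_gain(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=np.float64)
        return self.scale * np.exp(-0.5 * (f / self.lowpass_sigma_hz) ** 2)

    def littlewood_paley(self, freqs: np.ndarray) -> np.ndarray:
        """Sum of squared filter magnitudes over a frequency grid."""
        psi = self.wavelet_gains(freqs)
        return (psi ** 2).sum(axis=0) + self.lowpass_gain(freqs) ** 2


def build_filterbank(fs: float, n_filters: int, f_min: float, f_max: float,
                     T: float = 0.5) -> FilterBank:
    """Build a constant-Q Gabor filter bank.

    Centre frequencies are geometrically spaced from ``f_max`` down to
    ``f_min``; each wavelet's spectral std is 0.6*(r-1) times its centre
    frequency, with r the spacing ratio, so adjacent filters overlap near
    half maximum. The bank plus its low-pass is rescaled to satisfy the
    Littlewood-Paley bound with a small margin.
    """
    if not (0 < f_min < f_max <= fs / 2):
        raise ValueError(f"need 0 < f_min < f_max <= fs/2, got "
                         f"({f_min}, {f_max}) at fs={fs}")
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    if not T > 0:
        raise ValueError("invariance scale T must be positive")
    if n_filters == 1:
        centers = np.array([f_max])
        ratio = f_max / f_min
    else:
        centers = f_max * (f_min / f_max) ** (
            np.arange(n_filters) / (n_filters - 1))
        ratio = centers[0] / centers[1]
    sigmas = np.maximum(centers * 0.6 * (ratio - 1.0), 1.0 / (np.pi * T))

    bank = FilterBank(fs=fs, center_freqs=tuple(centers), sigmas=tuple(sigmas),
                      lowpass_T=T, scale=1.0)
    grid = np.linspace(0, fs / 2, 4096)
    peak = float(np.max(bank.littlewood_paley(grid)))
    return FilterBank(fs=fs, center_freqs=tuple(centers), sigmas=tuple(sigmas),
                      lowpass_T=T, scale=float(np.sqrt(_LP_TARGET / peak)))


@dataclass(frozen=True)
class ScatteringConfig:
    """Configuration of the three-layer scattering network.

    M, N, P are the filter counts per node in layers 1-3; T is the
    invariance scale of the averaging low-pass in seconds; ``f_min``/
    ``f_max`` bound the centre frequencies (defaults match the 20-700 Hz
    phonocardiogram band). ``log`` applies log(eps + .) to the averaged
    coefficients. ``subsample`` enables multirate computation.
    """

    M: int = 56
    N: int = 30
    P: int = 9
    T: float = 0.5
    fs: float = 1500.0
    f_min: float = 20.0
    f_max: float = 700.0
    log: bool = False
    eps: float = 1e-6
    subsample: bool = True

    def __post_init__(self) -> None:
        for name in ("M", "N", "P"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.f_min < self.f_max <= self.fs / 2):
            raise ValueError("need 0 < f_min < f_max <= fs/2")

    def banks(self) -> tuple[FilterBank, FilterBank, FilterBank]:
        return tuple(build_filterbank(self.fs, n, self.f_min, self.f_max, self.T)
                     for n in (self.M, self.N, self.P))


@dataclass(frozen=True)
class FeatureVector:
    """Time-averaged scattering coefficients with their frequency paths.

    ``path_labels`` holds one tuple per coefficient: () for order 0 and
    (l1[, l2[, l3]]) centre frequencies (Hz) for deeper orders.
    """

    values: np.ndarray
    path_labels: tuple[tuple[float, ...], ...]

    def __len__(self) -> int:
        return self.values.size


def enumerate_paths(config: ScatteringConfig) -> list[tuple[float, ...]]:
    """All retained frequency-decreasing paths, in deterministic order."""
    b1, b2, b3 = config.banks()
    paths: list[tuple[float, ...]] = [()]
    paths += [(f1,) for f1 in b1.center_freqs]
    for f1 in b1.center_freqs:
        paths += [(f1, f2) for f2 in b2.center_freqs if f2 < f1]
    for f1 in b1.center_freqs:
        for f2 in b2.center_freqs:
            if f2 < f1:
                paths += [(f1, f2, f3) for f3 in b3.center_freqs if f3 < f2]
    return paths


class _Node:
    __slots__ = ("layer", "label", "fc", "sigma", "length", "parent", "bank")

    def __init__(self, layer, label, fc, sigma, length, parent, bank):
        self.layer = layer
        self.label = label
        self.fc = fc
        self.sigma = sigma
        self.length = length
        self.parent = parent  # index into previous layer's node list
        self.bank = bank


class Scattering1D:
    """Scattering network compiled for a fixed signal length and rate."""

    def __init__(self, config: ScatteringConfig, n_samples: int):
        min_support = int(np.ceil(config.T * config.fs))
        if n_samples < min_support:
            raise ValueError(
                f"signal of {n_samples} samples is shorter than the "
                f"averaging support T*fs = {min_support}")
        self.config = config
        self.n = int(n_samples)
        self.df = config.fs / self.n
        self.banks = config.banks()
        self._build_plan()

    # -- plan ---------------------------------------------------------------

    def _child_length(self, fc: float, sigma: float, layer: int,
                      parent_len: int) -> int:
        """Output grid length for a node: smallest even length supporting the
        node's own filter, its envelope content and the next layer's
        eligible filters."""
        if not self.config.subsample:
            return parent_len
        need = 1.05 * (fc + 4 * sigma)
        need = max(need, 1.15 * 8 * sigma)
        if layer < 3:
            nxt = self.banks[layer]  # bank of layer+1 (0-based index = layer)
            elig = [f + 4 * s for f, s in zip(nxt.center_freqs, nxt.sigmas)
                    if f < fc]
            if elig:
                need = max(need, 1.15 * max(elig))
        length = int(np.ceil(2 * need / self.df))
        length += length % 2
        return int(min(max(length, 16), parent_len))

    def _build_plan(self) -> None:
        b1, b2, b3 = self.banks
        self.layers: list[list[_Node]] = [[], [], []]
        for i, (fc, sg) in enumerate(zip(b1.center_freqs, b1.sigmas)):
            self.layers[0].append(_Node(
                1, (fc,), fc, sg, self._child_length(fc, sg, 1, self.n), None, 0))
        for p, parent in enumerate(self.layers[0]):
            for fc, sg in zip(b2.center_freqs, b2.sigmas):
                if fc < parent.fc:
                    self.layers[1].append(_Node(
                        2, parent.label + (fc,), fc, sg,
                        self._child_length(fc, sg, 2, parent.length), p, 1))
        for p, parent in enumerate(self.layers[1]):
            for fc, sg in zip(b3.center_freqs, b3.sigmas):
                if fc < parent.fc:
                    self.layers[2].append(_Node(
                        3, parent.label + (fc,), fc, sg,
                        self._child_length(fc, sg, 3, parent.length), p, 2))
        self.path_labels: tuple[tuple[float, ...], ...] = tuple(
            [()] + [nd.label for layer in self.layers for nd in layer])
        # full-resolution wavelet gain tables, bins 0 .. n/2-1
        bins = np.arange(self.n // 2) * self.df
        self._psi_tables = [bank.wavelet_gains(bins).astype(np.float32)
                            for bank in self.banks]

    @property
    def n_paths(self) -> int:
        return len(self.path_labels)

    # -- transform ----------------------------------------------------------

    def _layer_pass(self, parent_specs: list[np.ndarray],
                    parent_lens: list[int], nodes: list[_Node],
                    table: np.ndarray) -> list[np.ndarray]:
        """Filter every node from its parent spectrum, modulus included.

        ``parent_specs[p]`` is the (B, m_p) FFT of parent p's signal.
        Returns each node's envelope |u| as a (B, L) real array, batching
        the inverse FFTs of nodes that share an output length.
        """
        groups: dict[int, list[int]] = {}
        for idx, nd in enumerate(nodes):
            groups.setdefault(nd.length, []).append(idx)
        out: list[Optional[np.ndarray]] = [None] * len(nodes)
        for L, idxs in groups.items():
            half = L // 2
            stack = np.empty((len(idxs), parent_specs[0].shape[0], L),
                             dtype=np.complex64)
            stack[:, :, half:] = 0.0
            for j, idx in enumerate(idxs):
                nd = nodes[idx]
                p = 0 if nd.parent is None else nd.parent
                spec = parent_specs[p]
                m = parent_lens[p]
                gains = table[self._filter_index(nd)][:half]
                stack[j, :, :half] = spec[:, :half] * (gains * (L / m))
            env = np.abs(sfft.ifft(stack, axis=-1))
            for j, idx in enumerate(idxs):
                out[idx] = env[j]
        return out  # type: ignore[return-value]

    def _filter_index(self, nd: _Node) -> int:
        return self.banks[nd.bank].center_freqs.index(nd.fc)

    def transform_batch(self, x: np.ndarray) -> np.ndarray:
        """Scattering coefficients for a (B, n) batch of signals."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.n:
            raise ValueError(f"expected length {self.n}, got {x.shape[1]}")
        B = x.shape[0]
        coeffs = [self.banks[0].scale * x.mean(axis=1, keepdims=True)]

        specs = [sfft.fft(x).astype(np.complex64)]
        lens = [self.n]
        for layer_idx in (0, 1, 2):
            nodes = self.layers[layer_idx]
            if not nodes:
                break
            envelopes = self._layer_pass(specs, lens, nodes,
                                         self._psi_tables[layer_idx])
            scale = self.banks[layer_idx].scale
            coeffs.append(np.stack(
                [scale * env.mean(axis=1) for env in envelopes], axis=1))
            if layer_idx == 2 or not self.layers[layer_idx + 1]:
                break
            specs = [sfft.fft(env.astype(np.float64)).astype(np.complex64)
                     for env in envelopes]
            lens = [nd.length for nd in nodes]
        S = np.concatenate([c.reshape(B, -1) for c in coeffs], axis=1)
        if self.config.log:
            S = np.log(self.config.eps + np.abs(S))
        return S

    def transform(self, x: np.ndarray) -> FeatureVector:
        values = self.transform_batch(np.asarray(x)[None, :])[0]
        return FeatureVector(values=values, path_labels=self.path_labels)

    def path_envelopes(self, x: np.ndarray) -> dict[tuple, np.ndarray]:
        """Pre-averaging envelope |...| of every retained path for one
        signal, keyed by frequency path. Diagnostic: energy accounting and
        oracle checks (use ``subsample=False`` for exact Parseval sums)."""
        x = np.asarray(x, dtype=np.float64)
        out: dict[tuple, np.ndarray] = {}
        specs = [sfft.fft(x[None, :]).astype(np.complex64)]
        lens = [self.n]
        for layer_idx in (0, 1, 2):
            nodes = self.layers[layer_idx]
            if not nodes:
                break
            envelopes = self._layer_pass(specs, lens, nodes,
                                         self._psi_tables[layer_idx])
            for nd, env in zip(nodes, envelopes):
                out[nd.label] = env[0]
            if layer_idx == 2 or not self.layers[layer_idx + 1]:
                break
            specs = [sfft.fft(env.astype(np.float64)).astype(np.complex64)
                     for env in envelopes]
            lens = [nd.length for nd in nodes]
        return out

    def transform_frames(self, x: np.ndarray) -> np.ndarray:
        """Low-passed, subsampled path outputs as a (n_paths, n_frames)
        matrix (frame rate 4/T), instead of whole-segment averages. This is
        where the invariance scale T visibly trades time resolution for
        shift stability."""
        x = np.asarray(x, dtype=np.float64)
        duration = self.n / self.config.fs
        n_frames = int(np.ceil(4.0 * duration / self.config.T))
        n_frames += n_frames % 2
        n_frames = min(n_frames, self.n)

        def smooth(u: np.ndarray, bank: FilterBank) -> np.ndarray:
            # low-pass then exact band-limited resample to the frame grid
            m = u.size
            half = n_frames // 2
            spec = sfft.rfft(u)[:half + 1] * bank.lowpass_gain(
                np.arange(half + 1) * self.df)
            return sfft.irfft(spec * (n_frames / m), n=n_frames)

        rows = [smooth(x, self.banks[0])]
        specs = [sfft.fft(x[None, :]).astype(np.complex64)]
        lens = [self.n]
        for layer_idx in (0, 1, 2):
            nodes = self.layers[layer_idx]
            if not nodes:
                break
            envelopes = self._layer_pass(specs, lens, nodes,
                                         self._psi_tables[layer_idx])
            bank = self.banks[layer_idx]
            rows += [smooth(env[0], bank) for env in envelopes]
            if layer_idx == 2 or not self.layers[layer_idx + 1]:
                break
            specs = [sfft.fft(env.astype(np.float64)).astype(np.complex64)
                     for env in envelopes]
            lens = [nd.length for nd in nodes]
        return np.stack(rows, axis=0)


@lru_cache(maxsize=8)
def _compiled(config: ScatteringConfig, n_samples: int) -> Scattering1D:
    return Scattering1D(config, n_samples)


def scattering_transform(wave: Waveform, config: ScatteringConfig
                         ) -> FeatureVector:
    """Scattering feature vector of a single waveform."""
    if abs(wave.fs - config.fs) > 1e-9:
        raise ValueError(f"waveform rate {wave.fs} != config rate {config.fs}")
    return _compiled(config, len(wave)).transform(wave.samples)


def features_for_dataset(segments: Sequence[Waveform],
                         config: ScatteringConfig,
                         batch: int = 16) -> tuple[np.ndarray, tuple]:
    """Feature matrix (one row per segment) and the shared path labels."""
    if not segments:
        raise ValueError("no segments given")
    n = len(segments[0])
    if any(len(s) != n or abs(s.fs - segments[0].fs) > 1e-9 for s in segments):
        raise ValueError("all segments must share length and sampling rate")
    net = _compiled(config, n)
    rows = []
    for start in range(0, len(segments), batch):
        block = np.stack([s.samples for s in segments[start:start + batch]])
        rows.append(net.transform_batch(block))
    return np.concatenate(rows, axis=0), net.path_labels


class ScatteringTransform(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer computing scattering features.

    Input ``X`` is a (n_segments, n_samples) array of equal-length signal
    segments sampled at ``fs``; output is the (n_segments, n_paths) matrix
    of (optionally log-scaled) scattering coefficients. Stateless apart from
    compiling the filter plan for the segment length seen in ``fit``.
    """

    def __init__(self, M: int = 56, N: int = 30, P: int = 9, T: float = 0.5,
                 fs: float = 1500.0, f_min: float = 20.0, f_max: float = 700.0,
                 log: bool = False, eps: float = 1e-3, subsample: bool = True):
        self.M = M
        self.N = N
        self.P = P
        self.T = T
        self.fs = fs
        self.f_min = f_min
        self.f_max = f_max
        self.log = log
        self.eps = eps
        self.subsample = subsample

    def _config(self) -> ScatteringConfig:
        return ScatteringConfig(M=self.M, N=self.N, P=self.P, T=self.T,
                                fs=self.fs, f_min=self.f_min, f_max=self.f_max,
                                log=self.log, eps=self.eps,
                                subsample=self.subsample)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be (n_segments, n_samples)")
        self.n_features_in_ = X.shape[1]
        net = _compiled(self._config(), X.shape[1])
        self.path_labels_ = net.path_labels
        self.n_paths_ = net.n_paths
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_features_in_"):
            raise RuntimeError("ScatteringTransform is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"X must be (n_segments, {self.n_features_in_})")
        net = _compiled(self._config(), X.shape[1])
        out = []
        for start in range(0, X.shape[0], 16):
            out.append(net.transform_batch(X[start:start + 16]))
        return np.concatenate(out, axis=0)
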