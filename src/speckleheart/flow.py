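"""Dense gradient-based optical flow for speckle tracking.

Implements Farneback's polynomial-expansion method: each frame is locally
approximated by a quadratic polynomial f(u) ~ c + b'u + u'Au via a
Gaussian-weighted least-squares fit (computed with separable correlations);
a rigid translation d between two frames then satisfies A d = -(b2 - b1)/2,
which is solved per pixel after averaging the normal equations over a
spatial window. The spatial mean of the per-pixel displacement map is the
vibration sample for that frame pair, and the sequence of means over a
video, projected onto its principal axis, is the raw sound signal.

Conventions: displacement (dx, dy) = (column, row) motion of the pattern
from frame a to frame b; row index increases downward. Boundary handling is
periodic by default, matching the simulator's Fourier translation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .signals import Waveform
from .speckle import SpeckleVideo


class LowTextureWarning(UserWarning):
    """Frame lacks the intensity texture needed for reliable tracking."""


@dataclass(frozen=True)
class FlowParams:
    """Parameters of the polynomial-expansion flow estimator.

    ``poly_ksize``/``poly_sigma`` control the Gaussian applicability of the
    local quadratic fit; ``win_size`` is the side of the Gaussian averaging
    window used when solving for the displacement; ``iterations`` adds
    warp-and-refine passes (useful above ~1 px/frame); ``levels`` enables a
    coarse-to-fine pyramid for large motions. ``texture_threshold`` is the
    minimum frame intensity variance (in squared counts) below which a frame
    is flagged as untrackable.
    """

    poly_ksize: int = 7
    poly_sigma: float = 1.2
    win_size: int = 15
    iterations: int = 1
    levels: int = 1
    boundary: str = "wrap"
    texture_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.poly_ksize % 2 == 0 or self.poly_ksize < 3:
            raise ValueError("poly_ksize must be odd and >= 3")
        if self.win_size < 3:
            raise ValueError("win_size must be >= 3")
        if self.iterations < 1 or self.levels < 1:
            raise ValueError("iterations and levels must be >= 1")


@dataclass(frozen=True)
class FlowField:
    """Per-pixel displacement map between two frames (px)."""

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self) -> None:
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx and dy must share a shape")


@dataclass(frozen=True)
class DisplacementTrace:
    """Frame-pair mean displacements of a video and their scalar projection.

    ``vectors`` has one (dx, dy) row per consecutive frame pair; ``scalar``
    is the signed projection of the (centred) vectors onto their first
    principal axis, sampled at the video frame rate — the raw sound signal.
    ``low_texture`` flags pairs where a frame fell below the texture
    threshold and a zero vector was substituted.
    """

    vectors: np.ndarray  # (n_pairs, 2)
    fs: float
    scalar: Waveform
    low_texture: np.ndarray  # (n_pairs,) bool

    def __post_init__(self) -> None:
        if len(self.scalar) != len(self.vectors):
            raise ValueError("scalar length must match the vector count")


# ---------------------------------------------------------------------------
# polynomial expansion


def _expansion_kernels(ksize: int, sigma: float):
    """1-D applicability kernels g, g*u, g*u^2 and the inverse Gram blocks."""
    r = (ksize - 1) // 2
    u = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-0.5 * (u / sigma) ** 2)
    g /= g.sum()
    k0, k1, k2 = g, g * u, g * u * u
    # Gram matrix of the basis [1, x, y, x^2, y^2, xy] under the separable
    # applicability; only the {1, x^2, y^2} block and three diagonal entries
    # are non-zero by symmetry.
    s0, s2, s4 = k0.sum(), k2.sum(), (g * u ** 4).sum()
    block = np.array([[s0, s2, s2],
                      [s2, s4, s2 * s2],
                      [s2, s2 * s2, s4]])
    block_inv = np.linalg.inv(block)
    gxx = s2 * s2  # Gram entry for x^2-type and xy basis functions
    return (k0.astype(np.float32), k1.astype(np.float32), k2.astype(np.float32),
            block_inv, 1.0 / s2 / s0, 1.0 / gxx)


def _poly_expansion(frames: np.ndarray, params: FlowParams):
    """Quadratic expansion coefficients for a (T, H, W) frame stack.

    Returns bx, by, a11, a12, a22 as (T, H, W) float32 arrays, where the
    local model is f(u) ~ c + bx*x + by*y + a11*x^2 + 2*a12*xy + a22*y^2.
    """
    k0, k1, k2, block_inv, inv_lin, inv_xy = _expansion_kernels(
        params.poly_ksize, params.poly_sigma)
    mode = params.boundary
    ax_x, ax_y = frames.ndim - 1, frames.ndim - 2

    cx0 = ndimage.correlate1d(frames, k0, axis=ax_x, mode=mode)
    cx1 = ndimage.correlate1d(frames, k1, axis=ax_x, mode=mode)
    cx2 = ndimage.correlate1d(frames, k2, axis=ax_x, mode=mode)

    m1 = ndimage.correlate1d(cx0, k0, axis=ax_y, mode=mode)   # 1
    m3 = ndimage.correlate1d(cx0, k1, axis=ax_y, mode=mode)   # y
    m5 = ndimage.correlate1d(cx0, k2, axis=ax_y, mode=mode)   # y^2
    m2 = ndimage.correlate1d(cx1, k0, axis=ax_y, mode=mode)   # x
    m6 = ndimage.correlate1d(cx1, k1, axis=ax_y, mode=mode)   # xy
    m4 = ndimage.correlate1d(cx2, k0, axis=ax_y, mode=mode)   # x^2

    bx = np.float32(inv_lin) * m2
    by = np.float32(inv_lin) * m3
    # coupled {1, x^2, y^2} block; the constant coefficient is not needed
    a11 = (np.float32(block_inv[1, 0]) * m1 + np.float32(block_inv[1, 1]) * m4
           + np.float32(block_inv[1, 2]) * m5)
    a22 = (np.float32(block_inv[2, 0]) * m1 + np.float32(block_inv[2, 1]) * m4
           + np.float32(block_inv[2, 2]) * m5)
    a12 = np.float32(0.5 * inv_xy) * m6
    return bx, by, a11, a12, a22


def _window_kernel(win_size: int) -> np.ndarray:
    u = np.arange(win_size, dtype=np.float64) - (win_size - 1) / 2
    sigma = max(win_size / 4.0, 1.0)
    w = np.exp(-0.5 * (u / sigma) ** 2)
    return (w / w.sum()).astype(np.float32)


def _solve_pairs(exp_a, exp_b, params: FlowParams):
    """Displacement fields from the expansions of two frame (stacks)."""
    bx1, by1, a11_1, a12_1, a22_1 = exp_a
    bx2, by2, a11_2, a12_2, a22_2 = exp_b
    a11 = 0.5 * (a11_1 + a11_2)
    a12 = 0.5 * (a12_1 + a12_2)
    a22 = 0.5 * (a22_1 + a22_2)
    db1 = 0.5 * (bx1 - bx2)
    db2 = 0.5 * (by1 - by2)

    g11 = a11 * a11 + a12 * a12
    g12 = a12 * (a11 + a22)
    g22 = a12 * a12 + a22 * a22
    h1 = a11 * db1 + a12 * db2
    h2 = a12 * db1 + a22 * db2

    w = _window_kernel(params.win_size)
    mode = params.boundary
    ax_x, ax_y = g11.ndim - 1, g11.ndim - 2
    for arr in (g11, g12, g22, h1, h2):
        ndimage.correlate1d(arr, w, axis=ax_x, mode=mode, output=arr)
        ndimage.correlate1d(arr, w, axis=ax_y, mode=mode, output=arr)

    det = g11 * g22 - g12 * g12
    eps = np.float32(1e-6) * (np.mean(det) + np.float32(1e-20))
    det = det + eps
    dx = (g22 * h1 - g12 * h2) / det
    dy = (g11 * h2 - g12 * h1) / det
    return dx, dy


def _warp(frame: np.ndarray, dx: np.ndarray, dy: np.ndarray,
          boundary: str) -> np.ndarray:
    h, w = frame.shape
    yy, xx = np.meshgrid(np.arange(h, dtype=np.float32),
                         np.arange(w, dtype=np.float32), indexing="ij")
    mode = "grid-wrap" if boundary == "wrap" else "nearest"
    return ndimage.map_coordinates(frame, [yy + dy, xx + dx], order=1,
                                   mode=mode)


def _downsample(frame: np.ndarray) -> np.ndarray:
    h, w = frame.shape
    return frame[: h - h % 2, : w - w % 2].reshape(h // 2, 2, w // 2, 2).mean(
        axis=(1, 3))


def dense_flow(frame_a: np.ndarray, frame_b: np.ndarray,
               params: FlowParams = FlowParams()) -> FlowField:
    """Per-pixel displacement map from ``frame_a`` to ``frame_b``.

    Coarse-to-fine over ``params.levels`` pyramid levels, with
    ``params.iterations`` warp-and-refine passes per level. Low-texture
    frames produce a :class:`LowTextureWarning` and a zero field.
    """
    a = np.asarray(frame_a, dtype=np.float32)
    b = np.asarray(frame_b, dtype=np.float32)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("frames must be 2-D")
    if min(np.var(a), np.var(b)) < params.texture_threshold:
        warnings.warn("frame texture below threshold; returning zero flow",
                      LowTextureWarning, stacklevel=2)
        return FlowField(dx=np.zeros_like(a), dy=np.zeros_like(a))

    pyr = [(a, b)]
    for _ in range(params.levels - 1):
        if min(pyr[-1][0].shape) < 2 * params.poly_ksize:
            break
        pyr.append((_downsample(pyr[-1][0]), _downsample(pyr[-1][1])))

    dx = dy = None
    for la, lb in reversed(pyr):
        if dx is None:
            dx = np.zeros_like(la)
            dy = np.zeros_like(la)
        else:
            dx = 2.0 * np.kron(dx, np.ones((2, 2), dtype=np.float32))[
                : la.shape[0], : la.shape[1]]
            dy = 2.0 * np.kron(dy, np.ones((2, 2), dtype=np.float32))[
                : la.shape[0], : la.shape[1]]
        exp_a = _poly_expansion(la[None], params)
        for _ in range(params.iterations):
            moved = _warp(lb, dx, dy, params.boundary) if (
                np.any(dx) or np.any(dy)) else lb
            exp_b = _poly_expansion(moved[None], params)
            ddx, ddy = _solve_pairs(exp_a, exp_b, params)
            dx = dx + ddx[0]
            dy = dy + ddy[0]
    return FlowField(dx=dx, dy=dy)


def mean_displacement(flow: FlowField) -> np.ndarray:
    """Arithmetic mean of the per-pixel displacement vectors, (dx, dy) px."""
    return np.array([float(np.mean(flow.dx)), float(np.mean(flow.dy))])


def _principal_projection(vectors: np.ndarray) -> np.ndarray:
    """Signed projection of (n, 2) vectors onto their first principal axis.

    The axis sign is fixed so its largest-magnitude component is positive
    (the overall sign of the sound is arbitrary; spectra are unaffected).
    """
    centred = vectors - vectors.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return centred @ axis


def extract_sound(video: SpeckleVideo, params: FlowParams = FlowParams(),
                  chunk_frames: int = 2048) -> DisplacementTrace:
    """Recover the raw vibration signal from a speckle video.

    Runs dense flow over every consecutive frame pair (expansions are
    computed once per frame and shared between the two pairs that use it),
    averages each displacement map to a single (dx, dy) vector, and projects
    the vector sequence onto its first principal axis to obtain the scalar
    sound trace at the video frame rate. Frames whose intensity variance is
    below ``params.texture_threshold`` yield a flagged zero vector.
    """
    n = len(video)
    if n < 2:
        raise ValueError("need at least 2 frames to extract sound")
    variances = video.frames.reshape(n, -1).astype(np.float32).var(axis=1)
    low_tex_frame = variances < params.texture_threshold
    vectors = np.zeros((n - 1, 2), dtype=np.float64)

    prev_exp = None
    for start in range(0, n - 1, chunk_frames):
        stop = min(start + chunk_frames + 1, n)  # overlap one frame
        block = video.frames[start:stop].astype(np.float32)
        exp = _poly_expansion(block, params)
        exp_a = tuple(f[:-1] for f in exp)
        exp_b = tuple(f[1:] for f in exp)
        dx, dy = _solve_pairs(exp_a, exp_b, params)
        npairs = stop - start - 1
        vectors[start:start + npairs, 0] = dx.reshape(npairs, -1).mean(axis=1)
        vectors[start:start + npairs, 1] = dy.reshape(npairs, -1).mean(axis=1)
        del exp, exp_a, exp_b, dx, dy

    low_texture = low_tex_frame[:-1] | low_tex_frame[1:]
    if np.any(low_texture):
        warnings.warn(f"{int(low_texture.sum())} frame pair(s) below the "
                      "texture threshold; zero vectors substituted",
                      LowTextureWarning, stacklevel=2)
        vectors[low_texture] = 0.0
    scalar = _principal_projection(vectors)
    return DisplacementTrace(
        vectors=vectors, fs=video.frame_rate,
        scalar=Waveform(samples=scalar, fs=video.frame_rate),
        low_texture=low_texture)
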