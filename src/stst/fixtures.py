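"""Seeded synthetic videos with analytically known ground-truth motion.

These generators exist so that every stage of the pipeline — motion-energy
features, optical-flow statistics, phase scrambling, full synthesis runs —
can be tested against known answers without downloading any data.  All
translation is toroidal (wraparound via Fourier phase ramps), which makes
global statistics such as the mean intensity exactly stationary.

Image coordinates: x grows rightward (columns), y grows downward (rows);
a motion direction of 0 rad is rightward, pi/2 is downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .videoio import Video


@dataclass
class SyntheticVideo:
    """A fixture video plus its ground-truth per-frame-pair flow."""

    video: Video
    flow_speed: np.ndarray  # (T-1,) px/frame
    flow_direction: np.ndarray  # (T-1,) radians in [0, 2pi)


def _per_pair(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"need a scalar or length-{n} sequence, got shape {arr.shape}")
    return arr


def _fourier_shift(frame: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Exact toroidal subpixel translation of an (H, W) image."""
    H, W = frame.shape
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    return np.real(np.fft.ifft2(np.fft.fft2(frame) * np.exp(-2j * np.pi * (fy * dy + fx * dx))))


def drifting_grating(
    H: int,
    W: int,
    T: int,
    spatial_freq: float = 4.0,
    direction: float | np.ndarray = 0.0,
    speed: float | np.ndarray = 1.0,
    seed: int = 0,
    contrast: float = 0.4,
    fps: float = 30.0,
) -> SyntheticVideo:
    """Sinusoidal luminance grating translating at a known velocity.

    `spatial_freq` is in cycles per frame width; `direction`/`speed` may be
    scalars or per-frame-pair sequences (length T-1).  The seed only draws a
    random starting phase.
    """
    dirs = _per_pair(direction, T - 1)
    spd = _per_pair(speed, T - 1)
    rng = np.random.default_rng(seed)
    phase0 = rng.uniform(0, 2 * np.pi)
    wavelength = W / spatial_freq
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    frames = []
    ox = oy = 0.0
    for t in range(T):
        if t > 0:
            ox += spd[t - 1] * np.cos(dirs[t - 1])
            oy += spd[t - 1] * np.sin(dirs[t - 1])
        u = (xx - ox) * np.cos(dirs[min(t, T - 2)]) + (yy - oy) * np.sin(dirs[min(t, T - 2)])
        lum = 0.5 + contrast * np.cos(2 * np.pi * u / wavelength + phase0)
        frames.append(np.repeat(lum[:, :, None], 3, axis=2))
    video = Video(np.clip(np.stack(frames), 0, 1), fps=fps)
    return SyntheticVideo(video, spd, np.mod(dirs, 2 * np.pi))


def translating_texture(
    H: int,
    W: int,
    T: int,
    speed: float | np.ndarray = 2.0,
    direction: float | np.ndarray = 0.0,
    seed: int = 0,
    cutoff: float = 0.15,
    contrast_profile: np.ndarray | None = None,
    channel_means: np.ndarray | None = None,
    fps: float = 30.0,
) -> SyntheticVideo:
    """Smooth seeded noise patch rigidly translating with wraparound.

    The base texture is low-pass-filtered Gaussian noise per RGB channel,
    rescaled into [0.1, 0.9]; translation is an exact toroidal Fourier
    shift, so the per-frame mean is constant to machine precision.

    `contrast_profile` (length T, values in (0, 1]) scales each frame's
    deviation from its channel means, giving a known time-varying contrast
    while leaving the mean intensity untouched.  `channel_means` (3 values in
    (0, 1)) recenters the channels to impose a color palette.
    """
    dirs = _per_pair(direction, T - 1)
    spd = _per_pair(speed, T - 1)
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    lowpass = np.exp(-(fx**2 + fy**2) / (2 * cutoff**2))
    base = np.empty((H, W, 3))
    for c in range(3):
        tex = np.real(np.fft.ifft2(np.fft.fft2(rng.standard_normal((H, W))) * lowpass))
        lo, hi = tex.min(), tex.max()
        base[:, :, c] = 0.1 + 0.8 * (tex - lo) / (hi - lo)
    if channel_means is not None:
        mu = base.mean(axis=(0, 1))
        base = np.clip(base - mu + np.asarray(channel_means, float), 0.02, 0.98)
    profile = np.ones(T) if contrast_profile is None else np.asarray(contrast_profile, float)
    if profile.shape != (T,):
        raise ValueError(f"contrast_profile must have length {T}")
    mu = base.mean(axis=(0, 1))
    frames = []
    ox = oy = 0.0
    for t in range(T):
        if t > 0:
            ox += spd[t - 1] * np.cos(dirs[t - 1])
            oy += spd[t - 1] * np.sin(dirs[t - 1])
            shifted = np.stack([_fourier_shift(base[:, :, c], oy, ox) for c in range(3)], axis=-1)
        else:
            shifted = base
        frames.append(mu + profile[t] * (shifted - mu))
    video = Video(np.clip(np.stack(frames), 0, 1), fps=fps)
    return SyntheticVideo(video, spd, np.mod(dirs, 2 * np.pi))


def colored_blobs(
    H: int,
    W: int,
    T: int,
    palette: np.ndarray,
    proportions: np.ndarray | None = None,
    seed: int = 0,
    fps: float = 30.0,
) -> Video:
    """Static frames tiled from the given RGB colors in stated proportions.

    Colors are laid out as vertical stripes whose widths follow
    `proportions` (equal by default); the seed shuffles the stripe order.
    """
    palette = np.atleast_2d(np.asarray(palette, dtype=np.float64))
    k = palette.shape[0]
    props = np.full(k, 1.0 / k) if proportions is None else np.asarray(proportions, float)
    props = props / props.sum()
    rng = np.random.default_rng(seed)
    order = rng.permutation(k)
    edges = np.rint(np.cumsum(np.concatenate([[0.0], props[order]])) * W).astype(int)
    frame = np.empty((H, W, 3))
    for i, ci in enumerate(order):
        frame[:, edges[i] : edges[i + 1]] = palette[ci]
    # guard against rounding leaving the last column unassigned
    frame[:, edges[-1] :] = palette[order[-1]]
    return Video(np.repeat(frame[None], T, axis=0), fps=fps)
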