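"""Spatiotemporal phase scrambling (STPS): the baseline generator.

Three steps: (1) one random 2D phase field per channel is added to the phase
spectrum of every frame (the same field for all frames); (2) a random phase
field is added to the 3D spatiotemporal spectrum, per channel; (3) the color
distribution of each scrambled frame is transferred back to the matching
original frame.  Phase-only steps preserve the amplitude spectra exactly.

Realness of the outputs is guaranteed by drawing the random phases as the
phase spectrum of white Gaussian noise, which is Hermitian-symmetric by
construction (conjugate frequency pairs get opposite phases; DC and Nyquist
bins stay real).  The DC phase offset is zeroed so means are untouched.
"""

from __future__ import annotations

import numpy as np

from .colortransfer import pdf_transfer
from .videoio import Video


def _random_phase_field(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Hermitian-symmetric uniform random phases with zero DC offset."""
    phases = np.angle(np.fft.fftn(rng.standard_normal(shape)))
    phases.flat[0] = 0.0  # leave the DC component untouched
    return phases


def phase_scramble_2d(video: Video, seed: int = 0, clip: bool = True) -> Video:
    """Add one random 2D phase field (per channel) to every frame's spectrum.

    With ``clip=False`` the (possibly out-of-range) inverse transform is
    returned untouched, preserving the 2D amplitude spectra exactly; the
    default clips to [0, 1] for displayable output.
    """
    px = video.pixels
    T, H, W, C = px.shape
    rng = np.random.default_rng(seed)
    out = np.empty_like(px)
    fields = [_random_phase_field((H, W), rng) for _ in range(C)]
    for c in range(C):
        shift = np.exp(1j * fields[c])
        for t in range(T):
            spec = np.fft.fft2(px[t, :, :, c])
            out[t, :, :, c] = np.real(np.fft.ifft2(spec * shift))
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return _video_unchecked(out, video.fps, clip)


def phase_scramble_3d(video: Video, seed: int = 0, clip: bool = True) -> Video:
    """Add a random 3D phase field to the full spatiotemporal spectrum."""
    px = video.pixels
    T, H, W, C = px.shape
    rng = np.random.default_rng(seed)
    out = np.empty_like(px)
    for c in range(C):
        shift = np.exp(1j * _random_phase_field((T, H, W), rng))
        spec = np.fft.fftn(px[:, :, :, c])
        out[:, :, :, c] = np.real(np.fft.ifftn(spec * shift))
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return _video_unchecked(out, video.fps, clip)


def _video_unchecked(pixels, fps, clipped: bool) -> Video:
    if clipped:
        return Video(pixels, fps=fps)
    v = Video.__new__(Video)  # bypass the [0,1] range check deliberately
    v.pixels = pixels
    v.fps = fps
    return v


def stps_generate(video: Video, seed: int = 0, color_iterations: int = 20) -> Video:
    """Full STPS pipeline: 2D scramble, 3D scramble, per-frame color transfer.

    The color reference for frame t is the original video's frame t.
    """
    scrambled = phase_scramble_3d(phase_scramble_2d(video, seed=seed), seed=seed + 1)
    out = np.empty_like(scrambled.pixels)
    for t in range(len(scrambled)):
        out[t] = pdf_transfer(
            scrambled.pixels[t], video.pixels[t], iterations=color_iterations, seed=seed + 2 + t
        )
    return Video(out, fps=video.fps)
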