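"""Video containers, frame I/O, color conversion and octave geometry.

A video is an ordered stack of RGB (or grayscale) frames with float pixel
intensities in [0, 1]; quantization to 8 bits happens only when writing to
disk.  Frame indices are 1-based in the documentation (frame t, its
predecessor t-1) and 0-based in code; the conversion happens here and only
here.

The lossless interchange format is a directory of zero-padded, numbered PNG
frames (lexical order = temporal order).  Container formats (MP4 et al.) are
delegated to imageio and are available only where an ffmpeg plugin is
installed.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio

from .autodiff import _lin_weights

#: Luma coefficients for RGB -> grayscale (ITU-R BT.601).
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

_FRAME_RE = re.compile(r"\.(png|tif|tiff|bmp|jpg|jpeg)$", re.IGNORECASE)


class VideoIOError(ValueError):
    """Unreadable, unwritable or malformed video input."""


@dataclass
class Video:
    """An ordered frame stack: pixels (T, H, W, C) in [0, 1], fps metadata."""

    pixels: np.ndarray
    fps: float = 30.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 4:
            raise VideoIOError("video pixels must have shape (T, H, W, C)")
        if self.pixels.shape[0] < 2:
            raise VideoIOError("a video needs at least 2 frames")
        if self.pixels.shape[3] not in (1, 3):
            raise VideoIOError("channel count must be 1 or 3")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise VideoIOError("pixel values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.pixels.shape

    def __len__(self) -> int:
        return self.pixels.shape[0]

    def frame(self, t: int) -> np.ndarray:
        """Frame t (1-based, matching the t / t-1 notation)."""
        if not 1 <= t <= len(self):
            raise IndexError(f"frame index {t} outside 1..{len(self)}")
        return self.pixels[t - 1]


def _quantize(frame: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(frame * 255.0), 0, 255).astype(np.uint8)


def read_video(path: str | os.PathLike) -> Video:
    """Read a video from a frame directory or (if supported) a container."""
    path = os.fspath(path)
    if os.path.isdir(path):
        names = sorted(n for n in os.listdir(path) if _FRAME_RE.search(n))
        if len(names) < 2:
            raise VideoIOError(f"{path}: need at least 2 frame images, found {len(names)}")
        frames = [iio.imread(os.path.join(path, n)) for n in names]
        fps = 30.0
        meta = os.path.join(path, "fps.txt")
        if os.path.exists(meta):
            fps = float(open(meta).read().strip())
    else:
        if not os.path.exists(path):
            raise VideoIOError(f"{path}: no such file")
        try:
            frames = list(iio.imread(path, index=None))
            fps = float(iio.immeta(path).get("fps", 30.0))
        except Exception as exc:  # pragma: no cover - depends on plugins
            raise VideoIOError(f"{path}: cannot decode ({exc})") from exc
    arr = np.stack([np.atleast_3d(f) for f in frames]).astype(np.float64)
    if arr.dtype != np.float64:  # pragma: no cover
        arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return Video(np.clip(arr, 0.0, 1.0), fps=fps)


def write_video(video: Video, path: str | os.PathLike, lossless: bool = True) -> None:
    """Write a video; lossless mode emits a PNG frame directory."""
    path = os.fspath(path)
    if lossless:
        os.makedirs(path, exist_ok=True)
        width = max(5, len(str(len(video))))
        for i in range(len(video)):
            frame = _quantize(video.pixels[i])
            if frame.shape[-1] == 1:
                frame = frame[..., 0]
            iio.imwrite(os.path.join(path, f"{i:0{width}d}.png"), frame)
        with open(os.path.join(path, "fps.txt"), "w") as fh:
            fh.write(f"{video.fps}\n")
    else:
        try:
            iio.imwrite(path, [_quantize(f) for f in video.pixels], fps=video.fps)
        except Exception as exc:
            raise VideoIOError(
                f"{path}: lossy container write needs an ffmpeg imageio plugin ({exc})"
            ) from exc


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Luma projection 0.299 R + 0.587 G + 0.114 B, keeping a channel axis."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise VideoIOError("to_grayscale expects an (H, W, 3) RGB frame")
    return (frame @ GRAY_WEIGHTS)[..., None]


def resize_bilinear(frame: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resize (half-pixel centers, no antialias prefilter)."""
    if height < 1 or width < 1:
        raise VideoIOError("target size must be positive")
    frame = np.asarray(frame, dtype=np.float64)
    H, W = frame.shape[:2]
    Mh = _lin_weights(height, H)
    Mw = _lin_weights(width, W)
    out = np.einsum("oh,hwc,pw->opc", Mh, np.atleast_3d(frame), Mw, optimize=True)
    return np.clip(out, 0.0, 1.0)


def octave_size(height: int, width: int, sigma: float, octave: int) -> tuple[int, int]:
    """Frame resolution at octave exponent `octave`: trunc(H * sigma**o).

    Truncation toward zero reproduces the coarse-to-fine schedule geometry
    (e.g. 360x640 at sigma 1.5 gives 240x426 and 160x284).
    """
    if sigma <= 1:
        raise VideoIOError("octave scale sigma must exceed 1")
    if octave > 0:
        raise VideoIOError("octave exponents are <= 0 (0 = native resolution)")
    # epsilon guards float dust (360 * 1.5**-1 = 239.99999999999997 -> 240)
    h = int(height * sigma**octave + 1e-9)
    w = int(width * sigma**octave + 1e-9)
    if h < 1 or w < 1:
        raise VideoIOError("octave size collapses below one pixel")
    return h, w
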