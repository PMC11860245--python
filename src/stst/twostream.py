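"""Two-stream feature models: spatial S(x_t) and temporal T(x_t, x_{t-1}).

Both streams expose named layer activations taken after the convolution and
its nonlinearity, reshaped to (N, M) matrices of N filters by M spatial
locations (filters major, row-major spatial order).  Any differentiable
model with this surface can drive the synthesis; three families ship here:

* ``vgg19`` — the VGG-19 convolutional feature hierarchy (texture layers
  conv1_1 ... conv5_1) with average pooling.  Weights are seeded random by
  default and can be loaded from an ``.npz`` file; no download is attempted.
* ``msoe`` — an analytic multiscale spacetime-oriented energy model: the
  frame pair is grayscaled, a Gaussian pyramid is built, quadrature pairs of
  oriented Gabor filters are combined across the two frames into
  direction-selective motion energies (right/left/down/up plus a static
  channel), divisively normalized across channels, and the per-scale maps
  are upsampled and concatenated into the ``concat`` layer.  Zero-mean
  filters make the model exactly invariant to global luminance offsets.
* ``fixture`` — tiny seeded random conv nets (arity 1 or 2) for desk-scale
  tests.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Var, as_var
from .videoio import GRAY_WEIGHTS


class ConfigError(ValueError):
    pass


def _prep(frame) -> Var:
    """Accept an (H, W, C) ndarray or a (C, H, W) Var; return (C, H, W) Var."""
    if isinstance(frame, Var):
        return frame
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[..., None]
    return Var(np.moveaxis(arr, -1, 0))


def _flatten(fmap: Var) -> Var:
    f, h, w = fmap.shape
    return fmap.reshape(f, h * w)


class StreamModel:
    """Base class: differentiable map from frame(s) to named feature maps."""

    input_arity: int = 1
    layer_names: tuple[str, ...] = ()

    def forward(self, *frames: Var) -> dict[str, Var]:
        raise NotImplementedError

    def activations(self, *frames, layers=None) -> dict[str, Var]:
        """Named (N, M) activation matrices for the requested layers."""
        layers = list(self.layer_names) if layers is None else list(layers)
        unknown = [l for l in layers if l not in self.layer_names]
        if unknown:
            raise ConfigError(f"unknown layer(s) {unknown}; model has {list(self.layer_names)}")
        if len(frames) != self.input_arity:
            raise ValueError(f"model expects {self.input_arity} frame(s), got {len(frames)}")
        fmaps = self.forward(*(_prep(f) for f in frames))
        return {l: _flatten(fmaps[l]) for l in layers}


def spatial_forward(model: StreamModel, x, layers) -> dict[str, np.ndarray]:
    if model.input_arity != 1:
        raise ValueError("spatial_forward requires an arity-1 model")
    return {k: v.value for k, v in model.activations(x, layers=layers).items()}


def temporal_forward(model: StreamModel, x_t, x_tm1, layers) -> dict[str, np.ndarray]:
    if model.input_arity != 2:
        raise ValueError("temporal_forward requires an arity-2 model")
    a, b = np.asarray(x_t), np.asarray(x_tm1)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return {k: v.value for k, v in model.activations(x_t, x_tm1, layers=layers).items()}


# -- fixture nets -----------------------------------------------------------


class FixtureNet(StreamModel):
    """Small seeded random conv net (<=3 layers, <=8 filters) for testing."""

    def __init__(self, seed: int = 0, arity: int = 1, in_channels: int = 3):
        rng = np.random.default_rng(seed)
        self.input_arity = arity
        cin = in_channels * arity
        widths = [6, 8]
        self.weights = []
        for cout in widths:
            w = rng.standard_normal((cout, cin, 3, 3)) * np.sqrt(2.0 / (cin * 9))
            self.weights.append(w)
            cin = cout
        self.layer_names = tuple(f"conv{i + 1}" for i in range(len(widths)))

    def forward(self, *frames: Var) -> dict[str, Var]:
        x = frames[0] if len(frames) == 1 else ad.concat(list(frames), axis=0)
        out = {}
        for name, w in zip(self.layer_names, self.weights):
            x = ad.conv2d(x, w).relu()
            out[name] = x
        return out


def make_fixture_model(seed: int, arity: int = 1) -> StreamModel:
    if arity not in (1, 2):
        raise ValueError("arity must be 1 or 2")
    return FixtureNet(seed=seed, arity=arity)


# -- VGG-19 spatial stream ---------------------------------------------------

_VGG_PLAN = [
    ("conv1_1", 64), ("conv1_2", 64), ("pool1", None),
    ("conv2_1", 128), ("conv2_2", 128), ("pool2", None),
    ("conv3_1", 256), ("conv3_2", 256), ("conv3_3", 256), ("conv3_4", 256), ("pool3", None),
    ("conv4_1", 512), ("conv4_2", 512), ("conv4_3", 512), ("conv4_4", 512), ("pool4", None),
    ("conv5_1", 512),
]


class VGG19Features(StreamModel):
    """VGG-19 conv hierarchy up to conv5_1, with 2x average pooling.

    Average pooling (rather than max) is the common choice for texture
    synthesis and keeps gradients smooth.  Weights: seeded He init, or load
    an ``.npz`` with arrays ``<layer>_W`` of shape (C_out, C_in, 3, 3) and
    optional ``<layer>_b``.
    """

    input_arity = 1

    def __init__(self, seed: int = 0, weights_path: str | None = None):
        self.layer_names = tuple(n for n, w in _VGG_PLAN if w is not None)
        rng = np.random.default_rng(seed)
        self.params: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        cin = 3
        for name, cout in _VGG_PLAN:
            if cout is None:
                continue
            w = (rng.standard_normal((cout, cin, 3, 3)) * np.sqrt(2.0 / (cin * 9))).astype(np.float32)
            self.params[name] = (w, np.zeros(cout, dtype=np.float32))
            cin = cout
        if weights_path is not None:
            self.load_weights(weights_path)

    def load_weights(self, path: str) -> None:
        data = np.load(path)
        for name in self.layer_names:
            if f"{name}_W" not in data:
                raise ConfigError(f"weights file lacks array {name}_W")
            w = np.asarray(data[f"{name}_W"], dtype=np.float32)
            b = np.asarray(data.get(f"{name}_b", np.zeros(w.shape[0])), dtype=np.float32)
            if w.shape != self.params[name][0].shape:
                raise ConfigError(f"{name}_W has shape {w.shape}")
            self.params[name] = (w, b)

    def forward(self, x: Var) -> dict[str, Var]:
        out = {}
        for name, cout in _VGG_PLAN:
            if cout is None:
                x = ad.avg_pool2(x)
                continue
            w, b = self.params[name]
            x = ad.conv2d(x, w.astype(np.float64), b.astype(np.float64)).relu()
            out[name] = x
        return out


# -- analytic MSOE temporal stream -------------------------------------------


def _gabor_pair(ksize: int, wavelength: float, sigma: float, along: str):
    """Even/odd quadrature Gabor pair modulated along 'x' or 'y', zero-mean."""
    r = np.arange(ksize) - (ksize - 1) / 2
    yy, xx = np.meshgrid(r, r, indexing="ij")
    env = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    u = xx if along == "x" else yy
    even = env * np.cos(2 * np.pi * u / wavelength)
    odd = env * np.sin(2 * np.pi * u / wavelength)
    even = even - env * (even.sum() / env.sum())  # kill DC response
    even /= np.linalg.norm(even)
    odd /= np.linalg.norm(odd)
    return even, odd


def _binomial5() -> np.ndarray:
    b = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
    return np.outer(b, b)


class MSOE(StreamModel):
    """Multiscale spacetime-oriented energy model over a frame pair.

    Channels per scale (in order): static, rightward, leftward, downward,
    upward motion energy, divisively normalized so the five channels sum to
    at most one per pixel.  Layers: ``scale0`` (finest) ... ``scale{n-1}``
    and ``concat`` (all scales upsampled to the input resolution).
    """

    input_arity = 2
    CHANNELS = ("static", "right", "left", "down", "up")

    def __init__(self, n_scales: int = 3, ksize: int = 7, wavelength: float = 4.0,
                 sigma: float = 2.0, norm_const: float = 0.01, gain: float = 10.0):
        self.n_scales = n_scales
        self.norm_const = norm_const
        # the five normalized channels sum to <= 1 (about 0.2 each); the gain
        # rescales them to O(1) so the temporal Gram statistics have a dynamic
        # range comparable to typical spatial conv activations
        self.gain = gain
        ex, ox = _gabor_pair(ksize, wavelength, sigma, "x")
        ey, oy = _gabor_pair(ksize, wavelength, sigma, "y")
        self._bank = {"x": (ex[None, None], ox[None, None]), "y": (ey[None, None], oy[None, None])}
        self._blur = _binomial5()[None, None]
        self._gray_w = GRAY_WEIGHTS.reshape(1, 3, 1, 1)
        self._sum5 = np.ones((1, 5, 1, 1))
        self.layer_names = tuple(f"scale{i}" for i in range(n_scales)) + ("concat",)

    def _gray(self, x: Var) -> Var:
        if x.shape[0] == 1:
            return x
        return ad.conv2d(x, self._gray_w)

    def forward(self, x_t: Var, x_tm1: Var) -> dict[str, Var]:
        if x_t.shape != x_tm1.shape:
            raise ValueError(f"frame shapes differ: {x_t.shape} vs {x_tm1.shape}")
        H, W = x_t.shape[1], x_t.shape[2]
        cur, prev = self._gray(x_t), self._gray(x_tm1)
        out: dict[str, Var] = {}
        upsampled = []
        for s in range(self.n_scales):
            if s > 0:
                cur = ad.downsample2(ad.conv2d(cur, self._blur))
                prev = ad.downsample2(ad.conv2d(prev, self._blur))
            energies = self._energies(cur, prev)
            out[f"scale{s}"] = energies
            upsampled.append(ad.resize_bilinear(energies, H, W))
        out["concat"] = ad.concat(upsampled, axis=0)
        return out

    def _energies(self, cur: Var, prev: Var) -> Var:
        chans = {}
        statics = []
        for axis, (plus_name, minus_name) in (("x", ("right", "left")), ("y", ("down", "up"))):
            even_k, odd_k = self._bank[axis]
            a_e, a_o = ad.conv2d(cur, even_k), ad.conv2d(cur, odd_k)
            b_e, b_o = ad.conv2d(prev, even_k), ad.conv2d(prev, odd_k)
            chans[plus_name] = (a_e - b_o) ** 2 + (a_o + b_e) ** 2
            chans[minus_name] = (a_e + b_o) ** 2 + (a_o - b_e) ** 2
            statics.append((a_e + b_e) ** 2 + (a_o + b_o) ** 2)
        # sum (not mean) over orientations: a static pattern then yields twice
        # the energy of each opponent channel, so "static" dominates at rest
        chans["static"] = statics[0] + statics[1]
        stack = ad.concat([chans[c] for c in self.CHANNELS], axis=0)
        denom = ad.conv2d(stack, self._sum5) + self.norm_const
        return stack / denom * self.gain


# -- registry ----------------------------------------------------------------

def get_model(name: str, seed: int = 0, weights_path: str | None = None, **kwargs) -> StreamModel:
    """Model registry: 'vgg19', 'msoe', 'fixture' (arity kwarg selects 1/2)."""
    name = name.lower()
    if name == "vgg19":
        return VGG19Features(seed=seed, weights_path=weights_path)
    if name == "msoe":
        return MSOE(**kwargs)
    if name == "fixture":
        return FixtureNet(seed=seed, arity=kwargs.get("arity", 1))
    raise ConfigError(f"unknown model '{name}' (choose vgg19, msoe or fixture)")
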