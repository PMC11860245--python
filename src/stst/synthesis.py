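"""The spatiotemporal style-transfer generation loop.

Each output frame is optimized independently by normalized gradient descent
on the combined two-stream loss, coarse-to-fine over a multiscale octave
schedule.  Perceptual stability across frames comes from four preconditioning
steps: total-variation regularization (weighted per octave), blending each
frame's initialization from the previous post-processed frame plus uniform
noise, mirror-padding the first xi frames (synthesized, then discarded), and
a per-frame color transfer toward a routed reference frame.

Gradients are taken only with respect to the current generated frame; the
previous generated frame enters the temporal stream as a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Var
from .colortransfer import pdf_transfer, regrain
from .losses import ConfigError, LossSpec, gram, total_loss
from .twostream import StreamModel
from .videoio import Video, octave_size, resize_bilinear


@dataclass
class OctaveSchedule:
    """Coarse-to-fine resolution schedule (octave exponents end at 0)."""

    octaves: list[int] = field(default_factory=lambda: [-2, -1, 0])
    sigma: float = 1.5
    iterations: list[int] = field(default_factory=lambda: [250, 750, 1000])
    learning_rates: list[float] = field(default_factory=lambda: [0.001, 0.003, 0.005])
    tv_weights: list[float] | None = field(default_factory=lambda: [0.05, 0.1, 0.5])

    def __post_init__(self):
        n = len(self.octaves)
        if len(self.iterations) != n or len(self.learning_rates) != n:
            raise ConfigError("octaves, iterations and learning_rates need equal lengths")
        if self.tv_weights is not None and len(self.tv_weights) != n:
            raise ConfigError("tv_weights must match the octave count")
        if any(i < 0 for i in self.iterations) or any(lr <= 0 for lr in self.learning_rates):
            raise ConfigError("iterations must be >= 0 and learning rates > 0")
        if sorted(self.octaves) != list(self.octaves) or self.octaves[-1] != 0:
            raise ConfigError("octaves must be ordered coarse->fine and end at 0")


@dataclass
class SynthesisConfig:
    loss_spec: LossSpec = field(default_factory=LossSpec)
    schedule: OctaveSchedule = field(default_factory=OctaveSchedule)
    phi: float = 0.95  # blending ratio toward the previous frame
    xi: int = 5  # mirror-padding frame count
    seed: int = 0
    color_transfer: bool = True
    color_reference: str | None = None  # target id; default: spatial-texture target
    color_iterations: int = 20
    grad_norm_epsilon: float = 1e-8

    def __post_init__(self):
        if not 0.0 <= self.phi <= 1.0:
            raise ConfigError("blending ratio phi must lie in [0, 1]")
        if self.xi < 0:
            raise ConfigError("padding frame count xi must be >= 0")


def mirror_pad(video: Video, xi: int) -> Video:
    """Prepend the first xi frames in reversed order ([a,b,c], 2 -> [b,a,a,b,c])."""
    if xi > len(video):
        raise ValueError(f"xi={xi} exceeds video length {len(video)}")
    if xi == 0:
        return video
    prefix = video.pixels[:xi][::-1]
    return Video(np.concatenate([prefix, video.pixels], axis=0), fps=video.fps)


def blend_init(g_prev: np.ndarray | None, phi: float, rng: np.random.Generator | int,
               shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Frame initialization  g <- phi * g_prev + (1 - phi) * U(0,1) noise.

    Without a predecessor the initialization is pure uniform noise.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if g_prev is None:
        if shape is None:
            raise ValueError("need a shape when no previous frame exists")
        return rng.uniform(0.0, 1.0, shape)
    noise = rng.uniform(0.0, 1.0, g_prev.shape)
    return phi * g_prev + (1.0 - phi) * noise


def normalize_gradient(grad: np.ndarray, eps: float = 1e-8, channel_axis: int = 0) -> np.ndarray:
    """Divide each channel by its std over the spatial dimensions (+ eps)."""
    grad = np.asarray(grad, dtype=np.float64)
    axes = tuple(i for i in range(grad.ndim) if i != channel_axis % grad.ndim)
    std = grad.std(axis=axes, keepdims=True)
    return grad / (std + eps)


def _chw(frame: np.ndarray) -> np.ndarray:
    return np.moveaxis(frame, -1, 0)


def _hwc(frame: np.ndarray) -> np.ndarray:
    return np.moveaxis(frame, 0, -1)


def _target_pack(spec: LossSpec, models: dict[str, StreamModel],
                 target_frames: dict[str, tuple[np.ndarray, np.ndarray | None]],
                 active_terms: list[str]) -> dict:
    """Precompute target activations and Gram matrices at the current octave."""
    pack: dict[str, dict] = {}
    for term in active_terms:
        stream = "spatial" if term.startswith("spatial") else "temporal"
        layers = spec.spatial_layers if stream == "spatial" else spec.temporal_layers
        tid = spec.routed_target(term)
        if tid not in target_frames:
            raise ConfigError(f"no target frames supplied for routed target '{tid}'")
        x_t, x_tm1 = target_frames[tid]
        entry = pack.setdefault(tid, {})
        if stream in entry:
            pass
        elif stream == "spatial":
            entry["spatial"] = {k: v.value for k, v in models["spatial"].activations(x_t, layers=layers).items()}
        else:
            if x_tm1 is None:
                raise ConfigError("temporal loss needs a previous target frame")
            entry["temporal"] = {
                k: v.value for k, v in models["temporal"].activations(x_t, x_tm1, layers=layers).items()
            }
        if term.endswith("texture"):
            entry[stream + "_gram"] = {k: gram(v) for k, v in entry[stream].items()}
    return pack


def optimize_frame(
    target_frames: dict[str, tuple[np.ndarray, np.ndarray | None]],
    g_init: np.ndarray,
    g_prev: np.ndarray | None,
    cfg: SynthesisConfig,
    models: dict[str, StreamModel],
    trace: list | None = None,
    frame_index: int = 0,
    drop_temporal: bool = False,
) -> np.ndarray:
    """Multiscale normalized-gradient descent on a single frame.

    `target_frames` maps target-id -> (x_t, x_{t-1} or None) at native
    resolution; `g_prev` is the previous generated (post-processed) frame.
    Returns the optimized frame before color transfer, clamped to [0, 1].
    """
    spec = cfg.loss_spec
    sched = cfg.schedule
    H, W = g_init.shape[:2]
    if drop_temporal:
        spec = replace(spec, theta=0.0, lam=0.0)
    active = spec.active_terms
    temporal_active = any(t.startswith("temporal") for t in active)
    if temporal_active and g_prev is None:
        raise ConfigError("temporal loss at the first frame has no predecessor; mirror-pad (xi >= 1)")
    g = g_init
    for k, octave in enumerate(sched.octaves):
        h, w = octave_size(H, W, sched.sigma, octave)
        g = resize_bilinear(g, h, w)
        resized_targets = {
            tid: (
                resize_bilinear(x_t, h, w),
                resize_bilinear(x_tm1, h, w) if x_tm1 is not None else None,
            )
            for tid, (x_t, x_tm1) in target_frames.items()
        }
        pack = _target_pack(spec, models, resized_targets, active)
        # previous generated frame enters the temporal stream as a constant
        g_prev_var = Var(_chw(resize_bilinear(g_prev, h, w))) if g_prev is not None else None
        omega = spec.omega if sched.tv_weights is None else sched.tv_weights[k]
        eta = sched.learning_rates[k]
        spatial_active = any(t.startswith("spatial") for t in active)
        for it in range(sched.iterations[k]):
            gvar = Var(_chw(g), requires_grad=True)
            generated: dict[str, dict] = {}
            if spatial_active:
                generated["spatial"] = models["spatial"].activations(gvar, layers=spec.spatial_layers)
            if temporal_active:
                generated["temporal"] = models["temporal"].activations(
                    gvar, g_prev_var, layers=spec.temporal_layers
                )
            loss, comps = total_loss(spec, pack, generated, g_frame=gvar, omega=omega,
                                     return_components=True)
            if not isinstance(loss, Var):  # every term disabled: nothing to do
                break
            loss.backward()
            step = normalize_gradient(gvar.grad, cfg.grad_norm_epsilon, channel_axis=0)
            g = np.clip(g - eta * _hwc(step), 0.0, 1.0)
            if trace is not None:
                row = {"frame": frame_index, "octave": octave, "iteration": it,
                       "total": float(loss.value)}
                row.update({k2: float(v.value if isinstance(v, Var) else v) for k2, v in comps.items()})
                trace.append(row)
    if g.shape[:2] != (H, W):
        g = resize_bilinear(g, H, W)
    return g


def synthesize_video(
    targets: dict[str, Video],
    cfg: SynthesisConfig,
    models: dict[str, StreamModel],
    trace: list | None = None,
) -> Video:
    """Run the full per-frame synthesis over mirror-padded targets.

    All routed targets must share length and frame shape.  Returns a video
    of the targets' length (the xi padded frames are discarded).  Output is
    deterministic given the config seed.
    """
    spec = cfg.loss_spec
    needed = {spec.routed_target(t) for t in spec.active_terms}
    missing = needed - set(targets)
    if missing:
        raise ConfigError(f"routed targets missing from inputs: {sorted(missing)}")
    shapes = {targets[tid].shape for tid in needed} or {next(iter(targets.values())).shape}
    if len(shapes) != 1:
        raise ValueError(f"routed targets disagree in shape: {shapes}")
    T, H, W, C = shapes.pop()
    temporal_terms = [t for t in spec.active_terms if t.startswith("temporal")]
    if temporal_terms and cfg.xi == 0:
        raise ConfigError("temporal losses need mirror padding (xi >= 1) for the first frame")

    padded = {tid: mirror_pad(v, cfg.xi) for tid, v in targets.items()}
    color_tid = cfg.color_reference
    if color_tid is None:
        color_tid = spec.routing.get("spatial_texture") or next(iter(targets))
    if cfg.color_transfer and color_tid not in padded:
        raise ConfigError(f"color reference target '{color_tid}' not supplied")

    rng = np.random.default_rng(cfg.seed)
    g_prev: np.ndarray | None = None
    outputs = []
    for t in range(1, T + cfg.xi + 1):  # 1-based over the padded sequence
        g_init = blend_init(g_prev, cfg.phi, rng, shape=(H, W, C))
        frame_targets = {
            tid: (v.pixels[t - 1], v.pixels[t - 2] if t >= 2 else None)
            for tid, v in padded.items()
        }
        g_opt = optimize_frame(
            frame_targets, g_init, g_prev, cfg, models,
            trace=trace, frame_index=t, drop_temporal=(t == 1),
        )
        if cfg.color_transfer:
            ref = padded[color_tid].pixels[t - 1]
            transferred = pdf_transfer(g_opt, ref, iterations=cfg.color_iterations,
                                       seed=cfg.seed + 1000 + t)
            g_post = regrain(transferred, g_opt)
        else:
            g_post = g_opt
        outputs.append(g_post)
        g_prev = g_post
    return Video(np.stack(outputs[cfg.xi :]), fps=next(iter(targets.values())).fps)
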