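"""Loss components of spatiotemporal style transfer.

Content loss compares layer activations directly (retinotopic match), texture
loss compares their Gram matrices (stationary statistics), and an anisotropic
total-variation regularizer suppresses high-frequency optimization noise.
All functions accept plain ndarrays or autodiff :class:`~stst.autodiff.Var`
nodes; with ndarrays they return floats, with a Var anywhere in the generated
arguments they return a gradient-ready Var.

An activation is an (N, M) matrix: N filters by M spatial locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Var, as_var

TERMS = ("spatial_content", "spatial_texture", "temporal_content", "temporal_texture")


class ConfigError(ValueError):
    """Invalid loss specification or routing."""


def _finish(x: Var, *inputs) -> Var | float:
    if any(isinstance(v, Var) and v.requires_grad for v in inputs):
        return x
    return float(x.value)


def content_loss(A, A_hat):
    """Mean squared activation difference: sum (A - Ahat)^2 / (2 N M)."""
    a, b = as_var(A), as_var(A_hat)
    if a.shape != b.shape:
        raise ValueError(f"activation shapes differ: {a.shape} vs {b.shape}")
    n, m = a.shape
    out = ((a - b) ** 2).sum() * (1.0 / (2 * n * m))
    return _finish(out, A, A_hat)


def gram(A):
    """Filter-correlation Gram matrix G = A A^T / (N M)."""
    a = as_var(A)
    n, m = a.shape
    g = (a @ a.T) * (1.0 / (n * m))
    return g if (isinstance(A, Var) and A.requires_grad) else g.value


def texture_loss(A, A_hat):
    """Squared Gram difference: sum (G - Ghat)^2 / (2 N^2).

    The Gram normalization by M makes the statistic independent of the
    spatial extent, so activations from different octave resolutions can be
    compared as long as the filter count N matches.
    """
    a, b = as_var(A), as_var(A_hat)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"filter counts differ: {a.shape[0]} vs {b.shape[0]}")
    ga = (a @ a.T) * (1.0 / (a.shape[0] * a.shape[1]))
    gb = (b @ b.T) * (1.0 / (b.shape[0] * b.shape[1]))
    out = ((ga - gb) ** 2).sum() * (1.0 / (2 * a.shape[0] ** 2))
    return _finish(out, A, A_hat)


def texture_loss_from_gram(G_target, A_hat):
    """Texture loss against a precomputed target Gram matrix."""
    gt = as_var(G_target)
    b = as_var(A_hat)
    n = b.shape[0]
    if gt.shape != (n, n):
        raise ValueError(f"Gram shape {gt.shape} does not match N={n}")
    gh = (b @ b.T) * (1.0 / (n * b.shape[1]))
    out = ((gt - gh) ** 2).sum() * (1.0 / (2 * n * n))
    return _finish(out, G_target, A_hat)


def tv_loss(frame, channel_axis: int = -1):
    """Anisotropic total variation, mean absolute neighbor difference.

    sum over channels and valid neighbor pairs of |g[i+1,j] - g[i,j]| +
    |g[i,j+1] - g[i,j]|, normalized by H*W*C.  Only in-bounds neighbor pairs
    contribute (the boundary rows/columns have no partner).
    """
    g = as_var(frame)
    if g.value.ndim == 2:
        g = g.reshape(g.shape[0], g.shape[1], 1)
    if channel_axis in (0, -3):
        hax, wax = 1, 2
    else:
        hax, wax = 0, 1
    sl = [slice(None)] * 3

    def shifted_diff(axis):
        a, b = [slice(None)] * 3, [slice(None)] * 3
        a[axis] = slice(1, None)
        b[axis] = slice(None, -1)
        return g[tuple(a)] - g[tuple(b)]

    total = shifted_diff(hax).abs().sum() + shifted_diff(wax).abs().sum()
    out = total * (1.0 / g.value.size)
    return _finish(out, frame)


@dataclass
class LossSpec:
    """Weights and layer routing of the combined synthesis loss.

    alpha/beta weight the spatial content/texture terms, theta/lam the
    temporal ones, omega the total-variation regularizer (a scalar here; the
    octave schedule may override it per octave).  `routing` names the target
    video each active term draws its statistics from; terms with weight zero
    are never computed and need no routed target.
    """

    alpha: float = 0.0
    beta: float = 1.0
    theta: float = 0.0
    lam: float = 1.0
    omega: float = 0.5
    spatial_layers: list[str] = field(default_factory=lambda: ["conv1_1", "conv2_1", "conv3_1", "conv4_1", "conv5_1"])
    temporal_layers: list[str] = field(default_factory=lambda: ["concat"])
    routing: dict[str, str] = field(default_factory=lambda: {t: "target" for t in TERMS})

    def __post_init__(self):
        for name in ("alpha", "beta", "theta", "lam", "omega"):
            if getattr(self, name) < 0:
                raise ConfigError(f"loss weight {name} must be >= 0")

    def routed_target(self, term: str) -> str:
        if term not in self.routing:
            raise ConfigError(f"no target routed for active loss term '{term}'")
        return self.routing[term]

    @property
    def active_terms(self) -> list[str]:
        w = dict(zip(TERMS, (self.alpha, self.beta, self.theta, self.lam)))
        return [t for t in TERMS if w[t] > 0]


def total_loss(
    spec: LossSpec,
    targets: dict,
    generated: dict,
    g_frame=None,
    omega: float | None = None,
    return_components: bool = False,
):
    """Combined loss  L = sum_l (a Lsc + b Lst) + sum_l (th Ltc + lam Ltt) + w Ltv.

    `targets` maps target-id -> {"spatial": {layer: activation}, ...}; a
    target may additionally carry precomputed Gram matrices under the keys
    "spatial_gram" / "temporal_gram", which texture terms then use directly.
    `generated` holds {"spatial": {layer: activation}, "temporal": {...}} of
    the frame being optimized.  Terms with zero weight are skipped entirely.
    """
    omega = spec.omega if omega is None else omega
    weights = {
        "spatial_content": spec.alpha,
        "spatial_texture": spec.beta,
        "temporal_content": spec.theta,
        "temporal_texture": spec.lam,
    }
    comps: dict[str, Var | float] = {}
    total = None
    for term in TERMS:
        w = weights[term]
        if w == 0:
            continue
        stream = "spatial" if term.startswith("spatial") else "temporal"
        layers = spec.spatial_layers if stream == "spatial" else spec.temporal_layers
        tid = spec.routed_target(term)
        if tid not in targets or stream not in targets[tid]:
            raise ConfigError(f"target '{tid}' provides no {stream} activations for '{term}'")
        tacts = targets[tid][stream]
        tgrams = targets[tid].get(stream + "_gram", {})
        gacts = generated[stream]
        acc = None
        for layer in layers:
            if layer not in gacts or (layer not in tacts and layer not in tgrams):
                raise ConfigError(f"layer '{layer}' missing from {stream} activations")
            if term.endswith("texture"):
                if layer in tgrams:
                    piece = texture_loss_from_gram(tgrams[layer], gacts[layer])
                else:
                    piece = texture_loss(tacts[layer], gacts[layer])
            else:
                piece = content_loss(tacts[layer], gacts[layer])
            acc = piece if acc is None else acc + piece
        comps[term] = acc
        total = acc * w if total is None else total + acc * w
    if omega > 0 and g_frame is not None:
        channel_axis = 0 if _is_cfirst(g_frame) else -1
        tv = tv_loss(g_frame, channel_axis=channel_axis)
        comps["tv"] = tv
        total = tv * omega if total is None else total + tv * omega
    if total is None:
        total = 0.0
    if return_components:
        return total, comps
    return total


def _is_cfirst(frame) -> bool:
    shp = frame.shape
    return len(shp) == 3 and shp[0] in (1, 3) and shp[2] not in (1, 3)
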