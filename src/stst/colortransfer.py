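"""3D color-distribution transfer with grain suppression.

`pdf_transfer` implements iterative distribution transfer: at every step the
RGB point clouds of the source and reference frames are rotated by a random
orthogonal matrix, the three rotated 1D marginals of the source are mapped
onto the reference's by sorted quantile matching, and the result is rotated
back.  Repeating with fresh rotations drives the full 3D color density of
the source toward the reference's.

`regrain` then suppresses the grain this per-pixel remapping introduces by
solving a smoothness-weighted reconstruction: the output is pulled toward
the transferred colors (data term) while its spatial gradient field is
pulled toward the original source's (gradient term), via damped Jacobi
iterations.  Bit-exactness with any specific published implementation is not
claimed.
"""

from __future__ import annotations

import numpy as np


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _match_marginal(src: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Monotone quantile mapping of `src` samples onto `ref`'s distribution."""
    order = np.argsort(src, kind="stable")
    ref_sorted = np.sort(ref)
    n_src, n_ref = len(src), len(ref)
    if n_src != n_ref:
        quantiles = (np.arange(n_src) + 0.5) / n_src
        ref_sorted = np.interp(quantiles * n_ref - 0.5, np.arange(n_ref), ref_sorted)
    out = np.empty_like(src)
    out[order] = ref_sorted
    return out


def pdf_transfer(source: np.ndarray, reference: np.ndarray, iterations: int = 20,
                 seed: int = 0, relaxation: float = 1.0) -> np.ndarray:
    """Transfer the reference frame's 3D color distribution onto the source.

    Both frames are (H, W, 3) in [0, 1]; returns a frame of the source's
    shape whose color density approximates the reference's.  Deterministic
    given the seed.  A constant reference short-circuits to that color.
    """
    source = np.asarray(source, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if source.ndim != 3 or source.shape[-1] != 3 or reference.shape[-1] != 3:
        raise ValueError("pdf_transfer expects (H, W, 3) RGB frames")
    ref = reference.reshape(-1, 3)
    if np.ptp(ref, axis=0).max() < 1e-12:
        return np.broadcast_to(ref[0], source.shape).copy()
    rng = np.random.default_rng(seed)
    x = source.reshape(-1, 3).copy()
    for _ in range(iterations):
        rot = _random_rotation(rng)
        xr = x @ rot.T
        rr = ref @ rot.T
        matched = np.column_stack([_match_marginal(xr[:, c], rr[:, c]) for c in range(3)])
        x = x + relaxation * (matched - xr) @ rot
    return np.clip(x.reshape(source.shape), 0.0, 1.0)


def regrain(transferred: np.ndarray, original_source: np.ndarray,
            iterations: int = 50, data_weight: float = 1.0) -> np.ndarray:
    """Recompose transferred colors with the source's spatial gradients.

    Minimizes  data_weight * ||u - transferred||^2 + ||grad u - grad source||^2
    by Jacobi relaxation with a fixed iteration cap.  `transferred` equal to
    the source is a fixed point (both terms are already satisfied).
    """
    t = np.asarray(transferred, dtype=np.float64)
    s = np.asarray(original_source, dtype=np.float64)
    if t.shape != s.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {s.shape}")
    u = t.copy()
    for _ in range(iterations):
        nb_u = np.zeros_like(u)
        nb_s = np.zeros_like(u)
        deg = np.zeros(u.shape[:2] + (1,) * (u.ndim - 2))
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            nb_u += _shift_edge(u, axis, shift)
            nb_s += _shift_edge(s, axis, shift)
            deg += 1  # interior approximation; edges get slight extra pull
        # stationarity: (data_weight + deg) u = data_weight t + nb_u + deg s - nb_s
        u = (data_weight * t + nb_u + deg * s - nb_s) / (data_weight + deg)
    return np.clip(u, 0.0, 1.0)


def _shift_edge(a: np.ndarray, axis: int, shift: int) -> np.ndarray:
    """Shift with edge replication (Neumann boundary)."""
    out = np.roll(a, shift, axis=axis)
    idx = [slice(None)] * a.ndim
    idx[axis] = 0 if shift > 0 else -1
    out[tuple(idx)] = a[tuple(idx)]
    return out
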