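"""Representation- and prediction-similarity metrics.

Linear centered kernel alignment (CKA) compares two activation matrices
(samples x features) up to orthogonal rotation and isotropic scaling; SSIM
compares two images structurally; cSSIM is SSIM conditioned on the previous
frame, which penalizes predictions that merely copy it:

    cSSIM(f_t, f_{t-1}, fhat_t) = (1 - SSIM(f_{t-1}, fhat_t)) * SSIM(f_t, fhat_t)

SSIM is computed on the grayscale image with an 11x11 Gaussian window
(sigma 1.5), K1 = 0.01, K2 = 0.03 and unit dynamic range.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .videoio import to_grayscale


def linear_cka(X: np.ndarray, Y: np.ndarray) -> float:
    """Linear-kernel CKA between (n_samples, n_features) matrices.

    Feature-space form: ||Yc^T Xc||_F^2 / (||Xc^T Xc||_F ||Yc^T Yc||_F) with
    column-centered matrices; equals the centered-Gram HSIC formulation.
    Returns nan when either input has no variance.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("CKA needs two 2D matrices with equal sample counts")
    if X.shape[0] < 2:
        raise ValueError("CKA needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    xx = np.linalg.norm(Xc.T @ Xc)
    yy = np.linalg.norm(Yc.T @ Yc)
    if xx == 0 or yy == 0:
        return float("nan")
    return float(np.linalg.norm(Yc.T @ Xc) ** 2 / (xx * yy))


def _ssim_prepare(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 3 and frame.shape[-1] == 3:
        frame = to_grayscale(frame)[..., 0]
    elif frame.ndim == 3:
        frame = frame[..., 0]
    return frame


def ssim(a: np.ndarray, b: np.ndarray, sigma: float = 1.5, truncate: float = 3.5,
         k1: float = 0.01, k2: float = 0.03, data_range: float = 1.0) -> float:
    """Mean structural similarity with a Gaussian weighting window.

    Gaussian moments use reflective boundaries and the map is cropped by the
    window radius before averaging, so border estimates with incomplete
    support do not contribute.
    """
    x, y = _ssim_prepare(a), _ssim_prepare(b)
    if x.shape != y.shape:
        raise ValueError(f"frame shapes differ: {x.shape} vs {y.shape}")
    filt = lambda img: gaussian_filter(img, sigma, truncate=truncate, mode="reflect")
    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    smap = ((2 * ux * uy + c1) * (2 * cxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = int(truncate * sigma + 0.5)
    if smap.shape[0] > 2 * pad and smap.shape[1] > 2 * pad:
        smap = smap[pad:-pad, pad:-pad]
    return float(smap.mean())


def cssim(f_t: np.ndarray, f_tm1: np.ndarray, f_hat: np.ndarray, **kwargs) -> float:
    """Copy-penalized SSIM: (1 - SSIM(f_{t-1}, fhat)) * SSIM(f_t, fhat)."""
    return (1.0 - ssim(f_tm1, f_hat, **kwargs)) * ssim(f_t, f_hat, **kwargs)


def sliding_cka(acts_a, acts_b, window: int = 5, step: int = 1) -> np.ndarray:
    """Per-window linear CKA over aligned per-frame activation sequences.

    `acts_a` / `acts_b` are sequences (length T) of per-frame feature arrays;
    each window stacks `window` consecutive frames (rows = frames x spatial
    locations treated as samples) before the CKA call.  Returns an array of
    length (T - window) // step + 1.
    """
    if len(acts_a) != len(acts_b):
        raise ValueError("activation sequences must be aligned (equal length)")
    T = len(acts_a)
    if window > T:
        raise ValueError(f"window {window} exceeds sequence length {T}")

    def stack(seq, lo, hi):
        mats = [np.asarray(m, dtype=np.float64).reshape(-1, np.asarray(m).shape[-1]) for m in seq[lo:hi]]
        return np.vstack(mats)

    out = []
    for lo in range(0, T - window + 1, step):
        out.append(linear_cka(stack(acts_a, lo, lo + window), stack(acts_b, lo, lo + window)))
    return np.array(out)
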