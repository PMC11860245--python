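"""Low-level spatiotemporal feature time series and comparison statistics.

Spatial features (per frame): mean pixel intensity and luminance contrast
(population standard deviation of the grayscale image).  Temporal features
(per consecutive frame pair): mean absolute pixel change and dense optical
flow summarized as mean magnitude (px/frame) and mean angle (radians).

Angle convention: x rightward, y downward, angle = atan2(vy, vx).  Per-pixel
angles are taken in (-pi, pi] before the arithmetic per-frame mean (the
reported series is wrapped to [0, 2pi)), which keeps rightward motion away
from the branch cut; a circular mean is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.registration import optical_flow_tvl1

from .videoio import Video, to_grayscale


@dataclass
class FeatureSeries:
    name: str
    values: np.ndarray
    units: str = "a.u."

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self):
        return len(self.values)


@dataclass
class FlowParams:
    """Dense optical flow settings.

    The reference pipeline ran Farnebäck with pyramid scale 0.5, 5 levels,
    window 13, 10 iterations, poly_n 5 and poly_sigma 1.1; those values are
    kept here for config compatibility but only apply when a Farnebäck
    backend is available.  The default backend is the TV-L1 solver from
    scikit-image, evaluated on the grayscaled frame pair.
    """

    backend: str = "tvl1"
    pyr_scale: float = 0.5
    levels: int = 5
    winsize: int = 13
    iterations: int = 10
    poly_n: int = 5
    poly_sigma: float = 1.1
    circular_mean: bool = False


def _frames(video) -> np.ndarray:
    if isinstance(video, Video):
        return video.pixels
    arr = np.asarray(video, dtype=np.float64)
    if arr.ndim != 4:
        raise ValueError("expected a Video or a (T, H, W, C) array")
    return arr


def pixel_intensity(video) -> FeatureSeries:
    """Per-frame mean pixel value over H, W and C."""
    px = _frames(video)
    return FeatureSeries("intensity", px.mean(axis=(1, 2, 3)))


def contrast(video) -> FeatureSeries:
    """Per-frame population std of the grayscale image over H x W."""
    px = _frames(video)
    vals = [to_grayscale(f).std() if f.shape[-1] == 3 else f.std() for f in px]
    return FeatureSeries("contrast", np.array(vals))


def pixel_change(video) -> FeatureSeries:
    """Mean absolute difference between consecutive frames (length T-1)."""
    px = _frames(video)
    return FeatureSeries("pixel_change", np.abs(np.diff(px, axis=0)).mean(axis=(1, 2, 3)))


def optical_flow_stats(video, params: FlowParams | None = None) -> tuple[FeatureSeries, FeatureSeries]:
    """Mean dense-flow magnitude and angle per consecutive frame pair."""
    params = params or FlowParams()
    if params.backend != "tvl1":
        raise ValueError(f"flow backend '{params.backend}' is not available")
    px = _frames(video)
    grays = [to_grayscale(f)[..., 0] if f.shape[-1] == 3 else f[..., 0] for f in px]
    mags, angs = [], []
    for prev, curr in zip(grays[:-1], grays[1:]):
        vy, vx = optical_flow_tvl1(prev, curr)
        mags.append(np.sqrt(vx**2 + vy**2).mean())
        theta = np.arctan2(vy, vx)
        if params.circular_mean:
            mean_ang = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
        else:
            mean_ang = theta.mean()
        angs.append(np.mod(mean_ang, 2 * np.pi))
    return (
        FeatureSeries("flow_magnitude", np.array(mags), units="px/frame"),
        FeatureSeries("flow_angle", np.array(angs), units="rad"),
    )


def series_similarity(a, b) -> tuple[float, float]:
    """(Pearson r, Euclidean distance) between two equal-length series.

    Returns (nan, ed) when either series has zero variance, where the
    correlation is undefined.
    """
    av = a.values if isinstance(a, FeatureSeries) else np.asarray(a, float)
    bv = b.values if isinstance(b, FeatureSeries) else np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError(f"series lengths differ: {av.shape} vs {bv.shape}")
    ed = float(np.linalg.norm(av - bv))
    if av.std() == 0 or bv.std() == 0 or len(av) < 3:
        return float("nan"), ed
    return float(stats.pearsonr(av, bv).statistic), ed


def color_histogram(video, bins: int = 16, smoothing: float = 1e-9) -> np.ndarray:
    """Smoothed, normalized bins^3 color histogram pooled across frames."""
    px = _frames(video)
    if px.shape[-1] != 3:
        raise ValueError("color histogram needs RGB frames")
    samples = px.reshape(-1, 3)
    hist, _ = np.histogramdd(samples, bins=bins, range=[(0, 1)] * 3)
    hist = hist + smoothing
    return hist / hist.sum()


def color_distribution_distance(a, b, bins: int = 16, smoothing: float = 1e-9) -> float:
    """KL divergence KL(P_a || P_b) between pooled 3D color histograms."""
    p = color_histogram(a, bins, smoothing)
    q = color_histogram(b, bins, smoothing)
    return float(np.sum(p * np.log(p / q)))


def palette(video, k: int = 5, seed: int = 0) -> np.ndarray:
    """k-means palette (k RGB centroids) of the pooled pixel colors.

    With fewer distinct colors than k, duplicate/degenerate centroids are
    possible and accepted.
    """
    from sklearn.cluster import KMeans

    px = _frames(video).reshape(-1, 3)
    if k < 1:
        raise ValueError("k must be >= 1")
    # subsample for speed on large videos; deterministic given the seed
    rng = np.random.default_rng(seed)
    if px.shape[0] > 100_000:
        px = px[rng.choice(px.shape[0], 100_000, replace=False)]
    km = KMeans(n_clusters=k, random_state=seed, n_init=4).fit(px)
    return np.clip(km.cluster_centers_, 0, 1)
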