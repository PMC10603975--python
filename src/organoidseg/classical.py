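"""Classical (non-learned) segmentation baselines.

Five methods spanning the standard computer-vision toolbox: fixed/Otsu
thresholding, seeded region growing, intensity k-means initialized and
refined by particle-swarm optimization, region-based (Chan-Vese style)
active contours, and marker-controlled watershed.  All share one global
convention with the phantom generator: the organoid is *dark* foreground
on a bright field by default (``polarity="dark"``), and the fixed
threshold (185) is stated on the 8-bit 0-255 scale.

Each method is exposed both as a scikit-learn style estimator operating on
stacks of images and as a per-image function.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import segmentation as skseg
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .imaging import BinaryMask, GrayscaleImage

__all__ = [
    "ClassicalParams",
    "threshold_segment",
    "region_growing",
    "kmeans_pso_segment",
    "active_contour_segment",
    "watershed_segment",
    "ThresholdSegmenter",
    "RegionGrowingSegmenter",
    "KMeansPSOSegmenter",
    "ActiveContourSegmenter",
    "WatershedSegmenter",
    "pso_kmeans_centroids",
]


@dataclass(frozen=True)
class ClassicalParams:
    """Shared defaults for the baseline suite."""

    fixed_threshold: float | str = 185  # 0-255 scale, or "otsu"
    region_threshold: float = 0.2
    growth_size: int = 1
    kmeans_k: int = 2
    swarm_size: int = 10
    pso_iterations: int = 20
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    contour_iterations: int = 100
    polarity: str = "dark"


def _pixels(img: GrayscaleImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, GrayscaleImage) else np.asarray(img, dtype=np.float64)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndi.label(mask)
    if n <= 1:
        return mask
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


# ---------------------------------------------------------------------------
# thresholding

def threshold_segment(
    img,
    threshold: float | str = 185,
    polarity: str = "dark",
    largest_component: bool = False,
) -> BinaryMask:
    """Global intensity threshold at a fixed 0-255 level or Otsu's.

    Dark polarity selects pixels strictly below the threshold (the default
    organoid-on-bright-field convention); bright polarity strictly above.
    A constant image has no Otsu threshold and raises.
    """
    x = _pixels(img)
    if threshold == "otsu":
        if np.ptp(x) == 0:
            raise ValueError("degenerate histogram: constant image has no Otsu threshold")
        t = float(skfilters.threshold_otsu(x))
    else:
        t = float(threshold) / 255.0
    mask = x < t if polarity == "dark" else x > t
    if largest_component and mask.any():
        mask = _largest_component(mask)
    return BinaryMask(labels=mask.astype(np.uint8))


# ---------------------------------------------------------------------------
# region growing

def region_growing(
    img,
    seeds=None,
    regional_threshold: float = 0.2,
    growth_size: int = 1,
    polarity: str = "dark",
) -> BinaryMask:
    """Seeded flood fill accepting frontier pixels whose intensity is
    within ``regional_threshold`` of the running region mean; the frontier
    dilates by ``growth_size`` pixels per iteration.

    Default seeds: the image center plus the global extremum of the
    foreground polarity (the darkest pixel for dark foreground).
    """
    x = _pixels(img)
    h, w = x.shape
    if seeds is None:
        extremum = np.unravel_index(np.argmin(x) if polarity == "dark" else np.argmax(x), x.shape)
        seeds = [(h // 2, w // 2), tuple(int(v) for v in extremum)]
    region = np.zeros_like(x, dtype=bool)
    for r, c in seeds:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"seed {(r, c)} outside image bounds {x.shape}")
        region[r, c] = True
    structure = ndi.generate_binary_structure(2, 2)  # 8-connected growth
    total = x[region].sum()
    count = int(region.sum())
    while True:
        frontier = ndi.binary_dilation(region, structure=structure, iterations=growth_size) & ~region
        if not frontier.any():
            break
        mean = total / count
        accept = frontier & (np.abs(x - mean) <= regional_threshold)
        if not accept.any():
            break
        region |= accept
        total += x[accept].sum()
        count += int(accept.sum())
    return BinaryMask(labels=region.astype(np.uint8))


# ---------------------------------------------------------------------------
# k-means with particle-swarm-optimized centroids

def pso_kmeans_centroids(
    values: np.ndarray,
    k: int = 2,
    swarm_size: int = 10,
    iterations: int = 20,
    inertia: float = 0.7,
    cognitive: float = 1.5,
    social: float = 1.5,
    rng: np.random.Generator | None = None,
):
    """Global-best PSO over intensity-space centroid positions.

    The objective is the within-cluster sum of squares of the pixel
    intensities.  Returns ``(best_centroids, objective_history,
    initial_centroids)``; the history is the global best per iteration and
    is non-increasing by construction.
    """
    rng = rng if rng is not None else np.random.default_rng()
    lo, hi = float(values.min()), float(values.max())

    def objective(cents: np.ndarray) -> float:
        d = (values[None, :] - cents[:, None]) ** 2
        return float(d.min(axis=0).sum())

    pos = rng.uniform(lo, hi, size=(swarm_size, k))
    pos.sort(axis=1)
    init = pos[0].copy()
    vel = np.zeros_like(pos)
    pbest = pos.copy()
    pbest_obj = np.array([objective(p) for p in pos])
    g = int(np.argmin(pbest_obj))
    gbest, gbest_obj = pbest[g].copy(), float(pbest_obj[g])
    history = [gbest_obj]
    for _ in range(iterations):
        r1 = rng.random(pos.shape)
        r2 = rng.random(pos.shape)
        vel = inertia * vel + cognitive * r1 * (pbest - pos) + social * r2 * (gbest - pos)
        pos = np.clip(pos + vel, lo, hi)
        obj = np.array([objective(p) for p in pos])
        improved = obj < pbest_obj
        pbest[improved] = pos[improved]
        pbest_obj[improved] = obj[improved]
        g = int(np.argmin(pbest_obj))
        if pbest_obj[g] < gbest_obj:
            gbest, gbest_obj = pbest[g].copy(), float(pbest_obj[g])
        history.append(gbest_obj)
    return gbest, history, init


def kmeans_pso_segment(
    img,
    k: int = 2,
    swarm_size: int = 10,
    iterations: int = 20,
    inertia: float = 0.7,
    cognitive: float = 1.5,
    social: float = 1.5,
    polarity: str = "dark",
    seed: int = 0,
) -> BinaryMask:
    """Intensity k-means whose centroids are found by PSO then refined by
    Lloyd iterations; foreground is the cluster whose mean matches the
    configured polarity (lowest mean for dark foreground)."""
    x = _pixels(img)
    if np.ptp(x) == 0:
        raise ValueError("degenerate clustering: constant image")
    values = x.ravel()
    rng = np.random.default_rng(seed)
    centroids, _, _ = pso_kmeans_centroids(
        values, k=k, swarm_size=swarm_size, iterations=iterations,
        inertia=inertia, cognitive=cognitive, social=social, rng=rng,
    )
    km = KMeans(n_clusters=k, init=centroids.reshape(-1, 1), n_init=1, random_state=0)
    labels = km.fit_predict(values.reshape(-1, 1)).reshape(x.shape)
    means = km.cluster_centers_.ravel()
    fg_cluster = int(np.argmin(means) if polarity == "dark" else np.argmax(means))
    return BinaryMask(labels=(labels == fg_cluster).astype(np.uint8))


# ---------------------------------------------------------------------------
# active contour (region-based, Chan-Vese style morphological evolution)

def _disk_level_set(shape, center=None, radius=None) -> np.ndarray:
    h, w = shape
    if center is None:
        center = (h / 2.0, w / 2.0)
    if radius is None:
        radius = min(h, w) / 3.0
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2).astype(np.int8)


def active_contour_segment(
    img,
    iterations: int = 100,
    init: np.ndarray | None = None,
    smoothing: int = 1,
    polarity: str = "dark",
) -> BinaryMask:
    """Region-based active contour (morphological Chan-Vese evolution)
    from a centered circular initialization (or a caller-supplied one),
    run for a fixed iteration budget.  The energy depends only on region
    means, so the result is invariant to positive intensity gain."""
    x = _pixels(img)
    if init is None:
        init = _disk_level_set(x.shape)
    init = np.asarray(init)
    if init.shape != x.shape or not init.any():
        raise ValueError("initialization must be a nonempty mask matching the image shape")
    if iterations == 0:
        return BinaryMask(labels=(init > 0).astype(np.uint8))
    kwargs = {}
    sig = inspect.signature(skseg.morphological_chan_vese).parameters
    iter_kw = "num_iter" if "num_iter" in sig else "max_num_iter"
    kwargs[iter_kw] = iterations
    ls = skseg.morphological_chan_vese(
        x, init_level_set=init, smoothing=smoothing, **kwargs
    ).astype(bool)
    if not ls.any() or ls.all():
        return BinaryMask(labels=ls.astype(np.uint8))
    inside_mean = x[ls].mean()
    outside_mean = x[~ls].mean()
    # keep the phase whose mean matches the foreground polarity
    if (polarity == "dark") != (inside_mean < outside_mean):
        ls = ~ls
    return BinaryMask(labels=ls.astype(np.uint8))


# ---------------------------------------------------------------------------
# watershed

def watershed_segment(
    img,
    polarity: str = "dark",
    interior_quantile: float = 0.05,
    presmooth_sigma: float = 2.0,
    markers: np.ndarray | None = None,
    return_basins: bool = False,
):
    """Gradient-magnitude watershed with two marker sets: interior markers
    at strong foreground-polarity extrema (after a mild Gaussian presmooth
    that suppresses shot noise), exterior markers on the image border.
    Foreground is the union of interior-marker basins.  A caller-supplied
    ``markers`` array (1 = exterior, 2 = interior) overrides the automatic
    marker search."""
    x = _pixels(img)
    xs = ndi.gaussian_filter(x, presmooth_sigma) if presmooth_sigma > 0 else x
    grad = skfilters.sobel(xs)
    if markers is None:
        q = np.quantile(xs, interior_quantile if polarity == "dark" else 1 - interior_quantile)
        interior = (xs <= q) if polarity == "dark" else (xs >= q)
        interior = ndi.binary_erosion(interior, iterations=1)
        if not interior.any():
            raise ValueError("no interior marker found at the configured quantile")
        markers = np.zeros(x.shape, dtype=np.int32)
        markers[0, :] = markers[-1, :] = markers[:, 0] = markers[:, -1] = 1  # exterior
        markers[interior] = 2
    else:
        markers = np.asarray(markers, dtype=np.int32)
        if not (markers == 2).any():
            raise ValueError("marker array contains no interior (2) markers")
    basins = skseg.watershed(grad, markers)
    mask = BinaryMask(labels=(basins == 2).astype(np.uint8))
    if return_basins:
        return mask, basins
    return mask


# ---------------------------------------------------------------------------
# estimator wrappers

class _StacklessSegmenter(BaseEstimator):
    """Base for per-image classical methods: ``fit`` only validates (the
    methods are training-free) and ``predict`` maps over an image stack."""

    def fit(self, X=None, y=None):
        self.is_fitted_ = True
        return self

    def _segment_one(self, pixels: np.ndarray) -> BinaryMask:  # pragma: no cover
        raise NotImplementedError

    def segment(self, img) -> BinaryMask:
        return self._segment_one(_pixels(img))

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        return np.stack([self._segment_one(x).labels for x in X])


class ThresholdSegmenter(_StacklessSegmenter):
    def __init__(self, threshold=185, polarity="dark", largest_component=False):
        self.threshold = threshold
        self.polarity = polarity
        self.largest_component = largest_component

    def _segment_one(self, pixels):
        return threshold_segment(pixels, self.threshold, self.polarity, self.largest_component)


class RegionGrowingSegmenter(_StacklessSegmenter):
    def __init__(self, regional_threshold=0.2, growth_size=1, polarity="dark", seeds=None):
        self.regional_threshold = regional_threshold
        self.growth_size = growth_size
        self.polarity = polarity
        self.seeds = seeds

    def _segment_one(self, pixels):
        return region_growing(
            pixels, self.seeds, self.regional_threshold, self.growth_size, self.polarity
        )


class KMeansPSOSegmenter(_StacklessSegmenter):
    def __init__(self, k=2, swarm_size=10, iterations=20, inertia=0.7,
                 cognitive=1.5, social=1.5, polarity="dark", random_state=0):
        self.k = k
        self.swarm_size = swarm_size
        self.iterations = iterations
        self.inertia = inertia
        self.cognitive = cognitive
        self.social = social
        self.polarity = polarity
        self.random_state = random_state

    def _segment_one(self, pixels):
        return kmeans_pso_segment(
            pixels, self.k, self.swarm_size, self.iterations, self.inertia,
            self.cognitive, self.social, self.polarity, self.random_state,
        )


class ActiveContourSegmenter(_StacklessSegmenter):
    def __init__(self, iterations=100, smoothing=1, polarity="dark"):
        self.iterations = iterations
        self.smoothing = smoothing
        self.polarity = polarity

    def _segment_one(self, pixels):
        return active_contour_segment(
            pixels, self.iterations, smoothing=self.smoothing, polarity=self.polarity
        )


class WatershedSegmenter(_StacklessSegmenter):
    def __init__(self, polarity="dark", interior_quantile=0.05):
        self.polarity = polarity
        self.interior_quantile = interior_quantile

    def _segment_one(self, pixels):
        return watershed_segment(pixels, self.polarity, self.interior_quantile)
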