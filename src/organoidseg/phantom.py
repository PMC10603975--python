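"""Synthetic bright-field organoid phantoms with paired ground truth.

Real bright-field acquisitions of brain organoids show a roundish dark body
(often with neuroepithelial buds deforming the outline after ~2 weeks of
culture), a brighter textured background populated by spreading cells, and
photon-count (shot) noise.  This module renders that scene structure
programmatically so the full training/evaluation pipeline can run without
access to wet-lab data: the ground-truth mask is the union of an ellipse
body and bud disks, the image is a smoothed piecewise-constant render with
debris speckles outside the mask, degraded by Poisson shot noise.

All randomness flows from ``numpy.random.Generator`` seeded by
``(seed, index)``, so a dataset is bit-reproducible from its parameters.
"""

from __future__ import annotations

import csv
import hashlib
import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.ndimage import gaussian_filter, binary_dilation

from .imaging import BinaryMask, GrayscaleImage, save_image, save_mask

__all__ = ["PhantomParams", "PhantomSample", "generate_phantom", "generate_dataset", "write_dataset"]


class GenerationError(RuntimeError):
    """Raised when the sampled geometry degenerates to an empty mask."""


@dataclass(frozen=True)
class PhantomParams:
    """Scene statistics of the synthetic organoid generator.

    Attributes
    ----------
    side : int
        Output frame size in pixels (250 matches the full-scale inputs).
    body_radius_range : (float, float)
        Organoid semi-axis range as a fraction of ``side``.
    n_buds_range : (int, int)
        Number of neuroepithelial protrusions (inclusive range).
    bud_radius_fraction : float
        Bud radius as a fraction of the body's minor semi-axis.
    body_intensity, background_intensity : float
        Mean intensities of organoid and background in [0, 1].  The default
        is a dark organoid on a bright field; swap the two values to flip
        the contrast sign.
    rim_darkening : float
        Extra attenuation on the organoid border (the optically dense rim).
    texture_amplitude : float
        Amplitude of the low-frequency background texture.
    debris_density : float
        Expected number of spreading-cell speckles per frame, placed
        outside the ground-truth mask.
    shot_noise_scale : float or None
        Photon-count scale lambda_max: pixel ~ Poisson(lambda_max * clean)
        / lambda_max.  ``None`` (or ``inf``) renders the noise-free scene.
    seed : int
        Base seed; combined with the phantom index it fully determines
        the output.
    """

    side: int = 250
    body_radius_range: tuple[float, float] = (0.15, 0.35)
    n_buds_range: tuple[int, int] = (0, 4)
    bud_radius_fraction: float = 0.3
    body_intensity: float = 0.30
    background_intensity: float = 0.80
    rim_darkening: float = 0.10
    texture_amplitude: float = 0.03
    debris_density: float = 30.0
    shot_noise_scale: float | None = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.body_radius_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("body_radius_range fractions must lie in (0, 0.5]")
        if not (0.0 < self.bud_radius_fraction <= 0.5):
            raise ValueError("bud_radius_fraction must lie in (0, 0.5]")
        for name in ("body_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_buds_range[0] < 0 or self.n_buds_range[1] < self.n_buds_range[0]:
            raise ValueError("n_buds_range must be a non-negative inclusive range")

    @property
    def contrast(self) -> float:
        return abs(self.background_intensity - self.body_intensity)

    def digest(self) -> str:
        """Stable short hash of the parameter set (manifest provenance)."""
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class PhantomSample:
    """One generated phantom with its identifier and provenance."""

    id: str
    image: GrayscaleImage
    mask: BinaryMask
    index: int
    params_digest: str


def _rng_for(params: PhantomParams, index: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, index])


def _render_mask(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    s = params.side
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy = s / 2 + rng.uniform(-0.08, 0.08) * s
    cx = s / 2 + rng.uniform(-0.08, 0.08) * s
    lo, hi = params.body_radius_range
    a = rng.uniform(lo, hi) * s
    b = rng.uniform(lo, hi) * s
    theta = rng.uniform(0.0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    n_buds = int(rng.integers(params.n_buds_range[0], params.n_buds_range[1] + 1))
    r_minor = min(a, b)
    for _ in range(n_buds):
        phi = rng.uniform(0.0, 2 * np.pi)
        # bud centered on the body boundary so it protrudes outward
        bx = cx + (a * np.cos(phi) * ct - b * np.sin(phi) * st)
        by = cy + (a * np.cos(phi) * st + b * np.sin(phi) * ct)
        br = params.bud_radius_fraction * r_minor * rng.uniform(0.6, 1.0)
        mask |= (xx - bx) ** 2 + (yy - by) ** 2 <= br**2
    if not mask.any():
        raise GenerationError("sampled geometry produced an empty mask")
    return mask


def _render_clean(params: PhantomParams, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    s = params.side
    scene = np.full((s, s), params.background_intensity, dtype=np.float64)
    scene[mask] = params.body_intensity
    # optically dense rim: border of the body slightly darker (or brighter
    # for inverted contrast) than its interior
    rim = binary_dilation(mask, iterations=2) & ~mask
    sign = 1.0 if params.background_intensity >= params.body_intensity else -1.0
    scene[rim] -= sign * params.rim_darkening

    if params.texture_amplitude > 0:
        texture = gaussian_filter(rng.standard_normal((s, s)), sigma=s / 25)
        tmax = np.abs(texture).max()
        if tmax > 0:
            scene += params.texture_amplitude * texture / tmax

    # spreading-cell debris: small blobs strictly outside the GT mask --
    # the structures the discussion identifies as false-positive bait
    n_debris = int(rng.poisson(params.debris_density))
    forbidden = binary_dilation(mask, iterations=3)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    for _ in range(n_debris):
        dy, dx = rng.uniform(0, s, size=2)
        if forbidden[int(dy), int(dx)]:
            continue
        sigma = rng.uniform(1.0, 3.0)
        amp = sign * rng.uniform(0.3, 0.8) * params.contrast
        blob = amp * np.exp(-(((yy - dy) ** 2 + (xx - dx) ** 2) / (2 * sigma**2)))
        blob[forbidden] = 0.0
        scene -= blob

    scene = gaussian_filter(scene, sigma=1.5)
    return np.clip(scene, 0.0, 1.0)


def generate_phantom(params: PhantomParams, index: int = 0) -> tuple[GrayscaleImage, BinaryMask]:
    """Render one phantom image/mask pair.

    The same ``(params, index)`` always produces a bit-identical pair.
    """
    rng = _rng_for(params, index)
    mask = _render_mask(params, rng)
    clean = _render_clean(params, mask, rng)
    lam = params.shot_noise_scale
    if lam is None or not np.isfinite(lam):
        noisy = clean
    else:
        noisy = rng.poisson(lam * clean).astype(np.float64) / lam
    img = GrayscaleImage(pixels=np.clip(noisy, 0.0, 1.0))
    return img, BinaryMask(labels=mask.astype(np.uint8))


def generate_dataset(n: int, params: PhantomParams) -> list[PhantomSample]:
    """Generate ``n`` phantoms with stable, index-derived identifiers."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    digest = params.digest()
    samples = []
    for i in range(n):
        img, mask = generate_phantom(params, index=i)
        samples.append(PhantomSample(id=f"{i:03d}", image=img, mask=mask, index=i, params_digest=digest))
    return samples


def write_dataset(samples: list[PhantomSample], out_dir: str | os.PathLike, seed: int | None = None) -> None:
    """Write ``images/NNN.png``, ``masks/NNN.png`` and ``manifest.csv``."""
    out_dir = os.fspath(out_dir)
    os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "masks"), exist_ok=True)
    with open(os.path.join(out_dir, "manifest.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "seed", "params_hash"])
        for s in samples:
            save_image(s.image, os.path.join(out_dir, "images", f"{s.id}.png"))
            save_mask(s.mask, os.path.join(out_dir, "masks", f"{s.id}.png"))
            writer.writerow([s.id, seed if seed is not None else "", s.params_digest])
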