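"""Training-set augmentation groups.

Two families are provided:

* the *classic* group — flips, 90-degree rotations and per-image whitening,
  with geometric transforms applied identically to image and mask;
* *noise-injection* groups — Gaussian, speckle, salt-and-pepper and shot
  (Poisson) noise on the image only.

The six loss-named groups (``bce``, ``bce_l1``, ``ls``, ``poisson``,
``wass``, ``pwass``) mirror the topology of adversarial-autoencoder
augmentation studies: the generative models themselves are prior work and
are not re-implemented here, so these groups are *emulated* by documented
transform+noise presets and carry ``emulated=True`` in every output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .imaging import BinaryMask, GrayscaleImage

__all__ = [
    "AugmentationStrategy",
    "AugmentedSample",
    "STRATEGY_NAMES",
    "get_strategy",
    "classic_augment",
    "inject_noise",
    "build_group",
]

NOISE_MODELS = ("gaussian", "speckle", "salt_pepper", "shot")

#: All eleven strategy names of the experiment plan:
#: one classic group, four direct noise injections, six emulated loss groups.
STRATEGY_NAMES = (
    "classic",
    "gaussian",
    "speckle",
    "salt_pepper",
    "shot",
    "bce",
    "bce_l1",
    "ls",
    "poisson",
    "wass",
    "pwass",
)

LOSS_GROUP_NAMES = ("bce", "bce_l1", "ls", "poisson", "wass", "pwass")
NOISE_GROUP_NAMES = ("gaussian", "speckle", "salt_pepper", "shot")

# default noise magnitudes (fractions of the [0,1] intensity scale)
DEFAULT_SIGMA = 0.05
DEFAULT_SP_RATE = 0.05
DEFAULT_SHOT_SCALE = 255.0


@dataclass(frozen=True)
class AugmentationStrategy:
    """A named augmentation recipe.

    ``emulated`` is True for the six loss-named groups, which stand in for
    generative-model outputs rather than reproducing them.
    """

    name: str
    params: dict[str, Any] = field(default_factory=dict)
    emulated: bool = False


# Emulated loss-group recipes: each is a classic geometric transform plus a
# mild, group-specific perturbation, chosen to give the eleven strategies
# distinct but realistic image statistics.
_EMULATED_RECIPES: dict[str, dict[str, Any]] = {
    "bce": {"noise": "gaussian", "sigma": 0.03},
    "bce_l1": {"noise": "gaussian", "sigma": 0.03, "renormalize": True},
    "ls": {"noise": "speckle", "sigma": 0.04},
    "poisson": {"noise": "shot", "lam": 500.0},
    "wass": {"noise": "salt_pepper", "rate": 0.02},
    "pwass": {"noise": "gaussian", "sigma": 0.02, "smooth": True},
}


def get_strategy(name: str, **overrides: Any) -> AugmentationStrategy:
    """Resolve a strategy name into its default recipe."""
    if name == "classic":
        return AugmentationStrategy("classic", dict(overrides))
    if name in NOISE_MODELS:
        params: dict[str, Any] = {"sigma": DEFAULT_SIGMA, "rate": DEFAULT_SP_RATE, "lam": DEFAULT_SHOT_SCALE}
        params.update(overrides)
        return AugmentationStrategy(name, params)
    if name in _EMULATED_RECIPES:
        params = dict(_EMULATED_RECIPES[name])
        params.update(overrides)
        return AugmentationStrategy(name, params, emulated=True)
    raise ValueError(f"unknown augmentation strategy {name!r}; known: {STRATEGY_NAMES}")


def _whiten(pixels: np.ndarray) -> np.ndarray:
    """Per-image standardization rescaled back into [0, 1] around 0.5."""
    mu = pixels.mean()
    sd = pixels.std()
    if sd == 0.0:
        return np.full_like(pixels, 0.5)
    z = (pixels - mu) / sd
    return 0.5 + z * (0.5 / np.abs(z).max())


CLASSIC_TRANSFORMS = ("hflip", "vflip", "rot90", "rot180", "rot270", "whiten")


def apply_transform(
    name: str, img: GrayscaleImage, mask: BinaryMask
) -> tuple[GrayscaleImage, BinaryMask]:
    """Apply one named classic transform to an aligned image/mask pair."""
    px, lab = img.pixels, mask.labels
    if name == "hflip":
        px, lab = px[:, ::-1], lab[:, ::-1]
    elif name == "vflip":
        px, lab = px[::-1, :], lab[::-1, :]
    elif name in ("rot90", "rot180", "rot270"):
        k = {"rot90": 1, "rot180": 2, "rot270": 3}[name]
        px, lab = np.rot90(px, k), np.rot90(lab, k)
    elif name == "whiten":
        px = _whiten(px)
    else:
        raise ValueError(f"unknown transform {name!r}")
    return (
        GrayscaleImage(pixels=px.copy(), source_bitdepth=img.source_bitdepth),
        BinaryMask(labels=lab.copy()),
    )


def classic_augment(
    img: GrayscaleImage, mask: BinaryMask, rng: np.random.Generator
) -> tuple[GrayscaleImage, BinaryMask]:
    """Apply one randomly chosen classic transform (flip / 90-degree
    rotation / whitening); geometric transforms hit image and mask alike,
    whitening leaves the mask untouched."""
    if img.shape != mask.shape:
        raise ValueError(f"image/mask shapes differ: {img.shape} vs {mask.shape}")
    name = CLASSIC_TRANSFORMS[rng.integers(len(CLASSIC_TRANSFORMS))]
    return apply_transform(name, img, mask)


def inject_noise(
    img: GrayscaleImage,
    model: str,
    params: dict[str, Any] | None = None,
    rng: np.random.Generator | None = None,
) -> GrayscaleImage:
    """Degrade an image with one of the four noise models.

    gaussian : x + N(0, sigma^2)
    speckle : x * (1 + N(0, sigma^2))
    salt_pepper : a fraction ``rate`` of pixels forced to 0 or 1 equiprobably
    shot : Poisson(lam * x) / lam  (photon-count noise at scale lam)

    Output is clipped to [0, 1]; the mask of a pair is never touched.
    """
    params = params or {}
    rng = rng if rng is not None else np.random.default_rng()
    x = img.pixels
    if model == "gaussian":
        sigma = float(params.get("sigma", DEFAULT_SIGMA))
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        out = x if sigma == 0 else x + rng.normal(0.0, sigma, size=x.shape)
    elif model == "speckle":
        sigma = float(params.get("sigma", DEFAULT_SIGMA))
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        out = x if sigma == 0 else x * (1.0 + rng.normal(0.0, sigma, size=x.shape))
    elif model == "salt_pepper":
        rate = float(params.get("rate", DEFAULT_SP_RATE))
        if not (0.0 <= rate <= 1.0):
            raise ValueError("salt/pepper rate must lie in [0, 1]")
        out = x.copy()
        hit = rng.random(x.shape) < rate
        out[hit] = rng.integers(0, 2, size=int(hit.sum())).astype(np.float64)
    elif model == "shot":
        lam = float(params.get("lam", DEFAULT_SHOT_SCALE))
        if lam <= 0:
            raise ValueError("shot-noise scale lam must be > 0")
        out = rng.poisson(lam * x).astype(np.float64) / lam
    else:
        raise ValueError(f"unknown noise model {model!r}; known: {NOISE_MODELS}")
    return GrayscaleImage(
        pixels=np.clip(out, 0.0, 1.0), source_bitdepth=img.source_bitdepth
    )


@dataclass(frozen=True)
class AugmentedSample:
    """An augmented pair with full provenance back to its source original."""

    id: str
    image: GrayscaleImage
    mask: BinaryMask
    source_id: str
    strategy: str
    emulated: bool


def _apply_strategy(
    strategy: AugmentationStrategy,
    img: GrayscaleImage,
    mask: BinaryMask,
    rng: np.random.Generator,
) -> tuple[GrayscaleImage, BinaryMask]:
    if strategy.name == "classic":
        return classic_augment(img, mask, rng)
    if strategy.name in NOISE_MODELS:
        return inject_noise(img, strategy.name, strategy.params, rng), mask
    # emulated loss groups: one classic transform, then the mild recipe noise
    img, mask = classic_augment(img, mask, rng)
    p = strategy.params
    noise_params = {k: p[k] for k in ("sigma", "rate", "lam") if p.get(k) is not None}
    img = inject_noise(img, p["noise"], noise_params, rng)
    if p.get("renormalize"):
        img, _ = apply_transform("whiten", img, mask)
    if p.get("smooth"):
        from scipy.ndimage import gaussian_filter

        img = GrayscaleImage(
            pixels=np.clip(gaussian_filter(img.pixels, sigma=0.7), 0.0, 1.0),
            source_bitdepth=img.source_bitdepth,
        )
    return img, mask


def build_group(
    originals,
    strategy: AugmentationStrategy | str,
    size: int,
    exclude_id: str | None = None,
    seed: int = 0,
) -> list[AugmentedSample]:
    """Build an augmentation group of ``size`` pairs.

    Items derive only from originals whose id differs from ``exclude_id``
    (the leave-one-out rule: the held-out image must not leak into the
    training set through any derivative).  Sources are drawn with
    replacement when ``size`` exceeds the available originals.
    """
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    pool = [s for s in originals if s.id != exclude_id]
    if not pool:
        raise ValueError("all originals are excluded; nothing to augment")
    if exclude_id is not None and len(pool) == len(list(originals)) and not any(
        s.id == exclude_id for s in originals
    ):
        raise ValueError(f"exclude_id {exclude_id!r} not present in originals")
    name_key = int.from_bytes(hashlib.sha256(strategy.name.encode()).digest()[:4], "little")
    rng = np.random.default_rng([seed, name_key])
    # cycle through sources first so every original contributes when size
    # >= len(pool); remainder drawn with replacement
    order = list(range(len(pool))) * (size // len(pool))
    order += list(rng.choice(len(pool), size=size - len(order), replace=True))
    out = []
    for j, idx in enumerate(order):
        src = pool[idx]
        img, mask = _apply_strategy(strategy, src.image, src.mask, rng)
        out.append(
            AugmentedSample(
                id=f"{strategy.name}-{j:03d}",
                image=img,
                mask=mask,
                source_id=src.id,
                strategy=strategy.name,
                emulated=strategy.emulated,
            )
        )
    return out
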