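"""Whole-slide-style patch extraction.

Pipeline (in order): downscale the slide by block averaging, build a
foreground mask by colour thresholding against the near-white background,
then sample random square patches, rejecting any candidate whose background
fraction reaches the exclusion limit, until a per-image cap is hit or the
attempt budget runs out.  Patches are sampled from the downscaled image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "PatchSpec",
    "Patch",
    "downscale",
    "foreground_mask",
    "extract_patches",
    "dataset_patch_count",
]


@dataclass(frozen=True)
class PatchSpec:
    """Patch-extraction parameters.

    Defaults mirror a whole-slide workflow: downscale ×4, 1024-pixel patches,
    at most 200 patches per image, candidates with ≥75 % background excluded.
    ``patch_size`` scales down (e.g. 64) for desk-scale images.
    """

    downscale_factor: int = 4
    patch_size: int = 1024
    max_patches_per_image: int = 200
    background_limit: float = 0.75
    background_luminance_threshold: float = 0.8
    max_attempts_per_patch: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.downscale_factor < 1:
            raise ConfigurationError("downscale_factor must be >= 1")
        if self.patch_size < 1 or self.max_patches_per_image < 0:
            raise ConfigurationError("patch_size and max_patches must be positive")
        if not 0.0 < self.background_limit <= 1.0:
            raise ConfigurationError("background_limit must lie in (0, 1]")
        if self.max_attempts_per_patch < 1:
            raise ConfigurationError("max_attempts_per_patch must be >= 1")


@dataclass
class Patch:
    pixels: np.ndarray
    origin: tuple[int, int]  # top-left (row, col) in downscaled coordinates
    parent_image_id: str
    background_fraction: float


def downscale(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling; output dims are floor(input/factor).

    Trailing rows/columns that do not fill a complete block are truncated.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be H×W×3 RGB")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    h, w = img.shape[0] // factor, img.shape[1] // factor
    if h == 0 or w == 0:
        raise ValueError("downscale factor larger than the image")
    if factor == 1:
        return img.copy()
    trimmed = img[: h * factor, : w * factor]
    return trimmed.reshape(h, factor, w, factor, 3).mean(axis=(1, 3))


def foreground_mask(image: np.ndarray, luminance_threshold: float = 0.8) -> np.ndarray:
    """True where a pixel is tissue: mean-channel luminance below the threshold.

    ``luminance_threshold`` is a fraction of full brightness (255); pixels at
    or above it count as (near-white) background.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be H×W×3 RGB")
    luminance = img.mean(axis=2) / 255.0
    return luminance < luminance_threshold


def extract_patches(
    image: np.ndarray, spec: PatchSpec, image_id: str = "image"
) -> list[Patch]:
    """Sample random accepted patches from one slide image.

    A candidate patch is accepted iff its background fraction is strictly
    below ``background_limit`` (a patch with exactly 75 % background is
    excluded under the default limit).  Sampling stops after
    ``max_patches_per_image`` acceptances or
    ``max_attempts_per_patch × max_patches_per_image`` attempts; a short
    count is a valid outcome.
    """
    small = downscale(image, spec.downscale_factor)
    h, w = small.shape[:2]
    if spec.patch_size > min(h, w):
        raise ConfigurationError(
            f"patch_size {spec.patch_size} exceeds downscaled image {h}x{w}"
        )
    background = ~foreground_mask(small, spec.background_luminance_threshold)
    rng = np.random.default_rng(spec.seed)
    patches: list[Patch] = []
    budget = spec.max_attempts_per_patch * spec.max_patches_per_image
    attempts = 0
    while len(patches) < spec.max_patches_per_image and attempts < budget:
        attempts += 1
        r = int(rng.integers(0, h - spec.patch_size + 1))
        c = int(rng.integers(0, w - spec.patch_size + 1))
        window = background[r : r + spec.patch_size, c : c + spec.patch_size]
        bg_frac = float(window.mean())
        if bg_frac >= spec.background_limit:
            continue
        patches.append(
            Patch(
                pixels=small[r : r + spec.patch_size, c : c + spec.patch_size].copy(),
                origin=(r, c),
                parent_image_id=image_id,
                background_fraction=bg_frac,
            )
        )
    return patches


def dataset_patch_count(
    images: list[np.ndarray], spec: PatchSpec
) -> tuple[int, list[int]]:
    """Total and per-image accepted patch counts over a collection of slides."""
    per_image = [
        len(extract_patches(img, spec, image_id=f"image_{i}"))
        for i, img in enumerate(images)
    ]
    return sum(per_image), per_image
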