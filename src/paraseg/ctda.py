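"""CT-aware data augmentation: joint affine transforms on image/mask pairs.

One augmentation is a random composition of a horizontal flip (probability
0.5), a rotation about the image center drawn uniformly from +/-20 degrees,
and a shift drawn uniformly from +/-5% of the image side independently per
axis — simulating patient positioning variation on the scanner table. The
same geometric map is applied to the image (bilinear resampling, air fill
of -1000 HU) and to its mask (nearest-neighbor resampling, zero fill), so
the pair stays consistent.

Composition order is fixed: flip, then rotate, then shift. The three maps
are composed into a single affine and resampled once, so the image is
interpolated only once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentationParams", "sample_params", "apply", "augment_dataset",
           "AugmentedSample", "AIR_FILL_HU", "SHIFT_LIMIT", "ANGLE_LIMIT_DEG"]

AIR_FILL_HU = -1000.0
SHIFT_LIMIT = 0.05
ANGLE_LIMIT_DEG = 20.0


@dataclass(frozen=True)
class AugmentationParams:
    """One sampled affine: shift fractions, flip flag, rotation angle."""

    dx: float = 0.0
    dy: float = 0.0
    hflip: bool = False
    angle_deg: float = 0.0

    def __post_init__(self):
        if abs(self.dx) > SHIFT_LIMIT + 1e-12 or abs(self.dy) > SHIFT_LIMIT + 1e-12:
            raise ValueError(f"shift ({self.dx}, {self.dy}) exceeds +/-{SHIFT_LIMIT}")
        if abs(self.angle_deg) > ANGLE_LIMIT_DEG + 1e-9:
            raise ValueError(f"|angle| {self.angle_deg} exceeds {ANGLE_LIMIT_DEG} deg")

    @property
    def is_identity(self) -> bool:
        return self.dx == 0.0 and self.dy == 0.0 and not self.hflip \
            and self.angle_deg == 0.0


def sample_params(rng: np.random.Generator | int) -> AugmentationParams:
    """Draw one transform: dx, dy ~ U(-0.05, 0.05); flip ~ Bernoulli(0.5);
    angle ~ U(-20, 20) degrees."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return AugmentationParams(
        dx=float(rng.uniform(-SHIFT_LIMIT, SHIFT_LIMIT)),
        dy=float(rng.uniform(-SHIFT_LIMIT, SHIFT_LIMIT)),
        hflip=bool(rng.random() < 0.5),
        angle_deg=float(rng.uniform(-ANGLE_LIMIT_DEG, ANGLE_LIMIT_DEG)),
    )


def _affine_matrices(params: AugmentationParams, n: int):
    """Inverse map (output coords -> input coords) as (matrix, offset).

    Coordinates are (row, col); the forward transform is
    flip -> rotate(center) -> shift, and scipy's affine_transform wants its
    inverse: unshift -> unrotate -> unflip.
    """
    c = (n - 1) / 2.0
    center = np.array([c, c])
    t = np.deg2rad(params.angle_deg)
    # inverse rotation (forward rotates content by +angle)
    rot = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
    flip = np.array([[1.0, 0.0], [0.0, -1.0 if params.hflip else 1.0]])
    shift = np.array([params.dy * n, params.dx * n])
    # x_in = F(R(x_out - shift - center)) + center, with F self-inverse
    matrix = flip @ rot
    offset = center - matrix @ (center + shift)
    return matrix, offset


def apply(image: np.ndarray, mask: np.ndarray, params: AugmentationParams):
    """Apply one joint transform; returns (image', mask') of unchanged shape.

    Image resampled bilinearly with out-of-frame regions filled with air HU;
    mask resampled nearest-neighbor with zero fill.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    if params.is_identity:
        return image.copy(), mask.copy()
    n = image.shape[0]
    matrix, offset = _affine_matrices(params, n)
    dtype = image.dtype
    img_t = ndimage.affine_transform(
        image.astype(np.float64), matrix, offset=offset, order=1,
        mode="constant", cval=AIR_FILL_HU,
    )
    if np.issubdtype(dtype, np.integer):
        img_t = np.rint(img_t).astype(dtype)
    else:
        img_t = img_t.astype(dtype)
    mask_t = ndimage.affine_transform(
        mask, matrix, offset=offset, order=0, mode="constant", cval=0,
    )
    return img_t, mask_t.astype(mask.dtype)


@dataclass
class AugmentedSample:
    """One training sample with provenance back to its source slice."""

    image: np.ndarray
    mask: np.ndarray
    source_index: int
    params: AugmentationParams | None  # None for a retained original


def augment_dataset(pairs, factor: int = 5, seed: int = 0) -> list[AugmentedSample]:
    """Expand a list of (image, mask) pairs by ``factor``.

    Output keeps each original once plus (factor - 1) independently sampled
    augmented copies, so len(output) == factor * len(pairs). Every copy
    records the params that produced it; replaying them on the source
    reproduces the copy bit-exactly.
    """
    if factor < 1:
        raise ValueError("augmentation factor must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[AugmentedSample] = []
    for i, (img, mask) in enumerate(pairs):
        out.append(AugmentedSample(np.asarray(img), np.asarray(mask), i, None))
        for _ in range(factor - 1):
            p = sample_params(rng)
            ai, am = apply(img, mask, p)
            out.append(AugmentedSample(ai, am, i, p))
    return out
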