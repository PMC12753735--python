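"""Image preprocessing: bilinear resize, unit rescaling, CLAHE contrast
enhancement, and the seven-operator affine augmentation family.

Scale convention: integer arrays are on the [0, 255] scale, float arrays
on the unit [0, 1] scale.  The dtype is the explicit scale flag;
:func:`normalize_unit` flips it and guards against double normalization.

The augmentation operators are a rotation sampled in [-20, 20] degrees,
width/height shifts in [-0.05, 0.05] of the image size, a shear factor in
[0, 0.05], zoom scale factors for a 0-0.05 zoom range, and a horizontal
flip, composed as a single affine map about the image centre; pixels
exposed by the transform are filled by clamp-to-edge nearest-neighbour
extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2ycbcr, ycbcr2rgb
from skimage.exposure import equalize_adapthist

__all__ = [
    "ResizeSpec",
    "ClaheParams",
    "AugmentRanges",
    "AffineAugmentConfig",
    "resize_bilinear",
    "normalize_unit",
    "restore_byte_scale",
    "clahe_enhance",
    "sample_augmentation",
    "apply_augmentation",
    "augment_batch",
]


@dataclass(frozen=True)
class ResizeSpec:
    """Target dims for separable bilinear resampling with half-pixel-centred
    source coordinates (each output pixel is the convex combination
    (1-a)*I[x1] + a*I[x2] of its two axis neighbours)."""

    out_height: int = 224
    out_width: int = 224

    def __post_init__(self):
        if self.out_height < 1 or self.out_width < 1:
            raise ValueError("resize target must be at least 1x1")


def _resample_axis(img: np.ndarray, out_len: int, axis: int) -> np.ndarray:
    in_len = img.shape[axis]
    # half-pixel-centred mapping; a is the fractional interpolation weight
    x = (np.arange(out_len) + 0.5) * (in_len / out_len) - 0.5
    x1 = np.floor(x).astype(np.int64)
    a = x - x1
    lo = np.clip(x1, 0, in_len - 1)
    hi = np.clip(x1 + 1, 0, in_len - 1)
    shape = [1] * img.ndim
    shape[axis] = out_len
    a = a.reshape(shape)
    return (1.0 - a) * np.take(img, lo, axis=axis) + a * np.take(img, hi, axis=axis)


def resize_bilinear(img: np.ndarray, spec: ResizeSpec) -> np.ndarray:
    """Separable bilinear resize; output dtype matches the input's."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    out = _resample_axis(img.astype(np.float64), spec.out_height, axis=0)
    out = _resample_axis(out, spec.out_width, axis=1)
    if np.issubdtype(img.dtype, np.integer):
        return np.rint(out).astype(img.dtype)
    return out.astype(img.dtype)


def normalize_unit(img: np.ndarray) -> np.ndarray:
    """Divide byte-scale pixels by 255, flipping the scale flag to unit.

    Rejects input that is already unit-scaled (float with values in
    [0, 1]) to guard against double normalization.
    """
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.floating) and img.size and img.max() <= 1.0 and img.min() >= 0.0:
        raise ValueError("input already unit-scaled; refusing to normalize twice")
    return (img.astype(np.float32) / 255.0).astype(np.float32)


def restore_byte_scale(img: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_unit` up to rounding."""
    img = np.asarray(img)
    if not np.issubdtype(img.dtype, np.floating):
        raise ValueError("input is not unit-scaled")
    return np.rint(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


@dataclass(frozen=True)
class ClaheParams:
    """Contrast-limited adaptive histogram equalization parameters.

    ``clip_limit`` uses the common OpenCV-style scale (default 2.0); it is
    mapped internally onto the normalized clip limit of the scikit-image
    backend (clip_limit / nbins with nbins = 256).  ``channels`` selects
    the luminance-only strategy (default; avoids hue shifts) or
    independent per-RGB-channel equalization.
    """

    clip_limit: float = 2.0
    tile_grid: tuple = (8, 8)
    channels: str = "luminance"  # luminance | rgb

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")
        if self.tile_grid[0] < 1 or self.tile_grid[1] < 1:
            raise ValueError("tile_grid must be at least (1, 1)")
        if self.channels not in ("luminance", "rgb"):
            raise ValueError("channels must be 'luminance' or 'rgb'")


def clahe_enhance(img: np.ndarray, p: ClaheParams | None = None) -> np.ndarray:
    """Per-tile clipped histogram equalization with bilinear inter-tile
    blending; byte-scale in, byte-scale out.

    A zero-dynamic-range image is returned unchanged (no contrast to
    redistribute), which also makes the operator idempotent on constants.
    """
    p = p or ClaheParams()
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.floating) and img.size and img.max() <= 1.0:
        raise ValueError("clahe_enhance expects the [0, 255] scale")
    h, w = img.shape[:2]
    if p.tile_grid[0] > h or p.tile_grid[1] > w:
        raise ValueError(f"tile_grid {p.tile_grid} larger than image dims {(h, w)}")
    if img.max() == img.min():
        return img.copy()
    kernel = (max(h // p.tile_grid[0], 1), max(w // p.tile_grid[1], 1))
    clip = p.clip_limit / 256.0
    x = img.astype(np.float64) / 255.0
    if img.ndim == 2 or p.channels == "rgb":
        if img.ndim == 2:
            out = equalize_adapthist(x, kernel_size=kernel, clip_limit=clip)
        else:
            out = np.stack(
                [equalize_adapthist(x[..., c], kernel_size=kernel, clip_limit=clip)
                 for c in range(x.shape[-1])], axis=-1)
    else:
        ycc = rgb2ycbcr(x)
        y = (ycc[..., 0] - 16.0) / 219.0  # video-range luma -> [0, 1]
        y_eq = equalize_adapthist(np.clip(y, 0, 1), kernel_size=kernel, clip_limit=clip)
        ycc[..., 0] = y_eq * 219.0 + 16.0
        out = np.clip(ycbcr2rgb(ycc), 0.0, 1.0)
    return np.rint(out * 255.0).astype(np.uint8)


@dataclass(frozen=True)
class AugmentRanges:
    """Closed sampling intervals for the augmentation operators."""

    rotation_deg: tuple = (-20.0, 20.0)
    shift_frac: tuple = (-0.05, 0.05)
    shear: tuple = (0.0, 0.05)
    zoom: tuple = (0.0, 0.05)  # alpha, beta = 1 + u, u in this range
    horizontal_flip: bool = True
    vertical_flip: bool = False  # off by default; not part of the core set


@dataclass(frozen=True)
class AffineAugmentConfig:
    """One sampled transform (identity by default)."""

    rotation_deg: float = 0.0
    shift_frac: tuple = (0.0, 0.0)  # (dx, dy) as fractions of (W, H)
    shear: float = 0.0
    zoom: tuple = (1.0, 1.0)  # (alpha, beta) width/height scale factors
    horizontal_flip: bool = False
    vertical_flip: bool = False

    def __post_init__(self):
        if self.zoom[0] == 0 or self.zoom[1] == 0:
            raise ValueError("zoom factors must be non-zero (non-invertible map)")


def sample_augmentation(
    ranges: AugmentRanges | None = None,
    seed: int | np.random.Generator = 0,
) -> AffineAugmentConfig:
    """Draw one transform uniformly from the stated intervals (seeded)."""
    ranges = ranges or AugmentRanges()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return AffineAugmentConfig(
        rotation_deg=float(rng.uniform(*ranges.rotation_deg)),
        shift_frac=(float(rng.uniform(*ranges.shift_frac)), float(rng.uniform(*ranges.shift_frac))),
        shear=float(rng.uniform(*ranges.shear)),
        zoom=(1.0 + float(rng.uniform(*ranges.zoom)), 1.0 + float(rng.uniform(*ranges.zoom))),
        horizontal_flip=bool(ranges.horizontal_flip and rng.random() < 0.5),
        vertical_flip=bool(ranges.vertical_flip and rng.random() < 0.5),
    )


def apply_augmentation(img: np.ndarray, t: AffineAugmentConfig) -> np.ndarray:
    """Apply the composed affine map about the image centre, then optional
    flips; exposed pixels filled by clamp-to-edge nearest-neighbour.

    Composition order is rotation -> shear -> zoom -> shift (one matrix),
    flips last.  Output dims and dtype equal the input's.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    h, w = img.shape[:2]
    th = np.deg2rad(t.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shear = np.array([[1.0, t.shear], [0.0, 1.0]])
    zoom = np.array([[t.zoom[0], 0.0], [0.0, t.zoom[1]]])
    a_xy = zoom @ shear @ rot  # applied to (x, y) column vectors
    shift = np.array([t.shift_frac[0] * w, t.shift_frac[1] * h])  # (dx, dy)
    # convert the (x, y) map to array (row, col) = (y, x) convention
    a_rc = np.array([[a_xy[1, 1], a_xy[1, 0]], [a_xy[0, 1], a_xy[0, 0]]])
    shift_rc = shift[::-1]
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    inv = np.linalg.inv(a_rc)
    offset = centre - inv @ (centre + shift_rc)
    x = img.astype(np.float64)
    if x.ndim == 2:
        out = ndi.affine_transform(x, inv, offset=offset, order=1, mode="nearest")
    else:
        m = np.eye(3)
        m[:2, :2] = inv
        off3 = np.array([offset[0], offset[1], 0.0])
        out = ndi.affine_transform(x, m, offset=off3, order=1, mode="nearest")
    if t.horizontal_flip:
        out = out[:, ::-1]
    if t.vertical_flip:
        out = out[::-1, :]
    if np.issubdtype(img.dtype, np.integer):
        return np.rint(out).astype(img.dtype)
    return out.astype(img.dtype)


def augment_batch(images: np.ndarray, rng: np.random.Generator,
                  ranges: AugmentRanges | None = None) -> np.ndarray:
    """Independently augment each image in a batch (training folds only)."""
    return np.stack([apply_augmentation(im, sample_augmentation(ranges, rng)) for im in images])
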