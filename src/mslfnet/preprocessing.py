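"""Preprocessing: deformation-free resizing, FOV masks, one-hot labels, augmentation.

Fundus datasets mix resolutions and aspect ratios, so images are brought to a
common canvas by *letterboxing* — uniform scaling plus symmetric zero padding
— which changes the canvas without distorting anatomy.  Only the circular
eyeball region (field of view, FOV) of a fundus photograph carries signal;
a binary FOV mask is recovered from the image by Otsu thresholding plus
morphological cleanup.  Labels are one-hot encoded over five channels in the
fixed order (MA, HE, SE, EX, background), background last so that the class
weights used by the loss align positionally with the lesion classes.

Training-time augmentation applies five stochastic transforms, each fired
independently with 50% probability by default: vertical flip, horizontal
flip, affine (small translation + shear), rotation, and photometric jitter
of brightness/contrast/saturation/hue within a 0.07 range.  Geometric
transforms are applied in lockstep to the image, every mask, and the label.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import filters, morphology
from skimage import transform as sktransform

from .synthetic import CLASS_NAMES, FundusSample

__all__ = [
    "PreprocessConfig",
    "OneHotLabel",
    "load_sample",
    "load_manifest",
    "letterbox_resize",
    "unletterbox_mask",
    "make_fov_mask",
    "encode_one_hot",
    "AugmentParams",
    "draw_augment_params",
    "augment",
    "BACKGROUND_INDEX",
]

#: Index of the background channel in one-hot labels (lesions first).
BACKGROUND_INDEX = 4


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    target_width: int = 1440
    target_height: int = 960
    fov_threshold: float | None = None  # None = Otsu's method
    augment: bool = True
    jitter_range: float = 0.07
    flip_prob: float = 0.5
    rotation_deg: float = 15.0
    translate_frac: float = 0.05
    shear_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.target_width <= 0 or self.target_height <= 0:
            raise ValueError("target dimensions must be positive")
        if self.jitter_range < 0:
            raise ValueError("jitter_range must be non-negative")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be a probability")
        if self.fov_threshold is not None and not 0.0 <= self.fov_threshold <= 1.0:
            raise ValueError("fov_threshold must be in [0, 1]")


@dataclasses.dataclass
class OneHotLabel:
    """Per-pixel one-hot class encoding, channels (MA, HE, SE, EX, background)."""

    y: np.ndarray  # (5, H, W) float32, exactly one channel set per pixel

    def class_index_map(self) -> np.ndarray:
        return np.argmax(self.y, axis=0)

    def validate(self) -> None:
        s = self.y.sum(axis=0)
        if not np.allclose(s, 1.0):
            raise ValueError("one-hot invariant violated: channel sums != 1")


def load_sample(row: dict[str, str | Path]) -> FundusSample:
    """Read one manifest row (image, ma, he, se, ex, fov paths) back to arrays."""
    def _read(path: str | Path) -> np.ndarray:
        try:
            return iio.imread(path)
        except OSError as exc:
            raise OSError(f"failed reading raster {path}: {exc}") from exc

    image = _read(row["image"]).astype(np.float32) / 255.0
    masks = np.stack([_read(row[c]) > 127 for c in CLASS_NAMES])
    fov = _read(row["fov"]) > 127
    sample = FundusSample(image=image, lesion_masks=masks, fov_mask=fov)
    sample.validate()
    return sample


def load_manifest(path: str | Path) -> list[dict[str, Path]]:
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            vals = line.strip().split("\t")
            rows.append({k: Path(v) for k, v in zip(header, vals)})
    return rows


def _letterbox_geometry(h: int, w: int, th: int, tw: int):
    scale = min(tw / w, th / h)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    pt, pl = (th - nh) // 2, (tw - nw) // 2
    return scale, nh, nw, pt, pl


def letterbox_resize(sample: FundusSample, config: PreprocessConfig) -> FundusSample:
    """Resize to the target canvas without deformation (uniform scale + pad).

    The scale is ``min(target_w/W, target_h/H)``; the residual canvas area is
    zero-padded, split floor/ceil between top/bottom (left/right).  The image
    is resampled bilinearly, all masks by nearest neighbour, with one shared
    geometric map.
    """
    h, w, _ = sample.image.shape
    if h == 0 or w == 0:
        raise ValueError("cannot letterbox a zero-sized raster")
    th, tw = config.target_height, config.target_width
    _, nh, nw, pt, pl = _letterbox_geometry(h, w, th, tw)
    if (nh, nw) == (h, w):
        content_img = sample.image
        content_masks = sample.lesion_masks
        content_fov = sample.fov_mask
    else:
        content_img = sktransform.resize(
            sample.image, (nh, nw), order=1, anti_aliasing=False,
            preserve_range=True).astype(np.float32)
        content_masks = np.stack([
            sktransform.resize(m.astype(np.uint8), (nh, nw), order=0,
                               anti_aliasing=False, preserve_range=True) > 0
            for m in sample.lesion_masks])
        content_fov = sktransform.resize(
            sample.fov_mask.astype(np.uint8), (nh, nw), order=0,
            anti_aliasing=False, preserve_range=True) > 0
    image = np.zeros((th, tw, 3), np.float32)
    image[pt:pt + nh, pl:pl + nw] = content_img
    masks = np.zeros((4, th, tw), bool)
    masks[:, pt:pt + nh, pl:pl + nw] = content_masks
    fov = np.zeros((th, tw), bool)
    fov[pt:pt + nh, pl:pl + nw] = content_fov
    return FundusSample(image=image, lesion_masks=masks, fov_mask=fov)


def unletterbox_mask(mask: np.ndarray, original_hw: tuple[int, int],
                     config: PreprocessConfig) -> np.ndarray:
    """Invert ``letterbox_resize`` for a binary mask (nearest-neighbour)."""
    h, w = original_hw
    _, nh, nw, pt, pl = _letterbox_geometry(h, w, config.target_height,
                                            config.target_width)
    content = mask[pt:pt + nh, pl:pl + nw]
    if (nh, nw) == (h, w):
        return content.copy()
    return sktransform.resize(content.astype(np.uint8), (h, w), order=0,
                              anti_aliasing=False, preserve_range=True) > 0


def make_fov_mask(image: np.ndarray,
                  threshold: float | None = None) -> np.ndarray:
    """Recover the circular eyeball mask from a fundus image in [0, 1].

    Thresholds the max-over-channels intensity (Otsu by default), then closes
    with a radius-5 disc, fills holes, and keeps the largest connected
    component.  Warns when the mask covers <10% or >95% of the canvas, which
    usually signals a thresholding failure.
    """
    gray = image.max(axis=2) if image.ndim == 3 else image
    if np.ptp(gray) < 1e-6:
        mask = gray > 0.5
        warnings.warn("constant image: FOV mask is trivially "
                      f"{'full' if mask.all() else 'empty'}", stacklevel=2)
        return mask
    thr = filters.threshold_otsu(gray) if threshold is None else threshold
    mask = gray > thr
    mask = morphology.closing(mask, morphology.disk(5))
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    frac = mask.mean()
    if frac < 0.10 or frac > 0.95:
        warnings.warn(f"FOV mask covers {frac:.1%} of the canvas; "
                      "threshold may have failed", stacklevel=2)
    return mask


def encode_one_hot(lesion_masks: np.ndarray,
                   fov: np.ndarray | None = None) -> OneHotLabel:
    """One-hot encode 4 disjoint lesion masks plus a trailing background channel.

    ``fov`` is accepted for interface symmetry with the rest of the pipeline;
    FOV handling happens via loss/evaluation masking, not label encoding.
    Overlapping lesion masks are rejected with the offending pixel count.
    """
    lesion_masks = np.asarray(lesion_masks, dtype=bool)
    if lesion_masks.shape[0] != 4:
        raise ValueError("expected 4 lesion masks in (MA, HE, SE, EX) order")
    overlap = lesion_masks.sum(axis=0, dtype=np.int64) > 1
    if overlap.any():
        raise ValueError(f"lesion masks overlap at {int(overlap.sum())} pixel(s); "
                         "one-hot encoding requires disjoint classes")
    background = ~lesion_masks.any(axis=0)
    y = np.concatenate([lesion_masks, background[None]]).astype(np.float32)
    label = OneHotLabel(y=y)
    label.validate()
    return label


@dataclasses.dataclass(frozen=True)
class AugmentParams:
    """Concrete draw of the five stochastic transforms (all sampled up front)."""

    vflip: bool
    hflip: bool
    do_affine: bool
    translate: tuple[float, float]  # pixels (tx, ty)
    shear_deg: float
    do_rotate: bool
    angle_deg: float
    do_jitter: bool
    brightness: float
    contrast: float
    saturation: float
    hue_shift: float


def draw_augment_params(config: PreprocessConfig, seed: int,
                        shape_hw: tuple[int, int]) -> AugmentParams:
    """Sample the five independent 50%-probability transform decisions."""
    rng = np.random.default_rng(seed)
    fires = rng.random(5) < config.flip_prob
    h, w = shape_hw
    j = config.jitter_range
    return AugmentParams(
        vflip=bool(fires[0]),
        hflip=bool(fires[1]),
        do_affine=bool(fires[2]),
        translate=(float(rng.uniform(-1, 1) * config.translate_frac * w),
                   float(rng.uniform(-1, 1) * config.translate_frac * h)),
        shear_deg=float(rng.uniform(-1, 1) * config.shear_deg),
        do_rotate=bool(fires[3]),
        angle_deg=float(rng.uniform(-1, 1) * config.rotation_deg),
        do_jitter=bool(fires[4]),
        brightness=float(rng.uniform(1 - j, 1 + j)),
        contrast=float(rng.uniform(1 - j, 1 + j)),
        saturation=float(rng.uniform(1 - j, 1 + j)),
        hue_shift=float(rng.uniform(-j, j)),
    )


def _warp_all(image: np.ndarray, index_map: np.ndarray, fov: np.ndarray,
              tform) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply one geometric map to image (bilinear) and labels (nearest)."""
    img = sktransform.warp(image, tform, order=1, cval=0.0,
                           preserve_range=True).astype(np.float32)
    idx = sktransform.warp(index_map.astype(np.float32), tform, order=0,
                           cval=float(BACKGROUND_INDEX),
                           preserve_range=True).astype(np.int64)
    fov_w = sktransform.warp(fov.astype(np.float32), tform, order=0,
                             cval=0.0, preserve_range=True) > 0.5
    return img, idx, fov_w


def augment(sample: FundusSample, label: OneHotLabel, config: PreprocessConfig,
            seed: int, params: AugmentParams | None = None
            ) -> tuple[FundusSample, OneHotLabel]:
    """Apply the five stochastic transforms; geometry in lockstep, jitter image-only.

    With ``config.augment`` false this is the identity.  ``params`` overrides
    the seeded draw (useful for forcing a single transform).  The one-hot
    invariant is preserved: geometric warps move a per-pixel class-index map
    with nearest-neighbour sampling and re-encode it afterwards.
    """
    if sample.image.shape[:2] != label.y.shape[1:]:
        raise ValueError("sample and label do not share geometry")
    if not config.augment:
        return sample, label
    if params is None:
        params = draw_augment_params(config, seed, sample.image.shape[:2])

    image = sample.image
    idx = label.class_index_map()
    fov = sample.fov_mask

    if params.vflip:
        image, idx, fov = image[::-1].copy(), idx[::-1].copy(), fov[::-1].copy()
    if params.hflip:
        image = image[:, ::-1].copy()
        idx = idx[:, ::-1].copy()
        fov = fov[:, ::-1].copy()
    if params.do_affine:
        h, w = idx.shape
        centre = np.array([w / 2.0, h / 2.0])
        shear = np.deg2rad(params.shear_deg)
        tform = (sktransform.AffineTransform(translation=-centre)
                 + sktransform.AffineTransform(shear=shear)
                 + sktransform.AffineTransform(translation=centre)
                 + sktransform.AffineTransform(translation=params.translate))
        image, idx, fov = _warp_all(image, idx, fov, tform.inverse)
    if params.do_rotate:
        h, w = idx.shape
        tform = sktransform.AffineTransform(
            rotation=np.deg2rad(params.angle_deg))
        centre = np.array([w / 2.0, h / 2.0])
        tform = (sktransform.AffineTransform(translation=-centre) + tform
                 + sktransform.AffineTransform(translation=centre))
        image, idx, fov = _warp_all(image, idx, fov, tform.inverse)
    if params.do_jitter:
        image = _colour_jitter(image, params)

    lesion_masks = np.stack([idx == c for c in range(4)])
    out_sample = FundusSample(image=image, lesion_masks=lesion_masks,
                              fov_mask=fov)
    out_label = encode_one_hot(lesion_masks)
    return out_sample, out_label


def _colour_jitter(image: np.ndarray, p: AugmentParams) -> np.ndarray:
    """Brightness/contrast/saturation as blends; hue as a cyclic HSV shift."""
    img = image * p.brightness
    gray = skcolor.rgb2gray(np.clip(img, 0, 1))
    img = (img - gray.mean()) * p.contrast + gray.mean()
    img = gray[..., None] * (1 - p.saturation) + img * p.saturation
    img = np.clip(img, 0.0, 1.0)
    hsv = skcolor.rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] + p.hue_shift) % 1.0
    return skcolor.hsv2rgb(hsv).astype(np.float32)
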