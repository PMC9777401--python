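"""Seedable generator of fundus-like images with ground-truth lesion masks.

Real fundus photographs show a bright circular field of view (FOV) on a black
background, a dark vascular tree, and — in diabetic retinopathy — four lesion
types spanning a wide size spectrum: microaneurysms (MA, few-pixel dark dots),
hemorrhages (HE, dark irregular blots), soft exudates (SE, large low-contrast
pale blobs) and hard exudates (EX, small bright deposits).  The generator
emulates exactly these structures so that every downstream component
(preprocessing, model, loss, evaluation) is testable without any dataset
download.  It does not attempt photorealism.

Lesions of different classes are kept spatially disjoint, which makes one-hot
label encoding well-defined.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = ["SynthConfig", "FundusSample", "generate_sample", "generate_dataset",
           "CLASS_NAMES"]

#: Fixed lesion-class order used throughout the package.
CLASS_NAMES = ("ma", "he", "se", "ex")

_MANIFEST_COLUMNS = ("image", "ma", "he", "se", "ex", "fov")


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic fundus generator.

    ``lesion_size_ranges`` holds per-class (min, max) radii in pixels, in the
    order (MA, HE, SE, EX).  Defaults give MA the smallest footprint and SE
    the largest, mirroring the real size spectrum (MA < EX < SE by area).
    """

    width: int = 128
    height: int = 128
    fov_radius_fraction: float = 0.45
    n_lesions_per_class: tuple[int, int, int, int] = (3, 2, 1, 2)
    lesion_size_ranges: tuple[tuple[float, float], ...] = (
        (1.0, 2.0),   # MA: few-pixel dots
        (3.0, 6.0),   # HE: mid-size blots
        (7.0, 12.0),  # SE: large diffuse blobs
        (3.0, 5.0),   # EX: small bright spots
    )
    n_vessels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if not 0.0 < self.fov_radius_fraction <= 1.0:
            raise ValueError("fov_radius_fraction must be in (0, 1]")
        if len(self.n_lesions_per_class) != 4 or any(
                n < 0 for n in self.n_lesions_per_class):
            raise ValueError("n_lesions_per_class must be 4 non-negative integers")
        if len(self.lesion_size_ranges) != 4 or any(
                lo > hi or lo <= 0 for lo, hi in self.lesion_size_ranges):
            raise ValueError("lesion_size_ranges must be 4 ordered (min,max) pairs")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be non-negative")


@dataclasses.dataclass
class FundusSample:
    """An RGB image with per-class lesion masks and a FOV mask, all H x W.

    ``image`` is float32 in [0, 1]; ``lesion_masks`` is a (4, H, W) boolean
    stack in (MA, HE, SE, EX) order; ``fov_mask`` is boolean.
    """

    image: np.ndarray
    lesion_masks: np.ndarray
    fov_mask: np.ndarray

    def validate(self) -> None:
        h, w, _ = self.image.shape
        if self.lesion_masks.shape != (4, h, w) or self.fov_mask.shape != (h, w):
            raise ValueError("rasters do not share a common geometry")
        if np.logical_and(self.lesion_masks.any(axis=0), ~self.fov_mask).any():
            raise ValueError("lesion pixels found outside the FOV mask")
        if self.lesion_masks.sum(axis=0, dtype=np.int64).max(initial=0) > 1:
            raise ValueError("lesion masks of different classes overlap")


def _splitmix64(x: int) -> int:
    """SplitMix64 finalizer; used to derive independent per-sample seeds."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return z ^ (z >> 31)


def sample_rng(seed: int, index: int) -> np.random.Generator:
    """RNG for sample ``index`` under global ``seed`` (splitmix-derived)."""
    return np.random.default_rng(_splitmix64((seed << 20) + index))


def _disc(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def _blob(h: int, w: int, cy: float, cx: float, r: float,
          rng: np.random.Generator) -> np.ndarray:
    """Irregular connected blob: a centre disc unioned with offset discs."""
    mask = _disc(h, w, cy, cx, r)
    for _ in range(rng.integers(2, 5)):
        dy, dx = rng.uniform(-r / 2, r / 2, size=2)
        mask |= _disc(h, w, cy + dy, cx + dx, r * rng.uniform(0.5, 0.9))
    return mask


def _vessel_mask(h: int, w: int, cy: float, cx: float, r_fov: float,
                 rng: np.random.Generator) -> np.ndarray:
    """One dark curvilinear distractor: a quadratic Bezier inside the FOV."""
    ang = rng.uniform(0, 2 * np.pi, size=3)
    rad = rng.uniform(0.15, 0.85, size=3) * r_fov
    pts = np.stack([cy + rad * np.sin(ang), cx + rad * np.cos(ang)], axis=1)
    t = np.linspace(0.0, 1.0, 4 * int(r_fov) + 8)[:, None]
    curve = ((1 - t) ** 2 * pts[0] + 2 * (1 - t) * t * pts[1] + t ** 2 * pts[2])
    mask = np.zeros((h, w), bool)
    ij = np.round(curve).astype(int)
    ok = (ij[:, 0] >= 0) & (ij[:, 0] < h) & (ij[:, 1] >= 0) & (ij[:, 1] < w)
    mask[ij[ok, 0], ij[ok, 1]] = True
    if rng.random() < 0.5:
        mask = ndimage.binary_dilation(mask)
    return mask


# Per-class appearance: (rgb multiplier or additive colour, additive?)
_LESION_STYLE = {
    0: (np.array([0.35, 0.30, 0.35]), False),  # MA: small dark dots
    1: (np.array([0.40, 0.25, 0.30]), False),  # HE: dark blots
    2: (np.array([1.25, 1.20, 1.10]), False),  # SE: pale, low contrast
    3: (np.array([1.00, 0.95, 0.55]), True),   # EX: bright yellow deposits
}


def generate_sample(config: SynthConfig, index: int = 0) -> FundusSample:
    """Generate one fundus-like sample with exact per-class lesion counts.

    Output is a pure function of ``(config, index)``.  Each requested lesion
    is a single connected component inside the FOV disc; components of all
    classes are pairwise disjoint and separated by at least one background
    pixel, so connected-component counts equal the requested counts exactly.

    Raises ``RuntimeError`` if a lesion cannot be placed within the retry
    budget (canvas too small for the requested configuration).
    """
    rng = sample_rng(config.seed, index)
    h, w = config.height, config.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_fov = config.fov_radius_fraction * min(h, w)
    fov = _disc(h, w, cy, cx, r_fov)

    # Background tissue: warm base colour, radial vignette, smooth texture.
    yy, xx = np.mgrid[:h, :w]
    rad = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / max(r_fov, 1.0)
    vign = np.clip(1.0 - 0.35 * rad ** 2, 0.0, 1.0)
    tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 3.0)
    tex = 0.04 * tex / max(np.abs(tex).max(), 1e-8)
    base = np.array([0.72, 0.38, 0.14])
    image = base[None, None, :] * (vign + tex)[..., None]

    for _ in range(config.n_vessels):
        vm = _vessel_mask(h, w, cy, cx, r_fov, rng) & fov
        image[vm] *= np.array([0.45, 0.30, 0.35])

    occupied = np.zeros((h, w), bool)
    lesion_masks = np.zeros((4, h, w), bool)
    for cls in range(4):
        lo, hi = config.lesion_size_ranges[cls]
        for k in range(config.n_lesions_per_class[cls]):
            placed = False
            for _ in range(500):
                r = rng.uniform(lo, hi)
                margin = r + 3.0
                if margin >= r_fov:
                    continue
                ang = rng.uniform(0, 2 * np.pi)
                rr = rng.uniform(0, r_fov - margin)
                ly, lx = cy + rr * np.sin(ang), cx + rr * np.cos(ang)
                mask = (_blob(h, w, ly, lx, r, rng) if cls == 1
                        else _disc(h, w, ly, lx, r))
                if not mask.any() or not (mask <= fov).all():
                    continue
                if (ndimage.binary_dilation(mask) & occupied).any():
                    continue
                lesion_masks[cls] |= mask
                occupied |= ndimage.binary_dilation(mask)
                colour, additive = _LESION_STYLE[cls]
                if cls == 2:  # SE: soft edge via feathered alpha
                    alpha = ndimage.gaussian_filter(mask.astype(float), 1.5)
                    alpha = np.clip(alpha, 0, 1)[..., None]
                    image = image * (1 - 0.5 * alpha) + 0.5 * alpha * (
                        image * colour[None, None, :])
                elif additive:
                    image[mask] = 0.35 * image[mask] + 0.65 * colour
                else:
                    image[mask] *= colour
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place lesion {k} of class {CLASS_NAMES[cls]!r} "
                    f"within the retry budget; canvas {w}x{h} too crowded")

    image = np.clip(image, 0.0, 1.0)
    image[~fov] = 0.0
    # Quantize to 8 bits so the on-disk PNG round-trips bit-identically.
    image = (np.round(image * 255.0).astype(np.uint8) / np.float32(255.0)).astype(
        np.float32)
    sample = FundusSample(image=image, lesion_masks=lesion_masks, fov_mask=fov)
    sample.validate()
    return sample


def generate_dataset(config: SynthConfig, n_samples: int,
                     out_dir: str | Path) -> list[dict[str, Path]]:
    """Write ``n_samples`` samples as 8-bit PNGs plus a TSV manifest.

    Per sample: one RGB image, four binary {0,255} lesion masks and one FOV
    mask.  The manifest (``manifest.tsv``) has one row per sample with columns
    (image, ma, he, se, ex, fov).  Returns the manifest as a list of per-sample
    path dictionaries keyed by those column names.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict[str, Path]] = []
    for i in range(n_samples):
        sample = generate_sample(config, index=i)
        row: dict[str, Path] = {}
        stem = f"sample_{i:04d}"
        try:
            path = out_dir / f"{stem}.png"
            iio.imwrite(path, np.round(sample.image * 255.0).astype(np.uint8))
            row["image"] = path
            for c, name in enumerate(CLASS_NAMES):
                path = out_dir / f"{stem}_{name}.png"
                iio.imwrite(path, sample.lesion_masks[c].astype(np.uint8) * 255)
                row[name] = path
            path = out_dir / f"{stem}_fov.png"
            iio.imwrite(path, sample.fov_mask.astype(np.uint8) * 255)
            row["fov"] = path
        except OSError as exc:
            raise OSError(f"failed writing raster {path}: {exc}") from exc
        rows.append(row)
    manifest = out_dir / "manifest.tsv"
    try:
        with open(manifest, "w") as fh:
            fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in _MANIFEST_COLUMNS) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing manifest {manifest}: {exc}") from exc
    return rows
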