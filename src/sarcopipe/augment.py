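"""Tumor-preserving augmentation and fixed-size training-pool construction.

Training pools are built per class to an exact target size by sampling
source slices uniformly *with replacement* (uniform over slices, not over
patients or sequences) and attaching a fresh transform seed to each draw.
The pool is a manifest, not a directory of files: a pool of 437,500 slices
per class exists as 875,000 CSV rows and is materialized lazily, one crop at
a time, during training. Transforms are the standard quartet — flips,
rotation, zoom, brightness — followed by a tumor-preserving crop to the
network input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import LABELS, SliceRecord

__all__ = [
    "AugmentConfig",
    "random_transform",
    "crop_to_roi",
    "augment_pool",
    "load_slice_image",
    "materialize",
    "POOL_COLUMNS",
]

POOL_COLUMNS = ["pool_id", "class", "source_slice_id", "transform_seed"]

_MAX_RETRIES = 10


@dataclass
class AugmentConfig:
    """Augmentation ranges and pool target.

    Ranges default to a general-purpose quartet: horizontal+vertical flips,
    rotation within ±20 degrees, zoom in [0.9, 1.1], multiplicative
    brightness in [0.8, 1.2]. ``target_per_class`` is the exact number of
    pool entries per class (437,500 at full scale; desk-scale runs use a few
    hundred).
    """

    target_per_class: int = 437_500
    flip: bool = True
    rotation_deg_range: tuple[float, float] = (-20.0, 20.0)
    zoom_range: tuple[float, float] = (0.9, 1.1)
    brightness_range: tuple[float, float] = (0.8, 1.2)
    crop_size: tuple[int, int] = (224, 224)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_per_class < 1:
            raise ValueError("target_per_class must be positive")
        if self.crop_size[0] < 1 or self.crop_size[1] < 1:
            raise ValueError("crop_size must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            not self.flip
            and self.rotation_deg_range == (0.0, 0.0)
            and self.zoom_range == (1.0, 1.0)
            and self.brightness_range == (1.0, 1.0)
        )


def _transform_bbox_affine(
    bbox: tuple[int, int, int, int],
    matrix: np.ndarray,
    shape: tuple[int, int],
) -> tuple[int, int, int, int] | None:
    """Axis-aligned envelope of a bbox mapped through a 2x3 affine (x, y)."""
    x0, y0, x1, y1 = bbox
    corners = np.array(
        [[x0, y0], [x1 - 1, y0], [x0, y1 - 1], [x1 - 1, y1 - 1]], dtype=float
    )
    mapped = corners @ matrix[:, :2].T + matrix[:, 2]
    h, w = shape
    eps = 1e-9
    nx0 = int(np.floor(mapped[:, 0].min() + eps))
    ny0 = int(np.floor(mapped[:, 1].min() + eps))
    nx1 = int(np.ceil(mapped[:, 0].max() - eps)) + 1
    ny1 = int(np.ceil(mapped[:, 1].max() - eps)) + 1
    nx0, ny0 = max(nx0, 0), max(ny0, 0)
    nx1, ny1 = min(nx1, w), min(ny1, h)
    if nx1 <= nx0 or ny1 <= ny0:
        return None
    return (nx0, ny0, nx1, ny1)


def random_transform(
    image: np.ndarray,
    bbox: tuple[int, int, int, int],
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Apply one random flip/rotation/zoom/brightness draw; track the bbox.

    The returned bbox is the axis-aligned envelope of the transformed tumor
    region, clipped to the canvas. A draw that would push the tumor fully
    off-canvas is re-drawn (bounded retries) before raising.
    """
    h, w = image.shape[:2]
    for _ in range(_MAX_RETRIES):
        hflip = config.flip and rng.random() < 0.5
        vflip = config.flip and rng.random() < 0.5
        angle = rng.uniform(*config.rotation_deg_range)
        zoom = rng.uniform(*config.zoom_range)
        brightness = rng.uniform(*config.brightness_range)

        out = np.asarray(image, dtype=np.float64)
        bx = bbox
        if hflip:
            out = out[:, ::-1]
            bx = (w - bx[2], bx[1], w - bx[0], bx[3])
        if vflip:
            out = out[::-1, :]
            bx = (bx[0], h - bx[3], bx[2], h - bx[1])

        if angle != 0.0 or zoom != 1.0:
            # rotate+zoom about the canvas centre as one affine map
            theta = np.deg2rad(angle)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            fwd = zoom * rot  # pixel (x, y) forward map
            cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
            centre = np.array([cx, cy])
            offset_fwd = centre - fwd @ centre
            # ndimage.affine_transform wants the inverse map in (row, col)
            inv = np.linalg.inv(fwd)
            inv_rc = inv[::-1, ::-1]  # swap x/y axes to row/col convention
            offset_rc = (centre - inv @ centre)[::-1]
            out = ndimage.affine_transform(
                out, inv_rc, offset=offset_rc, order=1, mode="reflect"
            )
            bx = _transform_bbox_affine(
                bx, np.column_stack([fwd, offset_fwd]), (h, w)
            )
            if bx is None:
                continue  # tumor left the canvas: re-draw

        out = np.clip(out * brightness, 0.0, 255.0)
        return out, bx
    raise ValueError("transform repeatedly pushed the tumor off-canvas")


def _resize_isotropic(image: np.ndarray, crop: tuple[int, int]) -> np.ndarray:
    """Upscale so the larger dimension meets the crop, then centre-pad."""
    ch, cw = crop
    h, w = image.shape[:2]
    scale = max(ch / h, cw / w)
    out = ndimage.zoom(image, (scale, scale), order=1)
    out = out[:ch, :cw]
    ph, pw = ch - out.shape[0], cw - out.shape[1]
    if ph or pw:
        out = np.pad(
            out,
            ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)),
            mode="edge",
        )
    return out


def _window_start(
    b0: int, b1: int, extent: int, crop: int, rng, deterministic: bool
) -> int:
    """Feasible window start on one axis: contains the bbox centre and the
    maximal feasible fraction of the bbox."""
    centre = (b0 + b1) // 2
    if b1 - b0 <= crop:
        lo, hi = b1 - crop, b0  # full bbox containment
    else:
        lo, hi = b0, b1 - crop  # window inside the bbox (overlap = crop)
        lo, hi = max(lo, centre - crop + 1), min(hi, centre)
    lo, hi = max(lo, 0), min(hi, extent - crop)
    if lo > hi:  # border clamping collapsed the range
        lo = hi = int(np.clip(centre - crop // 2, 0, extent - crop))
    if deterministic:
        return int(np.clip(centre - crop // 2, lo, hi))
    return int(rng.integers(lo, hi + 1))


def crop_to_roi(
    image: np.ndarray,
    bbox: tuple[int, int, int, int],
    crop_size: tuple[int, int] = (224, 224),
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
) -> np.ndarray:
    """Crop to ``crop_size`` keeping the tumor in scope.

    The window always contains the bbox centre and the maximal feasible
    fraction of the bbox; in deterministic mode (evaluation) it is centred
    on the tumor up to border clamping, otherwise the start is sampled
    uniformly among feasible positions. Images smaller than the crop are
    isotropically resized and padded first.
    """
    if image.size == 0:
        raise ValueError("empty image")
    if deterministic or rng is None:
        rng = np.random.default_rng(0)
    ch, cw = crop_size
    h, w = image.shape[:2]
    if h < ch or w < cw:
        return _resize_isotropic(np.asarray(image, dtype=np.float64), crop_size)
    if (h, w) == (ch, cw):
        return np.asarray(image, dtype=np.float64).copy()
    x0 = _window_start(bbox[0], bbox[2], w, cw, rng, deterministic)
    y0 = _window_start(bbox[1], bbox[3], h, ch, rng, deterministic)
    return np.asarray(image[y0 : y0 + ch, x0 : x0 + cw], dtype=np.float64).copy()


def augment_pool(records: list[SliceRecord], config: AugmentConfig) -> pd.DataFrame:
    """Build a balanced augmented-pool manifest.

    Exactly ``target_per_class`` entries per class; each entry draws its
    source slice uniformly with replacement from that class's slices and
    carries a fresh transform seed. Total pool size is
    ``2 * target_per_class``. Reproducible for a fixed config seed.
    """
    by_class = {label: [r for r in records if r.label == label] for label in LABELS}
    for label, rs in by_class.items():
        if not rs:
            raise ValueError(f"class {label!r} has no source slices")
    rng = np.random.default_rng(config.seed)
    rows = []
    pool_id = 0
    for label in LABELS:
        rs = by_class[label]
        picks = rng.integers(0, len(rs), size=config.target_per_class)
        seeds = rng.integers(0, 2**31 - 1, size=config.target_per_class)
        for pick, tseed in zip(picks, seeds):
            rows.append(
                {
                    "pool_id": pool_id,
                    "class": label,
                    "source_slice_id": rs[pick].slice_id,
                    "transform_seed": int(tseed),
                }
            )
            pool_id += 1
    return pd.DataFrame(rows, columns=POOL_COLUMNS)


def load_slice_image(record: SliceRecord) -> np.ndarray:
    """Read a slice image as a float64 grayscale array."""
    from PIL import Image

    with Image.open(record.image_path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64)


def materialize(
    record: SliceRecord,
    transform_seed: int,
    config: AugmentConfig,
    crop_size: tuple[int, int] | None = None,
) -> np.ndarray:
    """Materialize one pool entry: load, transform, crop.

    Returns a float64 array of ``crop_size`` (defaults to the config's crop)
    in [0, 255]. With an identity config the result is a plain resampled
    crop of the source image.
    """
    crop = crop_size or config.crop_size
    rng = np.random.default_rng(transform_seed)
    image = load_slice_image(record)
    if config.is_identity:
        out, bbox = np.asarray(image, dtype=np.float64), record.tumor_bbox
    else:
        out, bbox = random_transform(image, record.tumor_bbox, config, rng)
    return crop_to_roi(out, bbox, crop, rng=rng, deterministic=False)
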