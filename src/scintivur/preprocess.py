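"""Preprocessing of posterior renal scintigrams.

Pipeline: integral background subtraction (rectangular low-uptake ROIs
diagonally above each kidney) -> Otsu delineation of the bilateral cortical
outline -> fixed midline with symmetric completion when one kidney is
missing -> minimum bounding rectangle with >=10 px margins -> pad to a 2:1
aspect ratio -> bilinear resize to 224x448 -> split into two 224x224
per-kidney inputs.

Conventions: arrays are row-major, 0-based; boxes are half-open
(top, left, height, width). Images flow through as floats on the 8-bit
scale [0, 255] until `normalise`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure, transform
from skimage.filters import threshold_otsu

__all__ = [
    "PreprocessConfig",
    "AugmentConfig",
    "BilateralCrop",
    "KidneyROI",
    "otsu_threshold",
    "background_correct",
    "delineate_and_crop",
    "split_sides",
    "augment",
    "normalise",
    "preprocess_scan",
]

CROP_HEIGHT = 224
CROP_WIDTH = 448
ROI_SIZE = 224


@dataclass(frozen=True)
class AugmentConfig:
    p_flip: float = 0.5
    max_rotation_deg: float = 15.0
    crop_scale: tuple[float, float] = (0.8, 1.0)
    brightness: float = 0.15  # additive jitter as a fraction of 255
    contrast: float = 0.15  # multiplicative jitter around 1


@dataclass(frozen=True)
class PreprocessConfig:
    margin_px: int = 10
    min_component_area: int = 200  # px; smaller Otsu blobs are ignored
    background_roi_area_frac: float = 0.25  # of the kidney bounding box
    background_roi_offset_px: int = 5  # diagonal offset from the bbox corner
    norm_mean: float = 0.5  # on the [0,1] scale, after /255
    norm_std: float = 0.25
    augment: AugmentConfig = field(default_factory=AugmentConfig)


@dataclass(frozen=True)
class BilateralCrop:
    """Standardised 224x448 bilateral view with per-side masks."""

    image: np.ndarray  # float, (224, 448)
    midline_column: int  # splits into two 224x224 halves
    left_mask: np.ndarray  # bool, (224, 448)
    right_mask: np.ndarray
    crop_box: tuple[int, int, int, int]  # (top, left, height, width), source coords
    otsu_level: float = float("nan")

    def __post_init__(self) -> None:
        if self.image.shape != (CROP_HEIGHT, CROP_WIDTH):
            raise ValueError("bilateral crop must be exactly 224x448")


@dataclass(frozen=True)
class KidneyROI:
    """One 224x224 kidney input with the mask-mean tracer uptake."""

    side: str  # "left" | "right"
    image: np.ndarray  # float, (224, 224)
    mean_intensity: float  # mean grey level over the kidney mask
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.image.shape != (ROI_SIZE, ROI_SIZE):
            raise ValueError("kidney ROI must be exactly 224x224")


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu's threshold over the 256-bin histogram.

    Returns the level maximising between-class variance; foreground is
    ``image > threshold``. Raises on a constant image.
    """
    arr = np.asarray(image)
    if np.all(arr == arr.flat[0]):
        raise ValueError("degenerate histogram: image has a single intensity value")
    return float(threshold_otsu(arr, nbins=256))


def _kidney_components(mask: np.ndarray, min_area: int):
    """Largest (up to two) connected foreground components, left first."""
    labels = measure.label(mask, connectivity=2)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area]
    props.sort(key=lambda p: p.area, reverse=True)
    props = sorted(props[:2], key=lambda p: p.centroid[1])
    return props


def _clamp_box(top: int, left: int, h: int, w: int, shape: tuple[int, int]):
    t = max(0, top)
    l = max(0, left)
    b = min(shape[0], top + h)
    r = min(shape[1], left + w)
    return t, l, b - t, r - l


def background_correct(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Integral background subtraction.

    One rectangular low-uptake ROI is placed diagonally above-left of the
    left kidney's bounding box and one above-right of the right kidney's,
    each with ~25% of the kidney-box area; the pooled mean over both ROIs is
    subtracted from every pixel, clipping at 0.
    """
    config = config or PreprocessConfig()
    arr = np.asarray(image, dtype=float)
    level = otsu_threshold(arr)
    mask = arr > level
    props = _kidney_components(mask, config.min_component_area)
    if not props:
        raise ValueError("no kidney foreground detected; cannot place background ROIs")
    off = config.background_roi_offset_px
    scale = np.sqrt(config.background_roi_area_frac)
    boxes = []
    for which, p in enumerate(props if len(props) == 2 else props * 2):
        minr, minc, maxr, maxc = p.bbox
        bh, bw = maxr - minr, maxc - minc
        rh, rw = max(1, int(round(bh * scale))), max(1, int(round(bw * scale)))
        top = minr - off - rh
        left = minc - off - rw if which == 0 else maxc + off
        boxes.append(_clamp_box(top, left, rh, rw, arr.shape))
    pixels = []
    for t, l, h, w in boxes:
        if h > 0 and w > 0:
            pixels.append(arr[t : t + h, l : l + w].ravel())
    if not pixels:
        raise ValueError("background ROIs have zero area after clamping to the image")
    background = float(np.mean(np.concatenate(pixels)))
    return np.clip(arr - background, 0.0, None)


def delineate_and_crop(
    corrected: np.ndarray, config: PreprocessConfig | None = None
) -> BilateralCrop:
    """Bilateral contouring, fixed midline, symmetric completion and crop.

    The midline is the vertical line at the mean column-centroid of the two
    largest Otsu components and is computed once per scan. If only one
    kidney is detected, its mask is mirrored across the midline (taken at
    the image centre column) to complete the bilateral outline. The crop is
    the minimum bounding rectangle of the mask union with >=10 px margins
    (clamped at borders), widened so the midline sits at its centre, padded
    to a 2:1 aspect with the background median, and resized to 224x448.
    """
    config = config or PreprocessConfig()
    arr = np.asarray(corrected, dtype=float)
    level = otsu_threshold(arr)
    fg = arr > level
    props = _kidney_components(fg, config.min_component_area)
    if not props:
        raise ValueError("no kidney detected")
    labels = measure.label(fg, connectivity=2)
    union = np.zeros_like(fg)
    for p in props:
        union |= labels == p.label
    if len(props) == 2:
        midline = (props[0].centroid[1] + props[1].centroid[1]) / 2.0
        left_mask_src = labels == props[0].label
        right_mask_src = labels == props[1].label
    else:
        # single kidney: mirror across the canvas centre to complete the pair
        midline = arr.shape[1] / 2.0
        mirrored = _mirror_about(union, midline)
        if props[0].centroid[1] <= midline:
            left_mask_src, right_mask_src = union.copy(), mirrored
        else:
            left_mask_src, right_mask_src = mirrored, union.copy()
        union = union | mirrored

    m = config.margin_px
    rows = np.any(union, axis=1).nonzero()[0]
    cols = np.any(union, axis=0).nonzero()[0]
    top, bottom = int(rows[0]), int(rows[-1]) + 1
    left, right = int(cols[0]), int(cols[-1]) + 1
    top, bottom = max(0, top - m), min(arr.shape[0], bottom + m)
    # widen symmetrically so the midline is the horizontal centre
    half = max(midline - (left - m), (right + m) - midline)
    left = int(np.floor(midline - half))
    right = int(np.ceil(midline + half))
    left, right = max(0, left), min(arr.shape[1], right)
    crop_box = (top, left, bottom - top, right - left)

    crop = arr[top:bottom, left:right]
    lmask = left_mask_src[top:bottom, left:right]
    rmask = right_mask_src[top:bottom, left:right]
    bg_level = float(np.median(crop[crop <= level])) if np.any(crop <= level) else 0.0

    # pad to exact 2:1 (width = 2 * height), symmetric about the midline
    h, w = crop.shape
    if w < 2 * h:
        pad = 2 * h - w
        pl, pr = pad // 2, pad - pad // 2
        crop = np.pad(crop, ((0, 0), (pl, pr)), constant_values=bg_level)
        lmask = np.pad(lmask, ((0, 0), (pl, pr)))
        rmask = np.pad(rmask, ((0, 0), (pl, pr)))
    elif w > 2 * h:
        if w % 2:  # make width even, one column each side keeps the midline centred
            crop = np.pad(crop, ((0, 0), (1, 1)), constant_values=bg_level)
            lmask = np.pad(lmask, ((0, 0), (1, 1)))
            rmask = np.pad(rmask, ((0, 0), (1, 1)))
        pad_v = crop.shape[1] // 2 - h
        pt, pb = pad_v // 2, pad_v - pad_v // 2
        crop = np.pad(crop, ((pt, pb), (0, 0)), constant_values=bg_level)
        lmask = np.pad(lmask, ((pt, pb), (0, 0)))
        rmask = np.pad(rmask, ((pt, pb), (0, 0)))

    image = transform.resize(
        crop, (CROP_HEIGHT, CROP_WIDTH), order=1, preserve_range=True, anti_aliasing=False
    )
    lmask_r = transform.resize(lmask.astype(float), (CROP_HEIGHT, CROP_WIDTH), order=0) > 0.5
    rmask_r = transform.resize(rmask.astype(float), (CROP_HEIGHT, CROP_WIDTH), order=0) > 0.5
    return BilateralCrop(
        image=image,
        midline_column=CROP_WIDTH // 2,
        left_mask=lmask_r,
        right_mask=rmask_r,
        crop_box=crop_box,
        otsu_level=level,
    )


def _mirror_about(mask: np.ndarray, midline: float) -> np.ndarray:
    cols = np.arange(mask.shape[1])
    mirrored_cols = np.rint(2.0 * midline - cols).astype(int)
    valid = (mirrored_cols >= 0) & (mirrored_cols < mask.shape[1])
    out = np.zeros_like(mask)
    out[:, mirrored_cols[valid]] = mask[:, cols[valid]]
    return out


def split_sides(crop: BilateralCrop, patient_id: str = "") -> tuple[KidneyROI, KidneyROI]:
    """Split the bilateral crop at the midline into two 224x224 inputs.

    ``mean_intensity`` is the mean grey level over the kidney mask (tracks
    tracer uptake); if a mask half is empty the mean over the half-image is
    used as a fallback.
    """
    mid = crop.midline_column
    halves = {
        "left": (crop.image[:, :mid], crop.left_mask[:, :mid]),
        "right": (crop.image[:, mid:], crop.right_mask[:, mid:]),
    }
    rois = {}
    for side, (img, mask) in halves.items():
        mean = float(img[mask].mean()) if mask.any() else float(img.mean())
        rois[side] = KidneyROI(side=side, image=img, mean_intensity=mean, patient_id=patient_id)
    return rois["left"], rois["right"]


def augment(
    roi: KidneyROI,
    seed: int,
    config: AugmentConfig | None = None,
    enabled: bool = True,
) -> KidneyROI:
    """Seeded training-time augmentation; identity when disabled.

    Horizontal flip (p=0.5), rotation uniform in +/-15 degrees, random
    resized crop back to 224x224, and brightness/contrast jitter. Output
    stays on the [0, 255] scale.
    """
    if not enabled:
        return roi
    config = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    img = roi.image.astype(float)
    if rng.random() < config.p_flip:
        img = img[:, ::-1]
    angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
    img = transform.rotate(img, angle, order=1, preserve_range=True, mode="constant", cval=0.0)
    # random resized crop: sample an area fraction, crop, resize back
    scale = rng.uniform(*config.crop_scale)
    side = max(8, int(round(ROI_SIZE * np.sqrt(scale))))
    top = int(rng.integers(0, ROI_SIZE - side + 1))
    left = int(rng.integers(0, ROI_SIZE - side + 1))
    img = img[top : top + side, left : left + side]
    img = transform.resize(img, (ROI_SIZE, ROI_SIZE), order=1, preserve_range=True)
    gain = 1.0 + rng.uniform(-config.contrast, config.contrast)
    offset = 255.0 * rng.uniform(-config.brightness, config.brightness)
    img = np.clip(gain * img + offset, 0.0, 255.0)
    return replace(roi, image=img)


def normalise(
    roi: KidneyROI | np.ndarray, mean: float = 0.5, std: float = 0.25
) -> np.ndarray:
    """Scale [0,255] -> [0,1] then standardise: ``(x/255 - mean) / std``."""
    img = roi.image if isinstance(roi, KidneyROI) else np.asarray(roi, dtype=float)
    return ((img / 255.0 - mean) / std).astype(np.float32)


def preprocess_scan(
    image: np.ndarray, patient_id: str = "", config: PreprocessConfig | None = None
) -> tuple[BilateralCrop, KidneyROI, KidneyROI]:
    """Full deterministic chain: correct -> delineate/crop -> split."""
    config = config or PreprocessConfig()
    corrected = background_correct(image, config)
    crop = delineate_and_crop(corrected, config)
    left, right = split_sides(crop, patient_id=patient_id)
    return crop, left, right
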