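"""CT slice preparation: minimum-rectangle crops, Lanczos resize, windowing.

Two image inputs are produced per slice: the tumor cropped by its minimum
bounding rectangle, and the kidney-plus-tumor region cropped by the bounding
rectangle of the union of both masks.  Crops are resampled to a square model
input (128x128 by default) with a Lanczos kernel and intensity-windowed to
[0, 1].  Coordinates are 0-based row-major and boxes are inclusive on both
ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Tuple

import numpy as np
from PIL import Image

DEFAULT_WINDOW = (-200.0, 500.0)  # soft-tissue HU window for model input

# segmentation label convention for NIfTI volumes
LABEL_KIDNEY = 1
LABEL_TUMOR = 2


@dataclass
class SlicePair:
    """One axial CT slice with its kidney and tumor masks."""

    ct: np.ndarray
    tumor_mask: np.ndarray
    kidney_mask: np.ndarray
    patient_id: str
    slice_index: int

    def __post_init__(self):
        if self.tumor_mask.shape != self.ct.shape or self.kidney_mask.shape != self.ct.shape:
            raise ValueError("masks must match the CT raster shape")


def bounding_box(mask: np.ndarray) -> Tuple[int, int, int, int]:
    """Inclusive bounding box (rmin, rmax, cmin, cmax) of mask-true pixels."""
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    if not rows.any():
        raise ValueError("empty mask has no bounding box")
    rmin, rmax = np.where(rows)[0][[0, -1]]
    cmin, cmax = np.where(cols)[0][[0, -1]]
    return int(rmin), int(rmax), int(cmin), int(cmax)


def crop_min_rect(ct: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Crop the CT raster by the minimum rectangle containing the mask."""
    rmin, rmax, cmin, cmax = bounding_box(mask)
    return ct[rmin:rmax + 1, cmin:cmax + 1]


def resize_128(cropped: np.ndarray, size: int = 128) -> np.ndarray:
    """Lanczos (a=3) resampling of a crop to size x size, float output."""
    if cropped.size == 0:
        raise ValueError("cannot resize an empty crop")
    img = Image.fromarray(np.asarray(cropped, dtype=np.float32), mode="F")
    out = img.resize((size, size), Image.Resampling.LANCZOS)
    return np.asarray(out, dtype=np.float32)


def normalize_intensity(raster: np.ndarray,
                        window: Tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    """Clip to the HU window then map affinely to [0, 1]."""
    lo, hi = window
    if lo >= hi:
        raise ValueError(f"invalid window: lo={lo} >= hi={hi}")
    return (np.clip(raster, lo, hi) - lo) / (hi - lo)


def prepare_slice_inputs(pair: SlicePair, size: int = 128,
                         window: Tuple[float, float] = DEFAULT_WINDOW):
    """Model inputs for one slice: (tumor_crop, kidney_plus_tumor_crop).

    Both are size x size rasters in [0, 1].  The kidney-plus-tumor crop uses
    the bounding box of the union of the two masks, so it always spatially
    contains the tumor crop's source box.
    """
    tumor = normalize_intensity(resize_128(crop_min_rect(pair.ct, pair.tumor_mask), size),
                                window)
    union = pair.kidney_mask | pair.tumor_mask
    kidney = normalize_intensity(resize_128(crop_min_rect(pair.ct, union), size), window)
    return tumor, kidney


def iter_nifti_slices(image_path, seg_path, patient_id: str,
                      axis: int = 2) -> Iterator[SlicePair]:
    """Yield SlicePairs from a NIfTI volume and its segmentation.

    Segmentation labels: 0 background, 1 kidney, 2 tumor.  Slices without any
    tumor pixels are skipped.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(image_path)).dataobj)
    seg = np.asanyarray(nib.load(str(seg_path)).dataobj)
    if vol.shape != seg.shape:
        raise ValueError("image and segmentation shapes differ")
    for k in range(vol.shape[axis]):
        ct = np.take(vol, k, axis=axis).astype(np.float32)
        labels = np.take(seg, k, axis=axis)
        tumor = labels == LABEL_TUMOR
        if not tumor.any():
            continue
        yield SlicePair(ct=ct, tumor_mask=tumor, kidney_mask=labels == LABEL_KIDNEY,
                        patient_id=patient_id, slice_index=k)
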