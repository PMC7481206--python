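"""Contrast-enhancing ROI segmentation by normalized T1 subtraction.

Pre- and post-contrast T1-weighted volumes (assumed co-registered
upstream) are each z-scored within the brain mask, subtracted
voxel-wise, and voxels with a strictly positive difference are kept.
Small connected components (26-connectivity) are removed to suppress
salt noise. The resulting mask is the region from which ADC histograms
are taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError
from .volumes import AnatomicalVolume, _check_spacing


@dataclass
class EnhancementMask:
    """Binary contrast-enhancement mask with its grid spacing."""

    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got {self.mask.ndim}-D")
        self.voxel_size_mm = _check_spacing(self.voxel_size_mm)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cc(self) -> float:
        # 1 cc = 1000 mm^3
        return self.voxel_count * float(np.prod(self.voxel_size_mm)) / 1000.0


def normalize_volume(vol: AnatomicalVolume, brain_mask: np.ndarray) -> AnatomicalVolume:
    """Z-score a volume within the brain mask; outside voxels become 0.

    Within the mask the output has mean 0 and sample SD 1 (ddof=1).
    Constant input raises a :class:`ValidationError` ("zero variance").
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != vol.shape:
        raise ValidationError("brain mask shape does not match volume")
    if not brain_mask.any():
        raise ValidationError("brain mask is empty")
    inside = vol.values[brain_mask]
    sd = inside.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("zero variance: cannot normalize a constant-intensity volume")
    out = np.zeros_like(vol.values)
    out[brain_mask] = (inside - inside.mean()) / sd
    return AnatomicalVolume(values=out, voxel_size_mm=vol.voxel_size_mm, affine=vol.affine)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def t1_subtraction_mask(
    pre: AnatomicalVolume,
    post: AnatomicalVolume,
    brain_mask: np.ndarray,
    min_component_voxels: int = 10,
) -> EnhancementMask:
    """Segment contrast enhancement as positive normalized post−pre difference.

    Both volumes are z-scored within the brain mask, subtracted
    voxel-wise, and voxels with difference strictly > 0 retained.
    Connected components (26-connectivity) smaller than
    ``min_component_voxels`` are discarded.
    """
    if pre.shape != post.shape:
        raise ValidationError(f"shape mismatch: pre {pre.shape} vs post {post.shape}")
    npre = normalize_volume(pre, brain_mask)
    npost = normalize_volume(post, brain_mask)
    positive = (npost.values - npre.values) > 0
    positive &= np.asarray(brain_mask, dtype=bool)
    if min_component_voxels > 1 and positive.any():
        labels, n = ndimage.label(positive, structure=_STRUCT_26)
        if n:
            counts = np.bincount(labels.ravel())
            keep = counts >= min_component_voxels
            keep[0] = False
            positive = keep[labels]
    return EnhancementMask(mask=positive, voxel_size_mm=post.voxel_size_mm)


def check_measurable(mask: EnhancementMask, min_extent_mm: float = 10.0) -> bool:
    """Measurable-disease check: an axial slice with in-plane bounding box
    at least ``min_extent_mm`` in both directions (default 1 cm × 1 cm).

    "Axial" is the third array axis.
    """
    m = mask.mask
    dx, dy, _ = mask.voxel_size_mm
    for k in range(m.shape[2]):
        sl = m[:, :, k]
        if not sl.any():
            continue
        rows = np.flatnonzero(sl.any(axis=1))
        cols = np.flatnonzero(sl.any(axis=0))
        extent_x = (rows[-1] - rows[0] + 1) * dx
        extent_y = (cols[-1] - cols[0] + 1) * dy
        if extent_x >= min_extent_mm and extent_y >= min_extent_mm:
            return True
    return False


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
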