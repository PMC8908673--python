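"""Organoid and stain quantification on calibrated grayscale images.

Organoid counting mirrors a phase-contrast well scan: global Otsu threshold,
hole filling, 8-connected components, per-object area in um^2 from the pixel
scale; only objects of 2000 um^2 and more count as organoids (inclusive
threshold). Stain quantification reports the stain-positive pixel fraction of
the total area, as used for aSMA immunohistochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure

__all__ = [
    "CalibratedImage",
    "OrganoidSegmentation",
    "segment_objects",
    "apply_area_filter",
    "stain_positive_fraction",
]

DEFAULT_MIN_AREA_UM2 = 2000.0


@dataclass
class CalibratedImage:
    pixels: np.ndarray        # 2-D grayscale
    um_per_pixel: float
    channel: str = "phase"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("expected a single-channel 2-D image")
        if not self.um_per_pixel > 0:
            raise ValueError("um_per_pixel must be positive")


@dataclass
class OrganoidSegmentation:
    labels: np.ndarray                  # 0 = background
    areas_um2: dict[int, float]         # per retained label
    threshold_um2: float
    organoid_count: int
    total_area_um2: float
    border_labels: list[int] = field(default_factory=list)
    um_per_pixel: float = 1.0


def _label_areas(binary: np.ndarray, um_per_pixel: float):
    labels = measure.label(binary, connectivity=2)  # 8-connectivity
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    areas = {int(i): float(c) * um_per_pixel**2 for i, c in zip(ids, counts)}
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border_labels = [int(b) for b in border if b > 0]
    return labels, areas, border_labels


def segment_objects(
    img: CalibratedImage, threshold: float | None = None
) -> OrganoidSegmentation:
    """Segment bright objects on a dark background; no area filter yet.

    A constant image yields an empty segmentation rather than an error.
    Border-touching objects are retained but flagged in ``border_labels``.
    """
    px = img.pixels.astype(float)
    if np.all(px == px.flat[0]):
        return OrganoidSegmentation(
            labels=np.zeros(px.shape, dtype=int), areas_um2={},
            threshold_um2=0.0, organoid_count=0, total_area_um2=0.0,
            um_per_pixel=img.um_per_pixel,
        )
    thr = filters.threshold_otsu(px) if threshold is None else float(threshold)
    binary = ndimage.binary_fill_holes(px > thr)
    labels, areas, border_labels = _label_areas(binary, img.um_per_pixel)
    return OrganoidSegmentation(
        labels=labels, areas_um2=areas, threshold_um2=0.0,
        organoid_count=len(areas), total_area_um2=float(sum(areas.values())),
        border_labels=border_labels, um_per_pixel=img.um_per_pixel,
    )


def apply_area_filter(
    seg: OrganoidSegmentation, threshold_um2: float = DEFAULT_MIN_AREA_UM2
) -> OrganoidSegmentation:
    """Keep objects with area >= threshold (inclusive); recompute count/total."""
    keep = {lab: a for lab, a in seg.areas_um2.items() if a >= threshold_um2}
    labels = np.where(np.isin(seg.labels, list(keep)), seg.labels, 0)
    return OrganoidSegmentation(
        labels=labels, areas_um2=keep, threshold_um2=float(threshold_um2),
        organoid_count=len(keep), total_area_um2=float(sum(keep.values())),
        border_labels=[b for b in seg.border_labels if b in keep],
        um_per_pixel=seg.um_per_pixel,
    )


def stain_positive_fraction(
    img: CalibratedImage, stain_threshold: float | None = None
) -> float:
    """Stain-positive area as a percentage of the total image area.

    ``stain_threshold`` fixes the positivity cut; with None, Otsu is used
    (requires a non-constant image).
    """
    px = img.pixels.astype(float)
    if stain_threshold is None:
        if np.all(px == px.flat[0]):
            raise ValueError("constant image: supply an explicit stain_threshold")
        thr = filters.threshold_otsu(px)
    else:
        thr = float(stain_threshold)
    return float(100.0 * np.mean(px > thr))
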