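"""Analysis-region definition.

Two modes mirror the two tissue sources: the *marker-derived* mode segments
the proinsulin-positive area of a human section (threshold, close, fill,
size-filter), and the *manual* mode consumes a binary islet mask drawn for
a mouse section.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from punctaflux.preprocess import CleanChannel


@dataclasses.dataclass(frozen=True)
class ROIMask:
    """Binary analysis region with pixel/physical area accessors."""

    mask: np.ndarray
    mode: str = "marker_derived"  # marker_derived | manual

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 2 or arr.dtype != bool:
            object.__setattr__(self, "mask", arr.astype(bool))
        if self.mode not in ("marker_derived", "manual"):
            raise ValueError(f"unknown ROI mode {self.mode!r}")

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def is_empty(self) -> bool:
        return self.area_px == 0

    def area_um2(self, pixel_size_um: float) -> float:
        return roi_area_um2(self, pixel_size_um)


def segment_marker_roi(
    marker: CleanChannel | np.ndarray,
    min_area_px: int = 100,
    close_radius: int = 2,
    threshold: float | None = None,
) -> ROIMask:
    """Segment the marker-positive (proinsulin) area into a filled ROI.

    Steps: global Otsu threshold (or a fixed ``threshold``), morphological
    closing with a disk of ``close_radius``, hole filling, then removal of
    connected components smaller than ``min_area_px``.  An all-zero marker
    yields an empty ROI (flagged via :attr:`ROIMask.is_empty`), not an error.
    """
    arr = marker.data if isinstance(marker, CleanChannel) else np.asarray(marker, dtype=float)
    if arr.ndim != 2:
        raise ValueError("marker must be a 2D plane")
    if not np.any(arr > 0):
        return ROIMask(mask=np.zeros(arr.shape, dtype=bool), mode="marker_derived")
    if threshold is None:
        threshold = threshold_otsu(arr)
    binary = arr > threshold
    if close_radius > 0:
        binary = ndimage.binary_closing(binary, structure=disk(close_radius))
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= min_area_px)
        keep = keep[keep != 0]
        binary = np.isin(labels, keep)
    return ROIMask(mask=binary, mode="marker_derived")


def roi_area_um2(roi: ROIMask, pixel_size_um: float) -> float:
    """Physical ROI area: pixel count times the squared pixel pitch."""
    if not pixel_size_um > 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return roi.area_px * float(pixel_size_um) ** 2
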