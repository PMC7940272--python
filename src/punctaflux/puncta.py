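"""Puncta detection with a pixel-diameter gate, and area-normalised density.

Detection follows the identify-primary-objects recipe: median smoothing,
masking to the ROI, a global Otsu threshold computed over ROI pixels only,
8-connected labelling, then discarding objects whose equivalent diameter
falls outside a configured [d_min, d_max] gate.  Touching puncta merge
into one object (no declumping/watershed) — a documented limitation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from punctaflux.preprocess import CleanChannel, median_smooth
from punctaflux.roi import ROIMask

EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclasses.dataclass(frozen=True)
class Punctum:
    id: int
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    equivalent_diameter_px: float
    mean_intensity: float


@dataclasses.dataclass(frozen=True)
class PunctaSet:
    """Labelled puncta for one channel: label image plus per-object summaries.

    ``labels`` keeps only the objects that survived the diameter gate;
    background is 0.  Objects are sorted by id and their pixel sets are
    disjoint by construction.
    """

    labels: np.ndarray
    objects: tuple[Punctum, ...]
    channel_role: str = ""
    flag_empty_roi: bool = False

    @property
    def count(self) -> int:
        return len(self.objects)

    def pixel_set(self, object_id: int) -> set[tuple[int, int]]:
        rows, cols = np.nonzero(self.labels == object_id)
        return set(zip(rows.tolist(), cols.tolist()))


def equivalent_diameter(area_px: float) -> float:
    """Diameter of the circle with the same area: 2*sqrt(A/pi)."""
    return 2.0 * np.sqrt(area_px / np.pi)


def detect_puncta(
    channel: CleanChannel | np.ndarray,
    roi: ROIMask,
    d_min: float = 2.0,
    d_max: float = 10.0,
    median_radius: int = 1,
    threshold: float | None = None,
    channel_role: str = "",
) -> PunctaSet:
    """Detect diameter-gated puncta inside the ROI of one cleaned channel.

    ``threshold=None`` selects Otsu computed over ROI pixels only, so
    extra-islet background does not skew the cut; pass a number for a fixed
    threshold.  ``d_min``/``d_max`` bound the equivalent diameter in pixels.
    """
    if not d_min < d_max:
        raise ValueError(f"need d_min < d_max, got [{d_min}, {d_max}]")
    arr = channel.data if isinstance(channel, CleanChannel) else np.asarray(channel, dtype=float)
    if arr.shape != roi.mask.shape:
        raise ValueError(f"channel shape {arr.shape} != ROI shape {roi.mask.shape}")
    empty = PunctaSet(
        labels=np.zeros(arr.shape, dtype=np.int32),
        objects=(),
        channel_role=channel_role,
        flag_empty_roi=roi.is_empty,
    )
    if roi.is_empty:
        return empty

    if median_radius >= 1:
        arr = median_smooth(arr, radius=median_radius).data
    masked = np.where(roi.mask, arr, 0.0)
    roi_vals = arr[roi.mask]
    if threshold is None:
        if np.all(roi_vals == roi_vals.flat[0]):
            return empty  # constant ROI: nothing to separate
        threshold = threshold_otsu(roi_vals)
    binary = masked > threshold
    binary &= roi.mask
    labels, n = ndimage.label(binary, structure=EIGHT_CONN)
    if n == 0:
        return empty

    out_labels = np.zeros(arr.shape, dtype=np.int32)
    objects: list[Punctum] = []
    next_id = 1
    for prop in regionprops(labels, intensity_image=masked):
        d = equivalent_diameter(prop.area)
        if d < d_min or d > d_max:
            continue
        out_labels[labels == prop.label] = next_id
        objects.append(
            Punctum(
                id=next_id,
                area_px=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                equivalent_diameter_px=float(d),
                mean_intensity=float(prop.intensity_mean),
            )
        )
        next_id += 1
    return PunctaSet(labels=out_labels, objects=tuple(objects), channel_role=channel_role)


def puncta_density(puncta: PunctaSet, roi: ROIMask, pixel_size_um: float = 1.0) -> dict[str, float]:
    """Puncta count normalised to ROI area, on both px^2 and um^2 scales."""
    if roi.is_empty:
        raise ValueError("cannot normalise to a zero-area ROI")
    per_px2 = puncta.count / roi.area_px
    per_um2 = puncta.count / roi.area_um2(pixel_size_um)
    return {"count": float(puncta.count), "per_px2": per_px2, "per_um2": per_um2}
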