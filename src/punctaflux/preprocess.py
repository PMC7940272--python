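"""Per-channel cleanup: lower-quartile background subtraction and median smoothing."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage


@dataclasses.dataclass(frozen=True)
class CleanChannel:
    """A preprocessed intensity plane plus the provenance of the steps applied.

    ``provenance`` is an ordered tuple of ``(step, params)`` pairs so a run
    log can state exactly how each channel was produced.
    """

    data: np.ndarray
    provenance: tuple[tuple[str, dict], ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("CleanChannel holds a single 2D plane")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _as_plane(channel) -> tuple[np.ndarray, tuple]:
    if isinstance(channel, CleanChannel):
        return np.asarray(channel.data, dtype=np.float64), channel.provenance
    arr = np.asarray(channel, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2D intensity array")
    return arr, ()


def subtract_lower_quartile(channel, quantile: float = 0.25) -> CleanChannel:
    """Subtract the image-wide lower-quartile intensity, clamping at zero.

    The background estimate is the ``quantile`` (default 25th) percentile of
    *all* pixels of the channel, computed with linear interpolation; the
    output is ``max(v - Q, 0)`` pixelwise.  Subtraction runs image-wide,
    before any ROI masking, and is idempotent once at least a quarter of the
    pixels sit at zero.
    """
    arr, prov = _as_plane(channel)
    if arr.size == 0:
        raise ValueError("empty image")
    if not 0.0 <= quantile <= 1.0:
        raise ValueError(f"quantile must be in [0, 1], got {quantile}")
    q = float(np.quantile(arr, quantile))
    out = np.maximum(arr - q, 0.0)
    step = ("subtract_lower_quartile", {"quantile": quantile, "background": q})
    return CleanChannel(data=out, provenance=prov + (step,))


def median_smooth(channel, radius: int = 1) -> CleanChannel:
    """Median-filter with a (2r+1)x(2r+1) square window, reflect-padded edges."""
    arr, prov = _as_plane(channel)
    radius = int(radius)
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if 2 * radius + 1 > min(arr.shape):
        raise ValueError(
            f"median window {2 * radius + 1} exceeds image extent {min(arr.shape)}"
        )
    out = ndimage.median_filter(arr, size=2 * radius + 1, mode="reflect")
    step = ("median_smooth", {"radius": radius})
    return CleanChannel(data=out, provenance=prov + (step,))
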