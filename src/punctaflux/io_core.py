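"""Image and table I/O: multichannel stacks, binary masks, tidy result CSVs."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

CHANNEL_ROLES = (
    "proinsulin",
    "insulin",
    "lc3",
    "lamp1",
    "p62",
    "dapi",
    "em",
    "elem_N",
    "elem_P",
    "elem_Os",
)

GROUPS_MOUSE = ("NOR", "NOD_nondiabetic", "NOD_diabetic")
GROUPS_HUMAN = ("nondiabetic", "aab_positive", "t1d")
TREATMENTS = ("none", "chloroquine")


@dataclasses.dataclass(frozen=True)
class ChannelStack:
    """Registered 2D intensity channels sharing one pixel grid.

    Parameters
    ----------
    channels
        Mapping from channel role (e.g. ``"lc3"``, ``"lamp1"``,
        ``"proinsulin"``) to a 2D non-negative intensity array.
    pixel_size_um
        Pixel pitch in micrometres per pixel; must be positive.
    image_id
        Opaque identifier carried into every downstream record.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ChannelStack needs at least one channel")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        shapes = set()
        for role, arr in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {role!r} is not a 2D plane (ndim={arr.ndim})")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"channel {role!r} has non-finite or negative intensities")
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]

    def __contains__(self, role: str) -> bool:
        return role in self.channels


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Experimental factors for one image: disease group, treatment, subject."""

    group: str
    treatment: str = "none"
    subject_id: str = ""
    vocabulary: tuple[str, ...] = GROUPS_MOUSE + GROUPS_HUMAN

    def __post_init__(self) -> None:
        if self.group not in self.vocabulary:
            raise ValueError(f"group {self.group!r} not in declared vocabulary {self.vocabulary}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment {self.treatment!r} not in {TREATMENTS}")


def load_stack(path: str | Path, channel_map: Mapping[str, int], pixel_size_um: float) -> ChannelStack:
    """Read a single- or multi-page TIFF into a :class:`ChannelStack`.

    ``channel_map`` assigns a role to each page index, e.g.
    ``{"lc3": 0, "lamp1": 1, "proinsulin": 2}``.  Integer pixel data are
    preserved losslessly.  Pixel size is supplied explicitly rather than
    parsed from TIFF tags.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"image not found: {path}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, :, :]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected 2D pages, got array of ndim {pages.ndim}")
    n = pages.shape[0]
    channels = {}
    for role, idx in channel_map.items():
        if not 0 <= idx < n:
            raise IndexError(f"{path}: channel index {idx} out of range for {n} page(s)")
        channels[role] = pages[idx]
    return ChannelStack(channels=channels, pixel_size_um=float(pixel_size_um), image_id=path.stem)


def load_mask(path: str | Path):
    """Read a binary mask image; nonzero pixels become the ROI.

    Images with more than two distinct values are rejected rather than
    guessed at.  An all-zero mask is legal and returned flagged empty.
    """
    from punctaflux.roi import ROIMask  # local import avoids a cycle

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"mask not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse a grayscale-saved RGB mask
        if not np.all(arr == arr[..., :1]):
            raise ValueError(f"{path}: colour mask is ambiguous")
        arr = arr[..., 0]
    values = np.unique(arr)
    if values.size > 2:
        raise ValueError(
            f"{path}: mask has {values.size} distinct values; supply a binary mask "
            "or binarise explicitly before loading"
        )
    return ROIMask(mask=arr != 0, mode="manual")


# Column order is the public CSV schema; keep stable.
ISLET_COLUMNS = [
    "image_id",
    "subject_id",
    "group",
    "treatment",
    "roi_area_px",
    "roi_area_um2",
    "density_lc3_per_um2",
    "density_lamp1_per_um2",
    "density_p62_per_um2",
    "density_proinsulin_per_um2",
    "pct_lc3_in_lamp1",
    "pct_proins_in_lamp1",
    "flag_empty_roi",
    "flag_zero_children",
]


@dataclasses.dataclass
class IsletRecord:
    """One quantified islet: area-normalised densities and colocalisation."""

    image_id: str
    subject_id: str
    group: str
    treatment: str
    roi_area_px: int
    roi_area_um2: float
    density_lc3_per_um2: float = np.nan
    density_lamp1_per_um2: float = np.nan
    density_p62_per_um2: float = np.nan
    density_proinsulin_per_um2: float = np.nan
    pct_lc3_in_lamp1: float = np.nan
    pct_proins_in_lamp1: float = np.nan
    flag_empty_roi: bool = False
    flag_zero_children: bool = False

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in ISLET_COLUMNS}


def records_to_frame(records: list[IsletRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records], columns=ISLET_COLUMNS)


def write_islet_table(records: list[IsletRecord] | pd.DataFrame, path: str | Path) -> Path:
    """Write per-islet records as CSV with a stable column order."""
    path = Path(path)
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.10g")
    return path


def read_islet_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("group", "treatment") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: islet table missing columns {missing}")
    return frame
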