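"""Reading, splitting, merging and writing the pipeline's image and table artefacts.

The module mirrors the two batch-conversion roles of the acquisition side of
the workflow — multi-channel TIFF stacks in, single-channel grayscale TIFFs
out — plus CSV export of per-object measurements and RGB overlay rendering
for visual quality control.

Conventions (fixed once, used everywhere):

* pixel grids are row-major, 0-based; a pixel's centroid contribution is its
  integer index (no half-pixel offset);
* all physical distances are in micrometres; a pixel size must be known
  (TIFF resolution metadata or caller override) before any is reported;
* CSV tables are comma-delimited, UTF-8, Unix newlines, period decimal
  separator, floats at 9 significant digits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import (
    CalibrationError,
    EmptyStackError,
    ReadError,
    ShapeError,
    SuffixCountError,
    WriteError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import LabelMap

__all__ = [
    "ChannelImage",
    "MultiChannelImage",
    "read_stack",
    "write_stack",
    "split_channels",
    "merge_channels",
    "write_object_table",
    "read_object_table",
    "render_overlay",
    "write_overlay",
]

#: 1 inch / 1 cm expressed in micrometres, for TIFF resolution tags.
_UNIT_UM = {2: 25_400.0, 3: 10_000.0}

# Overlay palette: category -> RGB.  Green = accepted, magenta = discarded
# on size, yellow = discarded for touching the image border.
OVERLAY_COLORS = {
    "accepted": (0, 255, 0),
    "discarded_size": (255, 0, 255),
    "discarded_border": (255, 255, 0),
}


@dataclass
class ChannelImage:
    """One fluorescence channel: a calibrated 2D intensity grid.

    Parameters
    ----------
    channel_name
        Text label, e.g. ``"DAPI"``, ``"pimonidazole"``, ``"DRAQ7"``,
        ``"mAG"``, ``"mKO2"`` or ``"PBMC"``.
    pixels
        2D array of finite, non-negative intensities (arbitrary units).
        The native dtype is preserved so file round trips stay bit-exact.
    pixel_size_um
        Physical edge length of one pixel in micrometres (> 0).
    """

    channel_name: str
    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ShapeError("channel pixels must be a non-empty 2D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("channel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("channel intensities must be non-negative")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def as_float(self) -> np.ndarray:
        """Pixels as float64 (copy only when dtype conversion is needed)."""
        return np.asarray(self.pixels, dtype=np.float64)


@dataclass
class MultiChannelImage:
    """An ordered collection of channels sharing one grid and calibration."""

    channels: list[ChannelImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise EmptyStackError("a multi-channel image needs >= 1 channel")
        shapes = {c.shape for c in self.channels}
        if len(shapes) != 1:
            raise ShapeError(f"channel dimensions differ: {sorted(shapes)}")
        sizes = {c.pixel_size_um for c in self.channels}
        if len(sizes) != 1:
            raise ShapeError("channels disagree on pixel_size_um")
        names = [c.channel_name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"channel names not unique: {names}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def pixel_size_um(self) -> float:
        return self.channels[0].pixel_size_um

    @property
    def channel_names(self) -> list[str]:
        return [c.channel_name for c in self.channels]

    def __len__(self) -> int:
        return len(self.channels)

    def __getitem__(self, key: int | str) -> ChannelImage:
        if isinstance(key, str):
            for c in self.channels:
                if c.channel_name == key:
                    return c
            raise KeyError(key)
        return self.channels[key]


def _pixel_size_from_tags(page: "tifffile.TiffPage") -> float | None:
    """Pixel size in um from a page's resolution tags, if decodable."""
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except (KeyError, AttributeError):
        return None
    unit = int(getattr(unit, "value", unit))
    if unit not in _UNIT_UM:
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if num == 0 or den == 0:
        return None
    pixels_per_unit = num / den
    return _UNIT_UM[unit] / pixels_per_unit


def read_stack(
    path: str | os.PathLike,
    pixel_size_um: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> MultiChannelImage:
    """Read a single- or multi-plane grayscale TIFF as a channel stack.

    Each TIFF plane becomes one channel, in plane order, values preserved
    bit-exactly.  The pixel size comes from the file's resolution metadata;
    an explicit ``pixel_size_um`` override always wins; absence of both is a
    :class:`~spheroquant.errors.CalibrationError` because every downstream
    distance is reported in micrometres.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            planes = [p.asarray() for p in tf.pages]
            meta_px = _pixel_size_from_tags(tf.pages[0]) if tf.pages else None
    except FileNotFoundError as exc:
        raise ReadError(f"cannot read {path}: {exc}") from exc
    except Exception as exc:  # tifffile raises various decode errors
        raise ReadError(f"cannot decode {path} as TIFF: {exc}") from exc
    if len(planes) == 0:
        raise EmptyStackError(f"{path} contains no image planes")
    px = pixel_size_um if pixel_size_um is not None else meta_px
    if px is None:
        raise CalibrationError(
            f"{path} carries no pixel-size metadata and no override was given"
        )
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(len(planes))]
    if len(channel_names) != len(planes):
        raise ShapeError(
            f"{len(channel_names)} channel names for {len(planes)} planes"
        )
    return MultiChannelImage(
        [
            ChannelImage(name, plane, px)
            for name, plane in zip(channel_names, planes)
        ]
    )


def write_stack(stack: MultiChannelImage, path: str | os.PathLike) -> Path:
    """Write a channel stack as a multi-plane TIFF with resolution metadata."""
    path = Path(path)
    data = np.stack([c.pixels for c in stack.channels])
    ppcm = 10_000.0 / stack.pixel_size_um  # pixels per centimetre
    try:
        tifffile.imwrite(
            path, data, photometric="minisblack",
            resolution=(ppcm, ppcm), resolutionunit="CENTIMETER",
        )
    except OSError as exc:
        raise WriteError(f"cannot write {path}: {exc}") from exc
    return path


def split_channels(
    stack: MultiChannelImage,
    suffixes: Sequence[str],
    out_dir: str | os.PathLike,
    stem: str = "image",
) -> list[Path]:
    """Write one single-channel grayscale TIFF per channel.

    Files are named ``<stem><suffix_i>.tif`` in channel order; each output is
    pixel-identical to its source channel.  Fewer suffixes than channels is a
    :class:`~spheroquant.errors.SuffixCountError` (the batch-macro analogue of
    having to adjust the channel-count variable by hand).
    """
    if len(suffixes) < len(stack):
        raise SuffixCountError(
            f"{len(suffixes)} suffixes for {len(stack)} channels"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ppcm = 10_000.0 / stack.pixel_size_um
    paths = []
    for channel, suffix in zip(stack.channels, suffixes):
        p = out_dir / f"{stem}{suffix}.tif"
        try:
            tifffile.imwrite(
                p,
                channel.pixels,
                photometric="minisblack",
                resolution=(ppcm, ppcm),
                resolutionunit="CENTIMETER",
            )
        except OSError as exc:
            raise WriteError(f"cannot write {p}: {exc}") from exc
        paths.append(p)
    return paths


def merge_channels(channels: Iterable[ChannelImage]) -> ChannelImage:
    """Per-pixel maximum of the given channels, named ``"merged"``.

    Used to build a comprehensive nuclear image when no single stain marks
    every nucleus (e.g. mAG + mKO2 + DRAQ7 together cover cycling, arrested
    and dead nuclei).  Maximum, not sum: the result stays in the input
    intensity range and remains a valid seed image for segmentation.
    """
    channels = list(channels)
    if len(channels) == 0:
        raise ShapeError("merge_channels needs >= 1 channel")
    shape = channels[0].shape
    px = channels[0].pixel_size_um
    for c in channels[1:]:
        if c.shape != shape:
            raise ShapeError(f"channel shapes differ: {c.shape} vs {shape}")
        if c.pixel_size_um != px:
            raise ShapeError("channels disagree on pixel_size_um")
    merged = channels[0].pixels
    for c in channels[1:]:
        merged = np.maximum(merged, c.pixels)
    return ChannelImage("merged", merged, px)


def write_object_table(records: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Export per-object measurements as a delimited text table.

    Comma-delimited, UTF-8, Unix newlines, one header row then one row per
    object.  Floats are printed at 9 significant digits, which round-trips
    losslessly through ``float`` (9 < 15 decimal digits), so
    write -> read -> write is byte-identical.
    """
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            records.to_csv(fh, index=False, float_format="%.9g",
                           lineterminator="\n")
    except OSError as exc:
        raise WriteError(f"cannot write {path}: {exc}") from exc
    return path


def read_object_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a table written by :func:`write_object_table`."""
    try:
        return pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise ReadError(f"cannot read object table {path}: {exc}") from exc


def _rescale_to_u8(pixels: np.ndarray) -> np.ndarray:
    img = np.asarray(pixels, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255.0).astype(np.uint8)


def _boundary_pixels(labels: np.ndarray) -> np.ndarray:
    """Label pixels with any 8-neighbour of a different value.

    Pixels beyond the image edge count as background, so objects touching
    the border are outlined there too.
    """
    padded = np.pad(labels, 1, mode="constant", constant_values=0)
    boundary = np.zeros(labels.shape, dtype=bool)
    h, w = labels.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            neigh = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
            boundary |= neigh != labels
    return boundary & (labels > 0)


def render_overlay(
    image: ChannelImage, labels: "LabelMap", mode: str = "outlines"
) -> np.ndarray:
    """Render segmentation QC as an 8-bit RGB image.

    Object outlines (``mode="outlines"``) or full footprints
    (``mode="filled"``) are coloured by acceptance category — green for
    accepted, magenta for size-discarded, yellow for border-discarded —
    over the min/max-rescaled grayscale image.
    """
    if mode not in ("outlines", "filled"):
        raise ValueError(f"unknown overlay mode {mode!r}")
    lab = labels.labels
    if lab.shape != image.shape:
        raise ShapeError(
            f"label map {lab.shape} does not match image {image.shape}"
        )
    gray = _rescale_to_u8(image.pixels)
    rgb = np.stack([gray] * 3, axis=-1)
    paint = _boundary_pixels(lab) if mode == "outlines" else lab > 0
    for label_id, category in labels.categories.items():
        color = OVERLAY_COLORS[category]
        sel = paint & (lab == label_id)
        rgb[sel] = color
    return rgb


def write_overlay(rgb: np.ndarray, path: str | os.PathLike) -> Path:
    """Write an RGB overlay as PNG."""
    path = Path(path)
    try:
        iio.imwrite(path, rgb.astype(np.uint8), extension=".png")
    except OSError as exc:
        raise WriteError(f"cannot write {path}: {exc}") from exc
    return path
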