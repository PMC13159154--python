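"""Pre-analytical image processing for organ-chip micrographs.

Chips are imaged as overlapping fields of view and serial Z-slices; before
any quantitative analysis the slices are compressed to a 2D projection, the
fields are stitched, the background is flattened and the image is smoothed.
All operations work on :class:`ChipImage` / :class:`ZStack` containers and
return new objects (inputs are never mutated).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, opening


class Channel(str, enum.Enum):
    """Acquisition channel: label-free bright-field, or the two viability stains

    (DAPI band for the all-nuclei Hoechst stain, TRITC band for the
    dead-cell ethidium stain).
    """

    BF = "BF"
    DAPI = "DAPI"
    TRITC = "TRITC"


@dataclass
class ChipImage:
    """A single-channel 2D grayscale image of one chip at one timepoint."""

    pixels: np.ndarray
    channel: Channel = Channel.BF
    chip_id: str = ""
    day: int = 0
    pixel_size_um: float = 1.7
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("ChipImage requires a non-empty 2D array")
        if np.issubdtype(self.pixels.dtype, np.floating) and np.nanmin(self.pixels) < 0:
            raise ValueError("intensities must be non-negative")
        self.channel = Channel(self.channel)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=np.float64)

    def with_pixels(self, pixels: np.ndarray) -> "ChipImage":
        return replace(self, pixels=pixels)


@dataclass
class ZStack:
    """An ordered stack of same-shape 2D slices through the gel channel."""

    slices: list = field(default_factory=list)
    step_um: float = 14.0
    channel: Channel = Channel.BF
    chip_id: str = ""
    day: int = 0
    pixel_size_um: float = 1.7
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.slices = [np.asarray(s) for s in self.slices]
        if not self.slices:
            raise ValueError("ZStack requires at least one slice")
        shape = self.slices[0].shape
        for s in self.slices:
            if s.ndim != 2 or s.shape != shape:
                raise ValueError("all Z-slices must share one 2D shape")

    def __len__(self) -> int:
        return len(self.slices)


def max_project(stack: ZStack) -> ChipImage:
    """Maximum-intensity projection of a Z-stack into a single 2D image.

    Each output pixel is the per-pixel maximum over slices; a single-slice
    stack projects to itself.
    """
    pixels = np.max(np.stack(stack.slices, axis=0), axis=0)
    return ChipImage(
        pixels=pixels,
        channel=stack.channel,
        chip_id=stack.chip_id,
        day=stack.day,
        pixel_size_um=stack.pixel_size_um,
        bit_depth=stack.bit_depth,
    )


def mean_project(stack: ZStack) -> ChipImage:
    """Mean-intensity projection (alternative to :func:`max_project`)."""
    pixels = np.mean(np.stack(stack.slices, axis=0), axis=0)
    return ChipImage(
        pixels=pixels,
        channel=stack.channel,
        chip_id=stack.chip_id,
        day=stack.day,
        pixel_size_um=stack.pixel_size_um,
        bit_depth=stack.bit_depth,
    )


def stitch_tiles(tiles: Sequence[ChipImage], overlap_fraction: float) -> ChipImage:
    """Stitch a horizontal row of equal-shape tiles into one wide image.

    Tiles are assumed to be acquired left-to-right with a fixed fractional
    horizontal overlap (e.g. two 10%-overlapping fields of view per chip).
    The overlap region is blended with a linear ramp, which is exact on
    constant input so flat-field tiles stitch without a seam.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    if not 0.0 <= overlap_fraction < 0.5:
        raise ValueError("overlap_fraction must be in [0, 0.5)")
    shape = tiles[0].shape
    for t in tiles:
        if t.shape != shape:
            raise ValueError("tiles must share one shape")
    h, w = shape
    overlap = int(round(overlap_fraction * w))
    step = w - overlap
    out_w = w + step * (len(tiles) - 1)
    out = np.zeros((h, out_w), dtype=np.float64)
    weight = np.zeros(out_w, dtype=np.float64)

    ramp = np.ones(w, dtype=np.float64)
    if overlap > 0:
        ramp_up = np.linspace(0.0, 1.0, overlap + 2)[1:-1]
        ramp[:overlap] = ramp_up
        ramp[-overlap:] = ramp_up[::-1]

    for i, tile in enumerate(tiles):
        x0 = i * step
        wcol = ramp.copy()
        if i == 0 and overlap > 0:
            wcol[:overlap] = 1.0  # no left neighbour
        if i == len(tiles) - 1 and overlap > 0:
            wcol[-overlap:] = 1.0  # no right neighbour
        out[:, x0 : x0 + w] += tile.astype_float() * wcol
        weight[x0 : x0 + w] += wcol
    out /= weight[None, :]

    first = tiles[0]
    return ChipImage(
        pixels=out,
        channel=first.channel,
        chip_id=first.chip_id,
        day=first.day,
        pixel_size_um=first.pixel_size_um,
        bit_depth=first.bit_depth,
    )


def subtract_background(img: ChipImage, radius_px: int = 50) -> ChipImage:
    """Rolling-ball style background subtraction.

    The background estimate is a grayscale morphological opening with a disk
    of ``radius_px``; structures smaller than the disk survive subtraction
    while any smooth offset (including a constant) maps to zero. Output is
    clipped at zero.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    pixels = img.astype_float()
    footprint = disk(radius_px, decomposition="sequence")
    background = opening(pixels, footprint)
    out = np.clip(pixels - background, 0.0, None)
    return img.with_pixels(out)


def gaussian_smooth(img: ChipImage, sigma_px: float = 1.0) -> ChipImage:
    """Gaussian smoothing with reflective boundary; ``sigma_px=0`` is identity."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    pixels = img.astype_float()
    if sigma_px == 0:
        return img.with_pixels(pixels.copy())
    return img.with_pixels(ndi.gaussian_filter(pixels, sigma_px, mode="reflect"))


def normalize_contrast(img: ChipImage, low_pct: float = 1.0, high_pct: float = 99.0) -> ChipImage:
    """Optional plain percentile contrast normalization to [0, max_value].

    Stands in for vendor-specific display-conditioning steps; identity in
    spirit — it only rescales intensities and is off by default in the
    pipeline.
    """
    pixels = img.astype_float()
    lo, hi = np.percentile(pixels, [low_pct, high_pct])
    if hi <= lo:
        return img.with_pixels(pixels.copy())
    out = np.clip((pixels - lo) / (hi - lo), 0.0, 1.0) * img.max_value
    return img.with_pixels(out)
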