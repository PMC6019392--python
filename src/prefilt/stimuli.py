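"""Stimuli, behavioral foreground masks, and region isolation.

A stimulus is a grayscale natural image shown inside a circular aperture
embedded in a uniform gray field, with a pixels-per-degree scale tying
image coordinates to visual angle (the source experiment used a 20-degree,
500-pixel aperture, i.e. 25 px/deg).  A behavioral foreground mask is the
largest connected patch labeled "foreground" across the available manual
segmentations of that image; applying it to the stimulus isolates either
the foreground or the background, with the complementary region replaced
by the background gray.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "FOREGROUND",
    "BACKGROUND",
    "Stimulus",
    "ForegroundMask",
    "SegmentedStimulus",
    "circular_aperture",
    "make_stimulus",
    "select_foreground_mask",
    "downsample_mask",
    "isolate_region",
    "read_grayscale",
    "write_mask_png",
    "read_mask_png",
    "load_bsd_groundtruth",
    "labels_to_foreground",
]

FOREGROUND = "foreground"
BACKGROUND = "background"
_REGIONS = (FOREGROUND, BACKGROUND)


def circular_aperture(shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the circle inscribed in the image frame.

    A pixel is inside the aperture when its center lies within the circle
    inscribed in the (square) image; for non-square frames the smaller
    dimension sets the diameter.
    """
    h, w = shape
    r = min(h, w) / 2.0
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


@dataclass(frozen=True)
class Stimulus:
    """Grayscale image in a circular aperture on a uniform gray field."""

    pixels: np.ndarray
    aperture_mask: np.ndarray
    px_per_degree: float
    background_gray: float = 0.5
    id: str = "stim"

    def __post_init__(self) -> None:
        if self.pixels.shape != self.aperture_mask.shape:
            raise ValueError("pixels and aperture_mask must share a shape")
        if not (self.px_per_degree > 0):
            raise ValueError("px_per_degree must be positive")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel intensities must lie in [0, 1]")
        outside = self.pixels[~self.aperture_mask]
        if outside.size and not np.allclose(outside, self.background_gray, atol=1e-9):
            raise ValueError("pixels outside the aperture must equal background_gray")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ForegroundMask:
    """Binary per-pixel labeling of the behavioral foreground region."""

    pixels: np.ndarray
    source: str = "behavioral"  # behavioral | shuffled | synthetic

    def __post_init__(self) -> None:
        if self.pixels.dtype != bool:
            object.__setattr__(self, "pixels", self.pixels.astype(bool))
        if not self.pixels.any():
            raise ValueError("foreground mask has no true pixel")

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class SegmentedStimulus:
    """One region of a stimulus kept, the complement set to background gray."""

    pixels: np.ndarray
    region: str
    parent_id: str


def make_stimulus(
    pixels: np.ndarray,
    px_per_degree: float,
    background_gray: float = 0.5,
    id: str = "stim",
    aperture_mask: np.ndarray | None = None,
) -> Stimulus:
    """Frame an intensity image into the circular aperture.

    Pixels outside the aperture are overwritten with ``background_gray``;
    intensities are clipped to [0, 1].
    """
    px = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    if aperture_mask is None:
        aperture_mask = circular_aperture(px.shape)
    px = px.copy()
    px[~aperture_mask] = background_gray
    return Stimulus(px, aperture_mask, px_per_degree, background_gray, id)


def select_foreground_mask(
    segmentations: Sequence[np.ndarray], connectivity: int = 2
) -> ForegroundMask:
    """Largest connected foreground patch across behavioral segmentations.

    Each element of ``segmentations`` is a boolean map marking the pixels a
    subject labeled as foreground.  Patches are 8-connected components
    (``connectivity=2``); the single largest patch over all maps wins, ties
    broken by first occurrence in enumeration order (map order, then
    component label order).
    """
    if not len(segmentations):
        raise ValueError("no segmentation maps provided")
    structure = ndimage.generate_binary_structure(2, connectivity)
    best: np.ndarray | None = None
    best_size = 0
    for seg in segmentations:
        seg = np.asarray(seg, dtype=bool)
        if not seg.any():
            continue
        labels, n = ndimage.label(seg, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for lab in range(1, n + 1):
            size = int(sizes[lab - 1])
            if size > best_size:
                best_size = size
                best = labels == lab
    if best is None:
        raise ValueError("no foreground-labeled region in any segmentation map")
    return ForegroundMask(best, source="behavioral")


def downsample_mask(mask: ForegroundMask, target_shape: tuple[int, int]) -> ForegroundMask:
    """Area-average resample of a binary mask, re-binarized at 0.5.

    The mask is treated as a 0/1 intensity image, box-filtered to the
    target resolution (exact block averaging for integer factors), and a
    pixel is kept when its mean coverage is >= 0.5.
    """
    th, tw = target_shape
    sh, sw = mask.pixels.shape
    if th > sh or tw > sw:
        raise ValueError("target_shape must not exceed the source shape")
    img = Image.fromarray(mask.pixels.astype(np.float32), mode="F")
    means = np.asarray(img.resize((tw, th), Image.Resampling.BOX), dtype=float)
    out = means >= 0.5
    if not out.any():
        raise ValueError("mask is empty after downsampling")
    return ForegroundMask(out, source=mask.source)


def isolate_region(stim: Stimulus, mask: ForegroundMask, region: str) -> SegmentedStimulus:
    """Keep one region of the stimulus; gray out its complement.

    Kept-region pixels are copied from the stimulus; the complementary
    region (within the aperture) and the surround are set to the
    background gray.
    """
    if region not in _REGIONS:
        raise ValueError(f"region must be one of {_REGIONS}")
    if mask.pixels.shape != stim.pixels.shape:
        raise ValueError("mask and stimulus shapes differ")
    fg = mask.pixels & stim.aperture_mask
    keep = fg if region == FOREGROUND else (stim.aperture_mask & ~fg)
    out = np.full_like(stim.pixels, stim.background_gray)
    out[keep] = stim.pixels[keep]
    return SegmentedStimulus(out, region, stim.id)


# ---------------------------------------------------------------------------
# IO


def read_grayscale(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/JPEG, rescaled to [0, 1]."""
    img = Image.open(path)
    if img.mode not in ("L", "I;16", "I"):
        img = img.convert("L")
    arr = np.asarray(img, dtype=float)
    scale = 65535.0 if img.mode in ("I;16", "I") else 255.0
    return arr / scale


def write_mask_png(mask: ForegroundMask, path: str | Path) -> None:
    Image.fromarray(mask.pixels).convert("1").save(path)


def read_mask_png(path: str | Path) -> ForegroundMask:
    arr = np.asarray(Image.open(path).convert("L")) > 127
    return ForegroundMask(arr, source="behavioral")


def load_bsd_groundtruth(path: str | Path) -> list[np.ndarray]:
    """Integer label maps from a BSD500-style ground-truth ``.mat`` file.

    Returns one labeled-region map per human segmentation stored in the
    file's ``groundTruth`` cell array.
    """
    from scipy.io import loadmat

    mat = loadmat(str(path))
    if "groundTruth" not in mat:
        raise ValueError(f"{path}: no 'groundTruth' variable")
    cells = mat["groundTruth"].ravel()
    maps = []
    for cell in cells:
        seg = cell["Segmentation"][0, 0]
        maps.append(np.asarray(seg, dtype=int))
    return maps


def labels_to_foreground(labelmap: np.ndarray, fg_labels: Iterable[int]) -> np.ndarray:
    """Boolean foreground map from a labeled segmentation and label ids."""
    return np.isin(labelmap, list(fg_labels))
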