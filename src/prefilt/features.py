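"""Four untrained low-level image descriptors.

These are the literature-standard descriptor families built on edge
position, size and orientation, in simplified canonical parameterizations:

* ``spectral_summary`` — oriented multi-scale Gabor energies averaged over
  a spatial grid (a GIST-style spectral envelope);
* ``dense_gradient`` — signed gradient-orientation histograms pooled on a
  dense grid (a dense-SIFT-style descriptor);
* ``pyramid_gradient`` — unsigned edge-orientation histograms pooled over
  a spatial pyramid (a PHOG-style descriptor);
* ``local_binary_pattern`` — a histogram of rotation-robust uniform local
  binary pattern codes, folded so it is invariant to intensity inversion.

All descriptors are deterministic given pixels plus the parameters
recorded in :class:`FeatureVectorSet.params`, and are computed on the full
framed image (gray surround included).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from skimage.feature import local_binary_pattern

from ._util import block_reduce_mean, block_reduce_sum

__all__ = [
    "MODELS",
    "FeatureVectorSet",
    "spectral_summary",
    "dense_gradient",
    "pyramid_gradient",
    "lbp_histogram",
    "extract_all",
]

MODELS = ("spectral_summary", "dense_gradient", "pyramid_gradient", "local_binary_pattern")


@dataclass(frozen=True)
class FeatureVectorSet:
    """Per-stimulus descriptor vectors for one model (stimuli x dims)."""

    model: str
    vectors: np.ndarray
    params: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not np.isfinite(self.vectors).all():
            raise ValueError("feature vectors must be finite")

    @property
    def n_stimuli(self) -> int:
        return self.vectors.shape[0]


# ---------------------------------------------------------------------------
# Gabor spectral summary

_CENTER_FREQS = (0.05, 0.0957, 0.183, 0.35)  # cycles/pixel, ~1 octave apart
_SIGMA_LOG = np.log(2.0) / 2.0
_KAPPA = 8.0


@lru_cache(maxsize=8)
def _gabor_bank(shape: tuple[int, int], n_scales: int, n_orientations: int) -> np.ndarray:
    """Frequency-domain log-Gabor transfer functions (S, O, H, W).

    DC and the Nyquist row/column are zeroed so the bank is exactly
    symmetric under 90-degree image rotation (orientation index shifts by
    n_orientations // 2 when the image is rotated by 90 degrees).
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    rad = np.hypot(fy, fx)
    ang = np.arctan2(fy, fx)
    valid = (rad > 0) & (np.abs(fy) < 0.5) & (np.abs(fx) < 0.5)
    safe_rad = np.where(rad > 0, rad, 1.0)
    freqs = np.geomspace(_CENTER_FREQS[0], _CENTER_FREQS[-1], n_scales)
    thetas = np.arange(n_orientations) * np.pi / n_orientations
    bank = np.empty((n_scales, n_orientations, h, w))
    for s, f0 in enumerate(freqs):
        radial = np.exp(-(np.log(safe_rad / f0) ** 2) / (2 * _SIGMA_LOG**2))
        for o, th in enumerate(thetas):
            angular = np.exp(_KAPPA * (np.cos(2 * (ang - th)) - 1.0))
            bank[s, o] = np.where(valid, radial * angular, 0.0)
    return bank


def _spectral_stack(
    stack: np.ndarray, n_scales: int, n_orientations: int, grid: int
) -> np.ndarray:
    """Spectral-summary vectors for a (N, H, W) image stack."""
    n, h, w = stack.shape
    min_wavelength = int(np.ceil(1.0 / _CENTER_FREQS[0]))
    if min(h, w) < min_wavelength:
        raise ValueError(
            f"image {h}x{w} smaller than the largest filter wavelength ({min_wavelength} px)"
        )
    bank = _gabor_bank((h, w), n_scales, n_orientations)
    fts = np.fft.fft2(stack)
    out = np.empty((n, n_scales, n_orientations, grid, grid))
    for s in range(n_scales):
        for o in range(n_orientations):
            resp = np.fft.ifft2(fts * bank[s, o])
            energy = resp.real**2 + resp.imag**2
            out[:, s, o] = block_reduce_mean(energy, grid)
    return out.reshape(n, -1)


def spectral_summary(
    pixels: np.ndarray, n_scales: int = 4, n_orientations: int = 8, grid: int = 4
) -> np.ndarray:
    """Oriented multi-scale Gabor energies averaged over a spatial grid.

    Length = n_scales * n_orientations * grid**2 (512 at defaults).
    """
    centered = np.asarray(pixels, dtype=float)
    centered = centered - centered.mean()
    return _spectral_stack(centered[None], n_scales, n_orientations, grid)[0]


# ---------------------------------------------------------------------------
# Gradient descriptors


def _gradient(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gy, gx = np.gradient(np.asarray(pixels, dtype=float))
    return np.hypot(gy, gx), np.arctan2(gy, gx)


def dense_gradient(pixels: np.ndarray, grid: int = 8, n_bins: int = 8) -> np.ndarray:
    """Signed gradient-orientation histograms pooled on a dense grid.

    Magnitude-weighted histograms of gradient direction (0..360 deg,
    ``n_bins`` bins) in each cell of a ``grid x grid`` partition,
    concatenated.  Length = grid**2 * n_bins (512 at defaults).
    """
    mag, ang = _gradient(pixels)
    bins = np.floor((ang % (2 * np.pi)) / (2 * np.pi / n_bins)).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    cells = np.stack([block_reduce_mean(mag * (bins == b), grid) for b in range(n_bins)])
    return cells.reshape(n_bins, -1).T.ravel()  # cell-major, bins contiguous


def pyramid_gradient(pixels: np.ndarray, levels: int = 3, n_bins: int = 8) -> np.ndarray:
    """Unsigned edge-orientation histograms over a spatial pyramid.

    Levels 0..levels-1 partition the image into 1, 4, 16, ... cells; each
    cell holds a magnitude-weighted histogram of orientation modulo 180
    degrees.  The concatenation is normalized by total edge energy.
    Length = n_bins * (4**levels - 1) / 3 (168 at defaults).
    """
    mag, ang = _gradient(pixels)
    bins = np.floor((ang % np.pi) / (np.pi / n_bins)).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    base_grid = 2 ** (levels - 1)
    base = np.stack(
        [block_reduce_sum(mag * (bins == b), base_grid) for b in range(n_bins)]
    )  # (n_bins, base_grid, base_grid)
    parts: list[np.ndarray] = []
    for lev in range(levels):
        g = 2**lev
        f = base_grid // g
        pooled = base.reshape(n_bins, g, f, g, f).sum(axis=(2, 4))
        parts.append(pooled.ravel())
    vec = np.concatenate(parts)
    total = vec[:n_bins].sum()  # level-0 sum = total edge energy
    return vec / total if total > 0 else vec


# ---------------------------------------------------------------------------
# Local binary patterns


def lbp_histogram(pixels: np.ndarray, n_points: int = 8, radius: float = 1.0) -> np.ndarray:
    """Folded histogram of rotation-robust uniform LBP codes.

    Uniform rotation-invariant codes are binned by their number of set
    bits (0..n_points) plus one non-uniform bin; bins k and n_points - k
    are then merged so the histogram is invariant to intensity inversion
    (which complements every code).  A 1-pixel border (ceil(radius)) is
    excluded to avoid edge-padding artifacts.  The flat bin (all neighbors
    on the center side) is the first entry.  Length = n_points // 2 + 2
    (6 at defaults); normalized to sum 1.
    """
    import warnings

    with warnings.catch_warnings():
        # float input is intentional: ties are broken by the >= convention
        warnings.filterwarnings("ignore", message=".*floating-point images.*")
        codes = local_binary_pattern(
            np.asarray(pixels, dtype=float), n_points, radius, method="uniform"
        )
    b = int(np.ceil(radius))
    codes = codes[b:-b, b:-b].astype(int)
    hist = np.bincount(codes.ravel(), minlength=n_points + 2).astype(float)
    # folded[0] merges 0 and n_points set bits: the flat-pattern bin
    folded = [hist[k] + hist[n_points - k] for k in range(n_points // 2)]
    folded.append(hist[n_points // 2])
    folded.append(hist[n_points + 1])  # non-uniform bin
    vec = np.asarray(folded)
    return vec / vec.sum()


# ---------------------------------------------------------------------------


def extract_all(
    images: Sequence[np.ndarray] | np.ndarray,
    spectral_params: Mapping[str, int] | None = None,
) -> dict[str, FeatureVectorSet]:
    """Descriptor vectors of all four models for a common-shape image list.

    Row order follows stimulus order.  Raises on heterogeneous shapes or
    fewer than two stimuli.
    """
    arrs = [np.asarray(im, dtype=float) for im in images]
    if len({a.shape for a in arrs}) > 1 or (arrs and arrs[0].ndim != 2):
        raise ValueError("stimuli must share a common 2-D shape")
    stack = np.asarray(arrs)
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    sp = dict(n_scales=4, n_orientations=8, grid=4)
    if spectral_params:
        sp.update(spectral_params)
    centered = stack - stack.mean(axis=(1, 2), keepdims=True)
    spectral = _spectral_stack(centered, sp["n_scales"], sp["n_orientations"], sp["grid"])
    dense = np.stack([dense_gradient(im) for im in stack])
    pyramid = np.stack([pyramid_gradient(im) for im in stack])
    lbp = np.stack([lbp_histogram(im) for im in stack])
    return {
        "spectral_summary": FeatureVectorSet("spectral_summary", spectral, sp),
        "dense_gradient": FeatureVectorSet("dense_gradient", dense, {"grid": 8, "n_bins": 8}),
        "pyramid_gradient": FeatureVectorSet("pyramid_gradient", pyramid, {"levels": 3, "n_bins": 8}),
        "local_binary_pattern": FeatureVectorSet(
            "local_binary_pattern", lbp, {"n_points": 8, "radius": 1.0}
        ),
    }
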