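"""Parametric region-restricted image manipulations.

Three procedures, each applied in four steps of increasing strength to
either the foreground or the background of a stimulus:

* ``contrast`` — alpha blending of the targeted region toward the uniform
  background gray (alpha 1 = intact, alpha 0 = region removed);
* ``lowpass`` / ``highpass`` — 5th-order Butterworth filtering in the
  frequency domain, with cutoffs sampled log-uniformly between 0.05 and
  25 cycles/degree, composited back into the targeted region only, and the
  region's RMS contrast (std of intensities) restored exactly before
  clipping to [0, 1].

Filtering always happens on the full framed image; the filtered pixels are
then composited into the targeted region, so pixels outside that region
are bit-identical to the intact stimulus at every step.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .stimuli import BACKGROUND, FOREGROUND, ForegroundMask, Stimulus

__all__ = [
    "CONTRAST",
    "LOWPASS",
    "HIGHPASS",
    "FilterStep",
    "FilteredStimulus",
    "FilterSeriesConfig",
    "rms_contrast",
    "alpha_blend",
    "butterworth_response",
    "butterworth_filter_image",
    "log_spaced_cutoffs",
    "frequency_filter_region",
    "make_filter_series",
    "region_mask",
]

logger = logging.getLogger(__name__)

CONTRAST = "contrast"
LOWPASS = "lowpass"
HIGHPASS = "highpass"
_PROCEDURES = (CONTRAST, LOWPASS, HIGHPASS)


@dataclass(frozen=True)
class FilterStep:
    """One cell of the 2 regions x 3 procedures x 4 steps design."""

    procedure: str
    step_index: int  # 1..4, increasing filtering strength
    parameter: float  # alpha for contrast, cutoff in cycles/degree otherwise
    region: str

    def __post_init__(self) -> None:
        if self.procedure not in _PROCEDURES:
            raise ValueError(f"unknown procedure {self.procedure!r}")
        if self.region not in (FOREGROUND, BACKGROUND):
            raise ValueError(f"unknown region {self.region!r}")
        if not 1 <= self.step_index <= 4:
            raise ValueError("step_index must be in 1..4")
        if self.procedure == CONTRAST and not 0 <= self.parameter <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.procedure != CONTRAST and self.parameter <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class FilteredStimulus:
    """Output of one filtering step, with the RMS bookkeeping attached.

    ``rms_after`` is measured before the final clip to [0, 1]; for the
    spatial-frequency procedures it matches ``rms_before`` to ~1e-12.
    ``rms_after_clipped`` records the (possibly slightly perturbed) value
    after clipping.
    """

    pixels: np.ndarray
    step: FilterStep
    parent_id: str
    rms_before: float
    rms_after: float
    rms_after_clipped: float


@dataclass(frozen=True)
class FilterSeriesConfig:
    alpha_steps: tuple[float, ...] = (0.75, 0.5, 0.25, 0.0)
    cutoff_min_cpd: float = 0.05
    cutoff_max_cpd: float = 25.0
    n_steps: int = 4
    butterworth_order: int = 5


def region_mask(stim: Stimulus, mask: ForegroundMask, region: str) -> np.ndarray:
    """Boolean targeted-region mask, restricted to the aperture."""
    fg = mask.pixels & stim.aperture_mask
    if region == FOREGROUND:
        return fg
    if region == BACKGROUND:
        return stim.aperture_mask & ~fg
    raise ValueError(f"unknown region {region!r}")


def rms_contrast(pixels: np.ndarray, mask: np.ndarray) -> float:
    """RMS contrast of a region: population std of its intensities."""
    vals = np.asarray(pixels)[np.asarray(mask, dtype=bool)]
    if vals.size < 2:
        raise ValueError("RMS contrast undefined for a region of < 2 pixels")
    return float(np.std(vals))


def alpha_blend(
    stim: Stimulus, mask: ForegroundMask, region: str, alpha: float, step_index: int = 0
) -> FilteredStimulus:
    """Blend the targeted region toward the background gray.

    Within the region, pixel <- alpha * pixel + (1 - alpha) * gray; all
    other pixels are untouched.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    target = region_mask(stim, mask, region)
    rms0 = rms_contrast(stim.pixels, target)
    out = stim.pixels.copy()
    out[target] = alpha * out[target] + (1 - alpha) * stim.background_gray
    rms1 = float(np.std(out[target]))
    step = FilterStep(CONTRAST, step_index or 1, alpha, region)
    return FilteredStimulus(out, step, stim.id, rms0, rms1, rms1)


def butterworth_response(
    f: np.ndarray | float, cutoff: float, order: int = 5, mode: str = LOWPASS
) -> np.ndarray | float:
    """Radial Butterworth gain at spatial frequency ``f`` (same units as cutoff)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if order < 1:
        raise ValueError("order must be >= 1")
    f = np.asarray(f, dtype=float)
    if mode == LOWPASS:
        gain = 1.0 / np.sqrt(1.0 + (f / cutoff) ** (2 * order))
    elif mode == HIGHPASS:
        with np.errstate(divide="ignore"):
            ratio = np.where(f > 0, cutoff / np.where(f > 0, f, 1.0), np.inf)
        gain = np.where(f > 0, 1.0 / np.sqrt(1.0 + ratio ** (2 * order)), 0.0)
    else:
        raise ValueError(f"mode must be {LOWPASS!r} or {HIGHPASS!r}")
    return gain if gain.ndim else float(gain)


def log_spaced_cutoffs(
    fmin: float = 0.05, fmax: float = 25.0, n: int = 4
) -> np.ndarray:
    """``n`` cutoffs sampled linearly on a log axis, endpoints included."""
    return np.geomspace(fmin, fmax, n)


def butterworth_filter_image(
    pixels: np.ndarray,
    cutoff_cpd: float,
    px_per_degree: float,
    order: int = 5,
    mode: str = LOWPASS,
) -> np.ndarray:
    """Filter a whole image with a radially symmetric Butterworth gain.

    The cutoff is given in cycles/degree and converted to cycles/pixel via
    the stimulus scale.  Cutoffs above the Nyquist frequency (0.5 c/px) are
    applied as-is (near-all-pass for the lowpass branch) with a logged
    warning.
    """
    cutoff_cpp = cutoff_cpd / px_per_degree
    if cutoff_cpp > 0.5:
        logger.warning(
            "cutoff %.3g cpd is %.3g c/px, above Nyquist (0.5 c/px); applied as-is",
            cutoff_cpd,
            cutoff_cpp,
        )
    h, w = pixels.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    rad = np.hypot(fy, fx)
    gain = butterworth_response(rad, cutoff_cpp, order, mode)
    return np.real(np.fft.ifft2(np.fft.fft2(pixels) * gain))


def frequency_filter_region(
    stim: Stimulus,
    mask: ForegroundMask,
    region: str,
    step: FilterStep,
    order: int | None = None,
) -> FilteredStimulus:
    """Spatial-frequency filter one region, holding its RMS contrast fixed.

    The full framed image is filtered in the frequency domain; filtered
    pixels are composited into the targeted region only; the region is then
    affinely rescaled (fixed point: the intact region mean) so its RMS
    contrast matches the intact region exactly, and finally clipped to
    [0, 1].  A region with zero intact contrast is returned unchanged with
    a warning (filtering a uniform patch is undefined).
    """
    if step.procedure not in (LOWPASS, HIGHPASS):
        raise ValueError("frequency_filter_region requires a lowpass/highpass step")
    order = order if order is not None else 5
    target = region_mask(stim, mask, region)
    m0 = float(stim.pixels[target].mean())
    rms0 = rms_contrast(stim.pixels, target)
    if rms0 < 1e-12:
        logger.warning("region %r of %s is uniform; returned unchanged", region, stim.id)
        return FilteredStimulus(stim.pixels.copy(), step, stim.id, rms0, rms0, rms0)
    filtered = butterworth_filter_image(
        stim.pixels, step.parameter, stim.px_per_degree, order=order, mode=step.procedure
    )
    reg = filtered[target]
    mf, rf = float(reg.mean()), float(np.std(reg))
    if rf < 1e-15:
        logger.warning(
            "filter step %r removed all contrast from region %r of %s",
            step,
            region,
            stim.id,
        )
        scaled = np.full_like(reg, m0)
    else:
        scaled = m0 + (rms0 / rf) * (reg - mf)
    out = stim.pixels.copy()
    out[target] = scaled
    rms_pre = float(np.std(out[target]))
    clipped = np.clip(out, 0.0, 1.0)
    rms_post = float(np.std(clipped[target]))
    return FilteredStimulus(clipped, step, stim.id, rms0, rms_pre, rms_post)


def make_filter_series(
    stim: Stimulus,
    mask: ForegroundMask,
    region: str,
    config: FilterSeriesConfig | None = None,
) -> list[FilteredStimulus]:
    """The 12 filtered versions of one region: 4 contrast + 4 low + 4 high.

    Steps are ordered by increasing filtering strength within each
    procedure: descending alpha for contrast, descending cutoff for
    lowpass, ascending cutoff for highpass.
    """
    cfg = config or FilterSeriesConfig()
    if len(cfg.alpha_steps) != cfg.n_steps:
        raise ValueError("alpha_steps length must equal n_steps")
    cutoffs = log_spaced_cutoffs(cfg.cutoff_min_cpd, cfg.cutoff_max_cpd, cfg.n_steps)
    out: list[FilteredStimulus] = []
    for i, alpha in enumerate(cfg.alpha_steps, start=1):
        out.append(alpha_blend(stim, mask, region, alpha, step_index=i))
    for i, cut in enumerate(cutoffs[::-1], start=1):  # strength up as cutoff falls
        step = FilterStep(LOWPASS, i, float(cut), region)
        out.append(frequency_filter_region(stim, mask, region, step, cfg.butterworth_order))
    for i, cut in enumerate(cutoffs, start=1):  # strength up as cutoff rises
        step = FilterStep(HIGHPASS, i, float(cut), region)
        out.append(frequency_filter_region(stim, mask, region, step, cfg.butterworth_order))
    return out
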