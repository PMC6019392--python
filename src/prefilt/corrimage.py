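"""Correlation images: the pictorial per-ROI summary.

For each region (foreground, background) the best-correlating lowpass and
best-correlating highpass filtered versions are averaged pixelwise, and
every pixel's deviation from the background gray is scaled by the
region's best alpha (blending toward gray, consistent with the contrast
manipulation).  The two regional composites are then merged by the
foreground mask.  The result shows, at a glance, which contrast and
spatial-frequency content of each region the ROI's representational
geometry prefers.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from .filtering import (
    CONTRAST,
    HIGHPASS,
    LOWPASS,
    FilterSeriesConfig,
    FilteredStimulus,
    make_filter_series,
    region_mask,
)
from .stimuli import BACKGROUND, FOREGROUND, ForegroundMask, Stimulus

__all__ = ["CorrelationImage", "build_correlation_image", "montage", "save_correlation_image"]

_CELLS = [
    (region, proc, step)
    for region in (FOREGROUND, BACKGROUND)
    for proc in (CONTRAST, LOWPASS, HIGHPASS)
    for step in (1, 2, 3, 4)
]


@dataclass(frozen=True)
class CorrelationImage:
    pixels: np.ndarray
    roi_id: str
    chosen_steps: Mapping[str, Mapping[str, int]]  # region -> procedure -> step_index


def _best_step(
    rhos: Mapping[tuple[str, str, int], float], region: str, proc: str
) -> int:
    """Argmax-rho step index; ties break toward the less-filtered step."""
    best, best_rho = None, -np.inf
    for step in (1, 2, 3, 4):
        rho = rhos[(region, proc, step)]
        if rho > best_rho:
            best, best_rho = step, rho
    return best


def build_correlation_image(
    stim: Stimulus,
    mask: ForegroundMask,
    rhos: Mapping[tuple[str, str, int], float],
    roi_id: str,
    series: Mapping[str, Sequence[FilteredStimulus]] | None = None,
    config: FilterSeriesConfig | None = None,
) -> CorrelationImage:
    """Compose the correlation image from a (region, procedure, step) -> rho table.

    ``rhos`` must cover all 24 cells.  ``series`` may supply the
    precomputed 12-step filter series per region (keyed by region name);
    otherwise the needed filtered images are recomputed from ``stim`` and
    ``mask`` with ``config``.
    """
    missing = [c for c in _CELLS if c not in rhos]
    if missing:
        raise ValueError(f"rho table is missing cells: {missing}")

    gray = stim.background_gray
    out = np.full_like(stim.pixels, gray)
    chosen: dict[str, dict[str, int]] = {}
    for region in (FOREGROUND, BACKGROUND):
        if series is not None and region in series:
            reg_series = list(series[region])
        else:
            reg_series = make_filter_series(stim, mask, region, config)
        by_key = {(fs.step.procedure, fs.step.step_index): fs for fs in reg_series}
        best = {proc: _best_step(rhos, region, proc) for proc in (CONTRAST, LOWPASS, HIGHPASS)}
        chosen[region] = best
        lp = by_key[(LOWPASS, best[LOWPASS])].pixels
        hp = by_key[(HIGHPASS, best[HIGHPASS])].pixels
        alpha = by_key[(CONTRAST, best[CONTRAST])].step.parameter
        composite = gray + alpha * ((lp + hp) / 2.0 - gray)
        target = region_mask(stim, mask, region)
        out[target] = composite[target]
    return CorrelationImage(np.clip(out, 0.0, 1.0), roi_id, chosen)


def montage(images: Sequence[CorrelationImage], n_cols: int = 4, pad: int = 4) -> np.ndarray:
    """Tile correlation images into one array (gray padding between panels)."""
    if not images:
        raise ValueError("no images to tile")
    h, w = images[0].pixels.shape
    n = len(images)
    n_cols = min(n_cols, n)
    n_rows = -(-n // n_cols)
    canvas = np.full((n_rows * (h + pad) - pad, n_cols * (w + pad) - pad), 0.5)
    for k, im in enumerate(images):
        r, c = divmod(k, n_cols)
        canvas[r * (h + pad) : r * (h + pad) + h, c * (w + pad) : c * (w + pad) + w] = im.pixels
    return canvas


def save_correlation_image(ci: CorrelationImage, out_dir: str | Path) -> None:
    """Write the PNG and the chosen-steps JSON sidecar for one ROI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arr = np.round(ci.pixels * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(out / f"{ci.roi_id}.png")
    (out / f"{ci.roi_id}_chosen_steps.json").write_text(json.dumps(ci.chosen_steps, indent=2))
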