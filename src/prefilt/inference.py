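"""The three bespoke significance procedures.

* Foreground enhancement: does the behavioral segmentation explain the
  target representational geometry better than chance?  The null shuffles
  the foreground masks across stimuli (preserving the multiset of mask
  sizes, hence the fovea-to-periphery bias) and matches each randomly
  segmented image's RMS contrast to its behaviorally segmented
  counterpart, so size, location and contrast are all controlled.
* Control-voxel null: is a model-to-ROI correlation higher than that of
  random voxel sets of the same size drawn outside the ROIs, accepted
  only when their inter-subject reliability falls inside the ROI's own
  noise band (noise estimate +/- SE)?
* Background suppression: does filtering a region move the fixed-model
  correlation relative to the intact stimuli?  The observed difference of
  bootstrap means is compared with a permutation null built by pooling
  and re-splitting the two bootstrap distributions; a significant
  increase reads as suppression (the filtered-out content was noise to
  that ROI), a significant decrease as progressive decay.

All rank p-values use the add-one convention (1 + r) / (1 + n), so p is
never zero and is exact under exchangeability.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._util import substream
from .filtering import FilterStep, rms_contrast
from .rdm import (
    RDM,
    NoiseEstimate,
    compute_rdm,
    fit_fixed_model,
    mean_rdm,
    noise_estimate,
    normalize_rdm,
    spearman_rdm,
)
from .features import extract_all
from .stimuli import FOREGROUND, ForegroundMask, Stimulus, isolate_region

__all__ = [
    "PermutationResult",
    "ControlVoxelResult",
    "StepRecord",
    "SuppressionProfile",
    "rank_p_value",
    "fit_images_to_target",
    "foreground_enhancement_test",
    "control_voxel_null",
    "background_suppression_test",
]


def rank_p_value(observed: float, null: np.ndarray, tail: str = "greater") -> float:
    """Add-one permutation p-value of ``observed`` against ``null`` draws."""
    null = np.asarray(null, dtype=float)
    if tail == "greater":
        r = int(np.sum(null >= observed))
    elif tail == "two-sided":
        r = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    return (1 + r) / (1 + null.size)


@dataclass(frozen=True)
class PermutationResult:
    observed_rho: float
    null_rhos: np.ndarray
    p_value: float
    corrected_alpha_m: int
    significant: bool

    def __post_init__(self) -> None:
        n = self.null_rhos.size
        if not (1 / (n + 1) - 1e-12 <= self.p_value <= 1 + 1e-12):
            raise ValueError("p-value outside its attainable range")


@dataclass(frozen=True)
class ControlVoxelResult:
    """Permutation result plus the acceptance-band bookkeeping."""

    result: PermutationResult
    accepted_r12: np.ndarray  # inter-subject rho of every accepted draw
    band: tuple[float, float]
    attempts: int


@dataclass(frozen=True)
class StepRecord:
    step: FilterStep
    rho: float
    rho_se: float
    delta_vs_intact: float
    p_two_tailed: float
    direction: str  # decay | increase | flat


@dataclass(frozen=True)
class SuppressionProfile:
    """Per-ROI correlation trajectory across the 12 steps of one region."""

    roi_id: str
    region: str
    records: tuple[StepRecord, ...]

    def __post_init__(self) -> None:
        for r in self.records:
            if not 0 < r.p_two_tailed <= 1:
                raise ValueError("p-values must lie in (0, 1]")


def fit_images_to_target(
    images: Sequence[np.ndarray],
    target_rdm: RDM,
    n_folds: int = 5,
    seed: int = 0,
):
    """Descriptor RDMs of ``images`` -> normalized -> fixed-model fit.

    The four model RDMs are normalized per image set (each filtered set is
    its own model instantiation) before the cross-validated fit.
    """
    sets = extract_all(images)
    model_rdms = [
        normalize_rdm(compute_rdm(fvs.vectors, target_rdm.stimulus_ids))
        for fvs in sets.values()
    ]
    return fit_fixed_model(model_rdms, target_rdm, n_folds=n_folds, seed=seed), model_rdms


# ---------------------------------------------------------------------------
# Foreground enhancement


def _match_region_rms(
    pixels: np.ndarray, region: np.ndarray, target_rms: float
) -> np.ndarray:
    """Affinely rescale the region about its mean to a target RMS contrast."""
    out = pixels.copy()
    vals = out[region]
    sd = vals.std()
    if sd > 0:
        out[region] = vals.mean() + (target_rms / sd) * (vals - vals.mean())
    return np.clip(out, 0.0, 1.0)


def foreground_enhancement_test(
    stimuli: Sequence[Stimulus],
    masks: Sequence[ForegroundMask],
    target_rdm: RDM,
    n_perm: int = 1000,
    seed: int = 0,
    n_folds: int = 5,
    m: int = 1,
) -> PermutationResult:
    """Permutation test of foreground enhancement against shuffled masks.

    Each permutation re-assigns the behavioral masks to stimuli at random
    (fixed points allowed), isolates the foreground under the shuffled
    mask, matches its RMS contrast to the behaviorally segmented
    counterpart, and re-runs the full descriptor -> fixed-model pipeline
    against ``target_rdm``.  One-tailed add-one rank p; Bonferroni factor
    ``m`` sets the significance flag.
    """
    if len(stimuli) != len(masks):
        raise ValueError("one mask per stimulus required")
    n = len(stimuli)
    rng = substream(seed, "enhancement-permutations")
    # fixed fold partition shared by observed and null fits, for comparability
    fold_seed = seed

    true_seg = [isolate_region(s, mk, FOREGROUND) for s, mk in zip(stimuli, masks)]
    true_rms = [
        rms_contrast(seg.pixels, mk.pixels & s.aperture_mask)
        for seg, mk, s in zip(true_seg, masks, stimuli)
    ]
    observed_fit, _ = fit_images_to_target(
        [seg.pixels for seg in true_seg], target_rdm, n_folds=n_folds, seed=fold_seed
    )

    null_rhos = np.empty(n_perm)
    for p in range(n_perm):
        while True:
            perm = rng.permutation(n)
            if all(
                (masks[perm[i]].pixels & stimuli[i].aperture_mask).sum() >= 2
                for i in range(n)
            ):
                break
        images = []
        for i in range(n):
            mk = masks[perm[i]]
            region = mk.pixels & stimuli[i].aperture_mask
            seg = isolate_region(stimuli[i], mk, FOREGROUND)
            images.append(_match_region_rms(seg.pixels, region, true_rms[i]))
        fit, _ = fit_images_to_target(images, target_rdm, n_folds=n_folds, seed=fold_seed)
        null_rhos[p] = fit.rho

    p_value = rank_p_value(observed_fit.rho, null_rhos, "greater")
    return PermutationResult(
        observed_fit.rho, null_rhos, p_value, m, p_value < 0.05 / m
    )


# ---------------------------------------------------------------------------
# Control-voxel null


def control_voxel_null(
    pool_responses: tuple[np.ndarray, np.ndarray],
    roi_responses: tuple[np.ndarray, np.ndarray],
    model_rdm: RDM,
    noise: NoiseEstimate | None = None,
    n_valid: int = 1000,
    seed: int = 0,
    m: int = 27,
    n_boot_noise: int = 1000,
    max_draws: int = 10**6,
    min_rate: float = 1e-3,
) -> ControlVoxelResult:
    """ROI-specific null from control voxels matched on size and reliability.

    Draws voxel sets of the ROI's size (without replacement within a draw)
    from the control pool, accepts a draw only when the two subjects' null
    RDMs correlate within the ROI's noise band (noise estimate +/- SE),
    and correlates the subject-mean null RDM with ``model_rdm``.  The
    observed value is the model's correlation with the subject-mean ROI
    RDM.  One-tailed add-one rank p, Bonferroni factor ``m`` (default 27:
    3 descriptions + 12 + 12 filtering steps).
    """
    ids = model_rdm.stimulus_ids
    roi_rdms = [compute_rdm(r.T, ids) for r in roi_responses]
    if noise is None:
        noise = noise_estimate(roi_rdms, n_boot=n_boot_noise, seed=seed)
    lo = noise.rho_noise - noise.rho_noise_se
    hi = noise.rho_noise + noise.rho_noise_se
    observed = spearman_rdm(model_rdm, mean_rdm(roi_rdms))

    n_roi = roi_responses[0].shape[0]
    n_pool = pool_responses[0].shape[0]
    if n_pool < n_roi:
        raise ValueError("control pool smaller than the ROI voxel count")
    rng = substream(seed, "control-voxel-draws")
    null_rhos = np.empty(n_valid)
    accepted_r12 = np.empty(n_valid)
    accepted = 0
    attempts = 0
    while accepted < n_valid:
        if attempts >= max_draws:
            raise RuntimeError(
                "control-voxel acceptance band unattainable: "
                f"{accepted}/{attempts} draws accepted within "
                f"[{lo:.4f}, {hi:.4f}] (min rate {min_rate})"
            )
        attempts += 1
        idx = rng.choice(n_pool, size=n_roi, replace=False)
        null_s = [compute_rdm(r[idx].T, ids) for r in pool_responses]
        r12 = spearman_rdm(null_s[0], null_s[1])
        if not (lo <= r12 <= hi):
            continue
        null_rhos[accepted] = spearman_rdm(model_rdm, mean_rdm(null_s))
        accepted_r12[accepted] = r12
        accepted += 1
    p_value = rank_p_value(observed, null_rhos, "greater")
    result = PermutationResult(observed, null_rhos, p_value, m, p_value < 0.05 / m)
    return ControlVoxelResult(result, accepted_r12, (lo, hi), attempts)


# ---------------------------------------------------------------------------
# Background suppression


def background_suppression_test(
    intact_boot: np.ndarray,
    step_boot: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    m: int = 13,
    alpha: float = 0.05,
) -> tuple[float, float, str]:
    """Bootstrap-difference permutation test of one filtering step vs intact.

    The observed statistic is the difference of bootstrap means
    (step - intact).  The null pools both bootstrap distributions and
    randomly re-splits them (without replacement) into groups of the
    original sizes.  Two-tailed add-one p; Bonferroni factor ``m``
    (default 13: 12 steps + the intact-vs-segmented comparison).
    Returns (delta, p, direction), direction in {increase, decay, flat}.
    """
    intact_boot = np.asarray(intact_boot, dtype=float)
    step_boot = np.asarray(step_boot, dtype=float)
    if intact_boot.size == 0 or step_boot.size == 0:
        raise ValueError("bootstrap distributions must be nonempty")
    delta = float(step_boot.mean() - intact_boot.mean())
    pool = np.concatenate([step_boot, intact_boot])
    n1 = step_boot.size
    total = pool.sum()
    rng = substream(seed, "suppression-permutations")
    null = np.empty(n_perm)
    for k in range(n_perm):
        pick = rng.permutation(pool.size)[:n1]
        s1 = pool[pick].sum()
        null[k] = s1 / n1 - (total - s1) / (pool.size - n1)
    p = rank_p_value(delta, null, "two-sided")
    if p < alpha / m:
        direction = "increase" if delta > 0 else "decay"
    else:
        direction = "flat"
    return delta, p, direction
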