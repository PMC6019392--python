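"""End-to-end orchestration over a dataset directory.

A dataset directory (real or written by :mod:`prefilt.synthetic`) holds
stimuli and mask PNGs, an HDF5 file of per-ROI two-subject voxel
responses (optionally a control-voxel pool), and a JSON manifest.  For
each ROI, :func:`run_full` produces the intact/foreground/background
correlation table, the foreground-enhancement permutation p, the 24-step
suppression profiles for both regions, and the correlation images.
Every numeric output is regenerable from the config plus its seed; the
config is echoed verbatim into the results directory.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .corrimage import build_correlation_image, save_correlation_image
from .filtering import CONTRAST, FilterSeriesConfig, make_filter_series
from .inference import (
    StepRecord,
    SuppressionProfile,
    background_suppression_test,
    control_voxel_null,
    fit_images_to_target,
    foreground_enhancement_test,
)
from .rdm import (
    RDM,
    bootstrap_fit,
    compute_rdm,
    mean_rdm,
    noise_estimate,
)
from .stimuli import BACKGROUND, FOREGROUND, isolate_region
from .synthetic import SyntheticSet, load_dataset

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "DataError", "RunConfig", "run_full", "step_rho_table"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or inconsistent input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    dataset: str
    out: str
    seed: int = 0
    rois: Sequence[str] | None = None
    n_perm_enhancement: int = 200
    n_boot: int = 500
    n_perm_suppression: int = 2000
    n_folds: int = 5
    n_valid_control: int = 200
    m_suppression: int = 13
    m_control: int = 27
    alpha_steps: tuple[float, ...] = (0.75, 0.5, 0.25, 0.0)
    cutoff_min_cpd: float = 0.05
    cutoff_max_cpd: float = 25.0
    n_steps: int = 4
    butterworth_order: int = 5
    run_control_voxel: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "alpha_steps" in raw:
            raw["alpha_steps"] = tuple(raw["alpha_steps"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        if not Path(self.dataset).is_dir():
            raise ConfigError(f"dataset directory not found: {self.dataset}")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if len(self.alpha_steps) != self.n_steps:
            raise ConfigError("alpha_steps length must equal n_steps")

    def filter_config(self) -> FilterSeriesConfig:
        return FilterSeriesConfig(
            alpha_steps=tuple(self.alpha_steps),
            cutoff_min_cpd=self.cutoff_min_cpd,
            cutoff_max_cpd=self.cutoff_max_cpd,
            n_steps=self.n_steps,
            butterworth_order=self.butterworth_order,
        )


def _roi_rdms(ds: SyntheticSet, roi: str) -> tuple[list[RDM], RDM]:
    ids = tuple(s.id for s in ds.stimuli)
    r1, r2 = ds.responses[roi]
    subj = [compute_rdm(r1.T, ids), compute_rdm(r2.T, ids)]
    return subj, mean_rdm(subj)


def step_rho_table(
    ds: SyntheticSet,
    target: RDM,
    cfg: FilterSeriesConfig,
    n_folds: int = 5,
    seed: int = 0,
    n_boot: int = 0,
):
    """Fit the fixed model at each of the 24 (region, procedure, step) cells.

    Returns (rhos, boots, series_by_stimulus): ``rhos`` maps each cell to
    its cross-validated rho; ``boots`` maps it to the bootstrap rho
    distribution when ``n_boot`` > 0; ``series_by_stimulus`` keeps the
    per-stimulus 12-step series per region for the correlation images.
    """
    rhos: dict[tuple[str, str, int], float] = {}
    boots: dict[tuple[str, str, int], np.ndarray] = {}
    series_by_stimulus: dict[str, list] = {}
    for region in (FOREGROUND, BACKGROUND):
        all_series = [
            make_filter_series(s, m, region, cfg)
            for s, m in zip(ds.stimuli, ds.masks)
        ]
        series_by_stimulus[region] = all_series
        n_steps = len(all_series[0])
        for k in range(n_steps):
            step = all_series[0][k].step
            images = [ser[k].pixels for ser in all_series]
            fit, models = fit_images_to_target(images, target, n_folds=n_folds, seed=seed)
            key = (region, step.procedure, step.step_index)
            rhos[key] = fit.rho
            if n_boot:
                boots[key] = bootstrap_fit(models, target, n_boot=n_boot, seed=seed).rhos
    return rhos, boots, series_by_stimulus


def run_full(config: RunConfig) -> Path:
    """Run the complete analysis; returns the results directory."""
    config.validate()
    try:
        ds = load_dataset(config.dataset)
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise DataError(f"cannot load dataset {config.dataset}: {exc}") from exc
    rois = [r for r in ds.responses if r != "__control_pool__"]
    if config.rois:
        missing = set(config.rois) - set(rois)
        if missing:
            raise DataError(f"ROIs not in dataset: {sorted(missing)}")
        rois = list(config.rois)
    pool = ds.responses.get("__control_pool__")

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    fcfg = config.filter_config()
    ids = tuple(s.id for s in ds.stimuli)
    intact_images = [s.pixels for s in ds.stimuli]
    seg_images = {
        FOREGROUND: [
            isolate_region(s, m, FOREGROUND).pixels for s, m in zip(ds.stimuli, ds.masks)
        ],
        BACKGROUND: [
            isolate_region(s, m, BACKGROUND).pixels for s, m in zip(ds.stimuli, ds.masks)
        ],
    }

    rho_rows = []
    enh: dict[str, dict] = {}
    supp_rows = []
    for roi in rois:
        logger.info("ROI %s", roi)
        subj_rdms, target = _roi_rdms(ds, roi)
        noise = noise_estimate(subj_rdms, n_boot=config.n_boot, seed=config.seed)

        desc_boots: dict[str, np.ndarray] = {}
        for desc, images in (
            ("intact", intact_images),
            ("foreground", seg_images[FOREGROUND]),
            ("background", seg_images[BACKGROUND]),
        ):
            fit, models = fit_images_to_target(
                images, target, n_folds=config.n_folds, seed=config.seed
            )
            boot = bootstrap_fit(models, target, n_boot=config.n_boot, seed=config.seed)
            desc_boots[desc] = boot.rhos
            p_control = np.nan
            if pool is not None and config.run_control_voxel:
                pred = sum(w * m.matrix for w, m in zip(fit.mean_weights, models))
                pred_rdm = RDM(pred - np.diag(np.diag(pred)), ids)
                ctrl = control_voxel_null(
                    pool,
                    ds.responses[roi],
                    pred_rdm,
                    noise=noise,
                    n_valid=config.n_valid_control,
                    seed=config.seed,
                    m=config.m_control,
                )
                p_control = ctrl.result.p_value
            rho_rows.append(
                {
                    "roi": roi,
                    "description": desc,
                    "rho": fit.rho,
                    "se": boot.se,
                    "rho_noise": noise.rho_noise,
                    "rho_noise_se": noise.rho_noise_se,
                    "p_control_voxel": p_control,
                    "m": config.m_control,
                }
            )

        res = foreground_enhancement_test(
            ds.stimuli,
            ds.masks,
            target,
            n_perm=config.n_perm_enhancement,
            seed=config.seed,
            n_folds=config.n_folds,
        )
        enh[roi] = {
            "observed_rho": res.observed_rho,
            "p_value": res.p_value,
            "n_perm": config.n_perm_enhancement,
            "significant": bool(res.significant),
            "m": res.corrected_alpha_m,
        }

        rhos, boots, series = step_rho_table(
            ds, target, fcfg, n_folds=config.n_folds, seed=config.seed, n_boot=config.n_boot
        )
        for region in (FOREGROUND, BACKGROUND):
            records = []
            for (reg, proc, idx), boot in sorted(boots.items()):
                if reg != region:
                    continue
                delta, p, direction = background_suppression_test(
                    desc_boots["intact"],
                    boot,
                    n_perm=config.n_perm_suppression,
                    seed=config.seed,
                    m=config.m_suppression,
                )
                step = next(
                    fs.step
                    for fs in series[region][0]
                    if fs.step.procedure == proc and fs.step.step_index == idx
                )
                records.append(
                    StepRecord(step, rhos[(reg, proc, idx)], float(boot.std()), delta, p, direction)
                )
                supp_rows.append(
                    {
                        "roi": roi,
                        "region": region,
                        "procedure": proc,
                        "step_index": idx,
                        "parameter": step.parameter,
                        "rho": rhos[(reg, proc, idx)],
                        "se": float(boot.std()),
                        "delta_vs_intact": delta,
                        "p_two_tailed": p,
                        "direction": direction,
                        "m": config.m_suppression,
                    }
                )
            SuppressionProfile(roi, region, tuple(records))  # invariant check

        # correlation image for the first stimulus, plus the across-stimuli mean
        per_stim = []
        for i, (stim, mask) in enumerate(zip(ds.stimuli, ds.masks)):
            ci = build_correlation_image(
                stim,
                mask,
                rhos,
                roi,
                series={r: series[r][i] for r in series},
                config=fcfg,
            )
            per_stim.append(ci.pixels)
            if i == 0:
                save_correlation_image(ci, out / "corr_images")
        mean_pixels = np.mean(per_stim, axis=0)
        from .corrimage import CorrelationImage

        save_correlation_image(
            CorrelationImage(mean_pixels, f"{roi}_mean", ci.chosen_steps),
            out / "corr_images",
        )

    pd.DataFrame(rho_rows).to_csv(out / "rho_table.csv", index=False, float_format="%.6g")
    pd.DataFrame(supp_rows).to_csv(out / "suppression.csv", index=False, float_format="%.6g")
    (out / "enhancement.json").write_text(json.dumps(enh, indent=2, sort_keys=True))
    (out / "run_log.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True, default=list)
    )
    return out
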