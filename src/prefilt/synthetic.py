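"""Synthetic stimuli and neural observers with known segmentation behavior.

The generator replaces the downloads the real study used (natural images
with behavioral segmentations, and two subjects' voxel patterns): each
synthetic stimulus is a textured random blob (the foreground, with exact
ground-truth mask) over an independently textured background, framed in
the circular aperture on mid-gray.  A synthetic observer converts either
the intact image or one isolated region into a descriptor vector,
projects it through a fixed random linear map to voxels, and adds
independent Gaussian noise per subject — two "subjects" with shared
signal and independent noise.  Because the observer's selectivity (whole
image, foreground only, background only) is known by construction, it
serves as a ground-truth oracle for the enhancement and suppression
analyses.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from ._util import substream
from .features import extract_all
from .stimuli import (
    BACKGROUND,
    FOREGROUND,
    ForegroundMask,
    Stimulus,
    circular_aperture,
    isolate_region,
    make_stimulus,
)

__all__ = [
    "ObserverSpec",
    "SyntheticSet",
    "generate_stimuli",
    "simulate_observer",
    "project_latent",
    "random_latent_responses",
    "observer_feature_matrix",
    "write_dataset",
    "load_dataset",
]

_MODES = ("full_image", "foreground_only", "background_only")
_SIGNALS = ("descriptors", "pixel_pca")


@dataclass(frozen=True)
class ObserverSpec:
    """A simulated ROI: what it sees, how many voxels, how noisy."""

    mode: str = "full_image"
    n_voxels: int = 80
    noise_sd: float = 0.3  # in units of the per-voxel signal SD
    projection_seed: int = 0
    signal: str = "descriptors"  # or "pixel_pca" (model-mismatched observer)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.signal not in _SIGNALS:
            raise ValueError(f"signal must be one of {_SIGNALS}")
        if self.n_voxels < 10:
            raise ValueError("n_voxels must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticSet:
    stimuli: tuple[Stimulus, ...]
    masks: tuple[ForegroundMask, ...]
    responses: dict[str, tuple[np.ndarray, np.ndarray]]  # roi -> (subj1, subj2)

    def __post_init__(self) -> None:
        if len(self.stimuli) != len(self.masks):
            raise ValueError("stimuli and masks must be aligned")
        for name, (r1, r2) in self.responses.items():
            if not (np.isfinite(r1).all() and np.isfinite(r2).all()):
                raise ValueError(f"non-finite responses in ROI {name!r}")


# ---------------------------------------------------------------------------
# Stimuli


def _texture(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise texture with mean 0.5 and moderate contrast."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = noise.std()
    if sd > 0:
        noise = noise / sd * 0.15
    return np.clip(0.5 + noise, 0.02, 0.98)


def _blob_mask(
    shape: tuple[int, int],
    aperture: np.ndarray,
    area_frac: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Wobbly-ellipse foreground support with roughly the requested area."""
    h, w = shape
    ap_area = aperture.sum()
    target = area_frac * ap_area
    # fovea-to-periphery bias: centers cluster near the middle of the frame
    cy = h / 2 + rng.normal(0, h / 10)
    cx = w / 2 + rng.normal(0, w / 10)
    aspect = rng.uniform(0.45, 1.0)
    base = np.sqrt(target / (np.pi * aspect))
    a, b = base, base * aspect
    theta = rng.uniform(0, np.pi)
    # low-order angular wobble makes the outline blob-like, not elliptical
    n_harm = 3
    amp = rng.uniform(0.05, 0.18, n_harm)
    phase = rng.uniform(0, 2 * np.pi, n_harm)
    yy, xx = np.mgrid[:h, :w]
    dy, dx = yy - cy, xx - cx
    ry = -np.sin(theta) * dx + np.cos(theta) * dy
    rx = np.cos(theta) * dx + np.sin(theta) * dy
    rad = np.sqrt((rx / a) ** 2 + (ry / b) ** 2)
    ang = np.arctan2(ry, rx)
    wob = 1.0 + sum(
        amp[k] * np.cos((k + 2) * ang + phase[k]) for k in range(n_harm)
    )
    return (rad <= wob) & aperture


def generate_stimuli(
    n: int,
    image_size: int = 128,
    seed: int = 0,
    area_range: tuple[float, float] = (0.10, 0.60),
    aperture_degrees: float = 20.0,
) -> tuple[list[Stimulus], list[ForegroundMask]]:
    """Textured random-shape foregrounds over textured backgrounds.

    Foreground areas are drawn (and rejection-enforced) between 10% and
    60% of the aperture, mimicking the fovea-to-periphery bias of natural
    photographs.  The pixels-per-degree scale maps the aperture diameter
    to ``aperture_degrees`` of visual angle.
    """
    if n < 10:
        raise ValueError("need n >= 10 stimuli")
    rng = substream(seed, "generate-stimuli")
    shape = (image_size, image_size)
    aperture = circular_aperture(shape)
    ppd = image_size / aperture_degrees
    stimuli: list[Stimulus] = []
    masks: list[ForegroundMask] = []
    lo, hi = area_range
    for i in range(n):
        for _ in range(100):
            frac = rng.uniform(lo, hi)
            mask = _blob_mask(shape, aperture, frac, rng)
            realized = mask.sum() / aperture.sum()
            if mask.any() and lo <= realized <= hi:
                break
        else:  # pragma: no cover - rejection loop essentially never exhausts
            raise RuntimeError("could not draw a foreground within the area bounds")
        bg = _texture(shape, rng.uniform(1.0, 6.0), rng)
        fg = _texture(shape, rng.uniform(0.6, 3.0), rng)
        pixels = bg.copy()
        pixels[mask] = fg[mask]
        stimuli.append(make_stimulus(pixels, ppd, id=f"syn{i:04d}", aperture_mask=aperture))
        masks.append(ForegroundMask(mask, source="synthetic"))
    return stimuli, masks


# ---------------------------------------------------------------------------
# Observers


def observer_feature_matrix(
    stimuli: Sequence[Stimulus],
    masks: Sequence[ForegroundMask],
    mode: str,
) -> np.ndarray:
    """Concatenated, per-model standardized descriptor matrix (stimuli x D).

    Each model's columns are z-scored across stimuli and scaled by
    1/sqrt(dims) so the four descriptor families contribute equal total
    variance to the observer signal.
    """
    if mode == "full_image":
        images = [s.pixels for s in stimuli]
    elif mode == "foreground_only":
        images = [isolate_region(s, m, FOREGROUND).pixels for s, m in zip(stimuli, masks)]
    elif mode == "background_only":
        images = [isolate_region(s, m, BACKGROUND).pixels for s, m in zip(stimuli, masks)]
    else:
        raise ValueError(f"mode must be one of {_MODES}")
    sets = extract_all(images)
    blocks = []
    for name, fvs in sets.items():
        v = fvs.vectors
        mu, sd = v.mean(axis=0), v.std(axis=0)
        z = np.where(sd > 0, (v - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        blocks.append(z / np.sqrt(v.shape[1]))
    return np.hstack(blocks)


def _project_and_noise(
    signal: np.ndarray,
    n_voxels: int,
    noise_sd: float,
    projection_seed: int,
    noise_rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Project stimuli x D signal to voxels, standardize, add per-subject noise."""
    n_stim, d = signal.shape
    w = substream(projection_seed, "observer-projection").standard_normal((d, n_voxels))
    s = signal @ w / np.sqrt(d)
    s = s - s.mean(axis=0)
    sd = s.std(axis=0)
    s = s / np.where(sd > 0, sd, 1.0)
    resp1 = s.T + noise_sd * noise_rng.standard_normal((n_voxels, n_stim))
    resp2 = s.T + noise_sd * noise_rng.standard_normal((n_voxels, n_stim))
    return resp1, resp2


def simulate_observer(
    stimuli: Sequence[Stimulus],
    masks: Sequence[ForegroundMask],
    spec: ObserverSpec,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two subjects' voxel x stimulus responses for one simulated ROI.

    Both subjects share the deterministic signal (descriptor features of
    the image version the observer is selective for, through a fixed
    random projection); their Gaussian noise is independent, with SD
    ``spec.noise_sd`` in units of the per-voxel signal SD.
    """
    if spec.signal == "descriptors":
        X = observer_feature_matrix(stimuli, masks, spec.mode)
    else:  # pixel_pca: model-mismatched observer for robustness checks
        if spec.mode == "full_image":
            images = [s.pixels for s in stimuli]
        elif spec.mode == "foreground_only":
            images = [isolate_region(s, m, FOREGROUND).pixels for s, m in zip(stimuli, masks)]
        else:
            images = [isolate_region(s, m, BACKGROUND).pixels for s, m in zip(stimuli, masks)]
        flat = np.stack([im.ravel() for im in images])
        flat = flat - flat.mean(axis=0)
        k = min(len(images) - 1, 40)
        u, sv, _ = np.linalg.svd(flat, full_matrices=False)
        X = u[:, :k] * sv[:k]
    noise_rng = substream(seed, f"observer-noise-{spec.mode}-{spec.projection_seed}")
    return _project_and_noise(X, spec.n_voxels, spec.noise_sd, spec.projection_seed, noise_rng)


def project_latent(
    latent: np.ndarray,
    n_voxels: int,
    noise_sd: float,
    projection_seed: int = 0,
    noise_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-subject voxel responses sharing a caller-supplied latent signal."""
    noise_rng = substream(noise_seed, "project-latent-noise")
    return _project_and_noise(latent, n_voxels, noise_sd, projection_seed, noise_rng)


def random_latent_responses(
    n_stimuli: int,
    n_voxels: int,
    noise_sd: float,
    seed: int = 0,
    latent_dim: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-subject responses driven by a shared random latent, not the stimuli.

    Useful as a control-voxel pool: the inter-subject reliability matches
    an observer with the same ``noise_sd``, but the representational
    geometry is unrelated to any image descriptor.
    """
    rng = substream(seed, "latent-signal")
    latent = rng.standard_normal((n_stimuli, latent_dim))
    noise_rng = substream(seed, "latent-noise")
    return _project_and_noise(latent, n_voxels, noise_sd, seed + 1, noise_rng)


# ---------------------------------------------------------------------------
# Dataset directory round-trip


def write_dataset(
    out_dir: str | Path,
    stimuli: Sequence[Stimulus],
    masks: Sequence[ForegroundMask],
    responses: dict[str, tuple[np.ndarray, np.ndarray]],
    pool: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int | None = None,
) -> Path:
    """Write a self-contained dataset directory (PNGs + HDF5 + manifest)."""
    import h5py
    from PIL import Image

    out = Path(out_dir)
    (out / "stimuli").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for s, m in zip(stimuli, masks):
        arr = np.round(s.pixels * 65535).astype(np.uint16)
        Image.fromarray(arr).save(out / "stimuli" / f"{s.id}.png")
        Image.fromarray(m.pixels).convert("1").save(out / "masks" / f"{s.id}.png")
    with h5py.File(out / "responses.h5", "w") as f:
        for roi, (r1, r2) in responses.items():
            grp = f.create_group(f"rois/{roi}")
            grp.create_dataset("subject1", data=r1)
            grp.create_dataset("subject2", data=r2)
        if pool is not None:
            grp = f.create_group("control_pool")
            grp.create_dataset("subject1", data=pool[0])
            grp.create_dataset("subject2", data=pool[1])
    manifest = {
        "ids": [s.id for s in stimuli],
        "px_per_degree": stimuli[0].px_per_degree,
        "background_gray": stimuli[0].background_gray,
        "image_size": list(stimuli[0].shape),
        "rois": {roi: int(r1.shape[0]) for roi, (r1, _) in responses.items()},
        "seed": seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_dataset(path: str | Path) -> SyntheticSet:
    """Read back a dataset directory written by :func:`write_dataset`."""
    import h5py

    from .stimuli import read_grayscale, read_mask_png

    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    aperture = None
    stimuli: list[Stimulus] = []
    masks: list[ForegroundMask] = []
    for sid in manifest["ids"]:
        px = read_grayscale(root / "stimuli" / f"{sid}.png")
        if aperture is None:
            aperture = circular_aperture(px.shape)
        stimuli.append(
            make_stimulus(
                px,
                manifest["px_per_degree"],
                manifest["background_gray"],
                id=sid,
                aperture_mask=aperture,
            )
        )
        masks.append(read_mask_png(root / "masks" / f"{sid}.png"))
    responses: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    with h5py.File(root / "responses.h5", "r") as f:
        for roi in f["rois"]:
            responses[roi] = (
                f[f"rois/{roi}/subject1"][()],
                f[f"rois/{roi}/subject2"][()],
            )
        if "control_pool" in f:
            responses["__control_pool__"] = (
                f["control_pool/subject1"][()],
                f["control_pool/subject2"][()],
            )
    return SyntheticSet(tuple(stimuli), tuple(masks), responses)
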