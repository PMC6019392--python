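"""Representational dissimilarity matrices and the fixed-model fit.

An RDM holds 1 minus the Pearson correlation between every pair of
stimulus vectors (descriptor features or voxel patterns).  The fixed
model is a weighted sum of the four descriptor RDMs: weights are
estimated by ordinary least squares on 80% of the dissimilarities and
the Spearman correlation with the target RDM is evaluated on the
held-out 20%, averaged over 5 cross-validation folds.  Standard errors
come from bootstrap resampling of the stimuli (pairs of identical
resampled stimuli are dropped, as their dissimilarity is 0 by
construction); the noise estimate is the inter-subject RDM correlation,
an effective ceiling on any model's correlation with either subject.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from ._util import substream

__all__ = [
    "RDM",
    "FixedModelFit",
    "NoiseEstimate",
    "BootstrapResult",
    "compute_rdm",
    "normalize_rdm",
    "spearman_rdm",
    "mean_rdm",
    "fit_fixed_model",
    "bootstrap_fit",
    "bootstrap_spearman",
    "noise_estimate",
    "save_rdm_hdf5",
    "load_rdm_hdf5",
]


@dataclass(frozen=True)
class RDM:
    """Symmetric stimulus x stimulus dissimilarity matrix, zero diagonal."""

    matrix: np.ndarray
    stimulus_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.stimulus_ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match stimulus_ids")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if not np.isfinite(m).all():
            raise ValueError("RDM entries must be finite")
        object.__setattr__(self, "stimulus_ids", tuple(self.stimulus_ids))

    @property
    def n(self) -> int:
        return len(self.stimulus_ids)

    def upper(self) -> np.ndarray:
        """Condensed vector of the n(n-1)/2 upper-triangle dissimilarities."""
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]


@dataclass
class FixedModelFit:
    """Cross-validated weighted-sum fit of the four model RDMs.

    ``weights`` has one row of per-model OLS weights per fold;
    ``rho`` is the mean held-out Spearman correlation across folds.
    """

    weights: np.ndarray  # (n_folds, n_models)
    intercepts: np.ndarray  # (n_folds,)
    fold_rhos: np.ndarray  # (n_folds,)
    rho: float
    rho_se: float | None = None

    @property
    def mean_weights(self) -> np.ndarray:
        return self.weights.mean(axis=0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rho": self.rho,
            "rho_se": self.rho_se,
            "fold_rhos": self.fold_rhos.tolist(),
            "weights": self.weights.tolist(),
            "intercepts": self.intercepts.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass(frozen=True)
class NoiseEstimate:
    """Inter-subject RDM correlation with its bootstrap SE."""

    rho_noise: float
    rho_noise_se: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.rho_noise) or self.rho_noise_se < 0:
            raise ValueError("invalid noise estimate")


@dataclass(frozen=True)
class BootstrapResult:
    rhos: np.ndarray
    se: float


def compute_rdm(
    vectors: np.ndarray, stimulus_ids: Sequence[str] | None = None
) -> RDM:
    """1 minus Pearson correlation between every pair of row vectors."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[0] < 3:
        raise ValueError("need at least 3 stimuli for an RDM")
    ids = tuple(stimulus_ids) if stimulus_ids is not None else tuple(
        f"s{i:04d}" for i in range(vectors.shape[0])
    )
    sd = vectors.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance feature vector for stimulus {ids[bad[0]]!r}")
    mat = 1.0 - np.corrcoef(vectors)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return RDM(mat, ids)


def normalize_rdm(rdm: RDM) -> RDM:
    """Min-max rescale the off-diagonal dissimilarities to [0, 1]."""
    tri = rdm.upper()
    lo, hi = tri.min(), tri.max()
    if hi - lo <= 0:
        raise ValueError("constant off-diagonal: degenerate representational geometry")
    mat = (rdm.matrix - lo) / (hi - lo)
    np.fill_diagonal(mat, 0.0)
    return RDM(mat, rdm.stimulus_ids)


def _check_aligned(a: RDM, b: RDM) -> None:
    if a.stimulus_ids != b.stimulus_ids:
        raise ValueError("RDMs are not aligned on the same stimulus order")


def spearman_rdm(a: RDM, b: RDM) -> float:
    """Spearman rank correlation over the condensed upper triangles."""
    _check_aligned(a, b)
    return float(stats.spearmanr(a.upper(), b.upper()).statistic)


def mean_rdm(rdms: Sequence[RDM]) -> RDM:
    """Entrywise arithmetic mean of aligned RDMs (e.g. the two subjects)."""
    for r in rdms[1:]:
        _check_aligned(rdms[0], r)
    mat = np.mean([r.matrix for r in rdms], axis=0)
    return RDM(mat, rdms[0].stimulus_ids)


# ---------------------------------------------------------------------------
# Cross-validated fixed-model fit


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.spearmanr(x, y).statistic)


def _cv_fit(
    X: np.ndarray, y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS-train / Spearman-test over a random entry partition.

    Returns (weights (n_folds, k), intercepts, fold_rhos).
    """
    n_entries = y.size
    perm = rng.permutation(n_entries)
    folds = np.array_split(perm, n_folds)
    k = X.shape[1]
    weights = np.empty((n_folds, k))
    intercepts = np.empty(n_folds)
    fold_rhos = np.empty(n_folds)
    for i, test in enumerate(folds):
        if test.size < 10:
            raise ValueError("cross-validation folds must hold >= 10 dissimilarities")
        train = np.setdiff1d(perm, test, assume_unique=True)
        A = np.column_stack([X[train], np.ones(train.size)])
        coef, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        pred = X[test] @ coef[:k] + coef[k]
        weights[i] = coef[:k]
        intercepts[i] = coef[k]
        fold_rhos[i] = _spearman(pred, y[test])
    return weights, intercepts, fold_rhos


def _stimulus_fold_entries(
    n: int, n_folds: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_entries, test_entries) per fold when folding stimuli, not entries.

    Test entries are pairs with both stimuli held out; train entries are
    pairs with both stimuli in the training set (straddling pairs unused).
    """
    iu, ju = np.triu_indices(n, k=1)
    groups = np.array_split(rng.permutation(n), n_folds)
    out = []
    for g in groups:
        in_test = np.isin(iu, g) & np.isin(ju, g)
        in_train = ~np.isin(iu, g) & ~np.isin(ju, g)
        out.append((np.flatnonzero(in_train), np.flatnonzero(in_test)))
    return out


def fit_fixed_model(
    model_rdms: Sequence[RDM],
    target_rdm: RDM,
    n_folds: int = 5,
    seed: int = 0,
    fold_unit: str = "entries",
) -> FixedModelFit:
    """Cross-validated weighted-sum fit of model RDMs to a target RDM.

    ``fold_unit='entries'`` (default) partitions the condensed
    dissimilarities into 5 disjoint, exhaustive folds; ``'stimuli'``
    partitions the stimuli instead.  Model RDMs should be normalized to
    [0, 1] before fitting.
    """
    for m in model_rdms:
        _check_aligned(m, target_rdm)
    X = np.column_stack([m.upper() for m in model_rdms])
    y = target_rdm.upper()
    rng = substream(seed, "fixed-model-folds")
    if fold_unit == "entries":
        weights, intercepts, fold_rhos = _cv_fit(X, y, n_folds, rng)
    elif fold_unit == "stimuli":
        k = X.shape[1]
        pairs = _stimulus_fold_entries(target_rdm.n, n_folds, rng)
        weights = np.empty((n_folds, k))
        intercepts = np.empty(n_folds)
        fold_rhos = np.empty(n_folds)
        for i, (train, test) in enumerate(pairs):
            if test.size < 10:
                raise ValueError("cross-validation folds must hold >= 10 dissimilarities")
            A = np.column_stack([X[train], np.ones(train.size)])
            coef, *_ = np.linalg.lstsq(A, y[train], rcond=None)
            weights[i] = coef[:k]
            intercepts[i] = coef[k]
            fold_rhos[i] = _spearman(X[test] @ coef[:k] + coef[k], y[test])
    else:
        raise ValueError("fold_unit must be 'entries' or 'stimuli'")
    return FixedModelFit(weights, intercepts, fold_rhos, float(fold_rhos.mean()))


# ---------------------------------------------------------------------------
# Stimulus bootstrap


def _boot_entries(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the resampled condensed entries, same-same pairs dropped."""
    idx = rng.integers(0, n, size=n)
    iu, ju = np.triu_indices(n, k=1)
    bi, bj = idx[iu], idx[ju]
    keep = bi != bj
    return bi[keep], bj[keep]


def bootstrap_fit(
    model_rdms: Sequence[RDM],
    target_rdm: RDM,
    n_boot: int = 1000,
    seed: int = 0,
    n_folds: int = 5,
) -> BootstrapResult:
    """Bootstrap (over stimuli) of the cross-validated fixed-model rho."""
    for m in model_rdms:
        _check_aligned(m, target_rdm)
    rng = substream(seed, "bootstrap-fit")
    mats = [m.matrix for m in model_rdms]
    tmat = target_rdm.matrix
    n = target_rdm.n
    rhos = np.empty(n_boot)
    for b in range(n_boot):
        bi, bj = _boot_entries(n, rng)
        X = np.column_stack([m[bi, bj] for m in mats])
        y = tmat[bi, bj]
        _, _, fold_rhos = _cv_fit(X, y, n_folds, rng)
        rhos[b] = fold_rhos.mean()
    return BootstrapResult(rhos, float(rhos.std()))


def bootstrap_spearman(
    a: RDM, b: RDM, n_boot: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Bootstrap (over stimuli) of the Spearman correlation of two RDMs."""
    _check_aligned(a, b)
    rng = substream(seed, "bootstrap-spearman")
    rhos = np.empty(n_boot)
    for k in range(n_boot):
        bi, bj = _boot_entries(a.n, rng)
        rhos[k] = _spearman(a.matrix[bi, bj], b.matrix[bi, bj])
    return BootstrapResult(rhos, float(rhos.std()))


def noise_estimate(
    subject_rdms: Sequence[RDM], n_boot: int = 1000, seed: int = 0
) -> NoiseEstimate:
    """Inter-subject RDM correlation and its stimulus-bootstrap SE."""
    if len(subject_rdms) != 2:
        raise ValueError("noise estimation expects exactly two subject RDMs")
    s1, s2 = subject_rdms
    rho = spearman_rdm(s1, s2)
    boot = bootstrap_spearman(s1, s2, n_boot=n_boot, seed=seed)
    return NoiseEstimate(rho, boot.se)


# ---------------------------------------------------------------------------
# Persistence


def save_rdm_hdf5(rdm: RDM, path: str | Path, name: str = "rdm") -> None:
    import h5py

    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        grp = f.create_group(name)
        grp.create_dataset("matrix", data=rdm.matrix)
        grp.create_dataset(
            "stimulus_ids", data=np.array(rdm.stimulus_ids, dtype="S")
        )


def load_rdm_hdf5(path: str | Path, name: str = "rdm") -> RDM:
    import h5py

    with h5py.File(path, "r") as f:
        grp = f[name]
        mat = grp["matrix"][()]
        ids = tuple(s.decode() for s in grp["stimulus_ids"][()])
    return RDM(mat, ids)
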