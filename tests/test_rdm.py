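"""RDM construction, normalization, fixed-model fusion, bootstrap, noise ceiling."""
import numpy as np
import pytest
from scipy.stats import rankdata

from prefilt._util import substream
from prefilt.rdm import (
    RDM,
    bootstrap_fit,
    bootstrap_spearman,
    compute_rdm,
    fit_fixed_model,
    load_rdm_hdf5,
    mean_rdm,
    noise_estimate,
    normalize_rdm,
    save_rdm_hdf5,
    spearman_rdm,
)


def random_model_rdms(n, k=4, dim=30, seed=0):
    rng = substream(seed, "rdm-test-models")
    ids = tuple(f"s{i:03d}" for i in range(n))
    return [
        normalize_rdm(compute_rdm(rng.standard_normal((n, dim)), ids)) for _ in range(k)
    ], ids


class TestComputeRdm:
    def test_perfectly_correlated_rows_give_zero(self):
        v = np.array([[1, 2, 3], [2, 4, 6], [1, 1, 2]], dtype=float)
        rdm = compute_rdm(v)
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_give_two(self):
        v = np.array([[1, 2, 3], [3, 2, 1], [1, 1, 2]], dtype=float)
        assert compute_rdm(v).matrix[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_full_matrix_matches_hand_pearson(self):
        rows = np.array([[0.1, 0.5, 0.9], [0.2, 0.1, 0.7], [0.9, 0.3, 0.2]])

        def pearson(a, b):
            a, b = a - a.mean(), b - b.mean()
            return (a @ b) / np.sqrt((a @ a) * (b @ b))

        rdm = compute_rdm(rows)
        for i in range(3):
            for j in range(3):
                want = 0.0 if i == j else 1 - pearson(rows[i], rows[j])
                assert rdm.matrix[i, j] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_row_names_the_stimulus(self):
        v = np.array([[1, 2, 3], [5, 5, 5], [1, 1, 2]], dtype=float)
        with pytest.raises(ValueError, match="s0001"):
            compute_rdm(v)

    def test_too_few_rows_raise(self):
        with pytest.raises(ValueError, match="at least 3"):
            compute_rdm(np.array([[1, 2.0, 1], [2, 3, 5.0]]))


class TestNormalizeRdm:
    def _rdm_from_upper(self, vals):
        n = 3
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = vals
        m = m + m.T
        return RDM(m, ("a", "b", "c"))

    def test_hand_min_max(self):
        out = normalize_rdm(self._rdm_from_upper([0.2, 0.4, 1.0]))
        iu = np.triu_indices(3, 1)
        assert np.allclose(out.matrix[iu], [0.0, 0.25, 1.0])

    def test_idempotent_when_already_01(self):
        rdm = self._rdm_from_upper([0.0, 0.5, 1.0])
        out = normalize_rdm(rdm)
        assert np.allclose(out.matrix, rdm.matrix)

    def test_output_range_exact(self, rng):
        v = rng.random((8, 12))
        out = normalize_rdm(compute_rdm(v))
        tri = out.upper()
        assert tri.min() == 0.0 and tri.max() == 1.0
        assert np.allclose(np.diag(out.matrix), 0.0)

    def test_constant_offdiagonal_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_rdm(self._rdm_from_upper([0.4, 0.4, 0.4]))


class TestSpearmanRdm:
    def test_identity_is_one(self, rng):
        a = compute_rdm(rng.random((6, 10)))
        assert spearman_rdm(a, a) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        a = compute_rdm(rng.random((6, 10)))
        b = RDM(np.sqrt(a.matrix + 1.0) - 1.0, a.stimulus_ids)  # monotone, keeps 0 diag
        # restore exact zero diagonal lost to fp
        assert spearman_rdm(a, b) == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        a = compute_rdm(rng.random((4, 9)))
        b = compute_rdm(rng.random((4, 9)))
        ra, rb = rankdata(a.upper()), rankdata(b.upper())
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert spearman_rdm(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_and_order_invariant(self, rng):
        a = compute_rdm(rng.random((7, 10)))
        b = compute_rdm(rng.random((7, 10)))
        assert spearman_rdm(a, b) == pytest.approx(spearman_rdm(b, a))
        perm = np.array([3, 1, 0, 6, 2, 5, 4])
        ids = tuple(a.stimulus_ids[i] for i in perm)
        ap = RDM(a.matrix[np.ix_(perm, perm)], ids)
        bp = RDM(b.matrix[np.ix_(perm, perm)], ids)
        assert spearman_rdm(ap, bp) == pytest.approx(spearman_rdm(a, b), abs=1e-12)

    def test_misaligned_ids_raise(self, rng):
        a = compute_rdm(rng.random((4, 9)))
        b = RDM(a.matrix.copy(), ("w", "x", "y", "z"))
        with pytest.raises(ValueError, match="aligned"):
            spearman_rdm(a, b)


class TestFixedModelFit:
    def test_exact_weighted_sum_recovery(self):
        models, ids = random_model_rdms(50, seed=3)
        w = np.array([0.4, 0.3, 0.2, 0.1])
        target = RDM(sum(wi * m.matrix for wi, m in zip(w, models)), ids)
        fit = fit_fixed_model(models, target, seed=0)
        assert fit.rho >= 0.99
        assert np.abs(fit.mean_weights - w).max() < 1e-6
        assert fit.rho == pytest.approx(fit.fold_rhos.mean())

    def test_dominant_weight_for_single_informative_model(self):
        models, ids = random_model_rdms(40, seed=4)
        rng = substream(4, "jitter")
        # three near-constant models + one informative
        flat = []
        for m in models[:3]:
            mat = 0.5 + 0.01 * (m.matrix - 0.5)
            np.fill_diagonal(mat, 0.0)
            flat.append(RDM(mat, ids))
        informative = models[3]
        target = RDM(informative.matrix * 0.8, ids)
        fit = fit_fixed_model(flat + [informative], target, seed=1)
        w = np.abs(fit.mean_weights)
        assert w[3] > 3 * w[:3].max()

    def test_random_target_rho_near_zero(self):
        models, ids = random_model_rdms(40, seed=5)
        rng = substream(5, "null-target")
        rhos = [
            fit_fixed_model(
                models, compute_rdm(rng.standard_normal((40, 30)), ids), seed=s
            ).rho
            for s in range(20)
        ]
        assert abs(np.mean(rhos)) < 0.08

    def test_fold_seed_stability(self):
        models, ids = random_model_rdms(40, seed=6)
        rng = substream(6, "noisy-target")
        target_mat = sum(0.25 * m.matrix for m in models)
        noise = rng.standard_normal(target_mat.shape) * 0.05
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        target = RDM(target_mat + noise, ids)
        fit_a = fit_fixed_model(models, target, seed=1)
        fit_b = fit_fixed_model(models, target, seed=2)
        se = bootstrap_fit(models, target, n_boot=200, seed=0).se
        assert not np.allclose(fit_a.fold_rhos, fit_b.fold_rhos)
        assert abs(fit_a.rho - fit_b.rho) < se

    def test_stimulus_fold_unit_supported(self):
        models, ids = random_model_rdms(30, seed=7)
        target = RDM(sum(0.25 * m.matrix for m in models), ids)
        fit = fit_fixed_model(models, target, seed=0, fold_unit="stimuli")
        assert fit.rho > 0.95

    def test_small_folds_raise(self):
        models, ids = random_model_rdms(8, seed=8)
        target = models[0]
        with pytest.raises(ValueError, match=">= 10"):
            fit_fixed_model(models, target, n_folds=5, seed=0)


class TestBootstrap:
    def test_zero_noise_target_has_tiny_se(self):
        models, ids = random_model_rdms(30, seed=9)
        target = RDM(sum(0.25 * m.matrix for m in models), ids)
        boot = bootstrap_fit(models, target, n_boot=100, seed=0)
        assert boot.se < 0.01

    def test_se_decreases_with_n(self):
        ses = {}
        for n in (30, 120):
            rng = substream(n, "se-scaling")
            latent = rng.standard_normal((n, 20))
            a = compute_rdm(latent + 0.5 * rng.standard_normal(latent.shape))
            b = compute_rdm(latent + 0.5 * rng.standard_normal(latent.shape))
            ses[n] = bootstrap_spearman(a, b, n_boot=200, seed=0).se
        assert ses[120] < ses[30]

    def test_fixed_seed_reproducible(self):
        models, ids = random_model_rdms(30, seed=10)
        target = models[0]
        a = bootstrap_fit(models, target, n_boot=50, seed=3)
        b = bootstrap_fit(models, target, n_boot=50, seed=3)
        assert np.array_equal(a.rhos, b.rhos)


class TestNoiseEstimate:
    def test_identical_subjects_give_one(self, rng):
        a = compute_rdm(rng.random((15, 10)))
        est = noise_estimate([a, a], n_boot=50, seed=0)
        assert est.rho_noise == pytest.approx(1.0)

    def test_independent_rdms_near_zero(self):
        rng = substream(20, "independent")
        a = compute_rdm(rng.standard_normal((50, 30)))
        b = compute_rdm(rng.standard_normal((50, 30)))
        est = noise_estimate([a, b], n_boot=50, seed=0)
        assert abs(est.rho_noise) < 0.2

    def test_monotone_recovery_with_noise_level(self):
        rng = substream(21, "monotone")
        latent = rng.standard_normal((30, 20))
        rhos = []
        for sd in (1.5, 0.6, 0.1):
            a = compute_rdm(latent + sd * rng.standard_normal(latent.shape))
            b = compute_rdm(latent + sd * rng.standard_normal(latent.shape))
            rhos.append(noise_estimate([a, b], n_boot=10, seed=0).rho_noise)
        assert rhos[0] < rhos[1] < rhos[2]


class TestAveragingAndIO:
    def test_mean_rdm_entrywise(self, rng):
        a = compute_rdm(rng.random((5, 8)))
        b = compute_rdm(rng.random((5, 8)))
        m = mean_rdm([a, b])
        assert np.allclose(m.matrix, (a.matrix + b.matrix) / 2)

    def test_hdf5_roundtrip(self, tmp_path, rng):
        rdm = compute_rdm(rng.random((6, 10)))
        save_rdm_hdf5(rdm, tmp_path / "r.h5", name="test")
        back = load_rdm_hdf5(tmp_path / "r.h5", name="test")
        assert back.stimulus_ids == rdm.stimulus_ids
        assert np.allclose(back.matrix, rdm.matrix)
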