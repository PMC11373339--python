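"""Contracts and oracles for the eleven comparison imputers."""

import numpy as np
import pytest

from pepimpute.baselines import (
    REGISTRY,
    get_imputer,
    impute_bpca,
    impute_cf,
    impute_dae,
    impute_isvd,
    impute_knn,
    impute_median,
    impute_mice_ridge,
    impute_mindet,
    impute_minprob,
    impute_rf,
    run_imputer,
)
from pepimpute.datamodel import DataError

FAST_PARAMS = {
    "RF": {"trees": 10, "max_iter": 3},
    "DAE": {"epochs": 60},
    "VAE": {"epochs": 60},
    "CF": {"epochs": 120},
    "BPCA": {"max_iter": 60},
    "MICE": {"iters": 4},
}


def masked_matrix(rng, n=30, s=6, miss=0.2):
    A = rng.normal(size=(n, s))
    mask = rng.random((n, s)) < miss
    mask[:, 0] = False  # keep one fully observed column
    A[mask] = np.nan
    return A


@pytest.mark.parametrize("name", sorted(REGISTRY))
def test_common_contract(name, rng):
    """Observed entries bit-identical, no missing output, seeded determinism."""
    A = masked_matrix(rng)
    params = FAST_PARAMS.get(name, {})
    out1 = run_imputer(name, A, seed=11, **params)
    out2 = run_imputer(name, A, seed=11, **params)
    obs = np.isfinite(A)
    assert not np.isnan(out1).any()
    np.testing.assert_array_equal(out1[obs], A[obs])
    np.testing.assert_array_equal(out1, out2)


@pytest.mark.parametrize("name", ["Median", "MinDet", "KNN", "ISVD", "BPCA"])
def test_no_missing_is_identity(name, rng):
    A = rng.normal(size=(15, 5))
    out = run_imputer(name, A, seed=0, **FAST_PARAMS.get(name, {}))
    np.testing.assert_array_equal(out, A)


class TestMinDet:
    def test_quantile_convention(self):
        # column with observed values 1..100, q=0.01 -> linear-interpolation
        # quantile 1.99
        col2 = np.concatenate([[np.nan], np.arange(1.0, 101.0)])
        col1 = np.arange(1.0, 102.0)
        A = np.column_stack([col1, col2])
        out = impute_mindet(A, q=0.01)
        assert out[0, 1] == pytest.approx(1.99)

    def test_single_observed_value(self):
        A = np.array([[5.0, 1.0], [np.nan, 2.0]])
        assert impute_mindet(A)[1, 0] == pytest.approx(5.0)

    def test_all_missing_column_errors(self):
        with pytest.raises(DataError):
            impute_mindet(np.array([[np.nan, 1.0], [np.nan, 2.0]]))

    def test_fill_not_above_column_quantile(self, rng):
        A = masked_matrix(rng)
        out = impute_mindet(A, q=0.01)
        for j in range(A.shape[1]):
            fillers = out[~np.isfinite(A[:, j]), j]
            if fillers.size:
                assert (fillers <= np.nanquantile(A[:, j], 0.01) + 1e-12).all()


class TestMinProb:
    def test_zero_spread_equals_mindet(self, rng):
        A = masked_matrix(rng)
        np.testing.assert_allclose(impute_minprob(A, sd_scale=0.0, seed=1), impute_mindet(A))

    def test_monte_carlo_mean(self):
        col = np.arange(1.0, 101.0)
        A = np.column_stack([col, np.full(100, np.nan)])
        A[:, 1][:2] = [50.0, 60.0]
        big = np.tile(A, (100, 1))  # 9800 missing entries in column 2
        out = impute_minprob(big, q=0.01, sd_scale=0.5, seed=3)
        fills = out[~np.isfinite(big[:, 1]), 1]
        center = np.nanquantile(big[:, 1], 0.01)
        sd = 0.5 * np.nanstd(big[:, 1], ddof=1)
        se = sd / np.sqrt(fills.size)
        assert abs(fills.mean() - center) < 3 * se


class TestMedian:
    def test_row_median_and_fallback(self):
        A = np.array([[1.0, 2.0, np.nan], [np.nan, np.nan, np.nan], [0.3, 0.3, 0.3]])
        out = impute_median(A)
        assert out[0, 2] == pytest.approx(1.5)
        assert out[1, 0] == pytest.approx(np.nanmedian(A))  # global-median fallback

    def test_brute_force_oracle(self, rng):
        A = masked_matrix(rng, n=20)
        out = impute_median(A)
        gm = np.nanmedian(A)
        for i in range(A.shape[0]):
            row = A[i][np.isfinite(A[i])]
            expect = np.median(row) if row.size else gm
            for j in np.where(~np.isfinite(A[i]))[0]:
                assert out[i, j] == pytest.approx(expect)

    def test_row_permutation_equivariance(self, rng):
        A = masked_matrix(rng, n=12)
        perm = rng.permutation(12)
        np.testing.assert_array_equal(impute_median(A[perm]), impute_median(A)[perm])


def knn_brute_force(A, k):
    """Literal reimplementation of the documented KNN donor rule."""
    n, s = A.shape
    obs = np.isfinite(A)
    gm = np.nanmedian(A)
    out = A.copy()
    for i in range(n):
        if obs[i].all():
            continue
        dists = []
        for j in range(n):
            if j == i:
                continue
            co = obs[i] & obs[j]
            if co.any():
                d = np.sqrt((s / co.sum()) * np.sum((A[i, co] - A[j, co]) ** 2))
                dists.append((d, j))
        dists.sort(key=lambda t: (t[0], t[1]))
        neigh = [j for _, j in dists[:k]]
        row_vals = A[i][obs[i]]
        row_med = np.median(row_vals) if row_vals.size else gm
        for c in np.where(~obs[i])[0]:
            donors = [A[j, c] for j in neigh if obs[j, c]]
            out[i, c] = np.mean(donors) if donors else row_med
    return out


class TestKNN:
    def test_single_neighbor_copies_value(self):
        A = np.array([[1.0, 2.0, np.nan], [1.0, 2.0, 9.0], [50.0, 60.0, 70.0], [51.0, 61.0, 71.0]])
        out = impute_knn(A, k=1)
        assert out[0, 2] == pytest.approx(9.0)

    def test_complementary_duplicates_reconstruct(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        a = base.copy()
        a[2] = np.nan
        b = base.copy()
        b[1] = np.nan
        A = np.vstack([a, b, base + 40, base + 41])
        out = impute_knn(A, k=1)
        assert out[0, 2] == pytest.approx(3.0)
        assert out[1, 1] == pytest.approx(2.0)

    def test_brute_force_oracle(self, rng):
        for trial in range(5):
            A = masked_matrix(np.random.default_rng(trial), n=15, s=5, miss=0.3)
            np.testing.assert_allclose(impute_knn(A, k=4), knn_brute_force(A, 4), atol=1e-12)

    def test_column_permutation_equivariance(self, rng):
        A = masked_matrix(rng, n=25)
        perm = rng.permutation(A.shape[1])
        np.testing.assert_allclose(impute_knn(A, k=3)[:, perm], impute_knn(A[:, perm], k=3))

    def test_k_validation(self, rng):
        with pytest.raises(DataError):
            impute_knn(masked_matrix(rng), k=0)


class TestMICE:
    def test_collinear_recovery(self, rng):
        x = rng.normal(size=60)
        A = np.column_stack([x, 2 * x, x + 1.0])
        A[5, 1] = np.nan
        out = impute_mice_ridge(A, iters=15, seed=0)
        assert out[5, 1] == pytest.approx(2 * x[5], abs=1e-3)

    def test_needs_three_columns(self, rng):
        with pytest.raises(DataError):
            impute_mice_ridge(rng.normal(size=(10, 2)))


class TestRF:
    def test_step_function_recovery(self, rng):
        x = rng.uniform(-1, 1, size=150)
        y = np.where(x > 0, 3.0, -3.0) + rng.normal(0, 0.1, size=150)
        A = np.column_stack([x, y, rng.normal(size=150)])
        miss = rng.choice(150, size=20, replace=False)
        truth = A[miss, 1].copy()
        A[miss, 1] = np.nan
        out = impute_rf(A, trees=30, max_iter=5, seed=2)
        assert np.sqrt(np.mean((out[miss, 1] - truth) ** 2)) < 1.0


class TestISVD:
    def test_rank1_recovery(self, rng):
        u = rng.normal(size=40)
        v = rng.normal(size=8)
        A = np.outer(u, v)
        mask = rng.random(A.shape) < 0.1
        truth = A.copy()
        A[mask] = np.nan
        out = impute_isvd(A, rank=1, tol=1e-10, max_iter=500)
        assert np.abs(out[mask] - truth[mask]).max() < 1e-6

    def test_rank_validation(self, rng):
        with pytest.raises(DataError):
            impute_isvd(masked_matrix(rng, n=10, s=4), rank=4)


class TestBPCA:
    def test_low_rank_beats_median(self, rng):
        n, s, r = 80, 10, 2
        W = rng.normal(size=(s, r))
        Z = rng.normal(size=(n, r))
        A = Z @ W.T + rng.normal(0, 0.1, size=(n, s))
        mask = rng.random(A.shape) < 0.2
        truth = A.copy()
        A[mask] = np.nan
        out_b = impute_bpca(A, seed=0)
        out_m = impute_median(A)
        rmse_b = np.sqrt(np.mean((out_b[mask] - truth[mask]) ** 2))
        rmse_m = np.sqrt(np.mean((out_m[mask] - truth[mask]) ** 2))
        assert rmse_b < rmse_m

    def test_ard_prunes_pure_noise(self, rng):
        A = rng.normal(size=(50, 10))
        A[rng.random(A.shape) < 0.1] = np.nan
        _, model = impute_bpca(A, seed=0, return_model=True)
        assert model.n_effective_components_ <= 2


class TestDeepBaselines:
    def test_cf_recovers_rank1(self, rng):
        u = rng.normal(size=50)
        v = rng.normal(size=8)
        A = np.outer(u, v) * 0.3
        mask = rng.random(A.shape) < 0.15
        truth = A.copy()
        A[mask] = np.nan
        out = impute_cf(A, dim=4, epochs=800, lr=0.05, seed=1)
        assert np.sqrt(np.mean((out[mask] - truth[mask]) ** 2)) < 0.1

    def test_dae_uses_duplicate_rows(self, rng):
        base = rng.normal(size=(12, 6))
        A = np.vstack([base, base, base, base])
        mask = np.zeros_like(A, dtype=bool)
        mask[0, 2] = mask[13, 4] = True
        truth = A.copy()
        A[mask] = np.nan
        out = impute_dae(A, epochs=400, seed=0)
        # duplicates of the masked rows are fully observed, so the masked
        # cells are recoverable much better than by a constant fill
        assert np.abs(out[mask] - truth[mask]).mean() < np.abs(truth[mask]).mean()


def test_registry_lookup():
    assert get_imputer("median")[0] == "Median"
    assert get_imputer("KNN")[0] == "KNN"
    with pytest.raises(DataError):
        get_imputer("nope")
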