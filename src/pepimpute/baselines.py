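"""Classical and deep-learning comparison imputers behind one interface.

Every imputer maps a standardized-log matrix with NaN entries to a
completed matrix.  Contracts shared by all methods: observed entries are
bit-identical between input and output, the output has no missing
entries, and stochastic methods are deterministic given their seed.

Single-value methods: MinDet, MinProb, Median.
Local-similarity methods: KNN, MICE (Bayesian ridge), RF (missForest-style).
Global-structure methods: ISVD, BPCA, DAE, VAE, CF.

MICE and RF delegate to scikit-learn's IterativeImputer; the deep methods
(DAE, VAE, CF) are compact reference implementations on the package's
autodiff engine rather than replications of any specific published
architecture.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from . import autograd as ag
from .datamodel import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "REGISTRY",
    "get_imputer",
    "impute_mindet",
    "impute_minprob",
    "impute_median",
    "impute_knn",
    "impute_mice_ridge",
    "impute_rf",
    "impute_isvd",
    "impute_bpca",
    "impute_dae",
    "impute_vae",
    "impute_cf",
]


def _check(A: np.ndarray) -> tuple:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise DataError("expected a 2-D matrix")
    obs = np.isfinite(A)
    if not obs.any():
        raise DataError("all values are missing")
    return A, obs


def _finalize(A: np.ndarray, obs: np.ndarray, filled: np.ndarray) -> np.ndarray:
    out = np.asarray(filled, dtype=float).copy()
    out[obs] = A[obs]  # observed values pass through bit-identically
    if np.isnan(out).any():
        raise DataError("imputer left missing values")
    return out


# ---------------------------------------------------------------------------
# Single-value methods


def impute_mindet(A, q: float = 0.01) -> np.ndarray:
    """Fill each sample column's missing entries with its q-quantile of
    observed values (linear-interpolation quantile convention)."""
    A, obs = _check(A)
    if (obs.sum(axis=0) == 0).any():
        raise DataError("column with no observed values")
    fill = np.nanquantile(A, q, axis=0)
    out = np.where(obs, A, fill[None, :])
    return _finalize(A, obs, out)


def impute_minprob(A, q: float = 0.01, sd_scale: float = 0.01, seed: int = 0) -> np.ndarray:
    """Draw each missing entry from Normal(q-quantile of its column,
    (sd_scale * column sd)^2); zero-sd columns fall back to MinDet."""
    A, obs = _check(A)
    if (obs.sum(axis=0) == 0).any():
        raise DataError("column with no observed values")
    rng = np.random.default_rng(seed)
    centers = np.nanquantile(A, q, axis=0)
    out = A.copy()
    for j in range(A.shape[1]):
        miss = ~obs[:, j]
        if not miss.any():
            continue
        col = A[obs[:, j], j]
        sd = float(np.std(col, ddof=1)) if col.size > 1 else 0.0
        if sd > 0:
            out[miss, j] = rng.normal(centers[j], sd_scale * sd, size=miss.sum())
        else:
            logger.info("MinProb: zero-sd column %d, falling back to MinDet", j)
            out[miss, j] = centers[j]
    return _finalize(A, obs, out)


def impute_median(A) -> np.ndarray:
    """Peptide-wise (row) median of observed values; all-missing rows fall
    back to the global median of all observed entries."""
    A, obs = _check(A)
    global_med = float(np.nanmedian(A))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        row_med = np.nanmedian(A, axis=1)
    row_med = np.where(np.isfinite(row_med), row_med, global_med)
    out = np.where(obs, A, row_med[:, None])
    return _finalize(A, obs, out)


# ---------------------------------------------------------------------------
# Local-similarity methods


def impute_knn(A, k: int = 10) -> np.ndarray:
    """k-nearest-rows imputation.

    Distance between rows i and j is the Euclidean distance over their
    co-observed columns scaled by sqrt(s / #co-observed); each missing
    cell is the mean of the neighbor values observed in that column, with
    row-median (then global-median) fallback for unresolvable cells.
    """
    A, obs = _check(A)
    if k < 1:
        raise DataError("k must be >= 1")
    n, s = A.shape
    global_med = float(np.nanmedian(A))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_med = np.nanmedian(A, axis=1)
    row_med = np.where(np.isfinite(row_med), row_med, global_med)

    Z = np.where(obs, A, 0.0)
    O = obs.astype(float)
    # pairwise squared distance over co-observed columns, vectorized:
    # sum_c o_ic o_jc (a_ic - a_jc)^2, then scaled by s / co-count
    sq = Z**2
    co = O @ O.T
    d2 = (sq * O) @ O.T + O @ (sq * O).T - 2.0 * Z @ Z.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(co > 0, d2 * (s / co), np.inf)
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)

    out = A.copy()
    for i in range(n):
        miss_cols = np.where(~obs[i])[0]
        if miss_cols.size == 0:
            continue
        order = np.argsort(d2[i], kind="stable")
        neigh = [j for j in order[: k] if np.isfinite(d2[i, j])]
        for c in miss_cols:
            vals = [A[j, c] for j in neigh if obs[j, c]]
            out[i, c] = float(np.mean(vals)) if vals else row_med[i]
    return _finalize(A, obs, out)


def impute_mice_ridge(A, iters: int = 10, seed: int = 0) -> np.ndarray:
    """Chained equations over sample columns with Bayesian ridge
    regressions (single-imputation variant, posterior predictive means)."""
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import BayesianRidge

    A, obs = _check(A)
    if A.shape[1] < 3:
        raise DataError("MICE needs >= 3 sample columns")
    imp = IterativeImputer(
        estimator=BayesianRidge(),
        max_iter=iters,
        sample_posterior=False,
        initial_strategy="mean",
        random_state=seed,
        tol=1e-4,
        keep_empty_features=True,
    )
    return _finalize(A, obs, imp.fit_transform(A))


def impute_rf(A, trees: int = 100, max_iter: int = 10, tol: float = 1e-3, seed: int = 0) -> np.ndarray:
    """missForest-style imputation: iterated random-forest regressions per
    column, columns processed in increasing-missingness order."""
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    A, obs = _check(A)
    est = RandomForestRegressor(n_estimators=trees, random_state=seed, n_jobs=1)
    imp = IterativeImputer(
        estimator=est,
        max_iter=max_iter,
        tol=tol,
        initial_strategy="mean",
        imputation_order="ascending",
        random_state=seed,
        keep_empty_features=True,
    )
    return _finalize(A, obs, imp.fit_transform(A))


# ---------------------------------------------------------------------------
# Global-structure methods


def impute_isvd(A, rank: int | None = None, tol: float = 1e-4, max_iter: int = 100) -> np.ndarray:
    """Iterative SVD: refill missing entries from the rank-r reconstruction
    until the relative Frobenius change of the completed matrix < tol."""
    A, obs = _check(A)
    n, s = A.shape
    if rank is None:
        rank = max(1, min(n, s) // 2)
    if rank > min(n, s) - 1:
        raise DataError(f"rank {rank} too large for a {n} x {s} matrix")
    with np.errstate(all="ignore"):
        row_mean = np.nanmean(A, axis=1)
    row_mean = np.where(np.isfinite(row_mean), row_mean, float(np.nanmean(A)))
    X = np.where(obs, A, row_mean[:, None])
    prev_change = np.inf
    for _ in range(max_iter):
        U, svals, Vt = np.linalg.svd(X, full_matrices=False)
        recon = (U[:, :rank] * svals[:rank]) @ Vt[:rank]
        X_new = np.where(obs, A, recon)
        denom = np.linalg.norm(X) or 1.0
        change = np.linalg.norm(X_new - X) / denom
        X = X_new
        if change < tol:
            break
        prev_change = change
    else:
        logger.warning("ISVD did not converge in %d iterations (last change %.2e)", max_iter, prev_change)
    return _finalize(A, obs, X)


class _BPCA:
    """Variational PCA with automatic relevance determination (ARD).

    Rows are observations of dimension s.  Latent factors whose loading
    norms the ARD prior drives to zero are effectively pruned, so the
    model chooses its own rank.  Missing entries are filled with the
    posterior predictive mean at convergence.
    """

    def __init__(self, n_components=None, max_iter=200, rtol=1e-5, seed=0):
        self.q = n_components
        self.max_iter = max_iter
        self.rtol = rtol
        self.seed = seed

    def fit_transform(self, A, obs):
        n, d = A.shape
        q = self.q if self.q is not None else d - 1
        if not 1 <= q <= d - 1:
            raise DataError(f"n_components must be in [1, {d - 1}]")
        rng = np.random.default_rng(self.seed)
        with np.errstate(all="ignore"):
            col_mean = np.nanmean(A, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, float(np.nanmean(A)))
        X = np.where(obs, A, col_mean[None, :])
        mu = X.mean(axis=0)
        Xc = X - mu
        U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
        W = Vt[:q].T * (svals[:q] / np.sqrt(n))  # (d, q)
        resid = Xc - (U[:, :q] * svals[:q]) @ Vt[:q]
        tau = 1.0 / max(resid.var(), 1e-6)
        alpha = np.full(q, 1.0)

        # rows grouped by missingness pattern share the posterior algebra
        patterns: dict = {}
        for i in range(n):
            patterns.setdefault(obs[i].tobytes(), []).append(i)

        for _ in range(self.max_iter):
            W_old, X_old = W.copy(), X.copy()
            M = np.zeros((n, q))
            C_sum = np.zeros((q, q))
            for key, rows in patterns.items():
                o = np.frombuffer(key, dtype=bool)
                Wo = W[o]
                C = np.linalg.inv(np.eye(q) + tau * Wo.T @ Wo)
                Yo = X[np.ix_(rows, np.where(o)[0])] - mu[o]
                M[rows] = tau * Yo @ Wo @ C
                C_sum += len(rows) * C
                if not o.all():
                    X[np.ix_(rows, np.where(~o)[0])] = mu[~o] + M[rows] @ W[~o].T
            Xc = X - mu
            G = M.T @ M + C_sum + np.diag(alpha) / tau
            W = np.linalg.solve(G.T, (Xc.T @ M).T).T
            err = Xc - M @ W.T
            tau = n * d / max(
                float((err**2).sum() + np.trace(W.T @ W @ C_sum)), 1e-12
            )
            alpha = d / (np.sum(W**2, axis=0) + 1e-10)
            mu = X.mean(axis=0)
            dW = np.linalg.norm(W - W_old) / (np.linalg.norm(W_old) + 1e-12)
            dX = np.linalg.norm(X - X_old) / (np.linalg.norm(X_old) + 1e-12)
            if max(dW, dX) < self.rtol:
                break
        else:
            logger.warning("BPCA did not converge in %d iterations", self.max_iter)
        self.W_, self.alpha_, self.tau_ = W, alpha, tau
        norms = np.sum(W**2, axis=0)
        self.n_effective_components_ = int(np.sum(norms > 0.05 * norms.max())) if norms.max() > 0 else 0
        return X


def impute_bpca(A, n_components: int | None = None, max_iter: int = 200, seed: int = 0, return_model: bool = False):
    """Bayesian PCA imputation (variational, ARD-pruned rank)."""
    A, obs = _check(A)
    model = _BPCA(n_components=n_components, max_iter=max_iter, seed=seed)
    out = _finalize(A, obs, model.fit_transform(A, obs))
    return (out, model) if return_model else out


# ---------------------------------------------------------------------------
# Deep methods on the autodiff engine


def _affine_params(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return ag.parameter(rng.uniform(-limit, limit, size=(fan_in, fan_out))), ag.parameter(np.zeros(fan_out))


def _mse_on(pred, target_vals, flat_idx):
    diff = ag.sub(ag.take_flat(pred, flat_idx), ag.constant(target_vals))
    return ag.mean_all(ag.square(diff))


def impute_dae(A, hidden: int = 64, epochs: int = 300, lr: float = 1e-2, mask_frac: float = 0.2, seed: int = 0) -> np.ndarray:
    """Denoising autoencoder over peptide rows.

    Input per row: zero-filled abundance vector plus observed-indicator
    channel.  Each epoch corrupts a random fraction of observed entries
    and minimizes MSE on all observed entries (full batch).
    """
    A, obs = _check(A)
    n, s = A.shape
    rng = np.random.default_rng(seed)
    W1, b1 = _affine_params(rng, 2 * s, hidden)
    W2, b2 = _affine_params(rng, hidden, s)
    params = [W1, b1, W2, b2]
    opt = ag.Adam(params, lr=lr)
    obs_flat = np.flatnonzero(obs.reshape(-1))
    targets = A.reshape(-1)[obs_flat]

    def forward(inp):
        h = ag.relu(ag.add(ag.matmul(ag.constant(inp), W1), b1))
        return ag.add(ag.matmul(h, W2), b2)

    for _ in range(epochs):
        corrupt = obs & (rng.random((n, s)) >= mask_frac)
        inp = np.concatenate([np.where(corrupt, A, 0.0), corrupt.astype(float)], axis=1)
        loss = _mse_on(forward(inp), targets, obs_flat)
        if not np.isfinite(loss.data):
            raise FloatingPointError("DAE training diverged")
        opt.zero_grad()
        loss.backward()
        opt.step()
    inp = np.concatenate([np.where(obs, A, 0.0), obs.astype(float)], axis=1)
    return _finalize(A, obs, forward(inp).data)


def impute_vae(A, hidden: int = 64, latent: int = 8, epochs: int = 300, lr: float = 1e-2, beta: float = 0.05, seed: int = 0) -> np.ndarray:
    """Variational autoencoder over peptide rows (KL-regularized latent);
    imputation uses the deterministic pass through the latent mean."""
    A, obs = _check(A)
    n, s = A.shape
    rng = np.random.default_rng(seed)
    We, be = _affine_params(rng, 2 * s, hidden)
    Wm, bm = _affine_params(rng, hidden, latent)
    Wv, bv = _affine_params(rng, hidden, latent)
    Wd, bd = _affine_params(rng, latent, hidden)
    Wo, bo = _affine_params(rng, hidden, s)
    params = [We, be, Wm, bm, Wv, bv, Wd, bd, Wo, bo]
    opt = ag.Adam(params, lr=lr)
    obs_flat = np.flatnonzero(obs.reshape(-1))
    targets = A.reshape(-1)[obs_flat]
    inp = np.concatenate([np.where(obs, A, 0.0), obs.astype(float)], axis=1)

    def encode():
        h = ag.relu(ag.add(ag.matmul(ag.constant(inp), We), be))
        return ag.add(ag.matmul(h, Wm), bm), ag.add(ag.matmul(h, Wv), bv)

    def decode(z):
        h = ag.relu(ag.add(ag.matmul(z, Wd), bd))
        return ag.add(ag.matmul(h, Wo), bo)

    for _ in range(epochs):
        zmu, zlogvar = encode()
        noise = ag.constant(rng.standard_normal((n, latent)))
        z = ag.add(zmu, ag.mul(ag.exp(ag.mul(zlogvar, ag.constant(0.5))), noise))
        recon = _mse_on(decode(z), targets, obs_flat)
        # KL(q || N(0,I)) = -0.5 * sum(1 + logvar - mu^2 - exp(logvar))
        kl_terms = ag.sub(
            ag.add(ag.square(zmu), ag.exp(zlogvar)),
            ag.add(zlogvar, ag.constant(np.ones((n, latent)))),
        )
        loss = ag.add(recon, ag.mul(ag.mean_all(kl_terms), ag.constant(0.5 * beta)))
        if not np.isfinite(loss.data):
            raise FloatingPointError("VAE training diverged")
        opt.zero_grad()
        loss.backward()
        opt.step()
    zmu, _ = encode()
    return _finalize(A, obs, decode(zmu).data)


def impute_cf(A, dim: int = 8, epochs: int = 500, lr: float = 0.05, seed: int = 0) -> np.ndarray:
    """Collaborative filtering: peptide and sample embeddings with biases,
    trained to regress observed entries; missing entries from the
    dot-product predictor."""
    A, obs = _check(A)
    n, s = A.shape
    rng = np.random.default_rng(seed)
    scale = 0.1
    P = ag.parameter(rng.normal(0, scale, size=(n, dim)))
    Q = ag.parameter(rng.normal(0, scale, size=(s, dim)))
    bp = ag.parameter(np.zeros((n, 1)))
    bq = ag.parameter(np.zeros((1, s)))
    g = ag.parameter(np.array([[float(np.nanmean(A))]]))
    params = [P, Q, bp, bq, g]
    opt = ag.Adam(params, lr=lr)
    obs_flat = np.flatnonzero(obs.reshape(-1))
    targets = A.reshape(-1)[obs_flat]

    def predict():
        return ag.add(ag.add(ag.matmul(P, ag.transpose(Q)), bp), ag.add(bq, g))

    for _ in range(epochs):
        loss = _mse_on(predict(), targets, obs_flat)
        if not np.isfinite(loss.data):
            raise FloatingPointError("CF training diverged")
        opt.zero_grad()
        loss.backward()
        opt.step()
    return _finalize(A, obs, predict().data)


# ---------------------------------------------------------------------------
# Registry

REGISTRY = {
    "MinDet": impute_mindet,
    "MinProb": impute_minprob,
    "Median": impute_median,
    "KNN": impute_knn,
    "MICE": impute_mice_ridge,
    "RF": impute_rf,
    "ISVD": impute_isvd,
    "BPCA": impute_bpca,
    "DAE": impute_dae,
    "VAE": impute_vae,
    "CF": impute_cf,
}

_SEEDED = {"MinProb", "MICE", "RF", "BPCA", "DAE", "VAE", "CF"}


def get_imputer(name: str):
    """Case-insensitive registry lookup -> (canonical name, callable)."""
    for canon, fn in REGISTRY.items():
        if canon.lower() == name.lower():
            return canon, fn
    raise DataError(f"unknown imputation method {name!r}; choose from {sorted(REGISTRY)}")


def run_imputer(name: str, A: np.ndarray, seed: int = 0, **params) -> np.ndarray:
    """Run a registered imputer, passing `seed` only where it applies."""
    canon, fn = get_imputer(name)
    if canon in _SEEDED:
        params.setdefault("seed", seed)
    return fn(A, **params)
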