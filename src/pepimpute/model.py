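"""Attention-GNN peptide imputer with per-value Gaussian uncertainty.

The network fuses three inputs per peptide: its abundance vector across
samples, a sequence embedding, and the peptide-peptide graph.

Pipeline (n peptides, s samples, d-dim embeddings):

1. sequence projection  f_seq : (n, d) -> (n, 16), affine + ReLU;
2. latent fusion        f_lat : (n, enc + 16) -> (n, 128), two affine
   layers with ReLU between (enc = s, or 2s with the observed-indicator
   channel on);
3. graph attention: one GATv2-style dynamic-attention layer over the
   peptide graph with H heads, each head emitting floor(s/2) dims,
   concatenated -> (n, H * floor(s/2)); a self-connection is added per
   node so isolated peptides attend to themselves;
4. skip connection: f_fin : (n, H*floor(s/2) + 128) -> (n, 128) on the
   concatenation of attention output and latent representation;
5. two heads: f_mu -> (n, s) predicted means and f_sigma2 -> (n, s)
   predicted variances (softplus + 1e-6), both on the standardized-log
   scale.

Training is self-supervised in two rounds: round one fits only the mean
head with MSE on freshly masked entries (a fraction gamma ~ U[0.05, 0.15)
of observed values per step, 500 steps per epoch by default); round two
continues from the best round-one weights with the Gaussian negative
log-likelihood over both heads.  Both rounds early-stop on the validation
MSE and restore the best weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .datamodel import DataError, MaskPlan, TransformState, inverse_transform
from .graph import PeptideGraph

__all__ = [
    "ModelConfig",
    "ImputationResult",
    "PepGNN",
    "hash_embedder",
    "sample_training_mask",
    "loss_round1",
    "loss_round2",
    "train",
    "impute",
    "save_embeddings",
    "load_embeddings",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    embed_proj_dim: int = 16
    latent_dim: int = 128
    attention_heads: int = 64
    final_dim: int = 128
    gamma_interval: tuple = (0.05, 0.15)
    epoch_size: int = 500
    learning_rate: float = 1e-3
    round2_learning_rate: float | None = None  # default: 0.1 x learning_rate
    weight_decay: float = 0.0
    round2_selection: str = "nll"  # validation metric for round-2 early stopping ("nll" | "mse")
    max_epochs: int = 100
    patience: int = 5
    use_embeddings: bool = True
    use_gnn: bool = True
    use_mask_channel: bool = True
    dropout: float = 0.0  # train-time dropout on the two MLP hidden layers
    seed: int = 0

    def validate(self, n_samples: int):
        if min(self.embed_proj_dim, self.latent_dim, self.attention_heads, self.final_dim) < 1:
            raise DataError("all model dimensions must be positive")
        lo, hi = self.gamma_interval
        if not (0 < lo < hi < 1):
            raise DataError("gamma interval must satisfy 0 < lo < hi < 1")
        if n_samples < 2:
            raise DataError("need >= 2 samples (head width floor(s/2) >= 1)")

    def head_out_dim(self, n_samples: int) -> int:
        return n_samples // 2


@dataclass
class ImputationResult:
    """Completed matrix plus per-entry predicted mean/variance.

    ``completed`` is raw-scale with no missing entries: observed values are
    copied through exactly, imputed entries are the inverse-transformed
    predicted means.  ``mu``/``sigma2`` are on the standardized-log scale.
    """

    completed: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    imputed_mask: np.ndarray  # True where the value was imputed

    def __post_init__(self):
        if np.isnan(self.completed).any():
            raise DataError("completed matrix still contains missing values")
        if not (self.sigma2 > 0).all():
            raise DataError("sigma2 must be strictly positive everywhere")

    @property
    def provenance(self) -> np.ndarray:
        return np.where(self.imputed_mask, "imputed", "observed")

    @property
    def sigma(self) -> np.ndarray:
        """Predicted standard deviation (standardized-log scale)."""
        return np.sqrt(self.sigma2)


# ---------------------------------------------------------------------------
# Embeddings


def hash_embedder(sequences, d: int = 64, salt: str = "pepimpute") -> np.ndarray:
    """Deterministic k-mer-hash sequence embeddings (unit rows).

    A cheap, fully reproducible stand-in embedding: counts of 1-, 2- and
    3-mers are feature-hashed (blake2b) into ``d`` signed buckets and the
    row is L2-normalized.  Identical sequences map to identical rows.
    """
    if d < 1:
        raise DataError("embedding dimension must be >= 1")
    out = np.zeros((len(sequences), d))
    for r, seq in enumerate(sequences):
        if not seq:
            raise DataError(f"empty sequence at row {r}")
        for k in (1, 2, 3):
            for i in range(len(seq) - k + 1):
                digest = hashlib.blake2b(
                    (salt + seq[i : i + k]).encode(), digest_size=8
                ).digest()
                bucket = int.from_bytes(digest[:4], "little") % d
                sign = 1.0 if digest[4] % 2 == 0 else -1.0
                out[r, bucket] += sign
        norm = np.linalg.norm(out[r])
        if norm > 0:
            out[r] /= norm
    return out


def save_embeddings(path, peptide_ids, matrix: np.ndarray):
    """HDF5 embedding container: an id index plus an n x d float dataset."""
    import h5py

    matrix = np.asarray(matrix, dtype=np.float64)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("peptide_ids", data=np.array(peptide_ids, dtype="S"))
        fh.create_dataset("embeddings", data=matrix)


def load_embeddings(path, peptide_ids) -> np.ndarray:
    """Load embeddings and align rows to `peptide_ids`; error on missing ids."""
    import h5py

    with h5py.File(path, "r") as fh:
        ids = [x.decode() for x in fh["peptide_ids"][()]]
        mat = fh["embeddings"][()]
    index = {p: i for i, p in enumerate(ids)}
    missing = [p for p in peptide_ids if p not in index]
    if missing:
        raise DataError(f"embedding container lacks {len(missing)} peptide ids, e.g. {missing[:3]}")
    return mat[[index[p] for p in peptide_ids]]


# ---------------------------------------------------------------------------
# Network


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class PepGNN:
    """The imputation network: parameters, encoding, and forward pass."""

    def __init__(self, n_samples: int, embed_dim: int, graph: PeptideGraph, cfg: ModelConfig):
        cfg.validate(n_samples)
        self.cfg = cfg
        self.s = n_samples
        self.embed_dim = embed_dim
        self.hd = cfg.head_out_dim(n_samples)
        self.H = cfg.attention_heads
        self.src, self.dst = graph.directed_edge_arrays(include_self_loops=True)
        self.n_nodes = graph.n_nodes
        enc = 2 * n_samples if cfg.use_mask_channel else n_samples
        self.enc_width = enc
        self.sigma_scale = 1.0  # validation-calibrated variance scale
        rng = np.random.default_rng(cfg.seed)
        L, F, E = cfg.latent_dim, cfg.final_dim, cfg.embed_proj_dim
        att_out = self.H * self.hd
        p = {}
        p["seq_W"] = _glorot(rng, embed_dim, E)
        p["seq_b"] = np.zeros(E)
        p["lat_W1"] = _glorot(rng, enc + E, L)
        p["lat_b1"] = np.zeros(L)
        p["lat_W2"] = _glorot(rng, L, L)
        p["lat_b2"] = np.zeros(L)
        p["att_Wl"] = _glorot(rng, L, att_out)
        p["att_Wr"] = _glorot(rng, L, att_out)
        p["att_a"] = rng.uniform(-1, 1, size=(self.H, self.hd)) * np.sqrt(3.0 / self.hd)
        p["att_b"] = np.zeros((self.H, self.hd))
        p["fin_W1"] = _glorot(rng, att_out + L, F)
        p["fin_b1"] = np.zeros(F)
        p["fin_W2"] = _glorot(rng, F, F)
        p["fin_b2"] = np.zeros(F)
        p["mu_W"] = _glorot(rng, F, n_samples)
        p["mu_b"] = np.zeros(n_samples)
        p["sig_W"] = _glorot(rng, F, n_samples)
        p["sig_b"] = np.zeros(n_samples)
        self.params = {k: ag.parameter(v) for k, v in p.items()}

    # -- parameter plumbing -------------------------------------------------

    def param_list(self):
        return [self.params[k] for k in sorted(self.params)]

    def get_state(self) -> dict:
        return {k: t.data.copy() for k, t in self.params.items()}

    def set_state(self, state: dict):
        for k, t in self.params.items():
            t.data = state[k].copy()

    # -- forward ------------------------------------------------------------

    def encode(self, a_with_nan: np.ndarray) -> np.ndarray:
        """Missing-input encoding: zero-fill on the standardized scale plus,
        if enabled, a binary observed-indicator channel."""
        obs = np.isfinite(a_with_nan)
        filled = np.where(obs, a_with_nan, 0.0)
        if self.cfg.use_mask_channel:
            return np.concatenate([filled, obs.astype(float)], axis=1)
        return filled

    def forward(self, a_enc: np.ndarray, s_embed: np.ndarray, dropout_rng=None):
        """Run the network; returns (mu, sigma2) autograd tensors.

        `dropout_rng` enables train-time dropout (cfg.dropout) on the two
        MLP hidden layers; inference passes None (no dropout)."""
        if a_enc.shape != (self.n_nodes, self.enc_width):
            raise DataError(f"encoded input has shape {a_enc.shape}, expected {(self.n_nodes, self.enc_width)}")
        p = self.params

        def drop(t):
            if dropout_rng is None or self.cfg.dropout <= 0:
                return t
            keep = 1.0 - self.cfg.dropout
            mask = (dropout_rng.random(t.data.shape) < keep) / keep
            return ag.mul(t, ag.constant(mask))
        a_in = ag.constant(a_enc)
        if self.cfg.use_embeddings:
            if s_embed.shape[0] != self.n_nodes or s_embed.shape[1] != self.embed_dim:
                raise DataError("embedding matrix misaligned with the peptide set")
            e = ag.relu(ag.add(ag.matmul(ag.constant(s_embed), p["seq_W"]), p["seq_b"]))
        else:
            e = ag.constant(np.zeros((self.n_nodes, self.cfg.embed_proj_dim)))
        x0 = ag.concat([a_in, e], axis=1)
        h1 = drop(ag.relu(ag.add(ag.matmul(x0, p["lat_W1"]), p["lat_b1"])))
        h = ag.add(ag.matmul(h1, p["lat_W2"]), p["lat_b2"])  # (n, L)

        if self.cfg.use_gnn:
            z = self._attention(h)
        else:
            # ablation wiring: zeros of the same width keep f_fin's shape
            z = ag.constant(np.zeros((self.n_nodes, self.H * self.hd)))

        f0 = ag.concat([z, h], axis=1)
        f1 = drop(ag.relu(ag.add(ag.matmul(f0, p["fin_W1"]), p["fin_b1"])))
        f = ag.add(ag.matmul(f1, p["fin_W2"]), p["fin_b2"])
        mu = ag.add(ag.matmul(f, p["mu_W"]), p["mu_b"])
        sigma2 = ag.add(ag.softplus(ag.add(ag.matmul(f, p["sig_W"]), p["sig_b"])), ag.constant(1e-6))
        return mu, sigma2

    def _attention(self, h):
        """GATv2-style dynamic multi-head attention over the edge list.

        Per directed edge (j -> i) and head: score = a . LeakyReLU(W_l h_i
        + W_r h_j + b); coefficients softmax-normalize over each target
        node's in-neighborhood (self-loop included); messages are W_r h_j.
        """
        p = self.params
        E, H, hd = len(self.src), self.H, self.hd
        xl = ag.reshape(ag.matmul(h, p["att_Wl"]), (self.n_nodes, H, hd))
        xr = ag.reshape(ag.matmul(h, p["att_Wr"]), (self.n_nodes, H, hd))
        q = ag.add(ag.add(ag.gather_rows(xl, self.dst), ag.gather_rows(xr, self.src)), p["att_b"])
        scores = ag.sum_axis(ag.mul(ag.leaky_relu(q, 0.2), p["att_a"]), axis=2)  # (E, H)
        alpha = ag.segment_softmax(scores, self.dst, self.n_nodes)
        msg = ag.gather_rows(xr, self.src)  # (E, H, hd)
        weighted = ag.mul(ag.reshape(alpha, (E, H, 1)), msg)
        z = ag.segment_sum(weighted, self.dst, self.n_nodes)
        return ag.reshape(z, (self.n_nodes, H * hd))

    def predict(self, a_with_nan: np.ndarray, s_embed: np.ndarray):
        """Numpy-only forward convenience: returns (mu, sigma2) arrays;
        sigma2 includes the validation-calibrated scale factor."""
        mu, sigma2 = self.forward(self.encode(a_with_nan), s_embed)
        if not (np.isfinite(mu.data).all() and np.isfinite(sigma2.data).all()):
            raise FloatingPointError("non-finite network output")
        return mu.data, sigma2.data * self.sigma_scale


# ---------------------------------------------------------------------------
# Losses and training


def sample_training_mask(observed_idx: np.ndarray, gamma_interval, rng: np.random.Generator) -> np.ndarray:
    """Draw gamma ~ U[lo, hi) and pick floor(gamma * #observed) positions
    uniformly without replacement from the observed set."""
    observed_idx = np.asarray(observed_idx).reshape(-1, 2)
    if len(observed_idx) == 0:
        raise DataError("no observed positions to mask")
    gamma = rng.uniform(*gamma_interval)
    count = max(1, int(np.floor(gamma * len(observed_idx))))
    pick = rng.choice(len(observed_idx), size=count, replace=False)
    return observed_idx[pick]


def loss_round1(mu_vals: np.ndarray, truth_vals: np.ndarray) -> float:
    """MSE over masked positions (round-one objective, mean head only)."""
    mu_vals = np.asarray(mu_vals, dtype=float)
    truth_vals = np.asarray(truth_vals, dtype=float)
    if mu_vals.size == 0:
        raise DataError("empty masked set")
    return float(np.mean((mu_vals - truth_vals) ** 2))


def loss_round2(mu_vals, sigma2_vals, truth_vals, var_floor: float = 1e-6) -> float:
    """Gaussian negative log-likelihood, 0.5 * [log s2 + (y - mu)^2 / s2],
    averaged over masked positions; the constant term is dropped and the
    variance floored at `var_floor`."""
    mu_vals = np.asarray(mu_vals, dtype=float)
    s2 = np.maximum(np.asarray(sigma2_vals, dtype=float), var_floor)
    y = np.asarray(truth_vals, dtype=float)
    if mu_vals.size == 0:
        raise DataError("empty masked set")
    return float(np.mean(0.5 * (np.log(s2) + (y - mu_vals) ** 2 / s2)))


def _flat(idx: np.ndarray, s: int) -> np.ndarray:
    idx = np.asarray(idx).reshape(-1, 2)
    return idx[:, 0] * s + idx[:, 1]


def _run_round(model, a_train, s_embed, obs_idx, val_flat, val_truth, cfg, rng, nll: bool, history, lr=None):
    """One training round (shared protocol): per-step masking, gradient
    steps, per-epoch validation scoring, early stopping, best-weight
    restore.  Round one scores validation MSE of the mean head; round two
    scores the Gaussian NLL by default (ModelConfig.round2_selection) so
    the variance head participates in model selection."""
    s = model.s
    opt = ag.Adam(model.param_list(), lr=cfg.learning_rate if lr is None else lr, weight_decay=cfg.weight_decay)
    use_nll_metric = nll and cfg.round2_selection == "nll"

    def val_score():
        """Validation score; for NLL selection the sigma scale is first
        calibrated on the validation residuals (closed form), so model
        selection rewards per-value variance *structure* rather than a
        global scale that a constant head could match."""
        mu_v, s2_v = model.forward(a_full_enc, s_embed)
        mu_sel = mu_v.data.reshape(-1)[val_flat]
        if not use_nll_metric:
            return loss_round1(mu_sel, val_truth), 1.0
        s2_sel = np.maximum(s2_v.data.reshape(-1)[val_flat], 1e-6)
        resid2 = (np.asarray(val_truth) - mu_sel) ** 2
        scale = max(float(np.mean(resid2 / s2_sel)), 1e-6)
        return loss_round2(mu_sel, scale * s2_sel, val_truth), scale

    best_state = model.get_state()
    a_full_enc = model.encode(a_train)
    best_val, best_scale = val_score()
    history.append(best_val)
    stale = 0
    for _epoch in range(cfg.max_epochs):
        for _step in range(cfg.epoch_size):
            mask_idx = sample_training_mask(obs_idx, cfg.gamma_interval, rng)
            a_step = a_train.copy()
            a_step[mask_idx[:, 0], mask_idx[:, 1]] = np.nan
            mu_t, s2_t = model.forward(model.encode(a_step), s_embed, dropout_rng=rng)
            flat = _flat(mask_idx, s)
            target = ag.constant(a_train.reshape(-1)[flat])
            diff = ag.sub(ag.take_flat(mu_t, flat), target)
            if nll:
                s2_sel = ag.take_flat(s2_t, flat)
                loss = ag.mul(
                    ag.mean_all(ag.add(ag.log(s2_sel), ag.mul(ag.square(diff), ag.reciprocal(s2_sel)))),
                    ag.constant(0.5),
                )
            else:
                loss = ag.mean_all(ag.square(diff))
            if not np.isfinite(loss.data) or abs(loss.data) > 1e12:
                raise FloatingPointError(f"training diverged (loss {loss.data!r})")
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_metric, val_scale = val_score()
        history.append(val_metric)
        if val_metric < best_val - 1e-12:
            best_val = val_metric
            best_scale = val_scale
            best_state = model.get_state()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.set_state(best_state)
    if use_nll_metric:
        model.sigma_scale = best_scale
    return best_val


def train(
    std_matrix: np.ndarray,
    plan: MaskPlan,
    s_embed: np.ndarray,
    graph: PeptideGraph,
    cfg: ModelConfig,
) -> tuple:
    """Two-round self-supervised training.

    ``std_matrix`` is the standardized-log matrix of the *full* dataset;
    test and validation positions from `plan` are masked internally to
    form the training view.  Returns ``(model, info)`` where ``info``
    records per-epoch validation MSE for both rounds.
    """
    a_train = plan.apply(std_matrix)
    obs_idx = np.argwhere(np.isfinite(a_train))
    if len(obs_idx) == 0:
        raise DataError("training view has no observed values")
    n, s = a_train.shape
    model = PepGNN(s, s_embed.shape[1], graph, cfg)
    rng = np.random.default_rng(cfg.seed)
    val_flat = _flat(plan.val_idx, s)
    val_truth = plan.truth_at(plan.val_idx)
    info = {"round1_val_mse": [], "round2_val_history": []}
    lr2 = cfg.round2_learning_rate if cfg.round2_learning_rate is not None else 0.1 * cfg.learning_rate
    best1 = _run_round(model, a_train, s_embed, obs_idx, val_flat, val_truth, cfg, rng, False, info["round1_val_mse"])
    # warm-start the variance head at the round-1 residual variance
    model.params["sig_b"].data[:] = np.log(np.expm1(max(best1, 1e-4)))
    best2 = _run_round(model, a_train, s_embed, obs_idx, val_flat, val_truth, cfg, rng, True, info["round2_val_history"], lr=lr2)
    info["best_val_mse_round1"] = best1
    info["best_val_round2"] = best2  # MSE or NLL per cfg.round2_selection
    return model, info


def impute(
    model: PepGNN,
    std_view: np.ndarray,
    state: TransformState,
    s_embed: np.ndarray,
    raw_view: np.ndarray | None = None,
) -> ImputationResult:
    """Complete a matrix with the trained network.

    ``std_view`` is the standardized-log matrix whose NaN entries are to be
    imputed.  Observed entries are passed through unchanged (from
    ``raw_view`` when given, to preserve raw values bit for bit; otherwise
    via the inverse transform).
    """
    mu, sigma2 = model.predict(std_view, s_embed)
    obs = np.isfinite(std_view)
    if raw_view is None:
        raw_view = inverse_transform(std_view, state)
    completed = np.where(obs, np.where(obs, raw_view, 1.0), inverse_transform(mu, state))
    return ImputationResult(completed=completed, mu=mu, sigma2=sigma2, imputed_mask=~obs)


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(model: PepGNN, path):
    """Store parameters plus config and seed (npz + embedded JSON)."""
    cfg_json = json.dumps(asdict(model.cfg))
    arrays = {f"param_{k}": v.data for k, v in model.params.items()}
    np.savez(
        path,
        __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
        __meta__=np.array([model.s, model.embed_dim, model.n_nodes], dtype=float),
        __sigma_scale__=np.array(model.sigma_scale),
        **arrays,
    )


def load_checkpoint(path, graph: PeptideGraph) -> PepGNN:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["gamma_interval"] = tuple(cfg_dict["gamma_interval"])
        cfg = ModelConfig(**cfg_dict)
        s, embed_dim, n_nodes = (int(x) for x in data["__meta__"])
        if n_nodes != graph.n_nodes:
            raise DataError("checkpoint/graph node-count mismatch")
        model = PepGNN(s, embed_dim, graph, cfg)
        model.set_state({k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")})
        if "__sigma_scale__" in data.files:
            model.sigma_scale = float(data["__sigma_scale__"])
    return model
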