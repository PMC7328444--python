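"""Feed-forward proteochemometric network with entity embeddings.

Each of the fingerprint bits is treated as a 2-category categorical
variable with its own learned embedding vector per category; the
concatenated embeddings plus the scaled continuous descriptors feed three
hidden layers (2000 -> 1000 -> 500). Each hidden linear output passes ReLU,
then batch normalization, then dropout (0.25; 0.01 on the embeddings). The
final output is squashed through a logistic function onto the training-label
range expanded by a factor of 1.2 about its midpoint. Optimization is Adam
with decoupled weight decay (0.01) under a one-cycle learning-rate
schedule.

Test-time dropout (MC-dropout) provides the per-instance predictive spread
used for conformal prediction: the population SD over repeated stochastic
forward passes with dropout active and batch-norm in inference mode.

Implemented directly on NumPy (forward and backward passes by hand); the
arithmetic is plain dense linear algebra and runs on BLAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..featurization import FeatureMatrix
from .common import UncertaintyPrediction

_EPS = 1e-5


@dataclass
class FFNConfig:
    hidden_sizes: tuple = (2000, 1000, 500)
    dropout: float = 0.25
    embedding_dropout: float = 0.01
    weight_decay: float = 0.01
    output_range_factor: float = 1.2
    embedding_dim_per_bit: int = 2
    mc_passes: int = 100
    epochs: int = 20
    batch_size: int = 256
    max_lr: float = 1e-2
    pct_start: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 <= self.embedding_dropout < 1.0:
            raise ValueError("embedding_dropout must be in [0, 1)")
        if self.output_range_factor < 1.0:
            raise ValueError("output_range_factor must be >= 1")
        if self.mc_passes < 2:
            raise ValueError("mc_passes must be >= 2 for spread estimation")
        if self.embedding_dim_per_bit < 1:
            raise ValueError("embedding_dim_per_bit must be >= 1")


def _one_cycle_lr(step: int, total: int, max_lr: float, pct_start: float) -> float:
    """Cosine warmup from max_lr/25 to max_lr, then cosine anneal to
    max_lr/1e4."""
    warm = max(1, int(total * pct_start))
    if step < warm:
        t = step / warm
        lo = max_lr / 25.0
        return lo + (max_lr - lo) * (1 - np.cos(np.pi * t)) / 2
    t = (step - warm) / max(1, total - warm)
    lo = max_lr / 1e4
    return max_lr - (max_lr - lo) * (1 - np.cos(np.pi * t)) / 2


class _Adam:
    def __init__(self, shapes, beta1=0.9, beta2=0.99, eps=1e-8):
        self.m = [np.zeros(s, dtype=np.float32) for s in shapes]
        self.v = [np.zeros(s, dtype=np.float32) for s in shapes]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr, wd_mask, weight_decay):
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for p, g, m, v, wd in zip(params, grads, self.m, self.v, wd_mask):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            p -= lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
            if wd:
                p -= lr * weight_decay * p


class FFNModel:
    """3-hidden-layer regression network with per-bit entity embeddings."""

    def __init__(self, n_bits: int, n_cont: int, config: FFNConfig | None = None):
        self.config = config or FFNConfig()
        self.n_bits = n_bits
        self.n_cont = n_cont
        self.fitted = False
        self.y_lo = 0.0
        self.y_hi = 1.0
        self.schema: str | None = None
        rng = np.random.default_rng(self.config.seed)
        d = self.config.embedding_dim_per_bit
        self.E = rng.normal(0.0, 0.1, size=(n_bits, 2, d)).astype(np.float32)
        sizes = [n_bits * d + n_cont, *self.config.hidden_sizes, 1]
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            self.W.append(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)).astype(np.float32)
            )
            self.b.append(np.zeros(fan_out, dtype=np.float32))
        n_hidden = len(self.config.hidden_sizes)
        self.gamma = [np.ones(h, dtype=np.float32) for h in self.config.hidden_sizes]
        self.beta = [np.zeros(h, dtype=np.float32) for h in self.config.hidden_sizes]
        self.run_mean = [np.zeros(h, dtype=np.float32) for h in self.config.hidden_sizes]
        self.run_var = [np.ones(h, dtype=np.float32) for h in self.config.hidden_sizes]
        self._n_hidden = n_hidden

    # ---- forward ---------------------------------------------------------

    def _embed(self, X_bits: np.ndarray) -> np.ndarray:
        # emb[n, i, :] = E[i, 0] + bit * (E[i, 1] - E[i, 0]); bits are 0/1
        diff = self.E[:, 1, :] - self.E[:, 0, :]
        emb = self.E[None, :, 0, :] + X_bits[:, :, None] * diff[None]
        return emb.reshape(X_bits.shape[0], -1)

    def _forward(self, X_bits, X_cont, training: bool, dropout_rng=None, cache=None):
        use_dropout = dropout_rng is not None
        emb = self._embed(X_bits)
        if use_dropout and self.config.embedding_dropout > 0:
            p = self.config.embedding_dropout
            mask_e = (dropout_rng.random(emb.shape) >= p).astype(np.float32) / (1 - p)
            emb = emb * mask_e
        else:
            mask_e = None
        h = np.concatenate([emb, X_cont.astype(np.float32)], axis=1)
        if cache is not None:
            cache["emb_mask"] = mask_e
            cache["h0"] = h
        for i in range(self._n_hidden):
            z = h @ self.W[i] + self.b[i]
            a = np.maximum(z, 0.0)
            if training:
                mu = a.mean(axis=0)
                var = a.var(axis=0)
                self.run_mean[i] += 0.1 * (mu - self.run_mean[i])
                self.run_var[i] += 0.1 * (var - self.run_var[i])
            else:
                mu, var = self.run_mean[i], self.run_var[i]
            inv = 1.0 / np.sqrt(var + _EPS)
            xhat = (a - mu) * inv
            out = self.gamma[i] * xhat + self.beta[i]
            if use_dropout and self.config.dropout > 0:
                p = self.config.dropout
                mask = (dropout_rng.random(out.shape) >= p).astype(np.float32) / (1 - p)
                out = out * mask
            else:
                mask = None
            if cache is not None:
                cache[f"z{i}"] = z
                cache[f"xhat{i}"] = xhat
                cache[f"inv{i}"] = inv
                cache[f"mask{i}"] = mask
                cache[f"in{i}"] = h
            h = out
        z_out = (h @ self.W[-1] + self.b[-1]).ravel()
        if cache is not None:
            cache["h_last"] = h
            cache["z_out"] = z_out
        sig = 1.0 / (1.0 + np.exp(-z_out))
        y = self.y_lo + sig * (self.y_hi - self.y_lo)
        if cache is not None:
            cache["sig"] = sig
        return y

    # ---- backward --------------------------------------------------------

    def _backward(self, cache, dL_dy):
        span = self.y_hi - self.y_lo
        sig = cache["sig"]
        dz = (dL_dy * span * sig * (1 - sig)).astype(np.float32)[:, None]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        ggamma = [None] * self._n_hidden
        gbeta = [None] * self._n_hidden
        h_last = cache["h_last"]
        gW[-1] = h_last.T @ dz
        gb[-1] = dz.sum(axis=0)
        dh = dz @ self.W[-1].T
        for i in range(self._n_hidden - 1, -1, -1):
            mask = cache[f"mask{i}"]
            if mask is not None:
                dh = dh * mask
            xhat, inv = cache[f"xhat{i}"], cache[f"inv{i}"]
            ggamma[i] = (dh * xhat).sum(axis=0)
            gbeta[i] = dh.sum(axis=0)
            n = dh.shape[0]
            da = (self.gamma[i] * inv) * (
                dh - dh.mean(axis=0) - xhat * (dh * xhat).mean(axis=0)
            )
            dz_i = da * (cache[f"z{i}"] > 0)
            gW[i] = cache[f"in{i}"].T @ dz_i
            gb[i] = dz_i.sum(axis=0)
            dh = dz_i @ self.W[i].T
        demb = dh[:, : self.n_bits * self.config.embedding_dim_per_bit]
        if cache["emb_mask"] is not None:
            demb = demb * cache["emb_mask"]
        d = self.config.embedding_dim_per_bit
        G = demb.reshape(-1, self.n_bits, d)
        Xb = cache["X_bits"]
        gE = np.empty_like(self.E)
        gE[:, 1, :] = np.einsum("ni,nid->id", Xb, G)
        gE[:, 0, :] = G.sum(axis=0) - gE[:, 1, :]
        return gE, gW, gb, ggamma, gbeta

    # ---- training --------------------------------------------------------

    def fit(self, X_bits, X_cont, y) -> "FFNModel":
        cfg = self.config
        X_bits = np.ascontiguousarray(X_bits, dtype=np.float32)
        X_cont = np.ascontiguousarray(X_cont, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        mid = (y.max() + y.min()) / 2.0
        half = (y.max() - y.min()) / 2.0 * cfg.output_range_factor
        self.y_lo, self.y_hi = float(mid - half), float(mid + half)

        params = [self.E, *self.W, *self.b, *self.gamma, *self.beta]
        wd_mask = (
            [True]
            + [True] * len(self.W)
            + [False] * len(self.b)
            + [False] * (2 * self._n_hidden)
        )
        opt = _Adam([p.shape for p in params])
        rng = np.random.default_rng([cfg.seed, 17])
        drop_rng = np.random.default_rng([cfg.seed, 23])
        n = X_bits.shape[0]
        batches_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
        total_steps = cfg.epochs * batches_per_epoch
        step = 0
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                if len(idx) < 2:
                    continue  # batch statistics need >= 2 rows
                cache = {"X_bits": X_bits[idx]}
                pred = self._forward(
                    X_bits[idx], X_cont[idx], training=True, dropout_rng=drop_rng, cache=cache
                )
                dL_dy = 2.0 * (pred - y[idx]) / len(idx)
                gE, gW, gb, ggamma, gbeta = self._backward(cache, dL_dy)
                grads = [gE, *gW, *gb, *ggamma, *gbeta]
                lr = _one_cycle_lr(step, total_steps, cfg.max_lr, cfg.pct_start)
                opt.step(params, grads, lr, wd_mask, cfg.weight_decay)
                step += 1
        self.fitted = True
        return self

    # ---- inference -------------------------------------------------------

    def _split_matrix(self, matrix):
        if isinstance(matrix, FeatureMatrix):
            bits = matrix.block("fingerprint")
            start, _ = matrix.block_index["physchem"]
            cont = matrix.values[:, start:]
        else:
            X = np.asarray(matrix)
            bits, cont = X[:, : self.n_bits], X[:, self.n_bits :]
        if bits.shape[1] != self.n_bits or cont.shape[1] != self.n_cont:
            raise ValueError("feature schema mismatch with trained network")
        return bits.astype(np.float32), cont.astype(np.float32)

    def predict(self, matrix) -> np.ndarray:
        bits, cont = self._split_matrix(matrix)
        return self._forward(bits, cont, training=False, dropout_rng=None)


def train_ffn(matrix: FeatureMatrix, labels, config: FFNConfig | None = None) -> FFNModel:
    """Train on a FeatureMatrix whose fingerprint block is strictly 0/1."""
    config = config or FFNConfig()
    bits = matrix.block("fingerprint")
    if not np.all(np.isin(bits, (0.0, 1.0))):
        raise ValueError("fingerprint block must be binary 0/1")
    start, _ = matrix.block_index["physchem"]
    cont = matrix.values[:, start:]
    model = FFNModel(n_bits=bits.shape[1], n_cont=cont.shape[1], config=config)
    model.schema = matrix.schema_fingerprint()
    return model.fit(bits, cont, labels)


def mc_dropout_predict(
    model: FFNModel, matrix, passes: int | None = None, seed: int = 0
) -> UncertaintyPrediction:
    """Mean and population SD over stochastic forward passes with dropout
    active at inference (batch norm uses running statistics)."""
    if passes is None:
        passes = model.config.mc_passes
    if passes < 2:
        raise ValueError("need at least 2 passes for spread estimation")
    bits, cont = model._split_matrix(matrix)
    if model.config.dropout == 0.0 and model.config.embedding_dropout == 0.0:
        # degenerate case: every pass is the same deterministic forward pass
        mean = model._forward(bits, cont, training=False, dropout_rng=None)
        return UncertaintyPrediction(mean=mean, spread=np.zeros_like(mean))
    rng = np.random.default_rng([seed, 29])
    outs = np.stack(
        [
            model._forward(bits, cont, training=False, dropout_rng=rng)
            for _ in range(passes)
        ]
    )
    return UncertaintyPrediction(mean=outs.mean(axis=0), spread=outs.std(axis=0))


def extract_bit_embeddings(model: FFNModel) -> np.ndarray:
    """Learned 'present' (category-1) embedding vector per fingerprint bit:
    an (n_bits, embedding_dim) matrix."""
    if not model.fitted:
        raise ValueError("model is not trained")
    return np.array(model.E[:, 1, :], dtype=np.float64)
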