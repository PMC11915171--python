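"""Self-attention neural network (SANN) for malignant-transformation risk.

Each encoded clinical feature becomes a token through a learned
scalar-to-``dv`` embedding; a single scaled dot-product self-attention
layer re-weights the tokens by learned relevance,

    Attention(Q, K, V) = softmax(Q K' / sqrt(dk)) V,

and the flattened attended tokens feed a ReLU MLP with a sigmoid output —
the predicted probability of malignant transformation. With attention
disabled the same class is the plain ANN baseline (an MLP on the raw
feature vector). Training minimizes binary cross-entropy with Adam,
mini-batches, and early stopping on validation loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP, Adam, sigmoid

__all__ = [
    "SannConfig",
    "SannModel",
    "scaled_dot_attention",
    "build_model",
    "train_model",
    "predict_risk",
    "feature_attention_importance",
]


@dataclass
class SannConfig:
    """Hyperparameters for the attention classifier.

    ``dk``/``dv`` are the attention key/query and value dimensions;
    ``hidden_sizes`` the MLP widths; early stopping halts training after
    ``patience`` epochs without validation-loss improvement.
    """

    dk: int = 8
    dv: int = 8
    hidden_sizes: tuple[int, ...] = (32, 16)
    dropout: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.dk < 1 or self.dv < 1:
            raise ValueError("dk and dv must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if min(self.batch_size, self.max_epochs, self.patience) < 1:
            raise ValueError("batch_size, max_epochs, patience must be >= 1")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray):
    """Scaled dot-product attention for one token set.

    Returns ``(output, weights)`` where ``weights`` is the row-stochastic
    ``softmax(Q K' / sqrt(dk))`` matrix and ``output = weights @ V``; each
    output row is therefore a convex combination of the rows of V.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.ndim != 2 or K.ndim != 2 or V.ndim != 2:
        raise ValueError("Q, K, V must be 2-D")
    if Q.shape[1] != K.shape[1]:
        raise ValueError("Q and K must share the key dimension dk")
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must have the same number of rows")
    dk = Q.shape[1]
    S = Q @ K.T / np.sqrt(dk)
    S = S - S.max(axis=1, keepdims=True)
    W = np.exp(S)
    W /= W.sum(axis=1, keepdims=True)
    return W @ V, W


class SannModel:
    """Attention classifier (or plain MLP when ``with_attention=False``)."""

    def __init__(self, config: SannConfig, n_features: int, with_attention: bool):
        config.validate()
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        self.config = config
        self.n_features = n_features
        self.with_attention = with_attention
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        rng = np.random.default_rng(config.seed)
        m, dk, dv = n_features, config.dk, config.dv
        if with_attention:
            # small token embeddings keep the early attention logits near
            # uniform (standardized rare-level inputs can reach |x| ~ 10)
            self.Wemb = rng.normal(0.0, 1.0 / dv, size=(m, dv))
            self.bemb = np.zeros((m, dv))
            s = 1.0 / np.sqrt(dv)
            self.Wq = rng.normal(0.0, s, size=(dv, dk))
            self.Wk = rng.normal(0.0, s, size=(dv, dk))
            self.Wv = rng.normal(0.0, s, size=(dv, dv))
            mlp_in = m * dv
        else:
            mlp_in = m
        self.mlp = MLP([mlp_in, *config.hidden_sizes, 1], rng)

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        if self.with_attention:
            out.extend([self.Wemb, self.bemb, self.Wq, self.Wk, self.Wv])
        out.extend(self.mlp.parameters())
        return out

    def set_parameters(self, params: list[np.ndarray]) -> None:
        params = list(params)
        if self.with_attention:
            self.Wemb, self.bemb, self.Wq, self.Wk, self.Wv = params[:5]
            params = params[5:]
        self.mlp.set_parameters(params)

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False, rng=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got shape {X.shape}"
            )
        cache: dict = {"X": X}
        if self.with_attention:
            E = X[:, :, None] * self.Wemb[None] + self.bemb[None]  # (B, m, dv)
            Q = E @ self.Wq
            K = E @ self.Wk
            V = E @ self.Wv
            S = Q @ np.swapaxes(K, 1, 2) / np.sqrt(self.config.dk)
            S = S - S.max(axis=2, keepdims=True)
            A = np.exp(S)
            A /= A.sum(axis=2, keepdims=True)
            O = A @ V
            h = O.reshape(X.shape[0], -1)
            cache.update(E=E, Q=Q, K=K, V=V, A=A)
        else:
            h = X
        dropout = self.config.dropout if train else 0.0
        z, mlp_cache = self.mlp.forward(h, dropout=dropout, rng=rng)
        cache["mlp"] = mlp_cache
        logits = z[:, 0]
        return sigmoid(logits), cache

    def backward(self, cache: dict, dlogits: np.ndarray) -> list[np.ndarray]:
        dh, mlp_grads = self.mlp.backward(cache["mlp"], dlogits[:, None])
        if not self.with_attention:
            return mlp_grads
        X, E, Q, K, V, A = (cache[k] for k in ("X", "E", "Q", "K", "V", "A"))
        B, m, dv = E.shape
        dO = dh.reshape(B, m, dv)
        dA = dO @ np.swapaxes(V, 1, 2)
        dV = np.swapaxes(A, 1, 2) @ dO
        dS = A * (dA - (dA * A).sum(axis=2, keepdims=True))
        dS /= np.sqrt(self.config.dk)
        dQ = dS @ K
        dK = np.swapaxes(dS, 1, 2) @ Q
        dWq = np.einsum("bmd,bmk->dk", E, dQ)
        dWk = np.einsum("bmd,bmk->dk", E, dK)
        dWv = np.einsum("bmd,bmk->dk", E, dV)
        dE = dQ @ self.Wq.T + dK @ self.Wk.T + dV @ self.Wv.T
        dWemb = np.einsum("bm,bmd->md", X, dE)
        dbemb = dE.sum(axis=0)
        return [dWemb, dbemb, dWq, dWk, dWv, *mlp_grads]

    def attention_weights(self, X: np.ndarray) -> np.ndarray:
        """Per-sample attention matrices (B, m, m)."""
        if not self.with_attention:
            raise ValueError("model was built without attention")
        _, cache = self.forward(X, train=False)
        return cache["A"]


def build_model(
    config: SannConfig, n_features: int, with_attention: bool = True
) -> SannModel:
    """Seeded-deterministic model construction."""
    return SannModel(config, n_features, with_attention)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def train_model(
    model: SannModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: SannConfig | None = None,
) -> SannModel:
    """Mini-batch Adam on binary cross-entropy with early stopping.

    Training stops when validation loss has not improved for
    ``config.patience`` epochs; the weights of the best validation epoch
    are restored. Deterministic under a fixed seed (single-threaded).
    """
    config = config or model.config
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float).ravel()
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = X_train.shape[0]
    best_val = np.inf
    best_params = None
    best_epoch = -1
    stall = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            p, cache = model.forward(xb, train=True, rng=rng)
            ep_loss += _bce(p, yb) * len(idx)
            dlogits = (p - yb) / len(idx)
            grads = model.backward(cache, dlogits)
            params = model.parameters()
            opt.step(params, grads)
            model.set_parameters(params)
        p_val, _ = model.forward(X_val, train=False)
        val_loss = _bce(p_val, y_val)
        model.history["train_loss"].append(ep_loss / n)
        model.history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = [p.copy() for p in model.parameters()]
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    if best_params is not None:
        model.set_parameters(best_params)
    model.history["best_epoch"] = best_epoch
    return model


def predict_risk(model: SannModel, X: np.ndarray) -> np.ndarray:
    """Predicted MT probability per row, in (0, 1)."""
    p, _ = model.forward(np.asarray(X, dtype=float), train=False)
    return np.clip(p, 1e-12, 1 - 1e-12)


def feature_attention_importance(model: SannModel, X: np.ndarray) -> np.ndarray:
    """Mean attention received by each feature token, normalized to sum 1.

    Averages the attention weight each key token receives over all samples
    and query tokens — a direct readout of which clinical features the
    attention layer emphasises.
    """
    A = model.attention_weights(np.asarray(X, dtype=float))
    scores = A.mean(axis=(0, 1))
    total = scores.sum()
    if total <= 0:
        raise ValueError("degenerate attention weights")
    return scores / total
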