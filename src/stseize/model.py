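"""Channel-token Transformer encoder classifier.

Each EEG channel's 12-value rhythm-energy vector is one token; the token
sequence (no positional encoding -- channel order carries no spatial
metric here) passes through L stacked encoder layers of multi-head
self-attention (MSA) and a token-wise MLP.  The residual form of each
layer is

    y_i = MSA(LN(S_{i-1}))
    S_i = S_{i-1} + y_i + MLP(LN(y_i))

i.e. the MLP branch reads the *attention output* rather than the running
stream; a ``standard_block`` flag switches to the conventional pre-LN
block for ablation.  Classification max-pools over channels, then a small
MLP head with softmax yields P(non-seizure), P(seizure).  Because there
is no positional encoding and max-pool is symmetric, class probabilities
are invariant to channel permutations.

The network is small (d_model = 12 = feature width, h = 3 heads,
d_k = d_v = 4, L = 6) and is implemented directly in NumPy: explicit
forward pass, hand-derived backward pass (verified against finite
differences in the test suite), and an Adam loop with early stopping.
All randomness flows from a single integer seed, so training is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import FeatureMap

__all__ = [
    "EncoderConfig",
    "TrainConfig",
    "EncoderParams",
    "self_attention",
    "multi_head_attention",
    "encoder_forward",
    "classify",
    "predict_proba",
    "train",
    "channel_attention",
    "parameter_count",
    "init_params",
    "save_checkpoint",
    "load_checkpoint",
]

_LN_EPS = 1e-5


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the encoder and classification head."""

    d_model: int = 12
    h: int = 3
    d_k: int = 4
    d_v: int = 4
    L: int = 6
    d_ff: int = 48
    mlp_hidden: int = 32
    n_classes: int = 2
    dropout: float = 0.0
    seed: int = 0
    standard_block: bool = False

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.n_classes != 2:
            raise ValueError("binary classifier: n_classes must be 2")
        if self.d_model % self.h != 0:
            raise ValueError("d_model must be divisible by h")
        if not (self.d_k == self.d_v == self.d_model // self.h):
            raise ValueError(
                f"require d_k = d_v = d_model/h = {self.d_model // self.h}, "
                f"got d_k={self.d_k}, d_v={self.d_v}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (Adam with patience-based early stopping)."""

    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.1


class EncoderParams:
    """Flat dict of named parameter arrays with attribute-free access."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = arrays

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    def __setitem__(self, key: str, value: np.ndarray) -> None:
        self.arrays[key] = value

    def copy(self) -> "EncoderParams":
        return EncoderParams({k: v.copy() for k, v in self.arrays.items()})

    def keys(self):
        return self.arrays.keys()

    def zeros_like(self) -> "EncoderParams":
        return EncoderParams({k: np.zeros_like(v) for k, v in self.arrays.items()})


def init_params(config: EncoderConfig, rng: np.random.Generator | None = None) -> EncoderParams:
    """Xavier-uniform projection weights, unit LayerNorm gains, zero biases."""
    rng = rng or np.random.default_rng(config.seed)

    def xavier(shape):
        fan_in, fan_out = shape[-2], shape[-1]
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    d, h, dk, dv = config.d_model, config.h, config.d_k, config.d_v
    arrays: dict[str, np.ndarray] = {}
    for i in range(config.L):
        p = f"layer{i}/"
        arrays[p + "ln1_g"] = np.ones(d)
        arrays[p + "ln1_b"] = np.zeros(d)
        arrays[p + "Wq"] = xavier((h, d, dk))
        arrays[p + "Wk"] = xavier((h, d, dk))
        arrays[p + "Wv"] = xavier((h, d, dv))
        arrays[p + "Wo"] = xavier((h * dv, d))
        arrays[p + "ln2_g"] = np.ones(d)
        arrays[p + "ln2_b"] = np.zeros(d)
        arrays[p + "W1"] = xavier((d, config.d_ff))
        arrays[p + "b1"] = np.zeros(config.d_ff)
        arrays[p + "W2"] = xavier((config.d_ff, d))
        arrays[p + "b2"] = np.zeros(d)
    arrays["head/W1"] = xavier((d, config.mlp_hidden))
    arrays["head/b1"] = np.zeros(config.mlp_hidden)
    arrays["head/W2"] = xavier((config.mlp_hidden, config.n_classes))
    arrays["head/b2"] = np.zeros(config.n_classes)
    return EncoderParams(arrays)


def parameter_count(config: EncoderConfig) -> int:
    """Closed-form number of trainable scalars (independent of channel count)."""
    d, h, dk, dv = config.d_model, config.h, config.d_k, config.d_v
    per_layer = (
        2 * d  # ln1
        + h * d * dk * 2  # Wq, Wk
        + h * d * dv  # Wv
        + h * dv * d  # Wo
        + 2 * d  # ln2
        + d * config.d_ff + config.d_ff  # W1, b1
        + config.d_ff * d + d  # W2, b2
    )
    head = d * config.mlp_hidden + config.mlp_hidden + config.mlp_hidden * config.n_classes + config.n_classes
    return config.L * per_layer + head


# ---------------------------------------------------------------------------
# forward primitives


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv)


def _layer_norm_backward(dout, cache, g):
    xhat, inv = cache
    dg = (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
    db = dout.sum(axis=tuple(range(dout.ndim - 1)))
    dxhat = dout * g
    m = dxhat.mean(axis=-1, keepdims=True)
    mx = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m - xhat * mx)
    return dx, dg, db


def self_attention(
    S: np.ndarray,
    Wq: np.ndarray,
    Wk: np.ndarray,
    Wv: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-head scaled dot-product self-attention.

    Parameters may be batched: ``S`` has shape (..., n, d_model).  Returns
    (output (..., n, d_v), attention (..., n, n)); attention rows sum to 1.
    """
    S = np.asarray(S, dtype=np.float64)
    if S.shape[-1] != Wq.shape[0]:
        raise ValueError(
            f"token width {S.shape[-1]} does not match projection input {Wq.shape[0]}"
        )
    d_k = Wq.shape[1]
    Q = S @ Wq
    K = S @ Wk
    V = S @ Wv
    A = _softmax(Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k))
    return A @ V, A


def multi_head_attention(
    S: np.ndarray,
    Wq: np.ndarray,
    Wk: np.ndarray,
    Wv: np.ndarray,
    Wo: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-head self-attention; head projections stacked on axis 0.

    ``Wq/Wk/Wv`` have shape (h, d_model, d_k|d_v), ``Wo`` (h*d_v, d_model).
    Returns (output (..., n, d_model), attention (..., h, n, n)).
    """
    outs = []
    atts = []
    for hd in range(Wq.shape[0]):
        o, a = self_attention(S, Wq[hd], Wk[hd], Wv[hd])
        outs.append(o)
        atts.append(a)
    concat = np.concatenate(outs, axis=-1)
    att = np.stack(atts, axis=-3)  # (..., h, n, n)
    return concat @ Wo, att


def _msa_forward(z: np.ndarray, Wq, Wk, Wv, Wo):
    """Batched MSA with cache for backprop.  z: (B, n, d)."""
    d_k = Wq.shape[-1]
    # (B, h, n, dk): einsum over token width
    Q = np.einsum("bnd,hde->bhne", z, Wq)
    K = np.einsum("bnd,hde->bhne", z, Wk)
    V = np.einsum("bnd,hde->bhne", z, Wv)
    P = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    A = _softmax(P)
    O = A @ V  # (B, h, n, dv)
    B, h, n, dv = O.shape
    concat = np.moveaxis(O, 1, 2).reshape(B, n, h * dv)
    y = concat @ Wo
    cache = (z, Q, K, V, A, concat)
    return y, A, cache


def _msa_backward(dy, cache, Wq, Wk, Wv, Wo):
    z, Q, K, V, A, concat = cache
    d_k = Wq.shape[-1]
    B, n, _ = z.shape
    h, dv = Wv.shape[0], Wv.shape[2]
    dWo = np.einsum("bnc,bnd->cd", concat, dy)
    dconcat = dy @ Wo.T
    dO = np.moveaxis(dconcat.reshape(B, n, h, dv), 2, 1)  # (B, h, n, dv)
    dA = dO @ np.swapaxes(V, -1, -2)
    dV = np.swapaxes(A, -1, -2) @ dO
    # softmax backward row-wise
    dP = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    dP = dP / np.sqrt(d_k)
    dQ = dP @ K
    dK = np.swapaxes(dP, -1, -2) @ Q
    dWq = np.einsum("bnd,bhne->hde", z, dQ)
    dWk = np.einsum("bnd,bhne->hde", z, dK)
    dWv = np.einsum("bnd,bhne->hde", z, dV)
    dz = (
        np.einsum("bhne,hde->bnd", dQ, Wq)
        + np.einsum("bhne,hde->bnd", dK, Wk)
        + np.einsum("bhne,hde->bnd", dV, Wv)
    )
    return dz, dWq, dWk, dWv, dWo


def _relu(x):
    return np.maximum(x, 0.0)


def _dropout_mask(shape, rate, rng):
    if rate <= 0.0 or rng is None:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


def encoder_forward(
    S0: np.ndarray,
    params: EncoderParams,
    config: EncoderConfig,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Run the L-layer encoder.

    Parameters
    ----------
    S0 : ndarray, (n, d_model) or (B, n, d_model)
        Channel-token feature maps.

    Returns
    -------
    (S_L, attention) where attention is a list of per-layer arrays of shape
    (B, h, n, n); optionally the backprop cache.
    """
    S0 = np.asarray(S0, dtype=np.float64)
    squeeze = S0.ndim == 2
    if squeeze:
        S0 = S0[None]
    if S0.shape[-1] != config.d_model:
        raise ValueError(
            f"input width {S0.shape[-1]} != d_model {config.d_model}"
        )
    S = S0
    att_layers = []
    caches = []
    drop = config.dropout if train_mode else 0.0
    for i in range(config.L):
        p = f"layer{i}/"
        z1, ln1_cache = _layer_norm(S, params[p + "ln1_g"], params[p + "ln1_b"])
        y, A, msa_cache = _msa_forward(
            z1, params[p + "Wq"], params[p + "Wk"], params[p + "Wv"], params[p + "Wo"]
        )
        mask_y = _dropout_mask(y.shape, drop, rng)
        if mask_y is not None:
            y = y * mask_y
        if config.standard_block:
            mid = S + y
            z2, ln2_cache = _layer_norm(mid, params[p + "ln2_g"], params[p + "ln2_b"])
        else:
            z2, ln2_cache = _layer_norm(y, params[p + "ln2_g"], params[p + "ln2_b"])
        pre = z2 @ params[p + "W1"] + params[p + "b1"]
        hdn = _relu(pre)
        mask_u = _dropout_mask(hdn.shape, drop, rng)
        if mask_u is not None:
            hdn = hdn * mask_u
        u = hdn @ params[p + "W2"] + params[p + "b2"]
        if config.standard_block:
            S_next = mid + u
        else:
            S_next = S + y + u
        if not np.isfinite(S_next).all():
            raise FloatingPointError(f"non-finite activations in encoder layer {i}")
        att_layers.append(A)
        caches.append((S, z1, ln1_cache, msa_cache, mask_y, y, ln2_cache, pre, mask_u, hdn, z2))
        S = S_next
    att_out = [a[0] if squeeze else a for a in att_layers]
    S_out = S[0] if squeeze else S
    if return_cache:
        return S_out, att_out, caches
    return S_out, att_out


def _encoder_backward(dS, caches, params, config, grads):
    for i in reversed(range(config.L)):
        p = f"layer{i}/"
        S_in, z1, ln1_cache, msa_cache, mask_y, y, ln2_cache, pre, mask_u, hdn, z2 = caches[i]
        # S_out = S_in + y + u  (or mid + u with mid = S_in + y)
        du = dS
        grads[p + "b2"] += du.sum(axis=(0, 1))
        grads[p + "W2"] += np.einsum("bnf,bnd->fd", hdn, du)
        dhdn = du @ params[p + "W2"].T
        if mask_u is not None:
            dhdn = dhdn * mask_u
        dpre = dhdn * (pre > 0)
        grads[p + "b1"] += dpre.sum(axis=(0, 1))
        grads[p + "W1"] += np.einsum("bnd,bnf->df", z2, dpre)
        dz2 = dpre @ params[p + "W1"].T
        dz2_in, dg2, db2 = _layer_norm_backward(dz2, ln2_cache, params[p + "ln2_g"])
        grads[p + "ln2_g"] += dg2
        grads[p + "ln2_b"] += db2
        if config.standard_block:
            dmid = dS + dz2_in
            dy = dmid
            dS_in = dmid
        else:
            dy = dS + dz2_in
            dS_in = dS
        if mask_y is not None:
            dy = dy * mask_y
        dz1, dWq, dWk, dWv, dWo = _msa_backward(
            dy, msa_cache, params[p + "Wq"], params[p + "Wk"], params[p + "Wv"], params[p + "Wo"]
        )
        grads[p + "Wq"] += dWq
        grads[p + "Wk"] += dWk
        grads[p + "Wv"] += dWv
        grads[p + "Wo"] += dWo
        dz1_in, dg1, db1 = _layer_norm_backward(dz1, ln1_cache, params[p + "ln1_g"])
        grads[p + "ln1_g"] += dg1
        grads[p + "ln1_b"] += db1
        dS = dS_in + dz1_in
    return dS


def classify(S_L: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Max-pool over channels, MLP head, softmax.

    ``S_L``: (n, d_model) or (B, n, d_model).  Returns probabilities
    (2,) or (B, 2) for (non-seizure, seizure), summing to 1.
    """
    S_L = np.asarray(S_L, dtype=np.float64)
    squeeze = S_L.ndim == 2
    if squeeze:
        S_L = S_L[None]
    if S_L.shape[1] == 0:
        raise ValueError("empty channel dimension")
    pooled = S_L.max(axis=1)
    hdn = _relu(pooled @ params["head/W1"] + params["head/b1"])
    logits = hdn @ params["head/W2"] + params["head/b2"]
    probs = _softmax(logits)
    return probs[0] if squeeze else probs


def _forward_loss(X, y, params, config, train_mode=False, rng=None):
    """Mean cross-entropy and cached intermediates.  X: (B, n, d)."""
    S_L, att, caches = encoder_forward(
        X, params, config, train_mode=train_mode, rng=rng, return_cache=True
    )
    B = X.shape[0]
    pooled_idx = S_L.argmax(axis=1)  # (B, d) channel index of max
    pooled = S_L.max(axis=1)
    pre_h = pooled @ params["head/W1"] + params["head/b1"]
    hdn = _relu(pre_h)
    logits = hdn @ params["head/W2"] + params["head/b2"]
    probs = _softmax(logits)
    loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-12))
    cache = (caches, S_L, pooled_idx, pooled, pre_h, hdn, probs)
    return loss, probs, cache


def _backward_loss(X, y, params, config, cache):
    caches, S_L, pooled_idx, pooled, pre_h, hdn, probs = cache
    B, n, d = X.shape
    grads = {k: np.zeros_like(params[k]) for k in params.keys()}
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads["head/b2"] += dlogits.sum(axis=0)
    grads["head/W2"] += hdn.T @ dlogits
    dhdn = dlogits @ params["head/W2"].T
    dpre = dhdn * (pre_h > 0)
    grads["head/b1"] += dpre.sum(axis=0)
    grads["head/W1"] += pooled.T @ dpre
    dpooled = dpre @ params["head/W1"].T  # (B, d)
    dS_L = np.zeros_like(S_L)
    b_idx = np.repeat(np.arange(B), d)
    d_idx = np.tile(np.arange(d), B)
    np.add.at(dS_L, (b_idx, pooled_idx.ravel(), d_idx), dpooled.ravel())
    _encoder_backward(dS_L, caches, params, config, grads)
    return grads


def predict_proba(
    maps: list[FeatureMap] | np.ndarray,
    params: EncoderParams,
    config: EncoderConfig,
) -> np.ndarray:
    """Class probabilities for a batch of feature maps; (N, 2)."""
    X = _stack_maps(maps)
    S_L, _ = encoder_forward(X, params, config)
    return classify(S_L, params)


def _stack_maps(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return maps
    return np.stack([m.values for m in maps])


def train(
    maps: list[FeatureMap] | np.ndarray,
    labels: np.ndarray,
    config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[EncoderParams, list[dict]]:
    """Fit the classifier by Adam on mean cross-entropy.

    A seeded fraction of the training set is held out for early stopping
    (patience on validation loss, best parameters restored).  Returns the
    trained parameters and a per-epoch log of train/validation losses.
    Deterministic for a fixed ``config.seed``.
    """
    config = config or EncoderConfig()
    tc = train_config or TrainConfig()
    X = _stack_maps(maps).astype(np.float64)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed)
    params = init_params(config, rng)

    n = X.shape[0]
    order = rng.permutation(n)
    n_val = max(1, int(round(tc.val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if np.unique(y[tr_idx]).size < 2:  # tiny sets: keep everything for training
        tr_idx = order
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    m_state = params.zeros_like()
    v_state = params.zeros_like()
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_params = params.copy()
    bad_epochs = 0
    log: list[dict] = []
    for epoch in range(tc.max_epochs):
        perm = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for start in range(0, len(Xtr), tc.batch_size):
            idx = perm[start : start + tc.batch_size]
            loss, _, cache = _forward_loss(
                Xtr[idx], ytr[idx], params, config, train_mode=True, rng=rng
            )
            grads = _backward_loss(Xtr[idx], ytr[idx], params, config, cache)
            step += 1
            for k in params.keys():
                g = grads[k]
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                mhat = m_state[k] / (1 - beta1**step)
                vhat = v_state[k] / (1 - beta2**step)
                params[k] = params[k] - tc.lr * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += loss * len(idx)
        epoch_loss /= len(Xtr)
        val_loss, _, _ = _forward_loss(Xval, yval, params, config)
        log.append({"epoch": epoch, "train_loss": float(epoch_loss), "val_loss": float(val_loss)})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = params.copy()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= tc.patience:
                break
    return best_params, log


def channel_attention(att: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Per-channel attention weights from the last encoder layer.

    The h head matrices of the final layer are summed element-wise and each
    column of the sum is averaged, giving one nonnegative weight per
    channel (columns index the attended-to channel).
    """
    if isinstance(att, list):
        att = att[-1]
    att = np.asarray(att, dtype=np.float64)
    if att.ndim != 3:
        raise ValueError("expected (h, n, n) attention matrices of the last layer")
    summed = att.sum(axis=0)  # (n, n)
    return summed.mean(axis=0)  # column averages


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path: str | Path, params: EncoderParams, config: EncoderConfig) -> None:
    """Single-file checkpoint: parameter arrays plus embedded config."""
    arrays = {k.replace("/", "__"): v for k, v in params.arrays.items()}
    np.savez(path, __config__=np.bytes_(json.dumps(asdict(config)).encode()), **arrays)


def load_checkpoint(path: str | Path) -> tuple[EncoderParams, EncoderConfig]:
    with np.load(path) as data:
        cfg = EncoderConfig(**json.loads(bytes(data["__config__"]).decode()))
        arrays = {
            k.replace("__", "/"): data[k] for k in data.files if k != "__config__"
        }
    return EncoderParams(arrays), cfg
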