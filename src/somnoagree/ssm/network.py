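"""Hierarchical epoch/sequence recurrent network, NumPy implementation.

The architecture follows the established hierarchical design for
spectrogram-based sleep staging:

1. a learned filter bank projecting the 101 spectral bins of each STFT
   frame onto a small set of frequency subbands;
2. an epoch-level bidirectional recurrent layer over the 29 frames of a
   30-s epoch, pooled by additive (content-based) attention into one
   epoch embedding;
3. a sequence-level bidirectional recurrent layer over a window of
   consecutive epoch embeddings, modelling stage-transition context;
4. a softmax layer over the six classes (five stages + Invalid).

Recurrent cells are single-gate tanh units; at the widths used here
(tens of units) they train quickly on CPU and expose the same sequential
inductive bias as gated cells.  Forward and backward passes are written
explicitly (no autodiff dependency); gradients are verified against
finite differences in the test suite.

All arrays are float64.  Shapes: input ``x`` is (batch, seq_len, frames,
bins); logits are (batch, seq_len, classes).
"""

from __future__ import annotations

import numpy as np

__all__ = ["init_params", "forward", "backward", "loss_and_grads", "Adam", "softmax"]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


def init_params(
    n_bins: int,
    filterbank: int,
    epoch_hidden: int,
    seq_hidden: int,
    attention: int,
    n_classes: int,
    seed: int,
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    H, S, A = epoch_hidden, seq_hidden, attention
    p = {
        "Wf": _glorot(rng, (n_bins, filterbank)),
        "bf": np.zeros(filterbank),
        # epoch-level BiRNN
        "Wx_ef": _glorot(rng, (filterbank, H)),
        "Wh_ef": _glorot(rng, (H, H)),
        "b_ef": np.zeros(H),
        "Wx_eb": _glorot(rng, (filterbank, H)),
        "Wh_eb": _glorot(rng, (H, H)),
        "b_eb": np.zeros(H),
        # attention
        "Wa": _glorot(rng, (2 * H, A)),
        "ba": np.zeros(A),
        "va": _glorot(rng, (A, 1))[:, 0],
        # sequence-level BiRNN
        "Wx_sf": _glorot(rng, (2 * H, S)),
        "Wh_sf": _glorot(rng, (S, S)),
        "b_sf": np.zeros(S),
        "Wx_sb": _glorot(rng, (2 * H, S)),
        "Wh_sb": _glorot(rng, (S, S)),
        "b_sb": np.zeros(S),
        # output
        "Wo": _glorot(rng, (2 * S, n_classes)),
        "bo": np.zeros(n_classes),
    }
    return p


def _rnn_forward(z: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Unidirectional tanh RNN over axis 1; returns hidden states (N, T, H)."""
    n, t_len, _ = z.shape
    h = np.zeros((n, t_len, Wh.shape[0]))
    prev = np.zeros((n, Wh.shape[0]))
    zx = z @ Wx + b
    for t in range(t_len):
        prev = np.tanh(zx[:, t] + prev @ Wh)
        h[:, t] = prev
    return h


def _rnn_backward(
    z: np.ndarray, h: np.ndarray, dh_out: np.ndarray, Wx: np.ndarray, Wh: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """BPTT for the tanh RNN.  Returns (dz, dWx, dWh, db)."""
    n, t_len, _ = z.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(Wh.shape[0])
    dz = np.zeros_like(z)
    dh_next = np.zeros((n, Wh.shape[0]))
    for t in range(t_len - 1, -1, -1):
        dh = dh_out[:, t] + dh_next
        da = dh * (1.0 - h[:, t] ** 2)
        dWx += z[:, t].T @ da
        if t > 0:
            dWh += h[:, t - 1].T @ da
        db += da.sum(axis=0)
        dz[:, t] = da @ Wx.T
        dh_next = da @ Wh.T
    return dz, dWx, dWh, db


def forward(p: dict[str, np.ndarray], x: np.ndarray) -> tuple[np.ndarray, dict]:
    """Full forward pass; returns (logits, cache)."""
    B, L, T, F = x.shape
    flat = x.reshape(B * L, T, F)
    a_f = flat @ p["Wf"] + p["bf"]
    z = np.tanh(a_f)  # (BL, T, K)

    hf = _rnn_forward(z, p["Wx_ef"], p["Wh_ef"], p["b_ef"])
    hb = _rnn_forward(z[:, ::-1], p["Wx_eb"], p["Wh_eb"], p["b_eb"])[:, ::-1]
    h = np.concatenate([hf, hb], axis=-1)  # (BL, T, 2H)

    u = np.tanh(h @ p["Wa"] + p["ba"])  # (BL, T, A)
    e = u @ p["va"]  # (BL, T)
    alpha = softmax(e, axis=1)
    c = np.matmul(alpha[:, None, :], h)[:, 0]  # (BL, 2H)

    cs = c.reshape(B, L, -1)
    sf = _rnn_forward(cs, p["Wx_sf"], p["Wh_sf"], p["b_sf"])
    sb = _rnn_forward(cs[:, ::-1], p["Wx_sb"], p["Wh_sb"], p["b_sb"])[:, ::-1]
    s = np.concatenate([sf, sb], axis=-1)  # (B, L, 2S)

    logits = s @ p["Wo"] + p["bo"]
    cache = dict(x=x, z=z, hf=hf, hb=hb, h=h, u=u, alpha=alpha, c=c, cs=cs, sf=sf, sb=sb, s=s)
    return logits, cache


def backward(p: dict[str, np.ndarray], cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
    x = cache["x"]
    B, L, T, F = x.shape
    g: dict[str, np.ndarray] = {}

    s = cache["s"]
    C = dlogits.shape[-1]
    g["Wo"] = s.reshape(-1, s.shape[-1]).T @ dlogits.reshape(-1, C)
    g["bo"] = dlogits.sum(axis=(0, 1))
    ds = dlogits @ p["Wo"].T
    S = cache["sf"].shape[-1]
    dsf, dsb = ds[..., :S], ds[..., S:]

    cs = cache["cs"]
    dcs_f, g["Wx_sf"], g["Wh_sf"], g["b_sf"] = _rnn_backward(
        cs, cache["sf"], dsf, p["Wx_sf"], p["Wh_sf"]
    )
    dcs_b_rev, g["Wx_sb"], g["Wh_sb"], g["b_sb"] = _rnn_backward(
        cs[:, ::-1], cache["sb"][:, ::-1], dsb[:, ::-1], p["Wx_sb"], p["Wh_sb"]
    )
    dcs = dcs_f + dcs_b_rev[:, ::-1]
    dc = dcs.reshape(B * L, -1)

    h, u, alpha = cache["h"], cache["u"], cache["alpha"]
    dalpha = np.matmul(h, dc[:, :, None])[:, :, 0]  # (BL, T)
    dh = alpha[..., None] * dc[:, None, :]
    de = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
    g["va"] = u.reshape(-1, u.shape[-1]).T @ de.reshape(-1)
    du = de[..., None] * p["va"]
    dpre_u = du * (1.0 - u**2)
    g["Wa"] = h.reshape(-1, h.shape[-1]).T @ dpre_u.reshape(-1, dpre_u.shape[-1])
    g["ba"] = dpre_u.sum(axis=(0, 1))
    dh += dpre_u @ p["Wa"].T

    H = cache["hf"].shape[-1]
    dhf, dhb = dh[..., :H], dh[..., H:]
    z = cache["z"]
    dz_f, g["Wx_ef"], g["Wh_ef"], g["b_ef"] = _rnn_backward(
        z, cache["hf"], dhf, p["Wx_ef"], p["Wh_ef"]
    )
    dz_b_rev, g["Wx_eb"], g["Wh_eb"], g["b_eb"] = _rnn_backward(
        z[:, ::-1], cache["hb"][:, ::-1], dhb[:, ::-1], p["Wx_eb"], p["Wh_eb"]
    )
    dz = dz_f + dz_b_rev[:, ::-1]

    da_f = dz * (1.0 - z**2)
    g["Wf"] = x.reshape(-1, F).T @ da_f.reshape(-1, da_f.shape[-1])
    g["bf"] = da_f.sum(axis=(0, 1))
    return g


def loss_and_grads(
    p: dict[str, np.ndarray], x: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Mean cross-entropy over all epochs; returns (loss, grads, probs)."""
    logits, cache = forward(p, x)
    probs = softmax(logits)
    B, L, C = logits.shape
    n = B * L
    onehot = np.zeros_like(probs)
    idx = np.indices((B, L))
    onehot[idx[0], idx[1], y] = 1.0
    loss = float(-np.sum(onehot * np.log(np.maximum(probs, 1e-12))) / n)
    dlogits = (probs - onehot) / n
    grads = backward(p, cache, dlogits)
    return loss, grads, probs


class Adam:
    """Plain Adam with per-parameter moment buffers."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk**2
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
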