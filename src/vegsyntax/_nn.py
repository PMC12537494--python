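"""Compact bidirectional transformer encoder in numpy.

Implements the standard pre-norm encoder block (multi-head self-attention
+ GELU feed-forward, residual connections, layer norm) with an explicit
backward pass and an Adam optimizer.  Position information uses fixed
sinusoidal encodings, so the model generalizes to sequence lengths beyond
those seen in training (needed for open-ended assemblage completion).
The token-prediction head is weight-tied to the input embedding.

Everything is float32 and deterministic given the RNG passed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["EncoderConfig", "Encoder", "Adam"]

_NEG = np.float32(-1e9)
_LN_EPS = np.float32(1e-5)
# tanh-approximation GELU constants
_GELU_C = np.float32(np.sqrt(2.0 / np.pi))
_GELU_A = np.float32(0.044715)


@dataclass(frozen=True)
class EncoderConfig:
    vocab_size: int
    n_layers: int = 2
    d_model: int = 64
    n_heads: int = 4
    d_ff: int = 256
    max_len: int = 256
    dropout: float = 0.0
    n_classes: int = 0  # >0 attaches a classification head
    #: multiplier on the sinusoidal position table.  Unit-scale sinusoids
    #: would be ~50x larger than the 0.02-std token embeddings and drown
    #: the token signal, stalling training at the unigram distribution.
    pos_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if min(self.vocab_size, self.n_layers, self.d_model, self.n_heads,
               self.d_ff, self.max_len) <= 0:
            raise ValueError("all sizes must be positive")


def _sinusoidal(max_len: int, d: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float32)


def _gelu(x: np.ndarray) -> np.ndarray:
    # tanh approximation (the form used by most transformer stacks);
    # x*x*x, not x**3 — numpy's float power is orders of magnitude slower
    return 0.5 * x * (1.0 + np.tanh(_GELU_C * (x + _GELU_A * (x * x * x))))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    x2 = x * x
    t = np.tanh(_GELU_C * (x + _GELU_A * (x2 * x)))
    dinner = _GELU_C * (1.0 + 3.0 * _GELU_A * x2)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner


def _ln_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv)


def _ln_backward(dy, cache, g):
    xhat, inv = cache
    d = xhat.shape[-1]
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx.astype(np.float32), dg.astype(np.float32), db.astype(np.float32)


def _softmax(x: np.ndarray) -> np.ndarray:
    x = x - x.max(-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(-1, keepdims=True)


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: Optional[float] = 1.0) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                                for g in grads.values()))
            if total > self.clip_norm:
                scale = np.float32(self.clip_norm / (total + 1e-12))
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= (self.lr * (self.m[k] / bc1)
                          / (np.sqrt(self.v[k] / bc2) + self.eps)).astype(np.float32)


class Encoder:
    """Transformer encoder with token head and optional classifier head."""

    def __init__(self, config: EncoderConfig,
                 rng: Optional[np.random.Generator] = None) -> None:
        self.config = config
        rng = rng or np.random.default_rng(0)
        c = config
        init = lambda *shape: rng.normal(0.0, 0.02, shape).astype(np.float32)
        p: dict[str, np.ndarray] = {"emb": init(c.vocab_size, c.d_model),
                                    "out_b": np.zeros(c.vocab_size, np.float32)}
        for l in range(c.n_layers):
            for name in ("wq", "wk", "wv", "wo"):
                p[f"l{l}.{name}"] = init(c.d_model, c.d_model)
                p[f"l{l}.{name}_b"] = np.zeros(c.d_model, np.float32)
            p[f"l{l}.w1"] = init(c.d_model, c.d_ff)
            p[f"l{l}.w1_b"] = np.zeros(c.d_ff, np.float32)
            p[f"l{l}.w2"] = init(c.d_ff, c.d_model)
            p[f"l{l}.w2_b"] = np.zeros(c.d_model, np.float32)
            for ln in ("ln1", "ln2"):
                p[f"l{l}.{ln}_g"] = np.ones(c.d_model, np.float32)
                p[f"l{l}.{ln}_b"] = np.zeros(c.d_model, np.float32)
        p["lnf_g"] = np.ones(c.d_model, np.float32)
        p["lnf_b"] = np.zeros(c.d_model, np.float32)
        if c.n_classes > 0:
            p["pool_w"] = init(c.d_model, c.d_model)
            p["pool_b"] = np.zeros(c.d_model, np.float32)
            p["cls_w"] = init(c.d_model, c.n_classes)
            p["cls_b"] = np.zeros(c.n_classes, np.float32)
        self.params = p
        self.pos = _sinusoidal(c.max_len, c.d_model) * np.float32(c.pos_scale)

    # -- forward --------------------------------------------------------------
    def forward(self, ids: np.ndarray, pad_id: int,
                drop_rng: Optional[np.random.Generator] = None):
        """Hidden states (B,T,d) plus the cache needed for backward.

        Pass ``drop_rng`` to enable (inverted) dropout on the two sublayer
        outputs during training; inference runs without it.
        """
        c, p = self.config, self.params
        B, T = ids.shape
        if T > c.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {c.max_len}")
        use_drop = drop_rng is not None and c.dropout > 0.0

        def drop_mask(shape):
            if not use_drop:
                return None
            keep = 1.0 - c.dropout
            return (drop_rng.random(shape) < keep).astype(np.float32) / keep

        key_pad = (ids == pad_id)  # (B,T) True at padded keys
        attn_bias = np.where(key_pad[:, None, None, :], _NEG, np.float32(0.0))
        x = p["emb"][ids] + self.pos[None, :T]
        cache: dict = {"ids": ids, "attn_bias": attn_bias, "layers": []}
        H, dh = c.n_heads, c.d_model // c.n_heads
        scale = np.float32(1.0 / np.sqrt(dh))
        for l in range(c.n_layers):
            lc: dict = {"x_in": x}
            h, lc["ln1"] = _ln_forward(x, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            lc["h1"] = h
            q = h @ p[f"l{l}.wq"] + p[f"l{l}.wq_b"]
            k = h @ p[f"l{l}.wk"] + p[f"l{l}.wk_b"]
            v = h @ p[f"l{l}.wv"] + p[f"l{l}.wv_b"]
            q = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            k = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            v = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            s = q @ k.transpose(0, 1, 3, 2) * scale + attn_bias
            a = _softmax(s)
            o = (a @ v).transpose(0, 2, 1, 3).reshape(B, T, c.d_model)
            lc.update(q=q, k=k, v=v, a=a, o_pre=o)
            attn_out = o @ p[f"l{l}.wo"] + p[f"l{l}.wo_b"]
            lc["m1"] = drop_mask(attn_out.shape)
            if lc["m1"] is not None:
                attn_out = attn_out * lc["m1"]
            x = x + attn_out
            lc["x_mid"] = x
            h2, lc["ln2"] = _ln_forward(x, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
            lc["h2"] = h2
            z = h2 @ p[f"l{l}.w1"] + p[f"l{l}.w1_b"]
            lc["z"] = z
            g = _gelu(z)
            lc["g"] = g
            ffn_out = g @ p[f"l{l}.w2"] + p[f"l{l}.w2_b"]
            lc["m2"] = drop_mask(ffn_out.shape)
            if lc["m2"] is not None:
                ffn_out = ffn_out * lc["m2"]
            x = x + ffn_out
            cache["layers"].append(lc)
        cache["x_f"] = x
        hfinal, cache["lnf"] = _ln_forward(x, p["lnf_g"], p["lnf_b"])
        cache["hfinal"] = hfinal
        return hfinal, cache

    def _backward(self, dH: np.ndarray, cache: dict,
                  grads: dict[str, np.ndarray]) -> None:
        """Backprop dH (gradient at the final hidden states) into grads."""
        c, p = self.config, self.params
        ids = cache["ids"]
        B, T = ids.shape
        H, dh = c.n_heads, c.d_model // c.n_heads
        scale = np.float32(1.0 / np.sqrt(dh))

        dx, dg, db = _ln_backward(dH, cache["lnf"], p["lnf_g"])
        grads["lnf_g"] = grads.get("lnf_g", 0) + dg
        grads["lnf_b"] = grads.get("lnf_b", 0) + db

        def acc(key, val):
            grads[key] = grads.get(key, 0) + val.astype(np.float32)

        for l in reversed(range(c.n_layers)):
            lc = cache["layers"][l]
            # FFN branch: x = x_mid + gelu(LN2(x_mid) @ w1) @ w2
            dffn = dx if lc["m2"] is None else dx * lc["m2"]
            acc(f"l{l}.w2", lc["g"].reshape(-1, c.d_ff).T
                @ dffn.reshape(-1, c.d_model))
            acc(f"l{l}.w2_b", dffn.sum((0, 1)))
            dgel = dffn @ p[f"l{l}.w2"].T
            dz = dgel * _gelu_grad(lc["z"])
            acc(f"l{l}.w1", lc["h2"].reshape(-1, c.d_model).T
                @ dz.reshape(-1, c.d_ff))
            acc(f"l{l}.w1_b", dz.sum((0, 1)))
            dh2 = dz @ p[f"l{l}.w1"].T
            dx_mid, dg2, db2 = _ln_backward(dh2, lc["ln2"], p[f"l{l}.ln2_g"])
            acc(f"l{l}.ln2_g", dg2)
            acc(f"l{l}.ln2_b", db2)
            dx = dx + dx_mid  # residual

            # attention branch: x_mid = x_in + (A V) Wo
            do_proj = dx if lc["m1"] is None else dx * lc["m1"]
            acc(f"l{l}.wo", lc["o_pre"].reshape(-1, c.d_model).T
                @ do_proj.reshape(-1, c.d_model))
            acc(f"l{l}.wo_b", do_proj.sum((0, 1)))
            do = (do_proj @ p[f"l{l}.wo"].T).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            a, q, k, v = lc["a"], lc["q"], lc["k"], lc["v"]
            da = do @ v.transpose(0, 1, 3, 2)
            dv = a.transpose(0, 1, 3, 2) @ do
            ds = a * (da - (da * a).sum(-1, keepdims=True))
            dq = ds @ k * scale
            dk = ds.transpose(0, 1, 3, 2) @ q * scale
            dq = dq.transpose(0, 2, 1, 3).reshape(B, T, c.d_model)
            dk = dk.transpose(0, 2, 1, 3).reshape(B, T, c.d_model)
            dv = dv.transpose(0, 2, 1, 3).reshape(B, T, c.d_model)
            h1 = lc["h1"].reshape(-1, c.d_model)
            acc(f"l{l}.wq", h1.T @ dq.reshape(-1, c.d_model))
            acc(f"l{l}.wq_b", dq.sum((0, 1)))
            acc(f"l{l}.wk", h1.T @ dk.reshape(-1, c.d_model))
            acc(f"l{l}.wk_b", dk.sum((0, 1)))
            acc(f"l{l}.wv", h1.T @ dv.reshape(-1, c.d_model))
            acc(f"l{l}.wv_b", dv.sum((0, 1)))
            dh1 = (dq @ p[f"l{l}.wq"].T + dk @ p[f"l{l}.wk"].T
                   + dv @ p[f"l{l}.wv"].T)
            dx_in, dg1, db1 = _ln_backward(dh1, lc["ln1"], p[f"l{l}.ln1_g"])
            acc(f"l{l}.ln1_g", dg1)
            acc(f"l{l}.ln1_b", db1)
            dx = dx + dx_in

        demb = grads.get("emb")
        if demb is None or np.isscalar(demb):
            demb = np.zeros_like(p["emb"])
            grads["emb"] = demb
        np.add.at(demb, ids.reshape(-1), dx.reshape(-1, c.d_model))

    # -- losses ---------------------------------------------------------------
    def lm_logits(self, hidden: np.ndarray) -> np.ndarray:
        return hidden @ self.params["emb"].T + self.params["out_b"]

    def mlm_loss_and_grads(self, ids: np.ndarray, labels: np.ndarray,
                           pad_id: int, ignore: int = -100,
                           drop_rng: Optional[np.random.Generator] = None):
        """Mean masked-position cross-entropy and parameter gradients."""
        hidden, cache = self.forward(ids, pad_id, drop_rng=drop_rng)
        sel = labels != ignore
        n = int(sel.sum())
        if n == 0:
            return 0.0, {}
        hs = hidden[sel]                       # (n, d)
        logits = self.lm_logits(hs)            # (n, V)
        probs = _softmax(logits)
        y = labels[sel]
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads: dict[str, np.ndarray] = {}
        grads["out_b"] = dlogits.sum(0).astype(np.float32)
        grads["emb"] = (dlogits.T @ hs).astype(np.float32)  # tied head
        dhs = dlogits @ self.params["emb"]
        dH = np.zeros_like(hidden)
        dH[sel] = dhs
        self._backward(dH, cache, grads)
        return loss, grads

    def _pool(self, hidden: np.ndarray, ids: np.ndarray, pad_id: int):
        """Masked mean over non-pad positions (the pooled sequence state).

        Mean pooling is much better conditioned than single-slot [CLS]
        pooling for compact from-scratch encoders: every position feeds
        the classification gradient from the first step.
        """
        valid = (ids != pad_id).astype(np.float32)[:, :, None]
        n_valid = valid.sum(1)
        return (hidden * valid).sum(1) / n_valid, valid, n_valid

    def cls_loss_and_grads(self, ids: np.ndarray, y: np.ndarray, pad_id: int,
                           drop_rng: Optional[np.random.Generator] = None,
                           head_dropout: float = 0.0):
        """Mean classification cross-entropy via the pooled sequence state."""
        p = self.params
        hidden, cache = self.forward(ids, pad_id, drop_rng=drop_rng)
        h_cls, valid, n_valid = self._pool(hidden, ids, pad_id)
        pre = h_cls @ p["pool_w"] + p["pool_b"]
        pooled = np.tanh(pre)
        head_mask = None
        if drop_rng is not None and head_dropout > 0.0:
            keep = 1.0 - head_dropout
            head_mask = ((drop_rng.random(pooled.shape) < keep)
                         .astype(np.float32) / keep)
            pooled = pooled * head_mask
        logits = pooled @ p["cls_w"] + p["cls_b"]
        probs = _softmax(logits)
        B = len(y)
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-12)))
        dlogits = probs
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {
            "cls_w": (pooled.T @ dlogits).astype(np.float32),
            "cls_b": dlogits.sum(0).astype(np.float32)}
        dpooled = dlogits @ p["cls_w"].T
        if head_mask is not None:
            dpooled = dpooled * head_mask
            pooled = np.tanh(pre)  # pre-dropout activation for the tanh grad
        dpre = dpooled * (1.0 - pooled * pooled)
        grads["pool_w"] = (h_cls.T @ dpre).astype(np.float32)
        grads["pool_b"] = dpre.sum(0).astype(np.float32)
        dh_pool = dpre @ p["pool_w"].T
        dH = ((dh_pool[:, None, :] / n_valid[:, None, :]) * valid).astype(np.float32)
        self._backward(dH, cache, grads)
        return loss, grads

    # -- inference ------------------------------------------------------------
    def predict_lm_logits(self, ids: np.ndarray, pad_id: int) -> np.ndarray:
        hidden, _ = self.forward(ids, pad_id)
        return self.lm_logits(hidden)

    def predict_cls_probs(self, ids: np.ndarray, pad_id: int) -> np.ndarray:
        p = self.params
        hidden, _ = self.forward(ids, pad_id)
        h_pool, _, _ = self._pool(hidden, ids, pad_id)
        pooled = np.tanh(h_pool @ p["pool_w"] + p["pool_b"])
        return _softmax(pooled @ p["cls_w"] + p["cls_b"])
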