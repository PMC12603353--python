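"""Compact transformer encoder classifier for segment-level lifestyle calls.

Architecture: token + learned absolute position embeddings, a stack of
pre-norm transformer layers (multi-head self-attention + GELU feed-forward),
a final LayerNorm, and a learnable-weight pooling head: a trainable scoring
vector assigns one scalar per real token position, the scores are
softmax-normalized over real (non-PAD) positions, and the pooled vector is
the score-weighted sum of hidden states.  A linear map to two logits and a
softmax give (p_temperate, p_virulent); temperate is class 0 (the negative
class), virulent is class 1.

The network and its gradients are written directly in NumPy, with an AdamW
optimizer (decoupled weight decay) and a seeded training loop that is
bit-reproducible on a single device.  Two presets are provided: a
desk-scale model (2 layers, 4 heads, width 64) that trains on a CPU in
minutes, and a paper-scale preset (6 layers, 6 heads).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .segmentation import Segment
from .tokenization import LCATokenizer
from .sequence_io import TEMPERATE, VIRULENT

CLASS_ORDER = (TEMPERATE, VIRULENT)  # temperate = 0 (negative), virulent = 1


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int = 2
    n_heads: int = 4
    hidden_dim: int = 64
    ff_dim: Optional[int] = None  # default 4 * hidden_dim
    vocab_size: int = 4100
    max_len: int = 512
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def ff(self) -> int:
        return self.ff_dim if self.ff_dim is not None else 4 * self.hidden_dim


def tiny_config(vocab_size: int, max_len: int = 512, **kw) -> ModelConfig:
    """Desk-scale preset: 2 layers, 4 heads, width 64."""
    return ModelConfig(n_layers=2, n_heads=4, hidden_dim=64,
                       vocab_size=vocab_size, max_len=max_len, **kw)


def paper_scale_config(vocab_size: int, max_len: int = 512, **kw) -> ModelConfig:
    """Full-scale preset mirroring the published head: 6 layers, 6 heads."""
    return ModelConfig(n_layers=6, n_heads=6, hidden_dim=384,
                       vocab_size=vocab_size, max_len=max_len, **kw)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 5
    seed: int = 0
    weight_decay: float = 0.01
    optimizer: str = "adamw"
    loss: str = "cross_entropy"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adamw" or self.loss != "cross_entropy":
            raise ValueError("only AdamW + cross-entropy are implemented")


@dataclass
class SegmentPrediction:
    segment: Optional[Segment]
    p_virulent: float
    p_temperate: float
    flagged: bool = False  # True for too-short inputs given neutral p = 0.5

    def __post_init__(self) -> None:
        if abs(self.p_virulent + self.p_temperate - 1.0) > 1e-6:
            raise ValueError("class probabilities must sum to 1")


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def init_params(cfg: ModelConfig, rng: np.random.Generator, dtype=np.float32) -> dict:
    d, f = cfg.hidden_dim, cfg.ff
    std = 0.02

    def W(*shape):
        return rng.normal(0.0, std, size=shape).astype(dtype)

    p = {
        "tok_emb": W(cfg.vocab_size, d),
        "pos_emb": W(cfg.max_len, d),
        "ln_f_g": np.ones(d, dtype=dtype),
        "ln_f_b": np.zeros(d, dtype=dtype),
        "pool_u": W(d),
        "cls_W": W(d, 2),
        "cls_b": np.zeros(2, dtype=dtype),
    }
    for i in range(cfg.n_layers):
        p[f"l{i}_ln1_g"] = np.ones(d, dtype=dtype)
        p[f"l{i}_ln1_b"] = np.zeros(d, dtype=dtype)
        for name in ("q", "k", "v", "o"):
            p[f"l{i}_W{name}"] = W(d, d)
            p[f"l{i}_b{name}"] = np.zeros(d, dtype=dtype)
        p[f"l{i}_ln2_g"] = np.ones(d, dtype=dtype)
        p[f"l{i}_ln2_b"] = np.zeros(d, dtype=dtype)
        p[f"l{i}_W1"] = W(d, f)
        p[f"l{i}_b1"] = np.zeros(f, dtype=dtype)
        p[f"l{i}_W2"] = W(f, d)
        p[f"l{i}_b2"] = np.zeros(d, dtype=dtype)
    return p


# ---------------------------------------------------------------------------
# primitives (forward + backward)
# ---------------------------------------------------------------------------

_LN_EPS = 1e-5


def _layernorm_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, dg, db


_GELU_C = math.sqrt(2.0 / math.pi)


def _gelu_fwd(x):
    inner = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    return 0.5 * x * (1.0 + t), (x, t)


def _gelu_bwd(dy, cache):
    x, t = cache
    dinner = _GELU_C * (1.0 + 3 * 0.044715 * x**2)
    return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner)


def _softmax(x, axis=-1):
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# full model forward / backward
# ---------------------------------------------------------------------------

def forward(params: dict, cfg: ModelConfig, ids: np.ndarray, mask: np.ndarray,
            want_cache: bool = False, drop_rng: Optional[np.random.Generator] = None):
    """Logits (B, 2) for a batch of id/mask matrices.

    PAD positions are excluded both from attention (additive -inf bias on
    PAD keys) and from pooling (scores masked before the softmax), so they
    contribute exactly zero weight.  Inverted dropout on the two residual
    branches is active only when ``drop_rng`` is supplied (training).
    """
    B, L = ids.shape
    H, d = cfg.n_heads, cfg.hidden_dim
    dh = d // H
    dtype = params["tok_emb"].dtype
    maskf = mask.astype(dtype)
    neg = np.asarray(-1e9, dtype=dtype)

    p_drop = cfg.dropout if drop_rng is not None else 0.0

    def _dropout(a):
        if p_drop <= 0:
            return a, None
        keep = (drop_rng.random(a.shape) >= p_drop).astype(a.dtype) / (1 - p_drop)
        return a * keep, keep

    x = params["tok_emb"][ids] + params["pos_emb"][:L]
    att_bias = (1.0 - maskf)[:, None, None, :] * neg  # (B,1,1,L) on keys
    caches = []
    for i in range(cfg.n_layers):
        xn, ln1c = _layernorm_fwd(x, params[f"l{i}_ln1_g"], params[f"l{i}_ln1_b"])
        q = xn @ params[f"l{i}_Wq"] + params[f"l{i}_bq"]
        k = xn @ params[f"l{i}_Wk"] + params[f"l{i}_bk"]
        v = xn @ params[f"l{i}_Wv"] + params[f"l{i}_bv"]
        qh = q.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        kh = k.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        vh = v.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        att = qh @ kh.transpose(0, 1, 3, 2) / np.asarray(math.sqrt(dh), dtype) + att_bias
        A = _softmax(att)
        oh = A @ vh  # (B,H,L,dh)
        o = oh.transpose(0, 2, 1, 3).reshape(B, L, d)
        attn_out = o @ params[f"l{i}_Wo"] + params[f"l{i}_bo"]
        attn_out, attn_keep = _dropout(attn_out)
        x1 = x + attn_out
        x1n, ln2c = _layernorm_fwd(x1, params[f"l{i}_ln2_g"], params[f"l{i}_ln2_b"])
        hmid = x1n @ params[f"l{i}_W1"] + params[f"l{i}_b1"]
        hact, geluc = _gelu_fwd(hmid)
        ffn_out = hact @ params[f"l{i}_W2"] + params[f"l{i}_b2"]
        ffn_out, ffn_keep = _dropout(ffn_out)
        x = x1 + ffn_out
        if want_cache:
            caches.append((xn, ln1c, qh, kh, vh, A, o, x1, x1n, ln2c, hact, geluc,
                           attn_keep, ffn_keep))

    h, lnfc = _layernorm_fwd(x, params["ln_f_g"], params["ln_f_b"])
    scores = h @ params["pool_u"]  # (B, L)
    scores = np.where(mask > 0, scores, neg)
    alpha = _softmax(scores)  # zero weight on PAD positions
    pooled = np.einsum("bl,bld->bd", alpha, h)
    logits = pooled @ params["cls_W"] + params["cls_b"]
    if not want_cache:
        return logits
    cache = {
        "ids": ids, "maskf": maskf, "caches": caches, "h": h, "lnfc": lnfc,
        "alpha": alpha, "pooled": pooled, "L": L,
    }
    return logits, cache


def backward(params: dict, cfg: ModelConfig, cache: dict, dlogits: np.ndarray) -> dict:
    """Gradients for every parameter given d(loss)/d(logits)."""
    B = dlogits.shape[0]
    H, d = cfg.n_heads, cfg.hidden_dim
    dh = d // H
    L = cache["L"]
    h, alpha, pooled = cache["h"], cache["alpha"], cache["pooled"]
    grads: dict = {}

    grads["cls_W"] = pooled.T @ dlogits
    grads["cls_b"] = dlogits.sum(0)
    dpooled = dlogits @ params["cls_W"].T  # (B, d)

    dalpha = np.einsum("bd,bld->bl", dpooled, h)
    dh_pool = alpha[:, :, None] * dpooled[:, None, :]
    # softmax backward over positions (PAD alphas are exactly 0, so masked
    # score gradients vanish automatically)
    dscores = alpha * (dalpha - (dalpha * alpha).sum(-1, keepdims=True))
    grads["pool_u"] = np.einsum("bl,bld->d", dscores, h)
    dh_total = dh_pool + dscores[:, :, None] * params["pool_u"][None, None, :]

    dx, dg, db = _layernorm_bwd(dh_total, cache["lnfc"])
    grads["ln_f_g"], grads["ln_f_b"] = dg, db

    for i in reversed(range(cfg.n_layers)):
        (xn, ln1c, qh, kh, vh, A, o, x1, x1n, ln2c, hact, geluc,
         attn_keep, ffn_keep) = cache["caches"][i]
        # FFN branch
        dffn_out = dx if ffn_keep is None else dx * ffn_keep
        grads[f"l{i}_W2"] = hact.reshape(-1, hact.shape[-1]).T @ dffn_out.reshape(-1, d)
        grads[f"l{i}_b2"] = dffn_out.sum((0, 1))
        dhact = dffn_out @ params[f"l{i}_W2"].T
        dhmid = _gelu_bwd(dhact, geluc)
        grads[f"l{i}_W1"] = x1n.reshape(-1, d).T @ dhmid.reshape(-1, dhmid.shape[-1])
        grads[f"l{i}_b1"] = dhmid.sum((0, 1))
        dx1n = dhmid @ params[f"l{i}_W1"].T
        dx1_ln, dg, db = _layernorm_bwd(dx1n, ln2c)
        grads[f"l{i}_ln2_g"], grads[f"l{i}_ln2_b"] = dg, db
        dx1 = dx + dx1_ln
        # attention branch
        dattn_out = dx1 if attn_keep is None else dx1 * attn_keep
        grads[f"l{i}_Wo"] = o.reshape(-1, d).T @ dattn_out.reshape(-1, d)
        grads[f"l{i}_bo"] = dattn_out.sum((0, 1))
        do = dattn_out @ params[f"l{i}_Wo"].T
        doh = do.reshape(-1, L, H, dh).transpose(0, 2, 1, 3)
        dA = doh @ vh.transpose(0, 1, 3, 2)
        dvh = A.transpose(0, 1, 3, 2) @ doh
        datt = A * (dA - (dA * A).sum(-1, keepdims=True))
        scale = 1.0 / math.sqrt(dh)
        dqh = (datt @ kh) * scale
        dkh = (datt.transpose(0, 1, 3, 2) @ qh) * scale
        dq = dqh.transpose(0, 2, 1, 3).reshape(-1, L, d)
        dk = dkh.transpose(0, 2, 1, 3).reshape(-1, L, d)
        dv = dvh.transpose(0, 2, 1, 3).reshape(-1, L, d)
        dxn = dq @ params[f"l{i}_Wq"].T + dk @ params[f"l{i}_Wk"].T + dv @ params[f"l{i}_Wv"].T
        xn2 = xn.reshape(-1, d)
        grads[f"l{i}_Wq"] = xn2.T @ dq.reshape(-1, d)
        grads[f"l{i}_Wk"] = xn2.T @ dk.reshape(-1, d)
        grads[f"l{i}_Wv"] = xn2.T @ dv.reshape(-1, d)
        grads[f"l{i}_bq"] = dq.sum((0, 1))
        grads[f"l{i}_bk"] = dk.sum((0, 1))
        grads[f"l{i}_bv"] = dv.sum((0, 1))
        dx_ln, dg, db = _layernorm_bwd(dxn, ln1c)
        grads[f"l{i}_ln1_g"], grads[f"l{i}_ln1_b"] = dg, db
        dx = dx1 + dx_ln

    # embeddings
    grads["pos_emb"] = np.zeros_like(params["pos_emb"])
    grads["pos_emb"][:L] = dx.sum(0)
    dtok = np.zeros_like(params["tok_emb"])
    np.add.at(dtok, cache["ids"].reshape(-1), dx.reshape(-1, d))
    grads["tok_emb"] = dtok
    return grads


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE loss over the batch and d(loss)/d(logits)."""
    p = _softmax(logits.astype(np.float64))
    B = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(B), y], 1e-300)).mean()
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return float(loss), (dlogits / B).astype(logits.dtype)


class AdamW:
    """AdamW with decoupled weight decay (applied to matrices only)."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for key, p in params.items():
            g = grads[key]
            m = self.m[key]
            v = self.v[key]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.wd and p.ndim >= 2:
                p -= self.lr * self.wd * p
            p -= self.lr * update


# ---------------------------------------------------------------------------
# the classifier object
# ---------------------------------------------------------------------------

class EncoderClassifier:
    """Transformer encoder + pooling head bound to an LCA tokenizer."""

    def __init__(self, config: ModelConfig, tokenizer: LCATokenizer,
                 seed: int = 0, dtype=np.float32):
        if config.vocab_size != len(tokenizer.vocab):
            raise ValueError("config.vocab_size disagrees with the tokenizer vocabulary")
        self.config = config
        self.tokenizer = tokenizer
        self.seed = seed
        self.dtype = dtype
        self.params = init_params(config, np.random.default_rng(seed), dtype=dtype)

    # -- inference ---------------------------------------------------------

    def forward_ids(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Class probabilities (B, 2) ordered (temperate, virulent)."""
        if ids.max(initial=0) >= self.config.vocab_size:
            raise ValueError("token id out of vocabulary range")
        if ids.shape[0] == 0:
            raise ValueError("empty batch")
        logits = forward(self.params, self.config, ids, mask)
        return _softmax(logits.astype(np.float64))

    def predict_segments(self, segments: Sequence[Segment],
                         batch_size: int = 64) -> list[SegmentPrediction]:
        """Per-segment probabilities, output order = input order.

        Segments shorter than the tokenizer's k cannot be tokenized and get
        a neutral flagged p = 0.5 instead of an error.
        """
        if not segments:
            raise ValueError("no segments to predict")
        preds: list[Optional[SegmentPrediction]] = [None] * len(segments)
        encodable: list[int] = []
        for idx, seg in enumerate(segments):
            if len(seg.seq) < self.tokenizer.k:
                preds[idx] = SegmentPrediction(seg, 0.5, 0.5, flagged=True)
            else:
                encodable.append(idx)
        for lo in range(0, len(encodable), batch_size):
            chunk = encodable[lo : lo + batch_size]
            enc = [self.tokenizer.encode(segments[i].seq) for i in chunk]
            ids = np.stack([e.ids for e in enc])
            mask = np.stack([e.attention_mask for e in enc])
            probs = self.forward_ids(ids, mask)
            for row, i in enumerate(chunk):
                preds[i] = SegmentPrediction(
                    segments[i], p_virulent=float(probs[row, 1]),
                    p_temperate=float(probs[row, 0]),
                )
        return preds  # type: ignore[return-value]

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params)
        sidecar = {
            "model_config": asdict(self.config),
            "tokenizer": self.tokenizer.settings(),
            "seed": self.seed,
            "class_order": list(CLASS_ORDER),
            "vocab_hash": hash(self.tokenizer.vocab.tokens) & 0xFFFFFFFF,
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "EncoderClassifier":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        tok = LCATokenizer(**sidecar["tokenizer"])
        model = cls(ModelConfig(**sidecar["model_config"]), tok, seed=sidecar["seed"])
        with np.load(directory / "weights.npz") as data:
            model.params = {k: data[k] for k in data.files}
        return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class EpochTrace:
    epoch: int
    train_loss: float
    val_balanced_accuracy: float


@dataclass
class TrainResult:
    history: list[EpochTrace]
    best_epoch: int
    best_val_balanced_accuracy: float


def _encode_segments(segments: Sequence[Segment], tokenizer: LCATokenizer):
    enc = [tokenizer.encode(s.seq) for s in segments]
    ids = np.stack([e.ids for e in enc])
    mask = np.stack([e.attention_mask for e in enc])
    y = np.array([1 if s.label == VIRULENT else 0 for s in segments], dtype=np.int64)
    return ids, mask, y


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    accs = []
    for cls in (0, 1):
        sel = y_true == cls
        if sel.any():
            accs.append(float((y_pred[sel] == cls).mean()))
    return float(np.mean(accs))


def train(model: EncoderClassifier, train_segments: Sequence[Segment],
          val_segments: Sequence[Segment], cfg: TrainConfig) -> TrainResult:
    """Fine-tune/train the classifier; retains the best-validation weights.

    Raises on single-class training data and aborts on NaN loss.  Identical
    (seed, data, device) yields bitwise-identical loss traces.
    """
    labels = {s.label for s in train_segments}
    if len(labels - {None}) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    ids, mask, y = _encode_segments(train_segments, model.tokenizer)
    vids, vmask, vy = _encode_segments(val_segments, model.tokenizer) if val_segments else (None, None, None)
    opt = AdamW(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history: list[EpochTrace] = []
    best = (-1.0, -1, None)  # (val balacc, epoch, params snapshot)
    n = len(train_segments)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        drop_rng = rng if model.config.dropout > 0 else None
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            logits, cache = forward(model.params, model.config, ids[sel], mask[sel],
                                    want_cache=True, drop_rng=drop_rng)
            loss, dlogits = cross_entropy(logits, y[sel])
            if not math.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            grads = backward(model.params, model.config, cache, dlogits)
            opt.step(model.params, grads)
            losses.append(loss)
        if vids is not None and len(vids):
            probs = _predict_ids(model, vids, vmask, cfg.batch_size)
            val_bal = _balanced_accuracy(vy, (probs[:, 1] >= 0.5).astype(np.int64))
        else:
            val_bal = float("nan")
        history.append(EpochTrace(epoch, float(np.mean(losses)), val_bal))
        if not math.isnan(val_bal) and val_bal > best[0]:
            best = (val_bal, epoch, {k: v.copy() for k, v in model.params.items()})
    if best[2] is not None:
        model.params = best[2]
    return TrainResult(history=history, best_epoch=best[1],
                       best_val_balanced_accuracy=best[0])


def _predict_ids(model: EncoderClassifier, ids, mask, batch_size: int) -> np.ndarray:
    out = []
    for lo in range(0, len(ids), batch_size):
        out.append(model.forward_ids(ids[lo : lo + batch_size], mask[lo : lo + batch_size]))
    return np.concatenate(out)
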