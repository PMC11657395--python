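"""The network: sequence CNN, token assembly, transformer encoder, heads.

The model maps a one-hot DNA window plus a per-bin TF feature block to K
epigenomic signal tracks, one value per bin per track. Architecture:

* sequence module — five 1-D convolution blocks (conv, ReLU, max-pool) whose
  pool factors multiply to the bin size, so an L-bp window becomes
  L/bin_size tokens of C sequence channels;
* token assembly — concatenation of the C sequence channels with the
  n_tf_padded TF features of each bin (d_model = C + n_tf_padded);
* transformer module — N_t post-norm encoder layers (multi-head
  self-attention, add & norm, feed-forward, add & norm) over the tokens,
  with a learned absolute position embedding added once before layer 1;
* prediction module — an affine map per token to K signals (regression) or
  affine + sigmoid (classification).

Everything is implemented over ``autograd.numpy`` so losses and attribution
scores can be differentiated with reverse-mode autodiff; parameters live in a
flat ``dict[str, ndarray]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import autograd.numpy as anp


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    input_length: int = 128_000
    bin_size: int = 128
    seq_channels: int = 256
    n_tf_padded: int = 712
    n_heads: int = 8
    n_layers: int = 12
    n_signals: int = 8
    head_type: str = "regression"
    pool_factors: tuple[int, ...] = (2, 2, 2, 4, 4)
    conv_kernel: int = 9
    ffn_mult: int = 4

    def __post_init__(self) -> None:
        if self.head_type not in ("regression", "classification"):
            raise ValueError(f"unknown head_type {self.head_type!r}")
        if int(np.prod(self.pool_factors)) != self.bin_size:
            raise ValueError(
                f"product of pool_factors {self.pool_factors} must equal "
                f"bin_size {self.bin_size}"
            )
        if self.input_length % self.bin_size:
            raise ValueError("input_length must be a multiple of bin_size")
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}"
            )

    @property
    def d_model(self) -> int:
        return self.seq_channels + self.n_tf_padded

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    @property
    def tokens(self) -> int:
        return self.input_length // self.bin_size

    @property
    def ffn_dim(self) -> int:
        return self.ffn_mult * self.d_model

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["pool_factors"] = tuple(d["pool_factors"])
        return cls(**d)


#: Full-scale profile: 128-kb windows, 1000 tokens of width 968.
FULL_SCALE_CONFIG = ModelConfig()

#: Desk-scale profile used by the synthetic recovery experiments.
TOY_CONFIG = ModelConfig(
    input_length=4096,
    bin_size=128,
    seq_channels=16,
    n_tf_padded=8,
    n_heads=4,
    n_layers=2,
    n_signals=8,
    conv_kernel=5,
)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def init_params(
    config: ModelConfig,
    rng: np.random.Generator,
    dtype=np.float64,
) -> dict:
    """He/Glorot-style initialization of all trainable tensors.

    ``dtype=np.float32`` halves memory traffic for desk-scale training;
    float64 is the default for oracle-grade numerics.
    """
    p: dict[str, np.ndarray] = {}
    k = config.conv_kernel
    c_in = 4
    for i in range(len(config.pool_factors)):
        c_out = config.seq_channels
        p[f"conv{i}_W"] = rng.normal(0, np.sqrt(2.0 / (k * c_in)), (k, c_in, c_out))
        p[f"conv{i}_b"] = np.zeros(c_out)
        c_in = c_out
    d, h, dh = config.d_model, config.n_heads, config.d_head
    p["pos_emb"] = rng.normal(0, 0.02, (config.tokens, d))
    for l in range(config.n_layers):
        s = np.sqrt(1.0 / d)
        p[f"l{l}_Wq"] = rng.normal(0, s, (h, d, dh))
        p[f"l{l}_Wk"] = rng.normal(0, s, (h, d, dh))
        p[f"l{l}_Wv"] = rng.normal(0, s, (h, d, dh))
        p[f"l{l}_Wo"] = rng.normal(0, np.sqrt(1.0 / d), (h * dh, d))
        p[f"l{l}_bo"] = np.zeros(d)
        p[f"l{l}_ln1_g"] = np.ones(d)
        p[f"l{l}_ln1_b"] = np.zeros(d)
        p[f"l{l}_W1"] = rng.normal(0, np.sqrt(2.0 / d), (d, config.ffn_dim))
        p[f"l{l}_b1"] = np.zeros(config.ffn_dim)
        p[f"l{l}_W2"] = rng.normal(0, np.sqrt(1.0 / config.ffn_dim),
                                   (config.ffn_dim, d))
        p[f"l{l}_b2"] = np.zeros(d)
        p[f"l{l}_ln2_g"] = np.ones(d)
        p[f"l{l}_ln2_b"] = np.zeros(d)
    p["head_W"] = rng.normal(0, np.sqrt(1.0 / d), (d, config.n_signals))
    p["head_b"] = np.zeros(config.n_signals)
    return {k: v.astype(dtype, copy=False) for k, v in p.items()}


def count_parameters(config: ModelConfig) -> int:
    """Exact count of trainable scalars implied by the configuration."""
    k, c = config.conv_kernel, config.seq_channels
    n = (k * 4 * c + c) + (len(config.pool_factors) - 1) * (k * c * c + c)
    d, h, dh, f = config.d_model, config.n_heads, config.d_head, config.ffn_dim
    n += config.tokens * d  # position embedding
    per_layer = 3 * h * d * dh + h * dh * d + d  # QKV + output proj
    per_layer += 2 * (2 * d)                     # two layer norms
    per_layer += d * f + f + f * d + d           # feed-forward
    n += config.n_layers * per_layer
    n += d * config.n_signals + config.n_signals
    return n


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def _conv1d_same(x, W, b):
    """'same' 1-D convolution via kernel-tap matmuls; x is (B, L, Cin)."""
    k = W.shape[0]
    pad_l = (k - 1) // 2
    pad_r = k - 1 - pad_l
    xp = anp.concatenate(
        [anp.zeros((x.shape[0], pad_l, x.shape[2])),
         x,
         anp.zeros((x.shape[0], pad_r, x.shape[2]))],
        axis=1,
    )
    L = x.shape[1]
    out = anp.tensordot(xp[:, 0:L, :], W[0], axes=([2], [0]))
    for w in range(1, k):
        out = out + anp.tensordot(xp[:, w : w + L, :], W[w], axes=([2], [0]))
    return out + b


def _maxpool(x, factor):
    B, L, C = x.shape
    return anp.max(anp.reshape(x, (B, L // factor, factor, C)), axis=2)


def sequence_embed(params: dict, onehot, config: ModelConfig):
    """(B, L, 4) one-hot -> (B, tokens, C) sequence features."""
    if onehot.ndim == 2:
        onehot = onehot[np.newaxis]
    if onehot.shape[1] != config.input_length:
        raise ValueError(
            f"input length {onehot.shape[1]} != configured "
            f"{config.input_length}"
        )
    x = onehot
    for i, f in enumerate(config.pool_factors):
        x = _conv1d_same(x, params[f"conv{i}_W"], params[f"conv{i}_b"])
        x = anp.maximum(x, 0.0)  # ReLU after every convolution
        x = _maxpool(x, f)
    return x


def assemble_tokens(seq_emb, tf_block):
    """Concatenate sequence channels with TF features along the feature axis."""
    if seq_emb.ndim == 2:
        seq_emb = seq_emb[np.newaxis]
    if tf_block.ndim == 2:
        tf_block = tf_block[np.newaxis]
    if seq_emb.shape[1] != tf_block.shape[1]:
        raise ValueError(
            f"token count mismatch: sequence {seq_emb.shape[1]} vs TF "
            f"{tf_block.shape[1]}"
        )
    return anp.concatenate([seq_emb, tf_block], axis=2)


def _layer_norm(x, g, b, eps=1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return g * (x - mu) / anp.sqrt(var + eps) + b


def _softmax(x):
    m = anp.max(x, axis=-1, keepdims=True)
    e = anp.exp(x - m)
    return e / anp.sum(e, axis=-1, keepdims=True)


def _gelu(x):
    return 0.5 * x * (1.0 + anp.tanh(0.7978845608028654 * (x + 0.044715 * x**3)))


def transformer_forward(
    params: dict,
    tokens,
    config: ModelConfig,
    return_attention: bool = False,
):
    """Encoder stack. Returns (hidden, attentions-or-None).

    ``attentions`` is a list of length n_layers of (B, n_heads, T, T) arrays,
    each row of each attention matrix a softmax over keys.
    """
    if tokens.ndim == 2:
        tokens = tokens[np.newaxis]
    if tokens.shape[2] != config.d_model:
        raise ValueError(
            f"token width {tokens.shape[2]} != d_model {config.d_model}"
        )
    x = tokens + params["pos_emb"][np.newaxis, : tokens.shape[1], :]
    scale = 1.0 / np.sqrt(config.d_head)
    attentions = [] if return_attention else None
    for l in range(config.n_layers):
        q = anp.einsum("btd,hde->bhte", x, params[f"l{l}_Wq"])
        k = anp.einsum("btd,hde->bhte", x, params[f"l{l}_Wk"])
        v = anp.einsum("btd,hde->bhte", x, params[f"l{l}_Wv"])
        att = _softmax(anp.einsum("bhte,bhse->bhts", q, k) * scale)
        if return_attention:
            attentions.append(att)
        heads = anp.einsum("bhts,bhse->bhte", att, v)
        B, h, T, dh = heads.shape
        concat = anp.reshape(anp.transpose(heads, (0, 2, 1, 3)), (B, T, h * dh))
        attn_out = anp.tensordot(concat, params[f"l{l}_Wo"], axes=([2], [0]))
        attn_out = attn_out + params[f"l{l}_bo"]
        x = _layer_norm(x + attn_out, params[f"l{l}_ln1_g"], params[f"l{l}_ln1_b"])
        ff = _gelu(anp.tensordot(x, params[f"l{l}_W1"], axes=([2], [0]))
                   + params[f"l{l}_b1"])
        ff = anp.tensordot(ff, params[f"l{l}_W2"], axes=([2], [0])) + params[f"l{l}_b2"]
        x = _layer_norm(x + ff, params[f"l{l}_ln2_g"], params[f"l{l}_ln2_b"])
    return x, attentions


def predict(params: dict, hidden, config: ModelConfig):
    """Per-token affine head; classification adds a sigmoid."""
    out = anp.tensordot(hidden, params["head_W"], axes=([hidden.ndim - 1], [0]))
    out = out + params["head_b"]
    if config.head_type == "classification":
        out = 1.0 / (1.0 + anp.exp(-out))
    return out


def model_forward(
    params: dict,
    onehot,
    tf_block,
    config: ModelConfig,
    return_attention: bool = False,
    return_hidden: bool = False,
):
    """Full pipeline: one-hot + TF block -> per-bin signal predictions.

    Returns ``(pred, attentions, hidden)`` with the latter two ``None`` unless
    requested. ``pred`` is (B, tokens, K); singleton batch axes are added for
    2-D inputs but not squeezed on output.
    """
    seq = sequence_embed(params, onehot, config)
    tok = assemble_tokens(seq, tf_block)
    hidden, attn = transformer_forward(params, tok, config, return_attention)
    pred = predict(params, hidden, config)
    return pred, attn, (hidden if return_hidden else None)


# ---------------------------------------------------------------------------
# Attention summaries
# ---------------------------------------------------------------------------

@dataclass
class AttentionSummary:
    """Concrete attention matrices for a single window (one batch element)."""

    attentions: np.ndarray  # n_layers x n_heads x T x T

    def __post_init__(self) -> None:
        self.attentions = np.asarray(self.attentions, dtype=float)
        if self.attentions.ndim != 4:
            raise ValueError("expected n_layers x n_heads x T x T")

    @classmethod
    def from_forward(cls, attn_list) -> "AttentionSummary":
        return cls(np.stack([np.asarray(a)[0] for a in attn_list]))

    @property
    def layer_head_average(self) -> np.ndarray:
        """Average over all layers and heads (the pair-scoring matrix)."""
        return self.attentions.mean(axis=(0, 1))

    def last_layer_average(self, last_n_layers: int = 1) -> np.ndarray:
        """Head average over the last n layers (the contact-guidance matrix)."""
        return self.attentions[-last_n_layers:].mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: dict, config: ModelConfig) -> None:
    """Single-file archive: config JSON + named weight tensors."""
    np.savez(path, __config__=np.array(config.to_json()), **params)


def load_checkpoint(path) -> tuple[dict, ModelConfig]:
    with np.load(path, allow_pickle=False) as z:
        config = ModelConfig.from_json(str(z["__config__"]))
        params = {k: z[k] for k in z.files if k != "__config__"}
    return params, config
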