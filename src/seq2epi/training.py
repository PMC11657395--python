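"""Losses and training loops.

Two loss terms drive the model:

* a masked multi-task MSE — for a training instance (context i, window),
  the squared error is averaged over bins and, within each bin, over the
  index set B_i of signals actually measured in that context, so missing
  tracks can never leak gradient;
* an optional contact-guidance term (CSL) — one minus the mean row-wise
  cosine similarity between the head-averaged last-layer attention matrix
  and the row-normalized bin-level chromatin-contact matrix H̃, weighted by
  alpha (default 2). Rows of H̃ with no observed loops are treated as
  missing data and excluded.

Optimization is Adam over minibatches of (context, window) instances,
deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import autograd.numpy as anp
from autograd import value_and_grad

from .core_data import BinnedRegion
from .model import ModelConfig, model_forward, init_params

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Masked multi-task loss
# ---------------------------------------------------------------------------

def masked_mse(pred, target, avail):
    """Masked multi-task MSE.

    ``pred``/``target`` are (B, T, K) (a 2-D (T, K) pair is promoted);
    ``avail`` is (B, K) boolean — the per-context availability set B_i.
    Each instance contributes ``mean_bins( sum_{k in B_i} (y-yhat)^2 / |B_i| )``;
    an instance with no available signal contributes 0.
    """
    pred_arr = pred if hasattr(pred, "ndim") else anp.array(pred)
    if pred_arr.ndim == 2:
        pred = anp.reshape(pred, (1,) + np.shape(pred))
        target = np.asarray(target)[np.newaxis]
        avail = np.asarray(avail)[np.newaxis]
    target = np.asarray(target)
    if not np.issubdtype(target.dtype, np.floating):
        target = target.astype(float)
    avail = np.asarray(avail, dtype=bool)
    if target.shape[0] != avail.shape[0] or target.shape[2] != avail.shape[1]:
        raise ValueError("avail must be (batch, signals)")
    if np.any(avail[:, np.newaxis, :] & ~np.isfinite(target)):
        raise ValueError("NaN/inf in available target cells")
    target = np.where(avail[:, np.newaxis, :], target, 0.0)
    n_avail = avail.sum(axis=1)  # |B_i|
    denom = np.maximum(n_avail, 1).astype(float)
    sq = (pred - target) ** 2 * avail[:, np.newaxis, :]
    per_instance = anp.mean(anp.sum(sq, axis=2), axis=1) / denom
    per_instance = per_instance * (n_avail > 0)
    return anp.mean(per_instance)


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Bin-level loop aggregate H and its row-normalized form H̃."""

    H: np.ndarray
    region: BinnedRegion | None = None
    resolution: int | None = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.ndim != 2 or self.H.shape[0] != self.H.shape[1]:
            raise ValueError("H must be square")
        if np.any(self.H < 0):
            raise ValueError("H must be non-negative")

    @property
    def row_sums(self) -> np.ndarray:
        return self.H.sum(axis=1)

    @property
    def valid_rows(self) -> np.ndarray:
        """Rows touched by at least one loop; all-zero rows are missing data."""
        return self.row_sums > 0

    @property
    def H_tilde(self) -> np.ndarray:
        rs = self.row_sums
        out = np.zeros_like(self.H)
        nz = rs > 0
        out[nz] = self.H[nz] / rs[nz, np.newaxis]
        return out


def read_bedpe(path, score_col: int = 7, q_col: int = 8) -> list[dict]:
    """Parse a BEDPE loop file; malformed lines are rejected by line number.

    Default layout: chrom1 start1 end1 chrom2 start2 end2 name score qvalue,
    with the score and q-value column indices configurable (0-based).
    """
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            needed = max(6, score_col + 1, q_col + 1)
            if len(f) < needed:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= {needed} fields, "
                    f"got {len(f)}"
                )
            try:
                rec = {
                    "chrom1": f[0], "start1": int(f[1]), "end1": int(f[2]),
                    "chrom2": f[3], "start2": int(f[4]), "end2": int(f[5]),
                    "score": float(f[score_col]), "q": float(f[q_col]),
                }
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            loops.append(rec)
    return loops


def build_contact_matrix(
    loops,
    region: BinnedRegion,
    q_threshold: float = 0.001,
) -> ContactMatrix:
    """Aggregate significant loops (q <= threshold) onto region bins.

    Each surviving loop adds its score to every (bin_a, bin_b) pair of the
    bin sets overlapped by its two anchors, symmetrically.
    """
    T = region.n_bins
    H = np.zeros((T, T))
    for loop in loops:
        if loop["q"] > q_threshold:
            continue
        bins_a = _overlapped_bins(loop["chrom1"], loop["start1"], loop["end1"], region)
        bins_b = _overlapped_bins(loop["chrom2"], loop["start2"], loop["end2"], region)
        if bins_a.size == 0 or bins_b.size == 0:
            continue
        for a in bins_a:
            for b in bins_b:
                H[a, b] += loop["score"]
                if a != b:
                    H[b, a] += loop["score"]
    return ContactMatrix(H=H, region=region, resolution=region.bin_size)


def _overlapped_bins(chrom: str, start: int, end: int, region: BinnedRegion):
    if chrom != region.chrom or end <= region.start or start >= region.end:
        return np.array([], dtype=int)
    lo = max(start, region.start)
    hi = min(end, region.end)
    first = (lo - region.start) // region.bin_size
    last = (hi - 1 - region.start) // region.bin_size
    return np.arange(first, last + 1)


# ---------------------------------------------------------------------------
# Contact guidance loss
# ---------------------------------------------------------------------------

def contact_guidance_loss(att_rows, h_tilde, valid_rows=None):
    """CSL = 1 - mean row-wise cosine(attention row, H̃ row) over valid rows.

    ``att_rows`` is the head-averaged last-layer attention matrix (T x T,
    possibly an autograd tracer); ``h_tilde`` the row-normalized contact
    matrix. Zero rows of H̃ are excluded; if every row is zero the loss is 0
    with a warning.
    """
    h_tilde = np.asarray(h_tilde, dtype=float)
    if valid_rows is None:
        valid_rows = h_tilde.sum(axis=1) > 0
    valid_rows = np.asarray(valid_rows, dtype=bool)
    if not valid_rows.any():
        warnings.warn("contact matrix has no nonzero rows; CSL = 0", stacklevel=2)
        return 0.0
    idx = np.nonzero(valid_rows)[0]
    a = att_rows[idx]
    h = h_tilde[idx]
    num = anp.sum(a * h, axis=1)
    den = anp.sqrt(anp.sum(a * a, axis=1)) * np.sqrt((h * h).sum(axis=1)) + _EPS
    return 1.0 - anp.mean(num / den)


def total_loss(pred, target, avail, att_rows=None, h_tilde=None, alpha=2.0,
               valid_rows=None):
    """masked MSE + alpha * CSL; alpha = 0 reduces exactly to the MSE."""
    loss = masked_mse(pred, target, avail)
    if alpha and att_rows is not None and h_tilde is not None:
        loss = loss + alpha * contact_guidance_loss(att_rows, h_tilde, valid_rows)
    return loss


# ---------------------------------------------------------------------------
# Datasets and the training loop
# ---------------------------------------------------------------------------

@dataclass
class WindowDataset:
    """Training instances = (context, window) pairs over a tiled region.

    ``onehot[w]`` is the (L, 4) one-hot of window w, ``tf_motif[w]`` its
    (T, n_tf_padded) motif-score block (already zero-padded), ``expression``
    the contexts x n_tf_padded processed TF profile (padded columns zero),
    ``targets[c, w]`` the (T, K) signal targets and ``avail[c]`` the
    availability mask. ``contacts[w]`` optionally holds the window's
    :class:`ContactMatrix` for attention guidance.
    """

    onehot: np.ndarray        # windows x L x 4
    tf_motif: np.ndarray      # windows x T x n_tf_padded
    expression: np.ndarray    # contexts x n_tf_padded
    targets: np.ndarray       # contexts x windows x T x K
    avail: np.ndarray         # contexts x K (bool)
    contacts: list | None = None
    context_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.targets.shape[0] != self.expression.shape[0]:
            raise ValueError("targets and expression disagree on contexts")
        if self.targets.shape[1] != self.onehot.shape[0]:
            raise ValueError("targets and onehot disagree on windows")

    @property
    def n_contexts(self) -> int:
        return self.expression.shape[0]

    @property
    def n_windows(self) -> int:
        return self.onehot.shape[0]

    def tf_block(self, context: int, window: int) -> np.ndarray:
        return self.tf_motif[window] * self.expression[context][np.newaxis, :]


@dataclass
class TrainConfig:
    learning_rate: float = 5e-5
    batch_size: int = 10
    steps: int = 1000
    alpha: float = 2.0
    last_n_layers: int = 1
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    warmup_steps: int = 0
    cosine_decay: bool = False
    min_lr_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def lr_at(self, step: int) -> float:
        """Learning rate at 1-based step: linear warmup, optional cosine decay."""
        lr = self.learning_rate
        if self.warmup_steps and step <= self.warmup_steps:
            return lr * step / self.warmup_steps
        if self.cosine_decay:
            span = max(self.steps - self.warmup_steps, 1)
            t = (step - self.warmup_steps) / span
            floor = self.min_lr_fraction * lr
            return floor + 0.5 * (lr - floor) * (1 + np.cos(np.pi * t))
        return lr


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; carries the last finite-loss parameters."""

    def __init__(self, step: int, params: dict, history: list):
        super().__init__(f"training diverged at step {step}")
        self.step = step
        self.params = params
        self.history = history


def train(
    params: dict | None,
    dataset: WindowDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
):
    """Adam minibatch training; returns (params, loss_history).

    Deterministic for a fixed seed and single-threaded math. Instances whose
    context has no available signal still contribute the CSL term when
    ``alpha > 0`` and contacts are present.
    """
    if dataset.n_windows == 0 or dataset.n_contexts == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(train_config.seed)
    if params is None:
        # float32 keeps desk-scale training fast; precision-critical
        # analyses run the forward pass in float64.
        params = init_params(model_config, rng, dtype=np.float32)
    params = {k: v.copy() for k, v in params.items()}

    use_csl = train_config.alpha > 0 and dataset.contacts is not None
    h_tilde = valid_rows = None
    if use_csl:
        h_tilde = np.stack([cm.H_tilde for cm in dataset.contacts])
        valid_rows = np.stack([cm.valid_rows for cm in dataset.contacts])

    def loss_fn(p, onehot, tf_blocks, targets, avail, ht, vr):
        pred, attn, _ = model_forward(
            p, onehot, tf_blocks, model_config, return_attention=use_csl
        )
        loss = masked_mse(pred, targets, avail)
        if use_csl:
            last = attn[-train_config.last_n_layers:]
            att_avg = last[0]
            for extra in last[1:]:
                att_avg = att_avg + extra
            att_avg = anp.mean(att_avg, axis=1) / len(last)  # (B, T, T)
            csl = 0.0
            n_valid = 0
            for b in range(ht.shape[0]):
                if vr[b].any():
                    csl = csl + contact_guidance_loss(att_avg[b], ht[b], vr[b])
                    n_valid += 1
            if n_valid:
                loss = loss + train_config.alpha * csl / n_valid
        return loss

    vg = value_and_grad(loss_fn)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    history = []
    last_good = params
    n_instances = dataset.n_contexts * dataset.n_windows
    for step in range(1, train_config.steps + 1):
        idx = rng.integers(0, n_instances, size=train_config.batch_size)
        cs, ws = np.divmod(idx, dataset.n_windows)
        onehot = dataset.onehot[ws]
        tf_blocks = np.stack(
            [dataset.tf_block(c, w) for c, w in zip(cs, ws)]
        )
        targets = dataset.targets[cs, ws]
        avail = dataset.avail[cs]
        ht = h_tilde[ws] if use_csl else None
        vr = valid_rows[ws] if use_csl else None
        loss, grads = vg(params, onehot, tf_blocks, targets, avail, ht, vr)
        loss = float(loss)
        if not np.isfinite(loss):
            raise TrainingDiverged(step, last_good, history)
        history.append(loss)
        last_good = params
        lr_t = train_config.lr_at(step) * (
            np.sqrt(1 - train_config.beta2**step) / (1 - train_config.beta1**step)
        )
        new = {}
        for k in params:
            g = np.asarray(grads[k]).astype(params[k].dtype, copy=False)
            m[k] = train_config.beta1 * m[k] + (1 - train_config.beta1) * g
            v[k] = train_config.beta2 * v[k] + (1 - train_config.beta2) * g * g
            new[k] = params[k] - lr_t * m[k] / (np.sqrt(v[k]) + train_config.adam_eps)
        params = new
    return params, history


# ---------------------------------------------------------------------------
# Frozen-backbone fine-tuning for element-promoter pairs
# ---------------------------------------------------------------------------

def anchor_bins(region: BinnedRegion, anchor_start: int, anchor_end: int):
    """Bins whose midpoint lies inside the anchor interval."""
    mids = region.start + (np.arange(region.n_bins) + 0.5) * region.bin_size
    return np.nonzero((mids >= anchor_start) & (mids < anchor_end))[0]


def ep_features(
    params: dict,
    config: ModelConfig,
    onehot: np.ndarray,
    tf_block: np.ndarray,
    bins_a: np.ndarray,
    bins_b: np.ndarray,
) -> np.ndarray:
    """Concatenated last-layer hidden states of the two anchors' bins."""
    T = config.tokens
    for b in np.concatenate([bins_a, bins_b]):
        if not 0 <= b < T:
            raise ValueError(f"anchor bin {b} outside the {T}-token window")
    _, _, hidden = model_forward(
        params, onehot, tf_block, config, return_hidden=True
    )
    h = np.asarray(hidden)[0]
    return np.concatenate([h[bins_a].ravel(), h[bins_b].ravel()])


@dataclass
class MLPHead:
    """Two-hidden-layer MLP with a sigmoid output and frozen input scaling."""

    params: dict
    mu: np.ndarray
    sd: np.ndarray
    hidden: tuple[int, int] = (256, 256)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xn = (np.asarray(X, dtype=float) - self.mu) / self.sd
        return np.asarray(_mlp_forward(self.params, Xn))


def _mlp_forward(p, X):
    h = anp.maximum(anp.dot(X, p["W1"]) + p["b1"], 0.0)
    h = anp.maximum(anp.dot(h, p["W2"]) + p["b2"], 0.0)
    z = anp.dot(h, p["W3"]) + p["b3"]
    return 1.0 / (1.0 + anp.exp(-z[:, 0]))


def finetune_ep(
    features: np.ndarray,
    labels: np.ndarray,
    hidden: tuple[int, int] = (256, 256),
    steps: int = 300,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> MLPHead:
    """Train the classification head on frozen-backbone pair features.

    The backbone never appears here — features are precomputed with
    :func:`ep_features` under fixed parameters, so backbone gradients are
    identically zero by construction.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_pairs, dim) matching labels")
    mu, sd = X.mean(axis=0), X.std(axis=0) + 1e-8
    Xn = (X - mu) / sd
    rng = np.random.default_rng(seed)
    d = X.shape[1]
    p = {
        "W1": rng.normal(0, np.sqrt(2.0 / d), (d, hidden[0])),
        "b1": np.zeros(hidden[0]),
        "W2": rng.normal(0, np.sqrt(2.0 / hidden[0]), (hidden[0], hidden[1])),
        "b2": np.zeros(hidden[1]),
        "W3": rng.normal(0, np.sqrt(1.0 / hidden[1]), (hidden[1], 1)),
        "b3": np.zeros(1),
    }

    def loss_fn(pp):
        prob = _mlp_forward(pp, Xn)
        prob = anp.clip(prob, 1e-9, 1 - 1e-9)
        return -anp.mean(y * anp.log(prob) + (1 - y) * anp.log(1 - prob))

    vg = value_and_grad(loss_fn)
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v2 = {k: np.zeros_like(v) for k, v in p.items()}
    for step in range(1, steps + 1):
        _, g = vg(p)
        lr_t = learning_rate * np.sqrt(1 - 0.999**step) / (1 - 0.9**step)
        for k in p:
            m[k] = 0.9 * m[k] + 0.1 * g[k]
            v2[k] = 0.999 * v2[k] + 0.001 * g[k] ** 2
            p[k] = p[k] - lr_t * m[k] / (np.sqrt(v2[k]) + 1e-8)

    return MLPHead(params=p, mu=mu, sd=sd, hidden=hidden)
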