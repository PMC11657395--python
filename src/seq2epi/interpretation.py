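"""Attribution and scoring machinery.

* Gradient importance scores (GIS): for a window and context, the mean
  absolute gradient of a predicted signal at a TF's bound bins with respect
  to that TF's input feature — either the combined motif x expression
  product entry (default) or the raw expression entry. IGIS integrates the
  per-signal GIS by averaging descending ranks across the K signals.
* Attention pair scores: element-gene scores read off the layer/head
  averaged attention matrix, either as the total attention received by the
  element's token (column mode) or the direct element-to-TSS entry.
* Log-ratio variant-effect scores (LOS): signed per-signal log ratios of
  model outputs under the alternative vs reference allele at the variant's
  bin, plus an attention LOS summing absolute log ratios of per-bin
  attention mass over the +/-5-bin neighbourhood.
* A k-mer count baseline and a percentile-rank prioritizer for variants
  against background SNPs (null expectation 0.5).
"""

from __future__ import annotations

import warnings

import numpy as np
from autograd import jacobian
from scipy.stats import rankdata

from .model import ModelConfig, model_forward

LOS_EPS = 1e-6


# ---------------------------------------------------------------------------
# Predict-function builders (close over frozen params and sequence)
# ---------------------------------------------------------------------------

def tf_input_predict_fn(params: dict, config: ModelConfig, onehot: np.ndarray):
    """Model output as a traceable function of the combined TF input block."""

    def fn(tf_block):
        pred, _, _ = model_forward(params, onehot, tf_block, config)
        return pred[0]

    return fn


def expression_predict_fn(
    params: dict,
    config: ModelConfig,
    onehot: np.ndarray,
    motif_padded: np.ndarray,
):
    """Model output as a traceable function of the expression vector."""

    def fn(expr_padded):
        tf_block = motif_padded * expr_padded[np.newaxis, :]
        pred, _, _ = model_forward(params, onehot, tf_block, config)
        return pred[0]

    return fn


# ---------------------------------------------------------------------------
# GIS / IGIS
# ---------------------------------------------------------------------------

def gis(
    predict_fn,
    tf_input: np.ndarray,
    tf_index: int,
    signal_index: int,
    binding_set: np.ndarray,
    target: str = "product",
) -> float:
    """Mean absolute gradient of one signal w.r.t. one TF over bound bins.

    ``predict_fn`` maps the differentiation target to a (T, K) prediction:
    the combined bins x n_tf block for ``target='product'`` (the gradient is
    the per-bin diagonal entry d yhat[l, k] / d tf[l, t]) or the expression
    vector for ``target='expression'``. An empty binding set is defined as
    GIS 0 with a warning.
    """
    binding_set = np.asarray(binding_set, dtype=int)
    if binding_set.size == 0:
        warnings.warn("empty binding set; GIS defined as 0", stacklevel=2)
        return 0.0

    def selected(x):
        return predict_fn(x)[binding_set, signal_index]

    jac = jacobian(selected)(np.asarray(tf_input, dtype=float))
    if target == "product":
        grads = jac[np.arange(binding_set.size), binding_set, tf_index]
    elif target == "expression":
        grads = jac[:, tf_index]
    else:
        raise ValueError(f"unknown GIS target {target!r}")
    return float(np.mean(np.abs(grads)))


def gis_table(
    predict_fn,
    tf_input: np.ndarray,
    motif_scores: np.ndarray,
    target: str = "product",
) -> np.ndarray:
    """n_tf x K GIS matrix for one window and context.

    ``motif_scores`` (bins x n_tf, unpadded) defines each TF's binding set
    as the bins with a positive motif score. TFs with empty binding sets get
    a zero row.
    """
    motif_scores = np.asarray(motif_scores)
    T, n_tf = motif_scores.shape
    union = np.nonzero((motif_scores > 0).any(axis=1))[0]
    probe = predict_fn(np.asarray(tf_input, dtype=float))
    K = probe.shape[1]
    out = np.zeros((n_tf, K))
    if union.size == 0:
        warnings.warn("no TF binds any bin; GIS table is all zeros", stacklevel=2)
        return out

    for k in range(K):

        def selected(x, _k=k):
            return predict_fn(x)[union, _k]

        jac = jacobian(selected)(np.asarray(tf_input, dtype=float))
        if target == "product":
            diag = np.abs(jac[np.arange(union.size), union, :n_tf])  # |ζ∪| x n_tf
        elif target == "expression":
            diag = np.abs(jac[:, :n_tf])
        else:
            raise ValueError(f"unknown GIS target {target!r}")
        for t in range(n_tf):
            bound = motif_scores[union, t] > 0
            if bound.any():
                out[t, k] = diag[bound, t].mean()
    return out


def igis(gis_matrix: np.ndarray) -> np.ndarray:
    """Average descending rank of each TF across the K signals.

    Rank 1 is the largest GIS; ties receive the average of the ranks they
    span. A TF ranked first for every signal has IGIS exactly 1.
    """
    g = np.asarray(gis_matrix, dtype=float)
    if g.ndim != 2:
        raise ValueError("expected an n_tf x K GIS matrix")
    ranks = np.column_stack(
        [rankdata(-g[:, k], method="average") for k in range(g.shape[1])]
    )
    return ranks.mean(axis=1)


# ---------------------------------------------------------------------------
# Attention pair scores
# ---------------------------------------------------------------------------

def attention_pair_score(
    att: np.ndarray,
    element_bin: int,
    tss_bin: int,
    mode: str = "column",
    max_separation: int | None = None,
) -> float:
    """Element-gene score from the layer/head-averaged attention matrix.

    ``column`` (default): total attention received by the element's token
    from all query tokens. ``direct``: the single element-to-TSS entry.
    Pairs separated by more than ``max_separation`` bins are rejected
    (the 64-kbp filter at full scale).
    """
    att = np.asarray(att)
    T = att.shape[0]
    for b, what in ((element_bin, "element"), (tss_bin, "TSS")):
        if not 0 <= b < T:
            raise ValueError(f"{what} bin {b} outside [0, {T})")
    if max_separation is not None and abs(element_bin - tss_bin) > max_separation:
        raise ValueError(
            f"pair separation {abs(element_bin - tss_bin)} bins exceeds "
            f"window limit {max_separation}"
        )
    if mode == "column":
        return float(att[:, element_bin].sum())
    if mode == "direct":
        return float(att[element_bin, tss_bin])
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Variant-effect scores
# ---------------------------------------------------------------------------

def log_ratio(out_ref: np.ndarray, out_alt: np.ndarray,
              eps: float = LOS_EPS) -> np.ndarray:
    """Signed log((alt + eps)/(ref + eps)); negative outputs are floored at 0.

    The floor keeps ratios finite for regression heads that may emit small
    negative values; swapping ref and alt negates every component exactly.
    """
    ref = np.maximum(np.asarray(out_ref, dtype=float), 0.0) + eps
    alt = np.maximum(np.asarray(out_alt, dtype=float), 0.0) + eps
    # log(alt) - log(ref) rather than log(alt/ref): exactly antisymmetric
    return np.log(alt) - np.log(ref)


def los_signal(
    pred_ref: np.ndarray,
    pred_alt: np.ndarray,
    variant_bin: int,
    eps: float = LOS_EPS,
) -> np.ndarray:
    """Per-signal LOS at the variant's bin from two (T, K) predictions."""
    pred_ref = np.asarray(pred_ref)
    pred_alt = np.asarray(pred_alt)
    if pred_ref.shape != pred_alt.shape:
        raise ValueError("ref/alt predictions must have identical shape")
    return log_ratio(pred_ref[variant_bin], pred_alt[variant_bin], eps)


def attention_bin_mass(att: np.ndarray, mode: str = "column") -> np.ndarray:
    """Per-bin attention mass. Column mode: attention received by each bin."""
    att = np.asarray(att)
    if mode == "column":
        return att.sum(axis=0)
    if mode == "row_window":
        # caller restricts columns; here the plain row sums (near 1 for a
        # row-stochastic average) — useful only with column restriction.
        return att.sum(axis=1)
    raise ValueError(f"unknown attention mass mode {mode!r}")


def los_attention(
    att_ref: np.ndarray,
    att_alt: np.ndarray,
    variant_bin: int,
    half_width: int = 5,
    eps: float = LOS_EPS,
    mode: str = "column",
) -> float:
    """Sum over bins variant_bin-5 .. variant_bin+5 of |log mass ratio|.

    Offsets outside the token range are dropped with a warning (edge
    truncation).
    """
    mass_ref = attention_bin_mass(att_ref, mode)
    mass_alt = attention_bin_mass(att_alt, mode)
    T = mass_ref.size
    offsets = np.arange(-half_width, half_width + 1)
    bins = variant_bin + offsets
    inside = (bins >= 0) & (bins < T)
    if not inside.all():
        warnings.warn(
            f"attention LOS window truncated at sequence edge "
            f"({inside.sum()}/{bins.size} bins kept)",
            stacklevel=2,
        )
    bins = bins[inside]
    ratios = np.log((mass_alt[bins] + eps) / (mass_ref[bins] + eps))
    return float(np.abs(ratios).sum())


def variant_feature_vector(
    signal_los: np.ndarray, attention_los: np.ndarray
) -> np.ndarray:
    """Flatten per-context scores into the fixed-order feature vector.

    ``signal_los`` is contexts x K, ``attention_los`` contexts; the output
    is per context [K signal LOS..., attention LOS], concatenated — length
    (K + 1) * n_contexts (252 at the full 28-context, 8-signal scale).
    """
    signal_los = np.atleast_2d(np.asarray(signal_los, dtype=float))
    attention_los = np.asarray(attention_los, dtype=float).ravel()
    if signal_los.shape[0] != attention_los.size:
        raise ValueError("contexts mismatch between signal and attention LOS")
    return np.concatenate(
        [np.append(signal_los[c], attention_los[c])
         for c in range(signal_los.shape[0])]
    )


# ---------------------------------------------------------------------------
# Prioritization and baselines
# ---------------------------------------------------------------------------

def percentile_rank(score: float, background_scores: np.ndarray) -> float:
    """Fraction of background scores exceeding ``score`` (midrank ties).

    0.0 means the variant outscores every background SNP; the expectation
    under exchangeability is 0.5.
    """
    bg = np.asarray(background_scores, dtype=float)
    if bg.size == 0:
        raise ValueError("background is empty")
    greater = np.count_nonzero(bg > score)
    equal = np.count_nonzero(bg == score)
    return (greater + 0.5 * equal) / bg.size


def kmer_features(anchor_seq: str, k: int = 5) -> np.ndarray:
    """Overlapping k-mer counts over A/C/G/T — a 4^k baseline feature vector.

    k-mers containing ambiguous bases are dropped; sequences shorter than k
    yield a zero vector with a warning.
    """
    out = np.zeros(4**k)
    if len(anchor_seq) < k:
        warnings.warn(
            f"sequence shorter than k={k}; zero feature vector", stacklevel=2
        )
        return out
    from .core_data import encode_bases

    codes = encode_bases(anchor_seq)
    weights = 4 ** np.arange(k - 1, -1, -1)
    for i in range(codes.size - k + 1):
        window = codes[i : i + k]
        if (window > 3).any():
            continue
        out[int(window @ weights)] += 1
    return out


def fit_variant_classifier(
    X: np.ndarray,
    y: np.ndarray,
    kind: str = "rf",
    n_estimators: int = 10,
    seed: int = 0,
):
    """Thin trainer over LOS feature vectors (the features are the content).

    ``rf``: a random forest of ``n_estimators`` trees; ``mlp``: a small MLP.
    Returns a fitted scikit-learn estimator.
    """
    if kind == "rf":
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    elif kind == "mlp":
        from sklearn.neural_network import MLPClassifier

        clf = MLPClassifier(
            hidden_layer_sizes=(64,), max_iter=500, random_state=seed
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return clf.fit(np.asarray(X), np.asarray(y))
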