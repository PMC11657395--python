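"""Workflow glue: from files on disk to datasets, predictions and scores.

This module wires the building blocks together the way the CLI and the
recovery experiments use them: load a fixture or real data directory,
assemble a :class:`~seq2epi.training.WindowDataset`, predict whole contexts,
score variants and rank TFs. Nothing here adds modelling content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    BinnedRegion,
    SignalTensor,
    encode_bases,
    one_hot_from_codes,
    read_bed,
)
from .model import AttentionSummary, ModelConfig, model_forward
from .tf_features import (
    PWMSet,
    quantile_normalize,
    read_pwms_jaspar,
    scan_bins,
)
from .training import (
    WindowDataset,
    build_contact_matrix,
    ep_features,
    read_bedpe,
)
from .interpretation import (
    attention_pair_score,
    los_attention,
    los_signal,
    tf_input_predict_fn,
    gis_table,
    igis,
    variant_feature_vector,
)


@dataclass
class DataBundle:
    """Everything loaded from a data directory (simulated or real)."""

    region: BinnedRegion            # the full tiled span
    sequence: str
    windows: list[tuple]            # (chrom, start, end, name)
    pwms: PWMSet
    expression: np.ndarray          # contexts x n_tf (processed scale)
    tf_names: list[str]
    contexts: list[str]
    signals: SignalTensor           # observed values + mask over all bins
    motif_scores: np.ndarray        # bins x n_tf
    loops: list[dict] | None = None
    variants: list[dict] | None = None


def load_bundle(
    directory,
    fasta="genome.fa",
    regions="regions.bed",
    expression="expression.tsv",
    pwms="pwms.jaspar",
    signals="signals.h5",
    loops="loops.bedpe",
    variants="variants.vcf",
) -> DataBundle:
    """Load a directory laid out like the simulator's output."""
    from pyfaidx import Fasta

    d = Path(directory)
    tensor = SignalTensor.from_hdf5(d / signals)
    region = tensor.region
    if region is None:
        raise ValueError(f"{signals}: container lacks a region header")
    fa = Fasta(str(d / fasta))
    seq = str(fa[region.chrom][region.start : region.end])
    windows = read_bed(d / regions)
    pwm_set = read_pwms_jaspar(d / pwms)

    expr_df = pd.read_csv(d / expression, sep="\t", index_col=0)
    tf_names = pwm_set.names
    expr_df = expr_df.loc[tf_names, tensor.contexts]
    expr = quantile_normalize(expr_df.to_numpy()).T  # contexts x n_tf

    motif = scan_bins(pwm_set, seq, region)

    loop_recs = None
    if loops and (d / loops).exists():
        loop_recs = read_bedpe(d / loops)
    var_recs = None
    if variants and (d / variants).exists():
        var_recs = read_vcf_snvs(d / variants)

    return DataBundle(
        region=region,
        sequence=seq,
        windows=windows,
        pwms=pwm_set,
        expression=expr,
        tf_names=tf_names,
        contexts=tensor.contexts,
        signals=tensor,
        motif_scores=motif,
        loops=loop_recs,
        variants=var_recs,
    )


def read_vcf_snvs(path) -> list[dict]:
    """SNV records from a VCF (positions converted to 0-based)."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        if len(rec.REF) != 1 or any(len(a) != 1 for a in rec.ALT):
            continue  # SNVs only
        out.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS - 1,
                "id": rec.ID,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "info": dict(rec.INFO),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def window_slices(bundle: DataBundle, config: ModelConfig):
    """(start-bin, end-bin) token slice of each window in the tiled region."""
    out = []
    for chrom, start, end, *_ in bundle.windows:
        if end - start != config.input_length:
            raise ValueError(
                f"window {chrom}:{start}-{end} length {end - start} != "
                f"model input length {config.input_length}"
            )
        b0 = bundle.region.bin_of(start)
        out.append((b0, b0 + config.tokens))
    return out


def build_dataset(
    bundle: DataBundle,
    config: ModelConfig,
    context_indices=None,
    include_contacts: bool = False,
    q_threshold: float = 0.001,
    expression_override: np.ndarray | None = None,
    dtype=np.float32,
) -> WindowDataset:
    """Assemble training tensors for a subset of contexts.

    float32 by default: the training loop is memory-bandwidth bound and the
    signal rule never needs more than single precision.
    """
    if context_indices is None:
        context_indices = list(range(len(bundle.contexts)))
    context_indices = list(context_indices)
    n_tf = len(bundle.tf_names)
    pad = config.n_tf_padded
    if pad < n_tf:
        raise ValueError(f"model n_tf_padded {pad} < panel size {n_tf}")

    codes = encode_bases(bundle.sequence)
    slices = window_slices(bundle, config)
    onehot = np.stack(
        [
            one_hot_from_codes(
                codes[b0 * config.bin_size : b1 * config.bin_size]
            )
            for b0, b1 in slices
        ]
    ).astype(dtype)
    tf_motif = np.zeros((len(slices), config.tokens, pad), dtype=dtype)
    for w, (b0, b1) in enumerate(slices):
        tf_motif[w, :, :n_tf] = bundle.motif_scores[b0:b1]

    expr_src = (
        expression_override if expression_override is not None
        else bundle.expression
    )
    expression = np.zeros((len(context_indices), pad), dtype=dtype)
    expression[:, :n_tf] = expr_src[context_indices]

    targets = np.stack(
        [
            np.stack([bundle.signals.values[c, b0:b1] for b0, b1 in slices])
            for c in context_indices
        ]
    ).astype(dtype)
    avail = bundle.signals.mask[context_indices]

    contacts = None
    if include_contacts:
        if bundle.loops is None:
            raise ValueError("bundle has no loops to build contacts from")
        contacts = []
        for chrom, start, end, *_ in bundle.windows:
            wregion = BinnedRegion(chrom, start, end, config.bin_size)
            contacts.append(
                build_contact_matrix(bundle.loops, wregion, q_threshold)
            )

    return WindowDataset(
        onehot=onehot,
        tf_motif=tf_motif,
        expression=expression,
        targets=targets,
        avail=avail,
        contacts=contacts,
        context_names=[bundle.contexts[c] for c in context_indices],
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_context(
    params: dict,
    config: ModelConfig,
    dataset: WindowDataset,
    context: int,
    batch_windows: int = 8,
) -> np.ndarray:
    """Predict all windows for one dataset context -> (total bins, K)."""
    preds = []
    for i in range(0, dataset.n_windows, batch_windows):
        ws = range(i, min(i + batch_windows, dataset.n_windows))
        tf_blocks = np.stack([dataset.tf_block(context, w) for w in ws])
        pred, _, _ = model_forward(
            params, dataset.onehot[list(ws)], tf_blocks, config
        )
        preds.append(np.asarray(pred))
    return np.concatenate(preds).reshape(-1, config.n_signals)


def attention_summary_for_window(
    params: dict,
    config: ModelConfig,
    onehot: np.ndarray,
    tf_block: np.ndarray,
) -> AttentionSummary:
    _, attn, _ = model_forward(
        params, onehot, tf_block, config, return_attention=True
    )
    return AttentionSummary.from_forward(attn)


# ---------------------------------------------------------------------------
# Variant scoring
# ---------------------------------------------------------------------------

def score_variant(
    params: dict,
    config: ModelConfig,
    bundle: DataBundle,
    variant: dict,
    context_indices=None,
    attention_mode: str = "column",
) -> dict:
    """LOS features for one SNV across contexts.

    The variant's window is the tiling window containing it; the ref and alt
    windows differ at the variant base only, and the alt TF features are
    rescanned so motif-destroying substitutions propagate through both the
    sequence and the TF channels.
    """
    if context_indices is None:
        context_indices = list(range(len(bundle.contexts)))
    pos = variant["pos"]
    w = next(
        (i for i, (_, s, e, *_r) in enumerate(bundle.windows) if s <= pos < e),
        None,
    )
    if w is None:
        raise ValueError(f"variant at {pos} outside every window")
    chrom, start, end, *_ = bundle.windows[w]
    ref_seq = bundle.sequence[start - bundle.region.start
                              : end - bundle.region.start]
    off = pos - start
    if ref_seq[off].upper() != variant["ref"].upper():
        raise ValueError(
            f"reference mismatch at {pos}: genome {ref_seq[off]!r}, "
            f"VCF {variant['ref']!r}"
        )
    alt_seq = ref_seq[:off] + variant["alt"] + ref_seq[off + 1 :]

    wregion = BinnedRegion(chrom, start, end, config.bin_size)
    variant_bin = wregion.bin_of(pos)
    n_tf = len(bundle.tf_names)
    pad = config.n_tf_padded

    motif_ref = np.zeros((config.tokens, pad))
    motif_ref[:, :n_tf] = scan_bins(bundle.pwms, ref_seq, wregion)
    motif_alt = np.zeros((config.tokens, pad))
    motif_alt[:, :n_tf] = scan_bins(bundle.pwms, alt_seq, wregion)
    onehot_ref = one_hot_from_codes(encode_bases(ref_seq))
    onehot_alt = one_hot_from_codes(encode_bases(alt_seq))

    signal_los = np.zeros((len(context_indices), config.n_signals))
    att_los = np.zeros(len(context_indices))
    for ci, c in enumerate(context_indices):
        expr = np.zeros(pad)
        expr[:n_tf] = bundle.expression[c]
        tf_ref = motif_ref * expr[np.newaxis, :]
        tf_alt = motif_alt * expr[np.newaxis, :]
        pred_ref, attn_ref, _ = model_forward(
            params, onehot_ref, tf_ref, config, return_attention=True
        )
        pred_alt, attn_alt, _ = model_forward(
            params, onehot_alt, tf_alt, config, return_attention=True
        )
        signal_los[ci] = los_signal(
            np.asarray(pred_ref)[0], np.asarray(pred_alt)[0], variant_bin
        )
        att_ref = AttentionSummary.from_forward(attn_ref).layer_head_average
        att_alt = AttentionSummary.from_forward(attn_alt).layer_head_average
        att_los[ci] = los_attention(
            att_ref, att_alt, variant_bin, mode=attention_mode
        )

    return {
        "window": w,
        "variant_bin": variant_bin,
        "signal_los": signal_los,
        "attention_los": att_los,
        "features": variant_feature_vector(signal_los, att_los),
        "summary": float(np.abs(signal_los).sum(axis=1).max()),
    }


# ---------------------------------------------------------------------------
# Element-promoter pairs
# ---------------------------------------------------------------------------

def _loop_window_pairs(bundle: DataBundle, config: ModelConfig,
                       q_threshold: float = 0.001):
    """Map q-significant loops to (window, element_bin, tss_bin) triples.

    Loops whose anchors fall in different tiling windows are skipped; the
    first anchor is treated as the element, the second as the TSS side.
    """
    if bundle.loops is None:
        raise ValueError("bundle has no loops")
    triples = []
    for loop in bundle.loops:
        if loop["q"] > q_threshold:
            continue
        w = None
        for i, (chrom, start, end, *_r) in enumerate(bundle.windows):
            if (chrom == loop["chrom1"] and start <= loop["start1"] < end
                    and start <= loop["start2"] < end):
                w = i
                break
        if w is None:
            continue
        chrom, start, end, *_ = bundle.windows[w]
        wregion = BinnedRegion(chrom, start, end, config.bin_size)
        mid1 = (loop["start1"] + loop["end1"]) // 2
        mid2 = (loop["start2"] + loop["end2"]) // 2
        triples.append((w, wregion.bin_of(mid1), wregion.bin_of(mid2)))
    return triples


def ep_pair_table(
    params: dict,
    config: ModelConfig,
    bundle: DataBundle,
    context: int,
    q_threshold: float = 0.001,
):
    """Frozen-backbone features for loop pairs and mirrored negatives.

    Positives are the q-significant within-window loops; each negative
    mirrors the element anchor to the opposite side of the TSS (identical
    distance). Returns (X, y).
    """
    from .evaluation import matched_negative

    triples = _loop_window_pairs(bundle, config, q_threshold)
    n_tf = len(bundle.tf_names)
    pad = config.n_tf_padded
    expr = np.zeros(pad)
    expr[:n_tf] = bundle.expression[context]
    codes = encode_bases(bundle.sequence)

    feats, labels = [], []
    slices = window_slices(bundle, config)
    for w, b_e, b_t in triples:
        b0, _ = slices[w]
        onehot = one_hot_from_codes(
            codes[b0 * config.bin_size : (b0 + config.tokens) * config.bin_size]
        )
        tf_block = np.zeros((config.tokens, pad))
        tf_block[:, :n_tf] = bundle.motif_scores[b0 : b0 + config.tokens]
        tf_block = tf_block * expr[np.newaxis, :]
        feats.append(ep_features(params, config, onehot, tf_block,
                                 np.array([b_e]), np.array([b_t])))
        labels.append(1)
        mirror = matched_negative(b_t, b_e, window=(0, config.tokens))
        if mirror is None:
            continue
        feats.append(ep_features(params, config, onehot, tf_block,
                                 np.array([mirror]), np.array([b_t])))
        labels.append(0)
    return np.asarray(feats), np.asarray(labels)


def attention_pair_scores(
    params: dict,
    config: ModelConfig,
    bundle: DataBundle,
    context: int,
    mode: str = "column",
    q_threshold: float = 0.001,
) -> pd.DataFrame:
    """Attention scores for loops vs mirrored equidistant negatives."""
    from .evaluation import distance_band, matched_negative

    triples = _loop_window_pairs(bundle, config, q_threshold)
    n_tf = len(bundle.tf_names)
    pad = config.n_tf_padded
    expr = np.zeros(pad)
    expr[:n_tf] = bundle.expression[context]
    codes = encode_bases(bundle.sequence)
    slices = window_slices(bundle, config)

    att_cache: dict[int, np.ndarray] = {}
    rows = []
    for w, b_e, b_t in triples:
        if w not in att_cache:
            b0, _ = slices[w]
            onehot = one_hot_from_codes(
                codes[b0 * config.bin_size
                      : (b0 + config.tokens) * config.bin_size]
            )
            tf_block = np.zeros((config.tokens, pad))
            tf_block[:, :n_tf] = bundle.motif_scores[b0 : b0 + config.tokens]
            tf_block = tf_block * expr[np.newaxis, :]
            att_cache[w] = attention_summary_for_window(
                params, config, onehot, tf_block
            ).layer_head_average
        att = att_cache[w]
        dist = abs(b_e - b_t) * config.bin_size
        rows.append(
            {
                "window": w, "element_bin": b_e, "tss_bin": b_t,
                "distance": dist, "band": distance_band(dist), "label": 1,
                "score": attention_pair_score(att, b_e, b_t, mode),
            }
        )
        mirror = matched_negative(b_t, b_e, window=(0, config.tokens))
        if mirror is not None:
            rows.append(
                {
                    "window": w, "element_bin": mirror, "tss_bin": b_t,
                    "distance": dist, "band": distance_band(dist), "label": 0,
                    "score": attention_pair_score(att, mirror, b_t, mode),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TF ranking
# ---------------------------------------------------------------------------

def rank_tfs_for_window(
    params: dict,
    config: ModelConfig,
    bundle: DataBundle,
    window: int,
    context: int,
    target: str = "product",
) -> pd.DataFrame:
    """GIS table + IGIS for one (window, context) as a tidy frame."""
    chrom, start, end, *_ = bundle.windows[window]
    b0 = bundle.region.bin_of(start)
    n_tf = len(bundle.tf_names)
    pad = config.n_tf_padded
    motif = bundle.motif_scores[b0 : b0 + config.tokens]
    motif_padded = np.zeros((config.tokens, pad))
    motif_padded[:, :n_tf] = motif
    expr = np.zeros(pad)
    expr[:n_tf] = bundle.expression[context]
    codes = encode_bases(
        bundle.sequence[start - bundle.region.start
                        : end - bundle.region.start]
    )
    onehot = one_hot_from_codes(codes)

    if target == "product":
        fn = tf_input_predict_fn(params, config, onehot)
        tf_input = motif_padded * expr[np.newaxis, :]
    else:
        from .interpretation import expression_predict_fn

        fn = expression_predict_fn(params, config, onehot, motif_padded)
        tf_input = expr
    table = gis_table(fn, tf_input, motif, target=target)
    scores = igis(table)
    df = pd.DataFrame(table, index=bundle.tf_names,
                      columns=bundle.signals.signal_names)
    df["IGIS"] = scores
    return df.sort_values("IGIS")
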