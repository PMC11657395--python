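"""Metrics and experiment scaffolding.

Regression quality is reported cell-type-wise: for each test context the
Pearson and Spearman correlations and the prediction squared error
PSR = 1 - SS_res / SS_tot (an R^2 about the context mean) are computed
across all genomic loci. Binary tasks use trapezoidal auROC and step-wise
auPRC with unweighted macro averages. Element-gene pairs are stratified by
genomic distance into 0-20 / 20-40 / 40-64 kbp bands, and negatives are
matched either by mirroring the anchor to the opposite side of the TSS
(identical distance) or by stratified sampling that conserves the positive
distance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

DEFAULT_BANDS = ((0, 20_000), (20_000, 40_000), (40_000, 64_000))


# ---------------------------------------------------------------------------
# Regression metrics
# ---------------------------------------------------------------------------

def psr(y: np.ndarray, yhat: np.ndarray) -> float:
    """Prediction squared error: 1 - SS_res / SS_tot about the mean of y.

    Undefined (NaN) for constant truth vectors or fewer than two points.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have identical shape")
    if y.size < 2:
        return float("nan")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


@dataclass
class EvalReport:
    """Tidy per-context metric table."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["context", "metric", "value"]
        )
    )

    def value(self, context: str, metric: str) -> float:
        sel = self.table[
            (self.table["context"] == context) & (self.table["metric"] == metric)
        ]
        return float(sel["value"].iloc[0]) if len(sel) else float("nan")

    def mean(self, metric: str) -> float:
        sel = self.table[self.table["metric"] == metric]["value"]
        return float(sel.mean()) if len(sel) else float("nan")


def celltype_metrics(
    Y: np.ndarray,
    Yhat: np.ndarray,
    mask: np.ndarray | None = None,
    contexts: list[str] | None = None,
) -> EvalReport:
    """Per-context PCC, SCC and PSR across loci.

    ``Y``/``Yhat`` are loci x contexts; ``mask`` (contexts,) marks columns to
    evaluate. Columns with fewer than two valid points or constant truth get
    NaN metrics.
    """
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise ValueError("Y and Yhat must have identical shape")
    n_ctx = Y.shape[1]
    if contexts is None:
        contexts = [f"ctx{i}" for i in range(n_ctx)]
    if mask is None:
        mask = np.ones(n_ctx, dtype=bool)
    rows = []
    for k in range(n_ctx):
        if not mask[k]:
            continue
        y, yhat = Y[:, k], Yhat[:, k]
        if y.size < 2 or np.all(y == y[0]):
            vals = {"PCC": np.nan, "SCC": np.nan, "PSR": np.nan}
        else:
            vals = {
                "PCC": pearsonr(y, yhat).statistic,
                "SCC": spearmanr(y, yhat).statistic,
                "PSR": psr(y, yhat),
            }
        for metric, value in vals.items():
            rows.append({"context": contexts[k], "metric": metric, "value": value})
    return EvalReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Binary metrics
# ---------------------------------------------------------------------------

def binary_metrics(labels: np.ndarray, scores: np.ndarray) -> dict:
    """Trapezoidal auROC and step-wise auPRC for one unit.

    Returns NaNs (with a flag) when only one class is present.
    """
    from sklearn.metrics import average_precision_score, roc_auc_score

    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        return {"auROC": float("nan"), "auPRC": float("nan"),
                "single_class": True}
    return {
        "auROC": float(roc_auc_score(labels, scores)),
        "auPRC": float(average_precision_score(labels, scores)),
        "single_class": False,
    }


def macro_binary_metrics(labels: np.ndarray, scores: np.ndarray) -> dict:
    """Unweighted average of per-class auROC/auPRC (one-vs-rest columns)."""
    labels = np.atleast_2d(np.asarray(labels))
    scores = np.atleast_2d(np.asarray(scores))
    per_class = [
        binary_metrics(labels[:, j], scores[:, j]) for j in range(labels.shape[1])
    ]
    rocs = [m["auROC"] for m in per_class if not m["single_class"]]
    prcs = [m["auPRC"] for m in per_class if not m["single_class"]]
    return {
        "macro_auROC": float(np.mean(rocs)) if rocs else float("nan"),
        "macro_auPRC": float(np.mean(prcs)) if prcs else float("nan"),
        "per_class": per_class,
    }


# ---------------------------------------------------------------------------
# Distance stratification and matched negatives
# ---------------------------------------------------------------------------

def distance_band(distance: int, bands=DEFAULT_BANDS) -> str:
    """Half-open band label for a pair separation; beyond the last band ->
    ``out_of_range`` (such pairs are filtered)."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    for lo, hi in bands:
        if lo <= distance < hi:
            return f"{lo // 1000}-{hi // 1000}kbp"
    return "out_of_range"


def matched_negative(
    tss: int, anchor: int, window: tuple[int, int] | None = None
) -> int | None:
    """Mirror the anchor to the opposite side of the TSS (equal distance).

    Returns None when the mirror falls outside ``window`` or the anchor sits
    on the TSS (mirrors onto itself).
    """
    mirror = tss - (anchor - tss)
    if anchor == tss:
        return None
    if window is not None and not (window[0] <= mirror < window[1]):
        return None
    return mirror


def matched_negatives(pairs, window=None):
    """Vector version of :func:`matched_negative`; returns (list, n_skipped)."""
    out, skipped = [], 0
    for tss, anchor in pairs:
        neg = matched_negative(tss, anchor, window)
        if neg is None:
            skipped += 1
        else:
            out.append((tss, neg))
    return out, skipped


def matched_negative_distribution(
    positive_distances: np.ndarray,
    pool: np.ndarray,
    n_bins: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Sample |positives| pool indices conserving the distance distribution.

    Distances are stratified into equal-width bins over the positive range;
    within each bin, candidates are drawn without replacement when possible.
    An empty pool bin that positives occupy is an error naming the bin.
    """
    positive_distances = np.asarray(positive_distances, dtype=float)
    pool = np.asarray(pool, dtype=float)
    rng = np.random.default_rng(seed)
    edges = np.linspace(
        positive_distances.min(), positive_distances.max() + 1e-9, n_bins + 1
    )
    pos_bins = np.clip(np.digitize(positive_distances, edges) - 1, 0, n_bins - 1)
    pool_bins = np.clip(np.digitize(pool, edges) - 1, 0, n_bins - 1)
    chosen = []
    for b in range(n_bins):
        need = int((pos_bins == b).sum())
        if need == 0:
            continue
        candidates = np.nonzero(pool_bins == b)[0]
        if candidates.size == 0:
            raise ValueError(
                f"candidate pool has no distances in band "
                f"[{edges[b]:.0f}, {edges[b + 1]:.0f})"
            )
        replace = candidates.size < need
        chosen.append(rng.choice(candidates, size=need, replace=replace))
    return np.concatenate(chosen)


def kfold_contexts(contexts, n_splits: int = 5, seed: int = 0):
    """Seeded context-level folds: a partition, no context in two folds."""
    contexts = list(contexts)
    if n_splits > len(contexts):
        raise ValueError("more folds than contexts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(contexts))
    folds = [sorted(order[i::n_splits].tolist()) for i in range(n_splits)]
    return [[contexts[i] for i in fold] for fold in folds]
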