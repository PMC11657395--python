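"""The context token: per-bin TF motif scores combined with TF expression.

A cellular context is specified to the model as a TF reference profile — a
vector of (quantile-normalized, log1p) expression values of a panel of
transcription factors. Sequence specificity enters through a PWM scan: each
bin receives, per TF, the maximum log-odds match score of that TF's motif
inside the bin, floored at zero ("no reported binding"). The model input is
the element-wise product of the two, broadcast over bins, padded with exact
zeros to the model's TF width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .core_data import BinnedRegion, encode_bases

_NEG_INF = -1e9  # ambiguous bases poison any window they appear in


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """A position weight matrix stored as width x 4 log-odds scores."""

    name: str
    log_odds: np.ndarray  # width x 4

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 4:
            raise ValueError(f"PWM {self.name}: log_odds must be width x 4")
        if self.log_odds.shape[0] < 1:
            raise ValueError(f"PWM {self.name}: width must be >= 1")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError(f"PWM {self.name}: log_odds must be finite")

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def consensus_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.log_odds.argmax(axis=1))


def pwm_from_counts(
    name: str, counts: np.ndarray, pseudocount: float = 0.25
) -> PWM:
    """Log-odds PWM from a width x 4 count matrix against uniform background."""
    counts = np.asarray(counts, dtype=float)
    probs = (counts + pseudocount) / (counts + pseudocount).sum(
        axis=1, keepdims=True
    )
    return PWM(name=name, log_odds=np.log(probs / 0.25))


@dataclass
class PWMSet:
    """An ordered collection of per-TF PWMs."""

    pwms: list[PWM] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pwms)

    def __iter__(self):
        return iter(self.pwms)

    def __getitem__(self, i: int) -> PWM:
        return self.pwms[i]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pwms]


def read_pwms_jaspar(path, pseudocount: float = 0.25) -> PWMSet:
    """Read JASPAR-format count matrices into a log-odds PWMSet."""
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
        out.append(pwm_from_counts(m.name or m.matrix_id, counts, pseudocount))
    return PWMSet(out)


def write_pwms_jaspar(path, counts_by_name: dict[str, np.ndarray]) -> None:
    """Write integer count matrices in JASPAR (4-row) format."""
    with open(path, "w") as fh:
        for name, counts in counts_by_name.items():
            counts = np.asarray(counts)
            fh.write(f">{name} {name}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{int(c):6d}" for c in counts[:, bi])
                fh.write(f"{base} [{row} ]\n")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def scan_max_score(pwm: PWM, bin_sequence: str) -> float:
    """Maximum log-odds match of ``pwm`` within a bin, floored at 0.

    The forward strand only is scanned (use ``both_strands`` scanning at the
    region level for the optional double-strand mode). A bin shorter than the
    motif scores 0 with a warning.
    """
    codes = encode_bases(bin_sequence)
    if codes.size < pwm.width:
        warnings.warn(
            f"bin shorter than PWM {pwm.name} (len {codes.size} < width "
            f"{pwm.width}); scoring 0",
            stacklevel=2,
        )
        return 0.0
    scores = _offset_scores(pwm.log_odds, codes)
    return max(0.0, float(scores.max()))


def _offset_scores(log_odds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Sum of log-odds at every offset (vectorized over offsets)."""
    width = log_odds.shape[0]
    lo = np.hstack([log_odds, np.full((width, 1), _NEG_INF)])  # col 4: ambiguous
    n = codes.size - width + 1
    scores = np.zeros(n)
    for w in range(width):
        scores += lo[w, codes[w : w + n]]
    return scores


def reverse_complement_pwm(pwm: PWM) -> PWM:
    return PWM(name=pwm.name, log_odds=pwm.log_odds[::-1, ::-1].copy())


def scan_bins(
    pwms: PWMSet,
    sequence: str,
    region: BinnedRegion,
    both_strands: bool = False,
) -> np.ndarray:
    """Per-bin maximum motif score for every TF: a bins x n_tf matrix.

    Only windows fully contained in a bin contribute to that bin's score, so
    a bin's score is invariant to sequence outside the bin. Scores are floored
    at 0.
    """
    if len(sequence) != region.end - region.start:
        raise ValueError(
            f"sequence length {len(sequence)} != region span "
            f"{region.end - region.start}"
        )
    codes = encode_bases(sequence)
    bs = region.bin_size
    n_bins = region.n_bins
    out = np.zeros((n_bins, len(pwms)))
    for t, pwm in enumerate(pwms):
        variants = [pwm] + ([reverse_complement_pwm(pwm)] if both_strands else [])
        if pwm.width > bs:
            warnings.warn(
                f"bins shorter than PWM {pwm.name}; scoring 0", stacklevel=2
            )
            continue
        best = np.full(n_bins, -np.inf)
        for var in variants:
            scores = _offset_scores(var.log_odds, codes)
            # offset p starts a window inside bin p//bs iff p % bs <= bs-width
            padded = np.full(n_bins * bs, -np.inf)
            padded[: scores.size] = scores
            per_bin = padded.reshape(n_bins, bs)
            valid = bs - var.width
            best = np.maximum(best, per_bin[:, : valid + 1].max(axis=1))
        out[:, t] = np.maximum(best, 0.0)
    return out


# ---------------------------------------------------------------------------
# Expression processing and combination
# ---------------------------------------------------------------------------

def quantile_normalize(tpm: np.ndarray, log: bool = True) -> np.ndarray:
    """log1p then classical quantile normalization of a genes x contexts table.

    All columns are mapped onto the mean-of-sorted-columns reference
    distribution; tied values receive the mean of the reference values their
    ranks span (average-tie policy).
    """
    x = np.asarray(tpm, dtype=float)
    if np.any(x < 0):
        raise ValueError("TPM values must be non-negative")
    if log:
        x = np.log1p(x)
    if x.ndim != 2:
        raise ValueError("expected a genes x contexts matrix")
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for k in range(x.shape[1]):
        ranks = rankdata(x[:, k], method="average")  # 1..n, ties averaged
        out[:, k] = np.interp(ranks, np.arange(1, n + 1), reference)
    return out


def default_padded_width(n_tf: int) -> int:
    """Pad the TF panel to the next even width (711 -> 712)."""
    return n_tf if n_tf % 2 == 0 else n_tf + 1


def combine(
    motif_scores: np.ndarray,
    expression_row: np.ndarray,
    n_tf_padded: int | None = None,
) -> np.ndarray:
    """Element-wise product of motif scores and expression, zero-padded.

    ``out[j, t] = motif_scores[j, t] * expression_row[t]`` for real TFs;
    padded columns are exactly zero in both factors and in the product.
    """
    motif_scores = np.asarray(motif_scores, dtype=float)
    expression_row = np.asarray(expression_row, dtype=float)
    if motif_scores.ndim != 2:
        raise ValueError("motif_scores must be bins x n_tf")
    n_tf = motif_scores.shape[1]
    if expression_row.shape != (n_tf,):
        raise ValueError(
            f"expression has shape {expression_row.shape}, motif scores have "
            f"{n_tf} TFs"
        )
    if n_tf_padded is None:
        n_tf_padded = default_padded_width(n_tf)
    if n_tf_padded < n_tf:
        raise ValueError(f"n_tf_padded ({n_tf_padded}) < n_tf ({n_tf})")
    out = np.zeros((motif_scores.shape[0], n_tf_padded))
    out[:, :n_tf] = motif_scores * expression_row[np.newaxis, :]
    return out


@dataclass
class TFFeatureBlock:
    """Per-bin motif scores plus per-context expression for one TF panel."""

    motif_scores: np.ndarray          # bins x n_tf, >= 0
    expression: np.ndarray            # contexts x n_tf (processed scale)
    tf_names: list[str]
    n_tf_padded: int | None = None

    def __post_init__(self) -> None:
        self.motif_scores = np.asarray(self.motif_scores, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        if np.any(self.motif_scores < 0):
            raise ValueError("motif scores must be >= 0 (floored scan scores)")
        n_tf = self.motif_scores.shape[1]
        if self.expression.shape[1] != n_tf:
            raise ValueError("expression and motif_scores disagree on n_tf")
        if len(self.tf_names) != n_tf:
            raise ValueError("tf_names length mismatch")
        if self.n_tf_padded is None:
            self.n_tf_padded = default_padded_width(n_tf)

    @property
    def n_tf(self) -> int:
        return self.motif_scores.shape[1]

    def block_for(self, context_index: int) -> np.ndarray:
        """bins x n_tf_padded combined feature block for one context."""
        return combine(
            self.motif_scores,
            self.expression[context_index],
            self.n_tf_padded,
        )
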