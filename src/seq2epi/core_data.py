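"""Coordinate frame, preprocessing arithmetic, and I/O for binned genomic data.

Everything downstream of this module works on a :class:`BinnedRegion` — a
genomic window partitioned into fixed-width bins — together with a
:class:`SignalTensor` holding the processed epigenomic signal levels for a set
of cellular contexts, and a per-(context, signal) availability mask for tracks
that were never measured in a given context.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: The eight epigenomic tracks modelled by default, in canonical order.
DEFAULT_SIGNALS = (
    "DNase",
    "CTCF",
    "H3K27ac",
    "H3K4me3",
    "H3K36me3",
    "H3K27me3",
    "H3K9me3",
    "H3K4me1",
)

_ONEHOT_ROWS = {"A": 0, "C": 1, "G": 2, "T": 3}
# IUPAC ambiguity codes map to an all-zero row; anything else is rejected.
_IUPAC_AMBIGUOUS = set("NRYSWKMBDHV")


# ---------------------------------------------------------------------------
# Binned regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinnedRegion:
    """A genomic window tiled by fixed-width bins.

    Bin ``j`` spans ``[start + j*bin_size, start + (j+1)*bin_size)``.
    """

    chrom: str
    start: int
    end: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if self.end <= self.start:
            raise ValueError(
                f"empty region: end ({self.end}) must exceed start ({self.start})"
            )
        span = self.end - self.start
        remainder = span % self.bin_size
        if remainder:
            raise ValueError(
                f"region span {span} is not a multiple of bin_size "
                f"{self.bin_size} (remainder {remainder})"
            )

    @property
    def n_bins(self) -> int:
        return (self.end - self.start) // self.bin_size

    def bin_bounds(self, j: int) -> tuple[int, int]:
        """Base-pair bounds of bin ``j`` (0-based half-open)."""
        if not 0 <= j < self.n_bins:
            raise IndexError(f"bin index {j} out of range [0, {self.n_bins})")
        lo = self.start + j * self.bin_size
        return lo, lo + self.bin_size

    def bin_of(self, pos: int) -> int:
        """Bin index containing base-pair position ``pos``."""
        if not self.start <= pos < self.end:
            raise ValueError(
                f"position {pos} outside region "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        return (pos - self.start) // self.bin_size


def make_bins(chrom: str, start: int, end: int, bin_size: int) -> BinnedRegion:
    """Partition ``[start, end)`` on ``chrom`` into bins of ``bin_size`` bp."""
    return BinnedRegion(chrom=chrom, start=start, end=end, bin_size=bin_size)


# ---------------------------------------------------------------------------
# Count preprocessing
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw read counts for a set of loci across contexts.

    ``depths[k]`` is the total pooled library size of context ``k`` (not the
    within-window sum), used for depth normalization.
    """

    counts: np.ndarray  # loci x contexts
    depths: np.ndarray  # contexts

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a loci x contexts matrix")
        if self.depths.shape != (self.counts.shape[1],):
            raise ValueError(
                f"depths has shape {self.depths.shape}, expected "
                f"({self.counts.shape[1]},)"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.depths <= 0):
            raise ValueError("all library depths must be positive")


def normalize_counts(cm: CountMatrix) -> np.ndarray:
    """Depth-normalize raw counts: ``n_tilde[l,k] = N * n[l,k] / N_k``.

    ``N = min_k N_k`` is the smallest library; its column is returned
    unchanged, all other columns are scaled down to the common depth.
    """
    n_min = float(np.min(cm.depths))
    return n_min * cm.counts.astype(float) / cm.depths[np.newaxis, :]


def log1p_signal(x: np.ndarray) -> np.ndarray:
    """log(1 + x) elementwise; the pseudo-count stabilizes zero bins."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("log1p_signal requires non-negative input")
    return np.log1p(x)


def binarize_counts(raw: np.ndarray, threshold: int = 30) -> np.ndarray:
    """Binary open/closed labels: 1 iff raw count strictly exceeds threshold."""
    raw = np.asarray(raw)
    if np.any(raw < 0):
        raise ValueError("raw counts must be non-negative")
    return (raw > threshold).astype(np.int8)


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

def one_hot(seq: str) -> np.ndarray:
    """One-hot encode a DNA string as a length x 4 matrix (columns A,C,G,T).

    Ambiguous IUPAC bases (N etc.) become all-zero rows; characters outside
    the IUPAC alphabet are rejected with their position.
    """
    out = np.zeros((len(seq), 4), dtype=np.float64)
    for i, ch in enumerate(seq):
        c = ch.upper()
        row = _ONEHOT_ROWS.get(c)
        if row is not None:
            out[i, row] = 1.0
        elif c not in _IUPAC_AMBIGUOUS:
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}")
    return out


def encode_bases(seq: str) -> np.ndarray:
    """Integer-encode DNA (A,C,G,T -> 0..3; ambiguous IUPAC -> 4).

    Vectorized companion to :func:`one_hot` used by the motif scanner and the
    simulator; rejects non-IUPAC characters with their position.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    table = np.full(256, 255, dtype=np.uint8)
    for base, idx in _ONEHOT_ROWS.items():
        table[ord(base)] = idx
    for base in _IUPAC_AMBIGUOUS:
        table[ord(base)] = 4
    codes = table[arr]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"non-IUPAC character {seq[i]!r} at position {i}")
    return codes.astype(np.int64)


def one_hot_from_codes(codes: np.ndarray) -> np.ndarray:
    """One-hot matrix from integer codes (code 4 -> all-zero row)."""
    eye = np.vstack([np.eye(4), np.zeros((1, 4))])
    return eye[codes]


# ---------------------------------------------------------------------------
# Signal tensor container
# ---------------------------------------------------------------------------

@dataclass
class SignalTensor:
    """Processed signals: ``values[c, j, k]`` for context c, bin j, track k.

    ``mask[c, k]`` is True where track k was measured in context c. Missing
    cells are stored as zeros and must never contribute to losses or metrics;
    the mask — not a sentinel value — is the single source of truth.
    """

    values: np.ndarray              # contexts x bins x signals
    mask: np.ndarray                # contexts x signals (bool)
    signal_names: list[str] = field(default_factory=lambda: list(DEFAULT_SIGNALS))
    contexts: list[str] = field(default_factory=list)
    region: BinnedRegion | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be contexts x bins x signals")
        c, _, k = self.values.shape
        if self.mask.shape != (c, k):
            raise ValueError(
                f"mask has shape {self.mask.shape}, expected ({c}, {k})"
            )
        if len(self.signal_names) != k:
            raise ValueError("signal_names length must match values.shape[2]")
        if not self.contexts:
            self.contexts = [f"ctx{i}" for i in range(c)]
        bad = self.mask[:, np.newaxis, :] & ~np.isfinite(self.values)
        if bad.any():
            raise ValueError("values must be finite wherever mask is true")

    @property
    def n_contexts(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_signals(self) -> int:
        return self.values.shape[2]

    def to_hdf5(self, path) -> None:
        import h5py

        header: dict = {"version": 1}
        if self.region is not None:
            header["region"] = {
                "chrom": self.region.chrom,
                "start": self.region.start,
                "end": self.region.end,
                "bin_size": self.region.bin_size,
            }
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("mask", data=self.mask)
            f.create_dataset(
                "signal_names",
                data=np.array(self.signal_names, dtype=h5py.string_dtype()),
            )
            f.create_dataset(
                "contexts", data=np.array(self.contexts, dtype=h5py.string_dtype())
            )
            f.attrs["header"] = json.dumps(header, sort_keys=True)

    @classmethod
    def from_hdf5(cls, path) -> "SignalTensor":
        import h5py

        with h5py.File(path, "r") as f:
            values = f["values"][...]
            mask = f["mask"][...]
            signal_names = [s.decode() for s in f["signal_names"][...]]
            contexts = [s.decode() for s in f["contexts"][...]]
            header = json.loads(f.attrs["header"])
        region = None
        if "region" in header:
            r = header["region"]
            region = BinnedRegion(r["chrom"], r["start"], r["end"], r["bin_size"])
        return cls(
            values=values,
            mask=mask,
            signal_names=signal_names,
            contexts=contexts,
            region=region,
        )


# ---------------------------------------------------------------------------
# BED / count-table ingestion
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple]:
    """Parse a BED3+ file into (chrom, start, end, *rest) tuples.

    Malformed lines are rejected with their 1-based line number.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            records.append((fields[0], start, end, *fields[3:]))
    return records


def write_bed(path, records) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def load_signals(
    bed_path,
    counts_path,
    region: BinnedRegion,
    signal_names=DEFAULT_SIGNALS,
) -> SignalTensor:
    """Build a :class:`SignalTensor` from a locus BED and a long count table.

    The BED rows must be exactly the bins of ``region`` (same order). The
    count table is TSV with columns ``locus_id  context  signal  count  depth``
    where ``locus_id`` indexes BED rows and ``depth`` is the per-(context,
    signal) library size. A (context, signal) pair with no rows at all is
    recorded as unavailable in the mask; the processing pipeline for present
    pairs is depth normalization followed by log1p.
    """
    import pandas as pd

    loci = read_bed(bed_path)
    if len(loci) != region.n_bins:
        raise ValueError(
            f"{bed_path}: {len(loci)} loci, but region has {region.n_bins} bins"
        )
    for i, (chrom, start, end, *_rest) in enumerate(loci):
        if chrom != region.chrom or (start, end) != region.bin_bounds(i):
            raise ValueError(
                f"{bed_path}: locus {i} ({chrom}:{start}-{end}) does not match "
                f"bin {i} of region {region.chrom}:{region.start}-{region.end}"
            )

    table = pd.read_csv(
        counts_path,
        sep="\t",
        dtype={"locus_id": int, "context": str, "signal": str},
    )
    required = {"locus_id", "context", "signal", "count", "depth"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{counts_path}: missing columns {sorted(missing)}")
    if (table["locus_id"] < 0).any() or (table["locus_id"] >= region.n_bins).any():
        raise ValueError(f"{counts_path}: locus_id outside region bins")

    contexts = sorted(table["context"].unique())
    signal_names = list(signal_names)
    n_c, n_j, n_k = len(contexts), region.n_bins, len(signal_names)
    values = np.zeros((n_c, n_j, n_k))
    mask = np.zeros((n_c, n_k), dtype=bool)

    for k, sig in enumerate(signal_names):
        sub = table[table["signal"] == sig]
        present = [c for c in contexts if c in set(sub["context"])]
        if not present:
            continue
        counts = np.zeros((n_j, len(present)))
        depths = np.zeros(len(present))
        for ci, ctx in enumerate(present):
            rows = sub[sub["context"] == ctx]
            counts[rows["locus_id"].to_numpy(), ci] = rows["count"].to_numpy()
            depths[ci] = rows["depth"].iloc[0]
        processed = log1p_signal(normalize_counts(CountMatrix(counts, depths)))
        for ci, ctx in enumerate(present):
            c = contexts.index(ctx)
            values[c, :, k] = processed[:, ci]
            mask[c, k] = True

    return SignalTensor(
        values=values,
        mask=mask,
        signal_names=signal_names,
        contexts=contexts,
        region=region,
    )
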