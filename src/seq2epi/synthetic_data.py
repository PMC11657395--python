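"""Synthetic fixtures with planted, recoverable regulatory structure.

The generator emulates the statistical structure the model assumes, at desk
scale and with full ground truth:

* a random genome with consensus motif sites of a few *planted regulator*
  TFs written into recorded bins;
* cellular contexts specified by TF expression vectors — each context
  activates one planted regulator (round-robin) at a high level while the
  remaining planted TFs idle near zero, so contexts are distinguishable
  purely through expression;
* signals generated by a known rule,
  ``y[c,j,k] = softplus(sum_t W[t,k] * motif[j,t] * expr[c,t])``,
  smoothed over +/-s bins and optionally perturbed with Gaussian noise;
* an availability mask dropping a random subset of (context, signal) pairs;
* chromatin loops connecting planted element bins to designated "TSS" bins
  inside the same window (plus insignificant decoy loops that the q-value
  filter must remove);
* SNVs that either ablate a planted consensus base (effect variants) or
  fall in bins without planted sites (neutral variants).

Everything the pipeline ingests is written in its standard format (FASTA,
BED, TSV, HDF5, BEDPE, VCF) together with a truth JSON for recovery tests.
Outputs are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core_data import BinnedRegion, SignalTensor, DEFAULT_SIGNALS, write_bed
from .tf_features import PWMSet, pwm_from_counts, scan_bins, write_pwms_jaspar

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chrom: str = "chrS"
    genome_length: int = 524_288
    bin_size: int = 128
    window_length: int = 4_096
    n_tfs: int = 8
    n_planted_regulators: int = 4
    n_contexts: int = 6
    motif_width: int = 12
    sites_per_regulator: int = 60
    w_planted: float = 0.3
    w_background: float = 0.02
    smoothing_bins: int = 0
    noise_sd: float = 0.1
    mask_rate: float = 0.25
    loops_per_window: int = 1
    anchor_span_bins: int = 3
    n_decoy_loops: int = 20
    n_effect_variants: int = 30
    n_neutral_variants: int = 30
    active_low: tuple[float, float] = (0.01, 0.1)
    active_high: tuple[float, float] = (1.0, 2.0)
    background_expr: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if self.genome_length % self.window_length:
            raise ValueError("genome_length must be a multiple of window_length")
        if self.window_length % self.bin_size:
            raise ValueError("window_length must be a multiple of bin_size")
        if self.n_planted_regulators > self.n_tfs:
            raise ValueError("cannot plant more regulators than TFs")
        if self.noise_sd < 0 or not (0 <= self.mask_rate < 1):
            raise ValueError("noise_sd must be >= 0 and mask_rate in [0, 1)")

    @property
    def n_bins(self) -> int:
        return self.genome_length // self.bin_size

    @property
    def n_windows(self) -> int:
        return self.genome_length // self.window_length

    @property
    def bins_per_window(self) -> int:
        return self.window_length // self.bin_size


@dataclass
class SimResult:
    """Paths of the emitted files plus in-memory truth for convenience."""

    outdir: Path
    config: SimConfig
    truth: dict
    motif_scores: np.ndarray       # bins x n_tfs
    expression_true: np.ndarray    # contexts x n_tfs (signal-rule scale)
    clean: np.ndarray              # contexts x bins x K (noise-free rule)
    values: np.ndarray             # contexts x bins x K (observed)
    mask: np.ndarray               # contexts x K

    @property
    def paths(self) -> dict:
        d = self.outdir
        return {
            "fasta": d / "genome.fa",
            "regions": d / "regions.bed",
            "expression": d / "expression.tsv",
            "signals": d / "signals.h5",
            "signals_clean": d / "signals_clean.h5",
            "loops": d / "loops.bedpe",
            "variants": d / "variants.vcf",
            "pwms": d / "pwms.jaspar",
            "truth": d / "truth.json",
        }


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate(config: SimConfig, outdir) -> SimResult:
    """Generate the full fixture set under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    K = len(DEFAULT_SIGNALS)

    # --- PWMs: sharp random consensus motifs for every TF ------------------
    consensus_idx = rng.integers(0, 4, size=(config.n_tfs, config.motif_width))
    counts_by_name = {}
    pwms = []
    for t in range(config.n_tfs):
        # sharp consensus: chance matches in random sequence floor to 0
        counts = np.full((config.motif_width, 4), 1, dtype=int)
        counts[np.arange(config.motif_width), consensus_idx[t]] = 97
        name = f"TF{t}"
        counts_by_name[name] = counts
        pwms.append(pwm_from_counts(name, counts))
    pwm_set = PWMSet(pwms)
    write_pwms_jaspar(outdir / "pwms.jaspar", counts_by_name)

    # --- genome with planted consensus sites --------------------------------
    genome = rng.integers(0, 4, size=config.genome_length)
    capacity = config.n_bins
    need = config.n_planted_regulators * config.sites_per_regulator
    if need > capacity // 2:
        raise ValueError(
            f"requested {need} planted sites exceed genome capacity "
            f"({capacity} bins)"
        )
    site_bins = rng.choice(capacity, size=need, replace=False)
    offset = (config.bin_size - config.motif_width) // 2
    sites = []
    for i, b in enumerate(site_bins):
        t = i % config.n_planted_regulators
        pos = int(b) * config.bin_size + offset
        genome[pos : pos + config.motif_width] = consensus_idx[t]
        sites.append({"tf": int(t), "bin": int(b), "pos": pos})
    sites.sort(key=lambda s: s["pos"])
    seq = "".join(_BASES[i] for i in genome)
    with open(outdir / "genome.fa", "w") as fh:
        fh.write(f">{config.chrom}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")

    # --- windows -------------------------------------------------------------
    windows = [
        (config.chrom, w * config.window_length, (w + 1) * config.window_length,
         f"win{w}")
        for w in range(config.n_windows)
    ]
    write_bed(outdir / "regions.bed", windows)

    # --- expression: one active regulator per context (round-robin) ----------
    e_true = rng.uniform(*config.background_expr,
                         size=(config.n_contexts, config.n_tfs))
    active = []
    for c in range(config.n_contexts):
        r = c % config.n_planted_regulators
        active.append(r)
        for t in range(config.n_planted_regulators):
            lo, hi = (config.active_high if t == r else config.active_low)
            e_true[c, t] = rng.uniform(lo, hi)
    tf_names = [f"TF{t}" for t in range(config.n_tfs)]
    ctx_names = [f"ctx{c}" for c in range(config.n_contexts)]
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("gene\t" + "\t".join(ctx_names) + "\n")
        for t, name in enumerate(tf_names):
            tpm = np.expm1(e_true[:, t])
            fh.write(name + "\t" + "\t".join(f"{v:.8f}" for v in tpm) + "\n")

    # --- signal rule ----------------------------------------------------------
    region = BinnedRegion(config.chrom, 0, config.genome_length, config.bin_size)
    motif = scan_bins(pwm_set, seq, region)  # bins x n_tfs
    W = np.full((config.n_tfs, K), config.w_background)
    W[: config.n_planted_regulators] = config.w_planted
    W = W * rng.uniform(0.5, 1.5, size=W.shape)
    linear = np.einsum("ct,jt,tk->cjk", e_true, motif, W)
    clean = _softplus(linear)
    if config.smoothing_bins > 0:
        clean = uniform_filter1d(
            clean, size=2 * config.smoothing_bins + 1, axis=1, mode="nearest"
        )
    values = clean.copy()
    if config.noise_sd > 0:
        values = values + rng.normal(0, config.noise_sd, size=values.shape)
        values = np.maximum(values, 0.0)

    # --- availability mask ------------------------------------------------------
    mask = rng.random((config.n_contexts, K)) >= config.mask_rate
    for c in range(config.n_contexts):      # every context keeps >= 1 signal
        if not mask[c].any():
            mask[c, int(rng.integers(0, K))] = True
    for k in range(K):                       # every signal observed somewhere
        if not mask[:, k].any():
            mask[int(rng.integers(0, config.n_contexts)), k] = True

    tensor = SignalTensor(
        values=np.where(mask[:, None, :], values, 0.0),
        mask=mask,
        signal_names=list(DEFAULT_SIGNALS),
        contexts=ctx_names,
        region=region,
    )
    tensor.to_hdf5(outdir / "signals.h5")
    SignalTensor(
        values=clean,
        mask=np.ones_like(mask),
        signal_names=list(DEFAULT_SIGNALS),
        contexts=ctx_names,
        region=region,
    ).to_hdf5(outdir / "signals_clean.h5")

    # --- loops: planted element->TSS contacts plus insignificant decoys ---------
    bpw = config.bins_per_window
    site_bins_set = {s["bin"] for s in sites}
    contacts = []
    loop_lines = []
    for w in range(config.n_windows):
        in_window = [s for s in sites if w * bpw <= s["bin"] < (w + 1) * bpw]
        rng.shuffle(in_window)
        for s in in_window[: config.loops_per_window]:
            b_e = s["bin"]
            candidates = [
                b for b in range(w * bpw + 2, (w + 1) * bpw - 2)
                if b not in site_bins_set and abs(b - b_e) >= 4
            ]
            if not candidates:
                continue
            b_t = int(candidates[int(rng.integers(0, len(candidates)))])
            score = float(rng.uniform(5, 50))
            contacts.append(
                {"window": w, "element_bin": int(b_e), "tss_bin": b_t,
                 "tf": s["tf"], "score": score}
            )
            loop_lines.append(_loop_line(config, b_e, b_t, score, 1e-6,
                                         f"loop{len(contacts)}",
                                         span=config.anchor_span_bins))
    for d in range(config.n_decoy_loops):
        a, b = rng.integers(0, config.n_bins, size=2)
        loop_lines.append(
            _loop_line(config, int(a), int(b), float(rng.uniform(1, 5)),
                       float(rng.uniform(0.01, 0.5)), f"decoy{d}",
                       span=config.anchor_span_bins)
        )
    with open(outdir / "loops.bedpe", "w") as fh:
        fh.write("\n".join(loop_lines) + "\n")

    # --- variants -----------------------------------------------------------------
    info_pos = int(np.argmax(np.ptp(pwms[0].log_odds, axis=1)))  # same for all
    eff_sites = [sites[i] for i in
                 rng.choice(len(sites), size=config.n_effect_variants,
                            replace=False)]
    variants = []
    for s in eff_sites:
        t = s["tf"]
        ref_i = int(consensus_idx[t, info_pos])
        lo_row = pwms[t].log_odds[info_pos]
        alt_i = int(np.argmin(lo_row))
        variants.append(
            {"pos": s["pos"] + info_pos, "ref": _BASES[ref_i],
             "alt": _BASES[alt_i], "class": "effect", "tf": t,
             "bin": s["bin"]}
        )
    free_bins = np.array(sorted(set(range(config.n_bins)) - site_bins_set))
    for b in rng.choice(free_bins, size=config.n_neutral_variants, replace=False):
        pos = int(b) * config.bin_size + int(rng.integers(0, config.bin_size))
        ref_i = int(genome[pos])
        alt_i = int((ref_i + 1 + rng.integers(0, 3)) % 4)
        variants.append(
            {"pos": pos, "ref": _BASES[ref_i], "alt": _BASES[alt_i],
             "class": "neutral", "tf": -1, "bin": int(b)}
        )
    variants.sort(key=lambda v: v["pos"])
    with open(outdir / "variants.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={config.chrom},length={config.genome_length}>\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,'
                 'Description="Planted variant class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, v in enumerate(variants):
            fh.write(
                f"{config.chrom}\t{v['pos'] + 1}\tvar{i}\t{v['ref']}\t"
                f"{v['alt']}\t.\tPASS\tCLASS={v['class']}\n"
            )

    truth = {
        "config": asdict(config),
        "sites": sites,
        "active_regulator": active,
        "expression_true": e_true.tolist(),
        "W": W.tolist(),
        "mask": mask.tolist(),
        "contacts": contacts,
        "variants": variants,
        "tf_names": tf_names,
        "contexts": ctx_names,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)

    return SimResult(
        outdir=outdir,
        config=config,
        truth=truth,
        motif_scores=motif,
        expression_true=e_true,
        clean=clean,
        values=tensor.values,
        mask=mask,
    )


def _loop_line(config, bin_a, bin_b, score, q, name, span=1):
    """Anchors span ``span`` bins centred on the loop bins (clipped)."""
    bs = config.bin_size
    half = (span - 1) // 2
    lo_a = max(bin_a - half, 0) * bs
    hi_a = min(bin_a + half + 1, config.n_bins) * bs
    lo_b = max(bin_b - half, 0) * bs
    hi_b = min(bin_b + half + 1, config.n_bins) * bs
    return "\t".join(
        str(x)
        for x in (
            config.chrom, lo_a, hi_a, config.chrom, lo_b, hi_b,
            name, f"{score:.4f}", f"{q:.3e}",
        )
    )


def oracle_scores(truth: dict) -> dict:
    """Expected relationships derivable from the truth file alone.

    Keys for recovery tests: which TF should top GIS rankings in each
    context and window, which bin pairs are true contacts, and which
    variants carry a planted effect.
    """
    bpw = truth["config"]["window_length"] // truth["config"]["bin_size"]
    windows_of_tf: dict[int, set] = {}
    for s in truth["sites"]:
        windows_of_tf.setdefault(s["tf"], set()).add(s["bin"] // bpw)
    return {
        "regulator_of_context": {
            ctx: int(r)
            for ctx, r in zip(truth["contexts"], truth["active_regulator"])
        },
        "windows_with_regulator": {
            int(t): sorted(ws) for t, ws in windows_of_tf.items()
        },
        "true_contacts": [
            (c["window"], c["element_bin"], c["tss_bin"])
            for c in truth["contacts"]
        ],
        "effect_variants": [
            i for i, v in enumerate(truth["variants"]) if v["class"] == "effect"
        ],
        "neutral_variants": [
            i for i, v in enumerate(truth["variants"]) if v["class"] == "neutral"
        ],
        "expected_effect": [
            0.0 if v["class"] == "neutral" else 1.0 for v in truth["variants"]
        ],
    }
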