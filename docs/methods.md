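# Methods

## Model

`seq2epi` predicts K epigenomic signal tracks (default eight: DNase, CTCF,
H3K27ac, H3K4me3, H3K36me3, H3K27me3, H3K9me3, H3K4me1) over a genomic
window partitioned into fixed-width bins, conditioned on a cellular context
that is supplied *as input* — a TF reference profile of expression values
for a panel of transcription factors. Because the context is an input
rather than a learned output head, the model can predict for contexts never
seen in training, given only their expression.

The network has four parts:

1. **Sequence module.** The one-hot DNA window (L × 4, columns A, C, G, T;
   ambiguous bases are zero rows) passes through five 1-D convolution
   blocks, each a same-padded convolution → ReLU → max-pool. The pool
   factors multiply to the bin size, so L bp become T = L / bin_size tokens
   with C sequence channels. At full scale L = 128,000, bin = 128, C = 256,
   giving 1000 tokens; the desk-scale profile uses L = 4096 and C = 16.
2. **TF module.** Each TF's position weight matrix is scanned against each
   bin; the bin's score for that TF is the maximum sum of log-odds over all
   offsets fully inside the bin, floored at 0 ("no reported binding").
   Expression values (log1p TPM, quantile-normalized across contexts) are
   broadcast-multiplied with the motif scores and zero-padded to the model
   width n_tf (711 → 712 at full scale). The element-wise product means a
   TF contributes only where it both *can* bind (motif) and *is present*
   (expression).
3. **Transformer module.** Tokens of width d_model = C + n_tf (968 at full
   scale), plus a learned absolute position embedding, pass through N_t
   post-norm encoder layers: multi-head self-attention
   (softmax(QKᵀ/√d_k)V, n_h heads, d_k = d_v = d_model / n_h = 121 at full
   scale), add & norm, feed-forward, add & norm. Attention matrices are
   row-stochastic and can be captured for interpretation.
4. **Prediction module.** A per-token affine map to K values (regression)
   or affine + sigmoid (classification).

Unstated architectural details are set to conventional values and are all
configurable: convolution kernel 9 (5 in the desk profile), FFN width
4·d_model with GELU, dropout 0, pool factors (2, 2, 2, 4, 4).

## Losses and training

**Masked multi-task MSE.** A training instance is a (context, window) pair.
Contexts rarely have all K tracks measured; per instance the squared error
is summed over the available signal set B_i, divided by |B_i|, averaged
over bins, then over the minibatch. Instances with B_i empty contribute
zero. Missing tracks are stored as zeros behind a boolean mask and can
never leak into the loss.

**Contact guidance (CSL).** Chromatin loops (BEDPE with score and q-value)
are filtered at q ≤ 0.001 and aggregated onto bin pairs: each loop adds its
score to every (bin_a, bin_b) combination its two anchors overlap,
symmetrically, giving H; rows are normalized to sum to 1 (H̃), with all-zero
rows treated as missing data and excluded. The guidance term is
1 − mean row cosine between H̃ and the head-averaged attention of the last
encoder layer (configurable `last_n_layers`), and the total loss is
masked MSE + α·CSL with α = 2. The sign convention (lower = better, 0 =
perfect alignment) is this package's definition of the cosine-similarity
penalty.

**Optimizer.** Adam (β₁ = 0.9, β₂ = 0.999). The full-scale profile uses
learning rate 5×10⁻⁵ and batch 10; the desk profile uses 1×10⁻³,
batch 4, 1000 steps, 50-step linear warmup and cosine decay, chosen for
convergence at desk scale (the α = 0 arm reaches the analytic oracle floor
of the synthetic rule, see below). Training is deterministic given the seed
under single-threaded math. The implementation is numpy + reverse-mode
autodiff (`autograd`); parameters are float32 during training, float64 for
gradient-attribution analyses.

**Fine-tuning for element–promoter pairs.** The backbone is frozen; the
feature for a candidate pair is the concatenation of last-layer hidden
states of all bins whose midpoints fall inside the two anchors, and the
head is a two-hidden-layer MLP (256 units each at full scale, configurable)
with a sigmoid output trained by Adam on cross-entropy.

## Interpretation machinery

**GIS / IGIS.** The gradient importance score of TF t for signal k over a
window is the mean absolute gradient of the predicted signal at the TF's
bound bins ζ (bins with positive motif score) with respect to the TF's
input entry. Two differentiation targets are supported, because the two
downstream analyses need different questions answered: the combined
motif × expression product entry
(per-bin diagonal derivative ∂ŷ[l,k]/∂tf[l,t]), and the raw expression
entry ∂ŷ[l,k]/∂e_t. IGIS averages each TF's descending rank (1 = largest,
ties averaged) across the K signals. Empty ζ defines GIS = 0 with a
warning. Note that in a near-linear model the product-entry gradient is
independent of expression, so the expression target is the appropriate one
for asking "which expressed TF regulates this window" — the regulator
recovery experiment uses it.

**Attention pair scores.** Element–gene pairs within 64 kbp are scored from
the attention matrix averaged over all layers and heads: either the total
attention received by the element's token (column mode, default) or the
single element→TSS entry (direct mode).

**Variant LOS.** For an SNV centred in its window, the reference and
alternative windows are both run through the model — the alternative's TF
features are re-scanned, so motif-destroying substitutions propagate
through both the sequence and TF channels. Per signal, LOS =
log(output_alt + ε) − log(output_ref + ε) at the variant's bin (natural
log, ε = 10⁻⁶, negative regression outputs floored at 0; the score is
signed and exactly antisymmetric under ref/alt exchange). The attention LOS
sums |log mass ratio| over the 11 bins at offsets −5…+5, where a bin's mass
is the attention it receives summed over queries (column mass; the row sums
of a row-stochastic average are identically 1, so a plain row-mass variant
would be degenerate). Edge-truncated windows are summed over the surviving
bins with a warning. Per context the feature vector is the K signal LOS
plus the attention LOS — 9·|contexts| features (252 at the 28-context full
scale). Downstream classifiers (random forest with 10 trees, MLP) are thin
scikit-learn wrappers; the features are the content.

**Percentile-rank prioritization.** A variant's rank within its background
SNPs is the fraction of background scores exceeding it (midrank for ties);
exchangeable scores give 0.5 in expectation, which the acceptance suite
verifies by Monte Carlo.

**k-mer baseline.** Overlapping k-mer counts (k = 5 → 1024 features),
ambiguous k-mers dropped.

## Evaluation

Cell-type-wise metrics are computed within a test context across loci:
Pearson and Spearman correlations and PSR = 1 − SS_res/SS_tot about the
context mean (an R²; undefined for constant truth, reported missing).
Binary tasks use trapezoidal auROC and step-wise auPRC (scikit-learn), with
unweighted macro averages across classes. Element–gene pairs are
stratified into half-open distance bands 0–20/20–40/40–64 kbp; pairs beyond
64 kbp are excluded. Negatives are matched either exactly (anchor mirrored
to the opposite side of the TSS, identical distance) or distributionally
(stratified sampling over distance bins, seeded, erroring on uncoverable
bins).

## Synthetic data: what it emulates and what it does not

The generator plants recoverable structure at desk scale (defaults:
512-kb genome, 128-bp bins, 4-kb windows, 8 TFs of which 4 are planted
regulators, 6 contexts, 60 sites per regulator):

- **Motifs** are width-12 sharp consensus PWMs (97/1 count columns). In
  random sequence their best within-bin match almost always floors to 0,
  so planted sites dominate the signal variance. Real PWMs are broader;
  the sharpness is chosen so that desk-scale recovery tests measure
  context learning rather than motif-detection power.
- **Contexts** each activate one planted regulator (round-robin) at level
  U(1, 2) while the other planted TFs idle at U(0.01, 0.1) and
  non-regulator TFs sit at U(0.5, 1.5). Activation patterns are therefore
  near-orthogonal across regulators — the property that makes the
  expression-shuffle control collapse. Real contexts co-express many
  regulators.
- **Signals** follow y[c,j,k] = softplus(Σ_t W[t,k]·motif[j,t]·expr[c,t])
  with planted weights 0.3 and background weights 0.02 (each jittered
  ×U(0.5, 1.5)), optional moving-average smoothing over ±s bins
  (default s = 0: a per-bin rule; note that with s = 1 the target of *any*
  per-bin readout is capped at corr 1/√3 when variance is spike-dominated,
  which would confound recovery tests), plus Gaussian noise (sd 0.1) and
  clipping at 0. A 25% random (context, signal) mask emulates missing
  tracks.
- **Loops** connect one planted element bin per window to a non-site "TSS"
  bin, with anchors spanning 3 bins (384 bp) — a scaled version of 5-kb
  HiChIP anchors; 1-bin anchors would make the normalized contact rows
  one-hot, an attention target reachable only by saturating every head.
  Insignificant decoy loops (q ≥ 0.01) exercise the q-value filter.
- **Variants** either substitute the most informative consensus position of
  a planted site with the least-favoured base (effect) or fall in bins
  without planted sites (neutral).

Everything is written in the pipeline's interchange formats (FASTA, BED,
TSV, HDF5, BEDPE, VCF) plus a truth JSON; outputs are byte-identical for a
fixed seed. Passing the recovery tests demonstrates that the architecture,
losses and attribution machinery behave as designed on data that satisfy
the model's assumptions exactly; it does not demonstrate performance on
real epigenomes, whose motif grammar, context correlation structure and
noise are far richer.

## Numerical choices and degenerate inputs

- Quantile normalization resolves ties by assigning the mean of the
  reference values the tied ranks span.
- One-hot encoding: A=[1,0,0,0], C=[0,1,0,0], G=[0,0,1,0], T=[0,0,0,1];
  IUPAC ambiguity codes map to zero rows; other characters are rejected
  with their position.
- Binarization of raw counts is strict (> 30 → 1).
- Depth normalization scales every library to the smallest library's depth;
  the minimum-depth column is returned unchanged.
- Attention softmax is computed with max-subtraction; rows sum to 1 within
  1e−5 in float32.
- Bins shorter than a motif score 0 with a warning; empty contact maps give
  CSL 0 with a warning; a non-finite training loss aborts with the last
  finite-loss parameters attached to the exception.
- Scanning is forward-strand by default, with an optional both-strands
  mode for motifs whose orientation should not matter.

## Problem sizes

The shipped experiments run on the desk profile: 4096-bp windows
(32 tokens), d_model 24, 2 encoder layers, 4 heads, ~26k parameters,
1000 Adam steps per run — sizes chosen so the full recovery study (five
seeds, two training arms each) completes on a single CPU core. The
full-scale profile (`profiles/full.yaml`) configures the full geometry
(1000 tokens × 968) but is not exercised by the test suite beyond its
arithmetic.

## Known limitations

- No reverse-complement augmentation and no strand-aware pooling.
- `count_parameters` reports the exact trainable-scalar count of the
  configured model; since kernel and FFN sizes are free parameters here,
  no particular total is targeted.
- The fine-tuning feature width at full scale depends on the anchor→bin
  selection rule; the midpoint rule used here is one reasonable choice and
  is configurable.
- Attention-based pair scoring and LOS are only as meaningful as the
  trained attention; on an untrained model they are noise.
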