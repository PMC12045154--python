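# Methods

## Problem and model

Given an annotated sc/snRNA-seq reference (cells × genes counts with
per-cell cell-type labels) and an unannotated spatial transcriptomic dataset
(cells or spots × genes counts with 2-D coordinates), the package estimates,
for every spatial observation, a probability distribution over the
reference's cell types. Observations are classified independently: no
spatial smoothing or neighborhood operator is applied, so coordinates are
pass-through metadata. This keeps the model platform-agnostic and makes
single-cell and spot resolutions the same inference problem — at spot
resolution the softmax output is read as a soft type composition rather than
a single identity.

## Preprocessing

Both datasets are restricted to their shared genes, ordered by the
reference (the trained network's input layout is defined by the reference
panel). Each observation's counts are scaled to a library size of 1e4 and
log1p-transformed — standard library-size normalization; the classifier only
requires that reference and spatial data share one scheme. All-zero
observations are left at zero and counted in a warning. Duplicated gene
names keep the first occurrence, loudly.

## ACOSG marker selection

Two signals are combined.

**Penalized cosine score.** For gene g and type k,
λ_gk = ⟨x_g, u_k⟩ / (‖x_g‖‖u_k‖) with x_g the gene's normalized expression
over all reference cells and u_k the 0/1 type indicator (λ = 0 for all-zero
genes). The score

    score_gk = sign(λ_gk) · λ_gk² / (λ_gk² + μ Σ_{i≠k} λ_gi²)

penalizes genes similar to several types. μ ≥ 0 trades specificity against
raw similarity: μ = 0 collapses to sign(λ); the default μ = 1 weights own-
and cross-type similarity equally. The sign is preserved so anti-markers
rank last. λ is scale-free per gene, so the score is invariant to positive
rescaling of any gene's expression.

**Attention importance.** A small supervised network — a learned per-gene
scalar gate (softplus-transformed, initialized to 1) multiplying the input,
one 64-unit ReLU hidden layer, softmax output — is trained on the labeled
reference (Adagrad, lr 0.01, 30 epochs, batch 128). Gene g's importance is
the mean over training cells of |softplus(s_g)·x_cg|, softmax-normalized so
weights sum to 1. The per-gene hidden-layer weight rows are seeded by a hash
of the gene's *name* rather than its column position, which makes the whole
attention computation exactly equivariant under permutations of the input
gene order. Attention weights are per-gene scalars (not per gene-type
pairs): importance is a property of the gene within the whole labeling task.

**Fusion and selection.** fused_gk = score_gk · a_g / max_g a_g — a
multiplicative fusion that preserves the zeros of both orderings. By default
the top 50 genes per type by fused score are unioned (ties broken by
lexicographic gene name); the panel is emitted in reference gene order. A
global top-n mode (by max-over-types fused score) is available.

## Classifier

A five-hidden-layer fully connected network, widths (256, 128, 64, 128, 256),
ReLU, dropout 0.1. The symmetric bottleneck lets a single skip connection
add the first hidden layer's (post-dropout) activations to the fifth hidden
layer's pre-activations — equal widths by construction — giving the initial
stage a direct path to the terminal stage around the bottleneck.

Inputs are the normalized log-expression of the panel genes, standardized
per gene to zero mean and unit variance using *reference* statistics; the
same statistics are re-applied to spatial data (constant genes get std 1).
This removes platform scale differences between reference and spatial assays.

Training: mini-batch Adagrad (lr 0.01, batch 128, up to 100 epochs) on
cross-entropy (true-class probability clipped below at 1e-12), with a
stratified 10% validation split (at least one held-out cell per class), early
stopping after 10 epochs without validation improvement, and
best-validation-loss parameters retained. A non-finite loss aborts with the
epoch and batch named. Every random draw (init, shuffling, dropout, split)
comes from generators derived from the config seed, so identical
config + seed gives bitwise-identical histories and probability matrices on
one machine. Both networks are plain NumPy; training at the package's
default problem sizes takes seconds on one CPU.

## Evaluation system

Predicted and reference maps are compared per cell-type column with five
metrics, averaged unweighted over types:

- COS — cosine similarity (0 for an all-zero pair);
- PPMC — Pearson correlation (0 with a warning for constant vectors);
- SSIM — the structural-similarity composite computed *globally* on
  max-scaled columns (dynamic range L = 1, K1 = 0.01, K2 = 0.03).
  Observations are an unordered point set, not a raster, so no sliding
  window is meaningful;
- KL — KL(reference ‖ prediction) in nats after adding 1e-12 and
  renormalizing each vector to the simplex (direction: information lost when
  the prediction approximates the truth; the argument order makes the other
  direction available);
- JS — the symmetrized, ln 2-bounded counterpart.

**Acc Score.** For each metric the competing methods are ranked with the
best receiving rank M (ties get the average rank), so higher is always
better, and the mean rank across metrics divided by M gives a score in
(0, 1]. The ranked panel is COS, PPMC, SSIM, KL; JS is computed and reported
but excluded from ranking by default (configurable). Ranking is performed
within one dataset.

The confusion matrix reports, for each annotated type, the fraction of its
cells assigned to each predicted type (rows of non-empty classes sum to 1),
plus overall accuracy. Proportion similarity compares predicted type
proportions (column means of the probability matrix, or hard-label
frequencies) to reference proportions by PPMC and COS.

## Synthetic data

Counts are negative binomial with mean `base_mean` (default 2) and
dispersion 0.5 (inverse size; real UMI counts are overdispersed, and the NB
mean is available in closed form for checks). Each of K types owns a
disjoint block of `markers_per_type` genes whose mean is multiplied by
`fold_change`, so the expected top markers are known a priori. Defaults —
K = 5 types, 500 genes, 40 markers/type at 4-fold elevation, 200 reference
cells/type, 1000 spatial observations — are the package's reference study
conditions: big enough that marker selection and training are non-trivial,
small enough to run in seconds.

Spatial observations sit uniformly in the unit square. The `layers` layout
assigns types to K horizontal bands (laminar tissue architecture). At
`cells_per_spot = 1` each observation is one cell of its band's type and the
ground-truth proportions are one-hot. For multi-cell spots, the constituent
cells' types are drawn from a mixture whose weights follow a Gaussian kernel
of the distance between the spot's y coordinate and each band center
(bandwidth 1/(2K)), so mixing concentrates near band boundaries and per-spot
true proportions vary smoothly; spot counts are sums of single-cell draws
(equivalently one NB draw with m-fold mean and size).

The simulator emulates overdispersed counts, marker structure, laminar
layout and multi-cell mixing. It does **not** emulate platform-specific
noise (capture-efficiency differences between reference and spatial assays,
optical crowding, segmentation error, lateral diffusion, batch effects) or
correlated gene programs. Passing tests therefore demonstrate correctness of
the mechanics and recoverability under clean conditions, not performance on
real tissue.

## Numerical choices and degenerate inputs

- Probability rows are softmax outputs: non-negative, summing to 1 within
  1e-6; written CSVs round-trip within 1e-9.
- Argmax ties in hard labels resolve to the lowest vocabulary index.
- cosine λ of an all-zero gene is 0; a zero penalized-score denominator
  yields 0; an all-zero pair has COS 0; constant vectors have PPMC 0 with a
  warning; two all-zero vectors have SSIM 1 (the stabilizing constants
  dominate).
- Adagrad uses ε = 1e-10 in the denominator.
- `epochs = 0` returns the untrained (initialized) network with empty
  history; `learning_rate = 0` leaves parameters exactly at initialization.

## Limitations

- No use of spatial coordinates at inference time; tissues where context
  disambiguates transcriptionally similar types will not benefit from it.
- Attention importance is a single scalar per gene; genes informative for
  one rare type among many may be under-weighted relative to a per-(gene,
  type) scheme.
- The soft composition read-out at spot resolution is a classifier
  probability, not a deconvolution estimate; it tracks mixing proportions
  well empirically but carries no generative guarantee.
- Reference and spatial data are assumed to share gene identifiers; no
  ortholog mapping is provided for cross-species work.
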