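# Methods

## Problem setting

SELEX-seq experiments yield, for a transcription factor (complex), a table of
short DNA reads with a *relative binding affinity* in [0, 1], 1 being the
strongest observed binder. Two modeling questions drive this package:

1. **Strand handling.** A read and its reverse complement are the same
   double-stranded molecule, so a sound affinity model must score them
   identically. That can be enforced architecturally (reverse-complement
   weight sharing) or encouraged through DNA-specific data augmentation.
2. **Interpretation robustness.** Attribution methods assign each nucleotide
   an importance for the prediction; models retrained with different
   hyperparameters should yield similar importance maps if the attributions
   reflect biology rather than training noise.

## Models

### Canonical CNN

One convolution layer of `n_filters` motif scanners (4 × m matrices, default
m = 8 matching the TGAYNNAY core width), rectification with a learned
per-filter shift, non-overlapping max pooling (window p, default 1 for 14-mers
— p must divide the convolution output length), dropout (default rate 0.2),
a dense layer, and a sigmoid squashing the output into (0, 1). The loss is

    MSE + λ₁‖M‖₁ + λ₂‖M‖₂²,

penalties on filter weights only, minimized with Adam at learning rate λ₃.
Defaults: n_filters 16, λ₁ = 1e−6, λ₂ = 1e−4, λ₃ = 1e−3, 30 epochs, batch
256, early stopping on a 10% validation split with patience 5 (best-validation
parameters retained). A nine-point (λ₁, λ₂, λ₃) grid with k-fold
cross-validation (default k = 3) is provided for hyperparameter selection;
ties break toward the smaller λ₁ + λ₂, then candidate order.

### Reverse-complement weight-sharing CNN (CNN-RC)

Each learned filter F is paired with the derived filter
F′[i, j] = F[3−i, m−1−j] — the channel flip is the biological complement map
(the one-hot channel order (A, C, G, T) makes complementation i ↔ 3−i), and
the position reversal mirrors the scan direction. After pooling, a
weighted-sum layer learns one positional weight per channel, applied to the
derived channel in reversed position order, and the dense head sees the sum of
each pair (equivalently: the pair's dense weights are tied). With these three
ties the prediction is exactly invariant under reverse complementation, to
rounding error, at initialization and after every optimizer step. A final
sigmoid is applied, as in the canonical variant, so all models emit
comparable [0, 1] affinities.

### Self-attention regressor

One-hot input → dense embedding (4 → d_model, default 32) → additive
sinusoidal positional encoding (sin at even dimensions, cos at odd, frequency
10000^(2k/d_model)) → `n_layers` (default 2) multi-head self-attention layers
(`softmax(QKᵀ/√d_k)V`, default 8 heads, d_k = d_model/n_heads) → global
average pooling over positions → dense → sigmoid. Plain MSE loss, Adam.

Design choices made where the design was genuinely open: residual connections
and layer normalization wrap each attention layer — a stack of plain attention
transforms is unstable to train — and no position-wise feed-forward sublayer
is added, keeping the attention transform itself the only mixing operation.
The default learning rate 3e−3 was chosen as the most stable well-performing
setting in a coarse probe, mirroring how such rates are usually picked by grid
search. Because the positional encoding is built from the input length at
forward time, one model accepts both 14-bp raw reads and 38-bp RC-augmented
inputs; N padding embeds through the bias alone.

All three models run on a small in-package reverse-mode autodiff engine
(`rcbind.autodiff`); its hand-derived backward passes (including a fused
multi-head-attention node) are verified against central finite differences in
the test suite. Training is bit-reproducible given the seed.

### Aligned ridge baseline

Reads are scanned on both strands for the TGAYNNAY core; only reads with
exactly one occurrence are kept (both-strand counting keeps the filter
strand-symmetric; a window matching on both strands counts twice).
Reverse-strand hits are reverse-complemented so the core always sits forward;
a window of core ± 2 bp flanks (width 12) is extracted, and reads whose window
would run off the read are dropped and counted. Ridge regression on the
one-hot window (intercept unpenalized) with λ from seeded 10-fold CV completes
the baseline. Retention bookkeeping (kept + dropped-by-reason = input size) is
exposed, since discarding unalignable — disproportionately low-affinity —
reads is exactly the baseline's scientific weakness.

## Interpretation

- **ISM**: for every position and alternative base,
  Δ = (f(ŝ) − f(s)) · max(f(s), f(ŝ)). The max factor suppresses deltas
  between two non-binders and highlights changes involving strong binders.
  Reference-base entries are exactly 0.
- **Gradient*input**: ∂f/∂x elementwise with the one-hot input; off-reference
  entries vanish by construction.
- **DeconvNet**: identical to gradient backpropagation except each ReLU
  backward step rectifies the incoming signal instead of gating by the
  forward activation mask; defined for conv/ReLU/pool/dense models only.
- **Logo projection**: the observed-base score per position (for ISM this is
  identically zero, so the raw matrix is the informative export; both are
  written).
- **Consistency statistic**: for a method g and sequence s, importance
  matrices from three models trained with different hyperparameter sets are
  flattened (4L vectors) and the mean of the three distinct pairwise
  correlations (Pearson or Spearman) is reported as c(g, s). Zero-variance
  pairs are excluded with a warning rather than propagating NaN. The study
  protocol trains the three models, requires each to clear a configurable
  held-out R² floor, and evaluates c over a set of high-affinity sequences.

For sequences longer than the model input, a sliding window yields a
prediction track; per-position importance averages the windowed ISM deltas
over all covering windows (a max-by-magnitude option is provided — the mean is
the default because it damps single-window artifacts). Mutation effects are
reported as per-window fold change mutant/wild-type, with windows whose
wild-type prediction is below 0.01 flagged rather than trusted as ratios.

## The synthetic-data generator

The simulator defines the package's study conditions: a ground-truth binding
energy model with known optimum, from which seeded pools are drawn.

- **Energy model.** A 4 × 8 per-position energy matrix with zero energy on
  the consensus TGATTTAT (the Exd-Ubx cognate site); the true affinity of a
  read is exp(−β·(E_best − E_min)) with E_best the minimum window energy over
  all offsets on *both strands* — strand symmetry holds by construction and
  the optimal site scores exactly 1 (under the optional adjacent-pair
  interaction term, E_min is computed exactly by dynamic programming).
  Mismatch penalties are structured by pyrimidine/purine class: the
  transition at each position (A↔G, C↔T, class-preserving) costs 0.5–1.0 kT,
  the two class-flipping transversions 1.6–2.6 kT (seeded draws). This
  encodes the YR-stacking picture — the Y/R geometry of the site carries most
  of the binding energy while base functional groups fine-tune it — so
  degenerate low-affinity variants tend to conserve the consensus YR pattern.
- **Pool composition.** Default 90% of reads embed the (mutated) core at a
  uniform random offset and uniform random strand — a read has fixed adapter
  orientation but the site occurs on either strand — and 10% are uniform
  background. Substitutions hit each core position at rate 0.15 and are the
  transition with probability 0.7, emulating the variant spectrum of a
  late-round selected pool. Recorded affinity = clip(true + N(0, 0.02), 0, 1);
  clipping (rather than resampling) keeps the noise monotone.
- **Pairwise-interaction variant.** A seeded Gaussian (w−1) × 4 × 4
  adjacent-pair energy term (sd 0.6 in the comparison studies) creates
  non-additive structure that a mononucleotide ridge model cannot represent
  but the CNN can — the basis of the model-family comparison.

**What the simulator does not emulate** — and hence what passing tests do and
do not show about real data: round-to-round selection/enrichment dynamics, PCR
and sequencing bias, read counts (only the derived affinity table is
emulated), position-dependent or >2-body energetics beyond the adjacent-pair
term, and measurement-noise heteroscedasticity. Conclusions here are about
recoverability of a known landscape, not about real-data accuracy magnitudes.

### The low-affinity YR logo band

One finding from the package's own checks deserves a note. The logo pipeline
aligns every probe at its best filter window and compares the top and bottom
affinity cohorts. On the default 50 000-read pool, the *bottom 10 000* reads
(recorded affinity ≲ 0.05) carry sites degraded by ≥2 transversions or no
site at all; on a 14-bp read every 8-bp window overlaps the core, so their
scanner alignment is effectively random and their YR columns are close to
coin flips (the match of the bottom cohort's majority-YR string to the
consensus YR pattern is seed-dependent). The YR-conservation signature is
robustly present one band up: reads ranked 10 000–20 000 from the bottom
(affinity ≈ 0.05–0.18 — genuinely low-affinity but intact sites) give the
consensus YR pattern with per-column majorities of 0.60–0.68. Low-affinity YR
conservation is therefore a property of *bound degenerate sites*, and cohort
definitions that dip into unbindable sequence dilute it.

## Numerical choices

- One-hot channel order fixed to (A, C, G, T); N encodes as an all-zero
  column (contributes nothing to convolution sums); motif offsets 0-based,
  reverse-strand hits reported at the forward coordinate of the window start.
- Information content: per-column 2 − H (bits) with pseudocount 0.5 on
  frequencies; filter selection ties break to the lowest filter index.
- Cohort selection ties at the boundary break by input order (stable sort).
- Degenerate correlation inputs (constant predictions, zero-variance
  importance vectors) are reported as undefined / excluded with a warning,
  never as a number.
- Serialization is JSON (config + parameter tensors + seed); a loaded model
  predicts bit-identically.

## Problem sizes used by the test suite and acceptance script

Simulation-backed checks run on a 50 000-read default pool (training ≈ 25 s on
one CPU) for the headline fit, the consistency study (three 15-epoch models)
and the logo pipeline; the augmentation-strategy comparison and the
CNN-vs-ridge comparison use 20 000-read companion pools, with the
self-attention models trained 12 epochs there. These sizes are the package's
chosen study scale; accuracy at them is reported as measured (e.g. CNN-RC
held-out R² ≈ 0.96 at 50 000 reads, ≈ 0.88 at 20 000).

## Known limitations

- The CNN is single-layer by design; the 14-bp read length neither needs nor
  supports deeper stacks. Enhancer-scale scanning inherits the 14-bp horizon:
  cooperative, multi-site effects are invisible to a windowed model.
- DeconvNet is defined only for the CNN variants; the self-attention model
  supports ISM and Gradient*input.
- The MLR baseline's aligned-window width (core ± 2) and the both-strand
  exactly-one filter are package choices; other alignment conventions would
  change retention but not the qualitative comparison.
- CPU-only by construction; training cost grows linearly in pool size and
  epochs (≈ 1 s/epoch at 40 000 reads for the CNN, ≈ 7 s/epoch for the
  self-attention model).
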