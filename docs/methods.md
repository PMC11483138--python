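# Methods

## The reconstruction problem

Dissociated scRNA-seq measures per-cell expression for thousands of genes
but destroys spatial context; spatial transcriptomics (ST) keeps 2-D
coordinates but measures fewer genes, sparsely. Given an scRNA-seq matrix
(n_sc cells × C_p genes) and an ST matrix (n_st spots × C_q genes) from the
same tissue type, the package learns a map from the overlapping gene panel
C_o = C_p ∩ C_q of the single-cell data to the spatial expression of those
genes, so that the spatial profile of genes *not* used in training can be
predicted from their single-cell expression alone.

## Model

Tokens are genes. The network input is the overlap-gene block of the
scRNA-seq matrix transposed to C_o × n_sc, so each token's feature vector is
one gene's expression across all cells. Per scale Λ ∈ {Λ_1..Λ_N}:

1. **Projections.** Q, K, V = LeakyReLU(X·W + b), one affine map each.
2. **Gene correlation matrix.** S = softmax(Q·Kᵀ/√Λ), row-stochastic
   (C_o × C_o). Its diagonal scores each gene's attention on itself.
3. **Filtration.** The top ⌊C_o·φ⌋ genes by diag(S) are retained (ties to
   the lower index). Separate key/value projections are applied to the
   retained tokens only, and the full-token queries cross-attend to them:
   A = softmax(Q·K_fᵀ/√Λ)·V_f.
4. **Residual.** A learned affine alignment map sends the input tokens to
   width Λ; the residual λ·align(X) is added back. In the filtration path
   the residual is scattered to the retained rows only — dropped genes get
   a zero residual, so they cannot leak through the skip connection.
5. **Aggregation and decoding.** The N per-scale outputs are concatenated
   (width ΣΛ_i) and a two-layer MLP (affine → LeakyReLU → affine) maps each
   gene token to its predicted expression over the n_st spots.

Selection by top-k is discrete; gradients flow through the gathered values,
not through the ranking. S is recomputed from the current scale's Q, K on
the full token set at every forward pass.

Because all parameters are shared across tokens, a gene never seen in
training is still a valid input: held-out genes are predicted by running
their token vectors through the trained network. This is what makes
gene-fold cross-validation well defined, and it is the single most
consequential design interpretation in the package.

## Objective

With prediction P and reference ST matrix T (both n_st × C_o, in
normalized log space) and the binary mask M marking non-zero ST entries:

* L_recon = mean((P − T)²) over all entries,
* L_mask = Σ M⊙(P − T)² / max(1, ΣM) — squared error over *observed*
  entries; normalizing by the masked count keeps its scale comparable to
  L_recon regardless of sparsity, so one α₁ works across datasets,
* L_corr = 1 − mean over genes of ρ(P_:,j, T_:,j) — Pearson per gene
  column, with an ε-guard (1e-8) and ρ := 0 for numerically constant
  columns,
* total = L_recon + α₁·L_mask + α₂·L_corr (defaults α₁ = 0.1, α₂ = 0.5).

M = 1 at non-zero ST entries: only this polarity makes the masked term
emphasize observed expression; the complementary reading would re-weight
exactly the entries the reconstruction term already dominates.

## Training

Full-batch Adam (β₁ = 0.5, β₂ = 0.999) — the datasets are matrix-sized and
the correlation loss is a whole-column statistic, so minibatch semantics
would need inventing. A bias-corrected exponential moving average of the
parameters (decay 0.99 by default) provides the evaluation weights; the
bias correction (ema_t/(1 − d^t)) matters at desk-scale budgets of a few
hundred steps, where an uncorrected EMA would still be dominated by the
random initialization. Decay 0 reduces exactly to the raw parameters.

Cross-validation over genes: a seeded shuffle is chunked into K = 10 folds
(sizes differing by at most one); each fold's genes are held out, the model
is trained on the rest, and every gene is scored exactly once. When all
folds have equal size the K fold-models are trained simultaneously as a
*fold ensemble*: parameters carry a leading replica axis and every epoch is
one batched computation. The objective is the sum of per-replica losses and
replicas share no parameters, so each replica's gradient — and its whole
Adam/EMA trajectory — is identical to sequential training (verified to
1e-8 in the tests); only the arithmetic is batched.

Ablation variants are pure configuration: single widest scale
(module_variant_1), no filtration (module_variant_2), dropping
recon + mask (loss_variant_1), dropping corr (loss_variant_2).

## Synthetic paired data

The generator emulates the structure of real paired benchmarks rather than
any platform's noise model:

* spots tile the unit square on a regular grid; cells receive latent
  positions uniform on the same square, so both modalities sample the same
  spatial programs;
* a minority of marker genes (24 of 120 by default) each carry one spatial
  program — stripes (period 1/f in y), Gaussian blobs, or linear
  gradients — with lognormal amplitude spread (σ = 0.5);
* the remaining genes are not pure noise: like genes embedded in real
  co-expression modules, each loads weakly (σ = 0.3 of the pattern
  amplitude) on two random programs. Without this, background genes would
  be unpredictable in principle and fold-mean metrics would be dominated
  by a floor of zeros;
* per-gene baselines are lognormal (median 0.5, σ = 1), mimicking the
  orders-of-magnitude spread of transcript abundances;
* additive Gaussian noise (σ = 0.3), truncation at zero;
* ST sparsity: the smallest entries are zeroed until the target fraction
  (0.6) is reached — deterministic, so the mask structure is reproducible;
  a Bernoulli dropout mode is available via configuration;
* batch effect: each gene of the single-cell matrix is multiplied by a
  scale drawn from U(1, 2) and shifted by U(0, 0.5), then re-truncated.

What passing tests on this generator do *not* show: robustness to
platform-specific artifacts (UMI saturation, segmentation error, spot
mixtures), to non-overlapping cell-type composition between modalities, or
to panels orders of magnitude larger.

## Benchmark conditions and problem sizes

All directional experiments run at one fixed setting: 300 cells × 200
spots × 120 genes, 60% ST zeros, batch distortion on, attention scales
(32, 64, 128), decoder width 128, float32 arithmetic, 150 full-batch epochs
at learning rate 1e-3 with α₁ = 0.1, α₂ = 0.5, K = 10 folds, ten seeds.
The epoch budget is sized so the whole ten-seed, four-variant protocol
completes in minutes on one CPU; longer budgets raise every variant's
absolute held-out scores (the full model roughly doubles its mean PCC by
300 epochs) without changing the qualitative ordering of the variants.
The learning rate is chosen for this problem size; real datasets (larger
panels, wider scales) want the much smaller rates and longer budgets that
the YAML configuration exposes.

## Evaluation

Per held-out gene: Pearson and Spearman correlation (average ranks on
ties), RMSE, cosine similarity (0 when either vector is all-zero), and a
global-statistics SSIM: both spot vectors are min-max scaled to [0, 1] and
SSIM is computed from their overall means, variances and covariance with
C₁ = 0.01², C₂ = 0.03². Spots are not pixels; windowed SSIM would require
rasterizing irregular spot layouts, which introduces arbitrary artifacts.

Gene-filtration diagnostics: the model's contribution score is the mean of
diag(S) across scales on the full data; the overlap rate compares the top
⌊C_o·φ⌋ selected genes against the same number of top-variance genes of
the single-cell matrix, as a percentage of the selection. The
fraction-of-variance (FV) score is each gene's share of total spot
variance. The per-gene rank test contrasts predicted expression in the
top-quartile reference spots against the bottom quartile (two-sided
Wilcoxon rank-sum; exact null below 25 per group without ties, otherwise
the tie-corrected normal approximation); a constant reference column
records p = 1. Which two samples the test should compare is genuinely
open; the quartile contrast measures spatial-signal detectability of the
prediction, which is what the diagnostic is used for.

Batch-effect removal is made testable as an energy-distance comparison
over spot/cell point clouds in gene space: reconstruction vs. real ST
should be smaller than batch-shifted sc vs. real ST.

## Numerical and engineering choices

* Gradients come from a minimal reverse-mode autodiff over numpy arrays
  (`_autodiff.py`); softmax is max-stabilized; the correlation loss guards
  its denominator and zeroes degenerate columns outside the graph.
* LeakyReLU slope 0.01; seeded uniform fan-in initialization for all
  affine maps; λ = 1.0 by default, with an optional learnable-scalar mode.
* ⌊C_o·φ⌋ uses floor; a floor of zero is bumped to one retained gene
  (an empty key/value set is degenerate).
* The training loop is tuned for a single CPU: projections that share an
  input are evaluated as one fused GEMM (algebraically identical, tested),
  slice/gather gradients accumulate into shared buffers, Adam + EMA run as
  one fused pass over a flat parameter buffer (numba-compiled when
  available, numpy otherwise), and glibc's mmap threshold is raised so
  large per-epoch temporaries are reused rather than page-faulted.

## Known limitations

* With scale-free evaluation metrics (PCC, min-max SSIM), training on the
  correlation loss alone is a strong baseline at this problem size: it
  directly optimizes the quantity being scored, and nothing at 120 genes ×
  (32, 64, 128) scales makes it unstable. The full three-term objective
  wins on RMSE and against the module ablation, but its advantage over the
  correlation-only variant on correlation-family metrics emerges, if at
  all, only at much larger panels and widths than the bundled benchmark
  exercises.
* Fold-ensemble training requires equal fold sizes; unequal splits fall
  back to sequential training automatically.
* The h5 reader loads matrices densely; panels beyond ~10⁴ genes ×
  10⁵ cells are outside the intended scale.
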