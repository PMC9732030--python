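# Methods

## Problem setting

Given a binary association matrix `A ∈ {0,1}^{ns×nm}` between `ns` small
molecules (rows) and `nm` miRNAs (columns), plus one SM–SM similarity
matrix `SSM` and one miRNA–miRNA similarity matrix `SMR`, the model assigns
every pair a score in (0, 1) used to rank unknown pairs. Zeros in `A` mean
"not curated", never "known absent" — hence the ranking (not
classification) evaluation throughout.

## Similarity integration and normalization

Multiple similarity sources per entity type are fused by a weighted
elementwise average `Σᵢ wᵢ Sᵢ / Σᵢ wᵢ`; all weights default to 1 (equal
contribution). The integrated matrix is then normalized symmetrically,
`S̃ᵢⱼ = Sᵢⱼ / √(rowsumᵢ · colsumⱼ)`, which is invariant to global rescaling
of S and parallels the `D^{-1/2} S D^{-1/2}` graph normalization used later.
A plain-product denominator is available as `norm_style = product` for
comparison. Zero entries stay zero by construction, so all-zero rows pass
through without division failures. Complete (gap-free) matrices are
required; imputation of missing similarity entries is out of scope.

## Low-rank representation denoising

Curated association sets contain errors and are highly redundant (similar
molecules share miRNA partners), motivating the self-representation model
`A = A X + E` with

    min_{X,E} ‖X‖* + α‖E‖₂,₁  s.t.  A = A X + E,     α = 0.1 by default.

`X` (miRNA×miRNA by default; `lrr_side = sm` factors the transpose) is
pushed toward low rank by the nuclear norm, `E` toward column sparsity by
the L2,1 norm. The IALM solver introduces an auxiliary `J = X` and iterates
closed-form proximal steps:

1. `J ← SVT(X + Y₂/μ, 1/μ)` — singular-value soft-thresholding;
2. `X ← (I + AᵀA)⁻¹ (AᵀA − AᵀE + J + (AᵀY₁ − Y₂)/μ)` — the penalized
   least-squares solve, using a Cholesky factorization of `I + AᵀA` computed
   once (the matrix never changes across iterations);
3. `E ← L21-shrink(A − AX + Y₁/μ, α/μ)`;
4. multiplier updates `Y₁ += μ(A−AX−E)`, `Y₂ += μ(X−J)`; `μ ← min(ρμ, μ_max)`.

Defaults: `μ₀ = 1e-4`, `ρ = 1.1`, `μ_max = 1e10`, stopping when both
`‖A−AX−E‖∞` and `‖X−J‖∞` fall below `tol = 1e-7`, with a `max_iter = 500`
cap (non-convergence returns a flagged result plus a warning, not an
exception). IALM is not monotone in the Lagrangian, so convergence is
asserted through the final residuals, never through objective descent.

Two regimes of the balance parameter are worth knowing. For clean low-rank
data at moderate α the minimizer is the shape-interaction matrix
`X* = V_r V_rᵀ` (verified to 1e-3 relative error on noise-free rank-2
inputs). For *tiny* inputs or very small α, routing everything through `E`
(`X = 0, E = A`) can be globally cheaper — e.g. for the 2×2 all-ones matrix
at α = 0.1 the solver correctly returns `X = 0` because
`α‖A‖₂,₁ = 0.28 < 1 = ‖vvᵀ‖*`. Conversely, gross column corruptions are
identified by `E` only while `α‖corrupt column‖₂` stays below the ~unit
nuclear cost of self-representation. The denoised `A* = A X*` is kept
real-valued and used directly as edge weights; binarizing it would discard
the confidence information the decomposition produces.

## Heterogeneous graph

With the miRNA block first,

    AH = [[S̃MR, A*ᵀ], [A*, S̃SM]],   G = [[μ·S̃MR, A*ᵀ], [A*, μ·S̃SM]],
    H(0) = [[0, A*ᵀ], [A*, 0]],

where `S̃ = D^{-1/2} S D^{-1/2}` normalizes each similarity block and the
penalty factor `μ = 6` (distinct from the solver's μ) up-weights
within-type edges during propagation. Zero-degree nodes get zero normalized
rows (with a warning) rather than raising. For symmetric similarity inputs
both `AH` and `G` are symmetric, and the spectral radius of
`D^{-1/2} G D^{-1/2}` is at most 1, so activations cannot blow up with
depth.

## Encoder, attention, decoder

`L = 3` layers of `H(l+1) = ELU(Ĝ H(l) W(l))` with `Ĝ = D^{-1/2} G D^{-1/2}`,
embedding dimension `k = 64`. `W(0)` is `(nm+ns)×k`, later weights `k×k`,
all initialized Glorot-uniform from the run seed. During training only, two
dropout mechanisms regularize the model: edge dropout at rate β = 0.6
(independent Bernoulli mask on the entries of `Ĝ`, rescaled by 1/(1−β),
redrawn per layer per epoch) and feature dropout at rate γ = 0.4 on each
layer's input. Layer-attention scalars `a_l`, initialized to `1/(l+1)` and
freely trainable (no softmax constraint; `attn_init = uniform` is the
alternative), combine the layer outputs: `[Hm; Hs] = Σ_{l=1..L} a_l H(l)`
(the layer-0 input is deliberately excluded — it is the raw association
pattern the decoder should not shortcut to). Scores are
`A' = sigmoid(Hm W' Hsᵀ)` with a trainable `k×k` bilinear matrix `W'`.

## Training objective and optimization

The loss is full-matrix binary cross-entropy between `A'` and the original
binary `A` (not `A*` — the denoised matrix informs the graph, while the
supervised signal stays the curated labels), with positives weighted by the
negative:positive count ratio to counter the extreme class imbalance
(`loss = bce` disables the weighting). Optimization is Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at learning rate 0.00725 for 600 epochs by
default, full-batch. The implementation is dense numpy with hand-derived
exact gradients — backpropagation through the decoder, the attention
combination and the convolution stack, including the dropout masks; the
gradients are verified against central finite differences to 1e-6 in the
test suite. Given the seed, initialization, dropout masks and hence the
final scores are bit-reproducible. Softplus-based log terms keep the loss
finite for extreme logits; non-finite activations or losses abort with a
diagnostic naming the layer or epoch.

## Evaluation harnesses

Ranking AUC is the Mann–Whitney statistic (midrank ties) of held-out
("test") scores against candidate scores — identical to sweeping a rank
threshold and integrating the ROC. Candidates are always pairs unknown in
the full dataset; the held-out entries are zeroed in the training copy
*before* denoising, so no stage sees the test labels.

* **Global LOOCV** — each known pair held out in turn, candidates all
  unknown pairs; one pooled AUC over all held-out samples together with the
  candidate scores of each retrained model. (Pooling into a single ROC was
  chosen over averaging per-sample AUCs; both coincide at 1.0/0.5/0.0
  calibration points, and pooling weights every test-candidate comparison
  equally.)
* **miRNA-fixed / SM-fixed LOOCV** — candidates restricted to unknown pairs
  sharing the held-out pair's miRNA (resp. SM); pairs with empty candidate
  sets are skipped, warned about and counted.
* **Repeated k-fold** (k = 5; the published protocol repeats the partition
  100 times, and `repeats` accepts any count — the API default is a single
  repeat so that exploratory runs stay cheap) — known pairs split into
  near-equal folds; one AUC per fold; mean ± std.
  Partition randomness (`cv_seed`) is independent of model-weight
  randomness (`seed`).
* **Case studies** — for one SM, candidates ranked by descending score with
  lexicographic tie-breaking; mode 1 trains on everything, mode 2 deletes
  the SM's own associations first (cold start).
* **Random control** — a seeded uniform sample of unknown pairs with their
  scores and global ranks, the negative control for case-study hit rates.

Calibration invariants, enforced in the tests: an oracle scorer that ranks
every held-out pair above all candidates attains AUC exactly 1.0 in every
mode; a uniform-random scorer averages 0.5 (±0.02 over 200 replicates).

## Synthetic data

`generate(SyntheticSpec(...))` plants a block structure: entities are
assigned round-robin to `n_blocks` blocks; associations are
Bernoulli(p_in) within a block and Bernoulli(p_out) across; similarities
are `sim_in`/`sim_out` plus symmetric Gaussian jitter (σ = `sim_noise`),
clipped to [0, 1] with unit diagonal. Defaults (40 SMs, 120 miRNAs, 2
blocks, p_in = 0.06, p_out = 0.002, sim_in = 0.8, sim_out = 0.2,
σ = 0.05) emulate a small curated dataset: ≈150 expected associations,
≈3% density, and strongly informative similarities. `degree_filter` drops
zero-degree entities, mirroring the usual reduction of a sparse curated
matrix to its active sub-matrix.

What the generator does **not** emulate: heavy-tailed degree
distributions, correlated noise between similarity sources, partially
observed similarity matrices, or any chemistry. Passing tests on this data
therefore demonstrate that the pipeline recovers planted structure and that
its harnesses are calibrated — not that the published-scale accuracy on
real curated data is reproduced here.

A useful consequence of the generator's exchangeability: conditional on the
blocks, within-block entries are i.i.d., so *no* scorer can rank a held-out
within-block pair above other within-block unknowns better than chance. The
achievable CV AUC is therefore capped by the within/across-block candidate
mix — e.g. ≈0.785 for 30 SMs × 100 miRNAs with p_in = 0.3, p_out = 0.01
(measured with an oracle scorer given the true blocks). The trained
pipeline reaches ≈99% of that ceiling, which is the right yardstick for
end-to-end performance on this generator.

## Test and example problem sizes

The test suite and the worked examples run the full pipeline at reduced
sizes (tens of SMs, around a hundred miRNAs, 16–64-dimensional embeddings,
30–200 epochs), chosen so the whole suite completes in a few minutes while
still exercising every stage at meaningful signal-to-noise; all published
hyperparameter defaults are retained in `RunConfig` for full-scale runs.

## Known limitations

* Full-batch dense training: memory is O((nm+ns)²); practical to a few
  thousand entities, beyond which a sparse/minibatch implementation would
  be needed.
* No early stopping or validation split — a fixed epoch budget, per the
  published training protocol.
* The SM-fixed LOOCV mode conditions on SMs with very few associations and
  is intrinsically noisy on sparse data.
* The package consumes precomputed similarity matrices; computing them
  from raw chemistry/phenotype sources is out of scope.
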