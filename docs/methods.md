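# Methods

## Overview

`fusedrp` predicts the response (IC50) of cancer cell lines to drugs from
many weak data views rather than one descriptor. Drugs are represented by
their rows in twelve drug–drug similarity matrices (six molecular
fingerprint families, four biological-association profiles, a drug–drug
combined-score table, and the drug's IC50 interaction profile); cell lines
by three omics matrices over a fixed gene panel plus one cell–cell
similarity from IC50 profiles. A neural interaction network consumes one
row per view for each (drug, cell) pair and regresses the scalar IC50.

## Similarity views

Each feature matrix becomes a similarity view by row-wise Chebyshev
distance, `D(a,b) = max_c |v_ac − v_bc|`. The distance→similarity map is
`S = 1 − D` when every pairwise distance is already ≤ 1 (always true for
binary and unit-range features); otherwise the distance matrix is divided
by its maximum first (floor `1e-12` guards the all-identical-rows case,
which legitimately yields the all-ones similarity). The diagonal is forced
to 1 and the matrix is exactly symmetrized.

A consequence worth stating plainly: on *binary* rows the Chebyshev
distance is 0/1-valued, so two drugs are "similar" only when their feature
rows coincide exactly and binary views produce near-identity similarity
matrices. This is a property of the chosen metric, not an implementation
artifact; the metric is pluggable (`euclidean`, `cosine`, `cityblock`,
`correlation`) for users who want graded similarities from binary data.
The continuous views (RDKFP, ERGFP, the combined scores, the IC50
profiles) are the ones that carry graded between-drug structure.

The combined-score view is already a similarity (scores/1000 ∈ [0,1]); it
passes through unchanged apart from max-symmetrization. The three omics
matrices are *not* converted: the model consumes them as raw per-cell
feature vectors.

## Fusion and completion

Similarity network fusion (SNF) follows the standard cross-diffusion
scheme: each view is normalized into a full kernel `P` (diagonal 1/2,
off-diagonal rows summing to 1/2) and a sparse kernel `S` (row-stochastic
over each row's K strongest neighbours, self excluded, stable argsort for
ties); T rounds of `P_v ← S_v · mean(P_u, u≠v) · S_vᵀ` with symmetrization
and re-normalization, then the mean of the final kernels, symmetrized.
Defaults: `K = max(3, round(n/10))` capped at n−1, `T = 20`, `mu = 0.5`.
Our fusion entry points consume precomputed similarity views directly, so
`mu` (the kernel bandwidth) only enters through the optional
`affinity_from_distance` helper; it is recorded in the output parameters
for provenance. With `T = 0` the output is the symmetrized mean of the
full kernels (no diffusion).

Association views are incomplete: a drug absent from the source database
has an all-zero feature row (flagged at featurization). The six
fingerprint views are always dense, so their SNF fusion is used to
complete the five sparse views (combined, target, disease, miRNA, ADR):
for each flagged drug, its row *and* column are replaced by the
corresponding row of the fused fingerprint network (rescaled into [0,1] if
needed), the diagonal is restored to 1, and every other entry is left
bit-identical. The IC50-profile view is never completed; instead a
validation convention applies: drugs absent from the *training* response
table simply keep their fill-value profile (see leakage guards).

## The interaction network

Per pair (dᵢ, cⱼ), with K = 12 drug views and L = 4 cell views:

1. **Projections.** `g'_k = g_k G_k` and `h'_l = h_l H_l`, pure matrix
   products without bias, all into dimension *s*.
2. **Interaction module.** All K·L outer-product maps `g'_k ⊗ h'_l`
   (rank-1, s×s) are stacked as input channels of a CNN: two residual
   blocks (`x ↦ shortcut(x) + conv(relu(conv(x)))`, identity shortcut when
   channel counts match, else 1×1 conv), one further conv layer, ReLU,
   then global max-pooling. All K·L inner products `g'_k ⊙ h'_l` (the
   diagonals of the outer maps) are concatenated and passed through a
   four-layer MLP with ReLU on the hidden layers, linear output.
3. **Entity embeddings.** Three two-hidden-layer MLPs (hidden width *s*,
   ReLU): one on the drug's row of the fused network, one on the
   concatenated projected drug vectors, one on the concatenated projected
   cell vectors. The drug embedding is the concatenation of the first
   two outputs (width 2s); summation was the alternative reading and is
   rejected in favour of the more expressive concatenation.
4. **Head.** The four embeddings are concatenated in the fixed order
   (outer, inner, drug, cell) and mapped to the scalar by four fully
   connected layers, ReLU between, linear output.

Full-scale defaults mirror the published configuration: s = 128, inner MLP
1024/1024/512/128, CNN channels 48→32→32 with 3×3 kernels, head
512/256/128/1. Training: MSE loss, Adam (lr 1e-4, weight decay 3e-4,
coupled L2 form), early stopping when validation loss has not improved for
10 epochs, best-validation checkpoint restored.

Everything — including the convolution (im2col as one BLAS product; input
gradient as correlation with the rotated kernel) — is NumPy with
hand-written backprop. Every layer and the composed network are verified
against central-difference numerical gradients in the test suite. Max-pool
ties route the gradient to the first argmax (deterministic).

## Cell-line preprocessing

The three omics views are z-scored per feature using statistics of the
cell lines appearing in the training pairs only; validation/test-only cell
lines reuse those statistics. The similarity views are consumed as-is
(their scale is already [0,1]).

## Split schemes and leakage guards

* `random_811`: pairs shuffled 8:1:1 into train/val/test.
* `es1_drug_blind` / `es2_cell_blind`: 20% of the drugs (cells) are
  blinded — every one of their pairs is test, none appears in train or
  validation. Validation is *also* entity-blind: validation entities are
  disjoint from training entities and their pairs amount to ~1/6 of the
  non-test pairs. With seen-entity validation, early stopping selects
  models that memorize entity identity (the near-identity binary views
  make every drug's row an almost-one-hot identifier), which is exactly
  the failure mode a de-novo evaluation must not reward. An alternative
  reading that partitions the selected entities 4:1:1 into
  test/val-only/train-visible buckets is available via `es_mode="entities"`.
* `independent`: an external pair table is the test set verbatim;
  the internal table splits 9:1 into train/val.

Leakage guards enforced by construction and asserted in tests: the
IC50-profile matrices (and the similarity views derived from them) are
built from training-split triples only; blinded entities never occur in a
train or validation pair; standardization statistics come from training
cell lines.

## Synthetic benchmark

The generator plants a bilinear response surface: latents `u_i, w_j ~
N(0, I_d)` with d = 4, core `A` random, `IC50 = standardize(u A wᵀ) + ε`,
`ε ~ N(0, noise_sd²)`; because the noiseless surface is standardized to
unit variance, `noise_sd` reads as a fraction of the signal scale
(default 0.1). Around the signal it emulates every pipeline input:
fingerprints are thresholded (binary) or sigmoid-squashed (continuous)
random projections of `u_i`, so similar latents give similar fingerprints;
association edges fire with probability increasing in the latent affinity
to random per-partner anchors, with `floor(zero_row_fraction · n)` drugs
forced edgeless per view; combined scores are latent cosine affinities
scaled to 1..1000 on a random ~50% of drug pairs; omics are linear
read-outs of `w_j` plus noise (60-gene panel); ~85% of the drug×cell grid
is observed (~1020 triples at the default 30×40).

The bilinear form is chosen deliberately: it is the minimal structure the
multiplicative interaction module should recover. `planted_signal_check`
fits ridge regression on the flattened true-latent outer products and
reports held-out Pearson r — the ceiling a perfect latent-recovery model
could attain (≈ 0.995 at default noise).

What the generator does **not** emulate: real chemistry (the synthetic
SMILES are token strings), the heavy-tailed IC50 distributions of public
screens, dose–response measurement error structure, or batch effects.
Passing tests therefore demonstrate that the pipeline recovers a planted
multiplicative signal through the similarity machinery at small scale —
not that it attains any particular accuracy on real pharmacogenomic data.

## Desk-scale configuration

The synthetic benchmark runs a reduced configuration
(`benchmark_model_spec`): s = 16, CNN channels 8/8/8, inner MLP
128/128/64/32, head 64/32/16/1, lr 1e-3, weight decay 3e-4, batch 128.
Problem sizes (30 drugs × 40 cells, ~1020 pairs) and this architecture are
the package's desk-scale choices; the full-scale defaults remain those of
`ModelSpec()`.

Two small-data adaptations matter and are deliberate:

* **Ensembling.** Cold-start (entity-blind) runs train three
  independently initialized networks and average their predictions. With
  ~20 training drugs, single-network cold-start performance varies
  substantially across initializations; averaging de-correlates those
  errors. The random-split benchmark is stable seed-to-seed and uses a
  single network.
* **Longer patience for cold-start runs** (30 epochs, vs 10–15
  elsewhere). The entity-blind validation set contains only 3–4 drugs, so
  its loss is a noisy selection signal; with patience 10 it routinely
  stops before the similarity-mediated (generalizing) pathway has been
  learned, keeping an early memorization-flavoured checkpoint.

## Numerical choices and degenerate inputs

* Unknown IC50 entries in the profile matrices fill with 0 (documented,
  overridable); profile-derived distances above 1 trigger the max-rescale.
* Duplicate association edges collapse; duplicate (drug, cell) triples
  with conflicting IC50 raise.
* Combined-score diagonal is 1 by convention (self-combination undefined
  in the source databases); the two directions of a scored pair are
  reconciled by max.
* kNN selection in SNF uses a stable argsort; exact ties are resolved by
  index order. Rows whose off-diagonal mass is zero produce zero rows in
  the sparse kernel and a 1/2-diagonal row in the full kernel.
* The residual blocks apply no activation after the addition, so zeroing
  the residual branch makes a matched-channel block exactly the identity.
* float32 is the training dtype; float64 is used in gradient tests.

## Known limitations

* Chebyshev similarity on binary views is near-diagonal (above); with
  many binary views the model can identify drugs from their own rows,
  which inflates random-split performance relative to cold-start — the
  drug-blind scheme exists precisely to expose this.
* The distance→similarity transform is a convention; alternatives would
  change the similarity scale and SNF's neighbourhoods.
* The NumPy network is CPU-bound and sized for hundreds of entities, not
  for large screens; at full scale (s = 128, 82k pairs) a GPU framework
  would be the practical choice.
* The PSFP and ESPFP fingerprint families have no implementation in this
  stack; the RDKit backend substitutes deterministic hashed structural
  fingerprints at the published widths (documented in the API), and the
  fixture backend uses synthetic bitstrings throughout.
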