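# Methods

## Problem and model

The package infers the cell-cycle phase (G1, S, or merged G2/M) of a single
nucleus from a z-stack of a DNA-marker channel alone, by first learning a
self-supervised latent representation and then training a small supervised
head on top of the frozen encoder. The representation learner is a
β-variational autoencoder over stacks `x ∈ R^(P×H×W)` (P focal planes) with
diagonal-Gaussian posterior `q_φ(z|x) = N(μ(x), diag σ²(x))`, standard normal
prior, and two auxiliary objectives:

* **Reporter-intensity regression.** A single affine layer predicts the mean
  red and green PIP-FUCCI reporter intensities `(r̄, ḡ)` from the sampled
  latent `z`. Because the reporters encode phase (green present in G1 and
  G2/M, red in S and G2/M), this in-silico-labeling task pulls
  phase-discriminative image content into the latent code during training
  even though phase labels are never used. Targets are z-scored with
  training-split statistics, which are stored in the checkpoint so that
  inference-time predictions can be mapped back to camera units.
* **Temporal contrastive loss (NT-Xent).** The same nucleus in two
  consecutive frames is a positive pair; all other crops in the batch are
  negatives. With cosine similarity `sim` and temperature `τ`,

      l_ij = −log [ exp(sim(z_i,z_j)/τ) / Σ_k 1[(k,i)∉P] exp(sim(z_i,z_k)/τ) ]

  and the batch loss is `(1/2|P|) Σ_(i,j)∈P (l_ij + l_ji)` over unordered
  positive pairs. The denominator excludes `k = i` and every `k` positive for
  `i` — stricter than the original SimCLR denominator, which keeps the
  positive term; the difference is pinned down by a brute-force oracle test.
  Frames that are first or last in their track contribute one positive pair,
  interior frames two.

The composite objective is

    L = L_rec + β·KL(q_φ(z|x) ‖ N(0,I)) + λ1·MSE((r̄,ḡ),(r̂,ĝ)) + λ2·NT-Xent.

Classification trains two fully connected layers (latent → hidden → 3) with
cross-entropy on frozen posterior means μ; with the published latent and
hidden widths of 256 the head has exactly 66,563 parameters. The baseline is
a linear-kernel SVM on standardized nucleus area and total DNA-marker
intensity with balanced class weights (balancing is our addition: the macro
metric is class-balanced, so an unbalanced baseline would be handicapped for
an uninteresting reason).

## Numerical backbone

All networks run on a small reverse-mode automatic-differentiation engine
over float64 numpy arrays written for this package (`ccvae.autodiff`,
`ccvae.nn`), with strided-view im2col convolutions, max-pooling,
nearest-neighbour upsampling, batch normalization composed from
differentiable primitives, and Adam. Gradients of every operator are checked
against central finite differences in the test suite. Two encoder backbones
share one contract: `small` — four stride-2 3×3 convolution blocks
(12/24/48/96 channels, total stride 16), the profile used for every
experiment in this repository — and `resnet18`, the standard 18-layer
residual network with its first convolution widened to the number of focal
planes (total stride 32, ~12.8M parameters). Decoders mirror the encoders
with nearest-upsample + convolution stages (resize-conv rather than
transposed convolution: same expressiveness, no checkerboard artifacts, and
one fewer custom operator); the output layer is linear by default with a
configurable sigmoid.

## Loss scaling and default weights

The published weights (β = 0.01, λ1 = 1e4, λ2 = 100, τ = 0.7) are the
`LossWeights` defaults and were balanced against a *sum*-reduced
reconstruction error (the convention of the VAE framework the original
implementation used). The `reconstruction_loss` operation itself is defined
as ½·mean-MSE; the trainer rescales it to a per-stack sum (batch-averaged)
by default (`recon_reduction="sum"`), with the per-element mean available in
config. With mean reduction and β = 0.01 the KL term dominates the
desk-scale reconstruction term by two orders of magnitude and collapses the
posterior — visible in the per-step loss log, which always records raw
components.

`LossWeights.desk()` (β = 0.01, λ1 = λ2 = 1e3) applies the same calibration
principle the published grid search used — setting the auxiliary weights so
their terms start at a fixed ratio to the β-VAE term — under the desk-scale
conditions (5×32×32 stacks, z-scored targets). The desk
training profile (`TrainConfig.desk()`) is: Adam, learning rate 1e-3, batch
32, 10 epochs × 40 steps, latent 64, early-stopping patience 3 on the
validation total; an "epoch" is a fixed step count so run time is set by
configuration, not dataset size. Full-scale defaults (latent 256, learning
rate 1e-4, batch 128, 10 epochs) remain the dataclass defaults.

One training-protocol choice deserves emphasis: geometric augmentations
(90° rotations, flips) are drawn **per pair** in the desk profile — the
anchor's transform is replayed on its successor — while the general default
draws them independently per crop. With only ~16 tracks per desk-scale
batch, independent draws turn NT-Xent into a rotation-invariance task;
the encoder then collapses track-discriminative structure and temporal
retrieval degrades even as the contrastive loss falls. Replaying the
transform keeps the task about temporal adjacency, which is the point of
the term. Batches contain at most one pair per track, so same-track
non-adjacent frames are never mislabeled as negatives.

## Synthetic data: what it emulates, and what it does not

The generator (`ccvae.synthetic`) produces tracked nuclei as textured
ellipses in a 5-plane stack with progressively defocused planes (plane 0
sharpest):

* **Cycle structure.** Each track runs G1 → S → G2/M with phase fractions
  0.40/0.35/0.25 of a cycle length drawn from N(24, 3²) frames; these
  fractions are package defaults, not measured values. DNA content is 1
  genome equivalent through G1, ramps linearly to `dna_doubling` (default
  2.0, encoding replication) across S, and stays doubled in G2/M. Radius
  grows monotonically by ×1.3 per cycle.
* **Reporters.** Green present in G1 and G2/M, red in S and G2/M, with one
  multiplicative lognormal brightness factor per reporter per cell
  (CV 0.1) and additive per-frame noise — mirroring the strong
  between-cell marker variability that motivates track-level annotation.
* **Texture.** In-mask intensity is proportional to DNA content modulated by
  band-limited noise whose correlation length and contrast vary with cycle
  position: smooth/low-contrast decondensed chromatin in G1, fine punctate
  replication-foci-like texture in S, coarse high-contrast condensing
  chromatin toward G2/M. The texture field is zero-centered inside the
  nuclear mask, so the in-mask mean intensity tracks DNA content exactly;
  consecutive frames share a common texture component (correlation 0.7).
* **Confounders.** A deterministic `round(confounder_fraction · n_tracks)`
  tracks (default 20%) alternate between two planted failure modes of
  morphology-only classification: S-phase frames rendered 35% larger
  (mistakable for G2/M by size) and early-S frames held at the G1-end radius
  (mistakable for G1). Labels stay correct, so an area+intensity classifier
  carries an irreducible error on these tracks while chromatin texture still
  resolves them.
* **Truncations.** A fraction of tracks is cut to a window inside a single
  phase, emulating tracks clipped by the start or end of the movie; these
  are exactly the tracks the annotation module must exclude.

Not emulated: real chromatin texture statistics, mitotic figures,
segmentation errors, multi-nucleus crowding, photobleaching, or
domain shift between DNA markers. Passing ordering tests on this generator
shows that the implementation trains, that the auxiliary objectives do what
they claim, and that texture-sensitive features beat morphology when
morphology is confounded — it does not certify accuracy figures on real
microscopy.

The desk-scale calibration uses 0.8 μm pixels so that a ~6 px radius is a
plausible ~5 μm nucleus; the real-acquisition default (0.102 μm/px, 5 planes
at 1 μm spacing, 20 min frame interval) is the `Calibration` dataclass
default used in the conversion arithmetic.

## Annotation surrogate

Real annotation of the reference dataset was semi-manual; this package
implements a deterministic surrogate and never claims to reproduce manual
labels. Per channel, presence = median-smoothed intensity (window 3) above
0.3 × the per-track 95th percentile (the percentile, not the max, resists
single-frame spikes). Patterns map to phases (green→G1, red→S, both→G2/M,
neither→unlabeled early-G1); a monotone G1→S→G2/M labeling is then fitted by
exhaustively minimizing disagreement over both change points (O(L²) with
prefix sums; unlabeled-pattern frames carry no evidence; ties take the
earliest change points). Leading reporter-dark frames stay unlabeled.
Exclusions, in precedence order: `too_short` (< 6 frames), `single_phase`
(fewer than 2 distinct fitted phases), `truncated_ambiguous` (a fitted
transition within one smoothing window of the last frame). On noiseless
synthetic tracks the fitted change points equal the generator's exactly.

## Evaluation conventions

* Embeddings are always posterior means μ (deterministic; sampling is a
  training device).
* Macro-averaged accuracy = unweighted mean of per-class recalls; undefined
  (an error) if a class has no true instances.
* Top-1 retrieval: for each ordered temporally adjacent pair (i, j),
  success iff j is the strict Euclidean nearest neighbour of i (argmin ties
  resolve to the smallest row index, so a tie counts as success only if j is
  that index). Two pool scopes are provided: the whole table (default), in
  which an interior frame competes against both of its own neighbours and a
  smooth trajectory caps the score near 0.5, and a batched scope (pools of
  ~16 pairs, at most one pair per track, seeded assembly) matching how the
  metric is used with batch-assembled data. Experiments report the batched
  scope for this reason.
* SSIM: 11×11 Gaussian window (σ 1.5), K1 = 0.01, K2 = 0.03, valid-mode
  filtering, per plane and averaged; agreement with an independent reference
  implementation is enforced to 1e-6 in tests. Reconstruction SSIM is
  computed on a bounded test subset (64 crops) against decodes of μ.
* Cross-fold aggregation averages row-normalized confusion matrices, so each
  fold contributes equally regardless of size; summaries report mean ± sd
  over folds or seeds.
* Cross-validation groups by field of view. The original protocol's
  "validation = test" behaviour is available behind `merged_val_test=True`;
  the default splits held-out FOVs into disjoint validation and test halves
  because early stopping on the test set leaks. A single held-out FOV falls
  back to splitting by track.
* The 2-D latent map export uses UMAP (seeded) by default, with a PCA
  alternative used where exact determinism at negligible cost matters.

## Ablation harness

Variants: `none` (random frozen encoder), `ae` (β = 0 and z = μ — the
deterministic autoencoder limit, implemented in the same code path),
`beta_vae` (λ1 = λ2 = 0), `ccvae_no_time` (λ2 = 0), `ccvae` (full), and
`svm_baseline`. Each variant trains on identical data and seeds (fold 0 of a
5-fold FOV-grouped split of a fresh 64-track dataset per seed) and reports
reconstruction SSIM, batched top-1 retrieval, and macro accuracy as
mean ± sd over seeds. Expected desk-scale orderings (3 seeds, majority
verdict): full model above the λ2 = 0 ablation on retrieval; trained head
above the SVM on confounded data; plain AE best at reconstruction.

## Degenerate inputs and numerical details

All computation is float64. `log_var` heads start near zero scale (weights
×0.01) so initial posteriors sit near the prior. Cosine similarities add
1e-30 inside the row-norm square root; NT-Xent raises on an anchor with no
negatives, naming the anchor. Training aborts on a non-finite loss and
returns the best finite validation state. `validate_manifest` reports every
structural violation (frame gaps, duplicate tracks, FOV changes inside a
track, non-positive areas, plane-count mismatches) with its location rather
than failing fast. Checkpoints embed the model contract (latent dim,
backbone, plane count, image size, output activation) and loading refuses a
mismatch.

## Known limitations

* The desk-scale profile is the tested configuration; the `resnet18`
  backbone satisfies its shape/contract tests but is far too slow on one
  CPU for training experiments here.
* The annotation surrogate's thresholds are package choices; on real data
  they would need calibration against curated tracks.
* Absolute metric values at desk scale are not comparable to full-scale
  results; only orderings and invariances are asserted.
* UMAP determinism is guaranteed per environment, not across library
  versions.
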