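# ccvae — cell-cycle phase from a DNA marker alone

`ccvae` infers the cell-cycle phase (G1, S, G2/M) of single nuclei from
z-stacks of a generic DNA marker (SiR-DNA, Hoechst, DAPI), so that imaging
assays can recover cell-cycle context without spending fluorescent channels
on dedicated cycle reporters. It is aimed at computational biologists
working with high-content time-lapse screens who have tracked nucleus crops
and want phase labels or a phase-aware latent space.

## The model

The core is a cell-cycle-aware β-variational autoencoder. An encoder
`q_φ(z|x)` compresses a stack `x` (five focal planes of one nucleus) into a
latent code `z ∈ R^d`; a mirrored decoder reconstructs `x̂`. Two auxiliary
objectives shape the latent space during self-supervised training:

    L = ½·MSE(x, x̂) + β·KL(q_φ(z|x) ‖ N(0, I_d))
        + λ1·MSE((r̄, ḡ), (r̂, ĝ))          # PIP-FUCCI mean-intensity regression
        + λ2·NT-Xent(z; P, τ)                # temporal contrastive loss

where `(r̄, ḡ)` are the mean red/green PIP-FUCCI reporter intensities
(predicted from `z` by one affine layer — in-silico labeling), and the
NT-Xent term treats the same nucleus in consecutive frames as positive pairs
`P` against in-batch negatives, with cosine similarity and temperature `τ`.
Defaults follow the published configuration: β = 0.01, λ1 = 1e4, λ2 = 100,
τ = 0.7, d = 256. A two-layer head (67k parameters at d = 256) trained on
the frozen encoder's posterior means performs the final classification;
a linear SVM on nucleus area + total DNA intensity serves as the
classical-morphology baseline.

The package also provides: a rule-based annotator that labels tracks from
the temporal evolution of PIP-FUCCI intensities (and excludes tracks that
are too short, single-phase, or truncated), a synthetic tracked-nucleus
generator with planted size confounders that make the whole method testable
without any download, FOV-grouped cross-validation, evaluation metrics
(macro accuracy, top-1 temporal retrieval, SSIM, confusion matrices), and a
loss-ablation harness. Neural networks run on a small numpy autodiff engine
included in the package; no GPU or deep-learning framework is required.

## Worked example

Simulate a small dataset, pretrain, train the classifier head, and score it:

    ccvae simulate --out data --seed 5
    ccvae train-ssl --manifest data/manifest.csv --out run --seed 0
    ccvae train-classifier --checkpoint run/checkpoint.npz \
        --manifest data/manifest.csv --out head
    ccvae predict --head head --manifest data/manifest.csv --out pred.csv
    ccvae evaluate --predictions pred.csv --out metrics.json

On the default desk-scale conditions (64 tracks, 32×32 crops, 20% of tracks
size-confounded) this takes a few minutes on one CPU and `metrics.json`
contains:

    "macro_accuracy": 0.8985642296376914

i.e. the unweighted mean of the three per-class recalls, here scored on the
same manifest the head was trained on (a self-consistency demo; the
ablation harness and `scripts/acceptance.py` use proper FOV-grouped
held-out splits, where the full model reaches ≈ 0.86 macro accuracy against
≈ 0.71 for the area+intensity SVM baseline — the gap is the planted
confounder population, which only chromatin texture resolves). The same
library calls are available in Python
(`ccvae.synthetic`, `ccvae.training`, `ccvae.classification`,
`ccvae.evaluation`); `ccvae ablation` runs the full variant grid
(`none`, `ae`, `beta_vae`, `ccvae_no_time`, `ccvae`, `svm_baseline`).

Physical calibration helpers use the acquisition defaults (0.102 μm/px,
5 planes at 1 μm, 20 min frames): `px_to_um(173.90) → 17.74 μm`.

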