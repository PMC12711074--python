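"""Declarative experiment harness: trains the loss-ablation variants on
identical data and seeds and scores them with the evaluation module.

Variants successively remove elements of the full method:

==============  =====================================================
none            no pretext task; the frozen encoder keeps its random
                initialization
ae              deterministic autoencoder limit: beta = 0 and z = mu
                (no posterior sampling), no auxiliary heads
beta_vae        beta-VAE only (lambda1 = lambda2 = 0)
ccvae_no_time   full model minus the temporal contrastive term
                (lambda2 = 0)
ccvae           the full composite objective
svm_baseline    linear SVM on (area, total DNA intensity); no encoder
==============  =====================================================
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .classification import (BaselineFeatures, HeadConfig, extract_features,
                             predict_phase, svm_baseline, train_head)
from .data_model import CellCyclePhase, DatasetManifest, group_kfold
from .evaluation import (EmbeddingTable, confusion, macro_accuracy, ssim,
                         top1_retrieval)
from .objectives import LossWeights
from .synthetic import SyntheticConfig, generate_in_memory
from .training import TrainConfig, train_ssl
from .vae_core import VaeModel

__all__ = ["ExperimentSpec", "VARIANTS", "variant_settings", "run_ablation",
           "evaluate_variant_on_split"]

VARIANTS = ("none", "ae", "beta_vae", "ccvae_no_time", "ccvae", "svm_baseline")


@dataclass
class ExperimentSpec:
    variants: Tuple[str, ...] = VARIANTS
    seeds: Tuple[int, ...] = (0, 1, 2)
    dataset: SyntheticConfig = field(default_factory=SyntheticConfig)
    train: TrainConfig = field(default_factory=TrainConfig.desk)
    weights: LossWeights = field(default_factory=LossWeights.desk)
    head: HeadConfig = field(default_factory=HeadConfig.desk)
    k_folds: int = 5
    max_ssim_crops: int = 64
    retrieval_batch_size: Optional[int] = 32  # None: whole test set as pool

    def __post_init__(self):
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants {sorted(unknown)}")


def variant_settings(variant: str, base: LossWeights
                     ) -> Tuple[Optional[LossWeights], bool, bool]:
    """(loss weights, sample latent, pretrain at all) for a variant."""
    if variant == "none":
        return None, True, False
    if variant == "ae":
        return replace(base, beta=0.0, lambda1=0.0, lambda2=0.0), False, True
    if variant == "beta_vae":
        return replace(base, lambda1=0.0, lambda2=0.0), True, True
    if variant == "ccvae_no_time":
        return replace(base, lambda2=0.0), True, True
    if variant == "ccvae":
        return base, True, True
    raise ValueError(f"variant {variant!r} has no loss settings")


def _split_crop_sets(manifest: DatasetManifest, k: int, seed: int):
    split = group_kfold(manifest, k=k, seed=seed)
    fold = split.folds[0]
    return set(fold.train), set(fold.val), set(fold.test)


def _crops_by_id(manifest: DatasetManifest, ids) -> List:
    return [c for c in manifest.crops() if c.crop_id in ids]


def evaluate_variant_on_split(variant: str, manifest: DatasetManifest,
                              train_ids, val_ids, test_ids,
                              spec: ExperimentSpec, seed: int) -> Dict:
    """Train one variant on one split and return its metric row."""
    train_crops = _crops_by_id(manifest, train_ids)
    test_crops = _crops_by_id(manifest, test_ids)
    lab_train = [c for c in train_crops if c.label is not CellCyclePhase.UNLABELED]
    lab_test = [c for c in test_crops if c.label is not CellCyclePhase.UNLABELED]
    row: Dict = {"variant": variant, "seed": seed, "ssim": np.nan,
                 "top1_retrieval": np.nan, "macro_accuracy": np.nan}

    if variant == "svm_baseline":
        clf = svm_baseline(BaselineFeatures.from_crops(lab_train),
                           [c.label for c in lab_train])
        preds = clf.predict(BaselineFeatures.from_crops(lab_test))
        row["macro_accuracy"] = macro_accuracy(
            confusion([c.label for c in lab_test], preds))
        return row

    weights, sample_latent, pretrain = variant_settings(variant, spec.weights)
    cfg = replace(spec.train, seed=seed, sample_latent=sample_latent)
    if pretrain:
        model, _ = train_ssl(manifest, cfg, weights,
                             train_ids=set(train_ids), val_ids=set(val_ids))
    else:
        sample = next(manifest.crops())
        model = VaeModel(latent_dim=cfg.latent_dim,
                         n_planes=sample.image.shape[0],
                         image_size=sample.image.shape[1],
                         backbone=cfg.backbone, seed=seed)
        model.eval()

    # reconstruction quality on a bounded test subset
    if pretrain:
        subset = test_crops[:spec.max_ssim_crops]
        stack = np.stack([c.image for c in subset])
        recon = model.decode_np(extract_features(model, subset))
        rng_val = float(max(stack.max(), recon.max())
                        - min(stack.min(), recon.min()))
        row["ssim"] = float(np.mean([ssim(a, b, data_range=rng_val)
                                     for a, b in zip(stack, recon)]))

    feats_test = extract_features(model, test_crops)
    row["top1_retrieval"] = top1_retrieval(
        EmbeddingTable(
            embeddings=feats_test,
            track_ids=[c.track_id for c in test_crops],
            frame_indices=[c.frame_index for c in test_crops]),
        batch_size=spec.retrieval_batch_size, seed=seed)

    head = train_head(extract_features(model, lab_train),
                      [c.label for c in lab_train],
                      replace(spec.head, seed=seed), encoder=model)
    preds, _ = predict_phase(head, extract_features(model, lab_test))
    row["macro_accuracy"] = macro_accuracy(
        confusion([c.label for c in lab_test], preds))
    return row


def run_ablation(spec: ExperimentSpec,
                 out_dir: Optional[str] = None) -> Tuple[pd.DataFrame, Dict]:
    """Run every variant on every seed; emit the per-run table and the
    mean +/- sd summary per variant and metric."""
    rows = []
    for seed in spec.seeds:
        dataset_cfg = replace(spec.dataset, seed=seed)
        manifest, _ = generate_in_memory(dataset_cfg)
        train_ids, val_ids, test_ids = _split_crop_sets(
            manifest, spec.k_folds, seed)
        for variant in spec.variants:
            rows.append(evaluate_variant_on_split(
                variant, manifest, train_ids, val_ids, test_ids, spec, seed))
    table = pd.DataFrame(rows)
    summary: Dict = {}
    for variant in spec.variants:
        sub = table[table["variant"] == variant]
        summary[variant] = {
            metric: {"mean": float(np.nanmean(sub[metric])),
                     "sd": float(np.nanstd(sub[metric]))}
            if not sub[metric].isna().all() else None
            for metric in ("ssim", "top1_retrieval", "macro_accuracy")}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "ablation.csv"), index=False)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
    return table, summary
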