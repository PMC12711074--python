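"""Self-supervised training loop: temporal pair batches, geometric
augmentation, Adam optimization and early stopping.

Batches are assembled as anchor/successor pairs: half the batch are anchor
frames, each followed by the next frame of the same track, so the one-frame
shift acts as the semantic-preserving augmentation for the contrastive term.
At most one pair per track enters a batch, which guarantees that no
same-track non-adjacent frames are ever treated as negatives. Geometric
augmentations (90-degree rotations and flips) are drawn independently for
the two members of a pair.

An "epoch" is a fixed number of optimization steps (``steps_per_epoch``), so
that run time scales with configuration rather than dataset size; validation
loss is evaluated once per epoch on fixed held-out pair batches and the
parameters from the best validation epoch are returned.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .autodiff import Tensor, no_grad
from .data_model import DatasetManifest, NucleusCrop, Track
from .nn import Adam
from .objectives import LossWeights, PairSet, predict_intensities
from .vae_core import VaeModel

__all__ = ["TrainConfig", "PairBatch", "build_pair_batch", "augment",
           "train_ssl", "early_stop_index", "TrainingDiverged"]

AUGMENTATIONS = ("rotate90", "hflip", "vflip")


@dataclass
class TrainConfig:
    epochs: int = 10
    learning_rate: float = 1e-4
    batch_size: int = 128
    augmentations: Set[str] = field(default_factory=lambda: set(AUGMENTATIONS))
    early_stopping_patience: int = 3
    seed: int = 0
    backbone: str = "small"
    latent_dim: int = 256
    steps_per_epoch: int = 50
    n_val_batches: int = 4
    sample_latent: bool = True   # False: deterministic autoencoder limit z = mu
    paired_augment: bool = False  # draw one geometric transform per pair
    recon_reduction: str = "sum"  # "sum": per-stack sum of squared errors
    #   (batch-averaged), the convention the published weights were balanced
    #   against; "mean": per-element mean

    def __post_init__(self):
        if self.batch_size % 2 != 0:
            raise ValueError("batch_size must be even (anchor/successor pairs)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        unknown = set(self.augmentations) - set(AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentations {sorted(unknown)}")
        if self.recon_reduction not in ("sum", "mean"):
            raise ValueError("recon_reduction must be 'sum' or 'mean'")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """CPU-fast profile used for synthetic desk-scale experiments.

        Paired augmentation draws: with only a handful of distinct tracks
        per batch, independently rotated pair members push the encoder
        toward rotation invariance at the expense of track discriminability,
        which defeats the temporal term; replaying the anchor's transform on
        its successor keeps the contrastive task about temporal adjacency.
        """
        base = dict(epochs=10, learning_rate=1e-3, batch_size=32,
                    steps_per_epoch=40, latent_dim=64, backbone="small",
                    paired_augment=True)
        base.update(overrides)
        return cls(**base)


@dataclass
class PairBatch:
    crops: List[NucleusCrop]
    pair_set: PairSet


def build_pair_batch(manifest: DatasetManifest, batch_size: int,
                     rng: np.random.Generator,
                     crop_ids: Optional[Set[str]] = None) -> PairBatch:
    """Sample ``batch_size/2`` (frame, frame+1) adjacencies, at most one per
    track, uniformly and without replacement within the batch."""
    eligible = []  # (track, position of anchor crop)
    for track in manifest.tracks:
        crops = track.crops
        if crop_ids is not None:
            crops = [c for c in crops if c.crop_id in crop_ids]
        for a, b in zip(crops[:-1], crops[1:]):
            if b.frame_index == a.frame_index + 1:
                eligible.append((track.track_id, a, b))
    n_pairs = batch_size // 2
    order = rng.permutation(len(eligible))
    chosen, used_tracks = [], set()
    for idx in order:
        tid, a, b = eligible[idx]
        if tid in used_tracks:
            continue
        used_tracks.add(tid)
        chosen.append((a, b))
        if len(chosen) == n_pairs:
            break
    if len(chosen) < n_pairs:
        raise ValueError(f"only {len(chosen)} eligible pairs from distinct "
                         f"tracks; need {n_pairs}")
    crops: List[NucleusCrop] = []
    pair_set = PairSet()
    for a, b in chosen:
        pair_set.add(len(crops), len(crops) + 1)
        crops.extend([a, b])
    return PairBatch(crops=crops, pair_set=pair_set)


def augment(x: np.ndarray, rng: np.random.Generator,
            config: TrainConfig) -> np.ndarray:
    """Apply an independently drawn composition of 90-degree rotation and
    flips; all planes transformed identically."""
    aug = config.augmentations
    if "rotate90" in aug:
        if x.shape[-1] != x.shape[-2]:
            raise ValueError("rotate90 requires square images")
        k = int(rng.integers(4))
        if k:
            x = np.rot90(x, k, axes=(-2, -1))
    if "hflip" in aug and rng.integers(2):
        x = x[..., ::-1]
    if "vflip" in aug and rng.integers(2):
        x = x[..., ::-1, :]
    return np.ascontiguousarray(x)


def _augment_with_replay(x: np.ndarray, rng: np.random.Generator,
                         config: TrainConfig):
    """Like :func:`augment`, but also returns a closure replaying the same
    transform on another stack (paired-draw mode)."""
    aug = config.augmentations
    k = 0
    if "rotate90" in aug:
        if x.shape[-1] != x.shape[-2]:
            raise ValueError("rotate90 requires square images")
        k = int(rng.integers(4))
    h = "hflip" in aug and bool(rng.integers(2))
    v = "vflip" in aug and bool(rng.integers(2))

    def apply(y: np.ndarray) -> np.ndarray:
        if k:
            y = np.rot90(y, k, axes=(-2, -1))
        if h:
            y = y[..., ::-1]
        if v:
            y = y[..., ::-1, :]
        return np.ascontiguousarray(y)

    return apply(x), apply


def early_stop_index(val_losses: Sequence[float], patience: int) -> Tuple[int, int]:
    """(best index, stop index) under patience-limited early stopping.

    Training stops after ``patience`` consecutive evaluations without
    improvement over the best validation loss so far.
    """
    best_i, best, bad = 0, np.inf, 0
    for i, v in enumerate(val_losses):
        if v < best:
            best, best_i, bad = v, i, 0
        else:
            bad += 1
            if bad >= patience:
                return best_i, i
    return best_i, len(val_losses) - 1


class TrainingDiverged(RuntimeError):
    pass


def _standardize_stats(crops: List[NucleusCrop]) -> Tuple[np.ndarray, np.ndarray]:
    raw = np.array([[c.mean_red, c.mean_green] for c in crops])
    mean = raw.mean(axis=0)
    std = raw.std(axis=0)
    std[std < 1e-12] = 1.0
    return mean, std


def _batch_arrays(batch: PairBatch, model: VaeModel,
                  aug_rng: Optional[np.random.Generator],
                  config: Optional[TrainConfig]):
    imgs = []
    for k, crop in enumerate(batch.crops):
        img = crop.image
        if img is None:
            raise ValueError(f"crop {crop.crop_id} has no image loaded")
        if aug_rng is not None:
            if config.paired_augment and k % 2 == 1:
                # crops arrive as (anchor, successor) pairs; reuse the
                # transform drawn for the anchor
                img = _last_transform(img)
            else:
                img, _last_transform = _augment_with_replay(img, aug_rng,
                                                            config)
        imgs.append(img)
    x = np.stack(imgs)
    raw = np.array([[c.mean_red, c.mean_green] for c in batch.crops])
    targets = (raw - model.intensity_mean) / model.intensity_std
    return x, targets


def _loss_on_batch(model: VaeModel, batch: PairBatch, weights: LossWeights,
                   x: np.ndarray, targets: np.ndarray,
                   eps: Optional[np.ndarray], recon_reduction: str = "sum"):
    xt = Tensor(x)
    mu, log_var = model.encode_t(xt)
    if eps is None:
        z = mu
    else:
        z = mu + (log_var * 0.5).exp() * Tensor(eps)
    x_hat = model.decode_t(z)
    preds = predict_intensities(model.intensity_head, z)
    from .objectives import intensity_loss, nt_xent
    from .vae_core import kl_divergence, reconstruction_loss

    rec = reconstruction_loss(xt, x_hat)
    if recon_reduction == "sum":
        # per-stack sum of squared errors (batch-averaged): the convention
        # the published loss weights were balanced against
        rec = rec * float(np.prod(x.shape[1:]))
    kl = kl_divergence((mu, log_var))
    pip = intensity_loss(Tensor(targets), preds)
    nt = nt_xent(z, batch.pair_set, weights.temperature)
    total = rec + weights.beta * kl + weights.lambda1 * pip \
        + weights.lambda2 * nt
    terms = {"rec": rec.item(), "kl": kl.item(), "pip": pip.item(),
             "ntxent": nt.item(), "total": total.item()}
    return total, terms


def train_ssl(manifest: DatasetManifest, config: TrainConfig,
              weights: LossWeights = LossWeights(),
              train_ids: Optional[Set[str]] = None,
              val_ids: Optional[Set[str]] = None,
              run_dir: Optional[str] = None
              ) -> Tuple[VaeModel, List[Dict[str, float]]]:
    """Train the model on a manifest; labels are never consulted.

    ``train_ids``/``val_ids`` restrict the crop pool (crop ids as produced by
    the splitter); with no validation pool, one fifth of the training tracks
    is set aside. Returns the model holding the best-validation-epoch
    parameters and the per-epoch history of every loss term.
    """
    seq = np.random.SeedSequence(config.seed)
    init_s, batch_s, aug_s, eps_s, val_s = [
        np.random.default_rng(s) for s in seq.spawn(5)]
    sample = next(manifest.crops())
    if sample.image is None:
        raise ValueError("manifest crops must have images loaded")
    n_planes, image_size = sample.image.shape[0], sample.image.shape[1]
    model = VaeModel(latent_dim=config.latent_dim, n_planes=n_planes,
                     image_size=image_size, backbone=config.backbone,
                     seed=int(init_s.integers(2 ** 31)))
    if val_ids is None and train_ids is None:
        tracks = sorted(manifest.tracks, key=lambda t: t.track_id)
        n_val = max(1, len(tracks) // 5)
        val_tracks = tracks[-n_val:]
        val_ids = {c.crop_id for t in val_tracks for c in t.crops}
        train_ids = {c.crop_id for t in tracks[:-n_val] for c in t.crops}
    train_crops = [c for c in manifest.crops()
                   if train_ids is None or c.crop_id in train_ids]
    model.intensity_mean, model.intensity_std = _standardize_stats(train_crops)

    # validation batches cannot exceed one pair per eligible held-out track
    val_pool_tracks = 0
    for track in manifest.tracks:
        crops = [c for c in track.crops
                 if val_ids is None or c.crop_id in val_ids]
        if any(b.frame_index == a.frame_index + 1
               for a, b in zip(crops[:-1], crops[1:])):
            val_pool_tracks += 1
    val_batch_size = 2 * min(config.batch_size // 2, 16, val_pool_tracks)
    if val_batch_size < 4:
        raise ValueError("validation pool has fewer than two tracks with "
                         "consecutive frames")
    val_batches = [build_pair_batch(manifest, val_batch_size, val_s, val_ids)
                   for _ in range(config.n_val_batches)]
    val_arrays = [_batch_arrays(b, model, None, None) for b in val_batches]

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    log_fh = None
    if run_dir is not None:
        os.makedirs(run_dir, exist_ok=True)
        log_fh = open(os.path.join(run_dir, "loss_log.jsonl"), "w")
    history: List[Dict[str, float]] = []
    best_state, best_val, bad, step = None, np.inf, 0, 0
    diverged = False
    try:
        for epoch in range(config.epochs):
            model.train()
            sums: Dict[str, float] = {}
            for _ in range(config.steps_per_epoch):
                batch = build_pair_batch(manifest, config.batch_size,
                                         batch_s, train_ids)
                x, targets = _batch_arrays(batch, model, aug_s, config)
                eps = (eps_s.standard_normal((len(batch.crops),
                                              config.latent_dim))
                       if config.sample_latent else None)
                total, terms = _loss_on_batch(model, batch, weights, x,
                                              targets, eps,
                                              config.recon_reduction)
                if not np.isfinite(terms["total"]):
                    diverged = True
                    break
                optimizer.zero_grad()
                total.backward()
                optimizer.step()
                step += 1
                for k, v in terms.items():
                    sums[k] = sums.get(k, 0.0) + v
                if log_fh is not None:
                    log_fh.write(json.dumps({"step": step, **terms}) + "\n")
            if diverged:
                break
            entry = {f"train_{k}": v / config.steps_per_epoch
                     for k, v in sums.items()}
            model.eval()
            with no_grad():
                val_terms: Dict[str, float] = {}
                for b, (vx, vt) in zip(val_batches, val_arrays):
                    _, terms = _loss_on_batch(model, b, weights, vx, vt, None,
                                              config.recon_reduction)
                    for k, v in terms.items():
                        val_terms[k] = val_terms.get(k, 0.0) + v
            entry.update({f"val_{k}": v / len(val_batches)
                          for k, v in val_terms.items()})
            entry["epoch"] = epoch
            history.append(entry)
            if entry["val_total"] < best_val:
                best_val = entry["val_total"]
                best_state = copy.deepcopy(model.state_dict())
                bad = 0
            else:
                bad += 1
                if bad >= config.early_stopping_patience:
                    break
    finally:
        if log_fh is not None:
            log_fh.close()
    if best_state is None:
        raise TrainingDiverged("training produced no finite validation loss")
    model.load_state_dict(best_state)
    model.eval()
    return model, history
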