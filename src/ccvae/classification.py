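"""Supervised phase prediction on top of the frozen encoder, and the
area + total-DNA-intensity SVM baseline.

The classifier head is two fully connected layers (latent -> hidden -> 3)
trained with cross-entropy on the posterior means of a frozen encoder; with
the published latent and hidden widths of 256 it has exactly
256*256 + 256 + 256*3 + 3 = 66,563 trainable parameters. The baseline is a
linear-kernel SVM on the two standardized morphological features that were
traditionally used as a cell-cycle proxy; the synthetic generator plants
size confounders precisely so that this baseline carries irreducible error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .autodiff import Tensor, no_grad
from .data_model import CellCyclePhase, NucleusCrop, PHASE_ORDER
from .nn import Adam, Linear, Module
from .vae_core import VaeModel

__all__ = ["HeadConfig", "PhaseClassifier", "BaselineFeatures", "SvmBaseline",
           "extract_features", "count_head_parameters", "train_head",
           "predict_phase", "svm_baseline", "encoder_checksum"]

CLASS_ORDER = PHASE_ORDER  # (G1, S, G2M)


@dataclass
class HeadConfig:
    hidden: int = 256
    epochs: int = 1
    learning_rate: float = 1e-4
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.hidden < 1:
            raise ValueError("hidden width must be >= 1")

    @classmethod
    def desk(cls, **overrides) -> "HeadConfig":
        """Profile for small synthetic datasets, where a single epoch over a
        few hundred crops cannot converge: more epochs, larger steps."""
        base = dict(hidden=64, epochs=40, learning_rate=1e-3)
        base.update(overrides)
        return cls(**base)


class _Head(Module):
    def __init__(self, latent_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(latent_dim, hidden, rng)
        self.fc2 = Linear(hidden, len(CLASS_ORDER), rng)

    def forward(self, x):
        return self.fc2(self.fc1(x).relu())


@dataclass
class PhaseClassifier:
    encoder: Optional[VaeModel]
    head: _Head
    latent_dim: int
    hidden: int

    def logits(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        with no_grad():
            return self.head(Tensor(features)).data


@dataclass
class BaselineFeatures:
    """Per-crop area and total DNA-marker intensity, train-split standardized."""

    area_um2: np.ndarray
    total_dna_intensity: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([self.area_um2, self.total_dna_intensity])

    @staticmethod
    def from_crops(crops: Sequence[NucleusCrop]) -> "BaselineFeatures":
        return BaselineFeatures(
            area_um2=np.array([c.area_um2 for c in crops], dtype=float),
            total_dna_intensity=np.array([c.total_dna_intensity for c in crops],
                                         dtype=float))


def extract_features(model: VaeModel, crops: Union[Sequence[NucleusCrop],
                                                   np.ndarray],
                     batch_size: int = 64) -> np.ndarray:
    """Posterior means mu, one row per crop; deterministic (no sampling)."""
    if isinstance(crops, np.ndarray):
        stack = crops if crops.ndim == 4 else crops[None]
    else:
        stack = np.stack([c.image for c in crops])
    rows = []
    for start in range(0, len(stack), batch_size):
        rows.append(model.encode_np(stack[start:start + batch_size]).mu)
    return np.concatenate(rows, axis=0)


def count_head_parameters(classifier: Union[PhaseClassifier, _Head]) -> int:
    head = classifier.head if isinstance(classifier, PhaseClassifier) else classifier
    return int(sum(p.data.size for p in head.parameters()))


def _encode_labels(labels) -> np.ndarray:
    order = {p: i for i, p in enumerate(CLASS_ORDER)}
    order.update({p.value: i for i, p in enumerate(CLASS_ORDER)})
    try:
        y = np.array([order[l] for l in labels], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} is not one of "
                         f"{[p.value for p in CLASS_ORDER]}") from exc
    return y


def _cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    n, k = logits.shape
    shift = logits - np.max(logits.data, axis=1, keepdims=True)
    log_probs = shift - shift.exp().sum(axis=1, keepdims=True).log()
    picked = log_probs.gather_flat(np.arange(n) * k + y)
    return -picked.mean()


def train_head(features: np.ndarray, labels, config: HeadConfig = HeadConfig(),
               encoder: Optional[VaeModel] = None) -> PhaseClassifier:
    """Fit the two-layer head with cross-entropy; the encoder is never touched."""
    features = np.asarray(features, dtype=np.float64)
    y = _encode_labels(labels)
    present = set(np.unique(y))
    if present != set(range(len(CLASS_ORDER))):
        missing = [CLASS_ORDER[i].value for i in range(len(CLASS_ORDER))
                   if i not in present]
        raise ValueError(f"classes absent from training labels: {missing}")
    rng = np.random.default_rng(config.seed)
    head = _Head(features.shape[1], config.hidden, rng)
    optimizer = Adam(head.parameters(), lr=config.learning_rate)
    n = len(features)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = head(Tensor(features[idx]))
            loss = _cross_entropy(logits, y[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
    return PhaseClassifier(encoder=encoder, head=head,
                           latent_dim=features.shape[1], hidden=config.hidden)


def predict_phase(classifier: PhaseClassifier,
                  features: np.ndarray) -> Tuple[List[CellCyclePhase], np.ndarray]:
    """Predicted phases and softmax probability triples (order G1, S, G2M).

    Argmax ties resolve to the earlier class in the class order.
    """
    logits = classifier.logits(features)
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    preds = [CLASS_ORDER[i] for i in np.argmax(probs, axis=1)]
    return preds, probs


def encoder_checksum(model: VaeModel) -> float:
    """Order-stable digest of all encoder-side parameters."""
    total = 0.0
    for name, value in sorted(model.named_state()):
        if name.startswith(("encoder", "mu_head", "logvar_head")):
            arr = value.data if isinstance(value, Tensor) else value
            total += float(np.abs(arr).sum())
    return total


@dataclass
class SvmBaseline:
    scaler: StandardScaler
    svc: SVC

    def predict(self, features: BaselineFeatures) -> List[CellCyclePhase]:
        raw = self.svc.predict(self.scaler.transform(features.matrix))
        return [CellCyclePhase(v) for v in raw]

    def decision_function(self, features: BaselineFeatures) -> np.ndarray:
        return self.svc.decision_function(self.scaler.transform(features.matrix))


def svm_baseline(features: BaselineFeatures, labels) -> SvmBaseline:
    """Linear-kernel SVM on standardized (area, total DNA intensity)."""
    y = [l.value if isinstance(l, CellCyclePhase) else str(l) for l in labels]
    if len(set(y)) < 2:
        raise ValueError("svm baseline needs at least two classes")
    scaler = StandardScaler().fit(features.matrix)
    svc = SVC(kernel="linear", class_weight="balanced", random_state=0)
    svc.fit(scaler.transform(features.matrix), y)
    return SvmBaseline(scaler=scaler, svc=svc)
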