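"""Quantitative metrics: confusion matrix, macro-averaged accuracy, top-1
retrieval accuracy, SSIM, cross-fold aggregation and latent-map export.

Evaluation embeddings are always posterior means (deterministic). The top-1
retrieval metric scores temporal coherence: for every ordered pair of
temporally adjacent same-track crops (i, j), retrieval succeeds iff the
Euclidean nearest neighbour of z_i among all other rows is exactly z_j.
Macro-averaged accuracy is the unweighted mean of per-class recalls, which
is insensitive to class imbalance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import CellCyclePhase, PHASE_ORDER

__all__ = ["EmbeddingTable", "ConfusionMatrix", "confusion", "macro_accuracy",
           "top1_retrieval", "ssim", "export_embedding_map",
           "average_confusion", "metrics_summary"]


@dataclass
class EmbeddingTable:
    embeddings: np.ndarray          # (n, d) posterior means
    track_ids: Sequence[str]
    frame_indices: Sequence[int]
    true_labels: Optional[Sequence[CellCyclePhase]] = None
    pred_labels: Optional[Sequence[CellCyclePhase]] = None
    area_um2: Optional[np.ndarray] = None
    total_dna_intensity: Optional[np.ndarray] = None

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        n = len(self.embeddings)
        if len(self.track_ids) != n or len(self.frame_indices) != n:
            raise ValueError("metadata length must match embedding rows")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray              # (3, 3), rows true / columns predicted

    @property
    def classes(self) -> Tuple[CellCyclePhase, ...]:
        return PHASE_ORDER

    @property
    def row_normalized(self) -> np.ndarray:
        """Recall view: each row divided by its true-class total."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, self.counts / totals, 0.0)
        return out

    @property
    def col_normalized(self) -> np.ndarray:
        """Precision view: each column divided by its predicted total."""
        totals = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, self.counts / totals, 0.0)
        return out

    @property
    def per_class_recall(self) -> np.ndarray:
        return np.diag(self.row_normalized)

    @property
    def per_class_precision(self) -> np.ndarray:
        return np.diag(self.col_normalized)


def _as_phases(labels) -> List[CellCyclePhase]:
    out = []
    for l in labels:
        p = l if isinstance(l, CellCyclePhase) else CellCyclePhase(str(l))
        if p is CellCyclePhase.UNLABELED:
            raise ValueError("UNLABELED crops must be filtered before scoring")
        out.append(p)
    return out


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    t, p = _as_phases(true_labels), _as_phases(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label lists must have equal length")
    index = {phase: i for i, phase in enumerate(PHASE_ORDER)}
    counts = np.zeros((3, 3))
    for a, b in zip(t, p):
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(counts=counts)


def macro_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class recalls."""
    totals = cm.counts.sum(axis=1)
    if np.any(totals == 0):
        empty = [p.value for p, n in zip(PHASE_ORDER, totals) if n == 0]
        raise ValueError(f"macro accuracy undefined: no true instances of "
                         f"{empty}")
    return float(cm.per_class_recall.mean())


def _adjacent_pairs(table: EmbeddingTable) -> List[Tuple[int, int]]:
    index = {(t, f): k for k, (t, f) in
             enumerate(zip(table.track_ids, table.frame_indices))}
    pairs = []
    for k, (t, f) in enumerate(zip(table.track_ids, table.frame_indices)):
        for g in (f - 1, f + 1):
            j = index.get((t, g))
            if j is not None:
                pairs.append((k, j))
    return pairs


def top1_retrieval(table: EmbeddingTable, batch_size: Optional[int] = None,
                   seed: int = 0) -> float:
    """Fraction of ordered temporal-neighbour pairs (i, j) whose anchor's
    Euclidean nearest neighbour (ties to the smallest row index) is j.

    With ``batch_size=None`` the whole table is one retrieval pool. Note
    that an interior frame then competes against both of its own temporal
    neighbours, which bounds the score near one half on smooth trajectories.
    With a batch size, unordered adjacent pairs are grouped (at most one
    pair per track per batch, order seeded) and each anchor is scored
    within its batch only — the pool structure the metric was designed for,
    mirroring how training batches are assembled.
    """
    Z = table.embeddings
    if len(Z) < 2:
        raise ValueError("need at least two embeddings")
    pairs = _adjacent_pairs(table)
    if not pairs:
        raise ValueError("no temporally adjacent same-track pairs")
    if batch_size is None:
        d = cdist(Z, Z)
        np.fill_diagonal(d, np.inf)
        nearest = d.argmin(axis=1)  # argmin ties resolve to the smallest index
        hits = sum(1 for i, j in pairs if nearest[i] == j)
        return hits / len(pairs)
    # batched mode
    unordered = sorted({tuple(sorted(p)) for p in pairs})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unordered))
    track_of = list(table.track_ids)
    batches: List[List[Tuple[int, int]]] = []
    pending = [unordered[i] for i in order]
    per_batch = max(2, batch_size // 2)
    while pending:
        batch, used, rest = [], set(), []
        for p in pending:
            tid = track_of[p[0]]
            if tid in used or len(batch) == per_batch:
                rest.append(p)
            else:
                used.add(tid)
                batch.append(p)
        if len(batch) < 2:
            # tiny pools: relax the one-pair-per-track constraint rather
            # than dropping the leftovers
            batch = pending[:per_batch]
            rest = pending[per_batch:]
            if len(batch) < 2:
                break
        batches.append(batch)
        pending = rest
    hits = total = 0
    for batch in batches:
        rows = sorted({i for p in batch for i in p})
        pos = {r: i for i, r in enumerate(rows)}
        d = cdist(Z[rows], Z[rows])
        np.fill_diagonal(d, np.inf)
        nearest = d.argmin(axis=1)
        for a, b in batch:
            for i, j in ((a, b), (b, a)):
                hits += int(nearest[pos[i]] == pos[j])
                total += 1
    if total == 0:
        raise ValueError("no scorable pairs under the requested batch size")
    return hits / total


def _gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    r = (size - 1) / 2
    ax = np.arange(size) - r
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def _filter_valid(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    from scipy.signal import fftconvolve
    return fftconvolve(img, kernel, mode="valid")


def ssim(x: np.ndarray, y: np.ndarray, data_range: Optional[float] = None,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Structural similarity with an 11x11 Gaussian window (sigma 1.5).

    2-D inputs are scored directly; 3-D stacks are scored per plane and
    averaged. ``data_range`` defaults to the joint value range of the inputs.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if x.ndim == 3:
        return float(np.mean([ssim(xp, yp, data_range=data_range, k1=k1, k2=k2)
                              for xp, yp in zip(x, y)]))
    if data_range is None:
        data_range = float(max(x.max(), y.max()) - min(x.min(), y.min()))
        if data_range == 0:
            data_range = 1.0
    kernel = _gaussian_kernel()
    ux = _filter_valid(x, kernel)
    uy = _filter_valid(y, kernel)
    vx = _filter_valid(x * x, kernel) - ux ** 2
    vy = _filter_valid(y * y, kernel) - uy ** 2
    cxy = _filter_valid(x * y, kernel) - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2 * ux * uy + c1) * (2 * cxy + c2)
    den = (ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)
    return float(np.mean(num / den))


def average_confusion(matrices: Sequence[ConfusionMatrix]) -> np.ndarray:
    """Cross-fold aggregate: element-wise mean of row-normalized matrices,
    so every fold contributes equally regardless of its size."""
    return np.mean([cm.row_normalized for cm in matrices], axis=0)


def metrics_summary(per_fold_macro: Sequence[float],
                    matrices: Sequence[ConfusionMatrix],
                    top1: Optional[float] = None,
                    ssim_mean: Optional[float] = None) -> Dict:
    avg = average_confusion(matrices)
    return {
        "macro_accuracy": float(np.mean(per_fold_macro)),
        "macro_recall": float(np.mean(per_fold_macro)),
        "per_class_recall": np.diag(avg).tolist(),
        "per_class_precision": np.mean(
            [cm.per_class_precision for cm in matrices], axis=0).tolist(),
        "top1_retrieval": top1,
        "ssim_mean": ssim_mean,
        "n_folds": len(per_fold_macro),
        "mean": float(np.mean(per_fold_macro)),
        "sd": float(np.std(per_fold_macro)),
    }


def export_embedding_map(table: EmbeddingTable, out_csv: str,
                         method: str = "umap", seed: int = 0,
                         polyline_json: Optional[str] = None) -> np.ndarray:
    """Project embeddings to 2-D and write coordinates plus per-crop
    metadata; optionally write per-track trajectory polylines as JSON."""
    import pandas as pd

    Z = table.embeddings
    if len(Z) < 10:
        raise ValueError("need at least 10 rows to build a map")
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=2, random_state=seed,
                            n_neighbors=min(15, len(Z) - 1))
        coords = np.asarray(reducer.fit_transform(Z), dtype=float)
    elif method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed).fit_transform(Z)
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    df = pd.DataFrame({
        "x": coords[:, 0], "y": coords[:, 1],
        "track_id": list(table.track_ids),
        "frame_index": list(table.frame_indices),
        "phase": [str(p) for p in table.true_labels]
        if table.true_labels is not None else "",
        "pred_phase": [str(p) for p in table.pred_labels]
        if table.pred_labels is not None else "",
        "area_um2": table.area_um2 if table.area_um2 is not None else np.nan,
        "total_dna_intensity": table.total_dna_intensity
        if table.total_dna_intensity is not None else np.nan,
    })
    df.to_csv(out_csv, index=False)
    if polyline_json is not None:
        lines: Dict[str, List[List[float]]] = {}
        order = np.lexsort((np.asarray(table.frame_indices),
                            np.asarray(table.track_ids, dtype=object)))
        for i in order:
            lines.setdefault(str(table.track_ids[i]), []).append(
                [float(coords[i, 0]), float(coords[i, 1])])
        with open(polyline_json, "w") as fh:
            json.dump(lines, fh)
    return coords
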