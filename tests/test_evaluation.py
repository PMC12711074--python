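"""Metrics: confusion/macro accuracy, top-1 retrieval vs brute force,
SSIM vs an independent reference, embedding-map export."""

import json

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import ortho_group
from skimage.metrics import structural_similarity

from ccvae.data_model import CellCyclePhase
from ccvae.evaluation import (ConfusionMatrix, EmbeddingTable,
                              average_confusion, confusion, export_embedding_map,
                              macro_accuracy, ssim, top1_retrieval)

P = CellCyclePhase


def brute_force_top1(Z, track_ids, frames):
    """All-pairs-distance re-evaluation of whole-pool retrieval."""
    index = {(t, f): k for k, (t, f) in enumerate(zip(track_ids, frames))}
    d = cdist(Z, Z)
    hits = total = 0
    for k, (t, f) in enumerate(zip(track_ids, frames)):
        for g in (f - 1, f + 1):
            j = index.get((t, g))
            if j is None:
                continue
            total += 1
            best = min((d[k, m], m) for m in range(len(Z)) if m != k)[1]
            hits += (best == j)
    return hits / total


class TestConfusion:
    def test_perfect_predictions_identity(self):
        labels = [P.G1, P.S, P.G2M] * 4
        cm = confusion(labels, labels)
        assert np.array_equal(cm.row_normalized, np.eye(3))

    def test_hand_tallied_matrix(self):
        true = [P.G1, P.G1, P.S, P.S, P.G2M, P.G2M]
        pred = [P.G1, P.S, P.S, P.S, P.G1, P.G2M]
        cm = confusion(true, pred)
        expected = np.array([[1, 1, 0], [0, 2, 0], [1, 0, 1]])
        assert np.array_equal(cm.counts, expected)

    def test_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            confusion([P.G1, P.UNLABELED], [P.G1, P.G1])

    def test_published_recalls_average_to_82_percent(self):
        # counts engineered to reproduce the reported per-class recalls
        cm = ConfusionMatrix(counts=np.array([
            [86, 14, 0], [23, 77, 0], [17, 0, 83]], dtype=float))
        recalls = cm.per_class_recall
        assert np.allclose(recalls, [0.86, 0.77, 0.83])
        assert round(macro_accuracy(cm), 2) == 0.82


class TestMacroAccuracy:
    def test_identity_is_one(self):
        cm = confusion([P.G1, P.S, P.G2M], [P.G1, P.S, P.G2M])
        assert macro_accuracy(cm) == 1.0

    def test_balanced_classes_equal_plain_accuracy(self, rng):
        labels = [P.G1, P.S, P.G2M] * 30
        preds = [np.random.default_rng(1).choice([P.G1, P.S, P.G2M])
                 for _ in labels]
        cm = confusion(labels, preds)
        plain = np.mean([p is t for p, t in zip(preds, labels)])
        assert np.isclose(macro_accuracy(cm), plain)

    def test_empty_class_rejected(self):
        cm = confusion([P.G1, P.S], [P.G1, P.S])
        with pytest.raises(ValueError):
            macro_accuracy(cm)


class TestTop1Retrieval:
    def test_two_far_tracks_retrieve_perfectly(self):
        Z = np.array([[0.0], [0.1], [10.0], [10.1]])
        table = EmbeddingTable(Z, ["a", "a", "b", "b"], [0, 1, 0, 1])
        assert top1_retrieval(table) == 1.0

    def test_distractor_between_pair_fails_both_directions(self):
        Z = np.array([[0.0], [1.0], [0.4]])
        table = EmbeddingTable(Z, ["a", "a", "x"], [0, 1, 5])
        assert top1_retrieval(table) == 0.0

    def test_matches_brute_force_on_random_embeddings(self, rng):
        n_tracks, track_len = 20, 6
        Z = rng.normal(size=(n_tracks * track_len, 8))
        tids = [f"t{i}" for i in range(n_tracks) for _ in range(track_len)]
        frames = list(range(track_len)) * n_tracks
        assert top1_retrieval(EmbeddingTable(Z, tids, frames)) == \
            brute_force_top1(Z, tids, frames)

    def test_invariant_under_rigid_motion(self, rng):
        Z = rng.normal(size=(40, 5))
        tids = [f"t{i}" for i in range(10) for _ in range(4)]
        frames = list(range(4)) * 10
        Q = ortho_group.rvs(5, random_state=0)
        moved = Z @ Q + 3.0
        assert top1_retrieval(EmbeddingTable(Z, tids, frames)) == \
            top1_retrieval(EmbeddingTable(moved, tids, frames))

    def test_batched_mode_excludes_other_neighbours(self, rng):
        # a smooth 1-D trajectory: whole-pool retrieval is capped near 1/2
        # because both temporal neighbours compete; batched pools with one
        # pair per track remove the competitor
        Z = np.linspace(0, 1, 12)[:, None] ** 1.3
        tids = ["a"] * 6 + ["b"] * 6
        frames = list(range(6)) * 2
        table = EmbeddingTable(Z, tids, frames)
        assert top1_retrieval(table) <= 0.6
        assert top1_retrieval(table, batch_size=4, seed=0) >= \
            top1_retrieval(table)

    def test_no_pairs_rejected(self):
        table = EmbeddingTable(np.zeros((2, 1)), ["a", "b"], [0, 5])
        with pytest.raises(ValueError):
            top1_retrieval(table)


class TestSsim:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((32, 32))
        assert ssim(x, x.copy(), data_range=1.0) == pytest.approx(1.0)

    def test_inverted_checkerboard_is_negative(self):
        x = np.indices((24, 24)).sum(axis=0) % 2.0
        assert ssim(x, 1.0 - x, data_range=1.0) < 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((64, 64))
        y = np.clip(x + rng.normal(0, 0.2, x.shape), 0, 1)
        ref = structural_similarity(x, y, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False,
                                    data_range=1.0)
        assert abs(ssim(x, y, data_range=1.0) - ref) < 1e-6

    def test_stack_is_mean_of_planes(self, rng):
        x = rng.random((3, 32, 32))
        y = rng.random((3, 32, 32))
        per_plane = [ssim(a, b, data_range=1.0) for a, b in zip(x, y)]
        assert np.isclose(ssim(x, y, data_range=1.0), np.mean(per_plane))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(rng.random((16, 16)), rng.random((16, 17)))


class TestAggregation:
    def test_average_confusion_weights_folds_equally(self):
        big = confusion([P.G1] * 99 + [P.S, P.G2M],
                        [P.G1] * 99 + [P.S, P.G2M])
        small = confusion([P.G1, P.S, P.G2M], [P.S, P.S, P.G2M])
        avg = average_confusion([big, small])
        assert np.isclose(avg[0, 0], (1.0 + 0.0) / 2)


class TestEmbeddingExport:
    def _table(self, rng, n=30):
        return EmbeddingTable(
            embeddings=rng.normal(size=(n, 6)),
            track_ids=[f"t{i // 5}" for i in range(n)],
            frame_indices=[i % 5 for i in range(n)],
            true_labels=[P.G1] * n)

    def test_row_count_and_determinism(self, tmp_path, rng):
        import pandas as pd
        table = self._table(rng)
        a = export_embedding_map(table, str(tmp_path / "a.csv"), method="pca",
                                 seed=1)
        b = export_embedding_map(table, str(tmp_path / "b.csv"), method="pca",
                                 seed=1)
        assert np.array_equal(a, b)
        assert len(pd.read_csv(tmp_path / "a.csv")) == 30

    def test_polyline_lengths_match_track_lengths(self, tmp_path, rng):
        table = self._table(rng)
        export_embedding_map(table, str(tmp_path / "e.csv"), method="pca",
                             polyline_json=str(tmp_path / "lines.json"))
        lines = json.loads((tmp_path / "lines.json").read_text())
        assert all(len(v) == 5 for v in lines.values())
        assert len(lines) == 6

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            export_embedding_map(self._table(rng, n=5), "x.csv", method="pca")
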