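"""Reporter binarization, monotone change-point labeling, exclusions."""

import numpy as np
import pytest

from ccvae.annotation import (AnnotationParams, ReporterSeries,
                              _fit_change_points, annotate_dataset,
                              binarize_presence, label_track)
from ccvae.data_model import CellCyclePhase
from ccvae.synthetic import SyntheticConfig, generate_in_memory

P = CellCyclePhase


def _series(green, red, tid="t"):
    return ReporterSeries(track_id=tid, mean_red=np.array(red, float),
                          mean_green=np.array(green, float))


class TestBinarize:
    def test_clean_step_functions(self):
        s = _series([10, 10, 0, 0, 10], [0, 0, 10, 10, 10])
        g, r = binarize_presence(s, AnnotationParams(smoothing_window=1))
        assert list(g) == [True, True, False, False, True]
        assert list(r) == [False, False, True, True, True]

    def test_all_zero_channel_is_all_false(self):
        s = _series([0, 0, 0, 0], [5, 5, 5, 5])
        g, r = binarize_presence(s, AnnotationParams(smoothing_window=1))
        assert not g.any() and r.all()

    def test_agreement_with_ground_truth_on_noisy_tracks(self):
        config = SyntheticConfig(n_tracks=12, seed=5, reporter_noise_cv=0.1,
                                 reporter_additive_sd=3.0,
                                 truncation_fraction=0.0,
                                 confounder_fraction=0.0)
        manifest, synths = generate_in_memory(config)
        agree = total = 0
        for track, synth in zip(manifest.tracks, synths):
            g, r = binarize_presence(ReporterSeries.from_track(track),
                                     AnnotationParams())
            for gi, ri, st in zip(g, r, synth.states):
                agree += (gi == (st.true_green > 0))
                agree += (ri == (st.true_red > 0))
                total += 2
        assert agree / total >= 0.95


class TestChangePointFit:
    def test_exhaustive_fit_is_optimal_by_enumeration(self, rng):
        phases = [P.G1, P.S, P.G2M, P.UNLABELED]
        for _ in range(25):
            pattern = [phases[i] for i in rng.integers(0, 4, size=12)]
            c1, c2, cost = _fit_change_points(pattern)
            # brute-force re-evaluation of every (c1, c2) labeling
            best = min(
                sum(1 for t, p in enumerate(pattern)
                    if p is not P.UNLABELED and p is not (
                        P.G1 if t < a else P.S if t < b else P.G2M))
                for a in range(13) for b in range(a, 13))
            assert cost == best

    def test_labels_always_monotone(self, rng):
        phases = [P.G1, P.S, P.G2M]
        for _ in range(20):
            pattern = [phases[i] for i in rng.integers(0, 3, size=15)]
            series = _series(
                [10 if p in (P.G1, P.G2M) else 0 for p in pattern],
                [10 if p in (P.S, P.G2M) else 0 for p in pattern])
            ann = label_track(series, AnnotationParams(smoothing_window=1))
            if ann.excluded:
                continue
            seen = [p for i, p in enumerate(ann.labels)
                    if p is not P.UNLABELED
                    and (i == 0 or p is not ann.labels[i - 1])]
            assert seen == [q for q in (P.G1, P.S, P.G2M) if q in seen]


class TestLabelTrack:
    def test_clean_synthetic_change_points_recovered_exactly(self,
                                                             clean_dataset):
        _, manifest, synths = clean_dataset
        for track, synth in zip(manifest.tracks, synths):
            ann = label_track(ReporterSeries.from_track(track))
            assert ann.is_labeled
            assert ann.change_points == synth.change_points
            assert all(l == s.phase for l, s in zip(ann.labels, synth.states))

    def test_single_phase_track_excluded(self):
        s = _series([0] * 10, [10] * 10)
        ann = label_track(s)
        assert ann.excluded == "single_phase"

    def test_short_track_excluded(self):
        s = _series([10, 10, 0], [0, 10, 10])
        assert label_track(s, AnnotationParams(min_track_length=6)) \
            .excluded == "too_short"

    def test_leading_dark_frames_stay_unlabeled(self):
        s = _series([0, 0, 10, 10, 0, 0, 10, 10],
                    [0, 0, 0, 0, 10, 10, 10, 10])
        ann = label_track(s, AnnotationParams(smoothing_window=1))
        assert ann.is_labeled
        assert ann.labels[:2] == [P.UNLABELED, P.UNLABELED]
        assert ann.labels[2:4] == [P.G1, P.G1]

    def test_transition_at_video_end_is_ambiguous(self):
        # S -> G2M flip on the very last frames cannot be confirmed
        s = _series([0] * 10 + [10, 10], [10] * 12)
        ann = label_track(s, AnnotationParams(smoothing_window=3))
        assert ann.excluded == "truncated_ambiguous"

    def test_noise_recovery_degrades_gracefully(self):
        errors = {}
        for cv in (0.0, 0.05, 0.1):
            config = SyntheticConfig(n_tracks=16, seed=21,
                                     reporter_noise_cv=cv,
                                     reporter_additive_sd=60.0 * cv,
                                     truncation_fraction=0.0,
                                     confounder_fraction=0.0)
            manifest, synths = generate_in_memory(config)
            errs = []
            for track, synth in zip(manifest.tracks, synths):
                ann = label_track(ReporterSeries.from_track(track))
                if not ann.is_labeled:
                    continue
                errs.append(abs(ann.change_points[0] - synth.change_points[0]))
                errs.append(abs(ann.change_points[1] - synth.change_points[1]))
            errors[cv] = float(np.median(errs))
        assert errors[0.0] <= 1.0
        assert errors[0.0] <= errors[0.05] + 1e-9 or errors[0.0] <= errors[0.1] + 1e-9


class TestAnnotateDataset:
    def test_clean_dataset_fully_labeled(self, clean_dataset):
        _, manifest, _ = clean_dataset
        manifest, stats = annotate_dataset(manifest)
        assert stats["too_short"] == stats["single_phase"] == 0
        assert all(c.label is not P.UNLABELED for c in manifest.crops())

    def test_exclusion_counts_match_construction(self):
        config = SyntheticConfig(n_tracks=20, seed=2, truncation_fraction=0.2,
                                 confounder_fraction=0.0,
                                 reporter_noise_cv=0.0,
                                 reporter_additive_sd=0.0,
                                 pixel_noise_sd=0.0)
        manifest, synths = generate_in_memory(config)
        constructed = sum(s.truncated for s in synths)
        assert constructed == 4
        _, stats = annotate_dataset(manifest)
        assert stats["single_phase"] == constructed

    def test_idempotent(self, default_dataset):
        _, manifest, _ = default_dataset
        m1, s1 = annotate_dataset(manifest)
        labels1 = [c.label for c in m1.crops()]
        m2, s2 = annotate_dataset(m1)
        assert s1 == s2
        assert labels1 == [c.label for c in m2.crops()]
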