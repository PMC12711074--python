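"""Rule-based cell-cycle phase annotation from PIP-FUCCI intensity series.

The reporter logic: the green reporter (PIP-mVenus) is present in G1 and
G2/M and degraded during S; the red reporter (mCherry-Gem1-110) is present in
S and G2/M and absent in G1. Per-frame presence patterns therefore map to
phases as (green only) -> G1, (red only) -> S, (both) -> G2/M, (neither) ->
unlabeled (typically just-formed early-G1 nuclei). Because reporter
brightness varies strongly between cells, presence is thresholded relative to
each track's own robust maximum (95th percentile) after moving-median
smoothing, and the per-frame pattern is then reconciled into a monotone
G1 -> S -> G2/M sequence by exhaustively choosing the two change points that
minimize disagreement with the pattern.

Tracks that cannot be labeled reliably are excluded with a reason: shorter
than ``min_track_length`` frames; covering fewer than ``min_phases_required``
distinct phases; or ending mid-transition within the smoothing window of the
last frame (truncated at the end of the movie).

This is a deterministic surrogate for what is, in practice, a semi-manual
curation step; it makes no claim of reproducing manual labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import median_filter

from .data_model import CellCyclePhase, DatasetManifest, Track

__all__ = ["ReporterSeries", "AnnotationParams", "TrackAnnotation",
           "binarize_presence", "label_track", "annotate_dataset"]

EXCLUSION_REASONS = ("too_short", "single_phase", "truncated_ambiguous")


@dataclass
class ReporterSeries:
    track_id: str
    mean_red: np.ndarray
    mean_green: np.ndarray

    def __post_init__(self):
        self.mean_red = np.asarray(self.mean_red, dtype=float)
        self.mean_green = np.asarray(self.mean_green, dtype=float)
        if self.mean_red.shape != self.mean_green.shape:
            raise ValueError("red and green series must have equal length")
        if np.any(self.mean_red < 0) or np.any(self.mean_green < 0):
            raise ValueError("reporter means must be nonnegative")

    def __len__(self):
        return self.mean_red.size

    @staticmethod
    def from_track(track: Track) -> "ReporterSeries":
        return ReporterSeries(
            track_id=track.track_id,
            mean_red=np.array([c.mean_red for c in track.crops]),
            mean_green=np.array([c.mean_green for c in track.crops]))


@dataclass
class AnnotationParams:
    presence_threshold: float = 0.3   # fraction of the per-track 95th percentile
    smoothing_window: int = 3         # moving-median width (odd)
    min_track_length: int = 6
    min_phases_required: int = 2

    def __post_init__(self):
        if not 0 < self.presence_threshold < 1:
            raise ValueError("presence_threshold must lie in (0, 1)")
        if self.smoothing_window % 2 != 1:
            raise ValueError("smoothing_window must be odd")


@dataclass
class TrackAnnotation:
    track_id: str
    labels: List[CellCyclePhase] = field(default_factory=list)
    excluded: Optional[str] = None           # one of EXCLUSION_REASONS
    change_points: Optional[Tuple[int, int]] = None  # (G1->S, S->G2M)

    @property
    def is_labeled(self) -> bool:
        return self.excluded is None


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    return median_filter(x, size=window, mode="nearest")


def binarize_presence(series: ReporterSeries,
                      params: AnnotationParams) -> Tuple[np.ndarray, np.ndarray]:
    """Per-frame (green_on, red_on) booleans.

    Each channel is median-smoothed then thresholded at
    ``presence_threshold`` times its per-track 95th percentile; a channel
    that is zero everywhere yields all-false.
    """
    if len(series) == 0:
        raise ValueError("empty reporter series")
    out = []
    for chan in (series.mean_green, series.mean_red):
        sm = _smooth(chan, params.smoothing_window)
        thr = params.presence_threshold * np.percentile(sm, 95)
        out.append(sm > thr)
    return out[0], out[1]


_PATTERN_TO_PHASE = {
    (True, False): CellCyclePhase.G1,
    (False, True): CellCyclePhase.S,
    (True, True): CellCyclePhase.G2M,
    (False, False): CellCyclePhase.UNLABELED,
}


def _fit_change_points(pattern: List[CellCyclePhase]) -> Tuple[int, int, int]:
    """Exhaustive search over (c1, c2): G1 on [0,c1), S on [c1,c2), G2/M on
    [c2,L). Returns (c1, c2, disagreement); unlabeled-pattern frames carry no
    evidence and cost nothing. Ties resolve to the lexicographically smallest
    (c1, c2)."""
    L = len(pattern)
    # prefix counts of evidence against each phase
    not_g1 = np.zeros(L + 1, dtype=int)
    not_s = np.zeros(L + 1, dtype=int)
    not_g2 = np.zeros(L + 1, dtype=int)
    for t, p in enumerate(pattern):
        known = p is not CellCyclePhase.UNLABELED
        not_g1[t + 1] = not_g1[t] + int(known and p is not CellCyclePhase.G1)
        not_s[t + 1] = not_s[t] + int(known and p is not CellCyclePhase.S)
        not_g2[t + 1] = not_g2[t] + int(known and p is not CellCyclePhase.G2M)
    best = None
    for c1 in range(L + 1):
        for c2 in range(c1, L + 1):
            cost = not_g1[c1] + (not_s[c2] - not_s[c1]) + (not_g2[L] - not_g2[c2])
            if best is None or cost < best[2]:
                best = (c1, c2, cost)
    return best


def label_track(series: ReporterSeries,
                params: AnnotationParams = AnnotationParams()) -> TrackAnnotation:
    """Assign per-frame phases to one track, or exclude it with a reason."""
    L = len(series)
    if L < params.min_track_length:
        return TrackAnnotation(track_id=series.track_id, excluded="too_short")
    green_on, red_on = binarize_presence(series, params)
    pattern = [_PATTERN_TO_PHASE[(bool(g), bool(r))]
               for g, r in zip(green_on, red_on)]
    c1, c2, _ = _fit_change_points(pattern)
    labels = [CellCyclePhase.G1 if t < c1 else
              CellCyclePhase.S if t < c2 else CellCyclePhase.G2M
              for t in range(L)]
    # frames before the first reporter evidence stay unlabeled (early G1)
    lead = 0
    while lead < L and pattern[lead] is CellCyclePhase.UNLABELED:
        labels[lead] = CellCyclePhase.UNLABELED
        lead += 1
    distinct = {p for p in labels if p is not CellCyclePhase.UNLABELED}
    if len(distinct) < params.min_phases_required:
        return TrackAnnotation(track_id=series.track_id, excluded="single_phase")
    # a phase transition inside the smoothing window of the last frame cannot
    # be confirmed: the track was truncated by the end of the movie
    last_change = max((c for c in (c1, c2) if 0 < c < L), default=None)
    if last_change is not None and L - last_change < params.smoothing_window:
        return TrackAnnotation(track_id=series.track_id,
                               excluded="truncated_ambiguous")
    return TrackAnnotation(track_id=series.track_id, labels=labels,
                           change_points=(c1, c2))


def annotate_dataset(manifest: DatasetManifest,
                     params: AnnotationParams = AnnotationParams()
                     ) -> Tuple[DatasetManifest, Dict[str, int]]:
    """Label every track of a manifest.

    Returns a new manifest with rule-based labels (excluded tracks become
    UNLABELED on every frame) and the per-reason exclusion counts; the input
    manifest is left untouched (images are shared, not copied). The
    operation is deterministic and idempotent.
    """
    import dataclasses

    stats = {reason: 0 for reason in EXCLUSION_REASONS}
    stats["labeled_tracks"] = 0
    new_tracks = []
    for track in manifest.tracks:
        series = ReporterSeries.from_track(track)
        if len(series) != len(track):
            raise ValueError(f"track {track.track_id}: series length mismatch")
        ann = label_track(series, params)
        if ann.excluded is not None:
            stats[ann.excluded] += 1
            labels = [CellCyclePhase.UNLABELED] * len(track)
        else:
            stats["labeled_tracks"] += 1
            labels = ann.labels
        new_tracks.append(Track(
            track_id=track.track_id,
            crops=[dataclasses.replace(crop, label=lab)
                   for crop, lab in zip(track.crops, labels)]))
    out = DatasetManifest(tracks=new_tracks, calibration=manifest.calibration,
                          split_assignment=manifest.split_assignment,
                          root_dir=manifest.root_dir)
    return out, stats
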