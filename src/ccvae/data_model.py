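"""Core domain types, physical calibration, manifest I/O and validation, and
group-aware cross-validation splitting.

A dataset is a collection of tracked single-nucleus crops. Each crop is one
nucleus at one time point: a z-stack of the DNA-marker channel plus the mean
red/green PIP-FUCCI reporter intensities over the nucleus area, physical
measurements (area, total DNA-marker intensity), track/frame/field-of-view
bookkeeping, and an optional cell-cycle phase label. Tracks are strictly
contiguous in time: frame-to-frame linking without gap closing, merging or
splitting, so frame indices increase by exactly one.

Cross-validation folds are grouped by field of view (FOV): nuclei imaged in
the same FOV share illumination and focus conditions and must never be split
across train and held-out sets.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Calibration", "CellCyclePhase", "NucleusCrop", "Track", "DatasetManifest",
    "ValidationReport", "FoldSplit", "SplitResult",
    "px_to_um", "validate_manifest", "group_kfold",
    "read_manifest", "write_manifest", "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["crop_path", "track_id", "frame_index", "fov_id",
                    "mean_red", "mean_green", "area_um2",
                    "total_dna_intensity", "label", "fold"]


@dataclass(frozen=True)
class Calibration:
    """Physical acquisition parameters.

    Defaults correspond to a 63x objective acquiring 5 focal planes spaced
    1 um apart every 20 minutes, with 0.102 um pixels.
    """

    pixel_size_um: float = 0.102
    n_planes: int = 5
    plane_spacing_um: float = 1.0
    frame_interval_min: float = 20.0

    def __post_init__(self):
        for name in ("pixel_size_um", "n_planes", "plane_spacing_um",
                     "frame_interval_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"Calibration.{name} must be strictly positive")


class CellCyclePhase(enum.Enum):
    """The three scored interphase/mitosis classes; G2 and M are merged."""

    G1 = "G1"
    S = "S"
    G2M = "G2M"
    UNLABELED = "UNLABELED"

    def __str__(self):
        return self.value


PHASE_ORDER = (CellCyclePhase.G1, CellCyclePhase.S, CellCyclePhase.G2M)


@dataclass
class NucleusCrop:
    """One nucleus at one time point."""

    track_id: str
    frame_index: int
    fov_id: str
    mean_red: float
    mean_green: float
    area_um2: float
    total_dna_intensity: float
    label: CellCyclePhase = CellCyclePhase.UNLABELED
    image: Optional[np.ndarray] = None  # (planes, H, W), normalized DNA signal
    crop_path: str = ""

    @property
    def crop_id(self) -> str:
        return self.crop_path or f"{self.track_id}:{self.frame_index}"


@dataclass
class Track:
    """Time-ordered crops of one nucleus; frame indices contiguous."""

    track_id: str
    crops: List[NucleusCrop] = field(default_factory=list)

    def __len__(self):
        return len(self.crops)

    @property
    def fov_id(self) -> str:
        return self.crops[0].fov_id if self.crops else ""


@dataclass
class DatasetManifest:
    tracks: List[Track]
    calibration: Calibration = field(default_factory=Calibration)
    split_assignment: Optional[Dict[str, int]] = None
    root_dir: str = ""

    def crops(self):
        for track in self.tracks:
            yield from track.crops

    @property
    def n_crops(self) -> int:
        return sum(len(t) for t in self.tracks)

    def fov_ids(self) -> List[str]:
        return sorted({t.fov_id for t in self.tracks})


@dataclass
class ValidationReport:
    class_counts: Dict[str, int]
    labeled_total: int
    grand_total: int
    n_tracks: int
    violations: List[str]

    @property
    def is_valid(self) -> bool:
        return not self.violations


@dataclass
class FoldSplit:
    fold: int
    train: List[str]
    val: List[str]
    test: List[str]


@dataclass
class SplitResult:
    assignment: Dict[str, int]  # fov_id -> fold holding it out
    folds: List[FoldSplit]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def px_to_um(pixels: float, cal: Calibration) -> float:
    """Convert a length in pixels to micrometres."""
    arr = np.asarray(pixels, dtype=float)
    if np.any(arr < 0):
        raise ValueError("pixel length must be nonnegative")
    out = arr * cal.pixel_size_um
    return float(out) if np.isscalar(pixels) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# manifest validation
# ---------------------------------------------------------------------------

def validate_manifest(manifest: DatasetManifest) -> ValidationReport:
    """Check every structural invariant and tally per-class crop counts."""
    violations: List[str] = []
    counts = {p.value: 0 for p in CellCyclePhase}
    seen_track_ids: Dict[str, int] = {}
    for track in manifest.tracks:
        seen_track_ids[track.track_id] = seen_track_ids.get(track.track_id, 0) + 1
        if not track.crops:
            violations.append(f"track {track.track_id}: empty")
            continue
        fov = track.crops[0].fov_id
        prev = None
        for crop in track.crops:
            counts[crop.label.value] += 1
            if crop.track_id != track.track_id:
                violations.append(
                    f"track {track.track_id} frame {crop.frame_index}: "
                    f"crop track_id {crop.track_id} differs")
            if crop.fov_id != fov:
                violations.append(
                    f"track {track.track_id} frame {crop.frame_index}: "
                    f"fov changes within track")
            if crop.frame_index < 0:
                violations.append(
                    f"track {track.track_id}: negative frame_index")
            if prev is not None and crop.frame_index != prev + 1:
                violations.append(
                    f"track {track.track_id}: gap {prev}->{crop.frame_index}")
            prev = crop.frame_index
            if not crop.area_um2 > 0:
                violations.append(
                    f"track {track.track_id} frame {crop.frame_index}: "
                    f"area_um2 not positive")
            if crop.mean_red < 0 or crop.mean_green < 0:
                violations.append(
                    f"track {track.track_id} frame {crop.frame_index}: "
                    f"negative reporter mean")
            if crop.image is not None:
                if crop.image.shape[0] != manifest.calibration.n_planes:
                    violations.append(
                        f"track {track.track_id} frame {crop.frame_index}: "
                        f"{crop.image.shape[0]} planes, expected "
                        f"{manifest.calibration.n_planes}")
                if not np.all(np.isfinite(crop.image)):
                    violations.append(
                        f"track {track.track_id} frame {crop.frame_index}: "
                        f"non-finite image values")
    for tid, n in seen_track_ids.items():
        if n > 1:
            violations.append(f"track id {tid} appears {n} times")
    if manifest.split_assignment is not None:
        fovs = {t.fov_id for t in manifest.tracks}
        for fov in sorted(fovs):
            if fov not in manifest.split_assignment:
                violations.append(f"fov {fov}: missing fold assignment")
    labeled = sum(counts[p.value] for p in PHASE_ORDER)
    grand = labeled + counts[CellCyclePhase.UNLABELED.value]
    return ValidationReport(class_counts=counts, labeled_total=labeled,
                            grand_total=grand, n_tracks=len(manifest.tracks),
                            violations=violations)


# ---------------------------------------------------------------------------
# group-aware k-fold splitting
# ---------------------------------------------------------------------------

def group_kfold(manifest: DatasetManifest, k: int, seed: int,
                merged_val_test: bool = False) -> SplitResult:
    """Partition FOVs into ``k`` folds of near-equal crop count.

    Fold ``f`` holds out FOV group ``f``; the remaining groups train. With
    ``merged_val_test=True`` the held-out crops serve as both validation and
    test set (the protocol the original study used); by default the held-out
    FOVs are split into disjoint validation and test halves so early
    stopping never sees the test crops.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    fov_counts: Dict[str, int] = {}
    fov_crops: Dict[str, List[str]] = {}
    fov_tracks: Dict[str, List[Track]] = {}
    for track in manifest.tracks:
        fov_counts[track.fov_id] = fov_counts.get(track.fov_id, 0) + len(track)
        fov_crops.setdefault(track.fov_id, []).extend(
            c.crop_id for c in track.crops)
        fov_tracks.setdefault(track.fov_id, []).append(track)
    fovs = sorted(fov_counts)
    if len(fovs) < k:
        raise ValueError(f"{len(fovs)} fovs < k={k}")
    rng = np.random.default_rng(seed)
    order = [fovs[i] for i in rng.permutation(len(fovs))]
    # largest-first greedy balancing; ties resolved by sorted fov_id for
    # determinism beyond the seeded shuffle
    order.sort(key=lambda f: (-fov_counts[f], f))
    fold_load = [0] * k
    assignment: Dict[str, int] = {}
    for fov in order:
        f = int(np.argmin(fold_load))
        assignment[fov] = f
        fold_load[f] += fov_counts[fov]

    folds: List[FoldSplit] = []
    for f in range(k):
        held = sorted(fv for fv in fovs if assignment[fv] == f)
        train = [cid for fv in fovs if assignment[fv] != f
                 for cid in fov_crops[fv]]
        held_crops = [cid for fv in held for cid in fov_crops[fv]]
        if merged_val_test:
            folds.append(FoldSplit(fold=f, train=train, val=list(held_crops),
                                   test=list(held_crops)))
            continue
        if len(held) >= 2:
            # split held-out fovs into two near-equal halves by crop count
            val_f, test_f, val_n, test_n = [], [], 0, 0
            for fv in sorted(held, key=lambda x: (-fov_counts[x], x)):
                if val_n <= test_n:
                    val_f.append(fv)
                    val_n += fov_counts[fv]
                else:
                    test_f.append(fv)
                    test_n += fov_counts[fv]
            val = [cid for fv in val_f for cid in fov_crops[fv]]
            test = [cid for fv in test_f for cid in fov_crops[fv]]
        else:
            # a single held-out fov cannot be split by fov; fall back to
            # splitting its tracks (still no crop-level leakage)
            tracks = sorted(fov_tracks[held[0]], key=lambda t: t.track_id)
            val_t, test_t, val_n, test_n = [], [], 0, 0
            for t in sorted(tracks, key=lambda t: (-len(t), t.track_id)):
                if val_n <= test_n:
                    val_t.append(t)
                    val_n += len(t)
                else:
                    test_t.append(t)
                    test_n += len(t)
            val = [c.crop_id for t in val_t for c in t.crops]
            test = [c.crop_id for t in test_t for c in t.crops]
        folds.append(FoldSplit(fold=f, train=train, val=val, test=test))
    return SplitResult(assignment=assignment, folds=folds)


# ---------------------------------------------------------------------------
# manifest CSV I/O
# ---------------------------------------------------------------------------

def write_manifest(manifest: DatasetManifest, csv_path: str) -> None:
    rows = []
    for track in manifest.tracks:
        for crop in track.crops:
            fold = ""
            if manifest.split_assignment:
                fold = manifest.split_assignment.get(crop.fov_id, "")
            rows.append({
                "crop_path": crop.crop_path,
                "track_id": crop.track_id,
                "frame_index": crop.frame_index,
                "fov_id": crop.fov_id,
                "mean_red": f"{crop.mean_red:.6g}",
                "mean_green": f"{crop.mean_green:.6g}",
                "area_um2": f"{crop.area_um2:.6g}",
                "total_dna_intensity": f"{crop.total_dna_intensity:.6g}",
                "label": crop.label.value,
                "fold": fold,
            })
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(csv_path, index=False)


def read_manifest(csv_path: str, calibration: Optional[Calibration] = None,
                  load_images: bool = False) -> DatasetManifest:
    """Read a manifest CSV (and optionally its TIFF stacks) from disk."""
    try:
        df = pd.read_csv(csv_path, dtype={"track_id": str, "fov_id": str,
                                          "label": str, "fold": str},
                         keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read manifest {csv_path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise IOError(f"manifest {csv_path} is missing columns {missing}")
    root = os.path.dirname(os.path.abspath(csv_path))
    cal = calibration or Calibration()
    tracks: Dict[str, Track] = {}
    split: Dict[str, int] = {}
    have_folds = True
    for row in df.itertuples(index=False):
        image = None
        if load_images:
            import tifffile
            path = os.path.join(root, row.crop_path)
            try:
                image = tifffile.imread(path).astype(np.float64)
            except (OSError, ValueError) as exc:
                raise IOError(f"cannot read crop {path}: {exc}") from exc
        crop = NucleusCrop(
            track_id=str(row.track_id),
            frame_index=int(row.frame_index),
            fov_id=str(row.fov_id),
            mean_red=float(row.mean_red),
            mean_green=float(row.mean_green),
            area_um2=float(row.area_um2),
            total_dna_intensity=float(row.total_dna_intensity),
            label=CellCyclePhase(row.label),
            image=image,
            crop_path=str(row.crop_path),
        )
        tracks.setdefault(crop.track_id, Track(track_id=crop.track_id)) \
            .crops.append(crop)
        if str(row.fold) != "":
            split[crop.fov_id] = int(row.fold)
        else:
            have_folds = False
    for track in tracks.values():
        track.crops.sort(key=lambda c: c.frame_index)
    return DatasetManifest(tracks=list(tracks.values()), calibration=cal,
                           split_assignment=split if (split and have_folds) else None,
                           root_dir=root)
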