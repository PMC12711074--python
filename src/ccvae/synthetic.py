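"""Synthetic tracked-nucleus generator.

Emulates the statistical structure the method assumes about DNA-marker
time-lapse data:

* nuclei grow through the cycle (radius increases monotonically);
* total DNA-marker intensity is proportional to chromatin content, which is
  constant at 1 genome equivalent in G1, ramps linearly to ``dna_doubling``
  (default 2, replication) across S, and stays doubled in G2/M;
* the green reporter is present in G1 and G2/M and absent in S, the red
  reporter is present in S and G2/M and absent in G1, with a per-cell
  multiplicative brightness factor (lognormal) and per-frame additive noise;
* chromatin texture changes with cycle position (fine punctate replication
  foci in S, coarser higher-contrast condensation toward G2/M), which is the
  image cue that survives when size and intensity are confounded;
* a deterministic fraction of tracks is confounded: either S-phase frames
  rendered with enlarged radii, or early-S frames held at a G1-like radius,
  so that classifiers using only area and total intensity carry an
  irreducible error on these tracks;
* a fraction of tracks is truncated to a window inside a single phase,
  emulating tracks that start or end mid-movie.

All constants here are generator defaults of this package, not measured
values; the DNA-content doubling encodes the replication biology.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .data_model import (Calibration, CellCyclePhase, DatasetManifest,
                         NucleusCrop, Track, write_manifest)

__all__ = ["SyntheticConfig", "GroundTruthState", "SyntheticTrack",
           "sample_track", "render_crop", "realize_track",
           "generate_dataset", "generate_in_memory"]


@dataclass
class SyntheticConfig:
    n_tracks: int = 64
    image_size: int = 32
    cycle_length_mean: float = 24.0
    cycle_length_sd: float = 3.0
    phase_fractions: Tuple[float, float, float] = (0.40, 0.35, 0.25)
    base_radius_px: float = 6.0
    growth_factor: float = 1.3      # radius multiplier across one full cycle
    dna_doubling: float = 2.0       # chromatin content gain across S
    reporter_noise_cv: float = 0.1  # per-cell lognormal brightness CV
    reporter_additive_sd: float = 3.0   # per-frame camera noise (reporter units)
    pixel_noise_sd: float = 0.02
    confounder_fraction: float = 0.2
    truncation_fraction: float = 0.1
    n_fovs: int = 10
    seed: int = 0
    # secondary constants
    pixel_size_um: float = 0.8      # desk-scale sampling: radius ~5 um
    dna_brightness_cv: float = 0.25  # per-cell DNA-marker brightness CV
    defocus_sigma: float = 0.6      # added blur per plane index
    base_blur: float = 0.3          # optical blur of the sharpest plane
    green_level: float = 100.0      # reporter mean when "on"
    red_level: float = 120.0
    base_dna_level: float = 0.35    # in-mask intensity at 1 genome equivalent
    texture_rho: float = 0.7        # frame-to-frame texture correlation

    def __post_init__(self):
        fr = self.phase_fractions
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("phase_fractions must sum to 1")
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("phase_fractions must lie in [0, 1]")
        for name in ("confounder_fraction", "truncation_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_tracks", "image_size", "cycle_length_mean",
                     "base_radius_px", "growth_factor", "dna_doubling",
                     "n_fovs", "pixel_size_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruthState:
    """Noiseless per-frame state of a synthetic nucleus."""

    phase: CellCyclePhase
    cycle_position: float      # in [0, 1)
    radius_px: float
    dna_content: float         # genome equivalents in [1, dna_doubling]
    true_green: float          # noiseless reporter mean (incl. per-cell gain)
    true_red: float
    frame: int                 # frame index within the (possibly truncated) track
    texture_seed: int
    orientation: float
    eccentricity: float
    dna_brightness: float      # per-cell DNA-marker gain


@dataclass
class SyntheticTrack:
    track_id: str
    fov_id: str
    states: List[GroundTruthState]
    confounder: Optional[str]          # None | "large_s" | "small_early_s"
    truncated: bool
    change_points: Tuple[int, int]     # (G1->S, S->G2M) in pre-truncation frames
    offset: int                        # frames removed from the front by truncation


def _phase_lengths(L: int, fractions) -> Tuple[int, int, int]:
    n_g1 = max(1, round(fractions[0] * L))
    n_s = max(1, round(fractions[1] * L))
    n_g2 = max(1, L - n_g1 - n_s)
    return n_g1, n_s, n_g2


def sample_track(config: SyntheticConfig, rng: np.random.Generator,
                 track_id: str = "t0", fov_id: str = "fov0",
                 confounder: Optional[str] = None,
                 truncate: bool = False) -> SyntheticTrack:
    """Draw the ground-truth state sequence of one nucleus track.

    The full phase sequence is a contiguous G1 -> S -> G2/M run; with
    ``truncate`` the track is cut to a window inside a single phase.
    """
    L = max(9, int(round(rng.normal(config.cycle_length_mean,
                                    config.cycle_length_sd))))
    n_g1, n_s, n_g2 = _phase_lengths(L, config.phase_fractions)
    L = n_g1 + n_s + n_g2
    green_gain = float(np.exp(rng.normal(0.0, config.reporter_noise_cv)))
    red_gain = float(np.exp(rng.normal(0.0, config.reporter_noise_cv)))
    dna_gain = float(np.exp(rng.normal(0.0, config.dna_brightness_cv)))
    orientation = float(rng.uniform(0, np.pi))
    eccentricity = float(rng.uniform(0.85, 1.0))
    texture_seed = int(rng.integers(0, 2 ** 31 - 1))

    states: List[GroundTruthState] = []
    radius_floor = 0.0
    for t in range(L):
        pos = (t + 0.5) / L
        if t < n_g1:
            phase = CellCyclePhase.G1
            dna = 1.0
        elif t < n_g1 + n_s:
            phase = CellCyclePhase.S
            dna = 1.0 + (config.dna_doubling - 1.0) * (t - n_g1 + 1) / n_s
        else:
            phase = CellCyclePhase.G2M
            dna = config.dna_doubling
        radius = config.base_radius_px * config.growth_factor ** pos
        if confounder == "large_s" and phase is not CellCyclePhase.G1:
            radius *= 1.35
        if confounder == "small_early_s" and phase is CellCyclePhase.S \
                and (t - n_g1) < n_s / 2:
            radius = config.base_radius_px * config.growth_factor ** (n_g1 / L)
        radius = max(radius, radius_floor)  # keep growth monotone
        radius_floor = radius
        green = green_gain * config.green_level \
            if phase is not CellCyclePhase.S else 0.0
        red = red_gain * config.red_level \
            if phase is not CellCyclePhase.G1 else 0.0
        states.append(GroundTruthState(
            phase=phase, cycle_position=pos, radius_px=radius,
            dna_content=dna, true_green=green, true_red=red, frame=t,
            texture_seed=texture_seed, orientation=orientation,
            eccentricity=eccentricity, dna_brightness=dna_gain))

    offset = 0
    if truncate:
        # cut to a window inside a single phase (>= 6 frames when possible)
        spans = [(0, n_g1), (n_g1, n_g1 + n_s), (n_g1 + n_s, L)]
        start, stop = spans[int(np.argmax([b - a for a, b in spans]))]
        states = states[start:stop]
        offset = start
        for i, st in enumerate(states):
            st.frame = i
    return SyntheticTrack(track_id=track_id, fov_id=fov_id, states=states,
                          confounder=confounder, truncated=truncate,
                          change_points=(n_g1, n_g1 + n_s), offset=offset)


def _texture_params(config: SyntheticConfig, pos: float) -> Tuple[float, float]:
    """Texture correlation length and contrast as a function of cycle position."""
    f1, f2, _ = config.phase_fractions
    mids = [0.0, f1 / 2, f1 + f2 / 2, f1 + f2 + (1 - f1 - f2) / 2, 1.0]
    # decondensed (smooth, low contrast) in G1; fine punctate replication
    # foci in S; coarse high-contrast condensing chromatin toward G2/M
    sigma = float(np.interp(pos, mids, [2.4, 2.4, 0.6, 1.3, 1.3]))
    contrast = float(np.interp(pos, mids, [0.12, 0.12, 0.30, 0.42, 0.45]))
    return sigma, contrast


def _nucleus_mask(size: int, state: GroundTruthState) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    co, si = np.cos(state.orientation), np.sin(state.orientation)
    u = (xx - cx) * co + (yy - cy) * si
    v = -(xx - cx) * si + (yy - cy) * co
    a = state.radius_px
    b = state.radius_px * state.eccentricity
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_crop(state: GroundTruthState, config: SyntheticConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Render the 5-plane DNA-marker stack for one ground-truth state.

    Pixel intensity inside the nuclear ellipse is proportional to DNA content
    modulated by a band-limited chromatin texture; the planes are
    progressively defocused copies (plane 0 sharpest); additive Gaussian
    pixel noise is drawn from ``rng``.
    """
    size = config.image_size
    if state.radius_px + 3 > size / 2:
        raise ValueError(f"radius {state.radius_px:.1f} px does not fit in a "
                         f"{size} px image")
    mask = _nucleus_mask(size, state)
    sig_tex, contrast = _texture_params(config, state.cycle_position)
    base = np.random.default_rng(state.texture_seed).standard_normal((size, size))
    innov = np.random.default_rng(
        state.texture_seed + 1000003 * (state.frame + 1)) \
        .standard_normal((size, size))
    rho = config.texture_rho
    raw = np.sqrt(rho) * base + np.sqrt(1.0 - rho) * innov
    tex = gaussian_filter(raw, sig_tex, mode="wrap")
    tex = tex / max(tex.std(), 1e-12)
    # +/- 2 sd keeps intensities positive at the highest contrast, so the
    # zero clip below never biases in-mask means
    tex = np.clip(tex, -2.0, 2.0)
    # center within the mask: the in-mask mean then tracks DNA content
    # exactly instead of fluctuating with the texture realization
    tex = tex - tex[mask].mean()
    level = config.base_dna_level * state.dna_brightness * state.dna_content
    plane0 = mask * level * (1.0 + contrast * tex)
    cal = Calibration(pixel_size_um=config.pixel_size_um)
    planes = np.empty((cal.n_planes, size, size))
    for k in range(cal.n_planes):
        blurred = gaussian_filter(plane0, config.base_blur
                                  + config.defocus_sigma * k)
        planes[k] = blurred + rng.normal(0.0, config.pixel_noise_sd,
                                         (size, size))
    return np.clip(planes, 0.0, None)


def realize_track(synth: SyntheticTrack, config: SyntheticConfig,
                  rng: np.random.Generator) -> Track:
    """Render images and assemble the observable :class:`Track`."""
    track = Track(track_id=synth.track_id)
    px_area = config.pixel_size_um ** 2
    for state in synth.states:
        image = render_crop(state, config, rng)
        mask = _nucleus_mask(config.image_size, state)
        green = max(0.0, state.true_green
                    + rng.normal(0.0, config.reporter_additive_sd))
        red = max(0.0, state.true_red
                  + rng.normal(0.0, config.reporter_additive_sd))
        track.crops.append(NucleusCrop(
            track_id=synth.track_id,
            frame_index=state.frame,
            fov_id=synth.fov_id,
            mean_red=red,
            mean_green=green,
            area_um2=float(mask.sum()) * px_area,
            total_dna_intensity=float(image[0][mask].sum()),
            label=state.phase,
            image=image,
        ))
    return track


def _plan_tracks(config: SyntheticConfig):
    """Deterministic assignment of confounder/truncation roles to tracks."""
    n = config.n_tracks
    n_conf = int(round(config.confounder_fraction * n))
    n_trunc = int(round(config.truncation_fraction * n))
    roles = []
    for i in range(n):
        conf = None
        if i < n_conf:
            conf = "large_s" if i % 2 == 0 else "small_early_s"
        trunc = i >= n - n_trunc and conf is None
        roles.append((conf, trunc))
    return roles


def generate_in_memory(config: SyntheticConfig) -> Tuple[DatasetManifest,
                                                         List[SyntheticTrack]]:
    """Generate the full dataset with images held in memory."""
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(config.n_tracks)
    roles = _plan_tracks(config)
    tracks: List[Track] = []
    synths: List[SyntheticTrack] = []
    for i, (child, (conf, trunc)) in enumerate(zip(children, roles)):
        rng = np.random.default_rng(child)
        synth = sample_track(config, rng, track_id=f"track{i:04d}",
                             fov_id=f"fov{i % config.n_fovs:03d}",
                             confounder=conf, truncate=trunc)
        synths.append(synth)
        tracks.append(realize_track(synth, config, rng))
    cal = Calibration(pixel_size_um=config.pixel_size_um)
    return DatasetManifest(tracks=tracks, calibration=cal), synths


def generate_dataset(config: SyntheticConfig, out_dir: str) -> DatasetManifest:
    """Generate the dataset on disk: one multi-page TIFF per crop, a manifest
    CSV, and the resolved config as YAML."""
    import tifffile
    import yaml

    manifest, _ = generate_in_memory(config)
    os.makedirs(out_dir, exist_ok=True)
    for track in manifest.tracks:
        fov_dir = os.path.join(out_dir, track.fov_id)
        os.makedirs(fov_dir, exist_ok=True)
        for crop in track.crops:
            rel = os.path.join(track.fov_id,
                               f"{track.track_id}_f{crop.frame_index:03d}.tif")
            try:
                tifffile.imwrite(os.path.join(out_dir, rel),
                                 crop.image.astype(np.float32))
            except OSError as exc:
                raise IOError(f"cannot write {rel}: {exc}") from exc
            crop.crop_path = rel
    write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    cfg = asdict(config)
    cfg["phase_fractions"] = list(config.phase_fractions)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    manifest.root_dir = out_dir
    return manifest
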