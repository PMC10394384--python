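"""Synthetic phantom cohorts: labeled atlases, score-linked volumes, factor tables.

The clinical cohort behind the study design (116 depressed older adults with
standardized five-factor symptom scores) is not publicly deposited, so this
module generates a stand-in with the same statistical shape:

* an integer-labeled phantom atlas of non-overlapping ellipsoidal ROIs,
  organized into testing-set groups;
* a subject table of five standardized, mutually orthogonal factor scores
  (emulating varimax-rotated PCA scores: mean 0, SD 1, pairwise sample
  correlation ~ 0);
* per-subject intensity volumes: a smooth radial brain-like baseline plus
  Gaussian voxel noise, where designated ROIs carry a linear signal — voxel
  intensity shifted by ``effect_size * score`` (``intensity_shift`` mode) or
  local noise scaled by ``exp(effect_size * score)`` (``texture_scale``) —
  so a convolutional regressor can recover which regions are informative.

Everything is a deterministic function of (config, seed); per-subject seeds
are spawned from the master seed and recorded in the manifest.

The defaults mirror the study conditions (N = 116 subjects, 182 x 218 x 182
voxel grid, 34 ROIs in 10 groups); ``desk_preset`` gives a small profile
(40 subjects, 64-cubes, 6 ROIs) for CPU-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import AtlasLabelMap, ROISpec

__all__ = [
    "EffectSpec",
    "CohortConfig",
    "desk_preset",
    "generate_atlas",
    "generate_factor_scores",
    "render_subject_volume",
    "generate_cohort",
    "FACTOR_NAMES",
]

FACTOR_NAMES = ("Anhedonia", "Suicidality", "Appetite", "SleepDisturbance", "Anxiety")


class PlacementError(RuntimeError):
    """Raised when non-overlapping ROI placement fails within the attempt budget."""


@dataclass(frozen=True)
class EffectSpec:
    """A ground-truth association between one ROI and one factor.

    ``effect_size`` is in intensity units per score standard deviation
    (``intensity_shift``) or log-SD units per score SD (``texture_scale``).
    """

    roi_abbreviation: str
    factor_name: str
    effect_size: float
    mode: str = "intensity_shift"

    def __post_init__(self) -> None:
        if self.mode not in ("intensity_shift", "texture_scale"):
            raise ValueError(f"unknown effect mode {self.mode!r}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")


@dataclass(frozen=True)
class CohortConfig:
    """Phantom-cohort geometry and signal settings.

    Defaults mirror the study conditions: 116 subjects on a
    182 x 218 x 182 voxel grid with 34 ROIs in 10 testing sets.  Noise SD
    and baseline amplitude are in arbitrary intensity units; the baseline
    radial gradient spans ``baseline_amplitude`` units from center to edge
    so patches contain non-degenerate structure.
    """

    n_subjects: int = 116
    volume_shape: tuple[int, int, int] = (182, 218, 182)
    n_rois: int = 34
    n_groups: int = 10
    roi_radius_range: tuple[float, float] = (8.0, 16.0)
    noise_sd: float = 1.0
    baseline_amplitude: float = 10.0
    effects: tuple[EffectSpec, ...] = ()
    seed: int | None = None
    max_placement_attempts: int = 500

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_rois < 1 or self.n_groups < 1 or self.n_groups > self.n_rois:
            raise ValueError("need 1 <= n_groups <= n_rois")
        lo, hi = self.roi_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid roi_radius_range")
        if hi * 2 >= min(self.volume_shape):
            raise ValueError("ROIs do not fit inside the volume")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def desk_preset(effect_size: float = 2.0, noise_sd: float = 1.0,
                seed: int | None = None,
                signal_roi: str = "R01", signal_factor: str = "Anxiety",
                n_subjects: int = 40) -> CohortConfig:
    """Small-profile cohort for CPU runs: 40 subjects, 64-cube volumes,
    6 ellipsoidal ROIs in 6 groups, one intensity effect on one ROI.

    The default effect-to-noise ratio is 2 (a clearly recoverable signal);
    pass ``effect_size=0`` for a null cohort.
    """
    effects = ()
    if effect_size != 0.0:
        effects = (EffectSpec(signal_roi, signal_factor, effect_size),)
    return CohortConfig(
        n_subjects=n_subjects,
        volume_shape=(64, 64, 64),
        n_rois=6,
        n_groups=6,
        roi_radius_range=(5.0, 8.0),
        noise_sd=noise_sd,
        baseline_amplitude=10.0,
        effects=effects,
        seed=seed,
    )


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    lo = [max(0, int(np.floor(c - r))) for c, r in zip(center, radii)]
    hi = [min(s, int(np.ceil(c + r)) + 1) for s, c, r in zip(shape, center, radii)]
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    box = d <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = box
    return mask


def generate_atlas(config: CohortConfig,
                   rng: np.random.Generator | None = None) -> AtlasLabelMap:
    """Place ``n_rois`` non-overlapping ellipsoidal label regions.

    Labels are 1..n_rois; abbreviations R01..; hemispheres alternate
    left/right; groups are contiguous near-equal chunks named set01..,
    partitioning the ROI list.  Deterministic per seed.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        config.seed if rng is None else rng)
    shape = config.volume_shape
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    lo_r, hi_r = config.roi_radius_range

    group_chunks = np.array_split(np.arange(config.n_rois), config.n_groups)
    roi_group = {}
    for g, chunk in enumerate(group_chunks):
        for i in chunk:
            roi_group[int(i)] = f"set{g + 1:02d}"

    rois: list[ROISpec] = []
    for i in range(config.n_rois):
        placed = False
        for _ in range(config.max_placement_attempts):
            radii = rng.uniform(lo_r, hi_r, size=3)
            margin = radii + 1
            center = np.array([
                rng.uniform(m, s - m) for m, s in zip(margin, shape)
            ])
            mask = _ellipsoid_mask(shape, center, radii)
            if not mask.any() or (mask & occupied).any():
                continue
            labels[mask] = i + 1
            occupied |= mask
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place ROI {i + 1} of {config.n_rois} without overlap "
                f"after {config.max_placement_attempts} attempts"
            )
        rois.append(ROISpec(
            abbreviation=f"R{i + 1:02d}",
            name=f"synthetic ellipsoid region {i + 1}",
            hemisphere="left" if i % 2 == 0 else "right",
            atlas_labels=frozenset({i + 1}),
            group=roi_group[i],
        ))
    return AtlasLabelMap(labels=labels, voxel_size=(1.0, 1.0, 1.0), roi_table=rois)


def generate_factor_scores(n_subjects: int,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Five standardized, mutually orthogonal factor-score columns.

    Gaussian draws are column-centered, orthogonalized (QR), and rescaled to
    unit sample SD, emulating varimax-rotated PCA scores: each column has
    mean 0 and SD 1 and pairwise sample correlations are zero to floating
    point.  With fewer than 7 subjects the rank is insufficient for five
    orthogonal directions and the columns are only standardized.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    raw = rng.standard_normal((n_subjects, len(FACTOR_NAMES)))
    centered = raw - raw.mean(axis=0)
    if n_subjects >= len(FACTOR_NAMES) + 2:
        q, r = np.linalg.qr(centered)
        q = q * np.sign(np.diag(r))  # fix reflection ambiguity
        scores = q
    else:
        scores = centered
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    index = pd.Index([f"S{i + 1:03d}" for i in range(n_subjects)], name="subject_id")
    return pd.DataFrame(scores, index=index, columns=list(FACTOR_NAMES))


def render_subject_volume(atlas: AtlasLabelMap, scores_row: pd.Series,
                          config: CohortConfig,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """One subject's intensity volume: baseline + ROI signal + Gaussian noise.

    The baseline is a smooth radial gradient (bright center, dark edge).
    Each effect either shifts its ROI's voxels by ``effect_size * score``
    or rescales the local noise SD by ``exp(effect_size * score)``.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    shape = atlas.shape
    grids = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    center = [(s - 1) / 2 for s in shape]
    r2 = sum(((g - c) / (s / 2)) ** 2 for g, c, s in zip(grids, center, shape))
    vol = (config.baseline_amplitude * np.clip(1.0 - np.sqrt(r2), 0.0, 1.0)
           ).astype(np.float32)

    noise = rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)
    for effect in config.effects:
        roi = atlas[effect.roi_abbreviation]
        mask = np.isin(atlas.labels, sorted(roi.atlas_labels))
        score = float(scores_row[effect.factor_name])
        if effect.mode == "intensity_shift":
            vol[mask] += effect.effect_size * score
        else:  # texture_scale
            noise[mask] *= np.float32(np.exp(effect.effect_size * score))
    return vol + noise


def generate_cohort(config: CohortConfig, out_dir=None):
    """Full phantom cohort: atlas, per-subject volumes, scores, manifest.

    Returns ``(atlas, volumes, scores, manifest)``.  With ``out_dir`` set,
    volumes are written as NIfTI (``volumes`` maps subject to file path),
    the atlas as NIfTI + ROI CSV, scores as CSV, and the manifest — master
    and per-subject seeds plus the ground-truth effect list — as JSON.
    Regeneration from the same config reproduces byte-identical volumes.
    """
    ss = np.random.SeedSequence(config.seed)
    atlas_seed, score_seed, *subject_seeds = ss.spawn(2 + config.n_subjects)
    atlas = generate_atlas(config, np.random.default_rng(atlas_seed))
    scores = generate_factor_scores(config.n_subjects, np.random.default_rng(score_seed))

    for effect in config.effects:
        atlas[effect.roi_abbreviation]  # raises KeyError for unknown ROI

    manifest = {
        "seed": config.seed,
        "config": {**asdict(config), "effects": [asdict(e) for e in config.effects]},
        "subjects": {},
    }
    volumes: dict[str, object] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine),
                 out_path / "atlas_labels.nii.gz")
        pd.DataFrame([
            {"abbreviation": r.abbreviation, "name": r.name,
             "hemisphere": r.hemisphere,
             "labels": ";".join(str(v) for v in sorted(r.atlas_labels)),
             "group": r.group}
            for r in atlas.roi_table
        ]).to_csv(out_path / "roi_table.csv", index=False)
        scores.to_csv(out_path / "factor_scores.csv")

    for subject_id, seed in zip(scores.index, subject_seeds):
        vol = render_subject_volume(atlas, scores.loc[subject_id], config,
                                    np.random.default_rng(seed))
        manifest["subjects"][subject_id] = {"seed_entropy": int(seed.entropy)
                                            if isinstance(seed.entropy, int)
                                            else None,
                                            "spawn_key": list(seed.spawn_key)}
        if out_path is not None:
            p = out_path / f"{subject_id}.nii.gz"
            nib.save(nib.Nifti1Image(vol, np.eye(4)), p)
            volumes[subject_id] = p
        else:
            volumes[subject_id] = vol

    if out_path is not None:
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return atlas, volumes, scores, manifest
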