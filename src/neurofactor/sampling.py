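"""Overlap-constrained random patch sampling inside ROI masks.

Each ROI contributes a fixed number I of cubic intensity patches (default
five 32-cubes).  Patch centers are drawn uniformly from the ROI mask and a
candidate set is accepted only if every pair of patches overlaps by at most a
size-dependent cap: the cap grows linearly with ROI voxel count from 50% for
the smallest ROI of an atlas to 75% for the largest, so small regions are
allowed heavily overlapping patches while large ones get well-separated
coverage.  Candidate sets are redrawn up to ``max_attempts`` times; if a ROI
is still infeasible the cap is relaxed stepwise before giving up.

Centers are clamped so the full cube fits inside the volume (patches may
cover voxels outside the ROI, never outside the image).  A cube of edge s
spans the half-open range ``[c - s//2, c + s - s//2)`` on each axis.
Intensities are z-scored per volume (volume-wide mean/SD) before extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .atlas import AtlasLabelMap, BinaryMask, roi_mask

__all__ = [
    "SamplingConfig",
    "PatchCenter",
    "Patch",
    "overlap_fraction",
    "max_overlap_for_roi",
    "sample_patch_centers",
    "extract_patch",
    "extract_subject_patches",
    "normalize_volume",
]


class SamplingError(RuntimeError):
    """Raised when no center set satisfies the overlap constraint for a ROI."""


class GeometryError(ValueError):
    """Raised when a volume is too small to hold a single patch."""


@dataclass(frozen=True)
class SamplingConfig:
    """Patch-extraction parameters.

    Defaults follow the a-priori protocol: 32-cube patches, five per ROI,
    up to 20,000 candidate draws per ROI, overlap cap interpolated between
    50% and 75% across the atlas's ROI-size range, cap relaxed by 5 points
    per exhausted attempt budget.
    """

    patch_size: int = 32
    patches_per_roi: int = 5
    max_attempts: int = 20_000
    overlap_bounds: tuple[float, float] = (0.50, 0.75)
    relax_step: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.overlap_bounds
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError(f"overlap_bounds must satisfy 0 <= lo <= hi < 1, got {lo}, {hi}")
        if self.patches_per_roi < 1:
            raise ValueError("patches_per_roi must be >= 1")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if not (0.0 < self.relax_step < 1.0):
            raise ValueError("relax_step must be in (0, 1)")


@dataclass(frozen=True)
class PatchCenter:
    """Provenance of one patch: subject, ROI, and voxel coordinate.

    ``center`` is the coordinate actually used for extraction (clamped so the
    cube fits the volume); ``sampled_center`` is the in-mask draw before
    clamping and ``clamped`` records whether they differ.
    """

    subject_id: str
    roi_abbreviation: str
    center: tuple[int, int, int]
    sampled_center: tuple[int, int, int] | None = None
    clamped: bool = False
    overlap_cap: float | None = None  # active cap when the set was accepted


@dataclass(frozen=True)
class Patch:
    """A cubic intensity subvolume with provenance."""

    values: np.ndarray
    center: PatchCenter
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or len(set(v.shape)) != 1:
            raise ValueError(f"patch values must be cubic 3D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("patch contains non-finite values")


def _cube_bounds(center: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    half = size // 2
    lo = center - half
    return lo, lo + size


def overlap_fraction(center_a, center_b, patch_size: int) -> float:
    """Fraction of shared voxels between two equal cubes, in [0, 1].

    Two axis-aligned cubes of edge s centered at a and b share
    ``prod_i max(0, s - |a_i - b_i|)`` voxels; the fraction divides by s^3.
    Symmetric in its arguments; 1.0 for identical centers.
    """
    a = np.asarray(center_a, dtype=np.int64)
    b = np.asarray(center_b, dtype=np.int64)
    per_axis = np.maximum(0, patch_size - np.abs(a - b))
    return float(np.prod(per_axis) / patch_size**3)


def max_overlap_for_roi(
    mask: BinaryMask | int,
    config: SamplingConfig,
    size_range: tuple[int, int] | None = None,
) -> float:
    """Size-dependent overlap cap for one ROI.

    The cap interpolates linearly between ``overlap_bounds`` across the
    atlas's smallest-to-largest ROI voxel counts (``size_range``); without a
    size range the lower bound applies.  Monotonically non-decreasing in
    voxel count and clamped to the bounds.
    """
    count = mask if isinstance(mask, (int, np.integer)) else mask.voxel_count
    if count <= 0:
        raise ValueError("empty ROI mask has no overlap cap")
    lo, hi = config.overlap_bounds
    if size_range is None:
        return lo
    cmin, cmax = size_range
    if cmax <= cmin:
        return lo
    t = (count - cmin) / (cmax - cmin)
    return float(np.clip(lo + t * (hi - lo), lo, hi))


def _clamp_center(center: np.ndarray, size: int, volume_shape) -> np.ndarray:
    """Move a center inward so the full cube fits inside the volume."""
    half = size // 2
    lo = np.full(3, half)
    hi = np.asarray(volume_shape) - (size - half)
    if np.any(hi < lo):
        raise GeometryError(
            f"volume {tuple(volume_shape)} cannot hold a {size}^3 patch"
        )
    return np.clip(center, lo, hi)


def sample_patch_centers(
    mask: BinaryMask,
    volume_shape,
    config: SamplingConfig,
    rng: np.random.Generator,
    max_overlap: float | None = None,
    subject_id: str = "",
) -> list[PatchCenter]:
    """Draw I patch centers inside a ROI mask under the pairwise-overlap cap.

    One attempt draws a full candidate set of I in-mask centers (clamped so
    cubes fit the volume) and tests all pairwise overlap fractions against
    the active cap.  After ``max_attempts`` failed attempts the cap is
    relaxed by ``relax_step`` and the attempt counter resets; if the cap
    would exceed ``1 - relax_step`` a :class:`SamplingError` names the ROI.

    Reproducible: the same rng state yields bit-identical center lists.
    """
    if mask.voxel_count == 0:
        raise SamplingError(f"ROI {mask.roi.abbreviation!r} has an empty mask")
    coords = np.argwhere(mask.mask)
    n_vox = coords.shape[0]
    size = config.patch_size
    I = config.patches_per_roi
    cap = config.overlap_bounds[0] if max_overlap is None else float(max_overlap)

    half = size // 2
    lo = np.full(3, half)
    hi = np.asarray(volume_shape) - (size - half)
    if np.any(hi < lo):
        raise GeometryError(f"volume {tuple(volume_shape)} cannot hold a {size}^3 patch")
    iu, ju = np.triu_indices(I, 1)

    def _build(sampled: np.ndarray, clamped: np.ndarray,
               active_cap: float) -> list[PatchCenter]:
        return [
            PatchCenter(
                subject_id=subject_id,
                roi_abbreviation=mask.roi.abbreviation,
                center=tuple(int(v) for v in clamped[k]),
                sampled_center=tuple(int(v) for v in sampled[k]),
                clamped=bool(np.any(clamped[k] != sampled[k])),
                overlap_cap=active_cap,
            )
            for k in range(I)
        ]

    chunk = 256  # candidate sets are drawn and tested in vectorized batches
    while True:
        remaining = config.max_attempts
        while remaining > 0:
            m = min(chunk, remaining)
            sampled = coords[rng.integers(0, n_vox, size=(m, I))]
            clamped = np.clip(sampled, lo, hi)
            if I > 1:
                diff = np.abs(clamped[:, iu, :] - clamped[:, ju, :])
                shared = np.maximum(0, size - diff).prod(axis=2)
                ok = (shared <= (cap + 1e-12) * size**3).all(axis=1)
            else:
                ok = np.ones(m, dtype=bool)
            hits = np.nonzero(ok)[0]
            if hits.size:
                k = int(hits[0])
                return _build(sampled[k], clamped[k], cap)
            remaining -= m
        cap = cap + config.relax_step
        if cap > 1.0 - config.relax_step + 1e-12:
            raise SamplingError(
                f"ROI {mask.roi.abbreviation!r}: no feasible center set of size {I} "
                f"within {config.max_attempts} attempts even at overlap cap "
                f"{1.0 - config.relax_step:.2f}"
            )


def normalize_volume(volume: np.ndarray) -> tuple[np.ndarray, dict]:
    """Z-score a volume (volume-wide mean and SD); returns (array, record)."""
    v = np.asarray(volume, dtype=np.float32)
    mean = float(v.mean())
    sd = float(v.std())
    if sd == 0.0:
        return v - mean, {"kind": "zscore", "mean": mean, "sd": 0.0}
    return (v - mean) / sd, {"kind": "zscore", "mean": mean, "sd": sd}


def extract_patch(
    volume: np.ndarray,
    center: PatchCenter,
    config: SamplingConfig,
    *,
    normalized: bool = False,
) -> Patch:
    """Cut the cubic subvolume around a (possibly clamped) center.

    The volume is z-scored first unless ``normalized`` says the caller
    already did so.  Raises :class:`GeometryError` if the volume is smaller
    than the patch on any axis.
    """
    vol = np.asarray(volume)
    size = config.patch_size
    if any(s < size for s in vol.shape):
        raise GeometryError(
            f"volume shape {vol.shape} smaller than patch size {size} on some axis"
        )
    if normalized:
        arr, record = np.asarray(vol, dtype=np.float32), {"kind": "precomputed"}
    else:
        arr, record = normalize_volume(vol)
    c = np.asarray(center.center)
    clamped = _clamp_center(c, size, vol.shape)
    if np.any(clamped != c):
        center = replace(
            center,
            center=tuple(int(v) for v in clamped),
            sampled_center=center.sampled_center or tuple(int(v) for v in c),
            clamped=True,
        )
        c = clamped
    lo, hi = _cube_bounds(c, size)
    values = arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return Patch(values=np.ascontiguousarray(values), center=center, normalization=record)


def extract_subject_patches(
    volume: np.ndarray,
    atlas: AtlasLabelMap,
    config: SamplingConfig,
    rng: np.random.Generator,
    subject_id: str = "",
) -> list[Patch]:
    """I patches per ROI for all M ROIs of one subject (M*I patches total).

    Sampling failures are collected across ROIs and raised together so a
    single infeasible region reports alongside any others.
    """
    vol = np.asarray(volume)
    if vol.shape != atlas.shape:
        raise GeometryError(
            f"volume shape {vol.shape} does not match atlas shape {atlas.shape}"
        )
    counts = atlas.roi_voxel_counts()
    nonzero = [c for c in counts.values() if c > 0]
    size_range = (min(nonzero), max(nonzero)) if nonzero else None
    normalized, record = normalize_volume(vol)

    patches: list[Patch] = []
    failures: list[str] = []
    for roi in atlas.roi_table:
        mask = roi_mask(atlas, roi.abbreviation)
        try:
            cap = max_overlap_for_roi(mask, config, size_range)
            centers = sample_patch_centers(
                mask, vol.shape, config, rng, max_overlap=cap, subject_id=subject_id
            )
        except (SamplingError, ValueError) as exc:
            failures.append(str(exc))
            continue
        for center in centers:
            p = extract_patch(normalized, center, config, normalized=True)
            patches.append(Patch(values=p.values, center=p.center, normalization=record))
    if failures:
        raise SamplingError("; ".join(failures))
    return patches
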