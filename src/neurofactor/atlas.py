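"""Labeled atlas volumes and a-priori ROI definitions.

An atlas is an integer-labeled 3D volume (0 = background) plus a table mapping
short ROI codes to the label values that make up each region.  ROIs are
organized into named testing sets (groups); with the a-priori depression
configuration there are 34 lateralized ROIs in 10 groups.  The table is
explicit about numeric labels rather than hard-coding any particular atlas
release's numbering, so AAL2/AAL3-style parcellations from any release can be
used.

Voxel indices are 0-based and all geometry is in voxel units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ROISpec",
    "AtlasLabelMap",
    "BinaryMask",
    "load_label_map",
    "roi_mask",
    "list_roi_sets",
    "merge_hemispheres",
]

_HEMISPHERES = frozenset({"left", "right", "bilateral"})


class AtlasValidationError(ValueError):
    """Raised when a label volume or ROI table violates atlas invariants."""


@dataclass(frozen=True)
class ROISpec:
    """One region of interest: a named set of atlas label values.

    Parameters
    ----------
    abbreviation : short unique code, e.g. ``"ACCpre_L"``.
    name : free-text anatomical description.
    hemisphere : ``"left"``, ``"right"`` or ``"bilateral"``.
    atlas_labels : non-empty set of positive integer label values.
    group : testing-set name the ROI belongs to (each ROI is in exactly one).
    """

    abbreviation: str
    name: str
    hemisphere: str
    atlas_labels: frozenset[int]
    group: str

    def __post_init__(self) -> None:
        if not self.atlas_labels:
            raise AtlasValidationError(f"ROI {self.abbreviation!r}: atlas_labels is empty")
        if any(int(v) <= 0 for v in self.atlas_labels):
            raise AtlasValidationError(
                f"ROI {self.abbreviation!r}: atlas labels must be positive integers"
            )
        if self.hemisphere not in _HEMISPHERES:
            raise AtlasValidationError(
                f"ROI {self.abbreviation!r}: hemisphere {self.hemisphere!r} "
                f"not one of {sorted(_HEMISPHERES)}"
            )


@dataclass
class AtlasLabelMap:
    """Integer label volume plus its ROI table.

    ``labels`` is a 3D integer array where 0 is background; every nonzero
    value present in the array should appear in exactly one ROI's
    ``atlas_labels`` (unknown labels are allowed but reported at load time).
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    roi_table: list[ROISpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise AtlasValidationError(f"label volume must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise AtlasValidationError(f"label volume must be integer, got {self.labels.dtype}")
        abbrevs = [r.abbreviation for r in self.roi_table]
        dupes = {a for a in abbrevs if abbrevs.count(a) > 1}
        if dupes:
            raise AtlasValidationError(f"duplicate ROI abbreviations: {sorted(dupes)}")
        owners: dict[int, str] = {}
        for roi in self.roi_table:
            for lab in roi.atlas_labels:
                if lab in owners:
                    raise AtlasValidationError(
                        f"label {lab} claimed by both {owners[lab]!r} and {roi.abbreviation!r}"
                    )
                owners[lab] = roi.abbreviation

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_rois(self) -> int:
        return len(self.roi_table)

    def __getitem__(self, abbreviation: str) -> ROISpec:
        for roi in self.roi_table:
            if roi.abbreviation == abbreviation:
                return roi
        raise KeyError(f"unknown ROI abbreviation {abbreviation!r}")

    def roi_voxel_counts(self) -> dict[str, int]:
        """Voxel count of every ROI's mask, keyed by abbreviation."""
        counts = dict(zip(*np.unique(self.labels, return_counts=True)))
        return {
            roi.abbreviation: int(sum(counts.get(lab, 0) for lab in roi.atlas_labels))
            for roi in self.roi_table
        }


@dataclass(frozen=True)
class BinaryMask:
    """Boolean support of one ROI on the atlas grid."""

    mask: np.ndarray
    roi: ROISpec

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _parse_labels(cell: object) -> frozenset[int]:
    """Parse a semicolon-separated label cell like ``"5;6"``."""
    parts = [p.strip() for p in str(cell).split(";") if p.strip()]
    try:
        return frozenset(int(p) for p in parts)
    except ValueError as exc:
        raise AtlasValidationError(f"unparseable label cell {cell!r}") from exc


def load_label_map(label_volume_path, roi_table_path) -> AtlasLabelMap:
    """Load a NIfTI label volume and its CSV ROI table into an AtlasLabelMap.

    The CSV must have columns ``abbreviation,name,hemisphere,labels,group``
    with ``labels`` holding semicolon-separated integers.  Label values found
    in the volume but listed in no table row are reported with a warning and
    ignored; non-integer voxel data or duplicate abbreviations raise
    :class:`AtlasValidationError`.
    """
    img = nib.load(str(label_volume_path))
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise AtlasValidationError(
                f"{label_volume_path}: voxel data is not integer-valued"
            )
        data = rounded
    data = data.astype(np.int32)

    table = pd.read_csv(roi_table_path)
    required = {"abbreviation", "name", "hemisphere", "labels", "group"}
    missing = required - set(table.columns)
    if missing:
        raise AtlasValidationError(f"ROI table missing columns: {sorted(missing)}")

    rois = [
        ROISpec(
            abbreviation=str(row.abbreviation),
            name=str(row.name_) if hasattr(row, "name_") else str(row.name),
            hemisphere=str(row.hemisphere),
            atlas_labels=_parse_labels(row.labels),
            group=str(row.group),
        )
        for row in table.rename(columns={"name": "name_"}).itertuples(index=False)
    ]

    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    atlas = AtlasLabelMap(labels=data, voxel_size=voxel_size, roi_table=rois)

    known = set().union(*(r.atlas_labels for r in rois)) if rois else set()
    present = set(int(v) for v in np.unique(data)) - {0}
    orphans = present - known
    if orphans:
        warnings.warn(
            f"atlas labels present in volume but absent from ROI table, ignored: "
            f"{sorted(orphans)}",
            stacklevel=2,
        )
    return atlas


def roi_mask(atlas: AtlasLabelMap, abbreviation: str) -> BinaryMask:
    """Binary mask of one ROI: true exactly where the label value belongs to it."""
    roi = atlas[abbreviation]
    mask = np.isin(atlas.labels, sorted(roi.atlas_labels))
    return BinaryMask(mask=mask, roi=roi)


def list_roi_sets(atlas: AtlasLabelMap) -> dict[str, list[ROISpec]]:
    """Group the ROI table by testing set; groups partition the ROI list."""
    groups: dict[str, list[ROISpec]] = {}
    for roi in atlas.roi_table:
        groups.setdefault(roi.group, []).append(roi)
    return groups


def merge_hemispheres(atlas: AtlasLabelMap) -> AtlasLabelMap:
    """Merge left/right homologues into single bilateral ROIs.

    Homologues are ROIs within one group whose abbreviations differ only by a
    trailing ``_L``/``_R``.  The merged ROI pools both label sets.  Used when
    a non-lateralized reading of the a-priori region list is wanted.
    """
    merged: dict[tuple[str, str], list[ROISpec]] = {}
    for roi in atlas.roi_table:
        stem = roi.abbreviation
        for suffix in ("_L", "_R"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        merged.setdefault((stem, roi.group), []).append(roi)
    new_rois = []
    for (stem, group), members in merged.items():
        labels = frozenset().union(*(m.atlas_labels for m in members))
        hemi = members[0].hemisphere if len(members) == 1 else "bilateral"
        new_rois.append(
            ROISpec(
                abbreviation=stem,
                name=members[0].name,
                hemisphere=hemi,
                atlas_labels=labels,
                group=group,
            )
        )
    return AtlasLabelMap(labels=atlas.labels, voxel_size=atlas.voxel_size, roi_table=new_rois)
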