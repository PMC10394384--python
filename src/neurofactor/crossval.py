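"""Subject-level 10-fold cross-validation and hierarchical score aggregation.

Estimated scores are aggregated bottom-up: the ROI-level estimate is the mean
of that ROI's patch-level estimates, and the subject-level estimate is the
mean of the subject's ROI-level estimates.  Cross-validation splits at the
subject level — all patches of a subject stay on one side of every split —
so no subject's anatomy leaks from training into testing.  All five factor
models share one fold assignment so factor comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .network import NetworkConfig, PatchRegressor3D, TrainingConfig, assign_patch_labels

__all__ = [
    "FoldAssignment",
    "PredictionTable",
    "make_folds",
    "aggregate_roi_scores",
    "aggregate_subject_score",
    "run_cross_validation",
    "assign_patch_labels",
]


@dataclass(frozen=True)
class FoldAssignment:
    """A subject-level partition into n_folds disjoint, size-balanced folds."""

    n_folds: int
    mapping: dict[str, int]
    seed: int | None = None

    def __post_init__(self) -> None:
        folds = set(self.mapping.values())
        if folds and (min(folds) < 0 or max(folds) >= self.n_folds):
            raise ValueError("fold indices out of range")
        sizes = self.fold_sizes()
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")

    def fold_sizes(self) -> list[int]:
        counts = [0] * self.n_folds
        for f in self.mapping.values():
            counts[f] += 1
        return counts

    def test_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.mapping.items() if f == fold)

    def train_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.mapping.items() if f != fold)


def make_folds(subject_ids, n_folds: int = 10,
               rng: np.random.Generator | int | None = None,
               stratify_by=None) -> FoldAssignment:
    """Randomly partition subjects into balanced folds (sizes differ by <= 1).

    116 subjects into 10 folds gives six folds of 12 and four of 11.
    Deterministic given the seed / generator state.

    With ``stratify_by`` (a score per subject, aligned with ``subject_ids``),
    subjects are sorted by score and folds drawn within consecutive blocks,
    so every fold spans the score range and fold means stay close to the
    cohort mean.  This suppresses the cross-validation fold-mean artifact:
    with unstratified folds a held-out fold's mean score anti-correlates
    with its training set's mean, which biases pooled estimate-vs-truth
    correlations negative for any estimator that regresses toward the
    training mean.
    """
    subject_ids = [str(s) for s in subject_ids]
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("subject_ids contain duplicates")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(subject_ids) < n_folds:
        raise ValueError(f"{len(subject_ids)} subjects cannot fill {n_folds} folds")
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(0, 2**31 - 1))
    else:
        seed = rng

    mapping: dict[str, int] = {}
    if stratify_by is None:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold, (_, test_idx) in enumerate(splitter.split(subject_ids)):
            for i in test_idx:
                mapping[subject_ids[i]] = fold
    else:
        values = np.asarray(stratify_by, dtype=np.float64)
        if values.shape[0] != len(subject_ids):
            raise ValueError("stratify_by must align with subject_ids")
        gen = np.random.default_rng(seed)
        order = np.argsort(values, kind="stable")
        for start in range(0, len(order), n_folds):
            block = order[start:start + n_folds]
            folds = gen.permutation(n_folds)[:len(block)]
            for i, f in zip(block, folds):
                mapping[subject_ids[int(i)]] = int(f)
    return FoldAssignment(n_folds=n_folds, mapping=mapping, seed=seed)


def aggregate_roi_scores(patch_scores) -> float:
    """ROI-level estimate: arithmetic mean of the ROI's patch-level estimates."""
    arr = np.asarray(patch_scores, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty patch-score list")
    return float(arr.mean())


def aggregate_subject_score(roi_scores) -> float:
    """Subject-level estimate: arithmetic mean of the subject's ROI-level estimates."""
    arr = np.asarray(roi_scores, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty ROI-score list")
    return float(arr.mean())


@dataclass
class PredictionTable:
    """Patch-, ROI- and subject-level estimated scores with fold provenance.

    Invariants: each ROI-level value is the mean of its patch-level values;
    each subject-level value is the mean of that subject's ROI-level values;
    every record comes from a model that never saw the subject in training.
    """

    factor_name: str
    patch: pd.DataFrame = field(default_factory=pd.DataFrame)
    roi: pd.DataFrame = field(default_factory=pd.DataFrame)
    subject: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_patch_records(cls, records: pd.DataFrame, factor_name: str) -> "PredictionTable":
        """Build the hierarchy from patch-level rows.

        ``records`` needs columns subject_id, roi, patch_id, estimate, fold.
        """
        required = {"subject_id", "roi", "patch_id", "estimate", "fold"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"patch records missing columns {sorted(missing)}")
        patch = records.reset_index(drop=True).copy()
        roi = (
            patch.groupby(["subject_id", "roi"], as_index=False)
            .agg(estimate=("estimate", "mean"), fold=("fold", "first"))
        )
        subject = (
            roi.groupby("subject_id", as_index=False)
            .agg(estimate=("estimate", "mean"), fold=("fold", "first"))
        )
        return cls(factor_name=factor_name, patch=patch, roi=roi, subject=subject)

    def check_consistency(self, atol: float = 1e-12) -> None:
        """Recompute ROI/subject levels from patch rows; raise on mismatch."""
        rebuilt = PredictionTable.from_patch_records(self.patch, self.factor_name)
        for level in ("roi", "subject"):
            a = getattr(self, level).sort_values(
                [c for c in ("subject_id", "roi") if c in getattr(self, level).columns]
            )["estimate"].to_numpy()
            b = getattr(rebuilt, level).sort_values(
                [c for c in ("subject_id", "roi") if c in getattr(rebuilt, level).columns]
            )["estimate"].to_numpy()
            if not np.allclose(a, b, atol=atol, rtol=0):
                raise AssertionError(f"{level}-level estimates inconsistent with patch records")

    def to_tidy(self) -> pd.DataFrame:
        """One tidy frame: level, subject_id, roi, patch_id, estimate, fold, factor."""
        frames = []
        for level, df in (("patch", self.patch), ("roi", self.roi), ("subject", self.subject)):
            t = df.copy()
            t["level"] = level
            if "roi" not in t.columns:
                t["roi"] = ""
            if "patch_id" not in t.columns:
                t["patch_id"] = -1
            frames.append(t[["level", "subject_id", "roi", "patch_id", "estimate", "fold"]])
        out = pd.concat(frames, ignore_index=True)
        out["factor"] = self.factor_name
        return out

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame) -> "PredictionTable":
        factor = str(tidy["factor"].iloc[0]) if len(tidy) else ""
        patch = tidy[tidy["level"] == "patch"].drop(columns=["level", "factor"])
        roi = tidy[tidy["level"] == "roi"].drop(columns=["level", "factor", "patch_id"])
        subject = tidy[tidy["level"] == "subject"].drop(
            columns=["level", "factor", "patch_id", "roi"]
        )
        return cls(factor_name=factor,
                   patch=patch.reset_index(drop=True),
                   roi=roi.reset_index(drop=True),
                   subject=subject.reset_index(drop=True))


def run_cross_validation(
    patches,
    scores: pd.DataFrame,
    factor_name: str,
    folds: FoldAssignment,
    net_config: NetworkConfig | None = None,
    train_config: TrainingConfig | None = None,
) -> PredictionTable:
    """Per-fold train/predict over all subjects for one factor.

    For each fold a fresh network is trained on every patch of the other
    folds' subjects and applied to the held-out subjects' patches; patch-,
    ROI- and subject-level estimates are assembled by hierarchical
    averaging.  Every subject appears exactly once as a test subject.
    """
    net_config = net_config or NetworkConfig()
    train_config = train_config or TrainingConfig()
    patches = list(patches)
    subjects_with_patches = {p.center.subject_id for p in patches}
    assigned = set(folds.mapping)
    missing = sorted(subjects_with_patches - assigned)
    if missing:
        raise ValueError(f"subjects with patches but no fold: {missing}")

    X, y, subject_ids = assign_patch_labels(patches, scores, factor_name)
    subject_ids = np.asarray(subject_ids)
    rois = np.asarray([p.center.roi_abbreviation for p in patches])

    records = []
    for fold in range(folds.n_folds):
        test_set = set(folds.test_subjects(fold))
        train_mask = ~np.isin(subject_ids, sorted(test_set))
        test_mask = ~train_mask
        if not train_mask.any():
            raise ValueError(f"fold {fold}: empty training side")
        if not test_mask.any():
            continue
        # leakage guard: subject sets must be disjoint by construction
        assert not (set(subject_ids[train_mask]) & set(subject_ids[test_mask]))
        est = PatchRegressor3D(
            network_config=net_config,
            epochs=train_config.epochs,
            batch_size=train_config.batch_size,
            learning_rate=train_config.learning_rate,
            weight_decay=train_config.weight_decay,
            random_state=(None if train_config.seed is None
                          else int(train_config.seed) + fold),
        )
        est.fit(X[train_mask], y[train_mask])
        preds = est.predict(X[test_mask])
        idx = np.nonzero(test_mask)[0]
        for i, pred in zip(idx, preds):
            records.append({
                "subject_id": subject_ids[i],
                "roi": rois[i],
                "patch_id": int(i),
                "estimate": float(pred),
                "fold": fold,
            })
    table = PredictionTable.from_patch_records(pd.DataFrame(records), factor_name)
    covered = set(table.subject["subject_id"])
    if covered != subjects_with_patches:
        raise AssertionError("test folds do not cover the cohort")
    return table
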