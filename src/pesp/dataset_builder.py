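"""Turn feature series plus seizure annotations into labeled datasets.

Window labeling follows the standard preictal/interictal scheme: a
window is *preictal* (label 1) if its half-open interval intersects
``[onset - horizon, onset)`` for any seizure, *excluded* if it touches
an ictal interval or the post-ictal margin after it (the classifier is
trained only on preictal vs interictal states), and *interictal*
(label 0) otherwise.  Exclusion takes precedence over the preictal
label, so windows straddling an onset never enter the dataset.

Evaluation is leave-one-seizure-out: the held-out seizure's full
continuous segment forms the test set, all other seizures' preictal
windows plus the interictal pool form the training set.  Class
imbalance is handled by random undersampling of the majority class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .ordinal_entropy import FeatureSeries
from .signal_io import SeizureAnnotation

__all__ = [
    "LabeledDataset",
    "SplitSpec",
    "label_windows",
    "leave_one_seizure_split",
    "balance_undersample",
    "concat_datasets",
]

PREICTAL, INTERICTAL = 1, 0


@dataclass(frozen=True)
class SplitSpec:
    """Labeling and splitting parameters.

    preictal_horizon : minutes before onset labeled preictal (default 50,
    the Freiburg-database convention); exclusion_margin : minutes after
    seizure offset dropped from training (post-ictal dynamics are
    neither class).
    """

    preictal_horizon: float = 50.0
    exclusion_margin: float = 30.0
    balance_seed: int = 0
    test_seizure_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.preictal_horizon <= 0:
            raise ValidationError("preictal_horizon must be positive")
        if self.exclusion_margin < 0:
            raise ValidationError("exclusion_margin must be non-negative")


@dataclass
class LabeledDataset:
    """Feature vectors with preictal/interictal labels and provenance.

    ``features`` is (n_samples, n_channels); ``provenance`` carries a
    '<recording>/<seizure>' tag per row so leakage checks are exact.
    """

    features: np.ndarray
    labels: np.ndarray
    window_times: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        self.window_times = np.asarray(self.window_times, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=object)
        n = self.features.shape[0]
        if not (self.labels.size == self.window_times.size == self.provenance.size == n):
            raise ValidationError("features, labels, times and provenance must align row-wise")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0 (interictal) or 1 (preictal)")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(
            self.features[idx], self.labels[idx], self.window_times[idx], self.provenance[idx]
        )


def _intersects(a0: float, a1: float, b0: float, b1: float) -> bool:
    """Non-empty intersection of half-open intervals [a0,a1) and [b0,b1)."""
    return a0 < b1 and b0 < a1


def label_windows(
    fs: FeatureSeries,
    annotations: Sequence[SeizureAnnotation],
    spec: SplitSpec,
    recording_id: str = "rec",
) -> LabeledDataset:
    """Label each feature window preictal/interictal; drop ictal/post-ictal.

    Labels are a pure function of (window interval, annotations,
    horizon): the i-th window ``[start, start + window_len)`` is matched
    against every seizure's preictal interval ``[onset - horizon, onset)``
    and exclusion interval ``[onset, offset + margin)``.
    """
    anns = sorted(annotations, key=lambda a: a.onset)
    for prev, nxt in zip(anns, anns[1:]):
        if nxt.onset < prev.offset:
            raise ValidationError(
                f"overlapping annotations: [{prev.onset}, {prev.offset}) and [{nxt.onset}, {nxt.offset})"
            )
    horizon_s = spec.preictal_horizon * 60.0
    margin_s = spec.exclusion_margin * 60.0
    wlen = fs.config.window_len

    feats, labels, times, prov = [], [], [], []
    for i, t0 in enumerate(fs.window_starts):
        t1 = t0 + wlen
        excluded = any(_intersects(t0, t1, a.onset, a.offset + margin_s) for a in anns)
        if excluded:
            continue
        hit = [a for a in anns if _intersects(t0, t1, a.onset - horizon_s, a.onset)]
        if hit:
            label = PREICTAL
            tag = f"{recording_id}/sz@{hit[0].onset:.0f}"
        else:
            label = INTERICTAL
            tag = f"{recording_id}/interictal"
        feats.append(fs.values[:, i])
        labels.append(label)
        times.append(t0)
        prov.append(tag)
    return LabeledDataset(
        np.asarray(feats, dtype=float).reshape(len(feats), fs.n_channels),
        np.asarray(labels, dtype=int),
        np.asarray(times, dtype=float),
        np.asarray(prov, dtype=object),
    )


def concat_datasets(parts: Sequence[LabeledDataset]) -> LabeledDataset:
    parts = [p for p in parts if p.n_samples]
    if not parts:
        raise ValidationError("nothing to concatenate")
    return LabeledDataset(
        np.vstack([p.features for p in parts]),
        np.concatenate([p.labels for p in parts]),
        np.concatenate([p.window_times for p in parts]),
        np.concatenate([p.provenance for p in parts]),
    )


def leave_one_seizure_split(
    per_seizure: Dict[str, LabeledDataset],
    interictal_pool: LabeledDataset | None,
    test_id: str,
) -> Tuple[LabeledDataset, LabeledDataset]:
    """Hold one seizure's full segment out; train on the rest.

    Requires at least three seizures in total — with fewer, a model
    trained on a single seizure's preictal data tends to overfit that
    seizure, so such patients are not analyzed.
    """
    if len(per_seizure) < 3:
        raise ValidationError(
            f"need >= 3 seizures for leave-one-out evaluation, got {len(per_seizure)}"
        )
    if test_id not in per_seizure:
        raise ValidationError(f"unknown test seizure id {test_id!r}")
    test = per_seizure[test_id]
    train_parts = [ds for sid, ds in per_seizure.items() if sid != test_id]
    if interictal_pool is not None and interictal_pool.n_samples:
        train_parts.append(interictal_pool)
    train = concat_datasets(train_parts)
    overlap = set(train.provenance) & set(test.provenance)
    if overlap:
        raise ValidationError(f"train/test provenance overlap: {sorted(overlap)[:3]}")
    return train, test


def balance_undersample(train: LabeledDataset, seed: int) -> LabeledDataset:
    """Randomly undersample the majority class to the minority count.

    Selection is without replacement and deterministic for a given
    seed; all minority-class rows are preserved.
    """
    n1 = int(np.sum(train.labels == PREICTAL))
    n0 = int(np.sum(train.labels == INTERICTAL))
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present before balancing")
    if n0 == n1:
        return train.subset(np.arange(train.n_samples))
    rng = np.random.default_rng(seed)
    maj, n_keep = (INTERICTAL, n1) if n0 > n1 else (PREICTAL, n0)
    maj_idx = np.flatnonzero(train.labels == maj)
    keep_maj = rng.choice(maj_idx, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(train.labels != maj), keep_maj]))
    return train.subset(keep)
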