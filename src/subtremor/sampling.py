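"""Dataset splitting, cross-validation folds, and slicing-based oversampling.

The study design holds out a fixed number of test recordings per class
(10 per class in the clinical experiments, giving the 82% / 87%
train-validation fractions for the two- and three-class tasks), runs
stratified 5-fold cross-validation on the remainder, and balances each
training rotation by oversampling minority classes with randomized,
zero-padded time slices of existing sequences.  Validation folds keep the
original class distribution; augmented sequences never enter validation or
test sets.  Subject grouping is on by default because up to two recordings
may come from one subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureSequence

__all__ = [
    "Dataset",
    "FoldPlan",
    "AugmentationConfig",
    "holdout_split",
    "make_folds",
    "time_slice",
    "oversample_balance",
]


@dataclass
class Dataset:
    """Labeled feature sequences with recording/subject provenance."""

    sequences: list[FeatureSequence]

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.sequences])

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, indices) -> "Dataset":
        return Dataset([self.sequences[i] for i in indices])


@dataclass
class FoldPlan:
    """k-fold rotation over the train/validation pool.

    ``folds[i]`` holds the indices (into the pool dataset) validating in
    rotation i; the training indices of rotation i are every other fold.
    """

    k: int
    folds: list[list[int]]
    seed: int

    def rotation(self, i: int) -> tuple[list[int], list[int]]:
        """(train indices, validation indices) for rotation i."""
        val = self.folds[i]
        train = [j for f, fold in enumerate(self.folds) if f != i for j in fold]
        return train, val


@dataclass
class AugmentationConfig:
    """Randomized time-slice augmentation parameters.

    slice_fraction : (low, high) fraction of the frame count a slice may
        cover; the slice is re-placed at a random offset in an all-zero
        sequence of the original length.
    """

    slice_fraction: tuple[float, float] = (0.5, 1.0)
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        low, high = self.slice_fraction
        if not (0 < low <= high <= 1):
            raise ValueError("slice_fraction must satisfy 0 < low <= high <= 1")


def _subjects_of(ds: Dataset) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(ds.sequences):
        groups.setdefault(s.subject_id or f"_rec{i}", []).append(i)
    return groups


def holdout_split(dataset: Dataset, n_test_per_class: int = 10, seed: int = 0,
                  group_subjects: bool = True) -> tuple[Dataset, Dataset]:
    """Hold out exactly `n_test_per_class` recordings per class for testing.

    With subject grouping enabled no subject spans the split: test
    recordings are drawn subject-by-subject from single-recording subjects
    of that class first (so the per-class count lands exactly), falling
    back to multi-recording subjects whose recordings all fit.
    """
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    test_idx: list[int] = []
    for cls in np.unique(labels):
        cls_idx = np.nonzero(labels == cls)[0]
        if len(cls_idx) <= n_test_per_class:
            raise ValueError(
                f"class {cls} has {len(cls_idx)} recordings, "
                f"not enough to hold out {n_test_per_class}"
            )
        if group_subjects:
            groups = _subjects_of(dataset.subset(cls_idx))
            order = sorted(groups)
            rng.shuffle(order)
            chosen: list[int] = []
            for subj in order:
                members = [int(cls_idx[j]) for j in groups[subj]]
                if len(chosen) + len(members) <= n_test_per_class:
                    chosen.extend(members)
                if len(chosen) == n_test_per_class:
                    break
            if len(chosen) != n_test_per_class:
                raise ValueError(
                    f"cannot assemble {n_test_per_class} grouped test "
                    f"recordings for class {cls}"
                )
        else:
            chosen = rng.choice(cls_idx, size=n_test_per_class, replace=False).tolist()
        test_idx.extend(chosen)
    test_set = set(test_idx)
    trainval_idx = [i for i in range(len(dataset)) if i not in test_set]
    return dataset.subset(trainval_idx), dataset.subset(sorted(test_set))


def make_folds(trainval: Dataset, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold partition: each class split into k near-equal
    folds, shuffled with the seed, every index validating exactly once."""
    labels = trainval.labels
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        cls_idx = np.nonzero(labels == cls)[0]
        if len(cls_idx) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
        rng.shuffle(cls_idx)
        for f, chunk in enumerate(np.array_split(cls_idx, k)):
            folds[f].extend(int(i) for i in chunk)
    return FoldPlan(k=k, folds=[sorted(f) for f in folds], seed=seed)


def time_slice(seq: FeatureSequence, config: AugmentationConfig | None = None,
               seed: int | np.random.Generator = 0) -> FeatureSequence:
    """Augment one sequence by a randomized, zero-padded time slice.

    A contiguous slice of random length (within the configured fraction
    range) and random start is placed at a random offset in an all-zero
    sequence of the original frame count, varying the apparent start time
    of the tremor.  The label and provenance are preserved.
    """
    config = config or AugmentationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = seq.n_frames
    if n < 2:
        raise ValueError("sequence must have at least 2 frames")
    lo = max(1, int(round(config.slice_fraction[0] * n)))
    hi = max(lo, int(round(config.slice_fraction[1] * n)))
    length = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(0, n - length + 1))
    offset = int(rng.integers(0, n - length + 1))
    values = np.full_like(seq.values, config.pad_value)
    values[offset:offset + length] = seq.values[start:start + length]
    return FeatureSequence(values=values, columns=seq.columns, label=seq.label,
                           recording_id=seq.recording_id, subject_id=seq.subject_id)


def oversample_balance(training: Dataset, config: AugmentationConfig | None = None,
                       seed: int = 0) -> Dataset:
    """Balance class counts by augmenting minority classes with time slices.

    Originals are kept untouched; minority classes gain time-sliced copies
    of randomly chosen originals until every class matches the majority
    count (e.g. a rotation of 58 PD + 20 ET becomes 116 balanced samples).
    """
    config = config or AugmentationConfig()
    counts = training.class_counts()
    if len(counts) < 2:
        raise ValueError("oversampling needs at least two classes")
    rng = np.random.default_rng(seed)
    target = max(counts.values())
    out = list(training.sequences)
    labels = training.labels
    for cls, cnt in sorted(counts.items()):
        need = target - cnt
        if need <= 0:
            continue
        pool = np.nonzero(labels == cls)[0]
        picks = rng.choice(pool, size=need, replace=True)
        for p in picks:
            out.append(time_slice(training.sequences[int(p)], config, rng))
    return Dataset(out)
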