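"""Class counterbalancing and subject-grouped five-fold cross-validation.

Balancing: the majority class is randomly downsampled (without
replacement) until both classes are equal. The default strategy removes
images proportionally per subject (largest-remainder apportionment) so no
subject is disproportionately pruned; a plain cohort-wide draw is also
available.

Fold plan: the subjects are randomly partitioned into 5 equal groups; each
fold trains on 4 groups and tests on the held-out one, so no subject's
images ever appear on both sides of a split.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .imaging import HbImage


class DatasetError(ValueError):
    pass


@dataclass
class BalancedSet:
    """Images retained after counterbalancing, with per-class counts."""

    images: list[HbImage]
    n_rest: int
    n_clench: int

    def __post_init__(self) -> None:
        if self.n_rest != self.n_clench:
            raise DatasetError("balanced set must have equal class counts")


def _class_split(images: list[HbImage]) -> tuple[list[HbImage], list[HbImage]]:
    rest = [im for im in images if im.label == "rest"]
    clench = [im for im in images if im.label == "clench"]
    if not rest or not clench:
        raise DatasetError("both classes must be non-empty before balancing")
    return rest, clench


def _apportion(counts: dict[str, int], total_remove: int,
               rng: np.random.Generator) -> dict[str, int]:
    """Largest-remainder apportionment of removals across subjects."""
    total = sum(counts.values())
    quotas = {s: total_remove * c / total for s, c in counts.items()}
    base = {s: int(np.floor(q)) for s, q in quotas.items()}
    shortfall = total_remove - sum(base.values())
    order = sorted(counts, key=lambda s: (-(quotas[s] - base[s]), s))
    for s in order[:shortfall]:
        base[s] += 1
    for s, c in counts.items():  # never remove more than a subject has
        if base[s] > c:
            raise DatasetError("apportionment exceeded a subject's image count")
    return base


def balance_classes(images: list[HbImage], seed: int,
                    strategy: str = "per_subject") -> BalancedSet:
    """Downsample the majority class to the minority count (seeded).

    ``strategy='per_subject'`` removes proportionally from each subject's
    majority-class images; ``'cohort'`` draws uniformly over the whole
    majority class.
    """
    rest, clench = _class_split(images)
    if len(rest) == len(clench):
        return BalancedSet(images=list(images), n_rest=len(rest), n_clench=len(clench))
    major, minor = (rest, clench) if len(rest) > len(clench) else (clench, rest)
    n_remove = len(major) - len(minor)
    rng = np.random.default_rng(seed)

    if strategy == "cohort":
        drop = set(rng.choice(len(major), size=n_remove, replace=False).tolist())
        kept_major = [im for i, im in enumerate(major) if i not in drop]
    elif strategy == "per_subject":
        by_subject: dict[str, list[int]] = defaultdict(list)
        for i, im in enumerate(major):
            by_subject[im.subject_id].append(i)
        removals = _apportion({s: len(ix) for s, ix in by_subject.items()},
                              n_remove, rng)
        drop = set()
        for s in sorted(by_subject):
            ix = by_subject[s]
            drop |= set(rng.choice(ix, size=removals[s], replace=False).tolist())
        kept_major = [im for i, im in enumerate(major) if i not in drop]
    else:
        raise ValueError(f"unknown balancing strategy {strategy!r}")

    kept = kept_major + minor
    n_rest = sum(1 for im in kept if im.label == "rest")
    n_clench = len(kept) - n_rest
    return BalancedSet(images=kept, n_rest=n_rest, n_clench=n_clench)


@dataclass(frozen=True)
class FoldPlan:
    """Partition of the subjects into equal groups; one test group per fold."""

    groups: tuple[tuple[str, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        flat = [s for g in self.groups for s in g]
        if len(set(flat)) != len(flat):
            raise DatasetError("groups must not share subjects")
        sizes = {len(g) for g in self.groups}
        if len(sizes) != 1:
            raise DatasetError("groups must be equally sized")

    @property
    def n_folds(self) -> int:
        return len(self.groups)

    def split(self, fold: int) -> tuple[set[str], set[str]]:
        """(train subjects, test subjects) for one fold."""
        test = set(self.groups[fold])
        train = {s for g in self.groups for s in g} - test
        return train, test

    def fold_of(self, subject_id: str) -> int:
        for k, g in enumerate(self.groups):
            if subject_id in g:
                return k
        raise KeyError(subject_id)


def make_fold_plan(subject_ids: list[str], seed: int,
                   n_folds: int = 5) -> FoldPlan:
    """Seeded random partition of the subjects into ``n_folds`` equal groups."""
    if len(subject_ids) % n_folds != 0:
        raise DatasetError(
            f"{len(subject_ids)} subjects cannot form {n_folds} equal groups"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(sorted(subject_ids)))
    per = len(subject_ids) // n_folds
    groups = tuple(tuple(order[k * per:(k + 1) * per]) for k in range(n_folds))
    return FoldPlan(groups=groups, seed=seed)


def fold_images(balanced: BalancedSet, plan: FoldPlan,
                fold: int) -> tuple[list[HbImage], list[HbImage]]:
    """(train images, test images) for one fold — grouped by subject."""
    train_subj, test_subj = plan.split(fold)
    train = [im for im in balanced.images if im.subject_id in train_subj]
    test = [im for im in balanced.images if im.subject_id in test_subj]
    return train, test
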