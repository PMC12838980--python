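"""Subject-wise stratified splitting and cross-validation.

All partitioning happens at the subject level so that no individual's
images appear in more than one partition — the identity-leakage guarantee
that record-level splits of face data violate. Stratification is greedy:
subjects are characterized by their per-class record counts, sorted
largest-first, and each is assigned to the partition (or fold) whose
remaining deficit against its target is greatest.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .labels import FaceRecord, N_CLASSES

__all__ = ["SplitAssignment", "subject_split", "kfold_subjects", "fold_map",
           "record_split"]

PARTITIONS = ("train", "val", "test")
DEFAULT_RATIOS = (0.72, 0.08, 0.20)


@dataclass(frozen=True)
class SplitAssignment:
    """Mapping subject_id -> partition name plus the generating parameters."""

    assignment: dict[str, str]
    ratios: tuple[float, ...]
    seed: int

    def partition_of(self, subject_id: str) -> str:
        return self.assignment[subject_id]

    def tags(self, records: list[FaceRecord]) -> list[str]:
        return [self.assignment[r.subject_id] for r in records]

    def indices(self, records: list[FaceRecord], partition: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(records)
                         if self.assignment[r.subject_id] == partition], dtype=int)

    def verify_disjoint(self) -> None:
        # one partition per subject is structural for a dict; assert coverage
        bad = [s for s, p in self.assignment.items() if p not in PARTITIONS]
        if bad:
            raise AssertionError(f"subjects with invalid partition: {bad}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"ratios": list(self.ratios), "seed": self.seed,
             "assignment": self.assignment}, indent=2, sort_keys=True))


def _subject_table(records: list[FaceRecord]) -> dict[str, np.ndarray]:
    table: dict[str, np.ndarray] = {}
    for r in records:
        counts = table.setdefault(r.subject_id, np.zeros(N_CLASSES, dtype=np.int64))
        counts[r.label] += 1
    return table


def subject_split(records: list[FaceRecord],
                  ratios: tuple[float, float, float] = DEFAULT_RATIOS,
                  seed: int = 42) -> SplitAssignment:
    """Greedy subject-wise stratified train/val/test split.

    Whole subjects are assigned, largest first (seeded shuffle breaks size
    ties), each to the partition with the largest remaining deficit of
    records relative to its target fraction; per-class deficits break
    near-ties so class proportions track the targets too.
    """
    ratios = tuple(float(x) for x in ratios)
    if len(ratios) != 3:
        raise ValueError("need exactly three ratios (train, val, test)")
    if any(x <= 0 for x in ratios):
        raise ValueError(f"all split ratios must be positive, got {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {sum(ratios)}")
    table = _subject_table(records)
    if len(table) < 3:
        raise ValueError(f"need at least 3 subjects, got {len(table)}")
    total = sum(c.sum() for c in table.values())
    total_per_class = np.sum(list(table.values()), axis=0)
    rng = np.random.default_rng(seed)
    subjects = sorted(table)
    rng.shuffle(subjects)
    subjects.sort(key=lambda s: -table[s].sum())  # stable: keeps shuffled ties
    assigned = {p: 0.0 for p in PARTITIONS}
    assigned_class = {p: np.zeros(N_CLASSES) for p in PARTITIONS}
    assignment: dict[str, str] = {}
    for s in subjects:
        counts = table[s]

        def deficit(p: str) -> float:
            r = ratios[PARTITIONS.index(p)]
            size_gap = r * total - assigned[p]
            class_gap = float(np.sum(np.maximum(
                r * total_per_class - assigned_class[p], 0.0)))
            return size_gap / (r * total) + 0.1 * class_gap / (r * total)

        best = max(PARTITIONS, key=deficit)
        assignment[s] = best
        assigned[best] += counts.sum()
        assigned_class[best] += counts
    split = SplitAssignment(assignment=assignment, ratios=ratios, seed=seed)
    split.verify_disjoint()
    return split


def fold_map(records: list[FaceRecord], k: int = 5, seed: int = 42
             ) -> dict[str, int]:
    """Subject -> fold index for subject-wise k-fold CV."""
    table = _subject_table(records)
    n_subjects = len(table)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_subjects:
        raise ValueError(f"k={k} exceeds number of subjects ({n_subjects})")
    rng = np.random.default_rng(seed)
    subjects = sorted(table)
    rng.shuffle(subjects)
    subjects.sort(key=lambda s: -table[s].sum())
    fold_sizes = np.zeros(k)
    fold_counts = np.zeros(k, dtype=int)
    fold_of: dict[str, int] = {}
    for s in subjects:
        # fewest subjects first, then fewest records — keeps folds even
        f = min(range(k), key=lambda i: (fold_counts[i], fold_sizes[i]))
        fold_of[s] = f
        fold_sizes[f] += table[s].sum()
        fold_counts[f] += 1
    return fold_of


def kfold_subjects(records: list[FaceRecord], k: int = 5, seed: int = 42
                   ) -> list[SplitAssignment]:
    """Subject-wise k-fold CV as k (train/test) split assignments.

    Subjects are spread greedily so fold record-counts stay within one
    subject of each other; every subject lands in exactly one test fold.
    """
    fold_of = fold_map(records, k, seed)
    table = _subject_table(records)
    fold_sizes = np.zeros(k)
    for s, f in fold_of.items():
        fold_sizes[f] += table[s].sum()
    splits = []
    for f in range(k):
        assignment = {s: ("test" if fold_of[s] == f else "train")
                      for s in fold_of}
        test_frac = fold_sizes[f] / fold_sizes.sum()
        splits.append(SplitAssignment(assignment=assignment,
                                      ratios=(1.0 - test_frac, 0.0, test_frac),
                                      seed=seed))
    return splits


def record_split(records: list[FaceRecord],
                 ratios: tuple[float, float, float] = DEFAULT_RATIOS,
                 seed: int = 42, unsafe: bool = False) -> list[str]:
    """Record-level (non-subject) split — leaks identities across partitions.

    Only for demonstrations; refuses to run without ``unsafe=True``.
    """
    if not unsafe:
        raise ValueError(
            "record-level splitting leaks subject identity across partitions; "
            "pass unsafe=True only for demonstrations")
    rng = np.random.default_rng(seed)
    n = len(records)
    order = rng.permutation(n)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    tags = np.empty(n, dtype=object)
    tags[order[:n_train]] = "train"
    tags[order[n_train:n_train + n_val]] = "val"
    tags[order[n_train + n_val:]] = "test"
    return list(tags)
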