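"""Segment-based and subject-based k-fold train/test partitions.

The distinction between the two schemes is the whole point of the audit:

* ``split_segment_based`` partitions segment indices with no regard for which
  subject a segment came from — segments of one subject can sit on both
  sides of a fold (the leaky construction);
* ``split_subject_based`` partitions *unique subjects* into k chunks and
  tests each chunk's segments against models trained on the others, so no
  subject ever appears on both sides of a fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplitPlan",
    "split_segment_based",
    "split_subject_based",
    "leave_one_subject_out",
    "carve_validation",
]


@dataclass
class SplitPlan:
    """k folds of disjoint train/test segment-index sets.

    Invariants (enforced by construction, checkable via :meth:`verify`):
    per fold train and test are disjoint and cover all n indices; across
    folds the test sets are disjoint and cover all indices; for the
    subject_based scheme no subject token appears on both sides of any fold.
    """

    k: int
    folds: list[tuple[np.ndarray, np.ndarray]]
    scheme: str  # "segment_based" | "subject_based"
    seed: int
    n: int
    subjects: np.ndarray | None = field(default=None, repr=False)

    def verify(self) -> None:
        """Exhaustively check partition/coverage and subject exclusivity."""
        all_idx = set(range(self.n))
        seen_test: set[int] = set()
        for train, test in self.folds:
            train_set, test_set = set(train.tolist()), set(test.tolist())
            if train_set & test_set:
                raise AssertionError("train/test overlap within a fold")
            if train_set | test_set != all_idx:
                raise AssertionError("fold does not cover all indices")
            if seen_test & test_set:
                raise AssertionError("test sets overlap across folds")
            seen_test |= test_set
            if self.scheme == "subject_based":
                if self.subjects is None:
                    raise AssertionError("subject_based plan lacks subjects")
                train_subj = {self.subjects[i] for i in train}
                test_subj = {self.subjects[i] for i in test}
                if train_subj & test_subj:
                    raise AssertionError(
                        f"subjects {train_subj & test_subj} leak across a fold"
                    )
        if seen_test != all_idx:
            raise AssertionError("test sets do not cover all indices")

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "seed": self.seed,
                "k": self.k,
                "n": self.n,
                "folds": [
                    {"train": train.tolist(), "test": test.tolist()}
                    for train, test in self.folds
                ],
            }
        )

    @staticmethod
    def from_json(payload: str) -> "SplitPlan":
        obj = json.loads(payload)
        return SplitPlan(
            k=obj["k"],
            folds=[
                (np.asarray(f["train"], dtype=int), np.asarray(f["test"], dtype=int))
                for f in obj["folds"]
            ],
            scheme=obj["scheme"],
            seed=obj["seed"],
            n=obj["n"],
        )


def _deal_chunks(items: np.ndarray, k: int) -> list[np.ndarray]:
    """Split items into k near-equal chunks; sizes differ by <= 1.

    Remainder items are distributed one per chunk, largest chunks first.
    """
    n = len(items)
    base, rem = divmod(n, k)
    chunks, start = [], 0
    for j in range(k):
        size = base + (1 if j < rem else 0)
        chunks.append(items[start : start + size])
        start += size
    return chunks


def split_segment_based(n: int, k: int, seed: int) -> SplitPlan:
    """Shuffle segment indices and deal them into k near-equal test chunks."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} segments")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_chunks = _deal_chunks(order, k)
    folds = []
    for test in test_chunks:
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        folds.append((np.flatnonzero(mask), np.sort(test)))
    return SplitPlan(k=k, folds=folds, scheme="segment_based", seed=seed, n=n)


def split_subject_based(
    s: np.ndarray, k: int, seed: int, stratify_by: np.ndarray | None = None
) -> SplitPlan:
    """Partition unique subjects into k chunks; test each chunk's segments.

    With ``stratify_by`` (a per-segment label vector), subjects are dealt
    round-robin within each label stratum so folds stay group-balanced;
    by default subjects are chunked without stratification.
    """
    s = np.asarray(s)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    unique_subjects = np.unique(s)
    if len(unique_subjects) < k:
        raise ValueError(
            f"cannot make {k} folds from {len(unique_subjects)} unique subjects"
        )
    rng = np.random.default_rng(seed)

    if stratify_by is not None:
        stratify_by = np.asarray(stratify_by)
        subj_label = {}
        for subj in unique_subjects:
            labels = np.unique(stratify_by[s == subj])
            if len(labels) != 1:
                raise ValueError(f"subject {subj} has mixed labels; cannot stratify")
            subj_label[subj] = labels[0]
        chunk_lists: list[list] = [[] for _ in range(k)]
        offset = 0
        for lab in np.unique(list(subj_label.values())):
            members = np.array([u for u in unique_subjects if subj_label[u] == lab])
            members = members[rng.permutation(len(members))]
            for j, subj in enumerate(members):
                chunk_lists[(offset + j) % k].append(subj)
            offset += len(members)
        subject_chunks = [np.array(c) for c in chunk_lists]
    else:
        shuffled = unique_subjects[rng.permutation(len(unique_subjects))]
        subject_chunks = _deal_chunks(shuffled, k)

    folds = []
    n = len(s)
    for chunk in subject_chunks:
        test_mask = np.isin(s, chunk)
        folds.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return SplitPlan(
        k=k, folds=folds, scheme="subject_based", seed=seed, n=n, subjects=s
    )


def leave_one_subject_out(s: np.ndarray) -> SplitPlan:
    """Subject-based split with one fold per unique subject (LOSO)."""
    s = np.asarray(s)
    unique_subjects = np.unique(s)
    if len(unique_subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for subj in unique_subjects:
        test_mask = s == subj
        folds.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return SplitPlan(
        k=len(unique_subjects),
        folds=folds,
        scheme="subject_based",
        seed=0,
        n=len(s),
        subjects=s,
    )


def carve_validation(
    plan: SplitPlan, fraction: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Optionally carve a validation partition out of each fold's train set.

    Off by default everywhere in this package (no model selection is
    performed); provided for protocols that do tune hyperparameters.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for train, test in plan.folds:
        order = rng.permutation(len(train))
        n_val = max(1, int(round(fraction * len(train))))
        val = np.sort(train[order[:n_val]])
        tr = np.sort(train[order[n_val:]])
        out.append((tr, val, test))
    return out
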