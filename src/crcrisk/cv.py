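"""Deterministic OS-sorted five-fold scheme.

Instead of random shuffling, patients are sorted by ascending overall
survival time and dealt round-robin into k folds: the patient with the i-th
smallest OS goes to fold i mod k.  Every fold therefore spans the whole
survival range, making the folds homogeneous in survival time.  Ties are
broken by original row order (stable sort); the module contains no
randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of: np.ndarray  # per-patient fold index, aligned to row order

    def to_frame(self, patient_ids) -> pd.DataFrame:
        return pd.DataFrame({"patient_id": patient_ids, "fold": self.fold_of})


def make_folds(cohort: pd.DataFrame, k: int = 5) -> FoldAssignment:
    """Deal patients into k folds by ascending OS time (round robin)."""
    n = len(cohort)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} patients, got {n}")
    order = np.argsort(cohort["os_time"].to_numpy(float), kind="stable")
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % k
    return FoldAssignment(k=k, fold_of=fold_of)


def train_test_pairs(assignment: FoldAssignment):
    """Yield (train_indices, test_indices) for each fold, in fold order."""
    idx = np.arange(assignment.fold_of.size)
    for f in range(assignment.k):
        test = idx[assignment.fold_of == f]
        train = idx[assignment.fold_of != f]
        yield train, test


class OSSortedKFold:
    """sklearn-compatible cross-validator wrapping :func:`make_folds`.

    ``split(X, y)`` expects ``y`` to be the overall survival times (or any
    sort key); the dealing is deterministic, so there is no ``random_state``.
    """

    def __init__(self, n_splits: int = 5):
        self.n_splits = n_splits

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def split(self, X, y, groups=None):
        frame = pd.DataFrame({"os_time": np.asarray(y, dtype=float)})
        yield from train_test_pairs(make_folds(frame, self.n_splits))
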