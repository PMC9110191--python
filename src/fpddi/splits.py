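"""The two ten-fold cross-validation protocols.

Entire CV partitions the pooled samples themselves: every sample is tested
exactly once, and both drugs of a test pair will usually have been seen in
training pairs.  Composition CV instead partitions the *drugs* into K parts;
holding out one drug part routes every sample by how many of its two drugs are
held out: 0 held out -> training set, 1 -> ODIT (One Drug In Train) test set,
2 -> NDIT (No Drug In Train) test set.  ODIT and NDIT are the one- and
two-cold-start regimes: no held-out drug ever appears in a training pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .dataset import InteractionDataset


@dataclass
class EntireFoldPlan:
    """Sample-level K-fold assignment; fold sizes differ by at most one."""

    K: int
    assignment: np.ndarray  # fold index per sample, aligned with dataset.samples

    def test_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)

    def train_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != k)

    def iter_folds(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        for k in range(self.K):
            yield self.train_indices(k), self.test_indices(k)

    def to_frame(self, dataset: InteractionDataset) -> pd.DataFrame:
        df = dataset.to_frame()
        df["fold"] = self.assignment
        return df


@dataclass
class CompositionFold:
    """Per-fold sample routing of composition CV (disjoint, exhaustive)."""

    train: np.ndarray
    odit: np.ndarray
    ndit: np.ndarray


@dataclass
class CompositionSplit:
    """Drug-level K-fold partition and the induced train/ODIT/NDIT sets."""

    K: int
    drug_assignment: dict[str, int]
    folds: list[CompositionFold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.drug_assignment.items()), columns=["drug_id", "fold"]
        )


def _partition_sizes(n: int, K: int) -> np.ndarray:
    sizes = np.full(K, n // K, dtype=int)
    sizes[: n % K] += 1
    return sizes


def entire_cv_split(dataset: InteractionDataset, K: int = 10, seed: int = 0) -> EntireFoldPlan:
    """Randomly divide all samples (positives and negatives pooled) into K
    near-equal parts.

    No stratification by label: with a balanced dataset the random split is
    already near-balanced in expectation.
    """
    n = len(dataset.samples)
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if K > n:
        raise ValueError(f"K={K} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    start = 0
    for k, size in enumerate(_partition_sizes(n, K)):
        assignment[order[start : start + size]] = k
        start += size
    return EntireFoldPlan(K=K, assignment=assignment)


def composition_cv_split(
    dataset: InteractionDataset, K: int = 10, seed: int = 0
) -> CompositionSplit:
    """Divide the dataset's drugs into K near-equal parts and route samples.

    For fold k, a sample goes to the training set, the ODIT test set or the
    NDIT test set according to whether 0, 1 or 2 of its drugs fall in drug
    part k.  Only drugs that occur in samples are partitioned.
    """
    drug_ids = sorted({d for s in dataset.samples for d in s.pair})
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if K > len(drug_ids):
        raise ValueError(f"K={K} exceeds drug count {len(drug_ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(drug_ids))
    drug_assignment: dict[str, int] = {}
    start = 0
    for k, size in enumerate(_partition_sizes(len(drug_ids), K)):
        for idx in order[start : start + size]:
            drug_assignment[drug_ids[idx]] = k
        start += size

    fold_of = np.array(
        [[drug_assignment[s.pair[0]], drug_assignment[s.pair[1]]] for s in dataset.samples]
    )
    folds = []
    for k in range(K):
        held = (fold_of == k).sum(axis=1)  # how many of the pair's drugs are held out
        folds.append(
            CompositionFold(
                train=np.flatnonzero(held == 0),
                odit=np.flatnonzero(held == 1),
                ndit=np.flatnonzero(held == 2),
            )
        )
    return CompositionSplit(K=K, drug_assignment=drug_assignment, folds=folds)
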