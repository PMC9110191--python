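"""Balanced interaction dataset assembly.

Validated interacting pairs are the positive samples.  Negative samples are
presumed non-interactions, drawn uniformly at random among the drugs that
occur in the positives: pick two different drugs; if they do not form a known
positive pair, keep them; repeat until there are as many distinct negatives as
positives.  Pairs are unordered and stored in lexicographic canonical order so
{A, B} and {B, A} are one sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fingerprints import Drug

logger = logging.getLogger(__name__)


class CapacityError(ValueError):
    """Not enough non-positive pairs exist to balance the dataset."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered unordered pair; rejects self-pairs."""
    if a == b:
        raise ValueError(f"self-pair: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True, order=True)
class PairSample:
    """An unordered drug pair with a binary interaction label (1 = interacting)."""

    pair: tuple[str, str]
    label: int

    def __post_init__(self):
        if self.pair != canonical_pair(*self.pair):
            raise ValueError(f"pair {self.pair} is not in canonical order")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class InteractionDataset:
    """Drugs plus balanced labelled pair samples.

    Invariants (checked by :meth:`validate`): no duplicate pairs, no pair with
    both labels, equal positive and negative counts, and every referenced
    drug_id present in ``drugs``.
    """

    drugs: dict[str, Drug]
    samples: list[PairSample] = field(default_factory=list)

    @property
    def positives(self) -> list[PairSample]:
        return [s for s in self.samples if s.label == 1]

    @property
    def negatives(self) -> list[PairSample]:
        return [s for s in self.samples if s.label == 0]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [s.pair for s in self.samples]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int8)

    def validate(self) -> None:
        pairs = [s.pair for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate pair(s) in dataset")
        if len(self.positives) != len(self.negatives):
            raise ValueError(
                f"unbalanced dataset: {len(self.positives)} positives vs "
                f"{len(self.negatives)} negatives"
            )
        referenced = {d for s in self.samples for d in s.pair}
        missing = referenced - set(self.drugs)
        if missing:
            raise ValueError(f"samples reference unknown drug_id(s): {sorted(missing)[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, b, s.label) for s in self.samples for a, b in [s.pair]],
            columns=["drug_id_1", "drug_id_2", "label"],
        )


def load_positive_pairs(
    rows: Iterable[tuple[str, str]] | pd.DataFrame,
    known_ids: set[str] | None = None,
) -> list[PairSample]:
    """Canonicalise and deduplicate positive pair rows.

    Self-pairs and rows referencing drugs outside ``known_ids`` (e.g. drugs
    removed because their fingerprints could not be extracted) are dropped
    with a logged count rather than raising.
    """
    if isinstance(rows, pd.DataFrame):
        rows = list(zip(rows.iloc[:, 0].astype(str), rows.iloc[:, 1].astype(str)))
    seen: set[tuple[str, str]] = set()
    dropped_self = dropped_unknown = 0
    out: list[PairSample] = []
    for a, b in rows:
        a, b = str(a), str(b)
        if a == b:
            dropped_self += 1
            continue
        if known_ids is not None and (a not in known_ids or b not in known_ids):
            dropped_unknown += 1
            continue
        pair = canonical_pair(a, b)
        if pair in seen:
            continue
        seen.add(pair)
        out.append(PairSample(pair=pair, label=1))
    if dropped_self:
        logger.warning("dropped %d self-pair row(s)", dropped_self)
    if dropped_unknown:
        logger.warning("dropped %d row(s) referencing unknown drugs", dropped_unknown)
    return out


def sample_negatives(
    positives: Sequence[PairSample],
    drug_ids: Iterable[str],
    seed: int,
) -> list[PairSample]:
    """Draw as many distinct random non-interacting pairs as there are positives.

    ``drug_ids`` should be exactly the drugs occurring in the positives (the
    closed world the sampler operates over).  Rejection sampling with a seeded
    generator; a capacity pre-check guarantees termination.
    """
    ids = sorted(set(drug_ids))
    n_target = len(positives)
    positive_pairs = {s.pair for s in positives}
    capacity = comb(len(ids), 2) - len(positive_pairs)
    if capacity < n_target:
        raise CapacityError(
            f"only {capacity} candidate non-positive pairs exist among "
            f"{len(ids)} drugs; {n_target} negatives requested"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    # Rejection sampling is fast while the candidate space is sparse; fall
    # back to exhaustive enumeration when it gets tight.
    dense = n_target > 0.5 * capacity
    if dense:
        candidates = [
            (ids[i], ids[j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if (ids[i], ids[j]) not in positive_pairs
        ]
        picked = rng.choice(len(candidates), size=n_target, replace=False)
        chosen = {candidates[k] for k in picked}
    else:
        while len(chosen) < n_target:
            i, j = rng.choice(len(ids), size=2, replace=False)
            pair = canonical_pair(ids[i], ids[j])
            if pair not in positive_pairs:
                chosen.add(pair)
    return [PairSample(pair=p, label=0) for p in sorted(chosen)]


def build_dataset(
    drugs: Sequence[Drug] | Mapping[str, Drug],
    positive_rows: Iterable[tuple[str, str]] | pd.DataFrame,
    seed: int,
) -> InteractionDataset:
    """Assemble the balanced dataset from featurized drugs and positive rows.

    The drug universe of the dataset is the set of drugs occurring in the
    (filtered) positives; drugs never seen in a positive pair are retained in
    ``drugs`` for prediction but contribute no samples.
    """
    drug_map = dict(drugs) if isinstance(drugs, Mapping) else {d.drug_id: d for d in drugs}
    positives = load_positive_pairs(positive_rows, known_ids=set(drug_map))
    involved = sorted({d for s in positives for d in s.pair})
    negatives = sample_negatives(positives, involved, seed=seed)
    ds = InteractionDataset(drugs=drug_map, samples=positives + negatives)
    ds.validate()
    return ds


def read_pair_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited pair table: two drug_id columns, optional label column."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "label" in df.columns:
        df["label"] = df["label"].astype(int)
    return df


def write_pair_table(samples: Sequence[PairSample], path, sep: str = "\t",
                     with_label: bool = True) -> None:
    df = pd.DataFrame(
        [(s.pair[0], s.pair[1], s.label) for s in samples],
        columns=["drug_id_1", "drug_id_2", "label"],
    )
    if not with_label:
        df = df.drop(columns="label")
    df.to_csv(path, sep=sep, index=False)
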