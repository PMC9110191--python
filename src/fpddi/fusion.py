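"""Order-invariant fusion of two drug fingerprints into one pair feature vector.

A drug pair carries no order — {d1, d2} and {d2, d1} are the same candidate
interaction — so simply concatenating the two fingerprints would make the
feature vector depend on an arbitrary choice.  Three symmetric componentwise
operators avoid that:

- addition:     v_i = f_i(d1) + f_i(d2)        (values in {0, 1, 2})
- subtraction:  v_i = |f_i(d1) - f_i(d2)|      (values in {0, 1})
- hadamard:     v_i = f_i(d1) * f_i(d2)        (values in {0, 1})

Any non-empty subset of the three may be used; the chosen per-operator blocks
are concatenated in the fixed canonical order addition, subtraction, hadamard
so feature column meanings are stable across runs.  Values are kept as small
integers with no scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fingerprints import Drug


class FusionModel(Enum):
    ADDITION = "addition"
    SUBTRACTION = "subtraction"
    HADAMARD = "hadamard"

    @property
    def letter(self) -> str:
        return self.name[0]


#: Fixed concatenation order of fusion blocks.
CANONICAL_ORDER: tuple[FusionModel, ...] = (
    FusionModel.ADDITION,
    FusionModel.SUBTRACTION,
    FusionModel.HADAMARD,
)

#: The seven usable model combinations, as letter codes.
ALL_COMBINATIONS: tuple[str, ...] = ("A", "S", "H", "AS", "AH", "SH", "ASH")


def parse_models(spec: str | Iterable[FusionModel]) -> tuple[FusionModel, ...]:
    """Normalise a model-combination spec to canonical order.

    Accepts letter codes (``"AS"``, ``"ash"``), full names separated by ``+``
    or ``,`` (``"addition+subtraction"``), or an iterable of
    :class:`FusionModel`.  Raises ``ValueError`` on empty or unknown specs.
    """
    if isinstance(spec, str):
        text = spec.strip()
        if not text:
            raise ValueError("empty fusion model specification")
        if any(c in text for c in "+,"):
            parts = [p.strip().lower() for p in text.replace("+", ",").split(",") if p.strip()]
            models = [FusionModel(p) for p in parts]
        else:
            by_letter = {m.letter: m for m in FusionModel}
            try:
                models = [by_letter[c] for c in text.upper()]
            except KeyError as err:
                raise ValueError(f"unknown fusion model letter in {spec!r}") from err
    else:
        models = list(spec)
    if not models:
        raise ValueError("empty fusion model specification")
    if len(set(models)) != len(models):
        raise ValueError(f"repeated fusion model in {spec!r}")
    return tuple(m for m in CANONICAL_ORDER if m in models)


def models_code(models: Sequence[FusionModel]) -> str:
    """Letter code (e.g. ``"AS"``) of a model subset, in canonical order."""
    return "".join(m.letter for m in parse_models(models))


def fuse(fp1: np.ndarray, fp2: np.ndarray, model: FusionModel) -> np.ndarray:
    """Fuse two equal-length binary fingerprints with one symmetric operator."""
    a = np.asarray(fp1)
    b = np.asarray(fp2)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(np.int16)
    b = b.astype(np.int16)
    if model is FusionModel.ADDITION:
        return (a + b).astype(np.uint8)
    if model is FusionModel.SUBTRACTION:
        return np.abs(a - b).astype(np.uint8)
    if model is FusionModel.HADAMARD:
        return (a * b).astype(np.uint8)
    raise ValueError(f"unknown fusion model {model!r}")


@dataclass(frozen=True)
class PairFeatures:
    """Fused feature vector of one unordered drug pair.

    ``vector`` has length ``n_bits * len(models)``: one block per chosen
    fusion model, concatenated in canonical order.  Identical regardless of
    the order in which the two drugs were supplied.
    """

    pair: tuple[str, str]
    models: tuple[FusionModel, ...]
    vector: np.ndarray = field(repr=False)


def encode_pair(
    d1: Drug, d2: Drug, models: str | Iterable[FusionModel]
) -> PairFeatures:
    """Encode an unordered drug pair under a combination of fusion models."""
    if d1.drug_id == d2.drug_id:
        raise ValueError(f"self-pair: {d1.drug_id!r} supplied twice")
    chosen = parse_models(models)
    blocks = [fuse(d1.fingerprint, d2.fingerprint, m) for m in chosen]
    pair = tuple(sorted((d1.drug_id, d2.drug_id)))
    return PairFeatures(pair=pair, models=chosen, vector=np.concatenate(blocks))


def encode_pairs(
    drugs: Mapping[str, Drug],
    pairs: Sequence[tuple[str, str]],
    models: str | Iterable[FusionModel],
) -> np.ndarray:
    """Vectorised pair encoding: one feature row per (drug_id, drug_id) pair.

    Equivalent to stacking :func:`encode_pair` vectors but computed on the
    whole fingerprint matrix at once.
    """
    chosen = parse_models(models)
    ids = sorted(drugs)
    index = {d: k for k, d in enumerate(ids)}
    fp = np.vstack([drugs[d].fingerprint for d in ids]).astype(np.int16)
    i = np.array([index[a] for a, _ in pairs], dtype=np.intp)
    j = np.array([index[b] for _, b in pairs], dtype=np.intp)
    left, right = fp[i], fp[j]
    blocks = []
    for m in chosen:
        if m is FusionModel.ADDITION:
            blocks.append(left + right)
        elif m is FusionModel.SUBTRACTION:
            blocks.append(np.abs(left - right))
        else:
            blocks.append(left * right)
    if not pairs:
        return np.empty((0, fp.shape[1] * len(chosen)), dtype=np.uint8)
    return np.concatenate(blocks, axis=1).astype(np.uint8)
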