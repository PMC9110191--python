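"""Self-contained synthetic worlds for exercising the whole pipeline.

A world is a library of small valid molecules (assembled from a fixed
fragment alphabet of alkyl chains, rings, halogens and common functional
groups) plus interacting pairs produced by a latent fingerprint-dependent
rule: a pair is positive when the number of fingerprint bits the two
molecules share exceeds a threshold, with optional seeded label-flip noise.
Because the rule operates on fingerprint overlap, the signal is recoverable
from the fused pair features by construction — pipeline tests check the
machinery, not chemistry beyond what the features encode.

Worlds emit the exact file formats the real pipeline reads (drug table TSV,
positive pair TSV), so fixtures exercise the readers too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .fingerprints import Drug, Fingerprinter, default_fingerprinter, featurize_drugs

# Closed SMILES fragments: each parses on its own and any concatenation
# chain + ... + chain + terminal parses too (every fragment starts with an
# atom and closes its own rings, so appending extends the main chain).
_CHAIN_FRAGMENTS = (
    "C", "CC", "CCC", "CO", "CN", "CS", "C(C)", "C(=O)", "C=C",
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOC1", "C1CC1",
    "C(=O)O", "C(=O)N", "OC", "NC",
)
_TERMINAL_FRAGMENTS = ("", "F", "Cl", "Br", "I", "O", "N", "C#N", "C(=O)O", "C=O")


@dataclass
class SyntheticWorld:
    """A toy drug library, its positive pairs and the generative rule used."""

    drugs: list[tuple[str, str]]  # (drug_id, smiles)
    positives: list[tuple[str, str]]
    rule: dict = field(default_factory=dict)
    seed: int = 0


def make_drug_library(
    n: int,
    seed: int,
    max_attempts_per_molecule: int = 200,
) -> list[tuple[str, str]]:
    """Generate ``n`` distinct parseable molecules as (drug_id, smiles) rows.

    Molecules are seeded random concatenations of 1-5 chain fragments plus an
    optional terminal group; distinctness is enforced by canonical-form
    deduplication.  Raises when the fragment space cannot yield ``n`` distinct
    molecules within the attempt budget.
    """
    if n < 2:
        raise ValueError("need at least 2 molecules")
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    seen_canonical: set[str] = set()
    out: list[tuple[str, str]] = []
    attempts = 0
    while len(out) < n:
        if attempts > max_attempts_per_molecule * n:
            raise RuntimeError(
                f"fragment space exhausted: built {len(out)}/{n} distinct molecules"
            )
        attempts += 1
        k = int(rng.integers(1, 6))
        smiles = "".join(rng.choice(_CHAIN_FRAGMENTS) for _ in range(k))
        smiles += str(rng.choice(_TERMINAL_FRAGMENTS))
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - fragments are closed by design
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen_canonical:
            continue
        seen_canonical.add(canonical)
        out.append((f"D{len(out):04d}", smiles))
    return out


def shared_bit_counts(
    library: list[tuple[str, str]],
    fingerprinter: Fingerprinter | None = None,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """All unordered pairs and the number of fingerprint bits each pair shares."""
    fper = fingerprinter or default_fingerprinter()
    drugs, rejected = featurize_drugs(library, fingerprinter=fper)
    if len(rejected):  # pragma: no cover - library molecules always parse
        raise ValueError("synthetic library contains unparseable molecules")
    pairs = list(combinations([d.drug_id for d in drugs], 2))
    fp = np.vstack([d.fingerprint for d in drugs]).astype(np.int32)
    overlap = fp @ fp.T
    index = {d.drug_id: k for k, d in enumerate(drugs)}
    counts = np.array([overlap[index[a], index[b]] for a, b in pairs])
    return pairs, counts


def make_interactions(
    library: list[tuple[str, str]],
    threshold: int | None = None,
    noise: float = 0.05,
    seed: int = 0,
    fingerprinter: Fingerprinter | None = None,
) -> tuple[list[tuple[str, str]], dict]:
    """Label every unordered pair by the shared-fingerprint-bit rule and
    return the positive pairs.

    A pair is latently positive when its shared-bit count exceeds
    ``threshold``; each label is then flipped with probability ``noise``.
    ``threshold=None`` picks the 70th percentile of the pair shared-count
    distribution (about 30% positives).  An explicit threshold yielding under
    10% or over 90% positives triggers a warning and falls back to the
    percentile choice.
    """
    if not library:
        raise ValueError("empty library")
    pairs, counts = shared_bit_counts(library, fingerprinter=fingerprinter)
    auto = int(np.percentile(counts, 70))
    if threshold is None:
        threshold = auto
    latent = counts > threshold
    rate = latent.mean()
    if rate < 0.10 or rate > 0.90:
        warnings.warn(
            f"threshold {threshold} yields degenerate positive rate {rate:.2f}; "
            f"adjusting to {auto}",
            stacklevel=2,
        )
        threshold = auto
        latent = counts > threshold
    rng = np.random.default_rng(seed)
    flips = rng.random(len(pairs)) < noise
    labels = latent ^ flips
    positives = [p for p, lab in zip(pairs, labels) if lab]
    rule = {
        "kind": "shared_fingerprint_bits",
        "threshold": int(threshold),
        "noise": float(noise),
        "seed": int(seed),
        "n_pairs": len(pairs),
        "positive_rate": float(labels.mean()),
    }
    return positives, rule


def make_world(
    n: int = 60,
    seed: int = 0,
    noise: float = 0.05,
    threshold: int | None = None,
    fingerprinter: Fingerprinter | None = None,
) -> SyntheticWorld:
    """Library + interactions in one call; all randomness from ``seed``."""
    rng = np.random.default_rng(seed)
    lib_seed, label_seed = (int(s) for s in rng.integers(0, 2**31, size=2))
    library = make_drug_library(n, seed=lib_seed)
    positives, rule = make_interactions(
        library, threshold=threshold, noise=noise, seed=label_seed,
        fingerprinter=fingerprinter,
    )
    return SyntheticWorld(drugs=library, positives=positives, rule=rule, seed=seed)


def write_world(world: SyntheticWorld, directory) -> tuple[Path, Path]:
    """Write drugs.tsv and positives.tsv in the pipeline's input formats."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    drugs_path = directory / "drugs.tsv"
    pairs_path = directory / "positives.tsv"
    pd.DataFrame(world.drugs, columns=["drug_id", "smiles"]).to_csv(
        drugs_path, sep="\t", index=False
    )
    pd.DataFrame(world.positives, columns=["drug_id_1", "drug_id_2"]).to_csv(
        pairs_path, sep="\t", index=False
    )
    return drugs_path, pairs_path
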