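import zlib

import numpy as np
import pytest

from fpddi.dataset import build_dataset
from fpddi.fingerprints import Drug, InvalidStructureError, featurize_drugs


class ToyFingerprinter:
    """Deterministic chemistry-free encoder for pipeline tests.

    Hashes overlapping character bigrams of the input string into a small bit
    vector, so equal strings map to equal vectors and similar strings share
    bits.  Strings containing ``!`` are treated as unparseable.
    """

    def __init__(self, n_bits: int = 64):
        self.n_bits = n_bits

    def __call__(self, smiles: str) -> np.ndarray:
        if not smiles or "!" in smiles:
            raise InvalidStructureError(smiles)
        vec = np.zeros(self.n_bits, dtype=np.uint8)
        padded = f"^{smiles}$"
        for i in range(len(padded) - 1):
            bit = zlib.crc32(padded[i : i + 2].encode()) % self.n_bits
            vec[bit] = 1
        return vec


@pytest.fixture
def toy_fingerprinter():
    return ToyFingerprinter()


def random_drugs(n: int, n_bits: int = 64, seed: int = 0, density: float = 0.25):
    """Drugs with random fingerprints (no chemistry), for fast pipeline tests."""
    rng = np.random.default_rng(seed)
    return [
        Drug(f"D{i:03d}", f"smiles{i}", (rng.random(n_bits) < density).astype(np.uint8))
        for i in range(n)
    ]


def overlap_dataset(n_drugs: int = 20, n_bits: int = 64, seed: int = 0):
    """Balanced dataset whose labels follow a shared-bit rule on random drugs."""
    drugs = random_drugs(n_drugs, n_bits=n_bits, seed=seed)
    fp = np.vstack([d.fingerprint for d in drugs]).astype(int)
    overlap = fp @ fp.T
    counts = [
        overlap[i, j] for i in range(n_drugs) for j in range(i + 1, n_drugs)
    ]
    thr = int(np.percentile(counts, 70))
    positives = [
        (drugs[i].drug_id, drugs[j].drug_id)
        for i in range(n_drugs)
        for j in range(i + 1, n_drugs)
        if overlap[i, j] > thr
    ]
    return build_dataset(drugs, positives, seed=seed)


@pytest.fixture
def small_dataset():
    return overlap_dataset(n_drugs=20, seed=3)
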