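"""Drug representation as binary circular fingerprints.

A drug is identified by an opaque string id and a SMILES string; its numeric
representation is an ECFP4 (Morgan, radius 2) fingerprint folded to 1024 bits,
the standard substructure encoding for small-molecule machine learning.  Two
SMILES spellings of the same molecule map to the same fingerprint because the
encoder works on the parsed molecular graph, not the string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_BITS = 1024


class InvalidStructureError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"invalid structure: could not parse SMILES {smiles!r}")


class Fingerprinter(Protocol):
    """Anything that maps a SMILES string to a fixed-length binary vector.

    The default implementation is chemistry-aware (:class:`MorganFingerprinter`);
    tests may substitute a deterministic toy encoder so pipeline behaviour can
    be checked independently of the chemistry toolkit.
    """

    n_bits: int

    def __call__(self, smiles: str) -> np.ndarray: ...


class MorganFingerprinter:
    """ECFP4-style Morgan fingerprint, radius 2, folded to ``n_bits`` binary bits.

    Chirality/stereo flags are ignored (toolkit default).  Output is a dense
    uint8 0/1 vector.
    """

    def __init__(self, radius: int = 2, n_bits: int = N_BITS):
        from rdkit import RDLogger
        from rdkit.Chem import rdFingerprintGenerator

        # RDKit writes parse errors to stderr; invalid input is already
        # surfaced as InvalidStructureError, so silence the duplicate noise.
        RDLogger.DisableLog("rdApp.error")
        self.radius = radius
        self.n_bits = n_bits
        self._gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )

    def __call__(self, smiles: str) -> np.ndarray:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else None
        if mol is None:
            raise InvalidStructureError(str(smiles))
        fp = self._gen.GetFingerprint(mol)
        vec = np.zeros(self.n_bits, dtype=np.uint8)
        vec[list(fp.GetOnBits())] = 1
        return vec


_default_fingerprinter: MorganFingerprinter | None = None


def default_fingerprinter() -> MorganFingerprinter:
    global _default_fingerprinter
    if _default_fingerprinter is None:
        _default_fingerprinter = MorganFingerprinter()
    return _default_fingerprinter


@dataclass(frozen=True)
class Drug:
    """A drug with its identifier, SMILES notation and binary fingerprint."""

    drug_id: str
    smiles: str
    fingerprint: np.ndarray = field(repr=False)

    def __post_init__(self):
        fp = np.asarray(self.fingerprint, dtype=np.uint8)
        if fp.shape != (len(fp),) or not np.isin(fp, (0, 1)).all():
            raise ValueError("fingerprint must be a flat 0/1 vector")
        object.__setattr__(self, "fingerprint", fp)

    def __eq__(self, other):
        return (
            isinstance(other, Drug)
            and self.drug_id == other.drug_id
            and self.smiles == other.smiles
            and np.array_equal(self.fingerprint, other.fingerprint)
        )

    def __hash__(self):
        return hash(self.drug_id)


def fingerprint_of(smiles: str, fingerprinter: Fingerprinter | None = None) -> np.ndarray:
    """Encode one SMILES string as a binary fingerprint vector.

    Raises :class:`InvalidStructureError` for unparseable input.
    """
    fper = fingerprinter or default_fingerprinter()
    return fper(smiles)


def featurize_drugs(
    table: pd.DataFrame | Iterable[tuple[str, str]],
    fingerprinter: Fingerprinter | None = None,
) -> tuple[list[Drug], pd.DataFrame]:
    """Fingerprint a (drug_id, smiles) table, separating unparseable entries.

    Parameters
    ----------
    table
        DataFrame with columns ``drug_id`` and ``smiles``, or an iterable of
        ``(drug_id, smiles)`` pairs.  Identifiers must be unique.
    fingerprinter
        Encoder to use; defaults to the Morgan fingerprinter.

    Returns
    -------
    drugs, rejected
        One :class:`Drug` per parseable row, and a DataFrame of rejected rows
        with columns ``drug_id``, ``smiles``, ``reason``.  Row conservation
        holds: ``len(drugs) + len(rejected) == len(table)``.
    """
    if isinstance(table, pd.DataFrame):
        rows = list(zip(table["drug_id"].astype(str), table["smiles"].astype(str)))
    else:
        rows = [(str(d), str(s)) for d, s in table]

    ids = [d for d, _ in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({d for d in ids if ids.count(d) > 1})
        raise ValueError(f"duplicate drug_id(s): {dupes}")

    fper = fingerprinter or default_fingerprinter()
    drugs: list[Drug] = []
    rejected: list[dict] = []
    for drug_id, smiles in rows:
        try:
            fp = fper(smiles)
        except InvalidStructureError as err:
            rejected.append(
                {"drug_id": drug_id, "smiles": smiles, "reason": str(err)}
            )
            continue
        drugs.append(Drug(drug_id=drug_id, smiles=smiles, fingerprint=fp))

    if rejected:
        logger.warning(
            "removed %d/%d drugs whose fingerprints could not be extracted",
            len(rejected),
            len(rows),
        )
    return drugs, pd.DataFrame(rejected, columns=["drug_id", "smiles", "reason"])


def read_drug_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited drug table with columns ``drug_id`` and ``smiles``."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"drug_id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"drug table {path} lacks column(s) {sorted(missing)}")
    return df


def write_fingerprint_matrix(drugs: Sequence[Drug], path, sep: str = "\t") -> None:
    """Dump drug fingerprints as delimited text: drug_id + one 0/1 column per bit."""
    if not drugs:
        pd.DataFrame(columns=["drug_id"]).to_csv(path, sep=sep, index=False)
        return
    n = len(drugs[0].fingerprint)
    mat = pd.DataFrame(
        np.vstack([d.fingerprint for d in drugs]),
        columns=[f"f{i + 1}" for i in range(n)],
    )
    mat.insert(0, "drug_id", [d.drug_id for d in drugs])
    mat.to_csv(path, sep=sep, index=False)
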