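"""SMILES validation and Morgan fingerprint encoding.

A molecule enters the model only if rdkit can parse its SMILES; the 2D
structure is then encoded as a binary Morgan (circular-substructure)
fingerprint. Radius 2 over 2048 bits — the ECFP4-equivalent community
standard — is the default; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "Fingerprint",
    "InvalidSMILESError",
    "validate_smiles",
    "morgan_fingerprint",
]

# parse failures are reported through InvalidSMILESError, not the rdkit log
RDLogger.DisableLog("rdApp.error")

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048


class InvalidSMILESError(ValueError):
    """Raised when a SMILES string cannot be parsed; drives compound exclusion."""


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary Morgan fingerprint."""

    bits: np.ndarray
    radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0/1")
        object.__setattr__(self, "bits", bits)

    @property
    def n_bits(self) -> int:
        return self.bits.shape[0]

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def validate_smiles(smiles: str) -> str:
    """Parse a SMILES string and return its canonical form.

    Raises
    ------
    InvalidSMILESError
        If rdkit cannot parse (and sanitise) the input.
    """
    if not smiles or not smiles.strip():
        raise InvalidSMILESError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSMILESError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def smiles_is_valid(smiles: str) -> bool:
    try:
        validate_smiles(smiles)
    except InvalidSMILESError:
        return False
    return True


def morgan_fingerprint(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> Fingerprint:
    """Encode a SMILES as a binary Morgan fingerprint bit vector.

    Counts are binarised; the encoding is deterministic and invariant to the
    atom ordering of the input SMILES (any SMILES of the same molecule yields
    the same bits).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSMILESError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return Fingerprint(bits=bits, radius=radius)
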