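"""Circular substructure fingerprints (Morgan/ECFP) for drug structures.

The corpus convention is radius-2 fingerprints folded to 512 bits. RDKit is
the chemistry backend; it is an optional dependency because synthetic
corpora carry precomputed bit vectors on the record itself.
"""

from __future__ import annotations

import numpy as np

__all__ = ["encode_fingerprint", "fingerprint_bit_names"]

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 512


class StructureParseError(ValueError):
    """Raised when a structure string cannot be parsed as a molecule."""


def fingerprint_bit_names(n_bits: int = DEFAULT_N_BITS) -> list[str]:
    """Stable column names for the fingerprint view (``fp_0000`` ...)."""
    return [f"fp_{i:04d}" for i in range(n_bits)]


def encode_fingerprint(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    drug_id: str | None = None,
) -> np.ndarray:
    """Morgan fingerprint of ``smiles`` folded to ``n_bits`` bits.

    Deterministic: the same structure always yields the same bit vector.

    Raises
    ------
    StructureParseError
        If the structure string is not a valid molecule; the message names
        ``drug_id`` when given.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" for drug {drug_id!r}" if drug_id else ""
        raise StructureParseError(f"unparseable structure {smiles!r}{who}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr
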