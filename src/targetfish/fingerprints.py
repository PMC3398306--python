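"""Binary circular fingerprints and bit-vector arithmetic.

Molecules are represented as fixed-length binary vectors produced by a hashed
circular (Morgan-type) fingerprint: each atom-centred substructural
environment up to a bond radius is hashed into a bit position.  The default
radius-2 / 1024-bit setting is the common ECFP4-like choice; the model layer
only ever sees the bit vectors, so radius and length are free parameters.

All downstream distance computations reduce to Hamming disagreement counts
between bit vectors, computed on bit-packed arrays with XOR + popcount.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 1024


class FingerprintError(ValueError):
    """A compound's structure could not be featurized.

    Carries the offending compound id so callers can log-and-skip or abort.
    """

    def __init__(self, compound_id: str, reason: str):
        self.compound_id = compound_id
        self.reason = reason
        super().__init__(f"compound {compound_id!r}: {reason}")


def featurize_compounds(
    smiles_map: Mapping[str, str],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    on_error: str = "raise",
) -> dict[str, np.ndarray]:
    """Map compound ids to binary circular-fingerprint vectors.

    SMILES are parsed with RDKit, so any two spellings of the same molecule
    yield an identical vector (canonicalization is implicit in the molecular
    graph).  ``on_error`` is ``"raise"`` (abort on the first unparseable
    SMILES) or ``"skip"`` (drop the compound with a logged warning).
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")
    RDLogger.DisableLog("rdApp.error")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out: dict[str, np.ndarray] = {}
    for cid, smi in smiles_map.items():
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is None:
            err = FingerprintError(cid, f"unparseable SMILES {smi!r}")
            if on_error == "raise":
                raise err
            import logging

            logging.getLogger(__name__).warning("skipping %s", err)
            continue
        out[cid] = np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)
    return out


def hamming_disagreement(a: np.ndarray, b: np.ndarray) -> int:
    """Number of bit positions in which two fingerprints disagree."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def pack_bits(vectors: Iterable[np.ndarray]) -> np.ndarray:
    """Stack 0/1 vectors into a bit-packed uint8 matrix (one row per vector)."""
    mat = np.asarray(list(vectors), dtype=np.uint8)
    if mat.ndim != 2:
        raise ValueError("expected a non-empty sequence of equal-length bit vectors")
    return np.packbits(mat, axis=1)


def pairwise_disagreement(queries: np.ndarray, training: np.ndarray) -> np.ndarray:
    """Disagreement-count matrix between two bit-packed row sets.

    ``queries`` (q rows) and ``training`` (t rows) must be packed with
    :func:`pack_bits` from vectors of equal unpacked dimension.  Returns a
    q x t int64 matrix of Hamming disagreements.
    """
    if queries.shape[1] != training.shape[1]:
        raise ValueError("packed width mismatch between query and training sets")
    xor = queries[:, None, :] ^ training[None, :, :]
    return np.bitwise_count(xor).sum(axis=2, dtype=np.int64)
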