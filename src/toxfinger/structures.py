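"""Pluggable structure→fingerprint adapter.

The pipeline consumes fingerprint matrices and never requires a chemistry
backend; this adapter exists for users who start from SMILES.  It computes
Morgan (ECFP-like) bits through RDKit, imported lazily, or falls back to
reading a precomputed matrix.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .fpkit import FingerprintMatrix


def smiles_to_fingerprints(
    smiles: Sequence[str],
    ids: Sequence[str] | None = None,
    n_bits: int = 1024,
    radius: int = 2,
) -> FingerprintMatrix:
    """Compute binary Morgan fingerprints from SMILES via RDKit.

    Raises ImportError with guidance when RDKit is unavailable and
    ValueError on unparseable SMILES.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "RDKit is required for SMILES ingestion; install the 'chem' "
            "extra or provide precomputed fingerprint matrices"
        ) from exc

    ids = list(ids) if ids is not None else [f"mol{i}" for i in
                                             range(len(smiles))]
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits
    )
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        fp = gen.GetFingerprint(mol)
        arr = np.zeros(n_bits)
        for b in fp.GetOnBits():
            arr[b] = 1.0
        rows.append(arr)
    return FingerprintMatrix(
        sample_ids=ids,
        bit_ids=[f"morgan{radius}_{i:04d}" for i in range(n_bits)],
        values=np.vstack(rows) if rows else np.zeros((0, n_bits)),
        mode_tag="binary",
    )
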