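"""Exhaustive nearest-neighbor analysis and fingerprint resolution statistics.

Given a set of MinHashed fingerprints, every molecule's nearest neighbor (self
excluded) is found by a chunked all-pairs scan; molecules whose nearest
neighbor sits at estimated Jaccard distance exactly zero are *indistinguishable*
in that fingerprint space.  Stratifying the counts by hydroxyl group number
separates lipid-like from carbohydrate-like chemistry, and the fingerprint-bin
occupancy (how many molecules share one identical fingerprint) measures how
finely a fingerprint resolves a database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .minhash import MinHashedFingerprint
from .shingling import StandardizedMolecule

__all__ = [
    "NearestNeighborResult",
    "all_nn_distances",
    "count_indistinguishable",
    "hydroxyl_count",
    "bin_occupancy",
]

logger = logging.getLogger(__name__)

_CHUNK = 32  # rows per block in the all-pairs scan (caps the boolean workspace)

#: two-coordinate oxygen bearing exactly one hydrogen: alcohol or acid OH
_HYDROXYL_PATTERN = Chem.MolFromSmarts("[OX2H1]")


@dataclass(frozen=True)
class NearestNeighborResult:
    molecule_id: str
    nn_id: str
    nn_distance: float


def _fp_matrix(fps: Sequence[MinHashedFingerprint]) -> np.ndarray:
    d, seed = fps[0].d, fps[0].seed
    for fp in fps:
        if fp.d != d or fp.seed != seed:
            from .minhash import IncompatibleFingerprintError

            raise IncompatibleFingerprintError("fingerprints must share d and seed")
    return np.stack([fp.values for fp in fps]).astype(np.uint32)


def all_nn_distances(
    fps: Sequence[MinHashedFingerprint], ids: Sequence[str]
) -> list[NearestNeighborResult]:
    """Nearest neighbor of every molecule under estimated Jaccard distance.

    Self-matches are excluded; ties resolve to the lexicographically smallest
    neighbor id.  The scan is O(n^2) in blocks of rows, with progress logging.
    """
    if len(fps) != len(ids) or len(fps) < 2:
        raise ValueError("need >= 2 molecules with aligned ids")
    matrix = _fp_matrix(fps)
    n, d = matrix.shape
    results: list[NearestNeighborResult] = []
    for start in range(0, n, _CHUNK):
        block = matrix[start : start + _CHUNK]
        # matches (b, n): number of equal components against every molecule
        matches = (block[:, None, :] == matrix[None, :, :]).sum(axis=2)
        for bi in range(block.shape[0]):
            i = start + bi
            row = matches[bi].astype(float) / d
            row[i] = -1.0  # exclude self
            best_sim = row.max()
            # smallest id among equally similar neighbors
            tied = np.nonzero(row == best_sim)[0]
            nn = min(tied, key=lambda j: ids[j])
            results.append(
                NearestNeighborResult(
                    molecule_id=ids[i],
                    nn_id=ids[nn],
                    nn_distance=1.0 - float(best_sim),
                )
            )
        if start // _CHUNK % 10 == 0:
            logger.debug("all_nn_distances: %d / %d molecules done", min(start + _CHUNK, n), n)
    return results


def count_indistinguishable(nn_results: Sequence[NearestNeighborResult]) -> int:
    """Molecules whose nearest neighbor has identical fingerprint (JD = 0)."""
    return sum(1 for r in nn_results if r.nn_distance == 0.0)


def hydroxyl_count(mol: StandardizedMolecule | Chem.Mol) -> int:
    """Number of OH groups (alcohols and carboxylic acids alike)."""
    rdmol = mol.mol if isinstance(mol, StandardizedMolecule) else mol
    return len(rdmol.GetSubstructMatches(_HYDROXYL_PATTERN))


def bin_occupancy(
    fps: Sequence[MinHashedFingerprint],
) -> list[tuple[bytes, int]]:
    """Group molecules by identical full fingerprint, largest groups first.

    Returns (fingerprint bytes, molecule count) pairs; group sizes sum to the
    dataset size.  A fingerprint that resolves a database perfectly yields
    only singleton groups.
    """
    counts: dict[bytes, int] = {}
    for fp in fps:
        key = fp.values.astype("<u4").tobytes()
        counts[key] = counts.get(key, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
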