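"""Approximate k-NN search over MinHashed fingerprints with an LSH forest.

Each of the forest's trees views the fingerprint components in its own random
order and stores, sorted, a fixed-depth prefix key per molecule.  A query
descends every tree to the longest prefix it shares with any stored key;
candidates gathered across trees (over-fetched by a constant factor) are then
re-ranked by the estimated Jaccard distance.  Searches are deterministic given
the index seed, and an exhaustive exact search ships alongside as the oracle.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np

from .minhash import MinHashedFingerprint

__all__ = ["LSHForest", "build_forest", "query_knn", "exact_knn", "DuplicateIdError"]

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 32
#: components per tree key; deeper prefixes only sharpen ties at extra memory
KEY_DEPTH = 32
#: candidates gathered before exact re-ranking, as a multiple of k
OVERFETCH = 4
#: floor on the candidate budget: all queries with OVERFETCH*k below this share
#: one candidate set, so growing k only extends the returned ranking (prefix
#: property) besides improving small-k recall
MIN_CANDIDATES = 128


class DuplicateIdError(ValueError):
    """Molecule ids in an index must be unique."""


@dataclass
class _Tree:
    permutation: np.ndarray          # component order for this tree's keys
    keys: list[bytes] = field(default_factory=list)      # sorted
    entries: list[int] = field(default_factory=list)     # row index, aligned


@dataclass
class LSHForest:
    """Prefix-tree index over MinHashed fingerprints (32 trees by default)."""

    d: int
    seed: int
    n_trees: int
    key_depth: int
    trees: list[_Tree]
    ids: list[str]
    matrix: np.ndarray  # (n, d) uint32, for exact re-ranking

    def __len__(self) -> int:
        return len(self.ids)


def _tree_key(values: np.ndarray, perm: np.ndarray) -> bytes:
    return values[perm].astype(">u4").tobytes()


def build_forest(
    fps: list[MinHashedFingerprint],
    ids: list[str],
    n_trees: int = DEFAULT_N_TREES,
    key_depth: int = KEY_DEPTH,
) -> LSHForest:
    """Index fingerprints for approximate nearest-neighbor queries.

    All fingerprints must share dimension and seed; ids must be unique.
    """
    if len(fps) != len(ids) or len(fps) == 0:
        raise ValueError("need equally many fingerprints and ids (>= 1)")
    if len(set(ids)) != len(ids):
        raise DuplicateIdError("duplicate molecule ids in index input")
    d, seed = fps[0].d, fps[0].seed
    for fp in fps:
        if fp.d != d or fp.seed != seed:
            from .minhash import IncompatibleFingerprintError

            raise IncompatibleFingerprintError(
                "all indexed fingerprints must share d and seed"
            )
    key_depth = min(key_depth, d)
    rng = np.random.default_rng(seed)
    matrix = np.stack([fp.values for fp in fps]).astype(np.uint32)
    trees = []
    for _ in range(n_trees):
        perm = rng.permutation(d)[:key_depth]
        keyed = sorted(
            (( _tree_key(matrix[i], perm), i) for i in range(len(fps))),
            key=lambda kv: (kv[0], ids[kv[1]]),
        )
        trees.append(
            _Tree(
                permutation=perm,
                keys=[k for k, _ in keyed],
                entries=[i for _, i in keyed],
            )
        )
    return LSHForest(
        d=d, seed=seed, n_trees=n_trees, key_depth=key_depth,
        trees=trees, ids=list(ids), matrix=matrix,
    )


def _candidates_in_tree(tree: _Tree, qkey: bytes, prefix_bytes: int) -> range:
    prefix = qkey[:prefix_bytes]
    lo = bisect.bisect_left(tree.keys, prefix)
    # any key starting with `prefix` sorts before prefix padded with 0xff
    hi = bisect.bisect_right(tree.keys, prefix + b"\xff" * (len(qkey) - prefix_bytes))
    return range(lo, hi)


def query_knn(
    forest: LSHForest, q: MinHashedFingerprint, k: int
) -> list[tuple[str, float]]:
    """Approximate k nearest neighbors by estimated Jaccard distance.

    Returns at most ``k`` (id, distance) pairs in ascending distance, ties
    broken by id.  Candidate gathering shortens the shared prefix until at
    least ``OVERFETCH * k`` candidates are found (or the prefix is empty, at
    which point every entry is a candidate).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if q.d != forest.d or q.seed != forest.seed:
        from .minhash import IncompatibleFingerprintError

        raise IncompatibleFingerprintError("query incompatible with index")
    qvals = q.values.astype(np.uint32)
    qkeys = [_tree_key(qvals, t.permutation) for t in forest.trees]
    budget = max(OVERFETCH * k, MIN_CANDIDATES)
    candidates: set[int] = set()
    for depth in range(forest.key_depth, -1, -1):
        candidates.clear()
        for tree, qkey in zip(forest.trees, qkeys):
            for pos in _candidates_in_tree(tree, qkey, 4 * depth):
                candidates.add(tree.entries[pos])
        if len(candidates) >= budget or depth == 0:
            break
    return _rank(forest, qvals, sorted(candidates), k)


def _rank(
    forest: LSHForest, qvals: np.ndarray, rows: list[int], k: int
) -> list[tuple[str, float]]:
    if not rows:
        return []
    sub = forest.matrix[rows]
    sims = (sub == qvals[None, :]).mean(axis=1)
    scored = sorted(
        ((1.0 - float(s), forest.ids[r]) for s, r in zip(sims, rows)),
    )
    return [(mid, dist) for dist, mid in scored[:k]]


def exact_knn(
    fps: list[MinHashedFingerprint],
    ids: list[str],
    q: MinHashedFingerprint,
    k: int,
) -> list[tuple[str, float]]:
    """Exhaustive k-NN under the estimated Jaccard distance (oracle).

    Same contract and tie rule as :func:`query_knn`, but scans every entry.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(fps) != len(ids) or not fps:
        raise ValueError("need equally many fingerprints and ids (>= 1)")
    for fp in fps:
        if fp.d != q.d or fp.seed != q.seed:
            from .minhash import IncompatibleFingerprintError

            raise IncompatibleFingerprintError("query incompatible with database")
    matrix = np.stack([fp.values for fp in fps]).astype(np.uint32)
    sims = (matrix == q.values.astype(np.uint32)[None, :]).mean(axis=1)
    scored = sorted((1.0 - float(s), mid) for s, mid in zip(sims, ids))
    return [(mid, dist) for dist, mid in scored[:k]]
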