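"""MinHashing and folding of shingle hash sets.

Shingles are mapped to 32-bit integers via SHA-1 truncation, then either

* **MinHashed**: for each of ``d`` universal-hash permutations
  ``h_i(x) = ((a_i * x + b_i) mod p) mod m`` with ``p = 2^61 - 1`` (Mersenne
  prime) and ``m = 2^32 - 1``, the fingerprint component ``i`` is the minimum
  of ``h_i`` over the hash set.  The fraction of matching components between
  two such fingerprints is an unbiased estimate of the Jaccard similarity of
  the underlying shingle sets; or
* **folded**: bit ``h mod length`` is set for every hash, giving a fixed-length
  binary fingerprint compared with the Dice coefficient.

All arithmetic in the MinHash path is exact unsigned 64-bit integer
arithmetic; ``a*x + b < 2^64`` because ``a, b, x < 2^32``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .shingling import ShingleSet, StandardizedMolecule, parse_and_standardize, shingle_set

__all__ = [
    "MERSENNE_PRIME",
    "MAX_HASH",
    "HashSeeds",
    "MinHashedFingerprint",
    "FoldedFingerprint",
    "IncompatibleFingerprintError",
    "EmptyFingerprintError",
    "hash_shingle",
    "hash_shingle_set",
    "minhash_fingerprint",
    "folded_fingerprint",
    "jaccard_similarity_estimate",
    "jaccard_distance_estimate",
    "exact_jaccard",
    "dice_similarity",
    "Variant",
    "VARIANTS",
    "fingerprint_molecule",
    "fingerprint_smiles",
]

MERSENNE_PRIME = np.uint64((1 << 61) - 1)
MAX_HASH = np.uint64((1 << 32) - 1)

_HASH_CHUNK = 256  # shingle hashes per vectorized MinHash block (cache-friendly)


class IncompatibleFingerprintError(ValueError):
    """Fingerprints with different dimension or seed cannot be compared."""


class EmptyFingerprintError(ValueError):
    """MinHashing requires at least one shingle hash."""


@dataclass(frozen=True)
class HashSeeds:
    """The ``d`` universal-hash coefficient pairs ``(a_i, b_i)``.

    Regenerated deterministically from ``seed`` so that fingerprints computed
    on different machines or runs are bit-identical.
    """

    a: np.ndarray
    b: np.ndarray
    seed: int
    d: int

    @classmethod
    def generate(cls, d: int = 1024, seed: int = 42) -> "HashSeeds":
        if d < 1:
            raise ValueError("d must be >= 1")
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 1 << 32, size=d, dtype=np.uint64)
        b = rng.integers(0, 1 << 32, size=d, dtype=np.uint64)
        return cls(a=a, b=b, seed=seed, d=d)


@dataclass(frozen=True)
class MinHashedFingerprint:
    """Vector of ``d`` per-permutation minima (each ``< 2^32 - 1``)."""

    values: np.ndarray
    radius: int
    d: int
    seed: int
    molecule_id: str = ""

    def __post_init__(self):
        if len(self.values) != self.d:
            raise ValueError("values length must equal d")


@dataclass(frozen=True)
class FoldedFingerprint:
    """Fixed-length bit vector from modulo folding of shingle hashes."""

    bits: np.ndarray
    radius: int
    molecule_id: str = ""

    @property
    def length(self) -> int:
        return len(self.bits)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def hash_shingle(shingle: bytes) -> int:
    """First 4 bytes (big-endian) of the SHA-1 digest of a shingle."""
    if not shingle:
        raise ValueError("shingle must be a non-empty byte-string")
    return int.from_bytes(hashlib.sha1(shingle).digest()[:4], "big")


def hash_shingle_set(shingles: ShingleSet | Iterable[bytes]) -> np.ndarray:
    """SHA-1 truncated hashes of a shingle set, as a deduplicated uint64 array."""
    values = {hash_shingle(s) for s in shingles}
    return np.fromiter(values, dtype=np.uint64, count=len(values))


_SHIFT61 = np.uint64(61)
_SHIFT32 = np.uint64(32)
_MASK32 = np.uint64((1 << 32) - 1)


def _mod_mersenne61_then_32(x: np.ndarray) -> None:
    """In-place ``(x mod 2^61-1) mod 2^32-1`` for uint64 arrays.

    Both moduli are Mersenne-form, so reduction is a digit-sum: shift/mask/add
    followed by one conditional subtract.  Equivalent to the direct ``%`` path
    but without the hardware division; exactness is pinned by tests.
    """
    p = MERSENNE_PRIME
    m = MAX_HASH
    # x < 2^64: one digit-sum pass gives y < 2^61 + 8, one subtract finishes
    y = x >> _SHIFT61
    x &= p
    x += y
    x -= p * (x >= p)
    # x < 2^61, reduce mod 2^32 - 1 with two digit-sum passes
    y = x >> _SHIFT32
    x &= _MASK32
    x += y
    y = x >> _SHIFT32
    x &= _MASK32
    x += y
    x -= m * (x >= m)


def minhash_fingerprint(
    hashes: np.ndarray | Iterable[int],
    seeds: HashSeeds,
    radius: int = 2,
    molecule_id: str = "",
) -> MinHashedFingerprint:
    """MinHash a set of 32-bit shingle hashes into a ``d``-dimensional vector.

    Component ``i`` is ``min over h of ((a_i*h + b_i) mod p) mod m``.
    """
    hs = np.asarray(list(hashes) if not isinstance(hashes, np.ndarray) else hashes, dtype=np.uint64)
    if hs.size == 0:
        raise EmptyFingerprintError("cannot MinHash an empty hash set")
    mins = np.full(seeds.d, MAX_HASH, dtype=np.uint64)
    a, b = seeds.a, seeds.b
    for start in range(0, hs.size, _HASH_CHUNK):
        block = hs[start : start + _HASH_CHUNK]
        # (n, d): a*h + b < 2^64, exact in uint64
        permuted = block[:, None] * a[None, :]
        permuted += b[None, :]
        _mod_mersenne61_then_32(permuted)
        np.minimum(mins, permuted.min(axis=0), out=mins)
    return MinHashedFingerprint(
        values=mins.astype(np.uint32),
        radius=radius,
        d=seeds.d,
        seed=seeds.seed,
        molecule_id=molecule_id,
    )


def folded_fingerprint(
    hashes: np.ndarray | Iterable[int],
    length: int = 2048,
    radius: int = 2,
    molecule_id: str = "",
) -> FoldedFingerprint:
    """Fold shingle hashes into a bit vector: bit ``h mod length`` is set."""
    if length < 1:
        raise ValueError("length must be >= 1")
    bits = np.zeros(length, dtype=bool)
    hs = np.asarray(list(hashes) if not isinstance(hashes, np.ndarray) else hashes, dtype=np.uint64)
    if hs.size:
        bits[(hs % np.uint64(length)).astype(np.int64)] = True
    return FoldedFingerprint(bits=bits, radius=radius, molecule_id=molecule_id)


def jaccard_similarity_estimate(
    f1: MinHashedFingerprint, f2: MinHashedFingerprint
) -> float:
    """Fraction of matching components — unbiased Jaccard estimate."""
    if f1.d != f2.d or f1.seed != f2.seed:
        raise IncompatibleFingerprintError(
            f"cannot compare fingerprints (d={f1.d},seed={f1.seed}) vs (d={f2.d},seed={f2.seed})"
        )
    return float(np.mean(f1.values == f2.values))


def jaccard_distance_estimate(f1: MinHashedFingerprint, f2: MinHashedFingerprint) -> float:
    return 1.0 - jaccard_similarity_estimate(f1, f2)


def exact_jaccard(s1: ShingleSet | set, s2: ShingleSet | set) -> float:
    """|intersection| / |union| of two shingle sets (brute-force oracle)."""
    a = s1.shingles if isinstance(s1, ShingleSet) else set(s1)
    b = s2.shingles if isinstance(s2, ShingleSet) else set(s2)
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / union


def dice_similarity(b1: FoldedFingerprint, b2: FoldedFingerprint) -> float:
    """Dice coefficient ``2|A∩B| / (|A| + |B|)`` on folded bit vectors."""
    if b1.length != b2.length:
        raise IncompatibleFingerprintError(
            f"bit-vector lengths differ: {b1.length} vs {b2.length}"
        )
    pa, pb = b1.popcount, b2.popcount
    if pa + pb == 0:
        raise ValueError("Dice similarity undefined for two all-zero vectors")
    inter = int(np.sum(b1.bits & b2.bits))
    return 2.0 * inter / (pa + pb)


# ---------------------------------------------------------------------------
# Fingerprint variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """One member of the MinHashed atom-pair fingerprint family.

    ``kind`` is ``"minhash"`` (MAP2/4/6/8 at 1024 or 2048 dimensions) or
    ``"folded"`` (foldedAP2/4/6/8 at 2048 bits).  ``include_distance=False``
    yields a substructure-only control in which the topological-distance token
    is removed from every shingle.
    """

    name: str
    radius: int
    dims: int
    kind: str = "minhash"
    include_distance: bool = True

    def __post_init__(self):
        if self.kind not in ("minhash", "folded"):
            raise ValueError(f"unknown variant kind: {self.kind}")
        if self.radius < 1 or self.dims < 1:
            raise ValueError("radius and dims must be >= 1")


def _standard_variants() -> dict[str, Variant]:
    out: dict[str, Variant] = {}
    for r in (1, 2, 3, 4):
        diameter = 2 * r
        for dims in (1024, 2048):
            name = f"MAP{diameter}-{dims}"
            out[name] = Variant(name=name, radius=r, dims=dims, kind="minhash")
        name = f"foldedAP{diameter}"
        out[name] = Variant(name=name, radius=r, dims=2048, kind="folded")
    return out


#: The twelve standard family members: MAP{2,4,6,8} x {1024, 2048} dimensions
#: plus foldedAP{2,4,6,8} at 2048 bits.
VARIANTS: dict[str, Variant] = _standard_variants()

#: Substructure-only control: MAP4 shingles with the distance token deleted.
SUBSTRUCTURE_CONTROL = Variant(
    name="SUB4-1024", radius=2, dims=1024, kind="minhash", include_distance=False
)


def fingerprint_molecule(
    mol: StandardizedMolecule,
    variant: Variant | str = "MAP4-1024",
    seeds: HashSeeds | None = None,
) -> MinHashedFingerprint | FoldedFingerprint:
    """Shingle, hash and compress a standardized molecule under one variant."""
    v = VARIANTS[variant] if isinstance(variant, str) else variant
    shingles = shingle_set(mol, r=v.radius, include_distance=v.include_distance)
    hashes = hash_shingle_set(shingles)
    if v.kind == "minhash":
        if seeds is None:
            seeds = HashSeeds.generate(d=v.dims)
        elif seeds.d != v.dims:
            raise IncompatibleFingerprintError(
                f"seed dimension {seeds.d} does not match variant {v.name}"
            )
        return minhash_fingerprint(
            hashes, seeds, radius=v.radius, molecule_id=mol.molecule_id
        )
    return folded_fingerprint(
        hashes, length=v.dims, radius=v.radius, molecule_id=mol.molecule_id
    )


def fingerprint_smiles(
    smiles: str,
    variant: Variant | str = "MAP4-1024",
    seeds: HashSeeds | None = None,
    molecule_id: str = "",
) -> MinHashedFingerprint | FoldedFingerprint:
    """Convenience path: SMILES in, fingerprint out."""
    mol = parse_and_standardize(smiles, molecule_id=molecule_id)
    return fingerprint_molecule(mol, variant=variant, seeds=seeds)
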