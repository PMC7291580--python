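"""MinHash core: hashing, Eq-style permutation minima, folding, similarities."""

import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapfp.minhash import (
    MAX_HASH,
    MERSENNE_PRIME,
    SUBSTRUCTURE_CONTROL,
    VARIANTS,
    EmptyFingerprintError,
    HashSeeds,
    IncompatibleFingerprintError,
    _mod_mersenne61_then_32,
    dice_similarity,
    exact_jaccard,
    folded_fingerprint,
    hash_shingle,
    jaccard_similarity_estimate,
    minhash_fingerprint,
)


class TestHashShingle:
    def test_sha1_truncation_test_vector(self):
        # first word of the standard SHA-1 digest of "abc"
        assert hash_shingle(b"abc") == 0xA9993E36 == 2_845_392_438

    def test_deterministic(self):
        assert hash_shingle(b"C|2|O") == hash_shingle(b"C|2|O")

    def test_matches_reference_sha1(self, rng):
        for _ in range(50):
            payload = rng.bytes(12)
            expected = int.from_bytes(hashlib.sha1(payload).digest()[:4], "big")
            assert hash_shingle(payload) == expected

    def test_collisions_stay_near_birthday_bound(self, rng):
        n = 200_000
        shingles = {rng.bytes(10) for _ in range(n)}
        values = {hash_shingle(s) for s in shingles}
        # expected collisions ~ n^2 / 2^33 ~ 4.7 for n = 2e5
        assert len(values) >= len(shingles) - 50


class TestModularReduction:
    @given(st.lists(st.integers(0, 2**64 - 1), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=50)
    def test_matches_direct_modulo(self, xs):
        arr = np.array(xs, dtype=np.uint64)
        expected = arr % MERSENNE_PRIME % MAX_HASH
        got = arr.copy()
        _mod_mersenne61_then_32(got)
        assert np.array_equal(expected, got)


class TestMinHashFingerprint:
    def test_singleton_permutation_is_analytic(self):
        # ((3*5 + 7) mod p) mod m = 22
        seeds = HashSeeds(
            a=np.array([3], dtype=np.uint64),
            b=np.array([7], dtype=np.uint64),
            seed=0,
            d=1,
        )
        assert minhash_fingerprint([5], seeds).values[0] == 22

    def test_empty_set_rejected(self, seeds1024):
        with pytest.raises(EmptyFingerprintError):
            minhash_fingerprint([], seeds1024)

    def test_superset_never_increases_components(self, seeds1024, rng):
        base = rng.integers(0, 1 << 32, size=64, dtype=np.uint64)
        extra = np.concatenate([base, rng.integers(0, 1 << 32, size=16, dtype=np.uint64)])
        f1 = minhash_fingerprint(base, seeds1024)
        f2 = minhash_fingerprint(extra, seeds1024)
        assert np.all(f2.values <= f1.values)

    def test_seed_reproducibility(self, rng):
        hashes = rng.integers(0, 1 << 32, size=100, dtype=np.uint64)
        a = minhash_fingerprint(hashes, HashSeeds.generate(256, seed=7))
        b = minhash_fingerprint(hashes, HashSeeds.generate(256, seed=7))
        assert np.array_equal(a.values, b.values)

    def test_values_below_maximum_hash(self, seeds1024, rng):
        hashes = rng.integers(0, 1 << 32, size=50, dtype=np.uint64)
        fp = minhash_fingerprint(hashes, seeds1024)
        assert fp.values.max() < int(MAX_HASH)


class TestFoldedFingerprint:
    def test_empty_set_folds_to_zero_vector(self):
        assert folded_fingerprint([], length=128).popcount == 0

    def test_modulo_collision(self):
        fp = folded_fingerprint([3, 3 + 2048], length=2048)
        assert fp.popcount == 1 and fp.bits[3]

    def test_popcount_bounded_by_set_size(self, rng):
        hashes = rng.integers(0, 1 << 32, size=300, dtype=np.uint64)
        assert folded_fingerprint(hashes, length=2048).popcount <= 300


class TestJaccardEstimate:
    def test_self_similarity_is_one(self, seeds1024, rng):
        fp = minhash_fingerprint(rng.integers(0, 1 << 32, size=50, dtype=np.uint64), seeds1024)
        assert jaccard_similarity_estimate(fp, fp) == 1.0

    def test_disjoint_sets_estimate_near_zero(self, seeds1024, rng):
        f1 = minhash_fingerprint(rng.integers(0, 1 << 31, size=100, dtype=np.uint64), seeds1024)
        f2 = minhash_fingerprint(
            rng.integers(1 << 31, 1 << 32, size=100, dtype=np.uint64), seeds1024
        )
        assert jaccard_similarity_estimate(f1, f2) <= 0.02

    def test_unbiased_for_known_jaccard(self, rng):
        # random 32-bit elements (as SHA-1 output would be), J = 100/200 = 0.5
        pool = np.unique(rng.integers(0, 1 << 32, size=400, dtype=np.uint64))[:200]
        a = pool[:150]
        b = pool[50:]
        estimates = []
        for seed in range(200):
            seeds = HashSeeds.generate(d=128, seed=seed)
            estimates.append(
                jaccard_similarity_estimate(
                    minhash_fingerprint(a, seeds), minhash_fingerprint(b, seeds)
                )
            )
        assert abs(np.mean(estimates) - 0.5) < 0.02

    def test_estimator_within_three_sigma(self, seeds1024, rng):
        ok = 0
        n_pairs = 100
        for _ in range(n_pairs):
            size = int(rng.integers(20, 200))
            overlap = int(rng.integers(1, size))
            shared = rng.integers(0, 1 << 32, size=overlap, dtype=np.uint64)
            only_a = rng.integers(0, 1 << 32, size=size - overlap, dtype=np.uint64)
            only_b = rng.integers(0, 1 << 32, size=size - overlap, dtype=np.uint64)
            sa = np.unique(np.concatenate([shared, only_a]))
            sb = np.unique(np.concatenate([shared, only_b]))
            j = exact_jaccard(set(sa.tolist()), set(sb.tolist()))
            est = jaccard_similarity_estimate(
                minhash_fingerprint(sa, seeds1024), minhash_fingerprint(sb, seeds1024)
            )
            sigma = np.sqrt(max(j * (1 - j), 1e-12) / 1024)
            ok += abs(est - j) <= 3 * sigma + 1e-12
        assert ok >= 95

    def test_incompatible_fingerprints_rejected(self, rng):
        h = rng.integers(0, 1 << 32, size=20, dtype=np.uint64)
        f1 = minhash_fingerprint(h, HashSeeds.generate(128, seed=1))
        f2 = minhash_fingerprint(h, HashSeeds.generate(128, seed=2))
        with pytest.raises(IncompatibleFingerprintError):
            jaccard_similarity_estimate(f1, f2)


class TestExactJaccardAndDice:
    def test_exact_jaccard_examples(self):
        assert exact_jaccard({b"a", b"b", b"c"}, {b"b", b"c", b"d"}) == 0.5
        assert exact_jaccard({b"a"}, {b"a"}) == 1.0
        assert exact_jaccard({b"a"}, {b"b"}) == 0.0

    def test_dice_examples(self):
        b1 = folded_fingerprint([1, 2, 3, 4], length=64)
        b2 = folded_fingerprint([3, 4, 5, 6, 7, 8], length=64)
        assert dice_similarity(b1, b2) == pytest.approx(2 * 2 / 10)
        assert dice_similarity(b1, b1) == 1.0

    def test_dice_undefined_for_empty_vectors(self):
        z = folded_fingerprint([], length=64)
        with pytest.raises(ValueError):
            dice_similarity(z, z)

    def test_dice_length_mismatch(self):
        with pytest.raises(IncompatibleFingerprintError):
            dice_similarity(folded_fingerprint([1], 64), folded_fingerprint([1], 128))

    def test_fold_dice_tracks_exact_set_dice_when_collisions_rare(self, rng):
        for _ in range(10):
            a = set(rng.integers(0, 1 << 32, size=40, dtype=np.uint64).tolist())
            b = set(rng.integers(0, 1 << 32, size=40, dtype=np.uint64).tolist()) | set(
                list(a)[:20]
            )
            exact_dice = 2 * len(a & b) / (len(a) + len(b))
            folded_dice = dice_similarity(
                folded_fingerprint(np.fromiter(a, np.uint64), 2048),
                folded_fingerprint(np.fromiter(b, np.uint64), 2048),
            )
            assert abs(folded_dice - exact_dice) <= 0.05


class TestVariantMatrix:
    def test_twelve_standard_variants(self):
        assert len(VARIANTS) == 12
        minhashed = [v for v in VARIANTS.values() if v.kind == "minhash"]
        folded = [v for v in VARIANTS.values() if v.kind == "folded"]
        assert len(minhashed) == 8 and len(folded) == 4
        assert {v.radius for v in VARIANTS.values()} == {1, 2, 3, 4}
        assert {v.dims for v in minhashed} == {1024, 2048}
        assert all(v.dims == 2048 for v in folded)

    def test_control_variant_strips_distance(self):
        assert SUBSTRUCTURE_CONTROL.include_distance is False
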