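# Methods notes

This note records the modelling and engineering decisions behind `mapfp`:
what is computed, which choices were genuinely open, and what the synthetic
test corpora do and do not demonstrate.

## Molecule standardization

Inputs are parsed with RDKit. Standardization keeps the largest fragment by
heavy-atom count (ties broken by the lexicographically smaller canonical
SMILES), removes stereochemistry by default (the fingerprint is defined on
non-isomeric SMILES; a flag retains it), and rejects molecules with fewer
than two heavy atoms — a single atom admits no atom pair. After
canonicalization the molecule is re-parsed so that atom indices are the
canonical ones; every downstream quantity is therefore independent of the
input atom numbering (a property the test suite checks on randomized
renderings).

## Shingling

The radius-*r′* environment of an atom is the **vertex-induced subgraph** of
all atoms within *r′* bonds of the center: bonds between two included atoms
are always retained, so ring closures inside the ball survive. The
environment is written as a canonical, non-isomeric SMILES rooted at the
center. Hydrogens are implicit throughout — they are neither centers nor
environment vertices.

A shingle is the UTF-8 byte-string `A|d|B` with `A ≤ B` lexicographically
and `d` the unpadded decimal bond-count distance. `|` cannot occur in
SMILES, so the three fields are always recoverable. Self-pairs are excluded;
each unordered pair contributes once per radius value; the result is a set
(duplicates collapse). For *n* heavy atoms this bounds the set size by
*r·n(n−1)/2*.

A *substructure-only control* variant deletes the distance token from every
shingle. It deliberately discards molecular shape and exists to quantify
what the atom-pair term contributes: scrambled heptapeptides (KLLKKLL vs
KLKKLLL) and long-chain alkanol homologs collapse to identical shingle sets
under the control but stay pairwise distinct under the full shingles.

## Hashing and MinHash

Shingles map to 32-bit integers as the first four bytes (big-endian) of
their SHA-1 digest; the exact truncation is pinned by test vectors. The
MinHash uses one universal-hash permutation per component,
`h_i(x) = ((a_i x + b_i) mod p) mod m` with `p = 2^61 − 1`, `m = 2^32 − 1`
and `a_i, b_i` drawn uniformly from `{0, …, 2^32 − 1}` by a NumPy
`default_rng` seeded generator (default seed 42). Dimension and seed are
recorded inside every fingerprint so that incompatible comparisons raise
instead of silently returning noise.

All arithmetic is exact unsigned 64-bit: `a·x + b < 2^64` because all three
operands are below 2^32. Both moduli are Mersenne-form, so the reduction is
implemented as digit-sum shifts plus one conditional subtract rather than
hardware division (~5× faster); a property test asserts bit-equality with
the direct `%` path over the full uint64 range.

One numerical caveat: a single linear permutation is only approximately
min-wise independent. On adversarially structured hash sets (e.g. arithmetic
progressions of small integers) the Jaccard estimator is visibly biased; on
SHA-1-distributed inputs — the only inputs the fingerprint ever produces —
the bias is negligible and the estimator behaves as unbiased within
binomial error (checked at d = 1024 over random set pairs: ≥ 95 % within
3σ).

Folded variants set bit `x mod 2048`; they trade the estimator property for
a fixed-length bit vector and are compared with Dice similarity, which is
undefined (and raises) for two empty vectors.

### Variant matrix

Twelve standard family members are exposed: MAP2/4/6/8 (radii 1–4) at 1024
and 2048 dimensions, and foldedAP2/4/6/8 at 2048 bits. Defaults follow the
best-performing configuration: MAP4 at d = 1024 for screening, d = 512 for
search indexes (halving d halves index memory at a small recall cost).

## Peptide structures

Sequences over the 20 proteogenic one-letter codes are assembled into linear
peptide SMILES by amide condensation of residue templates (backbone
`N–Cα–C(=O)` with the side chain on Cα; proline's ring includes the backbone
nitrogen). Heavy-atom counts therefore equal the sum of free-residue heavy
atoms minus one oxygen per bond, which the tests verify against RDKit.
"Protonated" means: N-terminal ammonium, Lys ammonium, Arg guanidinium;
His and the carboxylic acids stay neutral; the C-terminus is the free acid.
This is one defensible physiological-pH convention — the convention is a
config table (`protonate=False` gives the neutral forms), so a different
one can be matched if required. Chirality is never written (the fingerprint
is non-isomeric).

## Benchmark datasets

Per query peptide two analog families are generated:

* **scrambled** — unique uniform-random permutations of the query's residue
  multiset, query excluded. Requesting more members than distinct
  permutations exist raises; generation is rejection sampling with a retry
  bound.
* **mutated** — for each Hamming distance k = 1…L, `ceil(10000/L)` unique
  sequences differing from the query in exactly k positions, each mutated
  position receiving a uniformly chosen different residue; blocks
  concatenate in ascending k and truncate to the 10,000-member cap. For
  short queries the k = 1 space is smaller than the per-k target (a 10-mer
  has only 190 single-point mutants), so the per-k count is additionally
  capped by the number of distinct mutants that exist: 10-mers yield 9,190
  members, 20-mers 9,880, 30-mers the full 10,000 (truncated from 10,020).
  The full-size 10-mer count is combinatorially unattainable under
  uniqueness, and the corresponding acceptance test records that fact.

Labelling is a separable stage. The primary labeller runs `blastp` against
a `makeblastdb` database of the members (gap open 11 / extend 1, E = 10,
word size 3, BLOSUM62, SEG on, 500-hit default cap — note the cap, not the
E-threshold, is what bounds actives at 500 in large mutated sets) and marks
E < 10 hits active. An offline stub labels members active when positional
identity to the query is ≥ 30 %; it mimics the shape of homology labels
without BLAST statistics and is what the desk-scale screens and fixtures
use.

## Screening metrics

Scores come from max fusion: a member's score is its best similarity to any
of the query actives (Jaccard estimate for MinHashed, Dice for folded
variants). Ranking ties are resolved **pessimistically** — decoys precede
actives within a tie block — so enrichment never benefits from degenerate
scores. AUC is the Mann–Whitney statistic with ties counting ½ (average
ranks). EF(x) uses a top set of `ceil(x·N)`. RIE is the exponentially
weighted active-rank sum normalized by its uniform-ranking expectation
(closed-form geometric series); BEDROC rescales RIE between its exact
discrete worst- and best-case values, giving endpoints of exactly 0 and 1.
All four agree with RDKit's independent `ML.Scoring` implementations to
1e-9 on tie-free rankings, and with direct-summation oracles on enumerable
toy cases.

The default repetition scheme screens each dataset five times with five
query actives drawn per repetition (both configurable); variants are then
compared by per-metric average rank across datasets, ties sharing the mean
rank. The stored-training-list protocol (many pre-drawn query/decoy
subsets) is expressible through the same `run_benchmark` entry point by
supplying repetition draws via the seed.

## LSH forest

32 trees; each tree views the fingerprint components in its own random
order (permutations derived deterministically from the fingerprint seed)
and stores a sorted 32-component prefix key per molecule. A query descends
all trees simultaneously, shortening the shared prefix until at least
`max(4k, 128)` candidates are gathered, then re-ranks candidates by the
exact estimated Jaccard distance with ties broken by id. The fixed 128
candidate floor makes all small-k queries share one candidate set, so
growing k only extends the returned ranking (the prefix property); beyond
k = 32 the budget grows with k and the property is no longer guaranteed.
Key depth, tree count and over-fetch factor are engineering choices, set so
that recall@10 against the exhaustive oracle exceeds 0.8 with a wide margin
(measured ≈ 0.99 on the 1,000-molecule synthetic corpus).

## Nearest-neighbor analysis

The all-pairs scan is exact and chunked (32 rows per block) to bound the
boolean workspace; "indistinguishable" means all fingerprint components
equal (estimated JD = 0), which is the operational notion an LSH index
sees — the raw shingle-set comparison ships as an oracle for verifying
zero-distance calls. Hydroxyl counting matches any two-coordinate oxygen
bearing exactly one hydrogen (SMARTS `[OX2H1]`), so carboxylic-acid OH
counts along with alcohols; this single pattern is a documented choice.

## Synthetic corpora and what the tests show

The fixture generator assembles drug-like SMILES from randomized scaffold
templates and chain/ring fragments, validated and canonicalized through the
standardization path, plus the 30 query peptides with stub-labelled analog
sets and a C2–C20 alkanol homolog series. These corpora exercise every code
path deterministically, but they are synthetic: they do not reproduce the
property distributions, activity structure, or scale of curated databases,
so passing tests demonstrate correctness of the operations and the
qualitative discrimination behaviors, not field performance on real
screening collections.

Desk-scale problem sizes used by the tests and the acceptance script:
full-size (10,000-member) analog sets for the counting and BLAST-labelling
checks; 200-member scrambled sets × 3 queries × 3 repetitions for the
MAP4-vs-control screen; 1,000 molecules for LSH recall; 100 molecules × 10
renderings for order invariance; 100 random set pairs at d = 1024 for
estimator accuracy.

## Known limitations

* Exact hash values are implementation-defined (SHA-1 truncation and seed
  scheme); similarity-level behavior, not byte-level fingerprints, is the
  portable contract.
* Cyclic, branched, or D-amino-acid peptides are out of scope for the
  sequence-to-structure builder.
* The linear universal hash's min-wise independence caveat above.
* Tree-map layout/visualization of indexes is out of scope; the LSH forest
  serves search only.
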