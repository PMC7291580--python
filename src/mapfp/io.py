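"""File formats, fixture corpora, and persistence.

Covers the plain-text surfaces (SMILES lists, FASTA via Biopython, TSV dataset
manifests), a compact versioned binary store for fingerprints, and the
deterministic synthetic corpora used for desk-scale testing: template-derived
drug-like small molecules, random query peptides with scrambled/mutated analog
sets, and a homolog alkanol series.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .minhash import FoldedFingerprint, MinHashedFingerprint
from .peptides import (
    BenchmarkSet,
    PeptideSequence,
    generate_mutated_set,
    generate_scrambled_set,
    identity_stub_labeller,
    random_query_sequences,
)
from .shingling import MoleculeError, parse_and_standardize

__all__ = [
    "FormatError",
    "read_smiles_file",
    "write_smiles_file",
    "read_fasta",
    "write_fasta",
    "write_dataset_manifest",
    "read_dataset_manifest",
    "write_fingerprints",
    "read_fingerprints",
    "FixtureCorpus",
    "make_fixtures",
    "alkanol_series",
]

logger = logging.getLogger(__name__)

_MAGIC = b"MAPF"
_VERSION = 1


class FormatError(ValueError):
    """A persisted file does not match the expected binary layout."""


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------

def read_smiles_file(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(smiles, id)`` from a one-molecule-per-line SMILES file.

    Line format is ``<smiles>[<whitespace><id>]``; lines starting with ``#``
    and blank lines are ignored; ids default to ``mol_<line>``.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mid = parts[1].strip() if len(parts) > 1 else f"mol_{lineno}"
            yield smiles, mid


def write_smiles_file(path: str | Path, records: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for smiles, mid in records:
            fh.write(f"{smiles}\t{mid}\n")


def read_fasta(path: str | Path) -> Iterator[PeptideSequence]:
    for record in SeqIO.parse(str(path), "fasta"):
        yield PeptideSequence(str(record.seq), id=record.id)


def write_fasta(path: str | Path, peptides: Sequence[PeptideSequence]) -> None:
    records = [
        SeqRecord(Seq(p.residues), id=p.id or f"pep_{i}", description="")
        for i, p in enumerate(peptides)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_dataset_manifest(path: str | Path, benchmark_set: BenchmarkSet) -> None:
    """TSV manifest ``sequence  label  kind  k`` (k empty for scrambled sets)."""
    ks = benchmark_set.hamming_k or [None] * len(benchmark_set.members)
    with open(path, "w") as fh:
        fh.write("sequence\tlabel\tkind\tk\n")
        for (seq, label), k in zip(benchmark_set.members, ks):
            fh.write(f"{seq}\t{label}\t{benchmark_set.kind}\t{'' if k is None else k}\n")


def read_dataset_manifest(
    path: str | Path, query: PeptideSequence, seed: int = 0
) -> BenchmarkSet:
    members: list[tuple[str, str]] = []
    ks: list[int] = []
    kind = "scrambled"
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence\t"):
            raise FormatError(f"{path}: not a dataset manifest")
        for line in fh:
            seq, label, kind, k = line.rstrip("\n").split("\t")
            members.append((seq, label))
            if k:
                ks.append(int(k))
    return BenchmarkSet(
        query=query, members=members, kind=kind, seed=seed,
        hamming_k=ks if ks else None,
    )


# ---------------------------------------------------------------------------
# Fingerprint store
# ---------------------------------------------------------------------------

_HEADER = struct.Struct("<4sBBBIqQ")  # magic, version, kind, radius, dims, seed, count


def write_fingerprints(
    path: str | Path,
    fps: Sequence[MinHashedFingerprint | FoldedFingerprint],
) -> None:
    """Persist a homogeneous fingerprint list plus a sidecar id file.

    MinHashed records are little-endian 32-bit words; folded records are
    packed bits.  Mixed-variant input is rejected.
    """
    if not fps:
        raise ValueError("nothing to write")
    first = fps[0]
    kind = 0 if isinstance(first, MinHashedFingerprint) else 1
    radius = first.radius
    if kind == 0:
        dims, seed = first.d, first.seed
        homogeneous = all(
            isinstance(f, MinHashedFingerprint)
            and (f.d, f.seed, f.radius) == (dims, seed, radius)
            for f in fps
        )
    else:
        dims, seed = first.length, 0
        homogeneous = all(
            isinstance(f, FoldedFingerprint)
            and (f.length, f.radius) == (dims, radius)
            for f in fps
        )
    if not homogeneous:
        raise ValueError("mixed fingerprint variants cannot share a store")
    path = Path(path)
    with path.open("wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, _VERSION, kind, radius, dims, seed, len(fps)))
        for fp in fps:
            if kind == 0:
                fh.write(fp.values.astype("<u4").tobytes())
            else:
                fh.write(np.packbits(fp.bits).tobytes())
    ids_path = path.with_suffix(path.suffix + ".ids")
    ids_path.write_text(
        "".join(f"{fp.molecule_id}\n" for fp in fps)
    )


def read_fingerprints(
    path: str | Path,
) -> list[MinHashedFingerprint] | list[FoldedFingerprint]:
    """Bit-exact round trip of :func:`write_fingerprints`."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER.size:
        raise FormatError(f"{path}: truncated header")
    magic, version, kind, radius, dims, seed, count = _HEADER.unpack_from(raw)
    if magic != _MAGIC or version != _VERSION:
        raise FormatError(f"{path}: bad magic or version")
    record_size = 4 * dims if kind == 0 else (dims + 7) // 8
    expected = _HEADER.size + record_size * count
    if len(raw) != expected:
        raise FormatError(f"{path}: expected {expected} bytes, found {len(raw)}")
    ids_path = path.with_suffix(path.suffix + ".ids")
    ids = ids_path.read_text().splitlines() if ids_path.exists() else [""] * count
    if len(ids) != count:
        raise FormatError(f"{ids_path}: id count does not match record count")
    out = []
    offset = _HEADER.size
    for i in range(count):
        chunk = raw[offset : offset + record_size]
        offset += record_size
        if kind == 0:
            values = np.frombuffer(chunk, dtype="<u4").astype(np.uint32)
            out.append(
                MinHashedFingerprint(
                    values=values, radius=radius, d=dims, seed=seed,
                    molecule_id=ids[i],
                )
            )
        else:
            bits = np.unpackbits(np.frombuffer(chunk, dtype=np.uint8))[:dims].astype(bool)
            out.append(
                FoldedFingerprint(bits=bits, radius=radius, molecule_id=ids[i])
            )
    return out


# ---------------------------------------------------------------------------
# Synthetic fixture corpora
# ---------------------------------------------------------------------------

_TEMPLATES = [
    "CC({R})Nc1ccccc1",
    "O=C({R})Nc1ccc(C)cc1",
    "CN(C){R}",
    "c1ccc({R})nc1",
    "CC(=O)N({R})C",
    "OC({R})c1ccccc1",
    "{R}c1ccc(Cl)cc1",
    "CC(C)({R})O",
    "N#Cc1ccc({R})cc1",
    "O=S(=O)(N){R}",
    "O=C(O){R}",
    "COc1ccc({R})cc1",
]

_CHAIN_UNITS = ["C", "CC", "CO", "CN", "CCO", "CCN", "C(C)", "C(=O)", "CS", "C(F)"]

_TERMINAL_RINGS = ["", "c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCNCC1", "c1ccc(F)cc1", "c1ccco1"]


@dataclass
class FixtureCorpus:
    """Deterministic desk-scale stand-in corpora (synthetic, not real data)."""

    molecules: list[tuple[str, str]]            # (canonical smiles, id)
    queries: list[PeptideSequence]
    benchmark_sets: list[BenchmarkSet]          # stub-labelled
    alkanols: list[str]
    seed: int


def _random_fragment(rng: np.random.Generator) -> str:
    n_units = int(rng.integers(1, 4))
    frag = "".join(rng.choice(_CHAIN_UNITS) for _ in range(n_units))
    frag += str(rng.choice(_TERMINAL_RINGS))
    return frag


def alkanol_series(min_carbons: int = 2, max_carbons: int = 20) -> list[str]:
    """Linear alkan-1-ols C_n H_{2n+1} OH — a homolog series differing only in
    chain length, the classic probe of size perception."""
    return ["C" * n + "O" for n in range(min_carbons, max_carbons + 1)]


def make_fixture_molecules(
    n: int = 200, seed: int = 0
) -> list[tuple[str, str]]:
    """``n`` unique, standardizable drug-like SMILES from randomized templates."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 500 * n:
            raise RuntimeError("fixture molecule generation stalled")
        template = str(rng.choice(_TEMPLATES))
        smiles = template.replace("{R}", _random_fragment(rng))
        try:
            mol = parse_and_standardize(smiles)
        except MoleculeError:
            continue
        if mol.canonical_smiles in seen:
            continue
        seen.add(mol.canonical_smiles)
        out.append((mol.canonical_smiles, f"fix_{len(out):04d}"))
    return out


def make_fixtures(
    seed: int = 0,
    n_molecules: int = 200,
    n_queries: int | None = None,
    members_per_set: int = 1000,
) -> FixtureCorpus:
    """Assemble the full deterministic fixture corpus.

    Per query peptide, one scrambled and one mutated analog set are generated
    and labelled with the positional-identity stub labeller.  ``n_queries``
    limits the number of query peptides used (all 30 by default).
    """
    molecules = make_fixture_molecules(n=n_molecules, seed=seed)
    queries = random_query_sequences(seed=seed + 1)
    if n_queries is not None:
        queries = queries[:n_queries]
    benchmark_sets: list[BenchmarkSet] = []
    for qi, q in enumerate(queries):
        for kind, gen in (
            ("scrambled", generate_scrambled_set),
            ("mutated", generate_mutated_set),
        ):
            bset = gen(q, members_per_set, seed=seed + 100 + qi)
            labels = identity_stub_labeller(q, bset.sequences)
            bset.members = list(zip(bset.sequences, labels))
            benchmark_sets.append(bset)
    return FixtureCorpus(
        molecules=molecules,
        queries=queries,
        benchmark_sets=benchmark_sets,
        alkanols=alkanol_series(),
        seed=seed,
    )
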