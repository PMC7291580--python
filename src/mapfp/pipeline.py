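"""Glue joining peptide datasets, fingerprint variants, and the benchmark.

Turns labelled peptide analog sets into screening datasets (sequence ->
protonated SMILES), fingerprints them under any family variant with per-run
caching, and drives :func:`mapfp.screening.run_benchmark`.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .minhash import (
    FoldedFingerprint,
    HashSeeds,
    MinHashedFingerprint,
    VARIANTS,
    Variant,
    dice_similarity,
    fingerprint_molecule,
    jaccard_similarity_estimate,
)
from .peptides import BenchmarkSet, peptide_to_smiles
from .screening import ScreeningDataset, run_benchmark
from .shingling import parse_and_standardize

__all__ = [
    "screening_dataset_from_benchmark_set",
    "variant_similarity",
    "make_fingerprint_fn",
    "run_peptide_benchmark",
    "benchmark_manifests",
]

logger = logging.getLogger(__name__)


def screening_dataset_from_benchmark_set(bset: BenchmarkSet) -> ScreeningDataset:
    """Convert a labelled peptide analog set into SMILES structures + labels."""
    structures = [peptide_to_smiles(seq) for seq, _ in bset.members]
    labels = [label for _, label in bset.members]
    return ScreeningDataset(
        name=f"{bset.query.id or bset.query.residues}_{bset.kind}",
        structures=structures,
        labels=labels,
    )


def variant_similarity(variant: Variant):
    """Similarity appropriate for a variant: Jaccard estimate or Dice."""
    if variant.kind == "minhash":
        return jaccard_similarity_estimate
    return dice_similarity


def make_fingerprint_fn(seed: int = 42):
    """Fingerprint factory with per-(structure, variant) caching.

    Scrambled analog sets reuse residue compositions heavily, so caching by
    canonical SMILES avoids recomputing identical fingerprint inputs.
    """
    seeds_cache: dict[int, HashSeeds] = {}
    fp_cache: dict[tuple[str, str], MinHashedFingerprint | FoldedFingerprint] = {}

    def fingerprint_fn(structures: Sequence[str], variant: Variant):
        if variant.kind == "minhash" and variant.dims not in seeds_cache:
            seeds_cache[variant.dims] = HashSeeds.generate(d=variant.dims, seed=seed)
        seeds = seeds_cache.get(variant.dims)
        out = []
        for smi in structures:
            key = (smi, variant.name)
            if key not in fp_cache:
                mol = parse_and_standardize(smi)
                fp_cache[key] = fingerprint_molecule(mol, variant=variant, seeds=seeds)
            out.append(fp_cache[key])
        return out

    return fingerprint_fn


def run_peptide_benchmark(
    benchmark_sets: Sequence[BenchmarkSet],
    variants: Sequence[Variant | str],
    seed: int = 0,
    repetitions: int = 5,
    queries_per_repetition: int = 5,
    fingerprint_seed: int = 42,
) -> pd.DataFrame:
    """Screen labelled peptide analog sets with the requested variants."""
    resolved = [VARIANTS[v] if isinstance(v, str) else v for v in variants]
    datasets = [screening_dataset_from_benchmark_set(b) for b in benchmark_sets]
    return run_benchmark(
        datasets,
        resolved,
        fingerprint_fn=make_fingerprint_fn(seed=fingerprint_seed),
        similarity_fn=variant_similarity,
        repetitions=repetitions,
        queries_per_repetition=queries_per_repetition,
        seed=seed,
    )


def benchmark_manifests(
    manifest_paths: Sequence[str],
    queries_fasta: str,
    variant_names: Sequence[str],
    seed: int = 0,
    repetitions: int = 5,
    queries_per_repetition: int = 5,
) -> pd.DataFrame:
    """CLI entry: load labelled TSV manifests and run the benchmark."""
    from . import io as mio
    from pathlib import Path

    queries = {q.id: q for q in mio.read_fasta(queries_fasta)}
    sets = []
    for path in manifest_paths:
        stem = Path(path).stem
        qid, _, kind = stem.rpartition("_")
        if qid not in queries:
            raise ValueError(f"{path}: no query {qid!r} in {queries_fasta}")
        sets.append(mio.read_dataset_manifest(path, queries[qid]))
    return run_peptide_benchmark(
        sets,
        variant_names,
        seed=seed,
        repetitions=repetitions,
        queries_per_repetition=queries_per_repetition,
    )
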