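"""Atom-pair molecular shingling.

A molecule is decomposed into *atom-pair shingles*: for every unordered pair
of heavy atoms ``(j, k)`` and every radius ``1..r``, the circular substructures
around ``j`` and ``k`` are written as canonical rooted SMILES and joined with
the topological (bond-count) distance separating the pair::

    min(CS, CS') | distance | max(CS, CS')

The two SMILES are placed in lexicographical order so that a shingle does not
depend on the orientation of the pair.  The resulting set of byte-strings is
the substrate of the MinHashed atom-pair fingerprints in :mod:`mapfp.minhash`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "MoleculeError",
    "InvalidStructureError",
    "TooSmallError",
    "StandardizedMolecule",
    "ShingleSet",
    "parse_and_standardize",
    "circular_environment_smiles",
    "topological_distances",
    "shingle_set",
    "corpus_unique_shingles",
    "SHINGLE_SEPARATOR",
]

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Field separator inside a shingle.  ``|`` never occurs in SMILES, so the
#: three fields can always be recovered unambiguously.
SHINGLE_SEPARATOR = b"|"

MIN_HEAVY_ATOMS = 2


class MoleculeError(ValueError):
    """Base class for molecule standardization failures."""


class InvalidStructureError(MoleculeError):
    """The input SMILES could not be parsed into a molecule."""


class TooSmallError(MoleculeError):
    """The standardized molecule has fewer than two heavy atoms."""


@dataclass(frozen=True)
class StandardizedMolecule:
    """A parsed, canonicalized, single-fragment heavy-atom graph.

    Hydrogens are implicit throughout: they are never shingle centers nor
    environment vertices.  Stereochemistry is stripped by default so that the
    canonical SMILES is non-isomeric.
    """

    mol: Chem.Mol
    source_smiles: str
    canonical_smiles: str
    molecule_id: str = ""

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumAtoms()


@dataclass(frozen=True)
class ShingleSet:
    """Set of atom-pair shingle byte-strings for one molecule.

    ``radius`` is the maximal circular-substructure radius r; every radius
    value ``1..r`` contributes shingles.  For a single-fragment molecule with
    n heavy atoms the set holds at most ``r * n * (n - 1) / 2`` members.
    """

    shingles: frozenset[bytes]
    radius: int
    molecule_id: str = ""

    def __len__(self) -> int:
        return len(self.shingles)

    def __iter__(self) -> Iterator[bytes]:
        return iter(self.shingles)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) == 1:
        return mol
    # largest by heavy-atom count; ties resolved by smallest canonical SMILES
    best = max(frags, key=lambda f: (f.GetNumAtoms(), _neg_smiles_key(f)))
    return best


class _neg_smiles_key:
    """Orders molecules so that max() prefers the lexicographically smaller SMILES."""

    def __init__(self, mol: Chem.Mol):
        self.smi = Chem.MolToSmiles(mol)

    def __lt__(self, other: "_neg_smiles_key") -> bool:
        return self.smi > other.smi


def parse_and_standardize(
    smiles: str, strip_stereo: bool = True, molecule_id: str = ""
) -> StandardizedMolecule:
    """Parse a SMILES and standardize it for shingling.

    The largest fragment (by heavy-atom count) is retained for multi-fragment
    inputs, stereo descriptors are removed when ``strip_stereo`` is set, and
    molecules with fewer than two heavy atoms are rejected.

    Raises
    ------
    InvalidStructureError
        If the SMILES cannot be parsed.
    TooSmallError
        If fewer than 2 heavy atoms remain after standardization.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"cannot parse SMILES: {smiles!r}")
    mol = _largest_fragment(mol)
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    if mol.GetNumAtoms() < MIN_HEAVY_ATOMS:
        raise TooSmallError(
            f"{smiles!r}: fewer than {MIN_HEAVY_ATOMS} heavy atoms after standardization"
        )
    canonical = Chem.MolToSmiles(mol, isomericSmiles=not strip_stereo)
    # re-parse so atom numbering is the canonical one, independent of input order
    mol = Chem.MolFromSmiles(canonical)
    return StandardizedMolecule(
        mol=mol,
        source_smiles=smiles,
        canonical_smiles=canonical,
        molecule_id=molecule_id,
    )


def circular_environment_smiles(
    mol: StandardizedMolecule, atom_index: int, radius: int
) -> str:
    """Canonical rooted SMILES of the circular substructure around one atom.

    The environment is the vertex-induced subgraph of all atoms within
    ``radius`` bonds of the center (every bond between two included atoms is
    retained, so ring closures inside the ball survive).  The SMILES is rooted
    at the center atom, canonical, and non-isomeric, hence independent of the
    input atom numbering.
    """
    n = mol.num_heavy_atoms
    if not 0 <= atom_index < n:
        raise IndexError(f"atom index {atom_index} out of range for {n} atoms")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    dists = topological_distances(mol)
    atoms = [int(a) for a in np.nonzero(dists[atom_index] <= radius)[0]]
    return Chem.MolFragmentToSmiles(
        mol.mol,
        atomsToUse=atoms,
        rootedAtAtom=atom_index,
        canonical=True,
        isomericSmiles=False,
    )


def topological_distances(mol: StandardizedMolecule) -> np.ndarray:
    """Symmetric matrix of shortest-path bond counts between heavy atoms."""
    return Chem.GetDistanceMatrix(mol.mol).astype(np.int32)


def _environments(mol: StandardizedMolecule, r: int, dists: np.ndarray) -> list[list[bytes]]:
    """Per-atom rooted environment SMILES for every radius 1..r, as bytes."""
    envs: list[list[bytes]] = []
    for idx in range(mol.num_heavy_atoms):
        row = dists[idx]
        per_atom: list[bytes] = []
        for rad in range(1, r + 1):
            atoms = [int(a) for a in np.nonzero(row <= rad)[0]]
            smi = Chem.MolFragmentToSmiles(
                mol.mol,
                atomsToUse=atoms,
                rootedAtAtom=idx,
                canonical=True,
                isomericSmiles=False,
            )
            per_atom.append(smi.encode("utf-8"))
        envs.append(per_atom)
    return envs


def shingle_set(
    mol: StandardizedMolecule, r: int = 2, include_distance: bool = True
) -> ShingleSet:
    """All atom-pair shingles of a molecule up to radius ``r``.

    One shingle ``min(CS,CS')|TP|max(CS,CS')`` is emitted for every unordered
    heavy-atom pair and every radius ``1..r``; the result is deduplicated.

    ``include_distance=False`` drops the topological-distance token, which
    degrades the shingles to a pure circular-substructure description.  This
    control variant deliberately discards molecular shape and is used to
    demonstrate what the distance term contributes.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    dists = topological_distances(mol)
    envs = _environments(mol, r, dists)
    n = mol.num_heavy_atoms
    shingles: set[bytes] = set()
    for j in range(n):
        for k in range(j + 1, n):
            tp = str(int(dists[j, k])).encode("ascii") if include_distance else b""
            for rad_idx in range(r):
                a = envs[j][rad_idx]
                b = envs[k][rad_idx]
                if b < a:
                    a, b = b, a
                shingles.add(a + SHINGLE_SEPARATOR + tp + SHINGLE_SEPARATOR + b)
    return ShingleSet(
        shingles=frozenset(shingles), radius=r, molecule_id=mol.molecule_id
    )


def corpus_unique_shingles(
    smiles_stream: Iterable[str | tuple[str, str]],
    r: int = 2,
    with_frequencies: bool = True,
) -> tuple[int, Counter[bytes]]:
    """Distinct shingles over a corpus, with per-shingle document frequency.

    Each molecule contributes every shingle at most once (document counting).
    Unparseable or too-small inputs are skipped and reported through a single
    log summary.
    """
    frequencies: Counter[bytes] = Counter()
    unique: set[bytes] = set()
    skipped = 0
    for item in smiles_stream:
        smi, mid = item if isinstance(item, tuple) else (item, "")
        try:
            mol = parse_and_standardize(smi, molecule_id=mid)
        except MoleculeError:
            skipped += 1
            continue
        shingles = shingle_set(mol, r=r).shingles
        if with_frequencies:
            frequencies.update(shingles)
        else:
            unique.update(shingles)
    if skipped:
        logger.warning("corpus_unique_shingles: skipped %d unparseable/too-small molecules", skipped)
    if with_frequencies:
        return len(frequencies), frequencies
    return len(unique), frequencies
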