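"""Peptide sequence handling and benchmark dataset generation.

Linear peptides over the 20 proteogenic L-amino acids are converted to
protonated, non-chiral SMILES by amide condensation of residue templates, and
two families of analog datasets are generated per query sequence:

* **scrambled** — unique random permutations of the query's residues, probing
  whether a fingerprint perceives residue *order* (all members share the
  query's composition);
* **mutated** — unique sequences at Hamming distance exactly k from the query
  for every k in ``1..L``, probing graded sequence similarity.

Members are labelled active/decoy either with ``blastp`` (the external
sequence-similarity authority, using its classic default parameters) or with a
shipped positional-identity stub labeller that needs no external tool.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "PeptideSequence",
    "BenchmarkSet",
    "AlphabetError",
    "InsufficientDiversityError",
    "GenerationError",
    "ExternalDependencyError",
    "random_query_sequences",
    "peptide_to_smiles",
    "generate_scrambled_set",
    "generate_mutated_set",
    "BlastConfig",
    "blast_label",
    "identity_stub_labeller",
]

logger = logging.getLogger(__name__)

#: The 20 proteogenic amino acids, one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

# Side-chain SMILES fragments attached to the alpha carbon.  Lys and Arg are
# protonated (ammonium / guanidinium); His and the carboxylic acids are kept
# neutral.  Glycine has no side chain and proline is templated separately
# because its backbone nitrogen sits in the pyrrolidine ring.
_SIDE_CHAINS_PROTONATED = {
    "A": "C",
    "C": "CS",
    "D": "CC(=O)O",
    "E": "CCC(=O)O",
    "F": "Cc1ccccc1",
    "G": "",
    "H": "Cc1c[nH]cn1",
    "I": "C(C)CC",
    "K": "CCCC[NH3+]",
    "L": "CC(C)C",
    "M": "CCSC",
    "N": "CC(N)=O",
    "Q": "CCC(N)=O",
    "R": "CCCNC(=[NH2+])N",
    "S": "CO",
    "T": "C(C)O",
    "V": "C(C)C",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
}
_SIDE_CHAINS_NEUTRAL = dict(
    _SIDE_CHAINS_PROTONATED, K="CCCCN", R="CCCNC(=N)N"
)


class AlphabetError(ValueError):
    """A residue letter outside the 20 proteogenic one-letter codes."""


class InsufficientDiversityError(ValueError):
    """The query has too few distinct permutations for the requested set size."""


class GenerationError(RuntimeError):
    """Rejection-sampling retry bound exhausted during dataset generation."""


class ExternalDependencyError(RuntimeError):
    """A required external executable (blastp/makeblastdb) is missing."""


@dataclass(frozen=True)
class PeptideSequence:
    """A linear peptide over the proteogenic one-letter alphabet."""

    residues: str
    id: str = ""

    def __post_init__(self):
        if not self.residues:
            raise AlphabetError("empty peptide sequence")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise AlphabetError(
                f"non-proteogenic residue(s) {sorted(bad)} in {self.residues!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass
class BenchmarkSet:
    """One labelled analog dataset for a single query peptide.

    ``members`` holds ``(sequence, label)`` pairs with label in
    ``{"active", "decoy"}`` (or ``""`` before labelling); ``hamming_k`` aligns
    with members for mutated sets and is ``None`` for scrambled sets.
    """

    query: PeptideSequence
    members: list[tuple[str, str]]
    kind: str  # "scrambled" | "mutated"
    seed: int
    hamming_k: list[int] | None = None

    @property
    def sequences(self) -> list[str]:
        return [seq for seq, _ in self.members]

    @property
    def n_actives(self) -> int:
        return sum(1 for _, lab in self.members if lab == "active")


def random_query_sequences(seed: int = 0) -> list[PeptideSequence]:
    """Thirty random linear query peptides: ten each of lengths 10, 20, 30.

    Residues are drawn i.i.d. uniformly over the 20 proteogenic amino acids.
    """
    rng = np.random.default_rng(seed)
    queries: list[PeptideSequence] = []
    for length in (10, 20, 30):
        for i in range(10):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
            queries.append(PeptideSequence(seq, id=f"query_{length}mer_{i:02d}"))
    return queries


def peptide_to_smiles(seq: PeptideSequence | str, protonate: bool = True) -> str:
    """Assemble the linear-peptide SMILES by amide condensation.

    With ``protonate`` the N-terminal amine and the Lys/Arg side chains carry
    positive charges; carboxylic acids and His stay neutral.  The output is
    non-chiral and deterministic; its heavy-atom count equals the sum of the
    free-residue heavy atoms minus one oxygen per peptide bond.
    """
    pep = seq if isinstance(seq, PeptideSequence) else PeptideSequence(seq)
    side_chains = _SIDE_CHAINS_PROTONATED if protonate else _SIDE_CHAINS_NEUTRAL
    parts: list[str] = []
    for i, aa in enumerate(pep.residues):
        n_term = i == 0
        if aa == "P":
            n_atom = "[NH2+]1" if (n_term and protonate) else "N1"
            ca = "C(CCC1)"
        else:
            n_atom = "[NH3+]" if (n_term and protonate) else "N"
            side = side_chains[aa]
            ca = f"C({side})" if side else "C"
        parts.append(n_atom + ca + "C(=O)")
    return "".join(parts) + "O"


def _distinct_permutations(residues: str) -> int:
    counts = Counter(residues)
    total = math.factorial(len(residues))
    for c in counts.values():
        total //= math.factorial(c)
    return total


def generate_scrambled_set(
    query: PeptideSequence | str, n: int = 10_000, seed: int = 0
) -> BenchmarkSet:
    """``n`` unique random permutations of the query's residues.

    Every member shares the query's residue multiset; the query itself is
    excluded.  Raises :class:`InsufficientDiversityError` when fewer than
    ``n`` distinct permutations (excluding the query) exist.
    """
    pep = query if isinstance(query, PeptideSequence) else PeptideSequence(query)
    if _distinct_permutations(pep.residues) - 1 < n:
        raise InsufficientDiversityError(
            f"{pep.residues!r} has fewer than {n} distinct non-identity permutations"
        )
    rng = np.random.default_rng(seed)
    residues = np.array(list(pep.residues))
    members: set[str] = set()
    ordered: list[str] = []
    max_tries = 200 * n + 10_000
    tries = 0
    while len(ordered) < n:
        if tries >= max_tries:
            raise GenerationError("retry bound exhausted generating scrambled set")
        tries += 1
        cand = "".join(rng.permutation(residues))
        if cand != pep.residues and cand not in members:
            members.add(cand)
            ordered.append(cand)
    return BenchmarkSet(
        query=pep,
        members=[(s, "") for s in ordered],
        kind="scrambled",
        seed=seed,
    )


def _n_possible_mutants(length: int, k: int) -> int:
    return math.comb(length, k) * 19**k


def generate_mutated_set(
    query: PeptideSequence | str, cap: int = 10_000, seed: int = 0
) -> BenchmarkSet:
    """Point-mutation analogs at every Hamming distance ``k = 1..L``.

    For each k the target count is ``ceil(cap / L)`` unique sequences that
    differ from the query in exactly k positions, each mutated position
    receiving a uniformly chosen *different* residue.  When the combinatorial
    space at a given k is smaller than the target (single-point mutants of a
    10-mer number only 190), the count is capped at the number of distinct
    mutants that exist.  Blocks are concatenated in ascending k and the result
    truncated to the first ``cap`` members.
    """
    pep = query if isinstance(query, PeptideSequence) else PeptideSequence(query)
    length = len(pep)
    per_k = math.ceil(cap / length)
    rng = np.random.default_rng(seed)
    query_arr = np.array(list(pep.residues))
    members: list[tuple[str, str]] = []
    ks: list[int] = []
    for k in range(1, length + 1):
        target = min(per_k, _n_possible_mutants(length, k))
        block: set[str] = set()
        ordered: list[str] = []
        max_tries = 500 * target + 10_000
        tries = 0
        while len(ordered) < target:
            if tries >= max_tries:
                raise GenerationError(
                    f"retry bound exhausted at Hamming distance {k} for {pep.residues!r}"
                )
            tries += 1
            positions = rng.choice(length, size=k, replace=False)
            cand = query_arr.copy()
            for pos in positions:
                current = cand[pos]
                options = [a for a in AMINO_ACIDS if a != current]
                cand[pos] = options[rng.integers(len(options))]
            cand_s = "".join(cand)
            if cand_s not in block:
                block.add(cand_s)
                ordered.append(cand_s)
        members.extend((s, "") for s in ordered)
        ks.extend([k] * len(ordered))
    members = members[:cap]
    ks = ks[:cap]
    return BenchmarkSet(
        query=pep, members=members, kind="mutated", seed=seed, hamming_k=ks
    )


# ---------------------------------------------------------------------------
# Labelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlastConfig:
    """blastp parameters; defaults are the classic NCBI settings.

    ``max_target_seqs`` keeps blastp's default 500-hit cap, which bounds the
    number of actives a large analog set can contain.
    """

    gap_open: int = 11
    gap_extend: int = 1
    evalue: float = 10.0
    word_size: int = 3
    matrix: str = "BLOSUM62"
    seg: str = "yes"
    max_target_seqs: int = 500
    blastp_exe: str = "blastp"
    makeblastdb_exe: str = "makeblastdb"


def blast_label(
    query: PeptideSequence | str,
    members: Sequence[str],
    config: BlastConfig | None = None,
    keep_report: Path | None = None,
) -> list[str]:
    """Label members active/decoy by a blastp search of the query against them.

    Members hit with expectation value below ``config.evalue`` become actives;
    all others are decoys.  The raw tabular report can be retained for audit
    via ``keep_report``.
    """
    config = config or BlastConfig()
    pep = query if isinstance(query, PeptideSequence) else PeptideSequence(query)
    for exe in (config.blastp_exe, config.makeblastdb_exe):
        if shutil.which(exe) is None:
            raise ExternalDependencyError(
                f"required executable {exe!r} not found on PATH"
            )
    with tempfile.TemporaryDirectory(prefix="mapfp_blast_") as tmp:
        tmpdir = Path(tmp)
        db_fasta = tmpdir / "members.fasta"
        with db_fasta.open("w") as fh:
            for i, seq in enumerate(members):
                fh.write(f">m{i}\n{seq}\n")
        query_fasta = tmpdir / "query.fasta"
        query_fasta.write_text(f">query\n{pep.residues}\n")
        subprocess.run(
            [config.makeblastdb_exe, "-in", str(db_fasta), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
        out = tmpdir / "hits.tsv"
        cmd = [
            config.blastp_exe,
            "-query", str(query_fasta),
            "-db", str(db_fasta),
            "-out", str(out),
            "-outfmt", "6 sseqid evalue",
            "-gapopen", str(config.gap_open),
            "-gapextend", str(config.gap_extend),
            "-evalue", str(config.evalue),
            "-word_size", str(config.word_size),
            "-matrix", config.matrix,
            "-seg", config.seg,
            "-max_target_seqs", str(config.max_target_seqs),
        ]
        subprocess.run(cmd, check=True, capture_output=True)
        report = out.read_text()
        if keep_report is not None:
            keep_report.write_text(report)
        hits: set[int] = set()
        for line in report.splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed blastp report line: {line!r}")
            sid, evalue = fields[0], float(fields[1])
            if evalue < config.evalue:
                hits.add(int(sid[1:]))
    return ["active" if i in hits else "decoy" for i in range(len(members))]


def identity_stub_labeller(
    query: PeptideSequence | str,
    members: Sequence[str],
    min_identity: float = 0.3,
) -> list[str]:
    """Offline stand-in for BLAST: positional-identity threshold labelling.

    A member is active when the fraction of positions matching the query is at
    least ``min_identity`` (sequences of unequal length are compared over the
    shorter length, normalized by the longer).  Purely synthetic labelling for
    tests and desk-scale screens; it mimics the *shape* of homology labels,
    not BLAST statistics.
    """
    pep = query if isinstance(query, PeptideSequence) else PeptideSequence(query)
    q = pep.residues
    labels = []
    for seq in members:
        short = min(len(q), len(seq))
        matches = sum(1 for a, b in zip(q[:short], seq[:short]) if a == b)
        identity = matches / max(len(q), len(seq))
        labels.append("active" if identity >= min_identity else "decoy")
    return labels
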