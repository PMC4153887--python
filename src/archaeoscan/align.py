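"""Shared local-alignment engine for homology calls.

All homology operations in the package (readthrough detection, pyl-cassette
calls, orthology, spacer matching) go through Smith-Waterman local alignment:
BLOSUM62 with affine gap penalties 11/1 for proteins, +2/-3 with gaps 5/2 for
nucleotides.  Identity is matches over alignment columns and coverage is
aligned query positions over query length, both in percent — explicit
definitions standing in for search-tool statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

# Residues outside the BLOSUM62 alphabet are remapped before scoring:
# pyrrolysine is scored as lysine (its closest standard residue),
# selenocysteine as cysteine, J (I/L ambiguity) as leucine.
_PROTEIN_REMAP = str.maketrans({"O": "K", "U": "C", "J": "L", "*": "X"})


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of a query against one subject."""

    query_id: str
    subject_id: str
    score: float
    identity: float  # percent: matches / alignment columns
    coverage: float  # percent: aligned query positions / query length
    matches: int
    alignment_length: int


@lru_cache(maxsize=1)
def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


@lru_cache(maxsize=1)
def dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def sanitize_protein(seq: str) -> str:
    return seq.upper().translate(_PROTEIN_REMAP)


def align_protein(query: str, subject: str) -> tuple[float, int, int, int]:
    """Best local protein alignment.

    Returns (score, matches, alignment_columns, aligned_query_positions);
    all zeros when no positive-scoring alignment exists.
    """
    return _align(protein_aligner(), sanitize_protein(query), sanitize_protein(subject))


def align_dna(query: str, subject: str) -> tuple[float, int, int, int]:
    return _align(dna_aligner(), query.upper(), subject.upper())


def _align(aligner, query: str, subject: str) -> tuple[float, int, int, int]:
    if not query or not subject:
        return (0.0, 0, 0, 0)
    try:
        alignments = aligner.align(query, subject)
        if len(alignments) == 0:
            return (0.0, 0, 0, 0)
        aln = alignments[0]
    except (ValueError, OverflowError):
        return (0.0, 0, 0, 0)
    if aln.score <= 0:
        return (0.0, 0, 0, 0)
    counts = aln.counts()
    q_blocks = aln.aligned[0]
    aligned_query = int(sum(e - s for s, e in q_blocks))
    return (float(aln.score), int(counts.identities), int(aln.length), aligned_query)


def best_local_hit(
    query_id: str,
    query: str,
    subjects: dict[str, str],
    min_identity: float = 0.0,
    min_coverage: float = 0.0,
    protein: bool = True,
    min_score: float = 0.0,
) -> LocalHit | None:
    """Best qualifying subject for one query.

    Subjects are ranked by alignment score, ties broken by lexicographic
    subject id (a deterministic stand-in for e-value ordering).  Only
    subjects passing the identity/coverage thresholds — and, when
    ``min_score`` is set, a raw-score significance floor — qualify; ``None``
    when none do.
    """
    if not query:
        return None
    align_fn = align_protein if protein else align_dna
    best: LocalHit | None = None
    for sid in sorted(subjects):
        score, matches, columns, aligned_q = align_fn(query, subjects[sid])
        if columns == 0 or score < min_score:
            continue
        identity = 100.0 * matches / columns
        coverage = 100.0 * aligned_q / len(query)
        if identity < min_identity or coverage < min_coverage:
            continue
        if best is None or score > best.score:
            best = LocalHit(query_id, sid, score, identity, coverage, matches, columns)
    return best
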