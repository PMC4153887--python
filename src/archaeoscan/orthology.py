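"""Best-hit orthology, 3-way core-genome partition and outgroup screening.

Orthologous relationships are established from best local-alignment hits
(Smith-Waterman, BLOSUM62, affine gaps 11/1) with the screening thresholds
of 30% identity and 80% query-length coverage.  Orthology is best-hit based
by default, matching the screening procedure; a reciprocal-best-hit mode is
provided as an option.  Ties in score break by lexicographic subject id so
the output is independent of input protein order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

import pandas as pd

from .align import LocalHit, best_local_hit


@dataclass
class Proteome:
    id: str
    proteins: dict[str, str]

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"proteome {self.id!r} is empty")
        for pid, seq in self.proteins.items():
            if not seq:
                raise ValueError(f"protein {pid!r} in {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class OrthoParams:
    min_identity: float = 30.0
    min_coverage: float = 80.0
    reciprocal: bool = False


@dataclass
class VennPartition:
    """The 7 disjoint cells of a 3-proteome sharing partition.

    Cells are keyed by the sorted proteome-id pattern (e.g. "A", "A+B",
    "A+B+C"); each cell maps proteome id -> list of its protein ids whose
    sharing pattern is that cell.  Every protein of every proteome is
    assigned to exactly one cell.
    """

    proteome_ids: tuple[str, str, str]
    cells: dict[str, dict[str, list[str]]]

    def counts(self) -> dict[str, dict[str, int]]:
        return {
            cell: {pid: len(members) for pid, members in per.items()}
            for cell, per in self.cells.items()
        }

    def core_count(self, proteome_id: Optional[str] = None) -> int:
        core = self.cells["+".join(sorted(self.proteome_ids))]
        if proteome_id is None:
            proteome_id = sorted(self.proteome_ids)[0]
        return len(core.get(proteome_id, []))


def best_hits(
    query: Proteome, subject: Proteome, params: OrthoParams | None = None
) -> dict[str, LocalHit]:
    """Best qualifying subject per query protein.

    Queries with no subject passing the identity/coverage thresholds are
    absent from the result.  Reciprocal mode additionally requires the
    subject's best hit back into the query proteome to be the query.
    """
    params = params or OrthoParams()
    hits: dict[str, LocalHit] = {}
    for qid in sorted(query.proteins):
        hit = best_local_hit(
            qid, query.proteins[qid], subject.proteins,
            params.min_identity, params.min_coverage,
        )
        if hit is not None:
            hits[qid] = hit
    if params.reciprocal:
        back: dict[str, LocalHit] = {}
        for sid in sorted(subject.proteins):
            h = best_local_hit(
                sid, subject.proteins[sid], query.proteins,
                params.min_identity, params.min_coverage,
            )
            if h is not None:
                back[sid] = h
        hits = {
            qid: h
            for qid, h in hits.items()
            if back.get(h.subject_id) is not None and back[h.subject_id].subject_id == qid
        }
    return hits


def venn_partition(
    p1: Proteome, p2: Proteome, p3: Proteome, params: OrthoParams | None = None
) -> VennPartition:
    """Partition each proteome's proteins by which other proteomes share them.

    A protein of proteome i is "shared with" proteome j iff it has a
    qualifying best hit in j; the core cell is shared-with-both.
    """
    params = params or OrthoParams()
    proteomes = {p.id: p for p in (p1, p2, p3)}
    if len(proteomes) != 3:
        raise ValueError("proteome ids must be distinct")
    shared: dict[tuple[str, str], set[str]] = {}
    for a, b in ((p1, p2), (p1, p3), (p2, p1), (p2, p3), (p3, p1), (p3, p2)):
        shared[(a.id, b.id)] = set(best_hits(a, b, params))
    ids = tuple(sorted(proteomes))
    cells: dict[str, dict[str, list[str]]] = {}
    for r in (1, 2, 3):
        for combo in combinations(ids, r):
            cells["+".join(combo)] = {pid: [] for pid in combo}
    for pid, prot in proteomes.items():
        others = [o for o in ids if o != pid]
        for protein_id in sorted(prot.proteins):
            pattern = sorted(
                [pid] + [o for o in others if protein_id in shared[(pid, o)]]
            )
            cells["+".join(pattern)][pid].append(protein_id)
    return VennPartition(ids, cells)


def screen_against(
    targets: dict[str, str],
    refs: Iterable[Proteome],
    params: OrthoParams | None = None,
) -> tuple[pd.DataFrame, int]:
    """Presence of each target protein in each reference proteome.

    Present iff any hit passes the thresholds (30% identity / 80% coverage
    by default).  Returns the boolean targets x references matrix and the
    count of targets absent from every reference.
    """
    params = params or OrthoParams()
    refs = list(refs)
    if not targets or not refs:
        raise ValueError("targets and refs must be non-empty")
    matrix = pd.DataFrame(
        False, index=sorted(targets), columns=[r.id for r in refs], dtype=bool
    )
    for tid in sorted(targets):
        for ref in refs:
            hit = best_local_hit(
                tid, targets[tid], ref.proteins,
                params.min_identity, params.min_coverage,
            )
            matrix.loc[tid, ref.id] = hit is not None
    absent_all = int((~matrix.any(axis=1)).sum())
    return matrix, absent_all
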