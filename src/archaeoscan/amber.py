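"""Pyrrolysine (Pyl) protein prediction from amber-codon readthrough.

In Pyl-decoding archaea the amber stop codon TAG can encode pyrrolysine, so
a genuine Pyl protein is deposited as a TAG-terminated CDS whose in-frame
3' continuation encodes the rest of the protein.  The detector finds every
TAG-terminated CDS, virtually translates the in-frame 3' flanking region up
to the next stop codon, and emits a candidate when the CDS product and the
extension share the same best homolog in a reference protein database.  The
two parts are then fused in silico with 'O' at the amber position.

The companion cassette detector calls the Pyl machinery: pylT (the
amber-suppressor tRNA with a CUA anticodon), pylS (Pyl-tRNA synthetase) and
the biosynthesis genes pylB, pylC, pylD, by homology against reference
family sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .align import LocalHit, best_local_hit
from .genome_io import (
    STOP_CODONS,
    FeatureSet,
    GeneFeature,
    GenomeRecord,
    extract_feature_sequence,
    reverse_complement,
    translate_cds,
)


@dataclass
class ReferenceProteinDB:
    """Reference proteins for homology calls: id -> amino-acid sequence."""

    entries: dict[str, str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, seq in self.entries.items():
            if not seq:
                raise ValueError(f"reference {pid!r} has empty sequence")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceProteinDB":
        from .genome_io import read_protein_fasta

        return cls(read_protein_fasta(path))


@dataclass
class PylScanParams:
    min_identity: float = 30.0
    min_coverage: float = 50.0  # of the query segment (fragments, not full genes)
    min_extension: int = 15  # aa
    min_score: float = 50.0  # raw-score floor, stands in for e-value significance
    max_fusions: int = 2  # in-frame ambers fused per locus
    require_best_hit: bool = True  # shared *best* hit vs merely shared hit


@dataclass
class ReadthroughCandidate:
    cds_id: str
    amber_genome_position: int  # coding-strand first base of the amber codon
    upstream_aa: str
    extension_aa: str
    upstream_hit: LocalHit
    extension_hit: LocalHit
    fused_protein: str
    n_ambers: int = 1


@dataclass
class PylCassette:
    present: dict[str, bool]
    feature_ids: dict[str, Optional[str]]

    @property
    def complete(self) -> bool:
        return all(self.present.values())


# ---------------------------------------------------------------------------


def _is_tag_terminated(genome: GenomeRecord, cds: GeneFeature) -> bool:
    seq = extract_feature_sequence(genome, cds)
    return len(seq) % 3 == 0 and seq.endswith("TAG")


def _codons_after(genome: GenomeRecord, cds: GeneFeature) -> Iterator[str]:
    """Successive codons after the CDS terminal codon, same strand and frame.

    Walks off the 3' end of the feature; on circular genomes wraps the
    origin, on linear ones stops at the sequence edge (possibly yielding a
    final partial codon, which callers treat as a truncation).
    """
    seq = genome.sequence
    L = len(seq)
    circular = genome.topology == "circular"
    if cds.strand == "+":
        pos = cds.segments[-1][1]  # 0-based index of first downstream base
        while True:
            if circular:
                codon = "".join(seq[(pos + k) % L] for k in range(3))
                pos += 3
                yield codon
                if pos > 2 * L:  # stopless circle guard
                    return
            else:
                codon = seq[pos : pos + 3]
                pos += 3
                yield codon
                if len(codon) < 3 or pos >= L:
                    return
    else:
        pos = cds.segments[-1][0] - 1  # 1-based start -> 0-based; walk down
        while True:
            if circular:
                codon = "".join(seq[(pos - 3 + k) % L] for k in range(3))
                pos -= 3
                yield reverse_complement(codon)
                if pos < -2 * L:
                    return
            else:
                lo = max(pos - 3, 0)
                codon = seq[lo:pos]
                pos -= 3
                yield reverse_complement(codon)
                if len(codon) < 3 or pos <= 0:
                    return


def _extension_segments(
    genome: GenomeRecord, cds: GeneFeature, max_segments: int
) -> tuple[list[str], str, bool]:
    """In-frame translations after the CDS, split at internal ambers.

    Returns (segments, final_stop, truncated): up to ``max_segments``
    amino-acid strings, each ended by a TAG except the last which ends at
    TAA/TGA (final_stop) or at a contig edge (truncated=True).
    """
    from .genome_io import CODON_TO_AA

    segments: list[str] = []
    current: list[str] = []
    final_stop = ""
    truncated = False
    for codon in _codons_after(genome, cds):
        if len(codon) < 3:
            truncated = True
            break
        if codon in STOP_CODONS:
            if codon == "TAG" and len(segments) + 1 < max_segments:
                segments.append("".join(current))
                current = []
                continue
            final_stop = codon
            break
        current.append("X" if "N" in codon else CODON_TO_AA[codon])
    else:
        truncated = True
    segments.append("".join(current))
    return segments, final_stop, truncated


def extension_translation(genome: GenomeRecord, cds: GeneFeature) -> str:
    """Virtual in-frame translation of the 3' flanking region of a
    TAG-terminated CDS, up to but excluding the next stop codon."""
    if not _is_tag_terminated(genome, cds):
        raise ValueError(f"CDS {cds.id!r} is not TAG-terminated")
    segments, _stop, _trunc = _extension_segments(genome, cds, max_segments=1)
    return segments[0]


def amber_position(cds: GeneFeature) -> int:
    """Genome coordinate of the coding-strand first base of the terminal TAG."""
    if cds.strand == "+":
        return cds.segments[-1][1] - 2
    return cds.segments[-1][0] + 2


def detect_readthrough_candidates(
    genome: GenomeRecord,
    features: FeatureSet,
    refdb: ReferenceProteinDB,
    params: Optional[PylScanParams] = None,
) -> list[ReadthroughCandidate]:
    """Scan TAG-terminated CDS for shared-homolog readthrough structure.

    A candidate is emitted when the CDS translation and each in-frame
    extension have qualifying best hits to the same reference protein.
    Zero candidates is a valid result.
    """
    params = params or PylScanParams()
    if not refdb.entries:
        raise ValueError("empty reference protein database")
    out: list[ReadthroughCandidate] = []
    for cds in features.of_kind("CDS"):
        if not _is_tag_terminated(genome, cds):
            continue
        cds_seq = extract_feature_sequence(genome, cds)
        upstream_aa = translate_cds(cds_seq, readthrough_amber=False)
        if not upstream_aa:
            continue
        up_hit = best_local_hit(
            cds.id, upstream_aa, refdb.entries,
            params.min_identity, params.min_coverage,
            min_score=params.min_score,
        )
        if up_hit is None:
            continue
        segments, _stop, truncated = _extension_segments(
            genome, cds, params.max_fusions
        )
        if truncated and not segments[-1]:
            segments = segments[:-1]
        if not segments:
            continue
        total_ext = sum(len(s) for s in segments)
        if total_ext < params.min_extension:
            continue
        ext_hits = []
        ok = True
        for seg in segments:
            hit = best_local_hit(
                cds.id, seg, refdb.entries,
                params.min_identity, params.min_coverage,
                min_score=params.min_score,
            )
            if hit is None or (params.require_best_hit and hit.subject_id != up_hit.subject_id):
                ok = False
                break
            if not params.require_best_hit:
                # shared-hit mode: any qualifying alignment to the upstream's
                # best subject is enough
                shared = best_local_hit(
                    cds.id, seg, {up_hit.subject_id: refdb.entries[up_hit.subject_id]},
                    params.min_identity, params.min_coverage,
                    min_score=params.min_score,
                )
                if shared is None:
                    ok = False
                    break
                hit = shared
            ext_hits.append(hit)
        if not ok:
            continue
        fused = upstream_aa + "".join("O" + seg for seg in segments)
        out.append(
            ReadthroughCandidate(
                cds_id=cds.id,
                amber_genome_position=amber_position(cds),
                upstream_aa=upstream_aa,
                extension_aa=segments[0],
                upstream_hit=up_hit,
                extension_hit=ext_hits[0],
                fused_protein=fused,
                n_ambers=len(segments),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pyl cassette

_PYL_GENE = re.compile(r"pyl([SBCD])", re.IGNORECASE)
_PYLT = re.compile(r"tRNA-Pyl|pylT|anticodon\s*C[TU]A", re.IGNORECASE)


def _family_refs(refdb: ReferenceProteinDB) -> dict[str, dict[str, str]]:
    fams: dict[str, dict[str, str]] = {}
    for pid, seq in refdb.entries.items():
        text = pid + " " + refdb.descriptions.get(pid, "")
        m = _PYL_GENE.search(text)
        if m:
            fams.setdefault("pyl" + m.group(1).upper(), {})[pid] = seq
    return fams


def detect_pyl_cassette(
    genome: GenomeRecord,
    features: FeatureSet,
    refdb: ReferenceProteinDB,
    min_identity: float = 30.0,
    min_coverage: float = 50.0,
) -> PylCassette:
    """Call pylT/pylS/pylB/pylC/pylD presence.

    pylS/B/C/D are homology calls of annotated CDS against reference family
    sequences (reference ids or descriptions must name the family).  pylT is
    an annotated tRNA whose product marks the CUA (amber-suppressor)
    anticodon or names tRNA-Pyl; the annotation model carries no structured
    anticodon field, so the product text is the signal.
    """
    fams = _family_refs(refdb)
    present: dict[str, bool] = {}
    ids: dict[str, Optional[str]] = {}

    pylt = None
    for f in features.of_kind("tRNA"):
        if _PYLT.search(f.product):
            pylt = f.id
            break
    present["pylT"], ids["pylT"] = pylt is not None, pylt

    proteins = {
        f.id: translate_cds(extract_feature_sequence(genome, f))
        for f in features.of_kind("CDS")
        if f.length % 3 == 0
    }
    for name in ("pylS", "pylB", "pylC", "pylD"):
        refs = fams.get(name, {})
        found = None
        best_score = -1.0
        for fid, aa in proteins.items():
            if not refs or not aa:
                continue
            hit = best_local_hit(fid, aa, refs, min_identity, min_coverage)
            if hit is not None and hit.score > best_score:
                best_score = hit.score
                found = fid
        present[name], ids[name] = found is not None, found
    return PylCassette(present, ids)
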