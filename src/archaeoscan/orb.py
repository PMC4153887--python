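"""Replication-origin mapping via degenerate ORB motif scanning.

Archaeal replication origins carry pairs of Origin Recognition Box (ORB)
motifs bound by the Orc1/Cdc6 initiator, typically within a few kb of an
orc1/cdc6 gene.  The scanner finds every position on both strands within a
Hamming-distance budget of an IUPAC-aware consensus core (circular wrap
included), pairs nearby hits, derives per-genome consensus motifs by column
majority, and calls origin candidates where a motif pair lies near an
orc1/cdc6 gene.

Coordinates are 1-based inclusive; a hit spanning the origin of a circular
replicon keeps start within the genome and lets end run past it (end =
start + core_length - 1), which is stated in every report header.  Spacing
of a pair is start(hit2) - end(hit1) for hits ordered by start.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_io import FeatureSet, GeneFeature, GenomeRecord, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC.items()}

#: Methanomassiliicoccales 22-mer consensus core (the trailing 23rd base of
#: the printed consensus is unsupported by the underlying motifs and omitted).
DEFAULT_CORE = "GTTCCAGTGGAAATGGAGGGGT"

ORC1_CDC6_PATTERN = re.compile(r"orc1|cdc6", re.IGNORECASE)


@dataclass(frozen=True)
class OrbMotif:
    core: str = DEFAULT_CORE
    max_mismatch: int = 4

    def __post_init__(self) -> None:
        bad = [c for c in self.core.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"core contains non-IUPAC characters: {bad}")
        if self.max_mismatch >= len(self.core):
            raise ValueError("max_mismatch must be smaller than the core length")


@dataclass(frozen=True)
class OrbHit:
    start: int  # 1-based inclusive
    end: int
    strand: str
    mismatches: int
    matched_sequence: str  # in motif (coding) orientation


@dataclass(frozen=True)
class OrbPair:
    hit1: OrbHit  # ordered by start
    hit2: OrbHit
    spacing: int  # start(hit2) - end(hit1)
    orientation: str  # direct | inverted


@dataclass
class OriginCandidate:
    pair: OrbPair
    gene_id: str
    distance: int  # bp from pair midpoint to the nearest gene boundary
    side: str  # upstream | downstream | within (relative to gene orientation)


def _mismatch_profile(arr: np.ndarray, core: str) -> np.ndarray:
    """Mismatch count of every window of len(core) against the IUPAC core."""
    c = len(core)
    n_win = len(arr) - c + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int32)
    mism = np.zeros(n_win, dtype=np.int32)
    for j, sym in enumerate(core.upper()):
        allowed = np.zeros(256, dtype=bool)
        for b in IUPAC[sym]:
            allowed[ord(b)] = True
        mism += ~allowed[arr[j : j + n_win]]
    return mism


def _iupac_revcomp(core: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    return "".join(comp[c] for c in core.upper())[::-1]


def scan_motif(genome: GenomeRecord, motif: OrbMotif) -> list[OrbHit]:
    """All hits on both strands within the Hamming budget, sorted by start.

    A window matches the minus strand when its reverse complement matches
    the core; equivalently the forward window matches the reverse-complement
    of the IUPAC core, which is how both strands are scanned in one pass.
    Circular genomes are scanned across the origin by extending the sequence
    with its first core_length - 1 bases.
    """
    c = len(motif.core)
    if len(genome) < c:
        return []
    seq = genome.sequence
    if genome.topology == "circular":
        seq = seq + seq[: c - 1]
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits: list[OrbHit] = []
    L = len(genome)
    for strand, core in (("+", motif.core), ("-", _iupac_revcomp(motif.core))):
        mism = _mismatch_profile(arr, core)
        for pos in np.nonzero(mism <= motif.max_mismatch)[0]:
            start = int(pos) + 1
            if start > L:  # wrap duplicates
                continue
            window = seq[pos : pos + c]
            matched = window if strand == "+" else reverse_complement(window)
            hits.append(OrbHit(start, start + c - 1, strand, int(mism[pos]), matched))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def pair_hits(hits: list[OrbHit], max_pair_spacing: int = 300) -> list[OrbPair]:
    """All ordered pairs of distinct hits with 0 <= spacing <= max_pair_spacing."""
    ordered = sorted(hits, key=lambda h: (h.start, h.end, h.strand))
    pairs = []
    for i, h1 in enumerate(ordered):
        for h2 in ordered[i + 1 :]:
            spacing = h2.start - h1.end
            if spacing < 0:
                continue
            if spacing > max_pair_spacing:
                break
            orientation = "inverted" if h1.strand != h2.strand else "direct"
            pairs.append(OrbPair(h1, h2, spacing, orientation))
    return pairs


def derive_consensus(sequences: list[str]) -> str:
    """Per-column strict-majority consensus of co-aligned equal-length strings.

    Ties emit the minimal IUPAC code covering the tied bases.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    seqs = [s.upper() for s in sequences]
    out = []
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        winners = frozenset(b for b, n in counts.items() if n == top)
        if len(winners) == 1:
            out.append(next(iter(winners)))
        else:
            out.append(_SET_TO_IUPAC[winners])
    return "".join(out)


def find_initiator_genes(features: FeatureSet) -> list[GeneFeature]:
    return [
        f for f in features.of_kind("CDS") if ORC1_CDC6_PATTERN.search(f.product)
    ]


def call_origin(
    pairs: list[OrbPair],
    features: FeatureSet,
    origin_window: int = 10_000,
) -> list[OriginCandidate]:
    """Origin candidates: pairs whose midpoint lies near an orc1/cdc6 gene.

    Distance is from the pair midpoint to the nearest gene boundary (0 when
    the midpoint falls inside the gene); side is relative to the gene's
    orientation.  Pairs near several initiator genes report the nearest.
    """
    genes = find_initiator_genes(features)
    if not genes:
        warnings.warn("no orc1/cdc6 genes annotated; no origin candidates")
        return []
    out = []
    for pair in pairs:
        midpoint = (pair.hit1.start + pair.hit2.end) / 2.0
        best = None
        for g in genes:
            if g.start <= midpoint <= g.end:
                dist, side = 0, "within"
            elif midpoint < g.start:
                dist = int(g.start - midpoint)
                side = "upstream" if g.strand == "+" else "downstream"
            else:
                dist = int(midpoint - g.end)
                side = "downstream" if g.strand == "+" else "upstream"
            if best is None or dist < best[0]:
                best = (dist, side, g)
        dist, side, g = best
        if dist <= origin_window:
            out.append(OriginCandidate(pair, g.id, dist, side))
    return out
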