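"""Genome summary statistics: coding density, intergenic sizes, codon and
stop/start usage, and rRNA gene organization.

Coding density counts positions covered by at least one gene feature of any
kind (CDS and RNA genes), overlaps counted once.  Intergenic gaps are the
distances between consecutive gene intervals ignoring strand; overlapping or
abutting genes contribute a gap of 0, and circular genomes include the gap
that wraps the origin.  Standard deviations are population SDs, as these are
descriptive statistics over the complete gene complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    CODON_TO_AA,
    STOP_CODONS,
    FeatureSet,
    GenomeRecord,
    extract_feature_sequence,
)


@dataclass
class StopUsage:
    fraction_TAA: float
    fraction_TAG: float
    fraction_TGA: float
    n_cds: int  # CDS with a recognized terminal stop
    n_unrecognized: int  # CDS whose terminal codon is not a canonical stop


@dataclass
class CodonUsageTable:
    counts: dict[str, int]  # sense-codon counts (terminal stops excluded)
    stop_counts: dict[str, int]
    start_counts: dict[str, int]  # ATG / GTG / TTG / other
    n_cds: int
    n_skipped: int  # CDS whose length is not a multiple of 3

    def relative_by_amino_acid(self) -> dict[str, dict[str, float]]:
        """Per-amino-acid relative synonymous codon frequencies."""
        totals: dict[str, int] = {}
        for codon, n in self.counts.items():
            aa = CODON_TO_AA.get(codon)
            if aa is not None:
                totals[aa] = totals.get(aa, 0) + n
        out: dict[str, dict[str, float]] = {}
        for codon, n in self.counts.items():
            aa = CODON_TO_AA.get(codon)
            if aa is None or totals.get(aa, 0) == 0:
                continue
            out.setdefault(aa, {})[codon] = n / totals[aa]
        return out

    def gc3(self) -> float:
        """GC fraction at the third codon position of sense codons."""
        total = sum(self.counts.values())
        if total == 0:
            return float("nan")
        gc = sum(n for c, n in self.counts.items() if c[2] in "GC")
        return gc / total


@dataclass
class RrnaReport:
    classification: str  # operonic | scattered | undetermined
    gene_order: str  # e.g. "16S,23S,5S" in genome order
    pairs: list[dict] = field(default_factory=list)  # candidate 16S/23S pairs


@dataclass
class GenomeSummary:
    genome_size: int
    gc_fraction: float
    coding_fraction: float
    intergenic_mean: float
    intergenic_sd: float
    gene_counts: dict[str, int]
    cds_mean_length: float
    cds_median_length: float
    gene_gc_mean: float


# ---------------------------------------------------------------------------


def _all_segments(features: FeatureSet) -> list[tuple[int, int]]:
    segs = []
    for f in features:
        segs.extend(f.segments)
    return sorted(segs)


def _merged(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in segs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coding_density(genome: GenomeRecord, features: FeatureSet) -> float:
    """Fraction of genome positions covered by >= 1 gene feature."""
    if len(genome) == 0:
        raise ValueError("empty genome")
    segs = _all_segments(features)
    for s, e in segs:
        if e > len(genome):
            raise ValueError(f"feature segment {s}..{e} outside genome")
    covered = sum(e - s + 1 for s, e in _merged(segs))
    return covered / len(genome)


def intergenic_gaps(genome: GenomeRecord, features: FeatureSet) -> list[int]:
    """Gap sizes between consecutive gene intervals, strand-ignored.

    Consecutive intervals that abut or overlap contribute 0.  For circular
    genomes the gap wrapping the origin is included (also 0 when the first
    and last genes abut or overlap across the origin).
    """
    segs = _all_segments(features)
    if len(segs) < 2:
        raise ValueError("need at least two features for intergenic statistics")
    gaps = []
    running_end = segs[0][1]
    for s, e in segs[1:]:
        gaps.append(max(0, s - running_end - 1))
        running_end = max(running_end, e)
    if genome.topology == "circular":
        first_start = segs[0][0]
        wrap = (first_start - 1) + (len(genome) - running_end)
        gaps.append(max(0, wrap))
    return gaps


def intergenic_stats(genome: GenomeRecord, features: FeatureSet) -> tuple[float, float]:
    """(mean, population SD) of intergenic gap sizes in bp."""
    gaps = np.array(intergenic_gaps(genome, features), dtype=float)
    return float(gaps.mean()), float(gaps.std())


def stop_codon_usage(genome: GenomeRecord, features: FeatureSet) -> StopUsage:
    """Classify each CDS by its terminal codon on the coding strand."""
    cds = features.of_kind("CDS")
    if not cds:
        raise ValueError("no CDS features")
    counts = {"TAA": 0, "TAG": 0, "TGA": 0}
    unrecognized = 0
    for f in cds:
        seq = extract_feature_sequence(genome, f)
        stop = seq[-3:] if len(seq) >= 3 and len(seq) % 3 == 0 else ""
        if stop in counts:
            counts[stop] += 1
        else:
            unrecognized += 1
    n = sum(counts.values())
    if n == 0:
        return StopUsage(0.0, 0.0, 0.0, 0, unrecognized)
    return StopUsage(
        counts["TAA"] / n, counts["TAG"] / n, counts["TGA"] / n, n, unrecognized
    )


def codon_usage(genome: GenomeRecord, features: FeatureSet) -> CodonUsageTable:
    """Codon counts over all complete codons of all CDS.

    Terminal stop codons are tabulated separately; the start codon is
    tallied from codon 1 of each CDS.  CDS whose length is not a multiple
    of 3 are skipped and counted.
    """
    cds = features.of_kind("CDS")
    if not cds:
        raise ValueError("no CDS features")
    counts: dict[str, int] = {}
    stop_counts = {"TAA": 0, "TAG": 0, "TGA": 0}
    start_counts = {"ATG": 0, "GTG": 0, "TTG": 0, "other": 0}
    skipped = 0
    for f in cds:
        seq = extract_feature_sequence(genome, f)
        if len(seq) % 3 != 0 or len(seq) < 6:
            skipped += 1
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        start_counts[codons[0] if codons[0] in start_counts else "other"] += 1
        if codons[-1] in STOP_CODONS:
            stop_counts[codons[-1]] += 1
            codons = codons[:-1]
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
    return CodonUsageTable(counts, stop_counts, start_counts, len(cds) - skipped, skipped)


def rrna_organization(features: FeatureSet, max_operon_gap: int = 500) -> RrnaReport:
    """Classify rRNA gene organization as operonic or scattered.

    Operonic iff some 16S/23S pair lies on the same strand with an
    inter-feature gap of at most ``max_operon_gap`` bp; otherwise scattered.
    """
    r16 = features.of_kind("rRNA-16S")
    r23 = features.of_kind("rRNA-23S")
    all_rrna = sorted(
        features.of_kind("rRNA-5S", "rRNA-16S", "rRNA-23S"), key=lambda f: f.start
    )
    order = ",".join(f.kind.replace("rRNA-", "") for f in all_rrna)
    if not r16 or not r23:
        warnings.warn("missing 16S or 23S rRNA annotation; organization undetermined")
        return RrnaReport("undetermined", order)
    pairs = []
    operonic = False
    for a in r16:
        for b in r23:
            first, second = (a, b) if a.start <= b.start else (b, a)
            gap = second.start - first.end - 1
            same_strand = a.strand == b.strand
            within = same_strand and 0 <= gap <= max_operon_gap
            pairs.append(
                {"16S": a.id, "23S": b.id, "gap": gap,
                 "same_strand": same_strand, "operonic": within}
            )
            operonic = operonic or within
    return RrnaReport("operonic" if operonic else "scattered", order, pairs)


def summarize(genome: GenomeRecord, features: FeatureSet) -> GenomeSummary:
    """Table-style per-genome summary."""
    mean, sd = (float("nan"), float("nan"))
    if len(features) >= 2:
        mean, sd = intergenic_stats(genome, features)
    gene_counts: dict[str, int] = {}
    for f in features:
        gene_counts[f.kind] = gene_counts.get(f.kind, 0) + 1
    cds_lens = np.array([f.length for f in features.of_kind("CDS")], dtype=float)
    seq = genome.sequence
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    gene_gcs = []
    for f in features:
        s = extract_feature_sequence(genome, f)
        gene_gcs.append((s.count("G") + s.count("C")) / len(s))
    return GenomeSummary(
        genome_size=len(genome),
        gc_fraction=gc,
        coding_fraction=coding_density(genome, features),
        intergenic_mean=mean,
        intergenic_sd=sd,
        gene_counts=gene_counts,
        cds_mean_length=float(cds_lens.mean()) if cds_lens.size else float("nan"),
        cds_median_length=float(np.median(cds_lens)) if cds_lens.size else float("nan"),
        gene_gc_mean=float(np.mean(gene_gcs)) if gene_gcs else float("nan"),
    )
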