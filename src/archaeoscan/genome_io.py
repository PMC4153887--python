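"""Genome and annotation I/O with strand-aware sequence extraction.

Coordinates are 1-based inclusive throughout (the GenBank/GFF3 convention),
so no shifting occurs on read or write.  Features that wrap the origin of a
circular replicon are represented as two segments sharing one feature id,
listed in translation order.

Translation uses NCBI genetic code table 11 (bacterial/archaeal), with an
optional amber-suppression mode in which TAG encodes pyrrolysine ('O') and
translation continues; TAA and TGA always terminate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("CDS", "tRNA", "rRNA-5S", "rRNA-16S", "rRNA-23S", "ncRNA")

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)


class GenomeParseError(ValueError):
    """Raised when a genome or annotation file cannot be parsed."""


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """A replicon: id, uppercase DNA sequence and topology."""

    id: str
    sequence: str
    topology: str = "linear"  # {"circular", "linear"}

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has empty sequence")
        if re.search(r"[^ACGTN]", self.sequence):
            bad = sorted(set(re.findall(r"[^ACGTN]", self.sequence)))
            raise ValueError(f"genome {self.id!r}: non-ACGTN characters {bad}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A 1-based, strand-aware annotation interval.

    ``segments`` lists (start, end) pairs in translation order; it defaults
    to the single ``(start, end)`` interval and carries both parts of a
    wrap-around feature on a circular replicon.
    """

    id: str
    kind: str
    start: int
    end: int
    strand: str
    product: str = ""
    segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.id!r}: unknown kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id!r}: strand must be '+' or '-'")
        if not self.segments:
            self.segments = ((self.start, self.end),)
        for s, e in self.segments:
            if not (1 <= s <= e):
                raise ValueError(f"feature {self.id!r}: bad segment {s}..{e}")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)


@dataclass
class FeatureSet:
    """Features of one genome, kept sorted by start with unique ids."""

    genome_id: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.id))
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids: {dup}")

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def of_kind(self, *kinds: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind in kinds]

    def get(self, feature_id: str) -> GeneFeature:
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(feature_id)


# ---------------------------------------------------------------------------
# Reading


def read_genome(path, fmt: str = "fasta"):
    """Read genome sequences from FASTA or a GenBank flat file.

    FASTA returns a list of :class:`GenomeRecord`.  GenBank returns a list of
    ``(GenomeRecord, FeatureSet)`` tuples, with features mapped onto the
    internal annotation model (unmapped GenBank feature types are skipped).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt not in ("fasta", "genbank"):
        raise ValueError(f"unknown format {fmt!r}")
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # Biopython raises assorted exception types
        raise GenomeParseError(f"{path}: {exc}") from exc
    if not records:
        raise GenomeParseError(f"{path}: no records parsed as {fmt}")
    if fmt == "fasta":
        return [GenomeRecord(r.id, str(r.seq)) for r in records]
    out = []
    for r in records:
        topo = "circular" if r.annotations.get("topology") == "circular" else "linear"
        genome = GenomeRecord(r.id, str(r.seq), topology=topo)
        out.append((genome, _features_from_genbank(r)))
    return out


_GENBANK_KIND = {"CDS": "CDS", "tRNA": "tRNA", "ncRNA": "ncRNA", "misc_RNA": "ncRNA"}


def _features_from_genbank(rec: SeqRecord) -> FeatureSet:
    feats: list[GeneFeature] = []
    counter = 0
    for f in rec.features:
        kind = _GENBANK_KIND.get(f.type)
        if f.type == "rRNA":
            product = " ".join(f.qualifiers.get("product", [""]))
            m = re.search(r"(5S|16S|23S)", product)
            kind = f"rRNA-{m.group(1)}" if m else "ncRNA"
        if kind is None:
            continue
        counter += 1
        fid = f.qualifiers.get("locus_tag", f.qualifiers.get("gene", [None]))[0]
        if fid is None:
            fid = f"{rec.id}_{f.type}_{counter}"
        product = " ".join(f.qualifiers.get("product", [""]))
        segments = tuple(
            (int(part.start) + 1, int(part.end)) for part in f.location.parts
        )
        strand = "-" if f.location.strand == -1 else "+"
        feats.append(
            GeneFeature(
                id=fid,
                kind=kind,
                start=min(s for s, _ in segments),
                end=max(e for _, e in segments),
                strand=strand,
                product=product,
                segments=segments,
            )
        )
    return FeatureSet(rec.id, feats)


# ---------------------------------------------------------------------------
# GFF3

_GFF_TYPE = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA-5S": "rRNA",
    "rRNA-16S": "rRNA",
    "rRNA-23S": "rRNA",
    "ncRNA": "ncRNA",
}


def write_gff3(feature_sets: Iterable[FeatureSet], path) -> None:
    """Write features as GFF3 (version 3 pragma, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for fs in feature_sets:
            for f in fs:
                for s, e in f.segments:
                    attrs = [f"ID={f.id}", f"kind={f.kind}"]
                    if f.product:
                        attrs.append(f"product={_escape(f.product)}")
                    fh.write(
                        "\t".join(
                            [
                                fs.genome_id,
                                "archaeoscan",
                                _GFF_TYPE[f.kind],
                                str(s),
                                str(e),
                                ".",
                                f.strand,
                                ".",
                                ";".join(attrs),
                            ]
                        )
                        + "\n"
                    )


def _escape(text: str) -> str:
    return text.replace(";", "%3B").replace("=", "%3D").replace("\t", " ")


def _unescape(text: str) -> str:
    return text.replace("%3B", ";").replace("%3D", "=")


def read_gff3(path) -> dict[str, FeatureSet]:
    """Read GFF3 into FeatureSets keyed by genome (seqid).

    Rows sharing an ID are merged into one multi-segment feature (the
    wrap-around representation).  The ``kind`` attribute written by
    :func:`write_gff3` restores rRNA subtype; plain rRNA rows fall back to
    product-based detection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: dict[str, dict[str, dict]] = {}
    order: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GenomeParseError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attr = parts
            attrs = dict(
                kv.split("=", 1) for kv in attr.split(";") if "=" in kv
            )
            fid = attrs.get("ID", f"{seqid}_line{lineno}")
            kind = attrs.get("kind")
            if kind is None:
                if ftype == "rRNA":
                    m = re.search(r"(5S|16S|23S)", attrs.get("product", ""))
                    kind = f"rRNA-{m.group(1)}" if m else "ncRNA"
                elif ftype in _GENBANK_KIND:
                    kind = _GENBANK_KIND[ftype]
                else:
                    continue
            try:
                seg = (int(start), int(end))
            except ValueError as exc:
                raise GenomeParseError(f"{path}:{lineno}: bad coordinates") from exc
            genome_rows = rows.setdefault(seqid, {})
            if fid in genome_rows:
                genome_rows[fid]["segments"].append(seg)
            else:
                genome_rows[fid] = {
                    "kind": kind,
                    "strand": strand,
                    "product": _unescape(attrs.get("product", "")),
                    "segments": [seg],
                }
                order.setdefault(seqid, []).append(fid)
    out = {}
    for seqid, genome_rows in rows.items():
        feats = []
        for fid in order[seqid]:
            row = genome_rows[fid]
            segs = tuple(row["segments"])
            feats.append(
                GeneFeature(
                    id=fid,
                    kind=row["kind"],
                    start=min(s for s, _ in segs),
                    end=max(e for _, e in segs),
                    strand=row["strand"],
                    product=row["product"],
                    segments=segs,
                )
            )
        out[seqid] = FeatureSet(seqid, feats)
    return out


# ---------------------------------------------------------------------------
# Sequence extraction and translation


def extract_feature_sequence(genome: GenomeRecord, feature: GeneFeature) -> str:
    """Return the 5'→3' coding-strand sequence of a feature.

    Minus-strand features are reverse-complemented; multi-segment features
    are concatenated in the order their segments are listed (translation
    order).
    """
    parts = []
    for s, e in feature.segments:
        if not (1 <= s <= e <= len(genome)):
            raise ValueError(
                f"feature {feature.id!r}: segment {s}..{e} outside genome "
                f"{genome.id!r} of length {len(genome)}"
            )
        chunk = genome.sequence[s - 1 : e]
        parts.append(reverse_complement(chunk) if feature.strand == "-" else chunk)
    return "".join(parts)


def translate_cds(nt: str, readthrough_amber: bool = False) -> str:
    """Translate a coding sequence under genetic code table 11.

    Translation stops at the first stop codon (not included in the output).
    With ``readthrough_amber`` the amber codon TAG is decoded as pyrrolysine
    ('O') and translation continues; TAA and TGA always terminate.  Codons
    containing N translate to 'X'.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} is not a multiple of 3")
    aa = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            if codon == "TAG" and readthrough_amber:
                aa.append("O")
                continue
            break
        if "N" in codon:
            aa.append("X")
        else:
            aa.append(CODON_TO_AA[codon])
    return "".join(aa)


def write_protein_fasta(entries: dict[str, str], path, width: int = 70) -> None:
    """Write proteins as FASTA; the pyrrolysine letter 'O' is permitted."""
    with open(path, "w") as fh:
        for pid, seq in entries.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_protein_fasta(path) -> dict[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeParseError(f"{path}: no FASTA records")
    out: dict[str, str] = {}
    for r in records:
        if r.id in out:
            raise GenomeParseError(f"{path}: duplicate id {r.id!r}")
        out[r.id] = str(r.seq).upper()
    return out


def write_genome_fasta(genomes: Iterable[GenomeRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id} topology={g.topology}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")
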