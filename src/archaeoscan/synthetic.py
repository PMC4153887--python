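"""Synthetic archaeal-like genome generator with planted, truth-recorded signals.

Generates annotated genomes emulating the statistical envelope of small
archaeal chromosomes (1.5-3 Mbp at full scale, [G+C] 40-61%, coding density
~88-90%, mean CDS ~900 bp, configurable stop-codon usage) and plants
ground-truth instances of every signal the pipeline detects: amber-codon
(pyrrolysine) readthrough loci, the pylTSBCD cassette, ORB motif pairs
flanking an orc1/cdc6 gene, CRISPR repeat/spacer arrays and rRNA genes in
operonic or scattered arrangement.

The background is an order-0 model at the configured GC; coding regions are
sampled codon-by-codon with GC-weighted codon probabilities, so GC-dependent
statistics can be exercised across the realistic range.  Stop and start
codons are apportioned by largest remainder, making realized stop usage
match the configured fractions to within 1/n.  After assembly the background
is screened so that no window lies within Hamming distance 1 of a planted
ORB core and no exact off-array copy of a planted CRISPR repeat exists;
offending windows are re-rolled.  Everything is driven by one seeded RNG:
identical configs give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .genome_io import (
    CODON_TO_AA,
    FeatureSet,
    GeneFeature,
    GenomeRecord,
    reverse_complement,
    translate_cds,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
SENSE_CODONS = sorted(CODON_TO_AA)
CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _aa in CODONS_FOR_AA:
    CODONS_FOR_AA[_aa].sort()

#: Methanomassiliicoccales-type ORB core used as the default planted motif.
DEFAULT_ORB_CORE = "GTTCCAGTGGAAATGGAGGGGT"
#: 36-bp CRISPR direct repeat typical of gut-methanogen arrays.
DEFAULT_CRISPR_DR = "ATCTACACTAGTAGAAATTCTGAATGAGTTTTAGAC"


@dataclass
class PlantSpec:
    """One element to plant: kind plus kind-specific parameters."""

    kind: str  # {pyl_locus, pyl_cassette, orb_pair, crispr_array, rrna_set}
    params: dict = field(default_factory=dict)

    KINDS = ("pyl_locus", "pyl_cassette", "orb_pair", "crispr_array", "rrna_set")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown plant kind {self.kind!r}")


@dataclass
class SynthConfig:
    seed: int = 0
    genome_length: int = 200_000
    gc_fraction: float = 0.556
    target_coding_density: float = 0.89
    mean_cds_length: int = 900
    stop_usage: tuple[float, float, float] = (0.45, 0.10, 0.45)  # TAA, TAG, TGA
    start_usage: tuple[float, float, float] = (0.85, 0.10, 0.05)  # ATG, GTG, TTG
    n_genes: Optional[int] = None  # overrides the density-derived count
    topology: str = "circular"
    genome_id: str = "synth"
    planted: list[PlantSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(sum(self.stop_usage) - 1.0) > 1e-9:
            raise ValueError("stop_usage must sum to 1")
        if abs(sum(self.start_usage) - 1.0) > 1e-9:
            raise ValueError("start_usage must sum to 1")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must be in (0, 1)")
        if not (0.0 < self.target_coding_density <= 1.0):
            raise ValueError("target_coding_density must be in (0, 1]")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SynthConfig":
        d = json.loads(text)
        d["planted"] = [PlantSpec(**p) for p in d.get("planted", [])]
        d["stop_usage"] = tuple(d["stop_usage"])
        d["start_usage"] = tuple(d.get("start_usage", (0.85, 0.10, 0.05)))
        return cls(**d)


@dataclass
class PylLocusParts:
    """A planted readthrough locus in coding orientation.

    ``cds_nt`` is the annotated CDS: the first ``split_position`` codons of
    the reference followed by the amber TAG.  ``extension_nt`` continues in
    frame with the reference residues after the amber position and ends with
    a non-amber stop, so standard-code translation stops at the amber while
    readthrough translation yields the reference with 'O' substituted at
    position ``split_position + 1`` (1-based).
    """

    cds_nt: str
    extension_nt: str
    split_position: int
    fused_protein: str
    upstream_aa: str
    extension_aa: str


class PackingError(ValueError):
    """Planted footprint exceeds the genome length."""


# ---------------------------------------------------------------------------
# Codon-level sampling helpers


def _base_weights(gc: float) -> dict[str, float]:
    return {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}


def _codon_weights(codons: list[str], gc: float) -> np.ndarray:
    bw = _base_weights(gc)
    w = np.array([bw[c[0]] * bw[c[1]] * bw[c[2]] for c in codons], dtype=float)
    return w / w.sum()


def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=n, p=probs)) if n > 0 else ""


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def back_translate(protein: str, gc: float, rng: np.random.Generator) -> str:
    """Back-translate with codon choice weighted toward the target GC."""
    parts = []
    for aa in protein:
        codons = CODONS_FOR_AA.get(aa)
        if codons is None:  # X/O or other non-standard: encode as GCN-ish Ala
            codons = CODONS_FOR_AA["A"]
        parts.append(rng.choice(codons, p=_codon_weights(codons, gc)))
    return "".join(parts)


def _apportion(n: int, probs: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items over the given fractions."""
    raw = [n * p for p in probs]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(probs)), key=lambda i: (counts[i] - raw[i], i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# Planted element construction (all in coding orientation first)


def plant_pyl_locus(
    reference_protein: str,
    split_position: int,
    gc: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> PylLocusParts:
    """Encode a reference protein as a TAG-interrupted gene pair.

    The annotated CDS carries the first ``split_position`` residues and ends
    at the amber codon; the in-frame continuation encodes the residues after
    the amber-substituted one.  The readthrough fusion therefore equals the
    reference with 'O' at 1-based position ``split_position + 1`` and has
    the reference's length.
    """
    n = len(reference_protein)
    if not (1 < split_position < n - 1):
        # p = n-1 would leave an empty extension: also a terminal split
        raise ValueError(
            f"split_position must satisfy 1 < p < {n - 1}, got {split_position}"
        )
    rng = rng if rng is not None else np.random.default_rng(0)
    upstream_aa = reference_protein[:split_position]
    extension_aa = reference_protein[split_position + 1 :]
    cds_nt = back_translate(upstream_aa, gc, rng) + "TAG"
    terminal_stop = "TAA" if rng.random() < 0.5 else "TGA"
    extension_nt = back_translate(extension_aa, gc, rng) + terminal_stop
    fused = upstream_aa + "O" + extension_aa
    return PylLocusParts(
        cds_nt=cds_nt,
        extension_nt=extension_nt,
        split_position=split_position,
        fused_protein=fused,
        upstream_aa=upstream_aa,
        extension_aa=extension_aa,
    )


@dataclass
class _Block:
    seq: str
    features: list[GeneFeature]  # block-local 1-based coordinates
    kind: str  # "gene" or a plant kind
    truth: dict = field(default_factory=dict)
    # local (start, end, key) anchors remapped to genome coordinates on placement
    anchors: list[tuple[int, int, str]] = field(default_factory=list)


def _flip_block(block: _Block) -> _Block:
    """Reverse-complement a block, remapping features and anchors."""
    n = len(block.seq)
    feats = []
    for f in block.features:
        segs = tuple(
            sorted(((n - e + 1, n - s + 1) for s, e in f.segments))
        )
        feats.append(
            GeneFeature(
                id=f.id,
                kind=f.kind,
                start=n - f.end + 1,
                end=n - f.start + 1,
                strand="-" if f.strand == "+" else "+",
                product=f.product,
                segments=segs,
            )
        )
    anchors = [(n - e + 1, n - s + 1, key) for s, e, key in block.anchors]
    return _Block(
        seq=reverse_complement(block.seq),
        features=feats,
        kind=block.kind,
        truth=dict(block.truth, strand_flipped=True),
        anchors=anchors,
    )


def _build_gene_block(
    gid: str,
    n_codons: int,
    start_codon: str,
    stop_codon: str,
    gc: float,
    rng: np.random.Generator,
    product: str = "hypothetical protein",
) -> _Block:
    body = rng.choice(
        SENSE_CODONS, size=max(n_codons - 1, 1), p=_codon_weights(SENSE_CODONS, gc)
    )
    seq = start_codon + "".join(body) + stop_codon
    feat = GeneFeature(gid, "CDS", 1, len(seq), "+", product)
    return _Block(seq, [feat], "gene")


def _build_pyl_locus_block(
    spec: PlantSpec, gc: float, rng: np.random.Generator, idx: int
) -> _Block:
    params = spec.params
    ref = params.get("reference_protein")
    if ref is None:
        ref = random_protein(rng, int(params.get("reference_length", 300)))
    split = int(params.get("split_position", len(ref) // 2))
    parts = plant_pyl_locus(ref, split, gc, rng)
    cds_id = f"pyl_locus_{idx}"
    seq = parts.cds_nt + parts.extension_nt
    feat = GeneFeature(
        cds_id, "CDS", 1, len(parts.cds_nt), "+",
        "TAG-terminated methyltransferase-like protein",
    )
    truth = {
        "kind": "pyl_locus",
        "cds_id": cds_id,
        "reference_id": params.get("reference_id", f"ref_{cds_id}"),
        "reference_protein": ref,
        "split_position": split,
        "fused_protein": parts.fused_protein,
        "upstream_aa": parts.upstream_aa,
        "extension_aa": parts.extension_aa,
    }
    anchors = [
        (1, len(parts.cds_nt), "cds"),
        (len(parts.cds_nt) - 2, len(parts.cds_nt), "amber_codon"),
        (len(parts.cds_nt) + 1, len(seq), "extension_region"),
    ]
    return _Block(seq, [feat], "pyl_locus", truth, anchors)


_CASSETTE_LENGTHS = {"pylS": 420, "pylB": 350, "pylC": 360, "pylD": 270}


def _build_pyl_cassette_block(
    spec: PlantSpec, gc: float, rng: np.random.Generator, idx: int
) -> _Block:
    proteins = dict(spec.params.get("proteins", {}))
    for name, ln in _CASSETTE_LENGTHS.items():
        proteins.setdefault(name, random_protein(rng, ln))
        # genes are built with an ATG start, so the truth protein starts Met
        proteins[name] = "M" + proteins[name][1:]
    include = spec.params.get("include", ["pylT", "pylS", "pylB", "pylC", "pylD"])
    seq_parts: list[str] = []
    feats: list[GeneFeature] = []
    gene_ids: dict[str, str] = {}
    pos = 0
    for name in ["pylT", "pylS", "pylB", "pylC", "pylD"]:
        if name not in include:
            continue
        gid = f"{name}_{idx}"
        if name == "pylT":
            # tRNA-Pyl gene with the CTA anticodon embedded mid-gene
            body = random_dna(rng, 32, gc) + "CTA" + random_dna(rng, 37, gc)
            product = "tRNA-Pyl (anticodon CUA)"
            feats.append(GeneFeature(gid, "tRNA", pos + 1, pos + len(body), "+", product))
        else:
            stop = "TAA" if rng.random() < 0.5 else "TGA"
            body = "ATG" + back_translate(proteins[name][1:], gc, rng) + stop
            product = {
                "pylS": "pyrrolysyl-tRNA synthetase PylS",
                "pylB": "pyrrolysine biosynthesis protein PylB",
                "pylC": "pyrrolysine biosynthesis protein PylC",
                "pylD": "pyrrolysine biosynthesis protein PylD",
            }[name]
            feats.append(GeneFeature(gid, "CDS", pos + 1, pos + len(body), "+", product))
        gene_ids[name] = gid
        seq_parts.append(body)
        pos += len(body)
        gap = int(rng.integers(20, 120))
        seq_parts.append(random_dna(rng, gap, gc))
        pos += gap
    truth = {
        "kind": "pyl_cassette",
        "genes": gene_ids,
        "proteins": {k: proteins[k] for k in proteins if k in include or k != "pylT"},
        "include": list(include),
    }
    return _Block("".join(seq_parts), feats, "pyl_cassette", truth)


def _build_orb_pair_block(
    spec: PlantSpec, gc: float, rng: np.random.Generator, idx: int
) -> _Block:
    p = spec.params
    core = p.get("core", DEFAULT_ORB_CORE)
    spacing = int(p.get("spacing", 39))
    orientation = p.get("orientation", "inverted")
    gene_distance = int(p.get("gene_distance", 2000))
    with_gene = bool(p.get("with_gene", True))
    hit2 = reverse_complement(core) if orientation == "inverted" else core
    seq = core + random_dna(rng, spacing - 1, gc) + hit2
    feats: list[GeneFeature] = []
    anchors = [(1, len(core), "orb1"), (len(seq) - len(core) + 1, len(seq), "orb2")]
    truth = {
        "kind": "orb_pair",
        "core": core,
        "spacing": spacing,
        "orientation": orientation,
        "with_gene": with_gene,
    }
    if with_gene:
        pad = random_dna(rng, max(gene_distance - 1, 0), gc)
        stop = "TAA" if rng.random() < 0.5 else "TGA"
        gene_nt = "ATG" + back_translate(random_protein(rng, 400), gc, rng) + stop
        gid = f"cdc6_{idx}"
        gstart = len(seq) + len(pad) + 1
        feats.append(
            GeneFeature(
                gid, "CDS", gstart, gstart + len(gene_nt) - 1, "+",
                "orc1/cdc6 replication initiator protein",
            )
        )
        anchors.append((gstart, gstart + len(gene_nt) - 1, "gene"))
        seq = seq + pad + gene_nt
        truth["gene_id"] = gid
    return _Block(seq, feats, "orb_pair", truth, anchors)


def _build_crispr_block(
    spec: PlantSpec, gc: float, rng: np.random.Generator, idx: int
) -> _Block:
    p = spec.params
    dr = p.get("dr", DEFAULT_CRISPR_DR)
    n_spacers = int(p.get("n_spacers", 12))
    lo, hi = p.get("spacer_len_range", (25, 28))
    spacers = [
        random_dna(rng, int(rng.integers(lo, hi + 1)), gc) for _ in range(n_spacers)
    ]
    parts = [dr]
    anchors = [(1, len(dr), "repeat")]
    pos = len(dr)
    for sp in spacers:
        parts.append(sp)
        pos += len(sp)
        parts.append(dr)
        anchors.append((pos + 1, pos + len(dr), "repeat"))
        pos += len(dr)
    truth = {
        "kind": "crispr_array",
        "dr": dr,
        "n_repeats": n_spacers + 1,
        "n_spacers": n_spacers,
        "spacers": spacers,
    }
    return _Block("".join(parts), [], "crispr_array", truth, anchors)


_RRNA_LENGTHS = {"rRNA-16S": 1480, "rRNA-23S": 2900, "rRNA-5S": 120}


def _build_rrna_blocks(
    spec: PlantSpec, gc: float, rng: np.random.Generator, idx: int
) -> list[_Block]:
    arrangement = spec.params.get("arrangement", "scattered")
    kinds = ["rRNA-16S", "rRNA-23S", "rRNA-5S"]
    if arrangement == "operonic":
        seq_parts, feats, anchors, pos = [], [], [], 0
        for k in kinds:
            body = random_dna(rng, _RRNA_LENGTHS[k], gc)
            gid = f"{k.replace('rRNA-', 'rrn_')}_{idx}"
            feats.append(
                GeneFeature(gid, k, pos + 1, pos + len(body), "+",
                            f"{k.replace('rRNA-', '')} ribosomal RNA")
            )
            anchors.append((pos + 1, pos + len(body), k))
            seq_parts.append(body)
            pos += len(body)
            if k != "rRNA-5S":
                gap = int(rng.integers(60, 150))  # short ITS keeps the operon intact
                seq_parts.append(random_dna(rng, gap, gc))
                pos += gap
        truth = {"kind": "rrna_set", "arrangement": "operonic"}
        return [_Block("".join(seq_parts), feats, "rrna_set", truth, anchors)]
    blocks = []
    for k in kinds:
        body = random_dna(rng, _RRNA_LENGTHS[k], gc)
        gid = f"{k.replace('rRNA-', 'rrn_')}_{idx}"
        feat = GeneFeature(gid, k, 1, len(body), "+",
                           f"{k.replace('rRNA-', '')} ribosomal RNA")
        truth = {"kind": "rrna_set", "arrangement": "scattered", "member": k}
        blocks.append(_Block(body, [feat], "rrna_set", truth, [(1, len(body), k)]))
    return blocks


# ---------------------------------------------------------------------------
# Assembly


def generate_genome(
    config: SynthConfig,
) -> tuple[GenomeRecord, FeatureSet, dict]:
    """Generate a genome, its annotation, and the planted-truth record.

    Deterministic for a fixed config (single seeded RNG).  Raises
    :class:`PackingError` when the planted footprint cannot fit.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    L = config.genome_length

    planted_blocks: list[_Block] = []
    scattered_rrna: list[_Block] = []
    for idx, spec in enumerate(config.planted, start=1):
        if spec.kind == "pyl_locus":
            blocks = [_build_pyl_locus_block(spec, gc, rng, idx)]
        elif spec.kind == "pyl_cassette":
            blocks = [_build_pyl_cassette_block(spec, gc, rng, idx)]
        elif spec.kind == "orb_pair":
            blocks = [_build_orb_pair_block(spec, gc, rng, idx)]
        elif spec.kind == "crispr_array":
            blocks = [_build_crispr_block(spec, gc, rng, idx)]
        else:
            blocks = _build_rrna_blocks(spec, gc, rng, idx)
        strand = spec.params.get("strand")
        if strand == "-" or (strand is None and spec.kind != "rrna_set"
                             and rng.random() < 0.5):
            blocks = [_flip_block(b) for b in blocks]
        if spec.kind == "rrna_set" and len(blocks) > 1:
            scattered_rrna.extend(blocks)
        else:
            planted_blocks.extend(blocks)

    planted_bp = sum(len(b.seq) for b in planted_blocks + scattered_rrna)
    if planted_bp > L:
        raise PackingError(
            f"planted footprint {planted_bp} bp exceeds genome length {L} bp"
        )

    planted_feature_bp = sum(
        f.length for b in planted_blocks + scattered_rrna for f in b.features
    )
    target_coding_bp = int(round(config.target_coding_density * L))
    if config.n_genes is not None:
        n_bg = max(int(config.n_genes) - sum(
            len(b.features) for b in planted_blocks + scattered_rrna), 0)
    else:
        n_bg = max(
            int(round((target_coding_bp - planted_feature_bp) / config.mean_cds_length)),
            0,
        )

    # Background CDS lengths: gamma-distributed codon counts rescaled so the
    # realized coding density lands on target.
    mean_codons = config.mean_cds_length / 3
    if n_bg > 0:
        lens = rng.gamma(shape=2.0, scale=mean_codons / 2.0, size=n_bg)
        lens = np.maximum(lens, 60)
        want_bp = max(target_coding_bp - planted_feature_bp, n_bg * 180)
        lens = lens * (want_bp / 3) / lens.sum()
        codon_counts = np.maximum(lens.round().astype(int), 60)
    else:
        codon_counts = np.array([], dtype=int)

    stops = []
    for stop, cnt in zip(("TAA", "TAG", "TGA"), _apportion(n_bg, config.stop_usage)):
        stops.extend([stop] * cnt)
    starts = []
    for start, cnt in zip(("ATG", "GTG", "TTG"), _apportion(n_bg, config.start_usage)):
        starts.extend([start] * cnt)
    rng.shuffle(stops)
    rng.shuffle(starts)

    bg_blocks = []
    for i in range(n_bg):
        block = _build_gene_block(
            f"g{i + 1:05d}", int(codon_counts[i]), starts[i], stops[i], gc, rng
        )
        if rng.random() < 0.5:
            block = _flip_block(block)
        bg_blocks.append(block)

    # Interleave: planted blocks at random slots; scattered rRNA blocks at
    # spread-out slots with at least one intervening gene so no 16S/23S pair
    # can mimic an operon.
    items = list(bg_blocks)
    for b in planted_blocks:
        pos = int(rng.integers(0, len(items) + 1))
        items.insert(pos, b)
    if scattered_rrna:
        n = len(items)
        step = max(n // (len(scattered_rrna) + 1), 2)
        for j, b in enumerate(scattered_rrna):
            items.insert(min((j + 1) * step + j, len(items)), b)

    total_block_bp = sum(len(b.seq) for b in items)
    noncoding_bp = L - total_block_bp
    if noncoding_bp < len(items) + 1:
        raise PackingError(
            f"cannot fit {total_block_bp} bp of blocks plus intergenic spacing "
            f"into {L} bp"
        )
    n_gaps = len(items) + 1
    weights = rng.dirichlet(np.ones(n_gaps))
    gaps = rng.multinomial(noncoding_bp, weights)

    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    truth_entries: list[dict] = []
    offset = 0
    for i, block in enumerate(items):
        gap = int(gaps[i])
        seq_parts.append(random_dna(rng, gap, gc))
        offset += gap
        for f in block.features:
            segs = tuple((offset + s, offset + e) for s, e in f.segments)
            features.append(
                GeneFeature(
                    id=f.id, kind=f.kind, start=offset + f.start, end=offset + f.end,
                    strand=f.strand, product=f.product, segments=segs,
                )
            )
        if block.kind != "gene":
            entry = dict(block.truth)
            entry["span"] = [offset + 1, offset + len(block.seq)]
            for s, e, key in block.anchors:
                entry.setdefault("anchors", {}).setdefault(key, []).append(
                    [offset + s, offset + e]
                )
            truth_entries.append(entry)
        seq_parts.append(block.seq)
        offset += len(block.seq)
    seq_parts.append(random_dna(rng, int(gaps[-1]), gc))
    sequence = "".join(seq_parts)
    assert len(sequence) == L

    sequence = _screen_collisions(sequence, truth_entries, rng, gc)

    truth_entries = _postprocess_truth(truth_entries, features, sequence)
    genome = GenomeRecord(config.genome_id, sequence, topology=config.topology)
    feature_set = FeatureSet(config.genome_id, features)
    truth = {
        "genome_id": config.genome_id,
        "seed": config.seed,
        "genome_length": L,
        "n_features": len(features),
        "planted": truth_entries,
    }
    return genome, feature_set, truth


def _postprocess_truth(entries, features, sequence):
    """Fill genome-coordinate fields derived from anchors."""
    by_id = {f.id: f for f in features}
    for e in entries:
        anchors = e.get("anchors", {})
        if e["kind"] == "pyl_locus":
            cds = by_id[e["cds_id"]]
            e["cds_start"], e["cds_end"] = cds.start, cds.end
            e["strand"] = cds.strand
            amber = anchors["amber_codon"][0]
            # coordinate of the coding-strand T of the amber codon
            e["amber_genome_position"] = amber[0] if cds.strand == "+" else amber[1]
        elif e["kind"] == "orb_pair":
            hits = sorted(anchors["orb1"] + anchors["orb2"])
            flipped = e.pop("strand_flipped", False)
            strands = ("+", "-") if e["orientation"] == "inverted" else ("+", "+")
            if flipped:
                strands = tuple("-" if s == "+" else "+" for s in strands[::-1])
            e["hits"] = [
                {"start": s, "end": en, "strand": st}
                for (s, en), st in zip(hits, strands)
            ]
            if "gene_id" in e:
                g = by_id[e["gene_id"]]
                e["gene_start"], e["gene_end"], e["gene_strand"] = g.start, g.end, g.strand
        elif e["kind"] == "crispr_array":
            reps = sorted(anchors["repeat"])
            e["repeat_positions"] = [[s, en] for s, en in reps]
            if e.pop("strand_flipped", False):
                e["dr_as_planted"] = e["dr"]
                e["dr"] = reverse_complement(e["dr"])
                e["spacers"] = [reverse_complement(s) for s in e["spacers"]][::-1]
        e.pop("strand_flipped", None)
    return entries


def _screen_collisions(sequence, truth_entries, rng, gc):
    """Re-roll background windows colliding with planted ORB cores or DRs."""
    from .orb import OrbMotif, scan_motif  # local import avoids a cycle at import time

    def spans_for(kind, key):
        spans = []
        for e in truth_entries:
            if e["kind"] == kind:
                for s, en in e.get("anchors", {}).get(key, []):
                    spans.append((s, en))
        return spans

    for attempt in range(10):
        dirty = False
        seq_list = None
        for e in truth_entries:
            if e["kind"] == "orb_pair":
                core = e["core"]
                allowed = set()
                for s, en in e["anchors"].get("orb1", []) + e["anchors"].get("orb2", []):
                    allowed.add(s)
                g = GenomeRecord("screen", sequence)
                for hit in scan_motif(g, OrbMotif(core=core, max_mismatch=1)):
                    if hit.start in allowed:
                        continue
                    if seq_list is None:
                        seq_list = list(sequence)
                    s0 = (hit.start - 1) % len(sequence)
                    repl = random_dna(rng, len(core), gc)
                    for k, ch in enumerate(repl):
                        seq_list[(s0 + k) % len(sequence)] = ch
                    dirty = True
            elif e["kind"] == "crispr_array":
                dr = e["dr"]
                span = e["span"]
                for probe in (dr, reverse_complement(dr)):
                    start = 0
                    while True:
                        i = sequence.find(probe, start)
                        if i < 0:
                            break
                        start = i + 1
                        if span[0] - len(dr) <= i + 1 <= span[1]:
                            continue
                        if seq_list is None:
                            seq_list = list(sequence)
                        repl = random_dna(rng, len(dr), gc)
                        seq_list[i : i + len(dr)] = list(repl)
                        dirty = True
        if not dirty:
            return sequence
        sequence = "".join(seq_list)
    return sequence


# ---------------------------------------------------------------------------
# Orthology fixture design: proteome trios with prescribed family patterns


def make_proteome_trio(
    family_patterns: list[tuple[str, ...]],
    protein_length: int = 200,
    divergence: float = 0.10,
    seed: int = 0,
    proteome_ids: tuple[str, str, str] = ("A", "B", "C"),
) -> tuple[dict[str, dict[str, str]], list[dict]]:
    """Build three proteomes realizing a known family membership design.

    Each pattern is a subset of the proteome ids; members of a family carry
    copies of one ancestral random protein with ``divergence`` of positions
    substituted, so within-family identity stays far above the 30% screen
    while unrelated proteins share no long local alignment.  Returns the
    proteomes and a per-family design record (the generator truth).
    """
    rng = np.random.default_rng(seed)
    proteomes: dict[str, dict[str, str]] = {pid: {} for pid in proteome_ids}
    design = []
    for i, pattern in enumerate(family_patterns, start=1):
        ancestor = random_protein(rng, protein_length)
        members = {}
        for pid in proteome_ids:
            if pid not in pattern:
                continue
            seq = list(ancestor)
            n_mut = int(round(divergence * protein_length))
            sites = rng.choice(protein_length, size=n_mut, replace=False)
            for s in sites:
                choices = [a for a in AA20 if a != seq[s]]
                seq[s] = choices[int(rng.integers(len(choices)))]
            pid_name = f"{pid}_fam{i:03d}"
            proteomes[pid][pid_name] = "".join(seq)
            members[pid] = pid_name
        design.append({"family": i, "pattern": sorted(pattern), "members": members})
    return proteomes, design
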