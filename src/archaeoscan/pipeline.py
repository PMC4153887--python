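"""Pipeline orchestration: run every stage and emit machine-readable reports.

Reports are the pipeline's API: one versioned JSON summary plus per-module
TSV/GFF3/FASTA artifacts.  All coordinates in TSV/JSON reports are 1-based
inclusive; BED output is 0-based half-open (the BED standard); every file
carries a commented header line saying which.  Runs are deterministic for a
fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .amber import PylScanParams, ReferenceProteinDB, detect_pyl_cassette, \
    detect_readthrough_candidates
from .crispr import CrisprParams, array_summary, find_arrays
from .genome_io import (
    FeatureSet,
    GenomeRecord,
    read_genome,
    read_gff3,
    read_protein_fasta,
    write_genome_fasta,
    write_gff3,
    write_protein_fasta,
)
from .markers import classify_matrix, read_presence_matrix, read_taxon_groups
from .orb import OrbMotif, call_origin, pair_hits, scan_motif
from .orthology import OrthoParams, Proteome, screen_against, venn_partition
from .stats import codon_usage, rrna_organization, stop_codon_usage, summarize
from .synthetic import SynthConfig, generate_genome

logger = logging.getLogger("archaeoscan")

SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    genome: Optional[str] = None  # FASTA
    gff: Optional[str] = None
    genbank: Optional[str] = None
    refdb: Optional[str] = None  # protein FASTA for the Pyl scan
    proteomes: list[str] = field(default_factory=list)
    ref_proteomes: list[str] = field(default_factory=list)
    matrix: Optional[str] = None
    groups: Optional[str] = None
    out_dir: str = "archaeoscan_out"
    seed: int = 0
    orb_core: Optional[str] = None
    orb_max_mismatch: int = 4
    max_pair_spacing: int = 300
    origin_window: int = 10_000
    circular: bool = True

    @classmethod
    def from_json_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _load_genome(config: PipelineConfig) -> tuple[GenomeRecord, Optional[FeatureSet]]:
    if config.genbank:
        genome, features = read_genome(config.genbank, "genbank")[0]
        return genome, features
    if not config.genome:
        raise ValueError("config needs a genome (FASTA) or a GenBank file")
    genome = read_genome(config.genome, "fasta")[0]
    if config.circular:
        genome = GenomeRecord(genome.id, genome.sequence, topology="circular")
    features = None
    if config.gff:
        sets = read_gff3(config.gff)
        features = sets.get(genome.id) or next(iter(sets.values()))
    return genome, features


def _tsv(path: Path, comment: str, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_stats(genome, features, out_dir: Path) -> dict:
    summary = summarize(genome, features)
    report = {
        "genome_size": summary.genome_size,
        "gc_fraction": round(summary.gc_fraction, 4),
        "coding_fraction": round(summary.coding_fraction, 4),
        "intergenic_mean": round(summary.intergenic_mean, 2),
        "intergenic_sd": round(summary.intergenic_sd, 2),
        "gene_counts": summary.gene_counts,
        "cds_mean_length": round(summary.cds_mean_length, 1),
        "cds_median_length": summary.cds_median_length,
        "gene_gc_mean": round(summary.gene_gc_mean, 4),
    }
    if features.of_kind("CDS"):
        su = stop_codon_usage(genome, features)
        report["stop_usage"] = {
            "TAA": round(su.fraction_TAA, 4),
            "TAG": round(su.fraction_TAG, 4),
            "TGA": round(su.fraction_TGA, 4),
            "n_cds": su.n_cds,
            "n_unrecognized": su.n_unrecognized,
        }
        cu = codon_usage(genome, features)
        report["start_usage"] = cu.start_counts
        report["gc3"] = round(cu.gc3(), 4)
    rr = rrna_organization(features) if features.of_kind("rRNA-16S", "rRNA-23S") \
        else None
    if rr is not None:
        report["rrna_organization"] = {
            "classification": rr.classification, "gene_order": rr.gene_order,
        }
    with open(out_dir / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_pyl_scan(genome, features, refdb_path, out_dir: Path,
                 params: Optional[PylScanParams] = None) -> dict:
    refdb = ReferenceProteinDB.from_fasta(refdb_path)
    candidates = detect_readthrough_candidates(genome, features, refdb, params)
    cassette = detect_pyl_cassette(genome, features, refdb)
    rows = [
        [c.cds_id, c.amber_genome_position, len(c.upstream_aa), len(c.extension_aa),
         c.upstream_hit.subject_id, f"{c.upstream_hit.identity:.1f}",
         f"{c.extension_hit.identity:.1f}", c.n_ambers, len(c.fused_protein)]
        for c in candidates
    ]
    _tsv(
        out_dir / "pyl_candidates.tsv",
        "Pyl readthrough candidates; coordinates 1-based inclusive",
        ["cds_id", "amber_position", "upstream_aa", "extension_aa", "best_hit",
         "upstream_identity", "extension_identity", "n_ambers", "fused_length"],
        rows,
    )
    if candidates:
        write_protein_fasta(
            {f"{c.cds_id}_fused": c.fused_protein for c in candidates},
            out_dir / "pyl_fusions.faa",
        )
    return {
        "n_candidates": len(candidates),
        "candidates": [c.cds_id for c in candidates],
        "cassette": {k: bool(v) for k, v in cassette.present.items()},
    }


def run_orb_scan(genome, features, out_dir: Path, core=None, max_mismatch=4,
                 max_pair_spacing=300, origin_window=10_000) -> dict:
    motif = OrbMotif(core=core) if core else OrbMotif()
    if max_mismatch is not None:
        motif = OrbMotif(core=motif.core, max_mismatch=max_mismatch)
    hits = scan_motif(genome, motif)
    pairs = pair_hits(hits, max_pair_spacing)
    with open(out_dir / "orb_hits.bed", "w") as fh:
        fh.write("# ORB motif hits; BED: 0-based half-open\n")
        for h in hits:
            fh.write(f"{genome.id}\t{h.start - 1}\t{h.end}\tORB\t"
                     f"{h.mismatches}\t{h.strand}\n")
    _tsv(
        out_dir / "orb_pairs.tsv",
        "ORB motif pairs; coordinates 1-based inclusive; spacing = start2 - end1",
        ["start1", "end1", "strand1", "start2", "end2", "strand2", "spacing",
         "orientation"],
        [[p.hit1.start, p.hit1.end, p.hit1.strand, p.hit2.start, p.hit2.end,
          p.hit2.strand, p.spacing, p.orientation] for p in pairs],
    )
    origins = []
    if features is not None:
        origins = call_origin(pairs, features, origin_window)
        _tsv(
            out_dir / "origin_candidates.tsv",
            "Origin candidates; coordinates 1-based inclusive",
            ["pair_start", "pair_end", "gene_id", "distance", "side"],
            [[o.pair.hit1.start, o.pair.hit2.end, o.gene_id, o.distance, o.side]
             for o in origins],
        )
    return {
        "n_hits": len(hits),
        "n_pairs": len(pairs),
        "n_origin_candidates": len(origins),
        "core": motif.core,
    }


def run_crispr_scan(genome, out_dir: Path, params: Optional[CrisprParams] = None) -> dict:
    arrays = find_arrays(genome, params)
    _tsv(
        out_dir / "crispr_arrays.tsv",
        "CRISPR arrays; coordinates 1-based inclusive",
        ["start", "end", "dr_length", "dr_consensus", "n_repeats", "n_spacers",
         "spacer_len_min", "spacer_len_max"],
        [[a.start, a.end, len(a.dr_consensus), a.dr_consensus, a.n_repeats,
          a.n_spacers, array_summary(a)["spacer_len_min"],
          array_summary(a)["spacer_len_max"]] for a in arrays],
    )
    with open(out_dir / "crispr_repeats.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for i, a in enumerate(arrays, 1):
            for j, (s, e) in enumerate(a.repeat_positions, 1):
                fh.write(f"{genome.id}\tarchaeoscan\tdirect_repeat\t{s}\t{e}\t.\t+"
                         f"\t.\tID=crispr{i}_repeat{j};Parent=crispr{i}\n")
    spacer_entries = {
        f"crispr{i}_spacer{j}": sp
        for i, a in enumerate(arrays, 1)
        for j, sp in enumerate(a.spacers, 1)
    }
    if spacer_entries:
        with open(out_dir / "crispr_spacers.fna", "w") as fh:
            for name, sp in spacer_entries.items():
                fh.write(f">{name}\n{sp}\n")
    return {"n_arrays": len(arrays), "arrays": [array_summary(a) for a in arrays]}


def run_ortho(proteome_paths, ref_paths, out_dir: Path,
              params: Optional[OrthoParams] = None) -> dict:
    params = params or OrthoParams()
    proteomes = [
        Proteome(Path(p).stem, read_protein_fasta(p)) for p in proteome_paths
    ]
    report: dict = {"proteomes": {p.id: len(p) for p in proteomes}}
    if len(proteomes) >= 3:
        part = venn_partition(proteomes[0], proteomes[1], proteomes[2], params)
        report["venn_counts"] = part.counts()
        report["core_size"] = part.core_count()
        with open(out_dir / "venn_partition.json", "w") as fh:
            json.dump(part.counts(), fh, indent=2, sort_keys=True)
    if ref_paths:
        refs = [Proteome(Path(p).stem, read_protein_fasta(p)) for p in ref_paths]
        targets = proteomes[0].proteins
        matrix, absent = screen_against(targets, refs, params)
        matrix.astype(int).to_csv(out_dir / "outgroup_presence.tsv", sep="\t")
        report["outgroup_screen"] = {
            "n_targets": len(targets),
            "absent_from_all": absent,
        }
    return report


def run_markers(matrix_path, groups_path, out_dir: Path, strict=True) -> dict:
    matrix = read_presence_matrix(matrix_path)
    groups = read_taxon_groups(groups_path)
    cats, hist = classify_matrix(matrix, groups, strict=strict)
    _tsv(
        out_dir / "marker_categories.tsv",
        "Phyletic marker categories (1-6 or none) per family",
        ["family", "category"],
        [[fam, cat if cat is not None else "none"] for fam, cat in cats.items()],
    )
    return {"histogram": hist, "n_families": len(cats)}


def run_all(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns (and writes) the JSON summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("out_dir",)
        },
        "modules": {},
    }
    genome = features = None
    if config.genome or config.genbank:
        genome, features = _load_genome(config)
        logger.info("genome %s: %d bp", genome.id, len(genome))
        if features is not None and len(features) >= 2:
            summary["modules"]["stats"] = run_stats(genome, features, out_dir)
        if config.refdb and features is not None:
            summary["modules"]["pyl_scan"] = run_pyl_scan(
                genome, features, config.refdb, out_dir
            )
        summary["modules"]["orb_scan"] = run_orb_scan(
            genome, features, out_dir, config.orb_core, config.orb_max_mismatch,
            config.max_pair_spacing, config.origin_window,
        )
        summary["modules"]["crispr_scan"] = run_crispr_scan(genome, out_dir)
    if len(config.proteomes) >= 2:
        summary["modules"]["ortho"] = run_ortho(
            config.proteomes, config.ref_proteomes, out_dir
        )
    if config.matrix and config.groups:
        summary["modules"]["markers"] = run_markers(
            config.matrix, config.groups, out_dir
        )
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def simulate(
    configs: list[SynthConfig], out_dir, write_config: bool = True
) -> list[dict]:
    """Generate synthetic genomes and write FASTA + GFF3 + truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for config in configs:
        genome, features, truth = generate_genome(config)
        stem = out_dir / config.genome_id
        write_genome_fasta([genome], f"{stem}.fna")
        write_gff3([features], f"{stem}.gff3")
        with open(f"{stem}.truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        if write_config:
            with open(f"{stem}.config.json", "w") as fh:
                fh.write(config.to_json())
        records.append(truth)
    return records
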