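"""Amber-readthrough (Pyl) detection: planted recovery, fusion invariants and
specificity on TAG-rich genomes without readthrough structure."""

import pytest

from archaeoscan.amber import (
    PylScanParams,
    ReferenceProteinDB,
    detect_pyl_cassette,
    detect_readthrough_candidates,
    extension_translation,
)
from archaeoscan.genome_io import FeatureSet, GeneFeature, GenomeRecord
from archaeoscan.synthetic import (
    PlantSpec,
    SynthConfig,
    generate_genome,
    random_protein,
)

from conftest import truth_by_kind

import numpy as np


def _tag_cds(downstream: str) -> tuple[GenomeRecord, GeneFeature]:
    seq = "ATGAAATAG" + downstream
    return GenomeRecord("g", seq), GeneFeature("c", "CDS", 1, 9, "+")


class TestExtensionTranslation:
    def test_translates_up_to_next_stop(self):
        genome, cds = _tag_cds("GCATTGTAACCC")
        assert extension_translation(genome, cds) == "AL"

    def test_immediate_stop_gives_empty(self):
        genome, cds = _tag_cds("TAACCC")
        assert extension_translation(genome, cds) == ""

    def test_non_tag_cds_rejected(self):
        genome = GenomeRecord("g", "ATGAAATAACCC")
        with pytest.raises(ValueError):
            extension_translation(genome, GeneFeature("c", "CDS", 1, 9, "+"))

    def test_minus_strand_extension(self):
        # coding: ATG AAA TAG | GGG TAA  -> plant on minus strand
        coding = "ATGAAATAGGGGTAA"
        from archaeoscan.genome_io import reverse_complement
        genome = GenomeRecord("g", reverse_complement(coding) + "A" * 6)
        # coding CDS (ATG AAA TAG) sits at genome 7..15 on the minus strand;
        # its in-frame 3' flank runs leftward through GGG then the TAA stop.
        cds = GeneFeature("c", "CDS", 7, 15, "-")
        assert extension_translation(genome, cds) == "G"

    def test_planted_extension_length(self, planted_genome):
        genome, features, truth = planted_genome
        (pl,) = truth_by_kind(truth)["pyl_locus"]
        cds = features.get(pl["cds_id"])
        ext = extension_translation(genome, cds)
        assert ext == pl["extension_aa"]
        assert len(ext) == len(pl["reference_protein"]) - pl["split_position"] - 1


def _refdb_for(truth) -> ReferenceProteinDB:
    by_kind = truth_by_kind(truth)
    entries = {}
    for pl in by_kind.get("pyl_locus", []):
        entries[pl["reference_id"]] = pl["reference_protein"]
    for cass in by_kind.get("pyl_cassette", []):
        entries.update(cass["proteins"])
    rng = np.random.default_rng(99)
    for i in range(4):  # decoys
        entries[f"decoy_{i}"] = random_protein(rng, 240)
    return ReferenceProteinDB(entries)


class TestDetectReadthrough:
    def test_no_tag_terminated_cds_gives_empty(self):
        genome = GenomeRecord("g", "ATGAAATAA" + "C" * 12)
        fs = FeatureSet("g", [GeneFeature("a", "CDS", 1, 9, "+")])
        refdb = ReferenceProteinDB({"r": "MKLVH"})
        assert detect_readthrough_candidates(genome, fs, refdb) == []

    def test_planted_locus_recovered_exactly(self, planted_genome):
        genome, features, truth = planted_genome
        (pl,) = truth_by_kind(truth)["pyl_locus"]
        cands = detect_readthrough_candidates(genome, features, _refdb_for(truth))
        assert [c.cds_id for c in cands] == [pl["cds_id"]]
        c = cands[0]
        assert c.amber_genome_position == pl["amber_genome_position"]
        assert c.fused_protein == pl["fused_protein"]
        assert len(c.fused_protein) == len(pl["reference_protein"])
        assert c.upstream_hit.subject_id == pl["reference_id"]
        assert c.extension_hit.subject_id == pl["reference_id"]

    @pytest.mark.parametrize("frac", [0.1, 0.5, 0.9])
    def test_recovery_across_split_positions(self, frac):
        """'O' lands at split+1 of the fusion for early/middle/late ambers."""
        ref_len = 300
        split = int(ref_len * frac)
        cfg = SynthConfig(
            seed=200 + int(frac * 10), genome_length=30_000,
            planted=[PlantSpec("pyl_locus", {"split_position": split,
                                             "reference_length": ref_len})],
        )
        genome, features, truth = generate_genome(cfg)
        (pl,) = truth_by_kind(truth)["pyl_locus"]
        cands = detect_readthrough_candidates(genome, features, _refdb_for(truth))
        assert len(cands) == 1
        fused = cands[0].fused_protein
        assert fused[split] == "O"  # 1-based position split+1
        assert fused.count("O") == 1
        assert len(fused) == len(cands[0].upstream_aa) + 1 + \
            len(cands[0].extension_aa)

    def test_zero_false_positives_on_negative_genomes(self):
        """Genomes rich in TAG-stopped genes but with no planted readthrough
        structure yield no candidates at default thresholds."""
        rng = np.random.default_rng(17)
        refdb = ReferenceProteinDB(
            {f"ref_{i}": random_protein(rng, 260) for i in range(6)}
        )
        total = 0
        for seed in range(20):
            cfg = SynthConfig(seed=300 + seed, genome_length=25_000,
                              mean_cds_length=600,
                              stop_usage=(0.40, 0.25, 0.35))
            genome, features, _ = generate_genome(cfg)
            total += len(detect_readthrough_candidates(genome, features, refdb))
        assert total == 0

    def test_fusion_length_invariant_for_all_candidates(self, planted_genome):
        genome, features, truth = planted_genome
        for c in detect_readthrough_candidates(genome, features, _refdb_for(truth)):
            assert len(c.fused_protein) == \
                len(c.upstream_aa) + 1 + len(c.extension_aa)
            assert c.fused_protein[len(c.upstream_aa)] == "O"


class TestPylCassette:
    def test_planted_cassette_all_present(self, planted_genome):
        genome, features, truth = planted_genome
        cassette = detect_pyl_cassette(genome, features, _refdb_for(truth))
        assert cassette.complete
        (cass,) = truth_by_kind(truth)["pyl_cassette"]
        for name, fid in cass["genes"].items():
            assert cassette.feature_ids[name] == fid

    def test_genome_without_cassette_all_absent(self):
        rng = np.random.default_rng(5)
        cfg = SynthConfig(seed=31, genome_length=20_000)
        genome, features, _ = generate_genome(cfg)
        refdb = ReferenceProteinDB(
            {f"pyl{x}_ref": random_protein(rng, 300) for x in "SBCD"}
        )
        cassette = detect_pyl_cassette(genome, features, refdb)
        assert not any(cassette.present.values())

    def test_pylt_only_cassette(self):
        cfg = SynthConfig(
            seed=32, genome_length=20_000,
            planted=[PlantSpec("pyl_cassette", {"include": ["pylT"]})],
        )
        genome, features, truth = generate_genome(cfg)
        rng = np.random.default_rng(6)
        refdb = ReferenceProteinDB(
            {f"pyl{x}_ref": random_protein(rng, 300) for x in "SBCD"}
        )
        cassette = detect_pyl_cassette(genome, features, refdb)
        assert cassette.present["pylT"]
        assert not any(cassette.present[k] for k in ("pylS", "pylB", "pylC", "pylD"))
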