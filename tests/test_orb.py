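"""ORB motif scanning vs a brute-force Hamming oracle, pairing, consensus
derivation and origin calling."""

import pytest

from archaeoscan.genome_io import GenomeRecord, FeatureSet, GeneFeature, \
    reverse_complement
from archaeoscan.orb import (
    IUPAC,
    OrbHit,
    OrbMotif,
    call_origin,
    derive_consensus,
    pair_hits,
    scan_motif,
)
from archaeoscan.synthetic import (
    DEFAULT_ORB_CORE,
    PlantSpec,
    SynthConfig,
    generate_genome,
    random_dna,
)

from conftest import truth_by_kind

import numpy as np

# The ten co-aligned 22-base ORB motifs of the three gut-methanogen genomes
# (hyphen-free, in reported orientation).
REPORTED_ORB_MOTIFS = [
    "GTTCCAGTGGAAATGGTGGGGT",
    "GTTCCACTGGAAACAGAGGGGT",
    "TTTCCACTGGAAACAGAGGGGT",
    "GTTCCACTGGAAATGGTGGGGT",
    "ATTACAGTGGAAATGAAGGGGT",
    "TTTGCAGTGGAAATGAAGGGGT",
    "GTTCCAGTGGAAATGAAGGGGT",
    "TCTGCACTGGAAATGAAGGGGT",
    "GTTCCATTGGAAATCGGCAGGA",
    "GTTCCAGTGGAAATAAAGGGGT",
]


def brute_force_scan(genome: GenomeRecord, motif: OrbMotif) -> set:
    """Position-by-position IUPAC Hamming scan, both strands, wrap included."""
    c = len(motif.core)
    seq = genome.sequence
    if genome.topology == "circular":
        seq = seq + seq[: c - 1]
    found = set()
    for strand in ("+", "-"):
        core = motif.core if strand == "+" else None
        for i in range(min(len(seq) - c + 1, len(genome))):
            window = seq[i : i + c]
            probe = window if strand == "+" else reverse_complement(window)
            mism = sum(
                b not in IUPAC[m] for b, m in zip(probe, motif.core)
            )
            if mism <= motif.max_mismatch:
                found.add((i + 1, strand, mism))
    return found


class TestScanMotif:
    def test_exact_core_single_plus_hit(self):
        core = DEFAULT_ORB_CORE
        genome = GenomeRecord("g", core)
        hits = scan_motif(genome, OrbMotif(core=core, max_mismatch=0))
        assert [(h.start, h.end, h.strand, h.mismatches)
                for h in hits] == [(1, 22, "+", 0)]

    def test_reverse_complement_core_minus_hit(self):
        core = DEFAULT_ORB_CORE
        genome = GenomeRecord("g", reverse_complement(core))
        hits = scan_motif(genome, OrbMotif(core=core, max_mismatch=0))
        assert [(h.start, h.strand) for h in hits] == [(1, "-")]
        assert hits[0].matched_sequence == core

    def test_agrees_with_brute_force_oracle(self, rng):
        motif = OrbMotif(max_mismatch=4)
        for trial in range(6):
            seq = random_dna(rng, 20_000, 0.5)
            # salt with near-copies so matches exist
            for _ in range(5):
                pos = int(rng.integers(0, len(seq) - 22))
                copy = list(DEFAULT_ORB_CORE)
                for k in rng.choice(22, size=int(rng.integers(0, 6)), replace=False):
                    copy[k] = "ACGT"[int(rng.integers(4))]
                seq = seq[:pos] + "".join(copy) + seq[pos + 22 :]
            topo = "circular" if trial % 2 == 0 else "linear"
            genome = GenomeRecord("g", seq, topology=topo)
            got = {(h.start, h.strand, h.mismatches)
                   for h in scan_motif(genome, motif)}
            assert got == brute_force_scan(genome, motif)

    def test_strand_symmetry(self, rng):
        seq = random_dna(rng, 5_000, 0.5)
        pos = 1000
        seq = seq[:pos] + DEFAULT_ORB_CORE + seq[pos + 22 :]
        genome = GenomeRecord("g", seq)
        rc = GenomeRecord("g", reverse_complement(seq))
        motif = OrbMotif(max_mismatch=3)
        L = len(seq)
        mirrored = {
            (L - h.end + 1, "-" if h.strand == "+" else "+", h.mismatches)
            for h in scan_motif(genome, motif)
        }
        got = {(h.start, h.strand, h.mismatches) for h in scan_motif(rc, motif)}
        assert got == mirrored

    def test_hit_sets_monotone_in_mismatch_budget(self, rng):
        seq = random_dna(rng, 10_000, 0.5)
        genome = GenomeRecord("g", seq)
        prev: set = set()
        for k in range(0, 7):
            cur = {(h.start, h.strand)
                   for h in scan_motif(genome, OrbMotif(max_mismatch=k))}
            assert prev <= cur
            prev = cur


class TestPairHits:
    def test_reported_pair_geometry(self):
        """Hits at 78..99 (+) and 138..159 (-) pair at spacing 39, inverted."""
        h1 = OrbHit(78, 99, "+", 0, DEFAULT_ORB_CORE)
        h2 = OrbHit(138, 159, "-", 0, DEFAULT_ORB_CORE)
        (pair,) = pair_hits([h1, h2], max_pair_spacing=300)
        assert pair.spacing == 39
        assert pair.orientation == "inverted"

    def test_single_hit_no_pairs(self):
        assert pair_hits([OrbHit(10, 31, "+", 0, "x")]) == []

    def test_three_clustered_hits_enumerate_all_pairs(self):
        hits = [OrbHit(s, s + 21, "+", 0, "x") for s in (100, 200, 300)]
        pairs = pair_hits(hits, max_pair_spacing=300)
        got = {(p.hit1.start, p.hit2.start) for p in pairs}
        # exhaustive oracle: ordered pairs within spacing
        oracle = {
            (a.start, b.start)
            for i, a in enumerate(hits) for b in hits[i + 1 :]
            if 0 <= b.start - a.end <= 300
        }
        assert got == oracle == {(100, 200), (200, 300), (100, 300)}


class TestConsensus:
    def test_majority(self):
        assert derive_consensus(["ACGT", "ACGA", "ACGT"]) == "ACGT"

    def test_tie_emits_iupac(self):
        assert derive_consensus(["A", "C"]) == "M"
        assert derive_consensus(["AG", "CG", "TG", "GG"]) == "NG"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            derive_consensus(["AC", "ACG"])

    def test_reported_motif_consensus_matches_hand_tally(self):
        """Column majority over the ten reported 22-base motifs equals an
        independent per-column count."""
        from collections import Counter

        expected = []
        for col in zip(*REPORTED_ORB_MOTIFS):
            counts = Counter(col)
            top = max(counts.values())
            winners = sorted(b for b, n in counts.items() if n == top)
            if len(winners) == 1:
                expected.append(winners[0])
            else:
                code = {frozenset(v): k for k, v in IUPAC.items()}
                expected.append(code[frozenset(winners)])
        assert derive_consensus(REPORTED_ORB_MOTIFS) == "".join(expected)


class TestCallOrigin:
    def _features(self, genes):
        return FeatureSet("g", [
            GeneFeature(gid, "CDS", s, e, strand, "orc1/cdc6 replication initiator")
            for gid, s, e, strand in genes
        ])

    def _pair_at(self, start):
        h1 = OrbHit(start, start + 21, "+", 0, "x")
        h2 = OrbHit(start + 60, start + 81, "-", 0, "x")
        return pair_hits([h1, h2])[0]

    def test_pair_beyond_window_excluded(self):
        pair = self._pair_at(1000)
        feats = self._features([("cdc6_a", 60_000, 61_200, "+")])
        assert call_origin([pair], feats, origin_window=10_000) == []

    def test_two_genes_candidate_names_nearest(self):
        pair = self._pair_at(10_000)
        feats = self._features([
            ("cdc6_far", 300_000, 301_200, "+"),
            ("cdc6_near", 13_000, 14_200, "+"),
        ])
        (cand,) = call_origin([pair], feats, origin_window=10_000)
        assert cand.gene_id == "cdc6_near"
        assert cand.side == "upstream"
        assert cand.distance == pytest.approx(13_000 - (10_000 + 10_000 + 81) / 2, abs=1)

    def test_no_initiator_genes_warns_empty(self):
        pair = self._pair_at(100)
        feats = FeatureSet("g", [GeneFeature("x", "CDS", 500, 700, "+", "other")])
        with pytest.warns(UserWarning):
            assert call_origin([pair], feats) == []


class TestPlantedRecovery:
    def test_planted_pairs_found_exactly_over_seeds(self):
        """Planted ORB pairs are the only 0-mismatch hits, at truth
        coordinates, and the origin call names the planted initiator gene."""
        for seed in range(20):
            cfg = SynthConfig(
                seed=400 + seed, genome_length=25_000, mean_cds_length=600,
                planted=[PlantSpec("orb_pair", {"gene_distance": 2000})],
            )
            genome, features, truth = generate_genome(cfg)
            (ob,) = truth_by_kind(truth)["orb_pair"]
            hits = scan_motif(genome, OrbMotif(core=ob["core"], max_mismatch=0))
            got = [(h.start, h.end, h.strand) for h in hits]
            want = [(h["start"], h["end"], h["strand"]) for h in ob["hits"]]
            assert got == want
            (pair,) = pair_hits(hits)
            assert pair.spacing == ob["spacing"]
            assert pair.orientation == ob["orientation"]
            (cand,) = call_origin([pair], features, origin_window=10_000)
            assert cand.gene_id == ob["gene_id"]
            assert cand.distance <= 3_000
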