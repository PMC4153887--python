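"""Coding density, intergenic gaps (vs a mask-based oracle), codon usage and
rRNA organization."""

import numpy as np
import pytest

from archaeoscan.genome_io import FeatureSet, GeneFeature, GenomeRecord, \
    reverse_complement
from archaeoscan.stats import (
    codon_usage,
    coding_density,
    intergenic_gaps,
    intergenic_stats,
    rrna_organization,
    stop_codon_usage,
    summarize,
)
from archaeoscan.synthetic import SynthConfig, PlantSpec, generate_genome

from conftest import truth_by_kind


def _fs(genome_id, intervals, kind="CDS", strand="+"):
    return FeatureSet(genome_id, [
        GeneFeature(f"f{i}", kind, s, e, strand) for i, (s, e) in enumerate(intervals)
    ])


class TestCodingDensity:
    def test_full_coverage(self):
        g = GenomeRecord("g", "A" * 90)
        assert coding_density(g, _fs("g", [(1, 90)])) == 1.0

    def test_overlaps_counted_once(self):
        g = GenomeRecord("g", "A" * 1000)
        assert coding_density(g, _fs("g", [(1, 100), (51, 150)])) == pytest.approx(0.150)

    def test_synthetic_density_within_tolerance_of_target(self):
        cfg = SynthConfig(seed=9, genome_length=120_000, target_coding_density=0.89)
        genome, features, _ = generate_genome(cfg)
        assert abs(coding_density(genome, features) - 0.89) <= 0.02


class TestIntergenicGaps:
    def test_single_gap(self):
        g = GenomeRecord("g", "A" * 300)
        mean, sd = intergenic_stats(g, _fs("g", [(1, 100), (201, 300)]))
        assert (mean, sd) == (100.0, 0.0)

    def test_abutting_genes_contribute_zero(self):
        g = GenomeRecord("g", "A" * 200)
        mean, _ = intergenic_stats(g, _fs("g", [(1, 100), (101, 200)]))
        assert mean == 0.0

    def test_wrap_gap_counted_on_circular(self):
        g = GenomeRecord("g", "A" * 100, topology="circular")
        gaps = intergenic_gaps(g, _fs("g", [(11, 40), (61, 90)]))
        assert sorted(gaps) == [20, 20]  # internal 41..60 and wrap 91..100+1..10

    def test_fewer_than_two_features_signalled(self):
        g = GenomeRecord("g", "A" * 100)
        with pytest.raises(ValueError):
            intergenic_stats(g, _fs("g", [(1, 50)]))

    def test_matches_mask_oracle_on_random_fixtures(self, rng):
        """Gap multiset == uncovered runs between covered blocks, padded with
        zeros for abutting/contained feature pairs (plus the wrap run)."""
        for trial in range(50):
            L = int(rng.integers(200, 2000))
            n = int(rng.integers(2, 25))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(1, L - 10))
                e = min(int(s + rng.integers(5, 120)), L)
                ivs.append((s, e))
            topo = "circular" if trial % 2 == 0 else "linear"
            g = GenomeRecord("g", "A" * L, topology=topo)
            fs = _fs("g", ivs)
            gaps = intergenic_gaps(g, fs)
            # oracle: boolean mask -> maximal uncovered runs
            mask = np.zeros(L, dtype=bool)
            for s, e in ivs:
                mask[s - 1 : e] = True
            segs = sorted(ivs)
            first, last = segs[0][0], max(e for _, e in segs)
            if topo == "circular":
                rolled = np.roll(mask, -(first - 1))
                covered_span = rolled
                runs = _run_lengths(~covered_span)
            else:
                runs = _run_lengths(~mask[first - 1 : last])
            n_pairs = n - 1 + (1 if topo == "circular" else 0)
            oracle = sorted(runs + [0] * (n_pairs - len(runs)))
            assert sorted(gaps) == oracle


def _run_lengths(mask: np.ndarray) -> list:
    runs, count = [], 0
    for v in mask:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def test_conservation_identity_on_circular_genome(planted_genome):
    genome, features, _ = planted_genome
    density = coding_density(genome, features)
    gaps = intergenic_gaps(genome, features)
    assert density == pytest.approx(1 - sum(gaps) / len(genome))


class TestStopUsage:
    def test_simple_fractions(self):
        seq = "".join(["ATGAAATAA"] * 9 + ["ATGAAATAG"])
        g = GenomeRecord("g", seq)
        fs = _fs("g", [(i * 9 + 1, i * 9 + 9) for i in range(10)])
        su = stop_codon_usage(g, fs)
        assert su.fraction_TAG == pytest.approx(0.10)
        assert su.fraction_TAA == pytest.approx(0.90)
        assert su.n_cds == 10

    def test_fractions_sum_to_one(self, planted_genome):
        genome, features, _ = planted_genome
        su = stop_codon_usage(genome, features)
        assert su.fraction_TAA + su.fraction_TAG + su.fraction_TGA == \
            pytest.approx(1.0)

    def test_rare_amber_recovered_at_binomial_tolerance(self):
        cfg = SynthConfig(seed=12, genome_length=400_000, mean_cds_length=450,
                          stop_usage=(0.45, 0.016, 0.534))
        genome, features, _ = generate_genome(cfg)
        su = stop_codon_usage(genome, features)
        assert su.n_cds >= 500
        assert abs(su.fraction_TAG - 0.016) <= 0.01


class TestCodonUsage:
    def test_single_cds_counts(self):
        g = GenomeRecord("g", "ATGAAATAA")
        cu = codon_usage(g, _fs("g", [(1, 9)]))
        assert cu.counts == {"ATG": 1, "AAA": 1}
        assert cu.stop_counts["TAA"] == 1
        assert cu.start_counts["ATG"] == 1

    def test_codon_count_conservation(self, planted_genome):
        genome, features, _ = planted_genome
        cu = codon_usage(genome, features)
        total = sum(cu.counts.values()) + sum(cu.stop_counts.values())
        cds_bp = sum(
            f.length for f in features.of_kind("CDS") if f.length % 3 == 0
        )
        assert total == cds_bp // 3
        assert sum(cu.start_counts.values()) == cu.n_cds

    def test_per_aa_frequencies_sum_to_one(self, planted_genome):
        genome, features, _ = planted_genome
        rel = codon_usage(genome, features).relative_by_amino_acid()
        for aa, freqs in rel.items():
            assert sum(freqs.values()) == pytest.approx(1.0)

    def test_gc3_monotone_in_genome_gc(self):
        lo, flo, _ = generate_genome(
            SynthConfig(seed=13, genome_length=60_000, gc_fraction=0.41))
        hi, fhi, _ = generate_genome(
            SynthConfig(seed=13, genome_length=60_000, gc_fraction=0.61))
        assert codon_usage(lo, flo).gc3() < codon_usage(hi, fhi).gc3()


class TestRrnaOrganization:
    def _set(self, entries):
        return FeatureSet("g", [
            GeneFeature(f"r{i}", kind, s, e, strand)
            for i, (kind, s, e, strand) in enumerate(entries)
        ])

    def test_operonic_within_gap(self):
        fs = self._set([("rRNA-16S", 1000, 2500, "+"), ("rRNA-23S", 2600, 5500, "+")])
        rep = rrna_organization(fs, max_operon_gap=500)
        assert rep.classification == "operonic"
        assert rep.pairs[0]["gap"] == 99

    def test_distant_genes_scattered(self):
        fs = self._set([("rRNA-16S", 1000, 2500, "+"),
                        ("rRNA-23S", 402_600, 405_500, "+")])
        assert rrna_organization(fs).classification == "scattered"

    def test_missing_kind_warns_undetermined(self):
        fs = self._set([("rRNA-16S", 1000, 2500, "+")])
        with pytest.warns(UserWarning):
            rep = rrna_organization(fs)
        assert rep.classification == "undetermined"

    @pytest.mark.parametrize("arrangement", ["operonic", "scattered"])
    def test_planted_arrangement_recovered(self, arrangement):
        for seed in range(20):
            cfg = SynthConfig(
                seed=100 + seed, genome_length=40_000, mean_cds_length=600,
                planted=[PlantSpec("rrna_set", {"arrangement": arrangement})],
            )
            _, features, _ = generate_genome(cfg)
            assert rrna_organization(features).classification == arrangement


def test_statistics_invariant_under_reverse_complement(planted_genome):
    genome, features, _ = planted_genome
    L = len(genome)
    rc = GenomeRecord(genome.id, reverse_complement(genome.sequence),
                      topology=genome.topology)
    flipped = FeatureSet(genome.id, [
        GeneFeature(
            f.id, f.kind, L - f.end + 1, L - f.start + 1,
            "-" if f.strand == "+" else "+", f.product,
            tuple(sorted((L - e + 1, L - s + 1) for s, e in f.segments)),
        )
        for f in features
    ])
    assert coding_density(rc, flipped) == pytest.approx(
        coding_density(genome, features))
    m1, s1 = intergenic_stats(genome, features)
    m2, s2 = intergenic_stats(rc, flipped)
    assert (m2, s2) == (pytest.approx(m1), pytest.approx(s1))
    a = stop_codon_usage(genome, features)
    b = stop_codon_usage(rc, flipped)
    assert (a.fraction_TAA, a.fraction_TAG, a.fraction_TGA) == \
        (b.fraction_TAA, b.fraction_TAG, b.fraction_TGA)


def test_summary_report_fields(planted_genome):
    genome, features, _ = planted_genome
    s = summarize(genome, features)
    assert s.genome_size == len(genome)
    assert 0 <= s.coding_fraction <= 1
    assert s.gene_counts["CDS"] > 0
    assert s.cds_mean_length > 0
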